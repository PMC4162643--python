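"""Factorial statistics on directed-pair coherence tables.

The observational unit is one directed pair's band-averaged coherence (90
ordered pairs per 10-subject group per condition).  Two factorial designs are
fitted per signal:

* Condition (5 protocol phases) x Group (collective vs. individual), and
* Condition x Day (first vs. second session, collective groups only).

The three band coherences (LF, HF, VHF) are treated as dependent variables:
multivariate tests (Wilks' lambda, Pillai's trace) are reported alongside
per-band univariate F statistics (type-III sums of squares, sum-to-zero
contrasts), followed by Bonferroni-adjusted pairwise post-hoc contrasts on
the condition levels using the omnibus residual error term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

BAND_COLUMNS = ("LF", "HF", "VHF")
KEY_COLUMNS = (
    "signal", "source", "target", "condition", "group_setting",
    "experiment_index", "day", "condition_order",
)


def records_to_table(records) -> pd.DataFrame:
    """Pivot long-format pair records into one row per pair with band columns."""
    rows = [vars(r) if not isinstance(r, dict) else r for r in records]
    long = pd.DataFrame(rows)
    keys = [k for k in KEY_COLUMNS if k in long.columns]
    wide = long.pivot_table(
        index=keys, columns="band", values="coherence", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide


@dataclass
class EffectTable:
    """Fitted factorial model summaries for one signal."""

    signal: str
    factors: tuple[str, str]
    univariate: pd.DataFrame  # band, effect, F, df_num, df_den, p
    multivariate: pd.DataFrame | None = None  # effect, statistic, value, F, ...
    posthoc: dict = field(default_factory=dict)  # band -> adjusted-p DataFrame

    def univariate_f(self, band: str, effect: str) -> float:
        sel = self.univariate[
            (self.univariate.band == band) & (self.univariate.effect == effect)
        ]
        if sel.empty:
            raise KeyError(f"no effect {effect!r} for band {band!r}")
        return float(sel.F.iloc[0])


def _check_cells(df: pd.DataFrame, f1: str, f2: str) -> None:
    counts = df.groupby([f1, f2], observed=True).size()
    levels1, levels2 = df[f1].unique(), df[f2].unique()
    empty = [
        (a, b)
        for a in levels1
        for b in levels2
        if (a, b) not in counts.index
    ]
    if empty:
        raise ValueError(f"empty design cells: {empty}")


def _anova_two_way(y: np.ndarray, df: pd.DataFrame, f1: str, f2: str,
                   ss_type: int = 3) -> pd.DataFrame:
    """Univariate two-way ANOVA with interaction via statsmodels OLS."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    data = df[[f1, f2]].copy()
    data["y"] = y
    formula = f"y ~ C({f1}, Sum) * C({f2}, Sum)"
    fit = ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=ss_type)
    label = {
        f"C({f1}, Sum)": f1,
        f"C({f2}, Sum)": f2,
        f"C({f1}, Sum):C({f2}, Sum)": f"{f1}:{f2}",
    }
    out = []
    resid_ss = float(table.loc["Residual", "sum_sq"])
    df_den = float(table.loc["Residual", "df"])
    zero_resid = resid_ss <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2 * len(y))
    for row, eff in label.items():
        if row not in table.index:
            continue
        F = float(table.loc[row, "F"])
        p = float(table.loc[row, "PR(>F)"])
        if zero_resid:
            F, p = np.inf, 0.0
        out.append(
            dict(effect=eff, F=F, df_num=float(table.loc[row, "df"]),
                 df_den=df_den, p=p)
        )
    return pd.DataFrame(out)


def _manova(df: pd.DataFrame, bands, f1: str, f2: str) -> pd.DataFrame:
    from statsmodels.multivariate.manova import MANOVA

    lhs = " + ".join(bands)
    formula = f"{lhs} ~ C({f1}, Sum) * C({f2}, Sum)"
    mv = MANOVA.from_formula(formula, data=df)
    res = mv.mv_test()
    label = {
        f"C({f1}, Sum)": f1,
        f"C({f2}, Sum)": f2,
        f"C({f1}, Sum):C({f2}, Sum)": f"{f1}:{f2}",
    }
    rows = []
    for key, eff in label.items():
        if key not in res.results:
            continue
        stat = res.results[key]["stat"]
        for name in ("Wilks' lambda", "Pillai's trace"):
            rows.append(
                dict(
                    effect=eff,
                    statistic=name,
                    value=float(stat.loc[name, "Value"]),
                    F=float(stat.loc[name, "F Value"]),
                    df_num=float(stat.loc[name, "Num DF"]),
                    df_den=float(stat.loc[name, "Den DF"]),
                    p=float(stat.loc[name, "Pr > F"]),
                )
            )
    return pd.DataFrame(rows)


def one_way_f(table: pd.DataFrame, factor: str, value_col: str) -> tuple[float, float, float, float]:
    """One-way ANOVA F on a single factor: (F, df_num, df_den, p).

    With two levels this reduces algebraically to the squared pooled
    two-sample t statistic.
    """
    groups = [g[value_col].to_numpy() for _l, g in table.groupby(factor, observed=True)]
    if len(groups) < 2:
        raise ValueError("factor needs >= 2 levels")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_num = len(groups) - 1
    df_den = len(all_vals) - len(groups)
    F = (ss_between / df_num) / (ss_within / df_den)
    p = float(spstats.f.sf(F, df_num, df_den))
    return float(F), float(df_num), float(df_den), p


def bonferroni_posthoc(
    table: pd.DataFrame,
    factor: str,
    value_col: str,
    alpha: float = 0.05,
    mse: float | None = None,
    df_resid: float | None = None,
) -> pd.DataFrame:
    """All pairwise level contrasts, Bonferroni-adjusted.

    Pairwise t statistics use the pooled (omnibus) residual mean square when
    supplied, otherwise the within-level pooled variance; raw p-values are
    multiplied by the number of comparisons and capped at 1.
    """
    levels = sorted(table[factor].unique())
    if len(levels) < 2:
        raise ValueError("post-hoc needs a factor with >= 2 levels")
    groups = {lev: table.loc[table[factor] == lev, value_col].to_numpy()
              for lev in levels}
    if mse is None:
        ss = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        df_resid = sum(len(g) - 1 for g in groups.values())
        mse = ss / df_resid
    m = len(levels) * (len(levels) - 1) // 2
    out = pd.DataFrame(np.nan, index=levels, columns=levels, dtype=float)
    for a, b in itertools.combinations(levels, 2):
        ga, gb = groups[a], groups[b]
        se = np.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
        t = (ga.mean() - gb.mean()) / se
        p_raw = 2 * spstats.t.sf(abs(t), df_resid)
        p_adj = min(1.0, m * p_raw)
        out.loc[a, b] = out.loc[b, a] = p_adj
    return out


def _fit_factorial(
    table: pd.DataFrame,
    signal: str,
    factor: str,
    bands=BAND_COLUMNS,
    multivariate: bool = True,
    posthoc: bool = True,
    ss_type: int = 3,
) -> EffectTable:
    df = table[table.signal == signal].copy() if "signal" in table.columns else table.copy()
    if df.empty:
        raise ValueError(f"no rows for signal {signal!r}")
    missing = [b for b in bands if b not in df.columns]
    if missing:
        raise ValueError(f"missing band columns: {missing}")
    if df["condition"].nunique() < 2:
        raise ValueError("need at least 2 conditions")
    if df[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    _check_cells(df, "condition", factor)
    uni = []
    for band in bands:
        t = _anova_two_way(df[band].to_numpy(), df, "condition", factor, ss_type)
        t.insert(0, "band", band)
        uni.append(t)
    uni = pd.concat(uni, ignore_index=True)
    mv = _manova(df, bands, "condition", factor) if multivariate else None
    ph = {}
    if posthoc:
        for band in bands:
            sel = uni[(uni.band == band) & (uni.effect == "condition")]
            df_den = float(sel.df_den.iloc[0])
            # recover the omnibus MSE from the fitted model's residuals
            ph[band] = bonferroni_posthoc(
                df, "condition", band,
                mse=_omnibus_mse(df, band, "condition", factor),
                df_resid=df_den,
            )
    return EffectTable(signal=signal, factors=("condition", factor),
                       univariate=uni, multivariate=mv, posthoc=ph)


def _omnibus_mse(df: pd.DataFrame, band: str, f1: str, f2: str) -> float:
    """Residual mean square of the full two-way model (cell means)."""
    resid_ss = 0.0
    n = 0
    cells = 0
    for _key, g in df.groupby([f1, f2], observed=True):
        v = g[band].to_numpy()
        resid_ss += ((v - v.mean()) ** 2).sum()
        n += len(v)
        cells += 1
    return resid_ss / max(n - cells, 1)


def fit_condition_group_model(
    table: pd.DataFrame, signal: str, **kwargs
) -> EffectTable:
    """Condition x Group factorial model on one signal's coherence table."""
    return _fit_factorial(table, signal, "group_setting", **kwargs)


def fit_condition_day_model(
    table: pd.DataFrame, signal: str, **kwargs
) -> EffectTable:
    """Condition x Day factorial model (collective sessions)."""
    df = table
    if "group_setting" in df.columns:
        df = df[df.group_setting == "collective"]
        if df.empty:
            raise ValueError("no collective rows in table")
    if "day" not in df.columns:
        raise ValueError("day column missing")
    if df["day"].nunique() < 2:
        raise ValueError("both days must be present")
    return _fit_factorial(df, signal, "day", **kwargs)


#: univariate F statistics reported for the original recordings (accelerometer
#: signal), used by the replication report for side-by-side comparison
REFERENCE_EFFECTS = pd.DataFrame(
    [
        ("accel", "HF", "condition", 1, 44.24),
        ("accel", "HF", "condition:group_setting", 1, 3.40),
        ("accel", "HF", "condition:group_setting", 2, 2.56),
        ("accel", "VHF", "condition:group_setting", 1, 4.28),
        ("accel", "VHF", "group_setting", 2, 10.55),
        ("accel", "VHF", "condition:day", None, 3.39),
        ("resp_abd", "VHF", "day", None, 4.32),
        ("resp_abd", "VHF", "group_setting", 2, 5.20),
        ("resp_thor", "VHF", "group_setting", 1, 4.41),
        ("resp_thor", "VHF", "group_setting", 2, 7.94),
    ],
    columns=["signal", "band", "effect", "day", "F_reference"],
)


def replicate_database_s1_stats(
    source,
    signals=None,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Re-run the factorial models on a coherence table in the S1 schema.

    The exact case-inclusion rules behind the original error degrees of
    freedom are ambiguous, so every plausible variant is fitted — the
    Condition x Group model restricted to each day and pooled over days
    (with and without the final baseline), plus the Condition x Day model on
    collective rows — and all computed F values are reported, flagged with
    the closest match where a reference value exists.
    """
    from .io import read_database_s1

    table = read_database_s1(source) if not isinstance(source, pd.DataFrame) else source
    if signals is None:
        signals = sorted(table.signal.unique())
    if reference is None:
        reference = REFERENCE_EFFECTS
    rows = []
    for signal in signals:
        sub = table[table.signal == signal]
        variants: list[tuple[str, pd.DataFrame, str]] = []
        for day in sorted(sub.day.unique()):
            variants.append((f"group_day{day}", sub[sub.day == day], "group_setting"))
            nofinal = sub[(sub.day == day) & (sub.condition != "baseline2")]
            if nofinal.condition.nunique() >= 2:
                variants.append(
                    (f"group_day{day}_nofinal", nofinal, "group_setting")
                )
        if sub.day.nunique() > 1:
            variants.append(("group_pooled", sub, "group_setting"))
            coll = sub[sub.group_setting == "collective"]
            if coll.day.nunique() > 1:
                variants.append(("day_collective", coll, "day"))
        for name, data, factor in variants:
            if data.empty or data[factor].nunique() < 2:
                continue
            try:
                eff = _fit_factorial(
                    data, signal, factor, multivariate=False, posthoc=False
                )
            except ValueError:
                continue
            for _, r in eff.univariate.iterrows():
                rows.append(
                    dict(signal=signal, variant=name, band=r.band,
                         effect=r.effect.replace("condition:" + factor,
                                                 f"condition:{factor}"),
                         F=r.F, df_num=r.df_num, df_den=r.df_den, p=r.p)
                )
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    ref = reference.rename(columns={"effect": "effect", "band": "band"})
    report = report.merge(
        ref[["signal", "band", "effect", "F_reference"]].drop_duplicates(
            ["signal", "band", "effect"]
        ),
        on=["signal", "band", "effect"],
        how="left",
    )
    report["abs_diff"] = (report.F - report.F_reference).abs()
    report["closest_variant"] = False
    for key, grp in report.dropna(subset=["F_reference"]).groupby(
        ["signal", "band", "effect"]
    ):
        report.loc[grp.abs_diff.idxmin(), "closest_variant"] = True
    return report
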