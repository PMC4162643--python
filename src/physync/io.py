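"""File formats, pipeline configuration, and the end-to-end runner.

CSV is the canonical interchange: one file per subject-condition recording
(``time_s, ecg, resp_abd, resp_thor, accel``) with a JSON sidecar holding the
session config and generator ground truth, and a long-format coherence table
whose integer codings mirror the published supplementary database schema
(Condition 1 = initial baseline, 2 = final baseline, 3 = spontaneous,
4 = metronome, 5 = music; Group 0 = individual, 1 = collective;
Experiment 1-3; Day 1-2; Order 1-5).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gpdc import DEFAULT_BANDS, PairCoherenceRecord
from .synthetic import Recording

CONDITION_CODES = {
    "baseline1": 1,
    "baseline2": 2,
    "spontaneous": 3,
    "metronome": 4,
    "music": 5,
}
CONDITION_LABELS = {v: k for k, v in CONDITION_CODES.items()}
GROUP_CODES = {"individual": 0, "collective": 1}
GROUP_LABELS = {v: k for k, v in GROUP_CODES.items()}

RECORDING_COLUMNS = ("time_s", "ecg", "resp_abd", "resp_thor", "accel")


# --- recordings -------------------------------------------------------------

def write_recording_csv(rec: Recording, path, sidecar: dict | None = None) -> Path:
    """Write one recording as CSV plus a JSON sidecar with its metadata."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for name in RECORDING_COLUMNS[1:]:
        df[name] = rec.channels[name]
    df.to_csv(path, index=False, float_format="%.6g")
    meta = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "condition": rec.condition,
        "day": rec.day,
        "group_setting": rec.group_setting,
        "experiment_index": rec.experiment_index,
        "condition_order": rec.condition_order,
    }
    if rec.ground_truth is not None:
        meta["ground_truth"] = {
            "r_peak_times": np.asarray(rec.ground_truth["r_peak_times"]).tolist(),
            "rr_intervals": np.asarray(rec.ground_truth["rr_intervals"]).tolist(),
        }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_recording_csv(path) -> Recording:
    """Read a recording CSV (and its JSON sidecar, when present)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recording file lacks columns: {missing}")
    if df[list(RECORDING_COLUMNS)].isna().any().any():
        raise ValueError("recording contains non-numeric or missing cells")
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    t = df["time_s"].to_numpy()
    fs = float(meta.get("fs", 1.0 / np.median(np.diff(t))))
    truth = None
    if "ground_truth" in meta:
        truth = {
            "r_peak_times": np.asarray(meta["ground_truth"]["r_peak_times"]),
            "rr_intervals": np.asarray(meta["ground_truth"]["rr_intervals"]),
        }
    return Recording(
        subject_id=meta.get("subject_id", path.stem),
        channels={c: df[c].to_numpy(dtype=float) for c in RECORDING_COLUMNS[1:]},
        fs=fs,
        condition=meta.get("condition", ""),
        day=int(meta.get("day", 1)),
        group_setting=meta.get("group_setting", "collective"),
        experiment_index=int(meta.get("experiment_index", 1)),
        condition_order=int(meta.get("condition_order", 1)),
        ground_truth=truth,
    )


# --- coherence tables -------------------------------------------------------

def write_coherence_csv(records, path, config_hash: str | None = None) -> Path:
    """Long-format coherence CSV with the documented integer codings."""
    path = Path(path)
    rows = []
    for r in records:
        d = vars(r) if isinstance(r, PairCoherenceRecord) else dict(r)
        rows.append(
            {
                "Signal": d["signal"],
                "Source": d["source"],
                "Target": d["target"],
                "Band": d["band"],
                "Condition": CONDITION_CODES[d["condition"]],
                "Group": GROUP_CODES[d["group_setting"]],
                "Experiment": d["experiment_index"],
                "Day": d["day"],
                "Order": d["condition_order"],
                "Coherence": d["coherence"],
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return path


def _validate_codes(df: pd.DataFrame) -> None:
    checks = {
        "Condition": set(CONDITION_LABELS),
        "Group": set(GROUP_LABELS),
        "Experiment": {1, 2, 3},
        "Day": {1, 2},
        "Order": {1, 2, 3, 4, 5},
    }
    for col, allowed in checks.items():
        if col in df.columns:
            bad = set(df[col].unique()) - allowed
            if bad:
                raise ValueError(f"{col} codes out of range: {sorted(bad)}")


def read_database_s1(source) -> pd.DataFrame:
    """Read a coherence table in the supplementary-database schema.

    Accepts CSV or XLSX, in long form (``Band``/``Coherence`` columns) or
    wide form (``LF``/``HF``/``VHF`` columns); integer codes are mapped to
    labels exactly as documented.  Returns the wide analysis table used by
    :mod:`physync.group_stats`.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        source = Path(source)
        if source.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
            df = pd.read_excel(source)
        else:
            df = pd.read_csv(source, comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    required = {"Condition", "Group", "Day"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"schema mismatch, missing columns: {missing}")
    for col in ("Condition", "Group", "Experiment", "Day", "Order"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValueError(f"non-numeric cells in column {col}")
            df[col] = vals.astype(int)
    _validate_codes(df)

    bands_wide = [b for b in ("LF", "HF", "VHF") if b in df.columns]
    if not bands_wide:
        if not {"Band", "Coherence"} <= set(df.columns):
            raise ValueError("schema mismatch: need LF/HF/VHF or Band+Coherence")
        idx = [c for c in df.columns if c not in ("Band", "Coherence")]
        df = df.pivot_table(index=idx, columns="Band", values="Coherence",
                            aggfunc="first").reset_index()
        df.columns.name = None

    out = df.rename(
        columns={
            "Signal": "signal", "Source": "source", "Target": "target",
            "Experiment": "experiment_index", "Day": "day", "Order": "condition_order",
        }
    )
    out["condition"] = out.pop("Condition").map(CONDITION_LABELS)
    out["group_setting"] = out.pop("Group").map(GROUP_LABELS)
    if "signal" not in out.columns:
        out["signal"] = "accel"
    for col in ("LF", "HF", "VHF"):
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            if vals.isna().any():
                raise ValueError(f"non-numeric coherence values in {col}")
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"coherence values outside [0, 1] in {col}")
            out[col] = vals
    return out


def read_coherence_csv(path) -> pd.DataFrame:
    """Read a coherence CSV written by :func:`write_coherence_csv`."""
    return read_database_s1(path)


# --- pipeline configuration -------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable analysis parameters with the study's default values."""

    raw_fs: float = 400.0
    analysis_fs: float = 4.0
    mvar_order: int = 12
    n_freqs: int = 400
    freq_resolution: float = 0.005
    bands: tuple = tuple((b.name, b.f_low, b.f_high) for b in DEFAULT_BANDS)
    coherence_squared: bool = True
    seed: int = 0
    n_subjects: int = 10
    day: int = 1
    experiment_index: int = 1
    coupling: dict = field(default_factory=lambda: {"accel": 0.8, "resp": 0.5})
    signals: tuple = ("ecg", "resp_abd", "resp_thor", "accel")
    condition_durations: dict = field(
        default_factory=lambda: {
            "baseline1": 240.0, "spontaneous": 120.0, "music": 120.0,
            "metronome": 120.0, "baseline2": 240.0,
        }
    )
    ss_type: int = 3

    def __post_init__(self) -> None:
        if self.mvar_order < 1:
            raise ValueError("mvar_order must be >= 1")
        if self.raw_fs < self.analysis_fs:
            raise ValueError("raw_fs must be >= analysis_fs")
        if self.n_freqs < 2 or self.freq_resolution <= 0:
            raise ValueError("invalid frequency grid")
        for name, strength in self.coupling.items():
            if not 0 <= strength <= 1:
                raise ValueError(f"coupling[{name}] outside [0, 1]")

    def frequency_grid(self) -> np.ndarray:
        return np.arange(self.n_freqs) * self.freq_resolution

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["bands"] = tuple(tuple(b) for b in d["bands"])
        d["signals"] = tuple(d["signals"])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _session_config(cfg: PipelineConfig, group_setting: str):
    from .synthetic import CouplingSpec, SessionConfig, default_condition_specs, ARM_FREQ_HZ

    specs = default_condition_specs()
    resp_c = cfg.coupling.get("resp", 0.5)
    accel_c = cfg.coupling.get("accel", 0.8)
    for cond, by_sig in specs.items():
        resting = cond in ("baseline1", "baseline2")
        specs[cond] = {
            "ecg": dataclasses.replace(by_sig["ecg"], coupling_strength=resp_c),
            "resp_abd": dataclasses.replace(by_sig["resp_abd"], coupling_strength=resp_c),
            "resp_thor": dataclasses.replace(by_sig["resp_thor"], coupling_strength=resp_c),
            "accel": dataclasses.replace(by_sig["accel"], coupling_strength=accel_c),
        }
    conditions = tuple(
        (name, cfg.condition_durations[name])
        for name in ("baseline1", "spontaneous", "music", "metronome", "baseline2")
        if name in cfg.condition_durations
    )
    return SessionConfig(
        n_subjects=cfg.n_subjects,
        conditions=conditions,
        raw_fs=cfg.raw_fs,
        condition_specs=specs,
        day=cfg.day,
        group_setting=group_setting,
        experiment_index=cfg.experiment_index,
        seed=cfg.seed if group_setting == "collective" else cfg.seed + 10_000,
    )


def run_pipeline(config: PipelineConfig, out_dir,
                 group_settings=("collective", "individual")) -> Path:
    """simulate -> preprocess -> MVAR -> GPDC -> bands -> stats, to disk.

    Generates one session per group setting, writes a per-condition coherence
    CSV and, when both settings are present, the Condition x Group effect
    table per signal.  Every output carries the config hash; identical
    config and seed reproduce identical files.
    """
    import warnings

    from .gpdc import BandDefinition, band_average_all, build_pair_records, compute_gpdc
    from .group_stats import fit_condition_group_model, records_to_table
    from .mvar import fit_mvar_nuttall_strand
    from .preprocessing import preprocess_condition
    from .synthetic import generate_group_session

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    (out_dir / "config.json").write_text(config.to_json())
    bands = tuple(BandDefinition(*b) for b in config.bands)
    freqs = config.frequency_grid()

    all_records = []
    for setting in group_settings:
        session = generate_group_session(_session_config(config, setting))
        by_condition: dict[str, list] = {}
        for rec in session:
            by_condition.setdefault(rec.condition, []).append(rec)
        for cond, recs in by_condition.items():
            matrices = preprocess_condition(recs, signals=config.signals)
            cond_records = []
            for sig, mat in matrices.items():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = fit_mvar_nuttall_strand(mat, order=config.mvar_order)
                spectra = compute_gpdc(
                    model, freqs, subject_ids=mat.subject_ids,
                    squared=config.coherence_squared,
                )
                band_mats = band_average_all(spectra, bands)
                cond_records.extend(
                    build_pair_records(
                        band_mats, mat.subject_ids, signal=sig,
                        condition=mat.condition, group_setting=mat.group_setting,
                        experiment_index=mat.experiment_index, day=mat.day,
                        condition_order=mat.condition_order,
                    )
                )
            write_coherence_csv(
                cond_records, out_dir / f"coherence_{setting}_{cond}.csv",
                config_hash=chash,
            )
            all_records.extend(cond_records)

    write_coherence_csv(all_records, out_dir / "coherence_all.csv", config_hash=chash)
    if set(group_settings) >= {"collective", "individual"}:
        table = records_to_table(all_records)
        effect_rows = []
        for sig in config.signals:
            eff = fit_condition_group_model(table, sig, ss_type=config.ss_type)
            uni = eff.univariate.copy()
            uni.insert(0, "signal", sig)
            effect_rows.append(uni)
        effects = pd.concat(effect_rows, ignore_index=True)
        with open(out_dir / "effects_condition_group.csv", "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            effects.to_csv(fh, index=False)
    return out_dir
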