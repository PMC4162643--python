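import dataclasses

import numpy as np
import pandas as pd
import pytest

import physync as ps


@pytest.fixture(scope="session")
def small_session():
    """A 4-subject, single-condition collective session at a reduced raw rate."""
    cfg = ps.SessionConfig(
        n_subjects=4,
        conditions=(("metronome", 120.0),),
        raw_fs=200.0,
        seed=11,
    )
    return ps.generate_group_session(cfg)


def make_movement_session(coupling: float, setting: str, seed: int,
                          n_subjects: int = 5, raw_fs: float = 40.0):
    """One 2-minute movement condition with a given accel coupling strength."""
    specs = ps.synthetic.default_condition_specs(coupling)
    cfg = ps.SessionConfig(
        n_subjects=n_subjects,
        conditions=(("metronome", 120.0),),
        raw_fs=raw_fs,
        seed=seed,
        group_setting=setting,
        condition_specs=specs,
    )
    return ps.generate_group_session(cfg)


def movement_vhf_mean(coupling: float, setting: str, seed: int,
                      n_subjects: int = 5) -> float:
    """End-to-end mean off-diagonal VHF coherence of the accel channel."""
    import warnings

    recs = make_movement_session(coupling, setting, seed, n_subjects)
    mats = ps.preprocess_condition(recs, signals=("accel",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ps.fit_mvar_nuttall_strand(mats["accel"], order=12)
    vhf = ps.band_average(
        ps.compute_gpdc(model, subject_ids=mats["accel"].subject_ids), ps.VHF
    )
    off = ~np.eye(n_subjects, dtype=bool)
    return float(vhf[off].mean())


def make_balanced_table(rng: np.random.Generator, n_pairs: int = 90,
                        group_shift: dict | None = None,
                        noise_sd: float = 0.05,
                        bands=("LF", "HF", "VHF"),
                        days=(1,)) -> pd.DataFrame:
    """Balanced factorial coherence table with i.i.d. noise and optional shifts."""
    conds = ["baseline1", "spontaneous", "music", "metronome", "baseline2"]
    rows = []
    for cond in conds:
        for grp in ("collective", "individual"):
            for day in days:
                for pair in range(n_pairs):
                    row = dict(
                        signal="accel", source=f"A{pair}", target=f"B{pair}",
                        condition=cond, group_setting=grp,
                        experiment_index=1, day=day, condition_order=1,
                    )
                    for b in bands:
                        val = 0.3 + (noise_sd * rng.standard_normal() if noise_sd else 0.0)
                        if group_shift and grp in group_shift:
                            val += group_shift[grp].get(b, 0.0)
                        row[b] = val
                    rows.append(row)
    return pd.DataFrame(rows)
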