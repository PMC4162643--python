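"""Synthetic multi-subject physiological sessions with controllable coupling.

Generates group recording sessions (ECG, abdominal/thoracic respiration, one-arm
accelerometer magnitude) in which the degree of inter-subject synchrony is a
known, tunable parameter, so that every downstream stage — R-peak detection,
tachogram construction, MVAR fitting, GPDC, band statistics — can be tested
against ground truth without any real recording.

The coupling model: each oscillatory channel follows an instantaneous phase that
is a convex blend of a *common driver* phase (shared across subjects in a
"collective" session) and a subject-specific bounded random walk.  At coupling 1
with zero jitter all subjects oscillate identically; at coupling 0 they are
independent.  Heart-period variability is generated analytically (respiratory
sinus arrhythmia plus a slow 0.1 Hz component) and rendered as a template ECG,
so the true R-peak times are always known exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

SIGNAL_NAMES = ("ecg", "resp_abd", "resp_thor", "accel")

#: protocol conditions and default durations (seconds)
DEFAULT_CONDITIONS = (
    ("baseline1", 240.0),
    ("spontaneous", 120.0),
    ("music", 120.0),
    ("metronome", 120.0),
    ("baseline2", 240.0),
)

BASELINE_CONDITIONS = ("baseline1", "baseline2")

#: movement cue: 130 beats-per-minute metronome/music, entrained 1:2 by the arm
CUE_BPM = 130.0
ARM_ENTRAINMENT_RATIO = 2
ARM_FREQ_HZ = CUE_BPM / ARM_ENTRAINMENT_RATIO / 60.0  # ~1.083 Hz, inside VHF
RESP_FREQ_HZ = 0.25  # ~15 breaths/min, mid-HF


@dataclass(frozen=True)
class CouplingSpec:
    """How strongly one signal's oscillation is shared across subjects.

    Parameters
    ----------
    signal_name:
        One of ``ecg``, ``resp_abd``, ``resp_thor``, ``accel``.
    coupling_strength:
        In [0, 1]. 0 = subjects fully independent; 1 = common driver.
    driver_frequency:
        Oscillation fundamental in Hz; must lie in (0, 2] so it is
        representable at the 4 Hz analysis rate.
    phase_jitter_sd:
        Diffusion scale of the Wiener phase walk, in radians per square-root
        second, so the walk's statistics do not depend on the sampling rate.
    amplitude_cv:
        Coefficient of variation of the per-subject amplitude.
    amplitude:
        Base oscillation amplitude in signal units (0 turns the channel into
        pure noise, e.g. the accelerometer during rest).
    noise_sd:
        Additive white measurement noise, signal units.
    """

    signal_name: str
    coupling_strength: float = 0.5
    driver_frequency: float = RESP_FREQ_HZ
    phase_jitter_sd: float = 0.5
    amplitude_cv: float = 0.1
    amplitude: float = 1.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.signal_name not in SIGNAL_NAMES:
            raise ValueError(f"unknown signal {self.signal_name!r}")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if not 0.0 < self.driver_frequency <= 2.0:
            raise ValueError("driver_frequency must lie in (0, 2] Hz")


def default_condition_specs(
    coupling_strength: float = 0.5,
) -> dict[str, dict[str, CouplingSpec]]:
    """Per-condition, per-signal coupling specs mirroring the protocol.

    Respiration and heart period oscillate in every condition; the arm
    accelerometer is noise-only during the two resting baselines and
    oscillates near 1.083 Hz (half the 130 bpm cue) during the three
    movement conditions.
    """
    specs: dict[str, dict[str, CouplingSpec]] = {}
    for label, _dur in DEFAULT_CONDITIONS:
        resting = label in BASELINE_CONDITIONS
        specs[label] = {
            "ecg": CouplingSpec("ecg", coupling_strength, RESP_FREQ_HZ),
            "resp_abd": CouplingSpec("resp_abd", coupling_strength, RESP_FREQ_HZ),
            "resp_thor": CouplingSpec("resp_thor", coupling_strength, RESP_FREQ_HZ),
            "accel": CouplingSpec(
                "accel",
                coupling_strength,
                ARM_FREQ_HZ,
                amplitude=0.0 if resting else 1.0,
            ),
        }
    return specs


@dataclass
class SessionConfig:
    """One group session: subjects, protocol conditions, coupling structure."""

    n_subjects: int = 10
    conditions: Sequence[tuple[str, float]] = DEFAULT_CONDITIONS
    raw_fs: float = 400.0
    condition_specs: dict[str, dict[str, CouplingSpec]] | None = None
    day: int = 1
    group_setting: str = "collective"
    experiment_index: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if any(dur <= 0 for _lab, dur in self.conditions):
            raise ValueError("condition durations must be positive")
        if self.group_setting not in ("collective", "individual"):
            raise ValueError("group_setting must be 'collective' or 'individual'")
        if self.day not in (1, 2):
            raise ValueError("day must be 1 or 2")
        if self.condition_specs is None:
            self.condition_specs = default_condition_specs()


@dataclass
class Recording:
    """One subject's raw multichannel recording for one condition."""

    subject_id: str
    channels: dict[str, np.ndarray]
    fs: float
    condition: str
    day: int
    group_setting: str
    experiment_index: int = 1
    condition_order: int = 1
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def synth_rr_sequence(
    mean_rr: float,
    rsa_depth: float,
    resp_freq: float,
    lf_depth: float,
    duration: float,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.005,
    rsa_phase_fn=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate R-peak times with RSA- and LF-modulated heart periods.

    RR_k = mean_rr + rsa_depth*sin(2*pi*resp_freq*t_k)
                   + lf_depth*sin(2*pi*0.1*t_k) + noise,
    evaluated at the current peak time t_k; peak times are the cumulative
    sums starting at 0.  Returns ``(peak_times, rr_intervals)`` with
    ``len(rr) == len(peaks) - 1``; these are exact ground truth.

    ``rsa_phase_fn``, when given, replaces the analytic respiratory phase
    ``2*pi*resp_freq*t`` with an arbitrary phase trajectory (used to couple
    the RSA modulation to a shared respiratory driver).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0.4 <= mean_rr <= 1.5:
        raise ValueError("mean_rr must lie in [0.4, 1.5] s")
    if rsa_depth + lf_depth >= mean_rr / 2:
        raise ValueError("modulation depths could drive RR towards zero")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if rsa_phase_fn is None:
        rsa_phase_fn = lambda t: 2 * np.pi * resp_freq * t  # noqa: E731
    peaks = [0.0]
    rrs = []
    t = 0.0
    while True:
        rr = (
            mean_rr
            + rsa_depth * np.sin(float(rsa_phase_fn(t)))
            + lf_depth * np.sin(2 * np.pi * 0.1 * t)
            + (noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0)
        )
        rr = max(rr, 0.25)  # physiological floor, unreachable under the guard
        if t + rr > duration:
            break
        t += rr
        peaks.append(t)
        rrs.append(rr)
    if len(peaks) < 3:
        raise ValueError("duration too short for a tachogram")
    return np.asarray(peaks), np.asarray(rrs)


def synth_ecg(
    peak_times: Sequence[float],
    fs: float,
    duration: float,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.01,
    template_sd: float = 0.010,
) -> np.ndarray:
    """Render a template ECG: one narrow Gaussian R wave per peak time.

    The template (sd 10 ms, amplitude 1) guarantees that the within-beat
    global maximum of the clean waveform sits at the sample nearest each
    requested peak time; morphology beyond the R wave is deliberately absent.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size and np.any(np.diff(peak_times) <= 0):
        raise ValueError("peak times must be strictly increasing")
    if peak_times.size and (peak_times[0] < 0 or peak_times[-1] > duration):
        raise ValueError("peak times must lie within [0, duration]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    half = 5 * template_sd
    for tp in peak_times:
        lo = max(0, int((tp - half) * fs))
        hi = min(n, int((tp + half) * fs) + 1)
        x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tp) / template_sd) ** 2)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return x


def make_driver_phase(
    frequency: float,
    duration: float,
    fs: float,
    jitter_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Instantaneous phase 2*pi*f*t plus a Wiener phase walk.

    ``jitter_sd`` is the diffusion scale in rad/sqrt(s); increments scale
    with 1/sqrt(fs) so the trajectory statistics are rate-invariant.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = 2 * np.pi * frequency * t
    if jitter_sd > 0:
        step = jitter_sd / np.sqrt(fs)
        phase = phase + np.cumsum(step * rng.standard_normal(n))
    return phase


def blend_phase(
    spec: CouplingSpec,
    common_driver_phase: np.ndarray,
    duration: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Subject phase = c*common + (1-c)*independent phase walk.

    The independent component runs at the same fundamental but carries its
    own Wiener jitter and a random starting offset, so uncoupled subjects
    decorrelate over the recording.
    """
    n = int(round(duration * fs))
    if len(common_driver_phase) < n:
        raise ValueError("driver phase does not cover the requested duration")
    c = spec.coupling_strength
    if c >= 1.0:
        return np.asarray(common_driver_phase[:n], dtype=float)
    own = make_driver_phase(
        spec.driver_frequency, duration, fs, spec.phase_jitter_sd, rng
    )
    own = own + rng.uniform(0, 2 * np.pi)
    return c * common_driver_phase[:n] + (1.0 - c) * own


def synth_oscillatory_channel(
    spec: CouplingSpec,
    common_driver_phase: np.ndarray,
    duration: float,
    fs: float,
    subject_seed: int | np.random.Generator,
    phase: np.ndarray | None = None,
) -> np.ndarray:
    """One subject's oscillatory channel, phase-coupled to a common driver.

    The subject's instantaneous phase is
    ``c * common + (1 - c) * independent`` where ``c`` is the coupling
    strength and the independent component is a fresh phase walk at the same
    frequency.  With c = 1 and zero jitter all subjects' channels coincide
    (up to amplitude and noise draws).  A precomputed blended ``phase`` may
    be passed to render several channels sharing one phase trajectory.
    """
    n = int(round(duration * fs))
    rng = (
        np.random.default_rng(subject_seed)
        if not isinstance(subject_seed, np.random.Generator)
        else subject_seed
    )
    if phase is None:
        phase = blend_phase(spec, common_driver_phase, duration, fs, rng)
    amplitude = spec.amplitude * max(0.0, 1.0 + spec.amplitude_cv * rng.standard_normal())
    x = amplitude * np.sin(phase[:n])
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(n)
    return x


def generate_group_session(config: SessionConfig) -> list[Recording]:
    """Generate one full session: a Recording per subject per condition.

    Collective sessions share one driver-phase realization per (condition,
    signal); individual sessions draw an independent driver per subject,
    emulating participants recorded alone.  Fully deterministic under
    ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    recordings: list[Recording] = []
    specs = config.condition_specs
    assert specs is not None
    fs = config.raw_fs
    for ci, (label, dur) in enumerate(config.conditions):
        cond_specs = specs[label]
        cond_ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(ci,))
        drv_rng = np.random.default_rng(cond_ss.spawn(1)[0])
        # one shared driver realization per driver for the collective setting;
        # both respiration belts (and the RSA modulation) ride the resp driver
        common = {
            "resp": make_driver_phase(
                cond_specs["resp_abd"].driver_frequency,
                dur, fs, cond_specs["resp_abd"].phase_jitter_sd, drv_rng,
            ),
            "accel": make_driver_phase(
                cond_specs["accel"].driver_frequency,
                dur, fs, cond_specs["accel"].phase_jitter_sd, drv_rng,
            ),
        }
        for si in range(config.n_subjects):
            subj_ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(ci, si + 1)
            )
            rngs = [np.random.default_rng(s) for s in subj_ss.spawn(7)]
            channels: dict[str, np.ndarray] = {}
            truth: dict = {}

            if config.group_setting == "individual":
                # an independent driver realization per subject ("studied alone")
                drivers = {
                    "resp": make_driver_phase(
                        cond_specs["resp_abd"].driver_frequency,
                        dur, fs, cond_specs["resp_abd"].phase_jitter_sd, rngs[0],
                    ),
                    "accel": make_driver_phase(
                        cond_specs["accel"].driver_frequency,
                        dur, fs, cond_specs["accel"].phase_jitter_sd, rngs[0],
                    ),
                }
            else:
                drivers = common

            # one blended respiratory phase shared by both belts and the RSA
            resp_phase = blend_phase(
                cond_specs["resp_abd"], drivers["resp"], dur, fs, rngs[1]
            )
            accel_phase = blend_phase(
                cond_specs["accel"], drivers["accel"], dur, fs, rngs[2]
            )

            ecg_spec = cond_specs["ecg"]

            def phase_at(t: float, _ph=resp_phase, _fs=fs) -> float:
                # O(1) linear interpolation into the sampled phase trajectory
                i = min(int(t * _fs), len(_ph) - 2)
                frac = t * _fs - i
                return _ph[i] * (1 - frac) + _ph[i + 1] * frac
            peaks, rrs = synth_rr_sequence(
                mean_rr=0.85,
                rsa_depth=0.04 * ecg_spec.amplitude,
                resp_freq=ecg_spec.driver_frequency,
                lf_depth=0.03,
                duration=dur,
                seed=rngs[3],
                rsa_phase_fn=phase_at,
            )
            channels["ecg"] = synth_ecg(peaks, fs, dur, seed=rngs[4])
            truth["r_peak_times"] = peaks
            truth["rr_intervals"] = rrs

            for name, ph, rng in (
                ("resp_abd", resp_phase, rngs[5]),
                ("resp_thor", resp_phase, rngs[5]),
                ("accel", accel_phase, rngs[6]),
            ):
                sp = cond_specs[name]
                channels[name] = synth_oscillatory_channel(
                    sp, ph, dur, fs, rng, phase=ph
                )
            truth["driver_phases"] = {"resp": resp_phase, "accel": accel_phase}

            recordings.append(
                Recording(
                    subject_id=f"S{si + 1}",
                    channels=channels,
                    fs=config.raw_fs,
                    condition=label,
                    day=config.day,
                    group_setting=config.group_setting,
                    experiment_index=config.experiment_index,
                    condition_order=ci + 1,
                    ground_truth=truth,
                )
            )
    return recordings


def session_config_to_dict(config: SessionConfig) -> dict:
    """JSON-serializable view of a session config (for sidecar files)."""
    d = dataclasses.asdict(config)
    d["conditions"] = [list(c) for c in config.conditions]
    return d
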