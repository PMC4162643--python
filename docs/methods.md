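# Methods

## Scope and data flow

The package infers directed synchrony among the members of a group from four
physiological signal types: heart period (derived from ECG), abdominal and
thoracic respiration, and arm accelerometry. One signal type at a time, the
N subjects' series are treated as one N-channel system; directed coupling is
quantified by generalized partial directed coherence (GPDC) on a fitted
multivariate autoregressive (MVAR) model, reduced to band means, and analysed
with factorial fixed-effects models.

Stages: raw recordings (400 Hz) → 4 Hz detrended group matrices → MVAR fit
(Nuttall–Strand, order 12) → GPDC on a 400-point 0–2 Hz grid → LF/HF/VHF band
means → directed-pair records → Condition × Group and Condition × Day models.

## Preprocessing

**R-peak detection.** Band-pass 5–25 Hz (order-2 Butterworth, zero-phase),
squaring, 150 ms moving-average integration, threshold at median + 4·MAD of
the integrated energy, 250 ms refractory period, then snapping each detection
to the raw-signal maximum within ±50 ms (extended to the record boundary for
beats in the first/last 200 ms, where the band-pass transient shifts the
energy envelope). This is a standard QRS scheme; it assumes a clean,
positive-R morphology and performs no ectopic-beat correction.

**Heart-period series.** Each R-R interval (ms) is assigned to the time of
its terminating R peak; values are linearly interpolated onto a uniform 4 Hz
grid starting at the first assigned point (the second R peak) and ending at
the last assigned point (half-open: later grid points are dropped). Cubic
alternatives were considered and rejected as an unnecessary degree of
freedom; linear interpolation is the minimal convention and is recorded in
the output metadata.

**Resampling.** Other channels are low-passed with a zero-phase symmetric
FIR (Kaiser design, 80 dB, cutoff 2.2 Hz, transition ≈0.6 Hz at 400 Hz
input) and evaluated on the 4 Hz grid. Zero phase matters: phase relations
*between* subjects are the object of study, so any phase-distorting filter
would corrupt the estimand. Signal extension uses point (odd) reflection,
which preserves boundary value and slope and confines edge transients to
~1e-5 relative amplitude. A 1.9 Hz component survives within 0.1%; a 2.5 Hz
component retains <0.01% of its power after the 4 Hz decimation.

**Detrending and assembly.** Per-subject series are truncated to their
common time support (device-synchronized recordings are assumed aligned; no
cross-correlation alignment is attempted) and linearly detrended row-wise.

## MVAR estimation

The default estimator is the Nuttall–Strand algorithm: a multichannel
Burg-type lattice on forward/backward prediction errors. At stage m the
unbiased (1/(T−m)-normalised) error covariances ρ_f, ρ_b and cross-covariance
ρ_fb are formed, and the partial-correlation matrix Δ solves the two-sided
linear equation

    (ρ_f P_f⁻¹) Δ + Δ (P_b⁻¹ ρ_b) = 2 ρ_fb,

solved densely (scipy's Sylvester solver; N ≤ ~20 makes this trivial).
Reflection matrices K_f = −Δ P_b⁻¹ and K_b = −Δᵀ P_f⁻¹ propagate the
Levinson–Whittle updates of coefficients, error series, and error
covariances; the innovation covariance Σ_w is the final forward error
covariance. In the scalar case the recursion reduces exactly to Burg's
reflection coefficient. The lattice construction keeps fitted models stable
even in the short-window regime this analysis lives in (N = 10, p = 12,
T ≈ 480: 1200 coefficients from 4800 scalar samples); the package logs a
parameters-per-sample warning instead of refusing, and the test suite checks
the spectral radius on such windows.

Model order is fixed at 12 by default and configurable; no automatic order
selection is performed. One model is fitted per condition (no windowing of
the 2–4 minute conditions). An OLS estimator on lagged regressors provides
an independent cross-check route; on long simulated series the two agree
entrywise to well under 0.02 and both converge to generating parameters.

## GPDC

With Ā(f) = I − Σ_r A_r e^{−i2πfr/fs} and σ_k the innovation standard
deviations, π_{i←j}(f) = (Ā_ij/σ_i)/sqrt(Σ_k |Ā_kj|²/σ_k²). The stored value
is |π|², which lies in [0,1], gives an exactly unit diagonal for uncoupled
channels, and satisfies Σ_i |π_{i←j}|² = 1 per source column; |π| is
available behind a switch for sensitivity analysis. The σ-weighting makes
the measure invariant to rescaling any single channel (verified to 1e-6
end-to-end through refitting), which is why calibration differences between
subjects' sensors do not bias the comparison.

**Frequency grid.** 400 points at exactly 0.005 Hz spacing, f_k = 0.005·k,
k = 0..399, i.e. the range 0–2 Hz at the stated resolution (2.0 itself, the
Nyquist bin of the 4 Hz series, is the limit of the grid and carries no bin).
**Bands.** LF [0.035, 0.15), HF [0.15, 0.40), VHF [0.40, 2.0]; half-open
edges, so the bands tile the axis above 0.035 Hz without double counting;
the DC region below 0.035 Hz is in no band. Band values are arithmetic means
of |π|² over included bins.

**Null threshold.** Short-window GPDC estimates are biased away from zero.
The package's empirical null reference is the seed-averaged 95th percentile
of off-diagonal band coherence for 10 independent AR(1) channels fitted with
the production settings (T = 480, p = 12). Directed-coupling detection in the
tests requires the forward pair to exceed this level while the reverse pair
stays below it.

## Group statistics

The observational unit is one directed pair's band coherence (90 ordered
pairs per 10-subject group per condition); pairs are treated as exchangeable
observations with no pair-level random effect. LF/HF/VHF are joint dependent
variables: Wilks' Λ and Pillai's trace (with F approximations) are reported
for the multivariate tests, alongside per-band univariate F tests using
type-III sums of squares with sum-to-zero contrasts (configurable to type
I/II), because factorial cells can be unbalanced in practice. A noise-free
injected effect yields a zero residual; the univariate F is then flagged as
infinite rather than numerically exploded. Bonferroni post-hoc contrasts use
pairwise pooled-t statistics on the omnibus residual mean square, raw p
multiplied by the number of comparisons and capped at 1.

The supplementary-table replication path accepts a coherence table in the
documented integer coding (Condition 1–5, Group 0/1, Experiment 1–3, Day 1/2,
Order 1–5; CSV or XLSX — CSV is the canonical interchange, chosen so the
repository and CI carry no binary-format dependency). Because the exact
case-inclusion rules behind the published error degrees of freedom cannot be
reconstructed unambiguously, the replication report fits every plausible
variant (per-day and pooled Condition × Group, with and without the final
baseline, plus Condition × Day on collective rows) and flags the variant
closest to each stored reference F value rather than guessing one rule.

## Synthetic sessions

The generator emulates the study design: 10 subjects, conditions
baseline (240 s) / spontaneous / music / metronome (120 s each) / final
baseline (240 s), raw 400 Hz, recorded either collectively (shared driver
realization per condition) or individually (independent driver per subject).

* **Movement driver**: 130 bpm cue entrained 1:2 → 1.083 Hz fundamental,
  inside the VHF band (1:1 at 2.17 Hz would exceed it); ratio configurable.
  The accelerometer channel is pure noise during baselines.
* **Respiration driver**: 0.25 Hz (~15 breaths/min, mid-HF); the abdominal
  and thoracic belts share one phase trajectory with independent amplitudes
  and noise, and the RSA modulation of heart period rides the same phase.
* **Coupling model**: a subject's instantaneous phase is
  c·(common driver) + (1−c)·(own phase walk), c ∈ [0,1]. The independent
  component is a Wiener phase walk with diffusion 0.5 rad/√s (rate-invariant
  parameterisation), chosen so that uncoupled subjects decorrelate within a
  2–4 minute condition (mean |r| < 0.1 over 480 s) while a coupled group
  keeps a stable shared rhythm.
* **ECG**: heart period = 0.85 s mean, 40 ms RSA depth, 30 ms slow (0.1 Hz)
  modulation, 5 ms beat-to-beat noise, rendered as one Gaussian R-wave
  template (sd 10 ms, amplitude 1) per beat. Only R-peak localization is
  exercised downstream, so no PQRST morphology is modelled.

Ground truth (R-peak times, RR intervals, driver phases) is stored alongside
every recording; tests compare against stored truth, never truth re-derived
from the signals.

What the generator does **not** emulate: realistic ECG morphology and
artefacts, motion contamination of respiration belts, amplitude asymmetries
between abdominal and thoracic breathing, non-stationary movement tempo, or
any cardiorespiratory biophysics beyond sinusoidal RSA. Passing tests
therefore demonstrate that the pipeline recovers known coupling structure
under clean, stationary, phase-coupled oscillations — not that it is robust
to recording artefacts in field data.

## Problem sizes and numerical choices

Deterministic seeding throughout (NumPy `SeedSequence` spawning per
condition/subject), so identical config + seed reproduces byte-identical
outputs; every pipeline artifact carries a hash of its configuration.
Statistical calibration tests use 2000 balanced null replicates (type-I
error 0.05 ± 0.01); coupling-contrast and recovery properties use 20 seeds.
End-to-end session tests run with 4–5 subjects, single 120 s conditions and
reduced raw rates (40–200 Hz) — the generator is rate-invariant by
construction, and these sizes keep the full suite around a minute while
preserving the short-window fitting regime (T ≈ 480 at 4 Hz). Degenerate
inputs (constant channels, saturated designs, empty design cells, singular
lattice stages, sub-Nyquist rates, bands off the grid) raise informative
errors rather than propagating NaNs.

## Known limitations

* Pair observations are treated as independent in the factorial models,
  although the 90 directed pairs share 10 underlying subjects; reported p
  values inherit this (deliberate, design-matching) simplification.
* GPDC significance is assessed against an empirical finite-sample null,
  not asymptotic GPDC distribution theory.
* EDF input is not supported; CSV is the only recording interchange format.
* Legacy binary `.xls` tables must be converted to `.xlsx` or CSV first.
* The MVAR model assumes within-condition stationarity; drifting tempo or
  posture changes within a condition violate it.
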