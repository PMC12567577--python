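# Methods

This note documents the models, numerical choices and calibration behind
`tremorband`, and what the synthetic test suites do and do not demonstrate
about real recordings.

## Signal model and preprocessing

A trial is a 15 s tri-axial acceleration recording (m/s², 100 Hz) of a
resting hand. The analysis signal is the magnitude ‖a(t)‖ =
√(ax² + ay² + az²); per-axis analysis is deliberately not offered — the
magnitude is orientation-robust and is what downstream indices are defined
on. The chain is fixed and enforced by stage tags on the series object:

    magnitude → trim(5 s) → demean → zero-phase filter → Welch PSD

* **Trim.** The first `round(5 s × fs)` samples are dropped (transient
  adaptation after recording onset), leaving 1000 samples at the defaults
  and hence 0.1 Hz spectral resolution.
* **Demean.** Subtracting the arithmetic mean removes the DC component,
  which is dominated by gravity projected on the magnitude (≈ 9.81 m/s² for
  a supported resting hand).
* **Dual-branch filtering.** A 2nd-order Butterworth low-pass at 10 Hz
  (serving the 2–4 Hz band) and the complementary high-pass at 10 Hz
  (serving the 10–20 Hz band), each applied forward–backward
  (`scipy.signal.filtfilt`). The net phase is zero and the net amplitude
  response is |H(f)|² of the single pass — an effective 4th-order roll-off.
  "Second order" is read as the design order per pass; an alternative
  convention (order 1 per pass, netting 2nd order) can be had by passing
  `FilterSpec(order=1)`.
* **Edge handling.** Forward–backward IIR filtering needs signal extension;
  1000-sample segments make edge transients non-negligible at 2 Hz. We use
  symmetric reflection (`padtype="even"`) with 150 samples (1.5 s) per
  edge, configurable, well above the scipy default of 3× the coefficient
  count.
* **Digital vs analog response.** The filter is the standard bilinear
  design. Its exact amplitude response is the Butterworth form in the
  warped frequency u = tan(πf/fs)/tan(πfc/fs); at fs = 100 Hz it matches
  the continuous prototype to better than 0.5 % below ~5 Hz and exactly at
  the 10 Hz cutoff, but is up to ~3 % sharper at 15–20 Hz. Tests and the
  generator use the warped closed form (`butterworth_amplitude(..., fs=fs)`)
  as the analytic reference because that is the filter actually applied.

## Spectral estimation and the band indices

The PSD is a one-sided Welch estimate with a single Hamming window covering
the whole segment and zero overlap — i.e. one modified periodogram. Density
scaling divides by fs·Σw², so the trapezoid-integrated PSD equals the
window-power-corrected variance of the windowed input (Parseval; asserted
in tests to 2 %). Detrending inside the PSD routine is disabled: the series
is demeaned upstream and must not be processed twice.

Per band [f₁, f₂] (2–4 Hz from the LP branch, 10–20 Hz from the HP branch;
the pairing is fixed):

* L(f₁,f₂) = 1/|f₂−f₁| ∫ ln PSD(f) df — the band-average log amplitude.
  Multiplying signal amplitude by s shifts L by exactly 2·ln s.
* F(f₁,f₂) = ∫ f·PSD df / ∫ PSD df — the power-weighted centroid, always
  inside [f₁, f₂]; scale-invariant.

Both integrals use the trapezoidal rule on the 0.1 Hz grid restricted to
the band, edges inclusive (21 bins in 2–4 Hz). Rectangle-rule evaluation
would differ below reporting precision for smooth spectra; the trapezoid is
the least-surprise choice and is pinned against an independent loop-based
quadrature oracle to 1e-10. PSD bins below a floor ε = 1e-20 (m/s²)²/Hz are
clamped before the logarithm (ln 0 must not occur in an all-but-empty
band); every clamp is logged. F uses the raw bins and raises if the band
power is exactly zero — an undefined centroid is an error, not a number.

## Synthetic cohort generator

The generator emulates the statistical signature of a 50-participant,
2 limb × 2 condition resting-tremor study; it makes no attempt at
biomechanics. Each trial is gravity DC (z axis) + a 2–4 Hz component + a
10–20 Hz component + a broadband per-axis noise floor (ln PSD −16,
i.e. ~2.4 mm/s² RMS per axis — instrument-level noise).

**Band components.** Each band component is Gaussian noise synthesized in
the frequency domain with an exponentially tilted in-band PSD
exp(a + b·f). This makes the two targets closed-form and independently
steerable: the band-average ln PSD is a + b·(f₁+f₂)/2 and the centroid is
the centroid of exp(b·f) on [f₁, f₂] (solved for b with Brent's method).
The shape extends 0.5 Hz beyond the band edges so window leakage at a
sharp spectral step cannot bias the edge bins.

**Truth equals expectation.** Two analytic corrections make the injected
(level, centroid) equal the expectation of the pipeline-extracted (L, F):
the shape is divided by the paired branch's zero-phase PSD gain |H(f)|⁴
(exact warped closed form), and the underlying PSD carries a factor
exp(γ) ≈ 1.781 (Euler–Mascheroni): a single-window periodogram bin is
distributed as PSD·χ²₂/2, and E[ln(χ²₂/2)] = −γ. Measured over 20 default
cohorts, residual recovery bias is ≈ 0.01 log units for L and < 0.01 Hz
for F — the tested bounds are 0.2 and 0.1.

**Axis allocation.** Each trial draws a random fixed direction with polar
angle up to 45° from the gravity axis. Because the magnitude of
gravity + small tremor measures, to first order, the tremor's projection on
the gravity axis, the z component carries the calibrated signal and the
in-plane components are scaled by tan(θ) relative to it; quadratic
cross-terms are ≤ 1e-4 of in-band levels at the default amplitudes.

**Cohort structure and defaults.** Per participant, one (level, centroid)
offset pair per band is drawn from the between-subject distributions and
shared across all four cells; the condition shift and optional limb effect
are added on top. Defaults: PRE L(2–4) = −8.66, shift +3.79; PRE
F(2–4) = 3.165 Hz, shift −0.46 Hz; PRE L(10–20) = −8.975, shift +1.195;
PRE F(10–20) = 14.46 Hz, shift −0.335 Hz. Between-subject SDs are the
observed cell SDs averaged per band and deflated by √2, since observed SDs
mix subject spread with single-trial estimator noise (for L(2–4) the
estimator noise SD is ≈ 0.34, which recombines to ≈ 1.0 total — close to
the observed spread). All randomness flows from one root seed through
named (participant, stream) `SeedSequence` substreams, so cohorts are
reproducible and extensible.

**What the generator does not emulate.** The condition shift is uniform
across participants — within-subject variance is estimator noise only — so
F statistics and ηp² for the smaller effects come out larger than a real
cohort would give (e.g. ηp² ≈ 0.99 for the 10–20 Hz time effect, where
heterogeneous real responses yield ≈ 0.64). There is also no 1/f background
ramp, no movement artifacts, no inter-trial drift, and no deviation of the
noise floor from white. Passing calibration tests therefore demonstrates
correctness of the estimation chain and of the first-order statistical
design, not robustness to real-world artifacts.

## Inference

The 2×2 repeated-measures ANOVA uses the classical SS decomposition; each
1-df effect is tested against its own effect-by-subject interaction
(df = 1, n−1). For this design F(time) is identically the squared paired t
on limb-averaged scores — asserted to 1e-10 — and the decomposition is
pinned against a brute-force loop oracle and cross-checked against
statsmodels' `AnovaRM`. SS terms below 1e-12 of the total SS are snapped to
zero so degenerate tables (identical cells) report F = 0 rather than 0/0
rounding noise; a zero error SS with a non-zero effect reports F = +inf
with a warning.

Greenhouse–Geisser epsilon is implemented generally (orthonormal-contrast
form, clipped to [1/(k−1), 1]) but is identically 1 for 2-level factors;
reports state "epsilon = 1 (2 levels; sphericity not testable)" instead of
omitting it. Partial eta squared is SS_e/(SS_e+SS_err), with a companion
`from_F` for back-computation from published statistics; Cohen labels at
0.01/0.06/0.14.

Pairwise comparisons are paired t-tests over all m = 6 unordered cell
pairs; m = 6 is inferred from the adjusted threshold 0.05/6 ≈ 0.008 used by
such studies and is configurable. Both the raw and the capped adjusted
p = min(1, m·p) are emitted; the significance flag uses raw p < α/m.
Zero-variance contrasts are reported as degenerate, never dropped.
Shapiro–Wilk screening (per cell by default, difference scores optionally)
is advisory: no automatic nonparametric fallback is taken. Incomplete
participants are dropped listwise with a logged warning.

## Problem sizes in the test suite

Simulation-backed checks use: 500 null cohorts (n = 50) for type-I
calibration of the time effect (expected band 0.05 ± 0.02), 100 cohorts at
default effect sizes for power (> 99 % at p < 0.001) and the
pairwise-pattern recovery (≥ 95 %), and 20 cohorts for parameter-recovery
bias. These take a few minutes on one CPU; the null/power suites extract
only the low band they test. One caveat made explicit in the tests: with
both 10 Hz branches at fs = 100 Hz, the LP+HP output variances for white
noise sum to ≈ 89 % of the input (the dip around the shared cutoff), and
the test asserts that analytic value rather than a loose "≈ 100 %"
complementarity.

## Known limitations

* Batch effects, missing cells beyond listwise deletion, and unequal trial
  lengths within a cohort are out of scope.
* The band/branch pairing is fixed; cross-pairing (e.g. 2–4 Hz from the HP
  branch) is intentionally not exposed.
* No multitaper or averaged-segment Welch variants; the single full-length
  window is the method's defining choice, and its high per-bin variance is
  exactly what the γ-corrected generator calibration accounts for.
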