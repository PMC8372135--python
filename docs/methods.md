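# Methods

This note documents the models, the synthetic data, the numerical
choices, and what the test suite does and does not demonstrate.

## Measurement model and reduction

A measurement run is a burst of scans from three channels sharing one
sample spot: NIR (raw grid 939–1833 nm, 895 points, exactly 1 nm
spacing), and a UV-Vis detector serving both diffuse visible reflectance
and 365 nm-excited fluorescence (raw grid modelled as uniform over
320–889 nm, 288 points).  Reduction per sensor and run:

1. every scan is screened for saturation: ≥ 3 consecutive points at or
   above the detector ceiling (a plateau, not a single-pixel spike);
   a measurement is discarded for a sensor when more than half of that
   sensor's scans clip — saturation in practice affects the whole burst;
2. retained scans are averaged pointwise;
3. reflectance channels are corrected as `(scan − dark)/(white − dark)`,
   the emission channel as `scan − dark` (a white standard is meaningless
   for emission); `white − dark` must stay above a floor of 1e-9 counts,
   otherwise the reference is rejected as degenerate;
4. the spectrum is trimmed to the sensor's used range with closed
   interval bounds — on the 1 nm NIR grid, 1020–1833 nm retains exactly
   814 points.

The correction is exactly invariant to a common detector gain, and
averaging commutes with affine intensity maps; both are enforced as
property tests.

The used-range point counts of the real UV-Vis detector depend on a
nonlinear wavelength calibration that is not public; the uniform-grid
model used here yields 171 VIS and 222 FLUO points.  Downstream stages
never assume particular grid sizes.

## Synthetic study

The generator emulates the study design end to end: 16 EVOO, 32 RVOO,
9 olive-pomace, 12 other edible oils; 20 olive-based and 40 seed-oil
admixtures at 10/25/50 % (v/v) with base, adulterant and level drawn
uniformly; nine runs per sample (3 days × 3); 10 VIS + 10 FLUO + 255 NIR
scans per run; 122 FLUO and 90 VIS measurements clipped at the detector
ceiling by a seeded draw, so the saturation filter reproduces the
1161 − 122 = 1039 and 1161 − 90 = 1071 retained-measurement arithmetic
exactly.

Latent spectra are sums of Gaussian bands.  Fluorescence uses the
pheophytin-family structure of olive oils: a phenolic/carotenoid region
near 375 nm, the Soret band near 450 nm and the dominant q-band near
672 nm.  Class templates encode the chemistry qualitatively: EVOO has the
strongest q-band (9000 counts) and the smallest between-sample spread
(CV 0.08); refined olive grades keep ~20–30 % of the pigment amplitudes
with CV 0.30; seed oils keep < 5 % of EVOO's q-band.  Visible spectra are
`exp(−absorbance)` with the same pigments absorbing; NIR spectra share
four C–H overtone/combination bands across all classes with only 1–4 %
class-specific multipliers and CV ≤ 0.02, which deliberately makes
NIR-only models poor discriminators.  Individual oils perturb each band
amplitude with an independent unit-mean lognormal factor of the class CV.

Admixtures mix latent spectra linearly in volume fraction, ignoring
fluorescence inner-filter effects — a known simplification.  The
instrument model adds a dark level (100 counts, sd 2), a smooth gain
profile (30 000 counts peak), i.i.d. Gaussian scan noise (sd 15 counts)
and a per-(sample, day) uniform multiplicative drift of ±2 % emulating
storage over the measurement period.  No quantitative noise or drift
magnitudes are published for this device class; these are free
parameters of the generator, exposed in `InstrumentModel`, not claims
about any instrument.

Randomness is fully reproducible: each run's stream is derived by
hashing (seed, sample id, day, replicate), so any subset of the study
regenerates identically.

**What passing tests show — and don't.**  Between-sample variation is
drawn *independently per band*, while a real oil's pigments co-vary
(total pigment content rises and falls together).  Admixture directions
are therefore easier to distinguish from authentic EVOO variation here
than in real data: the synthetic study under scenario 1 reaches 100 %
on all classes including 10 % admixtures, whereas on real samples low
admixture levels are the documented failure mode.  Pipeline tests on
this generator demonstrate the machinery (no leakage, correct
arithmetic, monotone behaviour), not field performance.

## Preprocessing operators

* **SNV**: `(x − mean)/sd`, sd with denominator n − 1.
* **SNV + detrend**: least-squares quadratic in wavelength removed after
  SNV; the wavelength axis is centred and scaled before building the
  Vandermonde matrix for conditioning.  Output is orthogonal to
  {1, λ, λ²}.
* **Savitzky–Golay derivatives**: window 11, polynomial degree 2 (the
  minimal degree exact for both requested orders); the five edge points
  on each side are dropped rather than padded — no boundary data is
  fabricated.
* **Wavelet features**: linear interpolation onto 128 equally spaced
  points, periodized orthogonal DWT, concatenated detail coefficients —
  Haar levels 5–7 (4+2+1 = 7 features) or symlet-4 levels 3–5
  (16+8+4 = 28 features).  Details only: approximations carry baseline
  information the detrend operators already target.
* **Spectral splitting**: four contiguous sections, earlier sections
  take the remainder points (814 → 204/204/203/203); splitting applies
  *before* other preprocessing and each section is modelled separately.

The default grid crosses 6 preprocessings × (full + 4 sections) ×
5 algorithms = 150 models per sensor.  The grid is configuration-driven
and documents its own count rather than imitating any particular total.

## One-class models

All five expose `fit(X_evoo)` / `distance(X) ≥ 0`.

* **SIMCA** — mean-centred PCA; orthogonal distance q (squared residual
  norm) and score leverage h (Hotelling T²) each normalized by their
  training means; d = √((q/q₀)² + (h/h₀)²).  The SIMCA literature has
  several distance variants; the combined normalized form is adopted and
  frozen in oracle tests.  When training residuals are numerically zero
  (components span the data), the q-term treats any residual beyond
  round-off as decisively out-of-plane.
* **PCA residual** — raw Q statistic.  For *component selection only*
  the CV objective is Q normalized by the training-fold mean (raw Q
  decreases monotonically with components, so an unnormalized objective
  would always pick the largest candidate); the reported distance stays
  the raw Q.
* **kNN** — mean Euclidean distance to the k nearest training vectors
  (the simplest convention; neither max nor k-th distance).
* **Mahalanobis** — shrinkage Σ + λ·tr(Σ)/p·I with λ = 1e-3 by default:
  spectra have far more wavelengths than there are EVOO samples, so the
  raw covariance is singular.  Features are column-standardized first
  (conditioning only).
* **One-class SVM** — RBF kernel; "automatic" bandwidth via the median
  heuristic γ = 1/(2·median‖xᵢ−xⱼ‖²); ν = 0.1; reported distance is
  max(0, ρ − f(x)) so in-class points score exactly zero.

Hyperparameters (components, neighbours) are chosen by five-fold CV
grouped by sample, minimizing the mean held-out EVOO distance with exact
ties going to the simpler candidate.  On grouped low-rank data the
Q-residual objective recovers the true rank reliably (tested at ≥ 90 %
over 100 seeds); SIMCA's combined distance is flatter in the number of
components and its selection is correspondingly less decisive — one
reason the grid carries both model families.

## Splitting, ranking, selection

Outer evaluation uses sample-grouped splits at fraction 0.8
(floor(0.8·16) = 12 train / 4 test EVOOs), repeated 5 times by default
with per-sample distances averaged across repeats: a single split of a
16-oil library leaves only 4 held-out targets, far too few for a stable
AUROC.  AUROC is the Mann–Whitney pair statistic (ties count half),
computed per adversary group.  Selection replaces a manual pick with a
deterministic rule: rank score = unweighted mean of the three adversary
AUROCs, per-sensor quotas 6/2/2, exact ties broken by the
lexicographically smaller model key.

Final models are refit on the whole EVOO library; their calibration
distances come from grouped five-fold CV, never resubstitution, so a
sample is never scored by a model it helped fit.  Non-EVOO samples are
scored by the final fit.

## Fusion and scenarios

Per-model thresholds (not a single fused-score threshold) keep the
≥ 2-of-10 rule well defined.  Replicates are combined by mean distance
before thresholding; the boundary counts as in-class (conservative
toward the target class).  Scenario 1 sets each threshold to
(1 + 1e-6) × the model's largest calibrated EVOO per-sample distance —
zero calibration false negatives by construction.  Scenario 2 searches a
common quantile of the per-model EVOO calibration distances over the
grid 0.50 … 1.00 (step 0.01), maximizing fused admixture detection
subject to a fused EVOO correct rate ≥ 0.75, ties resolved toward the
higher EVOO rate and then the lower quantile; an infeasible floor falls
back to scenario-1 thresholds with a logged warning.  The search
procedure behind the published two-scenario idea is not documented
anywhere; this grid-over-quantiles rule is this package's own
reconstruction.  When the calibration data are strongly
separated the scenario-2 optimum can coincide with scenario 1 (no
trade-off exists to make); at other seeds the generator produces the
genuine trade-off, with scenario 2 trading a lower EVOO rate for full
admixture detection.

Single-sensor report columns rerun the identical fusion machinery
restricted to one sensor's selected models, with the quorum rescaled as
max(1, round(min_votes · n_sensor / n_total)).

## Problem sizes and runtimes

The default synthetic study is generated and reduced at full scale
(1161 runs, ≈ 300 k NIR scans, streamed one run at a time so peak memory
stays at a few MB).  The test suite exercises module logic on miniature
designs (8 EVOOs, 3–5 scans per run) and runs the full-scale study once
with a reduced grid (2 preprocessings × 2 splits × 5 algorithms,
2 outer repeats); the acceptance script runs the complete 150-point grid
with 5 outer repeats.

## Known limitations

* Gaussian, symmetric bands; real pigment bands are asymmetric.  Band
  shape is irrelevant to the pipeline logic and Gaussians keep oracles
  analytic.
* Independent per-band between-sample variation (see above) — the main
  reason synthetic admixture detection saturates at 100 %.
* Linear volume mixing of latent spectra ignores inner-filter and
  matrix effects.
* No geographic-origin structure, no photochemically accurate
  chlorophyll/pheophytin kinetics.
* The reference-chemistry checker (`check_reference_limits`) only
  verifies tabulated regulatory limits (peroxide ≤ 20 mEq O₂/kg,
  K232 ≤ 2.5, K268 ≤ 0.22, ΔK ≤ 0.01, MCPD/GE esters strictly below
  0.10/0.07/0.07 mg/kg, censored "<LOD" values passing); it does not
  model the wet-lab assays.
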