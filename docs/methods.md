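# Methods

## Scope and model

`headcrit` evaluates how well standard head injury criteria predict the head
injuries actually sustained by vulnerable road users (VRUs — pedestrians,
cyclists, electric-two-wheeler riders) struck by cars. Its inputs are the two
kinds of signal an accident reconstruction produces:

1. **Head-COG kinematics** — time histories of 3-axis linear acceleration,
   rotational acceleration and rotational velocity at the head's centre of
   gravity; these feed the five kinematics-based criteria.
2. **Brain element fields** — per-element volume plus first-principal-strain
   and pressure histories from a finite-element brain model; these feed the
   three deformation-based criteria.

Injury outcomes are Abbreviated Injury Scale scores: per-injury AIS for
diffuse axonal injury (DAI) and contusion, and the head-region maximum (MAIS),
all on the 0–6 scale.

## Kinematics-based criteria

With a(t) the resultant linear acceleration in g, α(t) the resultant
rotational acceleration in rad/s², and ω(t) the resultant rotational velocity
in rad/s:

* **HIC15** = max over windows [t₁, t₂] with 0 < t₂−t₁ ≤ 15 ms of
  (t₂−t₁)·[(1/(t₂−t₁))∫a dt]^2.5. Window endpoints are restricted to sample
  times; no interpolation. A `hic_window_max` override gives HIC36.
* **RIC** — the same maximization on α(t) with a 36 ms window. The cap is
  implemented as ≤ 36 ms rather than exactly 36 ms, for symmetry with HIC15;
  for unimodal pulses the two are equivalent, because extending a window of a
  non-negative signal at fixed mean never lowers the objective's maximizer
  class. Records shorter than 36 ms are evaluated over their full duration
  with a logged warning.
* **GAMBIT** = [(a_max/a_cr)ⁿ + (α_max/α_cr)ᵐ]^(1/s) with a_cr = 350 g,
  α_cr = 12 000 rad/s². The exponents are not standardized in all published
  forms; the defaults n = m = s = 2 are the common quadratic form and are
  configurable.
* **HIP** = max over t of m·Σᵢ aᵢ(t)∫₀ᵗaᵢ dτ + Σᵢ Iᵢᵢ·αᵢ(t)∫₀ᵗαᵢ dτ, with
  m = 4.5 kg, I = (0.016, 0.024, 0.022) kg·m², linear channels in m/s².
  Reported in kW. The signed maximum is taken — rebound power is negative and
  must not be rectified into a spurious peak.
* **BrIC** = ω_max/ω_cr + α_max/α_cr with ω_cr = 140 rad/s and
  α_cr = 12 000 rad/s². This additive form (with a rotational-acceleration
  term) is the variant used throughout this package; the axis-specific
  velocity-only form is out of scope.

**Window search.** HIC/RIC maximize over all O(n²) sample-time pairs using a
prefix trapezoidal integral: the window mean is (I[j]−I[i])/(t[j]−t[i]), and
for each start index the admissible end indices (those within the window cap)
are scanned vectorized. An independently coded exhaustive search — plain
per-window trapezoid accumulation — is kept in the test suite as the oracle;
the two agree to 1e-9 relative on random pulses up to 500 samples. Ties in
the objective may legitimately resolve to different windows; only the value
is compared.

**Units.** Channels are stored as read and converted lazily. The g constant
defaults to 9.81 m/s² and may be set to 9.8 to match sources that round it;
conversions are logged. HIC computed from the same signal stored in g or in
m/s² is identical after conversion (tested).

**Filtering.** Channel-frequency-class (CFC) filtering is available —
a 2-pole Butterworth run forward and backward (4-pole, phaseless) with the
−3 dB point at 1.65× the class frequency, requiring uniform sampling — but is
never applied implicitly: the default class is `none`, a bit-identical
passthrough.

**Integration.** Trapezoidal throughout: second-order accurate, exact for
piecewise-linear signals, and well-defined on non-uniform time grids (which
are accepted for integration but rejected for filtering).

## Deformation-based criteria

* **MPS** — the global maximum of first principal strain over all elements
  and timesteps. It is an element-wise maximum, not a volume percentile:
  published per-case values above 1.0 (up to 2.457 in the packaged DAI
  sub-table) are impossible for percentile-capped definitions on typical
  fields.
* **CSDM_x** — the fraction of total brain volume in elements whose strain
  exceeds threshold x (0.15 or 0.25) at *any* timestep (once-exceeded
  semantics).
* **DDM** — the fraction of volume whose pressure ever falls below a negative
  (tensile) threshold, default −100 kPa, with positive pressure meaning
  compression.

Exceedance comparisons are strict (`>` for strain, `<` for pressure);
boundary-equal elements are excluded. This follows the "exceeding a
threshold" reading and is configurable to inclusive. Element volumes are
treated as constant initial volumes — no time-varying volume data exist in
the packaged study. Strains are consumed as provided by the upstream solver
(first principal Green–Lagrange); no tensor computation is performed here.

## Evaluation against injury records

The evaluation statistic is the sample Pearson correlation
r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)²·Σ(yᵢ−ȳ)²) between each criterion column and
MAIS, with MAIS treated as numeric 0–6 — deliberately mirroring the source
analysis rather than using an ordinal method (a Spearman option exists for
sensitivity checks but is excluded from reproduction runs). All 31 cases
enter the MAIS analysis; the DAI and contusion sub-analyses use only the 8
and 7 cases with the respective AIS recorded (listwise exclusion of missing
sub-scores only). A constant input vector raises an error rather than
returning 0. Criteria are ranked by |r|.

Risk curves mapping a criterion value to an injury probability are pure
configuration: logistic p = 1/(1+e^−(b₀+b₁v)) with b₁ ≥ 0, or Weibull
p = 1−exp(−(v/λ)^k), both monotone with range [0, 1]. The literature curves
the packaged study cites are not parameterized in any packaged source, so the
shipped `default_risk_curves.yaml` contains plausible curves labelled as
approximations; they demonstrate the pipeline and are excluded from all
quantitative acceptance checks. Predicted probabilities are therefore
qualitative; the one robust statement — DDM values ≤ 0.0431 map to
near-floor contusion probability under any monotone curve anchored at the
published scales — holds regardless of the exact parameters.

## Packaged study tables

The 31-case accident study tables ship as checksum-verified CSV resources:
case metadata, injury ratings, per-case kinematic criterion values, and the
DAI (8 cases) and contusion (7 cases) deformation sub-tables. They are
stored verbatim, quirks included (one case has MAIS 4 with no DAI score;
another has MAIS 4 with no sub-injury listed at all — injuries outside the
two sub-studies); nothing is imputed. Vehicle dimension strings were split
into three integer fields when the resources were built. Reproducing the
published correlation table from these fixtures is deterministic; the
largest |computed − published| discrepancy is 0.0004, comfortably inside the
0.01 tolerance used by `reproduce_table5`.

## Synthetic data

The study's raw reconstruction outputs are not public, so generators with
known ground truth stand in for them. They are statistical emulators, not
biomechanics: passing tests on them demonstrates the *criteria and
evaluation machinery* are correct, not that any physical reconstruction is.

* **Pulses** (`synth_pulse`): constant, haversine (A·sin²(πt/T), the smooth
  standard idealization) and triangular shapes, each channel group scaled
  along a unit direction vector. Defaults (100 g linear, 5 000 rad/s²
  rotational, 40 rad/s, 20 ms, 0.1 ms sampling) sit in the mid-severity range
  of the packaged cohort. For constant pulses all five criteria have closed
  forms (e.g. HIC = A^2.5·min(T, 15 ms)); for the smooth shapes GAMBIT/BrIC
  remain exact and HIC/RIC/HIP ground truth is computed on a 16× finer grid
  and flagged as numeric. Closed forms are exact only when the window cap
  lands on the sample grid (it does at the default step). Real head pulses
  are multi-modal with rebound phases and sensor noise; these are not
  emulated.
* **Element fields** (`synth_element_field`): exceedance targets are met by
  construction, not sampling — elements are assigned to nested exceedance
  sets by greedy volume accumulation (largest first) until the target volume
  fraction is reached, then peak strains/pressure troughs are drawn strictly
  inside their band so strict comparisons classify exactly. Unreachable
  targets (with equal volumes, anything that is not a multiple of 1/n) raise
  an error naming the nearest reachable fractions; with unequal volumes the
  greedy prefix may miss an exactly-representable subset-sum — acceptable for
  a generator whose job is delivering a *known* fraction, since the achieved
  fraction is stored as the ground truth.
* **Cohorts** (`synth_cohort`): a standard-normal latent severity per case is
  discretized into MAIS 0–6 at fixed cut points (−1.1, −0.55, 0, 0.55, 1.1,
  1.65), giving a realistic MAIS spread with few 6s. The criterion value is a
  monotone link of severity (default: the MAIS score itself) plus Gaussian
  noise. When `noise_sd` is unset it is calibrated in closed form from the
  realized link/MAIS sample moments so the cohort's Pearson association
  approaches `target_r`: σ² = (cov(L,M)/r)²/var(M) − var(L); an explicit
  `noise_sd` overrides the calibration. At n = 5 000 the recovered r is
  within ±0.03 of a 0.6 target, consistent with the ≈(1−r²)/√n sampling
  error. Each generator draws from one seeded stream; seeds are mandatory.

## Numerical and design choices

* Trapezoidal integration everywhere a criterion integrates a channel.
* Window endpoints at sample times only; no sub-sample interpolation of
  peaks or windows.
* HIC/RIC window-cap comparisons use a 1e-9 relative tolerance so grid
  points nominally on the cap are admitted despite floating-point drift.
* Pearson r is clipped to [−1, 1] after computation to absorb rounding at
  |r| ≈ 1; reported tables round to 3 decimals, tests compare with
  tolerances, never by rounding.
* Records with fewer than 2 samples, non-monotone time, NaNs, non-positive
  volumes or ragged element grids are rejected at construction, not deep in
  a computation.

## Problem sizes

The test suite and acceptance script run in seconds: window-search oracle
equivalence uses 100 random pulses of 30–500 samples; deformation properties
use 100 constructed 50-element fields; cohort recovery uses n = 5 000. The
full published-table reproduction involves only 31 cases and is effectively
instant.

## Limitations

* The package evaluates criteria given reconstructed signals; it performs no
  accident reconstruction, multibody simulation or FE solving, and ships no
  per-case kinematics (none are public).
* Figure-level risk-probability values are not reproducible without the
  cited curves' parameters; only curve *properties* (monotone, bounded,
  logistic midpoint) are asserted.
* Pearson correlation on an ordinal 0–6 outcome is retained for fidelity to
  the source analysis, not because it is the best ordinal method.
* The synthetic cohort's criterion–severity link is homoscedastic Gaussian;
  real criterion values are heteroscedastic and heavy-tailed (the packaged
  RIC column spans 3.5×10⁶ to 8.5×10⁸).
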