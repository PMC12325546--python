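# Methods

`myostiff` quantifies how individual myofilament systems (actin thin
filaments, titin springs, and the myosin–titin composite "thick" filament)
contribute to the passive stiffness of cardiac muscle, separately along the
transverse axis (AFM nanoindentation of tissue slices) and the longitudinal
axis (tensile stretch of permeabilized fiber bundles and cardiomyocytes).
Because no raw instrument data accompany the study design the pipeline
operationalizes, every stage runs on synthetic inputs with known ground
truth; the worked numerical examples (the LTQ quotients and the additivity
arithmetic) use the published treatment medians directly.

## Transverse stiffness: windowed linearized-Hertz estimation

### Contact model

A rigid sphere of radius *r* indenting an elastic half-space of Young's
modulus *E* (Poisson ratio ν) carries the Hertz force

    F(δ) = (4/3) · E/(1 − ν²) · √r · δ^(3/2),

with δ the indentation depth. On an AFM, the observables are piezo height
*z* and cantilever deflection *d*; the force is *F = k·d* (spring constant
*k*) and the indentation is δ = (z − z_c) − d beyond the contact height z_c.
Defaults follow the experimental configuration: r = 4.9 µm, ν = 0.5,
k ∈ [0.224, 0.407] N/m (0.3 N/m default), maximum load ≤ 10 nN.

### The windowed slope and why it is Δ(F^{2/3})/Δd

The modulus is estimated inside two force windows, 2.00–2.25 nN and
4.00–4.25 nN (width ΔF = 0.25 nN), as

    E = (3/4) · S^(3/2) · (1 − ν²)/√r,

where *S* is the least-squares slope of F^(2/3) versus δ over the window
samples. Two readings of "ΔF^(2/3)/Δd" are conceivable; they differ
materially:

* **slope of F^(2/3) vs δ** (default, `pointwise_f23`): on an exact Hertz
  curve F^(2/3) is globally *linear* in δ, so this returns the true E for a
  window placed anywhere — the property that makes the two-window design
  coherent and that the test suite asserts at 0.5%;
* **(ΔF)^(2/3)/Δd** (`endpoint_ratio`, kept behind a switch for
  comparison): correct only for a window starting at zero force; at the
  4.00–4.25 nN window it misestimates a 1 kPa sample by well over 50%.

The first reading is therefore the implementation; the estimator is the
exact algebraic inverse of the generator, which the round-trip tests
exploit.

### Contact-point detection

The analysis software used in the original workflow does not document its
contact algorithm, so the method here is the package's own:

1. fit a line (baseline tilt) to a leading fraction of the ramp (default
   30%);
2. guard against the contact lying *inside* that region: halve the region
   while a quadratic term fitted to it is statistically significant
   (|c₂| > 4·SE(c₂)) — a straight noisy baseline has no curvature, a Hertz
   onset does;
3. take the first height where the tilt-corrected deflection exceeds
   `threshold_mult` (default 3) × baseline residual RMS and stays above it
   for `min_run` (default 5) samples;
4. refine by regressing F^(2/3) on (z − d) over the early-contact region
   (forces up to 25% of the curve maximum) and extrapolating to zero force.
   This refinement is exact on a noiseless Hertz curve because
   F^(2/3) = S·((z − d) − z_c).

All parameters are configurable. Note the windowed slope itself is invariant
to a pure contact-point shift (it only translates δ); contact accuracy
matters mainly for sample retention and QC.

### Noisy recordings

Deflection noise enters F^(2/3) and, through window selection on the noisy
force channel, attenuates the fitted slope. `analyze_curve(smooth_window=w)`
therefore applies a centred moving average to the deflection before
estimation. Because F^(2/3) is linear in δ over the *entire* contact,
local averaging does not bias the windowed slope while suppressing noise by
≈√w. Contact detection always runs on the raw channel — smoothing
correlates the noise, which defeats both the RMS threshold and the run-length
logic. With 0.5 nm deflection noise and w = 51, 200 replicate curves recover
a 1 kPa modulus to within ~2% in the mean; the 4.00–4.25 nN window shows the
lower coefficient of variation because the relative noise on F^(2/3) falls
with force.

### QC and aggregation

Per-curve estimates are flagged (and excluded from aggregation) when the
window holds fewer than `min_points` (default 5) samples, the slope is
non-positive, or the contact point falls in the last 10% of the ramp.
Per-location stiffness is the arithmetic mean of the surviving per-curve E
values (a median option exists); the study design averages ~7 indentations
per location. Force-map repeatability is a one-way random-effects
decomposition of log-E (the stiffness field is right-skewed) into
between-pixel and between-repeat variance by the method of moments.

## Longitudinal stiffness: stretch-peak analysis

Step-stretch protocols hold each commanded strain level (percent of slack
length) for a fixed duration; only the *peak* force per level is analyzed,
since the hold relaxes viscoelastically. Hold windows are the plateaus of
the strain-command signal. A guard band (default 5% of the plateau) is
trimmed from the *end* of each hold only: the informative peak sits at the
hold onset, so a start-side guard on a relaxing hold would bias peaks low;
`guard_start` exists for instruments whose command ramps rather than steps.

Three normalization conventions mirror the three preparations:

| mode             | reference                                  | preparation        |
|------------------|--------------------------------------------|--------------------|
| `max_pre`        | pre-phase peak at the longest stretch      | fresh fiber bundles |
| `ref_strain_pre` | pre-phase peak at a reference strain (25%) | glycerinated fibers |
| `pre_mean`       | pre-phase peak at the same strain          | cardiomyocytes     |

`max_pre` is applied per fiber (whether the original convention was
per-fiber or per-cohort is ambiguous; per-fiber keeps fibers comparable).
Relative force changes, reduction = (1 − post/pre)·100, are computed on raw
peaks per fiber and strain — the estimand is invariant to any normalization
whose reference is shared by the two phases — then summarized per strain by
the median with a distribution-free 95% CI. Force–strain relations are
summarized by unweighted second-order polynomial fits.

## Statistics

* **Paired changes**: rel_change = post/pre·100 per location (treatment
  view) and post/median(pre cohort)·100 (variability view).
* **Tukey screen**: fences Q1 − k·IQR, Q3 + k·IQR with k = 1.5; quartiles
  by linear interpolation of order statistics (conventions differ across
  software; this one is fixed and documented). Gaussian expectation of the
  flag rate is ≈0.7%.
* **ROUT screen** (Q = 1%): implemented for the pooled, constant-location
  model, since it is applied to stiffness-change values rather than a
  regression. Residuals from the median; robust scale = 68.27th percentile
  of absolute residuals × n/(n−1) (the RSDR); per-point t-like statistics on
  n−1 df tested from the most extreme inward with the sequential rule
  p₍ᵢ₎ < Q·(n−i+1)/n. A zero scale with off-median points flags exactly
  those points; an all-constant sample is reported as degenerate.
* **Relationship screen**: robust (repeated-median) fits of post on pre in
  linear and log–log space; a pair is excluded only when its standardized
  robust residual exceeds 3.5 under *both* models (the conjunction makes the
  screen deliberately conservative — it targets unmatched measurement
  locations, not distributional outliers).
* **Box–Cox**: λ maximizing the profile log-likelihood on the grid
  [−2, 2] step 0.01 (λ = 0 handled as log); engaged automatically when a
  Shapiro–Wilk test rejects normality at α = 0.05 — the codeable stand-in
  for quantile–quantile inspection.
* **Mixed model**: response ~ treatment (+ compression-force level when two
  levels are present) with a random intercept per measurement location,
  fitted by REML (statsmodels MixedLM). Fixed-effect p-values refer the Wald
  statistic to a t distribution with (paired locations − 1) degrees of
  freedom — the containment df of a within-location effect; the asymptotic
  normal reference rejects ~7% under the null at these cohort sizes, the t
  reference ~5% (≤6% over 2000 simulated null replicates). Bonferroni
  adjustment over the tested fixed terms.
* **Median ± 95% CI**: the classical sign-test order-statistic interval for
  n ≥ 6 (coverage ≥ nominal by the binomial argument); a seeded percentile
  bootstrap below that, with the method recorded.
* **One-sample t-test vs 100%** for single-level cardiomyocyte changes;
  **Mann–Whitney** (exact for small tie-free samples) for unpaired
  comparisons.

## The LTQ metric and additivity

For each filament system the longitudinal-to-transverse quotient is

    LTQ = (longitudinal median reduction) / (transverse median reduction),

reported half-up at two decimals, at two matched mechanical levels: **low**
pairs 10–12% fiber strain with the 2.00–2.25 nN window, **high** pairs 20%
strain with 4.00–4.25 nN. The longitudinal strain entering the low level is
10% for titin and thick-filament interventions and 12% for actin — the
lowest strain at which each intervention's reduction is resolved; this
pairing reproduces all six published quotients exactly (0.73/0.84 actin,
2.91/2.66 titin, 1.42/1.57 thick). CIs are not propagated through the ratio
(the quotients are point summaries).

Sequential-treatment additivity is arithmetic in baseline percentage points:
the second step's "additional" reduction adds to the first (24.2 + 18.7 =
42.9 observed), compared against the sum of standalone effects (20.6 + 33.5
= 54.1 predicted); the gap measures sub-additive (cooperative) filament
interaction.

## Synthetic-data generator: what it emulates, what it does not

* **Force curves**: exact Hertz contact with cantilever compliance — the
  deflection solves k·d = F((z − z_c) − d) per sample by a bracketed root
  finder at 1e−12 relative tolerance — plus linear baseline tilt and
  additive Gaussian noise on the *deflection* channel (the measured one).
  The instrument's actual noise magnitude and drift are not published;
  defaults (0.5 nm noise, tilt ~1e−3 when exercised) are configurable
  assumptions.
* **Stiffness fields**: log-normal around a 963.3 Pa median (the observed
  baseline median; the observed distribution is non-normal and
  right-skewed), dispersion 0.5–0.7 log-units.
* **Paired cohorts**: E_post = E_pre·(1 − effect/100)·exp(ε) with zero-median
  log-scale residual ε, so the generated *median* reduction equals the
  nominal effect exactly.
* **Stretch traces**: instantaneous strain steps landing exactly on a
  sample, quadratic peak law a·ε + b·ε², single-exponential hold relaxation
  (the shape is free since only peaks are analyzed), Gaussian force noise.

Not emulated: adhesion on retract, nonlinear drift, viscoelastic
(rate-dependent) indentation, finite section thickness (bottom effect),
sarcomere-length-based strain, and ECM heterogeneity structure. Passing
tests therefore demonstrate correctness of the *analysis* under the stated
physics, not robustness to every artifact of real recordings.

## Problem sizes and numerical choices

Test and acceptance runs use curves of 1500 samples with the ramp sized per
stiffness (contact at one third of the span, post-contact travel 1.3× the
travel needed to reach 4.25 nN), 200-replicate noise studies, paired cohorts
of 90 locations (40 for null calibration, 2000 replicates), 400-replicate
outlier-screen calibrations, and 8–10-fiber stretch cohorts — sizes at which
the Monte-Carlo bounds asserted by the tests are comfortably stable.
Root-finding uses brentq on a guaranteed bracket; window membership is a
closed interval; ties and degenerate inputs (constant samples, zero robust
scale, singular mixed-model fits) raise explicit, typed errors rather than
propagating silently.

## Known limitations

* The ROUT implementation targets the pooled constant model; it is not a
  general robust-regression outlier procedure.
* Mixed-model equivalence with the original SPSS analysis is asserted at the
  level of estimand definitions, not software settings.
* The LTQ is reported without uncertainty; propagating the component CIs
  would require the unpublished per-fiber data.
* The simulator's Hertz physics is the same model the estimator inverts;
  real-data model misfit (e.g. substrate stiffening) is out of scope by
  design.
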