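# Methods

## Model structure and assumptions

The package implements a two-stage relative-risk model in which free serum
estradiol (E₂F, mol/L) is the sole mediator between body mass index and
breast-cancer risk.

**Stage 1 — concentration.**  ln E₂F is linear in BMI
(`LogLinearModel(slope, intercept)`); natural logs are used everywhere
internally.  Three such lines are carried: postmenopausal non-users
(slope 0.068847 /(kg/m²), intercept −29.984, so estradiol rises ~7% per BMI
unit), premenopausal follicular phase (slope −0.039851, intercept −24.906),
and the dimensionless ERT-user/non-user concentration ratio
(slope −0.023098, intercept 1.2617).  The ERT-user concentration model is the
coefficient-wise sum of the base and ratio lines.

**Stage 2 — risk.**  Risk is log-linear in log concentration: a doubling of
E₂F multiplies risk by RR_d (1.50 postmenopausal, 1.7018 premenopausal
follicular).  The exponent applied to a concentration ratio is stored as
ln(RR_d)/ln 2, so no base conversions are repeated at evaluation time.

**Saturation.**  For postmenopausal equations, concentrations are clipped at a
cap before the ratio is taken.  The default cap is the printed operative
constant 7.50×10⁻¹³ mol/L; setting `saturation_cap: computed` in the config
uses the non-user concentration at BMI 30 instead (the two differ in the 4th
significant figure: 7.5008×10⁻¹³).  The premenopausal model has no cap and no
option to enable one — its defining equations contain no saturation operator.
The cap produces three qualitative behaviours the model is designed to
capture: a risk plateau for non-users above BMI 30, a flat BMI–risk profile
among ERT users (whose concentrations exceed the cap for all BMI ≥ 17.6), and
attenuation of the ERT excess risk with increasing BMI, reaching exactly 1.0
at BMI 30.

**Reference BMI.**  All relative risks are referenced to BMI 23 (configurable)
— a typical, healthy value near the centre of the BMI scale.  Composed models
fix their intercept from the condition RR(23) = 1 rather than from any printed
constant, so intercepts are internally consistent with slopes by construction;
printed intercepts are used only as test targets.  The composed ERT-user model
uses the *saturated* reference concentration min(cap, E₂F_ERT(23)) = cap.

**Validity ranges.**  BMI ≤ 0 is a hard error; BMI outside [15, 50] and
concentrations outside [10⁻¹⁵, 10⁻¹⁰] mol/L trigger `ModelValidityWarning`
(the validation studies span roughly BMI 18–35; extrapolation is flagged, not
forbidden).  The low-BMI end is genuinely unanchored — the ERT-vs-nonuser
equation grows without bound as BMI → 0 — which is why the warning floor sits
at 15.

## Fitting pipeline

All shipped constants are reproducible from summary tables:

* **Concentration fits** are unweighted OLS of per-stratum mean log E₂F on
  median BMI, requiring ≥ 3 strata (tables with fewer are excluded by rule).
  A `weight_by_n` option (per-stratum counts) exists for sensitivity analysis;
  the default is unweighted because stratum weighting is not part of the
  reference procedure.
* **ERT ratio fit**: OLS of the per-stratum difference of user and non-user
  mean log concentrations on median BMI (the log of the ratio of geometric
  means), requiring matched categories.  When weighted, the weight is the
  harmonic combination 1/(1/n_user + 1/n_nonuser), the inverse variance of a
  difference of two stratum means.
* **Per-doubling risk**: on a log-log plot of RR vs E₂F quantile midpoints,
  a least-squares line constrained through the reference quantile (RR = 1):
  slope s = Σwxy/Σwx² over non-reference rows, RR_d = 2^s.  Including the
  reference row in the residual sum is offered as a variant but is a no-op
  (its residual is identically zero), so both readings of "fitting a line
  through the reference value" coincide.  Case-count weighting is optional and
  off by default.  When a quantile table gives category bounds instead of
  midpoints, the geometric mean of the bounds should be used (fits are on the
  log scale); open-ended categories need explicit representative values.

Fits are backed by statsmodels OLS/WLS; the test suite cross-checks every fit
against a hand-rolled normal-equations solver.

## BMI distributions and population averaging

Parametric BMI distributions (lognormal, normal) are discretized on a
0.1 kg/m² grid over [15, 60] by default, each grid point receiving its cell's
CDF mass, renormalised over the support; this is well below the
refinement-stability tolerance (halving the step changes averaged risks by
< 10⁻⁴).  Conditional category medians interpolate linearly within grid cells
(deterministic and resolution-robust); single-point categories return the
point.

The shipped stand-in for the BMI distribution of US postmenopausal women is
lognormal with μ = ln 27.5 and σ = ln(31.5/24)/(2·0.67449) ≈ 0.2016, i.e.
matched to approximate quartiles 24 / 27.5 / 31.5 kg/m² of US
postmenopausal-age women (implied mean ≈ 28.1, SD ≈ 5.7).  It is a documented
synthetic approximation, not survey microdata: no survey weights, cycles, or
age/sex restriction structure.  Averaging the ERT-vs-nonuser risk over it
gives a population relative risk of ≈ 1.16; this figure should be read as
distribution-dependent (it decreases as the distribution shifts toward higher
BMI, since more mass lands on the saturated RR = 1 region).  Whether such an
average should be taken over never-users' BMI distribution or all
postmenopausal women is a modelling choice; any distribution can be supplied
via CSV or config.

## Validation machinery

Published RR-by-BMI-category tables (one reference category with RR 1 and no
CI) are compared with the model in three steps.  Representative BMIs: interior
bounded categories use the arithmetic midpoint (identical under closed or
half-open bound conventions); the lowest and highest categories — and any
open-ended category — use the conditional median of a supplied BMI
distribution.  Re-referencing: all RRs and CI bounds are divided by the
study's observed RR at the common reference BMI, obtained by log-linear
interpolation of ln RR between the bracketing categories (a nearest-category
option exists).  CIs are divided by the same divisor with no variance
propagation for the divisor's own uncertainty — the operation supports
re-plotting published intervals on a new reference, nothing more.  Rescaling
preserves all between-category ratios and is idempotent.  Calibration:
observed vs predicted RRs are fit by OLS and by case-count-weighted WLS, on
the RR scale by default (published calibration lines are of order slope 1,
intercept 0, consistent with either scale); a log-scale option regresses
ln(observed) on ln(predicted), under which a power distortion
observed = predicted^k appears directly as slope k.

Study fixtures used in tests are synthetic lookalikes produced by the
generator below; the package contains no values from the actual validation
cohorts (Pooling Project, EPIC, Million Women Study, CPS-II, WHI), whose
tables are not publicly printed.

## Synthetic-data generator

The generator owns the study conditions under which the pipeline is tested.
Noise enters only on the log scale, since every model relation is log-linear:

* concentration tables: mean_log_e2f = slope·median + intercept + ε,
  ε ~ N(0, sd/√n) — the sampling error of a stratum mean of n women with
  log-scale spread sd;
* quantile RR tables: ln RR = exponent·(ln E₂F − ln E₂F_ref) + ε, reference
  row exactly 1;
* study tables: ln RR = power·ln(model prediction) + ε, re-expressed against
  the study's own reference category; 95% CIs from
  SE(ln RR) = √(1/cases_i + 1/cases_ref), the standard lognormal
  approximation (no SE model is prescribed by the source figures);
* default category scheme <22.5, 22.5–25, 25–27.5, 27.5–30, ≥30, mirroring
  common epidemiological cuts.

Identical parameters and seed give byte-identical CSVs (seed and parameters
are recorded in a header comment).  The default seed is 20120116; all
Monte-Carlo tests pass explicit seeds.  What passing tests show: the fitting,
composition, rescaling and averaging machinery is correct under the model's
own assumptions (log-linearity, independent lognormal noise, exact category
structure).  What they do not show: anything about assay variability,
correlated errors across strata, residual confounding, or the adequacy of the
mediation hypothesis on real cohort data.

## Numerical choices and problem sizes

* All powers are computed as exp(exponent·ln ratio) in double precision;
  closed-form composed lines agree with the explicit two-stage pipeline to
  1e−10 relative over a 1,000-point BMI grid on [15, 45].
* The ERT-user reference concentration at BMI 23 evaluates to
  9.6170×10⁻¹³ mol/L under the default coefficients (the product of the base
  and ratio models).
* Monte-Carlo test sizes were chosen for tight statistical checks at
  interactive runtimes: 1,000 replicates for fit-bias checks (σ = 0.1,
  n = 100/stratum), 500 replicates for log-scale calibration-slope recovery,
  300 for variance-shrinkage comparisons.
* Degenerate inputs: a per-doubling RR of 1 is allowed and yields RR ≡ 1
  everywhere (useful null model); identical median BMIs raise a singular-fit
  error; a reference BMI whose concentration meets the cap is rejected
  (the composed model's reference risk would be undefined).
* CSV outputs print concentrations to 5 significant figures and RRs to 4
  decimals; comparisons against conventionally quoted values use the quoted
  precision (e.g. abstract-level RRs to 1 decimal).

## Known limitations

* Estrogen-only therapy only; combined estrogen/progestin HRT, SHBG/total-
  estradiol mass-action decomposition, receptor-subtype refinements and
  physical-activity effects are out of scope.
* Relative risks only — no absolute risk or incidence.
* The premenopausal branch rests on sparse follicular-phase summary data and
  carries wider structural uncertainty than the postmenopausal one; the
  calibration machinery exists precisely to quantify how much more extreme its
  predictions are than observations.
* The saturation threshold is a hypothesis: a hard cap is the simplest form
  consistent with the plateau phenomena; a gradually diminishing effect would
  fit the same qualitative facts.
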