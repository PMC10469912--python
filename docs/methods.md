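# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `earmorph`, and states what the synthetic cohorts do and do
not demonstrate.

## Landmark template

The ear is described by 41 points: seven ordered curves (outer helix 12,
inner helix 8, concha 6, lobe 5, tragus 3, antitragus 3, crus helicis 3)
plus one free anatomical point (intertragic incisure). No antihelix points
exist in the catalogue — antihelix annotations are not reproducible between
raters and are excluded. The interior points of every curve are
semilandmarks (26 of 41); curve endpoints and free points are fixed
anatomical anchors. The exact point catalogue is an artifact definition: the
published work reduced a 55-point template to 41 retained points without
listing them, so this package defines its own fixed catalogue honouring the
named regions. Coordinates are image pixels (x rightward, y downward,
origin top-left); all downstream geometry is convention-free after
superimposition.

## Superimposition

Pairwise superimposition removes translation, scale (unit centroid size)
and rotation; the rotation is constrained to determinant +1 everywhere.
Reflection is never fitted silently: allowing it would erase exactly the
left/right shape difference that the fluctuating-asymmetry index measures.
Left ears enter the analysis through an explicit mirror step instead.
Generalized Procrustes analysis iterates rotation-to-consensus with the
consensus re-scaled to unit centroid size each round (full-Procrustes
variant), stopping when the consensus moves < 1e-8 or after 100 rounds.
Because the photographs are uncalibrated, centroid size is never analysed.

Semilandmark sliding alternates GPA with per-configuration tangential
sliding (default 5 outer iterations, tolerance 1e-6). Tangents are unit
chords between a point's curve neighbours in that configuration. In the
default `bending_energy` mode the slide amounts solve
t = −(UᵀBU)⁻¹UᵀB(x − x̄) with B the thin-plate-spline bending-energy form of
the current consensus (kernel r²·log r², affine border (1, x, y); the
energy annihilates affine fields); `procrustes_distance` mode replaces B by
the identity, decoupling the solve per point. A near-singular reduced
system is regularized by a 1e-10 ridge with a warning. The mode's objective
is guaranteed non-increasing across outer iterations: an iteration whose
re-superimposition would raise the objective is reverted and iteration
stops. Anchors never move.

Validation (new-cohort) configurations are carried into the frozen training
frame by pairwise superimposition on the training consensus plus one
sliding pass against the frozen consensus bending form, then projection
onto the training PCA axes. Re-running the whole GPA with validation data
included would let validation ears influence the training frame, which the
train/validation split forbids.

## Shape PCA

PCA is computed by SVD of the centred flattened Procrustes coordinates
(82 columns); eigenvalues are s²/(n−1). The retained count k is the
smallest number of leading components whose cumulative variance fraction
reaches the target (default 0.90). k is data-dependent and is reported, not
asserted: on real photographs the published pipeline retained 8 components,
while the synthetic cohorts — whose fluctuating-asymmetry and measurement
noise are isotropic across landmarks rather than anatomically smooth —
spread variance across more dimensions (k ≈ 30 at default settings). This
is a known fidelity limit of the generator, not of the pipeline.

## Mixed-model covariate adjustment

Per retained component: PCᵢⱼ = α + age·β₁ + gender·β₂ + age·β₁ᵢ + εᵢⱼ, with
β₁ᵢ ~ N(0, σ_b²) a random age slope per individual and εᵢⱼ ~ N(0, σ_ε²).
Gender is coded 0 = female, 1 = male (any consistent coding only flips the
sign of β₂); there is no age×gender interaction. The model equation carries
a random slope only; because the prose description of the original design
is ambiguous ("random effect on age and individuals"), an independent
random intercept is available as an option (`random_intercept=True`,
diagonal covariance).

Fitting is REML, profiled over the variance ratio θ = σ_b²/σ_ε²: per
individual the marginal covariance is I + θzzᵀ (z the age vector), β is the
GLS solution, σ_ε² = RSS/(n−p), leaving a bounded one-dimensional search
over log θ (Nelder–Mead over two ratios with the random intercept). The
θ = 0 boundary is always compared explicitly; a boundary optimum is
returned with a `singular` flag rather than raised. Fixed-effect standard
errors come from the GLS information; the standard error of σ_b from a
finite-difference observed information in (σ_b, σ_ε). The implementation is
deliberately self-contained so that statsmodels' `MixedLM` can serve as an
independent cross-check in the test suite (fixed effects agree to 1e-4).

Residuals: *conditional* residuals subtract the individual's predicted
(BLUP) slope and are exactly mean-zero on the training data; *marginal*
residuals subtract fixed effects only. A patient unseen in training falls
back to marginal with a warning.

**Classifier features use marginal residuals on both sides.** With nearly
constant ages within a patient, the random-slope BLUP can absorb any
patient-constant shape offset — including the diagnostic group effect — so
conditional training features and marginal validation features would live
in systematically different distributions. Defining the features
identically for training and new patients avoids that shift; conditional
residuals remain available (and serialized) for model diagnostics.
Training-frozen fixed effects are applied to validation data; models are
never refit on validation cohorts.

## Severity and asymmetry scores

Severity per patient = left grade + right grade (Marx grades 0–4, where 0
is a normal ear and 1–4 are microtia grades I–IV; grades ≥ II cannot be
landmarked). Asymmetry is a mixed 0–3 scale: |left − right| when
max(grade) ≥ 2, else the normalized fluctuating-asymmetry index. Grades 0
and I are pooled for this rule, as in the clinical grade reporting. The raw
FA index of a bilateral grade 0–I patient is the full Procrustes distance
between the mirrored left and the right configuration (the age-closest
annotated pair when photographs repeat); normalization divides by the
training-cohort maximum, which is frozen and re-applied with clipping to
new data — the anchoring of "normalized between 0 and 1" is otherwise
unspecified. Patients lacking any photograph of one side have no scores and
are excluded from score-using designs. Group comparisons regress the score
on group indicators (reference group MFDM) with a patient random intercept
when repeated rows occur, and two-sided t tests on the coefficients.

## Classification designs

Features per ear: the k residuals, plus the patient's severity and
asymmetry broadcast to the patient's ear rows when the design includes
scores (the multiclass designs 2.1/2.2 by default; the binary design 1 and
genotype design 3 use residuals only). Rows missing required features are
dropped with a logged count; evaluation additionally drops validation rows
whose reference class is unknown to the trained model. XGBoost
hyperparameters: learning rate 0.3, γ = 0, max depth 6, logloss objective,
max 500 boosting rounds (reduced in the scaled-down analyses), single
thread, seeded. The iteration count is the argmin of the stratified 5-fold
cross-validated logloss curve; folds shrink with a warning when the rarest
class has fewer members than folds. No class weighting or resampling is
applied despite the control/syndrome imbalance, matching the published
design; a future option could expose it. Probabilities row-normalize to 1;
label = first maximal class in sorted label order.

## Metric conventions

Confusion matrices are prediction rows × reference columns. One-vs-all
sensitivity/specificity/balanced accuracy per reference class. In binary
reports the summary Se/Sp take the **alphabetically first label as the
positive class** — for Control/MFDM this makes "Se = 1.000" a statement
about controls, the reverse of clinical intuition; it is documented
wherever it surfaces. "Overall accuracy" is trace/total; multiclass
summaries sometimes print this very quantity as "balanced accuracy", and
the report exposes both names. The accuracy CI is exact Clopper–Pearson
(Beta quantiles); the accuracy test is one-sided exact binomial against the
no-information rate (largest reference-class frequency). AUC uses the
Mann–Whitney rank formulation with ties counted half; classes absent from
the references get NaN with a flag. The ICC is the two-way random-effects,
absolute-agreement, single-rater form ICC(2,1); the display rounding for
reports is half-up to 3 decimals (a printed source value of 0.954 for the
design-1 balanced accuracy corresponds to the computed 0.9545…).

## Synthetic cohort generator

The generator is the package's stand-in for the clinical photograph
database and defines the study conditions for every test:

- **Population.** Patients per group 471/31/9/15/24
  (control/MFDM/NAFD/TC/CHARGE) times a scale factor; validation cohorts
  default to 21/11/2/6/8 patients with exactly one photograph per ear.
  Female fractions 0.53/0.52/0.56/0.40/0.42; ages truncated log-normal
  matched to mean 7.2, SD 5.9 years, max 60.7; 1–5 photographs per patient
  at strictly increasing ages, taken in left/right pairs per visit.
- **Grades.** Per-ear Marx-grade distributions: controls, NAFD and CHARGE
  all grade 0–I; MFDM 92% grade 0–I, 3% II, 5% III; TC 80% grade 0–I, 17%
  II, 3% III. The pooled 0–I mass is split 70/30 between grades 0 and I (the
  split is not published; both are annotatable so nothing downstream
  depends on it). Grade ≥ II ears carry no landmarks. MFDM genotype classes
  follow the published cohort: splice 11/31, frameshift 9/31, nonsense
  7/31, deletion 4/31 — and carry **no** shape effect, matching the
  negative genotype–phenotype finding.
- **Shape model.** A stylized right-ear polyline (~170 px centroid size) on
  elliptical arcs. Group effects are fixed unit-norm displacement fields
  scaled by one parameter: MFDM — clockwise concha rotation, vertical
  concha shift, enlarged lobe, thickened helix; CHARGE — triangular concha,
  reduced lobe, thinner helix; TC — strongly reduced lobe, vertical
  stretch, displaced tragus; NAFD — expanded upper helix, lowered inner
  helix, prominent antitragus. The default effect scale is 18 px: the
  published work gives no quantitative effect sizes, and the package's
  stated default condition is *separable* groups (deformation clearly
  dominating the noise fields), making the scale a power knob, not an
  estimate.
- **Covariates and asymmetry.** Age acts on a lobe-elongation field at
  0.35 px/year (global growth would vanish under Procrustes scaling, so the
  age effect must be a shape change); gender on a concha/helix-width field
  at 2 px; per-individual random age slopes SD 0.12 px/year. Directional
  asymmetry is ±1.5 px on a whole-ear rotation/tragus field (opposite signs
  per side); fluctuating asymmetry is an i.i.d. per-coordinate field per
  ear, stable across that ear's photographs, with per-group SD 0.5 (control)
  / 1.5 (MFDM) / 1.1 (NAFD, TC) / 0.8 (CHARGE) px — ordered to reproduce
  the qualitative clinical finding that MFDM ears are more asymmetric than
  controls and CHARGE. Measurement noise 0.7 px per coordinate per
  photograph; each photograph receives a random similarity jitter (±0.25
  rad, ×e^±0.2, ±30 px) emulating uncalibrated framing.

**What passing tests show — and don't.** The synthetic cohorts verify the
pipeline end to end: superimposition invariances, covariate recovery,
score rules, separable-group recovery (> 0.9 held-out accuracy), chance
behaviour under null effects, and genotype non-separability. They do not
emulate photographic texture, automatic-landmarking error structure,
anatomically smooth biological variation (noise here is isotropic per
landmark), ethnicity, or clinical label noise — so synthetic accuracies say
nothing about performance on real photographs, and the published
real-photograph results are exercised only through the fixture confusion
matrices.

## Problem sizes in the shipped analyses

The analysis drivers and the acceptance script run the training simulation
at scale 0.5 of the emulated clinical population (~800 ear photographs) —
large enough for stable boosting while keeping a full run in tens of
seconds — and evaluate both on the study-sized 48-patient validation cohort
(drivers) and on an enlarged held-out cohort of 150 patients (acceptance),
the latter because a 27-row 4-class sample cannot estimate an error rate
more finely than 1/27. The mixed-model recovery harness uses 200 patients ×
3 photographs × 100 seeds. The 10⁻⁸/10⁻¹⁰ geometric tolerances in the tests
reflect double-precision algebra, not biological precision.

## Known limitations

- The semilandmark mask and the 41-point catalogue are artifact choices;
  results on real data would depend on the clinical template.
- FA is whole-configuration Procrustes-based; per-landmark FA variants are
  not implemented.
- Marginal-residual features discard individual-level adjustment for
  training patients (a deliberate trade against train/validation shift).
- UMAP determinism holds for a fixed seed and single-threaded execution.
- No probability calibration, class weighting, AUC confidence intervals or
  DeLong tests.
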