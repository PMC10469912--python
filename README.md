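# earmorph

Landmark-based geometric morphometrics and machine-learning classification of
external-ear (pinna) shape, built for syndrome diagnosis support in
craniofacial dysmorphology. The package models the ear phenotype of
**mandibulo-facial dysostosis with microcephaly (MFDM** — caused by
heterozygous *EFTUD2* variants**)** against non-syndromic controls and the
main differential diagnoses: Nager acro-facial dysostosis (NAFD), Treacher
Collins syndrome (TC) and CHARGE syndrome.

It is written for two audiences: morphometricians who need a tested,
reusable implementation of the landmark pipeline (Procrustes superimposition,
sliding semilandmarks, shape PCA, covariate adjustment, asymmetry
quantification), and clinical ML researchers who need the downstream
classification designs and their full metric reports. Since clinical ear
photographs cannot be redistributed, a synthetic landmark-cohort generator
with the same statistical structure (group deformations, age/gender effects,
repeated photographs per patient, directional and fluctuating asymmetry,
microtia-grade censoring) drives every analysis and test.

## The method

Each annotatable ear is a configuration of 41 named 2D landmarks on seven
curves (outer/inner helix, concha, lobe, tragus, antitragus, crus helicis;
the antihelix carries no landmarks because its points are not reproducible
between annotators). The pipeline, landmarks onward:

1. **Superimposition.** Left ears are mirrored to the right-ear frame, then
   all configurations are registered by Generalized Procrustes Analysis
   (rotation-only, unit centroid size — photographs are uncalibrated so size
   is not interpretable). Curve points are treated as *sliding
   semilandmarks*: they move along their local tangent to minimize the
   thin-plate-spline bending energy against the consensus (Procrustes-
   distance sliding is also available).
2. **Shape space.** PCA of the Procrustes coordinates; the smallest k
   components reaching 90% of the variance are retained, giving per-ear
   scores PC₁…PC_k.
3. **Covariate adjustment.** Per component, a linear mixed model

   PCᵢⱼ ~ α + age·β₁ + gender·β₂ + age·β₁ᵢ + εᵢⱼ

   with a random age slope β₁ᵢ per individual (REML), accounting for
   repeated photographs per patient. The residuals ε are the classifier's
   inputs; new patients (whose random effects are inestimable) get marginal
   residuals, and the pipeline uses marginal residuals as features on both
   sides so that training and validation are defined identically.
4. **Clinical scores.** Per patient: severity = sum of both ears' Marx
   microtia grades (0–8); asymmetry on a mixed 0–3 scale — |left − right|
   grade when the worse ear is grade ≥ II, else a fluctuating-asymmetry
   index (Procrustes distance between the mirrored left and the right ear,
   normalized to [0, 1] by the training-cohort maximum).
5. **Classification.** XGBoost (learning rate 0.3, γ = 0, depth 6, logloss)
   in four designs — 1: MFDM vs. control; 2.1: five classes; 2.2: the four
   syndromes; 3: *EFTUD2* genotype classes within MFDM — with the iteration
   count chosen by stratified 5-fold cross-validated logloss.
6. **Evaluation.** Confusion matrix (prediction rows × reference columns),
   one-vs-all sensitivity/specificity/balanced accuracy, overall accuracy
   with exact Clopper–Pearson 95% CI and a one-sided binomial test against
   the no-information rate, one-vs-all rank AUC, ROC curves, two-rater
   ICC(2,1), and UMAP embeddings (k = 15, cosine metric, min_dist 10⁻⁶).

## Worked example

The built-in reference confusion matrices (the binary and multiclass
validation results of the original clinical study) exercise the metric
engine:

```bash
earmorph evaluate --fixtures
```

```
design 1: accuracy 0.969 [0.838-0.999] p=2.5e-05
design 2.1: accuracy 0.811 [0.648-0.920] p=0.0017
design 2.2: accuracy 0.813 [0.544-0.960] p=0.0025
```

For design 1 ([[10, 0], [1, 21]] over MFDM/Control), the engine also reports
sensitivity 1.000, specificity 0.909 and balanced accuracy 0.955 — note the
binary summary takes the alphabetically first class (Control) as positive,
so "sensitivity 1.000" means every control was recognized and the single
error is one MFDM patient classified as control.

The full synthetic pipeline (the numbered drivers under `analysis/` run it
step by step; `earmorph run-all` runs it in one go):

```bash
python analysis/05_train_and_evaluate.py
```

```
design 1: accuracy 1.000 [0.891-1.000] (NIR p = 1.4e-06); one-vs-all AUC {'Control': 1.0, 'MFDM': 1.0}
design 2.1: accuracy 0.979 [0.889-0.999] (NIR p = 3.7e-16); one-vs-all AUC {'CHARGE': 1.0, 'Control': 1.0, 'MFDM': 1.0, 'NAFD': 1.0, 'TC': 1.0}
design 2.2: accuracy 1.000 [0.872-1.000] (NIR p = 3e-11); one-vs-all AUC {'CHARGE': 1.0, 'MFDM': 1.0, 'NAFD': 1.0, 'TC': 1.0}
```

Here the generator's group deformation fields dominate its noise terms, so
near-perfect held-out recovery is the expected behaviour (it validates the
pipeline's wiring, not clinical performance — see `docs/methods.md` for what
the synthetic cohorts do and do not show).

## Layout

- `src/earmorph/` — the library: `template`, `types`, `io`, `simulate`,
  `procrustes`, `semilandmarks`, `shapespace`, `asymmetry`, `mixedmodel`,
  `scores`, `classify`, `metrics`, `embed`, `fixtures`, `pipeline`, `cli`.
- `analysis/01…07_*.py` — numbered narrative drivers writing tables under
  `results/`.
- `tests/` — unit, property and acceptance suites (oracles: complex
  least-squares Procrustes, dense TPS solves, grid searches, statsmodels
  MixedLM, pingouin ICC, sklearn AUC).
- `docs/methods.md` — the model, parameter and design documentation.
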