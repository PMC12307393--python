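# mgrade — single-sample molecular tumor grading from gene expression

Histological tumor grade (G1–G4) is a strong prognostic factor in breast,
lung and kidney cancer, but it is assigned by eye: inter-observer agreement
is imperfect, and the large intermediate class (G2) carries little prognostic
information. `mgrade` trains **molecular grade** classifiers that assign a
binary risk class — mG1 (low) vs mG3/mG4 (high) — from RNA-seq or microarray
expression of a **single sample**, with no batch correction, cohort scaling
or reference distribution.

The package is aimed at computational oncologists who want to (re)train such
a classifier on their own labeled cohorts, stratify intermediate-grade
samples, and run the downstream survival and genomic-association analyses.

## Method

**1. Survival-driven labels from an unscaled grade index.** Differential
expression between histological high-grade (G3/G4) and low-grade (G1)
samples (Welch's t on log2 expression or log-CPM; BH FDR; per-cancer
|logFC| and expression-floor filters) yields two signature sets. Each sample
gets an unscaled gene-expression grade index

```
GGI(s) = Σ_{g ∈ up-in-high} x_gs − Σ_{g ∈ up-in-low} x_gs
```

on log2 values. Candidate thresholds at 1%-step percentiles of the GGI
distribution are each scored by a univariate Cox fit of the binary split;
the cutoff with the best Wald p (ties: concordance, then |log HR|) defines
the mG1 / mG3 training labels. No pathologist scaling enters the index.

**2. Rank transformation.** For classification, each sample's geneset values
are replaced by their within-sample ascending ranks (ties averaged, missing
omitted): `[x₁ … x_N] → [1 … N]`. Ranks depend only on the ordering of genes
inside one sample, so predictions are *bit-identical* for a sample processed
alone, inside any cohort, or after any strictly increasing per-batch
distortion — the property that makes this a single-sample method.

**3. Classifier and gene elimination.** A LightGBM binary classifier is
tuned by stratified 5-fold cross-validated negative log-loss. Mean |SHAP|
attributions (native TreeSHAP) rank the genes; the two least important are
dropped, the samples re-ranked, and the loop repeats until 20 genes remain.
The geneset with the best CV loss along the trace is refit as the final
model. Published per-cancer hyperparameters are built in
(BRCA `n_estimators=500, reg_alpha=0.3, reg_lambda=0.6, max_depth=-1`;
LUAD `500/0/0.6/-1`; ccRCC `200/0/0.6/-1`).

**4. Evaluation battery.** Cox models with stage / lymph-node covariates and
cohort strata, Harrell's concordance, IPCW integrated Brier score
(100–1700 days), Schoenfeld proportional-hazards checks, ROC AUC against
histological G1 vs G3/G4, the G2-split report, and mGrade-vs-stage
chi-square; plus differential mutation (Fisher), CNA cytoband
(ploidy-normalized, clipped to ±2) and protein (Mann–Whitney) tests between
mGrades, all BH-corrected.

A seeded synthetic-cohort generator (planted expression signature,
proportional-hazards survival, censoring, G2 relabeling, monotone batch
distortions, mutation/CNA/protein tables) makes every stage testable without
external data.

## Worked example

```python
import dataclasses
from mgrade import simulate, pipeline, classifier, surveval

cohort = simulate.generate_cohort(simulate.DEFAULT_SPEC)          # n=400, 2000 genes
result = pipeline.train_pipeline(cohort.expr, cohort.clin, seed=0)

print("signature:", len(result.signature.up_in_high), "up,",
      len(result.signature.up_in_low), "down")
print("GGI threshold:", round(result.labeling.threshold, 2))
print("elimination:", result.trace.sizes()[0], "->", result.trace.sizes()[-1],
      "genes over", len(result.trace.sizes()), "steps")

held = simulate.generate_cohort(
    dataclasses.replace(simulate.DEFAULT_SPEC, n_samples=200, seed=1))
prob, label = classifier.predict_single_sample(result.model,
                                               held.expr.sample_vector("S0000"))
print(f"sample S0000: P(high grade) = {prob:.3f} -> {label}")

preds = classifier.predict_cohort(result.model, held.expr)
fit = surveval.cox_fit_groups(preds["mgrade_label"], held.clin)
print(f"held-out Cox: HR = {fit.hazard_ratio:.2f}, p = {fit.p:.2g}, "
      f"concordance = {fit.concordance:.3f}")
```

prints

```
signature: 30 up, 30 down
GGI threshold: -43.73
elimination: 60 -> 20 genes over 21 steps
sample S0000: P(high grade) = 0.049 -> mG1
held-out Cox: HR = 1.96, p = 0.00011, concordance = 0.565
```

The signature recovers the generator's 60 planted genes; the threshold scan
splits the training cohort into the two risk groups; the elimination loop
walks from 60 to 20 genes two at a time; the single-sample call classifies a
held-out sample as low molecular grade with probability 0.049 of being
high-grade; and the predicted labels separate held-out survival (hazard
ratio ≈ 2 under 25% censoring of a planted 3× hazard).

A command-line interface mirrors the library:
`mgrade simulate | label | train | predict | evaluate | associate`
(see `mgrade --help`).

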