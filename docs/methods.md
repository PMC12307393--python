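# Methods

This note documents the models, estimators and design choices behind
`mgrade`, and what the synthetic-cohort tests do and do not demonstrate.

## Labeling model

Training labels are not histological grades. They are produced by a
survival-driven relabeling of the cohort:

1. **Differential expression.** Histological G3/G4 vs G1 samples are
   compared per gene with Welch's t-test on log2 expression (microarray) or
   log-CPM (RNA-seq counts path; pseudo-count 0.5, library-size normalized).
   We deliberately do not replicate limma/edgeR moderated statistics: the
   downstream contract is the *filtered geneset*, which is robust to the
   choice among reasonable two-group tests at the cohort sizes involved, and
   a moderated-variance test could be swapped in behind the same interface.
   Benjamini–Hochberg FDR is applied across all tested genes. Degenerate
   rules: a gene constant in both groups gets p = 1; all-missing genes are
   excluded with a warning.
2. **Signature filters.** q < 0.05 and |log2FC| > 1 by default; the LUAD
   configuration uses the asymmetric bounds +1.5 / −1.2. Expression floors
   are platform-specific: log-CPM ≥ 2 (RNA-seq), average log2 intensity > 3
   (breast-like arrays) or > 7 (kidney-like arrays). Filtering is a pure set
   operation — row order cannot matter, and tightening any threshold can
   only shrink the sets.
3. **Unscaled GGI.** Per sample, the sum of log2 expression over the
   up-in-high set minus the sum over the up-in-low set. Genes absent from
   the matrix and missing values are omitted; empty sums contribute zero.
   Unlike the original genomic grade index, no scaling against pathologist
   labels is performed; equal gene weights are used.
4. **Threshold scan.** Candidate cutoffs sit at the 1st–99th percentiles of
   the GGI distribution in 1-point steps. We read "1% intervals" as a
   percentile grid: a grid in raw variance units would be unbounded and
   dimensionally awkward; the grid definition is a parameter (`grid_step`).
   Cutoffs leaving either group under `min_group_frac` (default 0.10) of
   the cohort are discarded — an explicit guard against 1-vs-rest splits
   that trivially minimize p. Each surviving cutoff is scored by a
   univariate Cox fit of the binary indicator; selection is lexicographic:
   lowest Wald p, then highest concordance, then highest |log HR|. A
   combined criterion would need weights nobody has specified; the
   lexicographic order makes p primary and the other two pure tie-breakers,
   and the full scan table is returned so a user can audit the choice.
   Labels use the strict rule `high ⇔ GGI > threshold`; the high group is
   rendered mG3 (mG4 for ccRCC, whose WHO/ISUP grade 4 is the recognized
   aggressive category).

Because the scan minimizes p over ~99 correlated candidates, the selected
split on survival-independent data is selection noise; the test suite
quantifies this with a split-half design (threshold chosen on one half, Cox
p on the other) under a hazard ratio of 1.

## Rank transformation and classifier

Each sample's geneset values are replaced by within-sample ascending ranks
with average ranks for ties; missing values are omitted (their positions
stay missing and LightGBM handles them natively). The non-missing ranks of
a sample always sum to M(M+1)/2. Ranks are recomputed over the *active
geneset only* at every elimination step and at prediction time — ranking
over the geneset rather than a larger gene universe is what lets a model
artifact be applied to any platform where the geneset is measured.

Consequences worth stating precisely:

- **Batch independence holds at the classifier stage, not for the GGI.**
  The GGI is a sum and is *not* invariant to monotone distortions; the
  invariance claim applies to rank-stage predictions only, and tests assert
  it only there.
- For every sample, prediction alone, in any cohort, or after any strictly
  increasing per-sample transform is bit-identical, because the feature
  vector is identical.

The classifier is a LightGBM binary ensemble
(`deterministic=true, force_row_wise=true, n_jobs=1`, seeded) tuned by
stratified 5-fold CV on negative log-loss. During recursive elimination the
per-cancer published hyperparameters are used verbatim (grid disabled) —
the elimination signal is the SHAP ranking, which is stable across the
small grid, and a per-step grid search would multiply cost for no change in
the selected genesets; the final fit runs a small grid
(`n_estimators ∈ {100,200,500} × reg_alpha ∈ {0,0.3}`) centered on the
published optima. Both grids are caller-configurable.

SHAP attributions come from LightGBM's native TreeSHAP
(`pred_contrib=True`); per-sample attributions plus the base value
reconstruct the raw log-odds exactly, and importance is the mean absolute
attribution over the full labeled set. Elimination drops the two least
important genes per step (one when two would overshoot the stop size of
20); ties drop the lexicographically smallest gene ID first so builds are
reproducible. The final geneset is the trace step with minimal mean CV
loss, ties broken by smaller loss sd, then smaller geneset.

Prediction requires ≥ 90% of the model geneset measured in the sample
(`MIN_PRESENT_FRACTION`): missing genes are legitimately omitted from the
ranking, but beyond that fraction the remaining ranks no longer resemble
the training feature distribution. The 0.5 probability cutoff renders the
binary label; probabilities are reported uncalibrated.

## Survival evaluation

- **Cox fits** (lifelines): binary group contrast plus optional stage and
  lymph-node dummy covariates ("missing" levels dropped). Cohort enters as
  a *stratification* variable — each cohort keeps its own baseline hazard —
  which is the conservative reading of "accounting for cohort" and avoids
  forcing a proportional cohort effect.
- **Concordance**: Harrell's C with censoring-aware pair usability and 0.5
  for risk ties.
- **Integrated Brier score**: IPCW with Kaplan–Meier censoring weights
  (scikit-survival), trapezoidal integration over 100–1700 days on a
  100-point uniform grid. Group-label input predicts each sample's survival
  by its group's Kaplan–Meier curve; a probability matrix can be supplied
  directly. The window must be covered by follow-up.
- **PH checks**: scaled Schoenfeld residual tests (rank time transform).
- **AUC vs histology** excludes G2 and ungraded samples — the comparison is
  against the unambiguous histological extremes.
- **Stage association**: uncorrected contingency chi-square (Σ(O−E)²/E),
  so the statistic matches the textbook formula also for 2×2 tables; small
  expected counts trigger a warning rather than an error.

## Genomic associations

Mutations: VAF > 0.05; classifications Intron, 3'Flank, 5'Flank and
Synonymous_Mutation (plus the standard MAF spelling "Silent") excluded;
TTN, MUC16 and RYR2 excluded for length-driven background; then the top-k
most-mutated genes (default 15, 5 for ccRCC-like cohorts) are tested with
two-sided Fisher exact tests, BH-corrected. The binary-feature fold change
is log2 of the ratio of altered-sample percentages (high/low), with ±inf
sentinels when one group is clean — the test itself is still run.

CNA: normalized copy number = clip(total_cn − ploidy, −2, 2); cytoband
calls by any-overlap (≥1 bp, 0-based half-open; SEG-style 1-based input is
converted on read) with del/amp at the clipped extremes. A band hit by both
extremes takes the state covering more of its bases (tie: amp), so calls
are invariant to segment fragmentation. Amplifications and deletions are
separate BH families; bands with fewer than `min_altered` (default 3)
altered samples are dropped pre-test — "low number of alterations" is not
quantified anywhere authoritative, so the cutoff is explicit and
configurable. Two-sided tests throughout.

Proteins: two-sided Mann–Whitney U per protein, BH-corrected; the reported
fold change is the difference of group means (log-scale input assumed);
constant proteins get p = 1.

## Synthetic cohorts

The generator plants exactly the structure the pipeline assumes:

- Expression: per-gene baseline ~ N(8, 1.5²) on a log2-like scale, Gaussian
  noise (sd 1.0), and a ± effect/2 shift on the signal genes by latent
  class. Default fixture: n = 400, 2000 genes, 30 up + 30 down signal
  genes, effect 1.5, equal class proportions.
- Survival: exponential with baseline hazard 1/1500 events/day and a
  multiplicative hazard ratio (default 3) for latent-high — the simplest
  generator consistent with the proportional-hazards assumption the
  labeling stage exploits. Censoring: independent exponential calibrated to
  a 25% marginal censor fraction plus an administrative cutoff at 3000
  days, so the 100–1700-day Brier window is always covered.
- Grades: concordant with latent class except a random 20% relabeled G2
  *from both classes*, so tests can verify that the molecular split
  re-stratifies G2 risk.
- Stage and nodal status loosely track latent risk so association tests
  have signal; mutation/CNA/protein tables use class-specific Bernoulli or
  Gaussian rates. The genomic-feature stream is keyed separately from the
  expression stream so reusing one seed integer cannot couple the draws.

What passing tests show — and do not. The generator has independent genes,
Gaussian noise, exact proportional hazards and a planted two-class truth.
Recovery results (signature recall, threshold-scan accuracy ≈ 0.98,
held-out AUC ≈ 0.99) therefore demonstrate *correctness of the machinery*,
not expected performance on real tumors, where correlated co-expression,
platform effects, imperfect PH and biological heterogeneity all reduce
separability. The batch-independence results, by contrast, are exact
properties of the rank representation and transfer to real data as-is.

## Problem sizes and numerics

Simulation-based tests use fixture-scale problems (held-out n = 200 for the
end-to-end check; 20-seed retention and 100-seed null-scan studies at
n = 200 with a 2-point percentile grid for the null arm) — sizes chosen so
the full battery runs comfortably on a laptop while keeping every assertion
at the stated power. All randomness flows from explicit integer seeds;
LightGBM runs single-threaded deterministic. Cox fits that fail to converge
during the threshold scan skip the candidate with a warning; lifelines
convergence errors elsewhere surface as errors with diagnostics. Known
limitations: no probability calibration, no multi-class (G1/G2/G3) output
by design, no gene-ID harmonization across platforms (IDs are opaque
strings), and no modeling of gene–gene correlation in the generator.
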