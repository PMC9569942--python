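# Methods

This note documents the statistical procedures implemented in `recurnet`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical choices
that matter for reproducing results.

## Study design the package models

The target design is a two-group (BCR = biochemical recurrence, BRF =
recurrence-free) comparison of primary-tumor expression in the TMPRSS2-ERG
molecular subtype of locally advanced prostate cancer, observed in two
independent cohorts of miRNA-Seq/RNA-Seq counts, followed by (i) cross-cohort
differential expression, (ii) a differential miRNA-target correlation
interactome, (iii) pathway over-representation of network members, (iv) a
neural-network recurrence classifier combining expression with
clinicopathological covariates (ISUP grade group, pathological T stage,
Gleason score, preoperative PSA), and (v) qPCR delta-CT validation on an
extended sample set with technical triplicates.

## Normalization: TMM and CPM

`tmm_factors` implements the trimmed-mean-of-M-values procedure on raw
counts. The reference sample is the one whose 75th percentile of
library-size-scaled counts is closest to the mean such percentile. For each
sample, M-values (log2 ratio of scaled counts vs the reference) and A-values
(mean log-abundance) are computed over features nonzero in both samples;
both tails of M (30%) and of A (5%) are discarded by rank; the factor is 2
to the precision-weighted mean of the surviving M-values, with weights from
the delta-method binomial variance. Factors are rescaled to geometric mean 1,
so effective library sizes are `N_k * f_k`. Fewer than two shared nonzero
features yields factor 1 with a warning.

Two numerical facts worth knowing:

- Exact proportional columns give all M = 0 and factors exactly 1 (tested).
- Scaling one column by a positive constant leaves M, A and the trimming
  sets unchanged but rescales that sample's precision weights, so factors
  are only approximately invariant (observed shifts ~0.4% at typical
  library sizes; tested at 2%).

CPM is `count / (library_size * factor) * 1e6`; the log variant is
`log2(CPM + 1)`. The +1 prior keeps zero counts at exactly 0 on the log
scale; it is a documented choice, configurable only by computing CPM and
transforming externally.

## Differential expression

Per feature, the fold change is the ratio of group CPM means, annotated with
direction (↑ = higher in BCR); the test is Mann-Whitney on log2CPM values.
`mw_test` uses the exact permutation distribution when n1+n2 ≤ 20 and the
data are tie-free, otherwise the normal approximation with midranks,
tie-corrected variance and continuity correction; small tied samples fall
back to the approximation with a log note. The DE call thresholds the raw
Mann-Whitney p at alpha (default 0.05), with Benjamini-Hochberg FDR reported
alongside — thresholding on raw p reflects how the cross-cohort marker lists
that motivated this design were built; both thresholds are configurable.
An edgeR-style quasi-likelihood F-test is deliberately not provided: the DE
rule this pipeline implements is satisfied by the Mann-Whitney branch alone.

Cross-cohort intersection keeps features DE in both cohorts with the same
direction. The subsequent "high and stable expression" filter is an explicit
operationalization of an informal criterion: median log2CPM ≥ 1.0 in every
group of every cohort and detection (raw count > 0) in ≥ 80% of each group's
samples. Both values are configurable and should be treated as an
interpretation, not a canonical rule.

One caution: Benjamini-Hochberg adjusted values are *not* idempotent
(re-adjusting adjusted values inflates them further); the test suite checks
the step-up definition, monotonicity and bounds instead.

## Differential correlation and the network

For each catalog pair and group, Spearman (midranks), Pearson, and the
adjusted R² `1 − (1 − r_p²)(n − 1)/(n − 2)` of the simple regression of
target on source are computed on log2CPM (the scale choice is a documented
decision; correlations on raw counts are attenuated by library-size noise).
The differential-correlation statistic is Δ = r_s(BCR) − r_s(BRF), tested
with the two-sample Fisher r-to-z statistic with variance v = 1 by default;
the Fieller-Hartley-Pearson inflation v = 1.06 appropriate to Spearman
coefficients is a config switch. Correlations are clamped to |r| ≤ 1 − 1e−7
before atanh; groups need n ≥ 4 because the variance is 1/(n − 3).

Selection defaults to raw p ≤ 0.05 (FDR reported); the bundled demo pipeline
selects on BH FDR ≤ 0.05 instead. The reason is arithmetic: with ~200 null
catalog edges, a raw 5% threshold admits ~10 false pairs, which would drown
a planted signal of 20 true pairs; the FDR rule keeps expected decoy
contamination near 5% of selections while costing little power on strong
contrasts. Both rules, the alpha, and an optional |Δ| gate are exposed in
the config. The BH family is all scanned pairs of a run, not per edge type.

Selected miRNA-target pairs become the network's edges; nodes carry types
(inferred from the typed edges they participate in), per-cohort DE flags and
direction; PPI/TF-target/lncRNA-target catalog edges among included nodes
are appended with their own correlation annotations when scanned. Exports:
GraphML, node-link JSON (both losslessly re-importable) and edge-list TSV,
plus a per-node degree table as the static summary.

## Pathway over-representation

`ora_test(k, K, n, N)` is the upper-tail hypergeometric probability
P(X ≥ k) via the survival function. The universe defaults to the union of
all collection members — including annotation-table miRNAs — and can be
overridden. Query ids outside the universe are ignored (they carry no
information under the urn model: a practical consequence is that unannotated
decoys do not dilute enrichment unless an explicit universe includes them).
Significance defaults to raw p < 0.05 per set, with BH adjustment behind a
flag; sets are reported sorted by p with gene and miRNA overlaps listed
separately.

## The recurrence classifier

`nn.py` is a self-contained NumPy implementation: Glorot-uniform
initialization, seven hidden layers (default sizes 150, 120, 90, 60, 40, 30,
20; relu by default, tanh per layer), two softmax outputs trained with
categorical cross-entropy — the two-class form of binary cross-entropy under
a softmax pair — by mini-batch Adam (β1 = 0.9, β2 = 0.999, ε = 1e−8,
learning rate 0.003). Defaults the architecture leaves open are declared,
not inferred: 200 epochs, batch size 8, no early stopping. Inputs are
centered and scaled with training-set statistics only (zero-variance columns
get SD 1 with a warning). Ordinal encodings: ISUP 1-5; pT {pT3a: 1, pT3b: 2,
pT4: 3}; Gleason raw score. Hard labels use score > 0.5, ties toward BRF; a
Youden-optimal threshold is reported alongside for transparency.

Numerical choices: softmax and cross-entropy use the log-sum-exp form, so
the loss is finite for all finite inputs; the batch loss is a *mean*, so the
gradient of a duplicated sample equals the single-sample gradient.
`gradient_check` compares analytic gradients to central finite differences
(h = 1e−5) over a random parameter subset; its relative-error denominator is
floored at 1e−4 because finite differences carry ~1e−11 absolute rounding
noise, which would dominate the ratio for parameters with near-zero true
gradient. Everything (init, shuffling) is deterministic under the spec seed.

## Evaluation metrics

Confusion metrics treat BCR as positive: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), precision TP/(TP+FP), and Cohen's kappa
(p_o − p_e)/(1 − p_e) with marginal-product chance agreement. Undefined
rates are NaN with a warning, never silently 0. The ROC curve sweeps unique
score thresholds; tied scores move diagonally, making the trapezoid AUC
identical to the rank statistic U/(n₊ n₋) with half credit for ties (a
tested identity). AUC confidence intervals are out of scope.

## qPCR relative quantification

Technical replicates are averaged arithmetically on the CT scale; ΔCT is
mean CT of the target minus mean CT of the matched reference in the same
sample (gene targets → control gene, miRNA targets → control miRNA);
relative expression is 2^(−ΔCT), computed per sample before any group
summary (the alternative — exponentiating a group-mean ΔCT — is not used).
ΔCT removes sample-level offsets exactly (tested). Group contrasts use the
median ratio for the fold change (robust at n ≈ 31; mean ratio behind a
flag), Mann-Whitney for p, and the Spearman correlation between relative
expression and the binary group indicator (equivalent to a rank-biserial
association). Assays with p > alpha are flagged excluded from downstream
modelling. No replicate outlier rejection by default; a
drop-if-&gt;0.5-CT-from-median rule is available behind a flag. Efficiency
(Pfaffl) correction and standard curves are out of scope.

## The synthetic-cohort generator

The generator defines the study conditions the tests run under:

- **Counts**: negative binomial per feature, Var = μ + αμ². Baseline means
  are lognormal (meanlog 4.0, sdlog 1.2 — median ≈ 55 counts, a plausible
  small-RNA panel profile); dispersions are gamma(2, 0.05) (mean α = 0.1);
  library-size factors are lognormal with CV 30% so TMM is exercised
  nontrivially.
- **Planted DE**: a configured fraction of features (default 5%) gets a
  multiplicative group fold change (default 4), alternating directions.
- **Planted correlation**: pairs are coupled through a Gaussian copula on
  the latent scale, mapped through the NB quantile functions, so marginals
  are exact and the implied population Spearman coefficient has the closed
  form (6/π)·asin(ρ/2). Discretization and library-size noise attenuate the
  recovered coefficient slightly (tested: mean bias within 0.05 at the
  marginals used; somewhat larger on the normalized cohort scale at low
  abundance or low dispersion).
- **Clinical covariates**: generated conditionally on the recurrence label —
  a latent standard normal shifted by the configured effect, discretized
  into ISUP 1-5 and pT (frequencies matching a locally advanced case mix,
  ~52/45/3% for pT3a/pT3b/pT4); Gleason maps from ISUP; PSA is lognormal
  around 10 ng/mL with a log-scale shift. Group sizes are fixed by design,
  which is why covariates are drawn given the label rather than labels from
  a logistic model; the association structure is equivalent.
- **qPCR**: CT = intercept − slope·log2(expression) + N(0, σ), three
  technical replicates, σ = 0.15 CT and slope 1 (100% PCR efficiency) by
  default.
- **Classifier benchmark**: three gene-expression predictors and one miRNA
  predictor at standardized effect 1.5, plus informative ISUP and pT
  ordinals — the six-predictor design of the headline model.

What it does **not** emulate: read-level data, sequencing error, batch
effects, GC/length biases, inter-feature correlation beyond the planted
pairs, missing clinical data, or realistic pathway structure (gene sets are
random draws). Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under the declared generative model, not that the
biological conclusions of any particular cohort transfer.

## Pipeline, determinism, problem sizes

Stages communicate through plain-text files (TSV/JSON/GMT/CSV) in the output
directory and are independently runnable; `manifest.json` records SHA-256
hashes of every artifact plus the config snapshot and seed, and identical
config + seed reproduces identical hashes. All stage randomness derives from
the single global seed through fixed per-stage offsets (documented in
`PipelineConfig.stage_seed`), kept below 2³¹.

The demo configuration — two cohorts of 30 samples per group, 60 miRNAs,
300 mRNAs, 20 planted pairs (latent ρ 0.8 vs −0.2) among 200 decoys, a
400-sample classifier benchmark split 200/200, and a 31-sample qPCR set —
was chosen so that every stage has realistic power at desk-scale runtimes:
Fisher-z power for the planted contrast is ≈0.99 at n = 30/group, and the
six-predictor benchmark's Bayes-optimal AUC is ≈0.98, leaving headroom for
the ≥0.95 held-out target. Calibration checks use 10,000 null pairs; power
and recovery summaries use 500 replicates and 50 seeds respectively.

## Known limitations

- The Mann-Whitney exact branch requires tie-free data; heavily tied
  small-sample log2CPM vectors silently use the corrected approximation.
- Fisher's r-to-z on Spearman coefficients is approximate; the null
  rejection rate at n = 30/group sits near 0.053 rather than exactly 0.05
  (within the tested calibration band).
- The stability filter and the diffcor selection rule are interpretations of
  informal criteria; results can be sensitive to both and both are exposed
  in the config.
- The classifier reports both splits but no variance estimates; with
  samples sizes typical of this design (tens of cases), held-out metrics
  have wide sampling variability.
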