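# Methods

## The score and its assumptions

The signature score of a sample is the normalized mean rank of the
signature genes within the sample's expression profile, computed over a
fixed background universe. Formally, with universe size *N*, *g* usable
signature genes, and mean (tie-averaged, ascending) rank *m̄*:

S = (m̄ − (g+1)/2) / ((N − (g−1)/2) − (g+1)/2).

The numerator and denominator are the offsets of *m̄* from its minimum
(signature genes occupy the bottom *g* ranks) and maximum (top *g*
ranks), so S ∈ [0, 1] with the extremes attained exactly at those
configurations. Because only within-sample ranks enter, the score is
invariant to any strictly increasing per-sample transform (library-size
scaling, log transforms), which is what makes it portable across
platforms and normalization pipelines. The implemented variant is the
up-set-only, uncentered form; the centered variant used by some scoring
engines is S − 0.5, and no rank-dispersion weighting is applied. Ties get
average (fractional) ranks — deterministic and standard.

Assumptions worth keeping in mind: the score estimates the *absolute*
abundance signal of one cell population in a bulk profile; it degrades
when signature genes are expressed highly by other abundant populations
(the construction stages exist precisely to limit that), and it says
nothing about spatial arrangement.

### Background universe

The ranking universe is the set of genes with across-sample mean TPM
strictly above 1 in a reference compendium. When no reference is
supplied, the universe defaults to all genes of the scored matrix itself,
or to genes with mean TPM > 1 in the scored data when derived with
`compute_background` (flagged in output as a portability default). A
narrower universe changes N and hence all scores; comparisons are only
meaningful within one universe.

## Construction pipeline

Stages, each only removing genes (candidate ⊇ initial ⊇ final):

1. **Candidates**: union of CD8-specific genes and genes upregulated in
   sorted PD-1^hi CD8^+ T cells (DE thresholds: adjusted p < 0.05 and
   |log2FC| > 1, both strict).
2. **Tumor-expression filter**: drop genes whose *median* log2(TPM+1)
   across cancer cell lines is ≥ 3.1 (retain strictly below). The log
   base is a choice — the threshold was published as "log TPM" without a
   base — and log2(TPM+1) is the dominant RNA-seq convention; it is
   config-exposed (`ccle_median_logtpm_max`). Candidate genes absent from
   the cell-line matrix cannot be shown tumor-high and are retained with
   a warning (conservative).
3. **Percentile filter**: rank candidates by *mean* expression across the
   sorted PD-1^hi samples (mean rather than median is a choice,
   config-exposed) and keep the top `ceil(keep_frac * n)`; boundary ties
   break lexicographically by gene identifier for determinism. The keep
   fraction defaults to 0.6; a diagnostic scan over {0.2, 0.4, 0.6, 0.8}
   clusters the sorted-cell samples (distance 1 − Pearson, average
   linkage, two-group cut) at each fraction and reports the smallest
   fraction that perfectly separates PD-1^hi from other CD8 samples
   (otherwise the highest adjusted-Rand fraction). None of the clustering
   details were published; these are standard transcriptomics practice
   and give a testable rule. One caveat discovered in testing and worth
   recording: Pearson distance is shift-invariant, so a scanned subset
   consisting *only* of uniformly shifted genes cannot separate the
   classes — separation requires subsets mixing shifted and unshifted
   genes, which is the realistic case.
4. **Single-cell refinement**: cells pass QC (detected genes in
   [1000, 5000] inclusive, mitochondrial count fraction strictly below
   5%, "MT-" prefix by default and overridable); QC-passing cells are
   depth-normalized to TPM and scored with the initial signature over a
   background of genes with mean TPM > 1 in the cell data; the cluster
   with the highest mean score is taken as the PD-1^hi CD8^+ population
   (an effective tie, margin < 1e-12, is an error demanding review);
   markers of that cluster are genes expressed in ≥ 25% of cells on
   either side with |natural-log fold change| > 0.25 on library-size
   normalized (scale 1e4, log1p) data, tested by two-sided Wilcoxon
   rank-sum; the final signature is the intersection of the initial
   signature with the upregulated markers.

Upstream clustering of cells and the bulk differential-expression fit are
inputs, not implemented here.

## Evaluation

- **AUC** is the normalized rank-sum statistic (ties count 1/2), which
  equals the trapezoidal ROC area; verified against all-pairs
  enumeration.
- **Youden dichotomization** scans midpoints between adjacent distinct
  scores; "high" means strictly above the threshold; ties in J break
  toward higher sensitivity, then the lower threshold.
- **NRI** is the continuous (category-free) variant: each score is mapped
  to a predicted probability by its own univariate logistic fit. Under
  separation the fit is replaced by the score's percentile rank *in its
  given orientation* (higher = more likely responder) — deliberately not
  re-learning the direction, since an oriented biomarker that ranks
  responders last should be penalized, not silently flipped.
- **TMB combination** is a maximum-likelihood logistic fit on
  standardized predictors (comparable coefficients, stable optimization);
  zero-variance predictors are dropped, and separation falls back to a
  ridge-penalized fit that still returns probabilities with coefficients
  flagged non-finite.
- **Pan-cancer correlation**: the high-score threshold is the pooled
  80th percentile across all samples (per-type thresholds are exposed as
  an option); per type the fraction strictly above it is Pearson-
  correlated with the reported objective response rate, p via the
  t-transform with n − 2 df.
- The **absolute fraction** of PD-1^hi CD8^+ cells in a tumor is the
  product of the relative fraction within CD8^+ cells and the CD8^+
  fraction of the tumor.

## Survival

Kaplan–Meier estimation and Cox regression are delegated to lifelines
(Efron tie handling — better than Breslow under ties and the standard
default; Wald 95% intervals matching the symmetric-on-log-scale layout of
clinical tables). Categorical covariates expand against a stated
reference level; continuous covariates enter untransformed. Monotone
likelihood triggers a lightly penalized refit with a warning rather than
an unbounded estimate. Read-off rates (e.g. 12-month survival) use the
right-continuous step convention, so censoring exactly at the read-off
time counts as at-risk through it.

The log-rank statistic (observed − expected with hypergeometric variance)
and the Cox score test at β = 0 are implemented directly, independently
of lifelines, so the classical identity between the two on tie-free data
serves as a cross-implementation check rather than a tautology.

## Synthetic data: what it emulates, and what it does not

- `simulate_bulk_mixture`: two base profiles (log-normal baseline;
  signature genes multiplied by 2^effect in the PD-1^hi profile) mixed
  convexly on the *linear* TPM scale — physical mixing of cell
  populations is linear in transcript fractions — with per-gene
  multiplicative log-normal noise, columns renormalized to 1e6. Defaults:
  2000 genes, 30 signature genes (the scale of the real signature),
  fractions uniform on [0, 0.5] (absent through half the sample, covering
  the dynamic range of sorted-cell validation data), effect 2 log2 units,
  noise sd 0.2 log2 units.
- `simulate_scrna`: gamma-Poisson (negative-binomial) counts, per-gene
  log-normal baseline means (median 2, log-sd 1, dispersion size 1 —
  detection of roughly 1–1.5k of 2000 genes per cell, inside the QC
  window), one cluster with signature-gene means multiplied by the spike
  factor, mitochondrial genes carrying a fixed expected count fraction,
  optional planted QC violators.
- `simulate_cohort`: scores uniform on [0, 1]; durable-benefit response
  logistic in (score − 0.5); overall survival exponential with 12-month
  median in the low half and a planted hazard ratio in the high half
  (progression-free survival at twice the hazard); independent
  exponential censoring tuned to the requested rate; log-normal TMB,
  independent of the score by default. RECIST categories are generated
  consistently with the benefit labels (a fifth of each arm presents as
  stable disease with an informative duration), so the labeling logic is
  exercised end to end.

All generators are pure functions of (parameters, seed). What passing
tests on these data do *not* show: robustness to batch effects, ambient
RNA/doublets, non-proportional hazards, informative censoring, or
cross-platform normalization artifacts — none of which the generators
emulate.

The planted construction fixture uses 20 true genes, 10 tumor-high decoys
and 13 low-expression decoys. Thirteen (not a round 10) because the 60%
percentile cut keeps `ceil(0.6 * 33) = 20` genes — the cut then lands
exactly on the planted set, making exact recovery a sharp test rather
than an approximate one.

## Numerical and degenerate-input conventions

- Strict inequalities follow the published wording everywhere a boundary
  is stated: DE thresholds, tumor filter ("below 3.1"), background
  (mean TPM > 1), benefit duration ("more than 6 months"), mitochondrial
  fraction (< 5%), high-score groups (strictly above threshold/percentile).
- Detected-gene QC bounds are inclusive on both ends.
- Duplicate gene rows collapse by sum for counts and mean for TPM;
  stable disease without a benefit duration yields a missing label and is
  excluded from AUC; missing tokens are empty cells or "NA".
- Gene matching is exact string comparison with an optional case-folding
  flag; no ortholog mapping.
- Scores, AUC and Youden computations are exact rank arithmetic (no
  tolerance); oracle agreement is asserted at 1e-12.

## Problem sizes

The test and reproduction runs use 200 random matrices for the scoring
oracle, 500 instances for the AUC/Youden oracles, 100 single-cell
simulations (3 clusters × 100 cells × 2000 genes) for cluster recovery,
500 replicates of n = 300 for Wald coverage, and 1000 replicates of
n = 100 for type-I calibration — sizes at which the binomial bands in the
checks are meaningful while a full run stays around a minute.

## Known limitations

- Only 14 of the 31 genes of the published final signature are public;
  the bundled set is that named subset and scores computed with it are
  not numerically comparable to the original 31-gene score.
- The Youden cutoff is derived on the same cohort it stratifies (as in
  the original analyses); the optional split-sample mode is an extension,
  and in-sample cutoffs slightly inflate downstream log-rank type-I error
  (the null-calibration check bounds this at ≤ 8%).
- The background universe was published only via one reference
  compendium; whether it pooled cancer types is unknown, so pooled means
  are used.
- No confidence intervals for AUC beyond what a bootstrap would give;
  no proportional-hazards diagnostics beyond this note.
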