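# pd1sig

Rank-based quantification of tumor-infiltrating **PD-1^hi CD8^+ T cells**
from bulk RNA-seq, and evaluation of the resulting score as a biomarker of
response to immune checkpoint inhibitor (ICI) therapy.

PD-1^hi CD8^+ T cells are an exhausted, proliferating CD8 subpopulation
whose abundance in the tumor microenvironment predicts benefit from
anti-PD-1/PD-L1 therapy. `pd1sig` provides, for computational
immuno-oncologists and biomarker analysts:

- the **staged construction** of a PD-1^hi CD8^+ transcriptome signature
  from candidate gene lists, cancer cell-line expression, sorted-cell bulk
  profiles, and single-cell RNA-seq refinement;
- a **single-sample signature score** — the normalized mean rank of the
  signature genes within each sample's expression profile;
- **biomarker evaluation**: ROC/AUC, Youden-index dichotomization, net
  reclassification, logistic combination with tumor mutational burden
  (TMB), Kaplan–Meier / log-rank / Cox proportional-hazards survival
  analysis, and the pan-cancer response-rate correlation;
- a **synthetic-data module** generating bulk mixtures, clustered
  negative-binomial single-cell counts, and clinical cohorts with known
  ground truth, so every stage is testable offline.

## The score

For a sample with expression profile restricted to a background gene
universe *U* (|*U*| = *N*, by default genes with mean TPM > 1 in a
reference compendium), let *g* signature genes have mean rank
*m̄* (ascending ranks, average ranks for ties). The score is

    S = (m̄ − (g+1)/2) / ((N − (g−1)/2) − (g+1)/2)  ∈ [0, 1]

which is 0 when the signature genes are the *g* lowest-expressed genes of
the universe, 1 when they are the *g* highest, and invariant to any
strictly increasing per-sample transform of expression (TPM vs log TPM is
immaterial). The centered variant used by some scoring tools is simply
`S − 0.5`.

Signature construction applies, in order: differential-expression
thresholds (adjusted p < 0.05, |log2FC| > 1), a tumor-expression filter
(drop genes with median log2(TPM+1) ≥ 3.1 in cancer cell lines), a
low-expression percentile filter (keep the top 60% of candidates by mean
expression in sorted PD-1^hi CD8^+ samples, with a clustering-based cutoff
scan over 20–80%), and a single-cell refinement (QC → score clusters →
intersect with the top cluster's upregulated Wilcoxon markers). Each stage
only removes genes. The 14 published genes of the final signature
(exhaustion: CTLA4, PDCD1, TOX, SIRPG, HAVCR2, TIGIT, IGFLR1; cell cycle:
BARD1, CENPE, RAD51, SMC2, GINS2, CLSPN, CCNF) ship as
`pd1sig.gene_sets.pd1hi_core()`.

## Worked example

```python
import numpy as np, pandas as pd
from scipy.stats import pearsonr
import pd1sig as p

# a synthetic validation cohort: bulk mixtures with known PD-1hi fraction
x, truth = p.simulate_bulk_mixture(n_samples=60, seed=7)
bg = p.compute_background(x, min_mean_tpm=1.0)
sig = p.GeneSignature(truth.signature_genes, name="planted30")
scores = p.rank_score(x, sig, bg)
r, pv = pearsonr(scores["score"], truth.sample_fraction)

# a synthetic ICI cohort: response and survival driven by the true score
st, clin, _ = p.simulate_cohort(n=200, auc_target_slope=4.0,
                                hr_per_group=0.5, seed=1)
y = (clin.data["response"] == "DCB").astype(int).to_numpy()
a = p.auc(st["score"].to_numpy(), y)
thr, sens, spec, j = p.youden_cutoff(st["score"].to_numpy(), y)
t, e, m = clin.endpoint("os")
g = np.where(st["score"].to_numpy() > thr, "high", "low")[m]
chi2, df, lr_p = p.logrank_test(t, e, g)
fit = p.coxph_fit(t, e, pd.DataFrame({"high_score": (g == "high").astype(float)}))
```

This prints:

```
score vs true PD-1hi fraction: r=0.987, p=8.88e-48
response AUC=0.768; Youden threshold=0.640 (sens=0.56, spec=0.87)
OS log-rank: chi2=9.75, p=1.79e-03
             beta     HR  CI2.5  CI97.5      p
high_score -0.541  0.582  0.413   0.821  0.002
```

Read: the rank score tracks the planted PD-1^hi fraction almost exactly
(r = 0.987); in the simulated cohort the score predicts durable clinical
benefit (AUC 0.77), and patients above the Youden threshold have roughly
half the mortality hazard (HR 0.58, 95% CI 0.41–0.82) — the direction and
magnitude the simulation planted (true HR 0.5).

The same workflow is available from the shell:

```sh
pd1sig simulate bulk --seed 7 --n 60 --out sim/
pd1sig score --expr sim/expression.tsv --signature sig.gmt \
             --background-from-expr --out scores.tsv
pd1sig evaluate --scores scores.tsv --clinical clinical.tsv --mode auc --out report.tsv
pd1sig build-signature --cd8-genes cd8.txt --pd1hi-deg de.tsv --ccle ccle.tsv \
             --pd1hi-expr pd1hi.tsv --scrna counts/ --clusters clusters.tsv --out sig.gmt
```

## Layout

- `pd1sig.io` — expression matrices (TSV/CSV/MatrixMarket), gene sets
  (GMT/list), clinical tables, response labeling (DCB/NDB), identifier
  harmonization
- `pd1sig.config` — every pipeline threshold in one validated record
- `pd1sig.scoring` — background universe, rank score, housekeeping
  normalization, mean-expression comparator scores
- `pd1sig.construction` — the staged signature-building pipeline
- `pd1sig.evaluation` — AUC/ROC, Youden, NRI, TMB combination,
  stratification, pan-cancer ORR correlation
- `pd1sig.survival` — Kaplan–Meier, log-rank, Cox proportional hazards
- `pd1sig.synthetic` — generators and the planted construction fixture
- `docs/methods.md` — model assumptions, parameter choices, and known
  limitations
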