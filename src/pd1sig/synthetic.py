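"""Synthetic data with the statistical structure the method assumes.

Three generators cover the three data types the pipeline consumes:

* :func:`simulate_bulk_mixture` — bulk TPM profiles formed as convex
  mixtures of a background immune profile and a PD-1hi CD8+ profile (the
  signature genes shifted up), with multiplicative log-normal noise.
  Mixing acts on linear TPM because physical mixing of cell populations is
  linear in transcript fractions.
* :func:`simulate_scrna` — clustered negative-binomial counts with the
  signature genes' means multiplied in one spiked cluster, designated
  mitochondrial genes, and optional planted QC-violating cells.
* :func:`simulate_cohort` — an immunotherapy cohort whose response
  probability is logistic in the true score and whose survival is
  exponential with a hazard ratio between score-split groups; TMB is drawn
  independently of the score by default.

Every generator is a pure function of its parameters and seed, and returns
a :class:`SyntheticTruth` carrying the generative ground truth.
:func:`make_construction_fixture` plants a fully-known signature-building
problem (true genes, tumor-high decoys, low-expression decoys, spiked
single-cell cluster) for end-to-end pipeline checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix
from .construction import CellMatrix

__all__ = [
    "SyntheticTruth",
    "simulate_bulk_mixture",
    "simulate_scrna",
    "simulate_cohort",
    "ConstructionFixture",
    "make_construction_fixture",
]


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    sample_fraction: pd.Series | None = None  # true PD-1hi fraction/sample
    cell_cluster: pd.Series | None = None     # true cluster/cell
    signature_genes: list[str] | None = None  # planted signature
    score: pd.Series | None = None            # true score/sample (cohorts)
    group: pd.Series | None = None            # true high/low group (cohorts)


# ---------------------------------------------------------------------------
# bulk mixtures


def simulate_bulk_mixture(n_samples: int = 100, n_genes: int = 2000,
                          n_signature: int = 30,
                          fraction_range=(0.0, 0.5),
                          effect_log2fc: float = 2.0,
                          noise_sd: float = 0.2,
                          seed: int = 0,
                          fractions=None):
    """Bulk TPM matrix from mixtures with a known PD-1hi fraction.

    Two base profiles are drawn (log-normal baseline; the PD-1hi profile
    has the signature genes multiplied by ``2**effect_log2fc``); each
    sample mixes them by a uniform true fraction from ``fraction_range``,
    multiplicative log-normal noise with standard deviation ``noise_sd``
    (log2 units) is applied per gene, and columns are renormalized to sum
    to 1e6. Defaults emulate a validation cohort: a 31-gene-scale
    signature, fractions spanning absent to half the sample, and a 4-fold
    expression shift in the PD-1hi population.
    """
    lo, hi = fraction_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("fraction_range must be within [0, 1] with lo <= hi")
    if not 0 < n_signature < n_genes:
        raise ValueError("need 0 < n_signature < n_genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    sig_genes = genes[:n_signature]
    base = rng.lognormal(mean=1.0, sigma=1.5, size=n_genes)
    pd1hi = base.copy()
    pd1hi[:n_signature] *= 2.0 ** effect_log2fc
    if fractions is None:
        fractions = rng.uniform(lo, hi, size=n_samples)
    else:
        fractions = np.asarray(fractions, dtype=float)
        if len(fractions) != n_samples or ((fractions < 0) | (fractions > 1)).any():
            raise ValueError("explicit fractions must be n_samples values in [0, 1]")
    mix = np.outer(base, 1.0 - fractions) + np.outer(pd1hi, fractions)
    noise = 2.0 ** rng.normal(0.0, noise_sd, size=mix.shape)
    values = mix * noise
    values = values / values.sum(axis=0) * 1e6
    x = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                         unit="TPM")
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_samples": n_samples, "n_genes": n_genes,
            "n_signature": n_signature, "fraction_range": (lo, hi),
            "effect_log2fc": effect_log2fc, "noise_sd": noise_sd,
        },
        sample_fraction=pd.Series(fractions, index=samples),
        signature_genes=list(sig_genes),
    )
    return x, truth


# ---------------------------------------------------------------------------
# single-cell counts


def simulate_scrna(n_cells_per_cluster: int = 100, k_clusters: int = 3,
                   spiked_cluster: int = 0, n_genes: int = 2000,
                   n_signature: int = 50, nb_mean: float = 2.0,
                   nb_dispersion: float = 1.0, spike_factor: float = 4.0,
                   mito_fraction: float = 0.02,
                   n_mito_genes: int = 10,
                   n_qc_violators: int = 0,
                   nb_mean_sigma: float = 1.0,
                   seed: int = 0):
    """Clustered negative-binomial single-cell counts with one spiked
    cluster.

    Per-gene baseline means are log-normal around ``nb_mean``; counts are
    NB with size parameter ``nb_dispersion`` (gamma-Poisson). In the
    spiked cluster, the signature genes' means are multiplied by
    ``spike_factor``. Designated mitochondrial genes (``MT-`` prefix)
    contribute ``mito_fraction`` of counts in expectation. With
    ``n_qc_violators`` > 0, that many extra cells with very few detected
    genes are appended (cluster label of the last cluster).
    """
    if not 0 <= spiked_cluster < k_clusters:
        raise ValueError("spiked_cluster must index a cluster")
    if nb_mean <= 0 or nb_dispersion <= 0 or spike_factor <= 0:
        raise ValueError("NB parameters must be positive")
    if not 0.0 <= mito_fraction < 1.0:
        raise ValueError("mito_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_body = n_genes - n_mito_genes
    if n_signature >= n_body:
        raise ValueError("n_signature must be below n_genes - n_mito_genes")
    genes = [f"G{i:05d}" for i in range(n_body)] + [
        f"MT-{i}" for i in range(n_mito_genes)
    ]
    sig_genes = genes[:n_signature]
    body_means = rng.lognormal(mean=np.log(nb_mean), sigma=nb_mean_sigma,
                               size=n_body)
    # mito means scaled so mito genes carry mito_fraction of counts
    body_total = body_means.sum()
    mito_total = body_total * mito_fraction / (1.0 - mito_fraction)
    mito_means = np.full(n_mito_genes, mito_total / n_mito_genes)
    base_means = np.concatenate([body_means, mito_means])

    n_cells = n_cells_per_cluster * k_clusters
    cells = [f"C{i:05d}" for i in range(n_cells + n_qc_violators)]
    clusters = np.repeat(np.arange(k_clusters), n_cells_per_cluster)
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    for k in range(k_clusters):
        means = base_means.copy()
        if k == spiked_cluster:
            means[:n_signature] *= spike_factor
        size = nb_dispersion
        cols = clusters == k
        lam = rng.gamma(size, means[:, None] / size,
                        size=(n_genes, int(cols.sum())))
        counts[:, cols] = rng.poisson(lam)
    if n_qc_violators:
        # cells detecting far too few genes: most entries zeroed
        lam = rng.gamma(nb_dispersion, base_means[:, None] / nb_dispersion,
                        size=(n_genes, n_qc_violators))
        viol = rng.poisson(lam)
        keep = rng.random((n_genes, n_qc_violators)) < 0.1
        viol = np.where(keep, viol, 0)
        counts = np.concatenate([counts, viol], axis=1)
        clusters = np.concatenate(
            [clusters, np.full(n_qc_violators, k_clusters - 1)]
        )
    labels = pd.Series([f"c{k}" for k in clusters], index=cells)
    cm = CellMatrix(
        pd.DataFrame(counts, index=genes, columns=cells),
        unit="counts",
        clusters=labels,
    )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_cells_per_cluster": n_cells_per_cluster,
            "k_clusters": k_clusters, "spiked_cluster": spiked_cluster,
            "n_genes": n_genes, "n_signature": n_signature,
            "nb_mean": nb_mean, "nb_dispersion": nb_dispersion,
            "spike_factor": spike_factor, "mito_fraction": mito_fraction,
            "n_qc_violators": n_qc_violators,
        },
        cell_cluster=labels,
        signature_genes=list(sig_genes),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# clinical cohorts


def simulate_cohort(n: int = 200, auc_target_slope: float = 4.0,
                    hr_per_group: float = 0.5, censor_rate: float = 0.2,
                    tmb_independent: bool = True, seed: int = 0):
    """An immunotherapy cohort with score-driven response and survival.

    Scores are uniform on [0, 1]; response (durable benefit) is Bernoulli
    with logit ``slope * (score - 0.5)``. Survival is exponential with a
    median of 12 months in the low-score half (score <= 0.5) and hazard
    ratio ``hr_per_group`` in the high half; progression-free survival
    uses twice the hazard. Censoring is exponential with rate tuned to an
    expected ``censor_rate``. TMB is log-normal, independent of the score
    by default (set ``tmb_independent=False`` for a 0.5 Gaussian-copula
    correlation). Returns ``(score_table, clinical_table, truth)``.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    if hr_per_group <= 0:
        raise ValueError("hr_per_group must be positive")
    rng = np.random.default_rng(seed)
    samples = [f"P{i:04d}" for i in range(n)]
    score = rng.uniform(0.0, 1.0, size=n)
    logit = auc_target_slope * (score - 0.5)
    p_resp = 1.0 / (1.0 + np.exp(-logit))
    responder = rng.random(n) < p_resp

    # RECIST labels consistent with the benefit label; a fifth of each arm
    # presents as stable disease with an informative benefit duration
    recist = np.where(responder, "PR", "PD").astype(object)
    months = np.full(n, np.nan)
    sd_mask = rng.random(n) < 0.2
    recist[sd_mask] = "SD"
    months[sd_mask & responder] = rng.uniform(7.0, 24.0, (sd_mask & responder).sum())
    months[sd_mask & ~responder] = rng.uniform(0.0, 6.0, (sd_mask & ~responder).sum())

    high = score > 0.5
    lam_os = np.log(2.0) / 12.0 * np.where(high, hr_per_group, 1.0)
    os_t = rng.exponential(1.0 / lam_os)
    pfs_t = rng.exponential(1.0 / (2.0 * lam_os))
    if censor_rate > 0:
        lam_c = np.log(2.0) / 12.0 * censor_rate / (1.0 - censor_rate)
        cens = rng.exponential(1.0 / lam_c, size=n)
    else:
        cens = np.full(n, np.inf)
    os_time = np.minimum(os_t, cens)
    os_event = (os_t <= cens).astype(int)
    pfs_time = np.minimum(pfs_t, cens)
    pfs_event = (pfs_t <= cens).astype(int)

    z = rng.standard_normal(n)
    if tmb_independent:
        tmb = np.exp(1.6 + 0.8 * z)
    else:
        zs = (score - score.mean()) / score.std()
        tmb = np.exp(1.6 + 0.8 * (0.5 * zs + np.sqrt(1 - 0.25) * z))

    score_table = pd.DataFrame(
        {"score": score, "n_signature_used": 0, "n_background_used": 0},
        index=pd.Index(samples, name="sample"),
    )
    clinical = ClinicalTable(pd.DataFrame(
        {
            "sample": samples,
            "recist": recist,
            "benefit_months": months,
            "response": np.where(responder, "DCB", "NDB"),
            "os_time": os_time,
            "os_event": os_event,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "tmb": tmb,
            "age": np.round(rng.normal(62.0, 10.0, n), 1),
            "sex": rng.choice(["F", "M"], size=n),
        }
    ))
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n": n, "auc_target_slope": auc_target_slope,
            "hr_per_group": hr_per_group, "censor_rate": censor_rate,
            "tmb_independent": tmb_independent,
        },
        score=pd.Series(score, index=samples),
        group=pd.Series(np.where(high, "high", "low"), index=samples),
    )
    return score_table, clinical, truth


# ---------------------------------------------------------------------------
# planted construction fixture


@dataclass
class ConstructionFixture:
    """Inputs for one fully-known signature-construction problem.

    Plants 20 true signature genes, 10 tumor-high decoys (median
    log2(TPM+1) above the tumor-filter cutoff in the cell-line matrix) and
    13 low-expression decoys (below the 60% percentile cut in the PD-1hi
    bulk samples — 13 so that ceil(0.6 * 33) lands exactly on the 20 true
    genes), plus a spiked single-cell cluster elevating the true genes.
    """

    cd8_specific: list[str]
    de_table: pd.DataFrame
    lines: ExpressionMatrix
    pd1hi_expr: ExpressionMatrix
    cd8_expr: ExpressionMatrix
    cd8_labels: pd.Series
    cells: CellMatrix
    true_genes: list[str]
    tumor_decoys: list[str]
    low_decoys: list[str]


def make_construction_fixture(seed: int = 0) -> ConstructionFixture:
    rng = np.random.default_rng(seed)
    true_genes = [f"SIG{i:03d}" for i in range(20)]
    tumor_decoys = [f"TUM{i:03d}" for i in range(10)]
    low_decoys = [f"LOW{i:03d}" for i in range(13)]
    fillers = [f"BG{i:04d}" for i in range(100)]
    all_bulk = true_genes + tumor_decoys + low_decoys + fillers

    # candidate lists: split the plant across the two sources
    cd8_specific = true_genes[:10] + tumor_decoys
    de_rows = []
    for g in true_genes[10:]:
        de_rows.append({"gene": g, "log2fc": 2.5, "padj": 1e-4})
    for g in low_decoys:
        de_rows.append({"gene": g, "log2fc": 1.5, "padj": 1e-3})
    for g in fillers[:30]:  # nulls removed by the DE filter
        de_rows.append({"gene": g, "log2fc": 0.2, "padj": 0.5})
    de_table = pd.DataFrame(de_rows)

    # cancer cell lines: tumor decoys high (median log2TPM >> 3.1),
    # everything else low
    n_lines = 20
    tpm = rng.lognormal(mean=0.5, sigma=0.5, size=(len(all_bulk), n_lines))
    lines_df = pd.DataFrame(
        tpm, index=all_bulk, columns=[f"CL{i:02d}" for i in range(n_lines)]
    )
    lines_df.loc[tumor_decoys] = rng.lognormal(
        mean=5.0, sigma=0.3, size=(len(tumor_decoys), n_lines)
    )
    lines = ExpressionMatrix(lines_df, unit="TPM")

    # PD-1hi bulk samples: true genes well above the low decoys
    n_pd1 = 10
    pd1_df = pd.DataFrame(
        rng.lognormal(mean=1.0, sigma=0.3, size=(len(all_bulk), n_pd1)),
        index=all_bulk, columns=[f"PD1HI{i:02d}" for i in range(n_pd1)],
    )
    pd1_df.loc[true_genes] = rng.lognormal(
        mean=4.0, sigma=0.3, size=(len(true_genes), n_pd1)
    )
    pd1_df.loc[tumor_decoys] = rng.lognormal(
        mean=4.0, sigma=0.3, size=(len(tumor_decoys), n_pd1)
    )
    pd1hi_expr = ExpressionMatrix(pd1_df, unit="TPM")

    # CD8 compendium for the cutoff scan: 6 PD-1hi + 6 other samples,
    # true genes shifted +4 log2 units in the PD-1hi class, low noise
    cd8_samples = [f"CD8_{i:02d}" for i in range(12)]
    is_pd1hi = pd.Series([i < 6 for i in range(12)], index=cd8_samples)
    base = rng.lognormal(mean=1.0, sigma=0.5, size=len(all_bulk))
    cd8 = np.tile(base[:, None], (1, 12)) * 2.0 ** rng.normal(
        0.0, 0.1, size=(len(all_bulk), 12)
    )
    idx_true = [all_bulk.index(g) for g in true_genes]
    cd8[np.ix_(idx_true, np.where(is_pd1hi.to_numpy())[0])] *= 2.0 ** 4
    cd8_expr = ExpressionMatrix(
        pd.DataFrame(cd8, index=all_bulk, columns=cd8_samples), unit="TPM"
    )

    # single cells: spiked cluster elevates the true genes
    cells, _ = simulate_scrna(
        n_cells_per_cluster=60, k_clusters=3, spiked_cluster=0,
        n_genes=2000, n_signature=20, nb_mean=2.0, nb_dispersion=1.0,
        spike_factor=4.0, nb_mean_sigma=0.5, seed=int(rng.integers(2**31)),
    )
    # rename the spiked genes to the planted identifiers (and keep the
    # decoys present but unspiked so the refinement must reject them)
    rename = dict(zip(cells.genes[:20], true_genes))
    spare = [g for g in cells.genes[20:] if not g.startswith("MT-")]
    rename.update(dict(zip(spare, tumor_decoys + low_decoys)))
    cells = CellMatrix(
        cells.values.rename(index=rename), unit="counts",
        clusters=cells.clusters,
    )
    return ConstructionFixture(
        cd8_specific=cd8_specific,
        de_table=de_table,
        lines=lines,
        pd1hi_expr=pd1hi_expr,
        cd8_expr=cd8_expr,
        cd8_labels=is_pd1hi,
        cells=cells,
        true_genes=true_genes,
        tumor_decoys=tumor_decoys,
        low_decoys=low_decoys,
    )
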