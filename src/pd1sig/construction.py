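"""Staged construction of the PD-1hi CD8+ T-cell signature.

The pipeline starts from two candidate gene lists (CD8+-T-cell-specific
genes and genes upregulated in PD-1hi CD8+ T cells), then applies:

1. a tumor-expression filter — genes highly expressed in cancer cell lines
   (median log2(TPM+1) at or above a cutoff) are removed, keeping the
   signature immune-specific;
2. a low-expression percentile filter — only the top fraction of candidates
   by mean expression in sorted PD-1hi CD8+ samples is kept (the fraction
   can be chosen by a hierarchical-clustering separation scan), giving the
   *initial* signature;
3. a single-cell refinement — tumor-infiltrating immune cells pass QC, the
   cluster with the highest signature score is taken as the PD-1hi CD8+
   population, and the initial signature is intersected with that cluster's
   upregulated markers, giving the *final* signature.

Each stage only removes genes, so candidate ⊇ initial ⊇ final.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .config import PipelineConfig
from .io import ExpressionMatrix, GeneSignature
from .scoring import compute_background, rank_score

__all__ = [
    "CellMatrix",
    "filter_deg",
    "assemble_candidates",
    "tumor_expression_filter",
    "percentile_expression_filter",
    "scan_percentile_cutoffs",
    "qc_filter_cells",
    "find_cluster_markers",
    "identify_top_cluster",
    "refine_signature",
    "SignatureBuildResult",
    "build_signature",
]


# ---------------------------------------------------------------------------
# single-cell container


@dataclass
class CellMatrix:
    """Gene-by-cell matrix with mitochondrial flags and optional cluster
    labels. ``unit`` is ``"counts"`` or ``"TPM"``; mitochondrial genes
    default to the ``MT-`` identifier prefix (case-insensitive)."""

    values: pd.DataFrame
    unit: str = "counts"
    mito_genes: list[str] | None = None
    clusters: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "TPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative values in cell matrix")
        if self.unit == "counts" and not np.allclose(arr, np.round(arr)):
            raise ValueError("count matrix must hold integers")
        if self.mito_genes is None:
            self.mito_genes = [
                g for g in self.values.index
                if str(g).upper().startswith("MT-")
            ]
        if self.clusters is not None:
            self.clusters = pd.Series(self.clusters)
            missing = [c for c in self.values.columns
                       if c not in self.clusters.index]
            if missing:
                raise ValueError(
                    f"cluster labels missing for {len(missing)} cell(s)"
                )
            self.clusters = self.clusters.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)

    def detected_genes(self) -> pd.Series:
        return (self.values > 0).sum(axis=0)

    def mito_fraction(self) -> pd.Series:
        total = self.values.sum(axis=0)
        present = [g for g in self.mito_genes if g in self.values.index]
        mito = (self.values.loc[present].sum(axis=0) if present
                else pd.Series(0.0, index=self.values.columns))
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = mito / total
        return frac.fillna(0.0)

    def to_tpm(self) -> ExpressionMatrix:
        """Per-cell depth normalization to transcripts-per-million."""
        total = self.values.sum(axis=0)
        if (total <= 0).any():
            raise ValueError("cell with zero total counts")
        return ExpressionMatrix(self.values / total * 1e6, unit="TPM")

    def subset_cells(self, cells) -> "CellMatrix":
        clusters = self.clusters.loc[cells] if self.clusters is not None else None
        return CellMatrix(self.values[cells], unit=self.unit,
                          mito_genes=list(self.mito_genes), clusters=clusters)


# ---------------------------------------------------------------------------
# bulk filters


def filter_deg(de: pd.DataFrame, cfg: PipelineConfig | None = None) -> list[str]:
    """Differentially expressed genes: adjusted p strictly below the cutoff
    and absolute log2 fold change strictly above it.

    ``de`` needs columns ``gene``, ``log2fc``, ``padj``.
    """
    cfg = cfg or PipelineConfig()
    for col in ("gene", "log2fc", "padj"):
        if col not in de.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    if de.empty:
        raise ValueError("DE table is empty")
    if de["gene"].duplicated().any():
        raise ValueError("DE table has duplicate gene rows")
    if ((de["padj"] < 0) | (de["padj"] > 1)).any():
        raise ValueError("padj outside [0, 1]")
    keep = (de["padj"] < cfg.deg_padj_max) & (
        de["log2fc"].abs() > cfg.deg_abs_log2fc_min
    )
    return list(de.loc[keep, "gene"])


def assemble_candidates(cd8_specific, pd1hi_deg) -> GeneSignature:
    """Union of the two candidate lists, deduplicated and sorted."""
    cd8 = list(cd8_specific)
    deg = list(pd1hi_deg)
    if not cd8 or not deg:
        raise ValueError("both candidate gene lists must be non-empty")
    union = sorted(set(cd8) | set(deg))
    return GeneSignature(union, stage="candidate", name="candidates")


def tumor_expression_filter(candidates: GeneSignature,
                            lines: ExpressionMatrix,
                            cfg: PipelineConfig | None = None) -> GeneSignature:
    """Drop genes highly expressed in cancer cell lines.

    A gene is kept when its median log2(TPM+1) across cell-line samples is
    strictly below ``ccle_median_logtpm_max``; genes absent from the
    cell-line matrix cannot be shown tumor-high and are retained with a
    warning.
    """
    cfg = cfg or PipelineConfig()
    logx = lines.log2_tpm()
    medians = logx.values.median(axis=1)
    kept, absent = [], []
    for gene in candidates.genes:
        if gene not in medians.index:
            absent.append(gene)
            kept.append(gene)
        elif medians[gene] < cfg.ccle_median_logtpm_max:
            kept.append(gene)
    if absent:
        warnings.warn(
            f"{len(absent)} candidate gene(s) absent from the cell-line "
            f"matrix were retained: {absent[:5]}..."
        )
    if not kept:
        raise ValueError("tumor-expression filter removed every candidate")
    return GeneSignature(kept, stage="candidate", name="tumor_filtered")


def percentile_expression_filter(candidates: GeneSignature,
                                 pd1hi_expr: ExpressionMatrix,
                                 keep_frac: float) -> GeneSignature:
    """Keep the top ``ceil(keep_frac * n)`` candidates by mean expression
    across PD-1hi CD8+ samples; boundary ties resolve to the
    lexicographically first gene identifier."""
    if not 0.0 < keep_frac <= 1.0:
        raise ValueError("keep_frac must lie in (0, 1]")
    present = [g for g in candidates.genes if g in pd1hi_expr.values.index]
    missing = [g for g in candidates.genes if g not in pd1hi_expr.values.index]
    if missing:
        warnings.warn(
            f"{len(missing)} candidate gene(s) absent from the PD-1hi "
            "expression matrix were dropped by the percentile filter"
        )
    if not present:
        raise ValueError("no candidate genes present in PD-1hi matrix")
    means = pd1hi_expr.values.loc[present].mean(axis=1)
    k = int(np.ceil(keep_frac * len(present)))
    order = sorted(present, key=lambda g: (-means[g], g))
    return GeneSignature(sorted(order[:k]), stage="candidate",
                         name="percentile_filtered")


def scan_percentile_cutoffs(candidates: GeneSignature,
                            cd8_expr: ExpressionMatrix,
                            labels: pd.Series,
                            grid=(0.2, 0.4, 0.6, 0.8)):
    """Choose the keep-fraction by a cluster-separation scan.

    For each fraction the candidates are subset on the PD-1hi samples'
    mean expression, all CD8 samples are clustered (distance
    1 - Pearson correlation, average linkage, two-group cut), and the cut
    is compared with the true PD-1hi / other labels. The chosen fraction is
    the smallest achieving a perfect two-group separation, otherwise the
    one with the highest adjusted Rand agreement.

    ``labels`` is a boolean Series over samples, True for PD-1hi.
    Returns ``(chosen_fraction, report)`` with one report row per fraction.
    """
    labels = pd.Series(labels).reindex(cd8_expr.samples)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    labels = labels.astype(bool)
    if labels.nunique() < 2:
        raise ValueError("labels must contain both classes")
    if len(cd8_expr.samples) < 3:
        raise ValueError("need at least 3 samples for the cutoff scan")
    pd1hi_samples = list(labels.index[labels])
    pd1hi_view = ExpressionMatrix(cd8_expr.values[pd1hi_samples],
                                  unit=cd8_expr.unit)
    logx = cd8_expr.log2_tpm()
    rows = []
    for frac in sorted(grid):
        sub = percentile_expression_filter(candidates, pd1hi_view, frac)
        data = logx.values.loc[[g for g in sub.genes
                                if g in logx.values.index]]
        corr = np.corrcoef(data.to_numpy().T)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        cut = fcluster(z, t=2, criterion="maxclust")
        ari = adjusted_rand_score(labels.to_numpy(), cut)
        rows.append(
            {
                "fraction": frac,
                "n_genes": len(sub),
                "ari": ari,
                "perfect": bool(np.isclose(ari, 1.0)),
            }
        )
    report = pd.DataFrame(rows)
    perfect = report[report["perfect"]]
    if len(perfect):
        chosen = float(perfect["fraction"].iloc[0])
    else:
        chosen = float(
            report.sort_values(["ari", "fraction"],
                               ascending=[False, True])["fraction"].iloc[0]
        )
    return chosen, report


# ---------------------------------------------------------------------------
# single-cell refinement


def qc_filter_cells(cells: CellMatrix,
                    cfg: PipelineConfig | None = None) -> CellMatrix:
    """Standard cell QC: detected-gene count within the inclusive
    [min, max] window and mitochondrial count fraction strictly below the
    cutoff."""
    cfg = cfg or PipelineConfig()
    detected = cells.detected_genes()
    mito = cells.mito_fraction()
    keep = (
        (detected >= cfg.cell_min_genes)
        & (detected <= cfg.cell_max_genes)
        & (mito < cfg.cell_max_mito_frac)
    )
    if not keep.any():
        raise ValueError("QC removed every cell")
    return cells.subset_cells(list(cells.values.columns[keep]))


def _lognorm(values: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalization to ``scale`` counts per cell followed by
    natural log1p (the convention the marker fold-changes assume)."""
    total = values.sum(axis=0)
    return np.log1p(values / total * scale)


def find_cluster_markers(cells: CellMatrix, cluster,
                         cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Marker genes of one cluster versus all other cells.

    Candidate genes are expressed (raw value > 0) in at least
    ``marker_min_cell_frac`` of cells on either side. The fold change is
    ``log(mean(expm1(norm_in)) + 1) - log(mean(expm1(norm_out)) + 1)`` on
    natural-log library-size-normalized data, and the p-value is a
    two-sided Wilcoxon rank-sum test on the normalized values. Only genes
    with ``|logfc|`` strictly above ``marker_abs_logfc_min`` are reported;
    upregulated markers are those with positive fold change.
    """
    cfg = cfg or PipelineConfig()
    if cells.clusters is None:
        raise ValueError("cell matrix has no cluster labels")
    in_mask = (cells.clusters == cluster).to_numpy()
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise ValueError("need at least 3 cells on each side")
    raw = cells.values
    norm = _lognorm(raw)
    frac_in = (raw.loc[:, in_mask] > 0).mean(axis=1)
    frac_out = (raw.loc[:, ~in_mask] > 0).mean(axis=1)
    candidates = raw.index[
        (frac_in >= cfg.marker_min_cell_frac)
        | (frac_out >= cfg.marker_min_cell_frac)
    ]
    expm = np.expm1(norm)
    mean_in = expm.loc[candidates, in_mask].mean(axis=1)
    mean_out = expm.loc[candidates, ~in_mask].mean(axis=1)
    logfc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
    keep = logfc.abs() > cfg.marker_abs_logfc_min
    rows = []
    for gene in candidates[keep]:
        a = norm.loc[gene].to_numpy()[in_mask]
        b = norm.loc[gene].to_numpy()[~in_mask]
        p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append(
            {
                "gene": gene,
                "logfc": float(logfc[gene]),
                "p": float(p),
                "frac_in": float(frac_in[gene]),
                "frac_out": float(frac_out[gene]),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "logfc", "p", "frac_in",
                                      "frac_out"])
    return out.sort_values("gene").reset_index(drop=True)


def identify_top_cluster(scores: pd.Series, labels: pd.Series):
    """The cluster with the highest mean signature score.

    Returns ``(cluster, margin)`` with the margin between the best and the
    second-best cluster means; an effective tie demands manual review.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels).loc[scores.index]
    means = scores.groupby(labels).mean().sort_values(ascending=False)
    if len(means) < 2:
        raise ValueError("need at least 2 clusters")
    margin = float(means.iloc[0] - means.iloc[1])
    if margin < 1e-12:
        raise ValueError(
            "top clusters tie within 1e-12; manual review required"
        )
    return means.index[0], margin


def refine_signature(initial: GeneSignature, markers: pd.DataFrame,
                     logfc_min: float = 0.25) -> GeneSignature:
    """Intersect the initial signature with the upregulated markers of the
    top-scoring cluster to obtain the final signature."""
    if markers.empty:
        raise ValueError("marker table is empty")
    up = set(markers.loc[markers["logfc"] > logfc_min, "gene"])
    final = sorted(set(initial.genes) & up)
    if not final:
        raise ValueError(
            "no overlap between the initial signature and upregulated markers"
        )
    return GeneSignature(final, stage="final", name="PD1hiCD8T_final")


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SignatureBuildResult:
    """All stages of one signature-construction run, plus an audit trail."""

    candidate: GeneSignature
    initial: GeneSignature
    final: GeneSignature
    audit: dict = field(default_factory=dict)
    scan_report: pd.DataFrame | None = None
    chosen_fraction: float | None = None
    top_cluster: object | None = None
    markers: pd.DataFrame | None = None


def build_signature(cd8_specific, pd1hi_deg,
                    lines: ExpressionMatrix,
                    pd1hi_expr: ExpressionMatrix,
                    cells: CellMatrix,
                    cfg: PipelineConfig | None = None,
                    cd8_expr: ExpressionMatrix | None = None,
                    cd8_labels: pd.Series | None = None) -> SignatureBuildResult:
    """Run the full staged construction.

    ``cd8_specific`` and ``pd1hi_deg`` are gene lists (run
    :func:`filter_deg` on a DE table to obtain the latter). The cutoff scan
    runs only when ``cd8_expr`` and ``cd8_labels`` are supplied and is
    reported as a diagnostic; the percentile filter itself uses
    ``cfg.percentile_keep``. The single-cell refinement scores QC-passing
    cells with the initial signature (background: genes with mean TPM above
    the configured threshold in the cell data itself), takes the
    top-scoring cluster as the PD-1hi CD8+ population, and intersects the
    initial signature with that cluster's upregulated markers.
    """
    cfg = cfg or PipelineConfig()
    candidate = assemble_candidates(cd8_specific, pd1hi_deg)
    tumor_filtered = tumor_expression_filter(candidate, lines, cfg)

    scan_report, chosen = None, None
    if cd8_expr is not None and cd8_labels is not None:
        chosen, scan_report = scan_percentile_cutoffs(
            tumor_filtered, cd8_expr, cd8_labels, grid=cfg.percentile_grid
        )

    initial = percentile_expression_filter(
        tumor_filtered, pd1hi_expr, cfg.percentile_keep
    )
    initial = GeneSignature(initial.genes, stage="initial", name="initial")

    qc_cells = qc_filter_cells(cells, cfg)
    cell_tpm = qc_cells.to_tpm()
    background = compute_background(
        cell_tpm, min_mean_tpm=cfg.background_mean_tpm_min,
        source="cell-data (portability default)",
    )
    scores = rank_score(cell_tpm, initial, background)["score"]
    top, margin = identify_top_cluster(scores, qc_cells.clusters)
    markers = find_cluster_markers(qc_cells, top, cfg)
    final = refine_signature(initial, markers,
                             logfc_min=cfg.marker_abs_logfc_min)

    audit = {
        "n_cd8_specific": len(set(cd8_specific)),
        "n_pd1hi_deg": len(set(pd1hi_deg)),
        "n_candidate": len(candidate),
        "n_tumor_filtered": len(tumor_filtered),
        "n_initial": len(initial),
        "n_final": len(final),
        "n_cells_pre_qc": len(cells.cells),
        "n_cells_post_qc": len(qc_cells.cells),
        "top_cluster": top,
        "top_cluster_margin": margin,
        "chosen_fraction": chosen,
        "percentile_keep_used": cfg.percentile_keep,
    }
    return SignatureBuildResult(
        candidate=candidate,
        initial=initial,
        final=final,
        audit=audit,
        scan_report=scan_report,
        chosen_fraction=chosen,
        top_cluster=top,
        markers=markers,
    )
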