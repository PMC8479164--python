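"""Pipeline configuration.

Every threshold of the signature-construction and evaluation procedure lives
in one validated, serializable record, so a run is fully described by its
inputs plus a :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the signature pipeline.

    Parameters
    ----------
    deg_padj_max
        Adjusted-p cutoff for calling a gene differentially expressed
        (strict ``<``).
    deg_abs_log2fc_min
        Absolute log2 fold-change cutoff for DE calls (strict ``>``).
    ccle_median_logtpm_max
        Genes with median log2(TPM+1) in tumor cell lines at or above this
        value are considered tumor-intrinsic and removed (retain strictly
        below).
    percentile_grid
        Candidate keep-fractions scanned when choosing the low-expression
        cutoff.
    percentile_keep
        Fraction of candidate genes kept by the low-expression filter
        (ranked by mean expression in PD-1hi CD8+ samples).
    background_mean_tpm_min
        Genes with across-sample mean TPM strictly above this value form the
        ranking universe for scoring.
    cell_min_genes, cell_max_genes
        Inclusive bounds on detected genes per cell for single-cell QC.
    cell_max_mito_frac
        Cells at or above this mitochondrial count fraction are removed
        (strict ``<`` to keep).
    marker_min_cell_frac
        A gene must be expressed in at least this fraction of cells on one
        side of the comparison to be tested as a cluster marker.
    marker_abs_logfc_min
        Absolute natural-log fold-change cutoff for reporting markers.
    n_variable_genes
        Number of highly variable genes used by the synthetic single-cell
        workflow (dispersion ranking).
    dcb_sd_months_min
        Stable disease counts as durable clinical benefit only when benefit
        exceeds this many months (strict ``>``).
    pancancer_high_pct
        Pooled score percentile above which a sample counts as high-score in
        the per-cancer-type response-rate analysis.
    contrast_tertile
        Fraction of samples in each of the top/bottom score groups for the
        high-vs-low contrast.
    """

    deg_padj_max: float = 0.05
    deg_abs_log2fc_min: float = 1.0
    ccle_median_logtpm_max: float = 3.1
    percentile_grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    percentile_keep: float = 0.6
    background_mean_tpm_min: float = 1.0
    cell_min_genes: int = 1000
    cell_max_genes: int = 5000
    cell_max_mito_frac: float = 0.05
    marker_min_cell_frac: float = 0.25
    marker_abs_logfc_min: float = 0.25
    n_variable_genes: int = 3000
    dcb_sd_months_min: float = 6.0
    pancancer_high_pct: float = 0.80
    contrast_tertile: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        grid = tuple(float(f) for f in self.percentile_grid)
        object.__setattr__(self, "percentile_grid", grid)
        if not 0.0 <= self.deg_padj_max <= 1.0:
            raise ValueError("deg_padj_max must lie in [0, 1]")
        if self.deg_abs_log2fc_min < 0:
            raise ValueError("deg_abs_log2fc_min must be non-negative")
        if not grid or any(not 0.0 < f <= 1.0 for f in grid):
            raise ValueError("percentile_grid fractions must lie in (0, 1]")
        if not 0.0 < self.percentile_keep <= 1.0:
            raise ValueError("percentile_keep must lie in (0, 1]")
        if self.background_mean_tpm_min < 0:
            raise ValueError("background_mean_tpm_min must be non-negative")
        if not 0 < self.cell_min_genes <= self.cell_max_genes:
            raise ValueError("need 0 < cell_min_genes <= cell_max_genes")
        if not 0.0 < self.cell_max_mito_frac <= 1.0:
            raise ValueError("cell_max_mito_frac must lie in (0, 1]")
        if not 0.0 <= self.marker_min_cell_frac <= 1.0:
            raise ValueError("marker_min_cell_frac must lie in [0, 1]")
        if self.marker_abs_logfc_min < 0:
            raise ValueError("marker_abs_logfc_min must be non-negative")
        if self.n_variable_genes < 1:
            raise ValueError("n_variable_genes must be positive")
        if self.dcb_sd_months_min < 0:
            raise ValueError("dcb_sd_months_min must be non-negative")
        if not 0.0 < self.pancancer_high_pct < 1.0:
            raise ValueError("pancancer_high_pct must lie in (0, 1)")
        if not 0.0 < self.contrast_tertile <= 0.5:
            raise ValueError("contrast_tertile must lie in (0, 0.5]")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["percentile_grid"] = list(d["percentile_grid"])
        return d

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from YAML or a flat ``key=value`` file."""
        with open(path) as fh:
            text = fh.read()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = None
        if not isinstance(data, dict):
            data = {}
            for lineno, line in enumerate(text.splitlines(), start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(
                        f"line {lineno}: expected key=value, got {line!r}"
                    )
                key, _, value = line.partition("=")
                data[key.strip()] = yaml.safe_load(value.strip())
        return cls.from_dict(data)

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)
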