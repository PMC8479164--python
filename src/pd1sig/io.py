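"""Input/output and core containers.

Reads and writes gene-by-sample expression matrices (dense TSV/CSV, sparse
MatrixMarket triplets), gene sets (GMT or one-gene-per-line lists), and
clinical tables; derives clinical-benefit response labels; harmonizes gene
identifiers between matrices and signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "GeneSignature",
    "ClinicalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_set",
    "read_gene_sets",
    "write_gmt",
    "read_clinical",
    "label_response",
    "harmonize_genes",
]

RECIST_LEVELS = ("CR", "PR", "SD", "PD")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with a unit tag.

    ``values`` is a genes x samples DataFrame; ``unit`` is one of
    ``"TPM"``, ``"counts"`` or ``"log2TPM"``. TPM and count matrices must be
    non-negative; log-scale matrices (e.g. after housekeeping normalization)
    may contain negative entries.
    """

    values: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "counts", "log2TPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5]
            raise ValueError(f"duplicate gene identifiers: {list(dup)}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:5]
            raise ValueError(f"duplicate sample identifiers: {list(dup)}")
        if self.unit in ("TPM", "counts") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values in a {self.unit} matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log2_tpm(self) -> "ExpressionMatrix":
        """Return the matrix on the log2(TPM+1) scale."""
        if self.unit == "log2TPM":
            return self
        if self.unit != "TPM":
            raise ValueError("log2_tpm requires a TPM matrix")
        return ExpressionMatrix(np.log2(self.values + 1.0), unit="log2TPM")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], unit=self.unit)


@dataclass
class GeneSignature:
    """An ordered, duplicate-free gene set with a provenance stage tag."""

    genes: list[str]
    stage: str = "comparator"
    name: str = "signature"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        seen: dict[str, None] = {}
        dropped = 0
        for g in self.genes:
            if g in seen:
                dropped += 1
            else:
                seen[g] = None
        if dropped:
            warnings.warn(
                f"signature {self.name!r}: {dropped} duplicate gene(s) removed"
            )
        self.genes = list(seen)
        if self.stage not in ("candidate", "initial", "final", "comparator"):
            raise ValueError(f"unknown stage {self.stage!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in set(self.genes)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations for response and survival analysis.

    One row per sample. Recognized columns: ``sample``, ``recist``,
    ``benefit_months``, ``response`` (DCB/NDB), ``os_time``/``os_event``,
    ``pfs_time``/``pfs_event`` (months, binary flags), ``tmb``; any further
    columns are treated as covariates.
    """

    data: pd.DataFrame

    CORE = (
        "sample",
        "recist",
        "benefit_months",
        "response",
        "os_time",
        "os_event",
        "pfs_time",
        "pfs_event",
        "tmb",
    )

    def __post_init__(self) -> None:
        df = self.data
        if "sample" not in df.columns:
            raise ValueError("clinical table requires a 'sample' column")
        if df["sample"].duplicated().any():
            raise ValueError("duplicate sample identifiers in clinical table")
        if "recist" in df.columns:
            bad = set(df["recist"].dropna()) - set(RECIST_LEVELS)
            if bad:
                raise ValueError(f"unknown RECIST categories: {sorted(bad)}")
        for prefix in ("os", "pfs"):
            t, e = f"{prefix}_time", f"{prefix}_event"
            if e in df.columns:
                if t not in df.columns:
                    raise ValueError(f"{e} present without {t}")
                orphan = df[e].notna() & df[t].isna()
                if orphan.any():
                    raise ValueError(f"{e} set where {t} is missing")

    @property
    def samples(self) -> list[str]:
        return list(self.data["sample"])

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.CORE]

    def derive_response(self, mode: str = "dcb_ndb",
                        sd_months_min: float = 6.0) -> "ClinicalTable":
        """Fill the ``response`` column from RECIST and benefit duration."""
        df = self.data.copy()
        labels = [
            label_response(r, m, mode=mode, sd_months_min=sd_months_min)
            for r, m in zip(
                df.get("recist", pd.Series([None] * len(df))),
                df.get("benefit_months", pd.Series([None] * len(df))),
            )
        ]
        df["response"] = labels
        return ClinicalTable(df)

    def endpoint(self, which: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (times, events, mask of usable rows) for OS or PFS."""
        which = which.lower()
        if which not in ("os", "pfs"):
            raise ValueError("endpoint must be 'os' or 'pfs'")
        t = self.data[f"{which}_time"]
        e = self.data[f"{which}_event"]
        mask = t.notna() & e.notna()
        return t[mask].to_numpy(float), e[mask].to_numpy(int), mask.to_numpy()


# ---------------------------------------------------------------------------
# expression matrices


def _collapse_duplicates(df: pd.DataFrame, unit: str) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    how = "sum" if unit == "counts" else "mean"
    return df.groupby(level=0, sort=False).agg(how)


def read_expression_matrix(path, format: str = "tsv",
                           unit: str = "TPM") -> ExpressionMatrix:
    """Read a gene-by-sample matrix.

    ``format`` is ``"tsv"``/``"csv"`` (dense, genes in the first column,
    sample identifiers in the header) or ``"mtx_triplet"`` (a directory with
    ``matrix.mtx`` in MatrixMarket coordinate format plus ``genes.tsv`` and
    ``barcodes.tsv`` sidecars, genes x samples). Duplicate gene rows are
    collapsed by sum for counts and by mean otherwise.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        fields = header.split(sep)
        if len(fields) < 2:
            raise ParseError(f"{path}: line 1: header has fewer than 2 columns")
        names = fields[1:]
        if any(not n for n in names):
            raise ParseError(f"{path}: line 1: empty sample identifier in header")
        if len(set(names)) != len(names):
            raise ValueError(f"{path}: duplicate sample identifiers in header")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx_triplet":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar file: {f}")
        mat = scipy.io.mmread(mtx)
        genes = [ln.split("\t")[0].strip()
                 for ln in genes_f.read_text().splitlines() if ln.strip()]
        samples = [ln.strip() for ln in barcodes_f.read_text().splitlines()
                   if ln.strip()]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                           dtype=float)
        if dense.shape != (len(genes), len(samples)):
            raise ParseError(
                f"{mtx}: shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        if len(set(samples)) != len(samples):
            raise ValueError(f"{barcodes_f}: duplicate sample identifiers")
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")

    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    df = _collapse_duplicates(df, unit)
    return ExpressionMatrix(df, unit=unit)


def write_expression_matrix(x: ExpressionMatrix, path,
                            format: str = "tsv") -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        x.values.to_csv(path, sep=sep, index_label="gene")
    elif format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(x.values.to_numpy())
        scipy.io.mmwrite(path / "matrix.mtx", sparse)
        (path / "genes.tsv").write_text("\n".join(x.genes) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(x.samples) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# gene sets


def read_gene_sets(path, format: str = "gmt",
                   stage: str = "comparator") -> list[GeneSignature]:
    """Read gene sets: GMT (one per line) or a one-gene-per-line list."""
    path = Path(path)
    out: list[GeneSignature] = []
    if format == "gmt":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs name, description, "
                    "and at least one gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: empty gene list")
            out.append(GeneSignature(genes, stage=stage, name=name))
    elif format == "list":
        genes = [ln.strip() for ln in path.read_text().splitlines()
                 if ln.strip()]
        if not genes:
            raise ValueError(f"{path}: empty gene list")
        out.append(GeneSignature(genes, stage=stage, name=path.stem))
    else:
        raise ValueError(f"unknown format {format!r}")
    return out


def read_gene_set(path, format: str = "list",
                  stage: str = "comparator") -> GeneSignature:
    """Read a file expected to contain exactly one gene set."""
    sets = read_gene_sets(path, format=format, stage=stage)
    if len(sets) != 1:
        raise ValueError(
            f"{path} holds {len(sets)} gene sets; use read_gene_sets"
        )
    return sets[0]


def write_gmt(signatures, path) -> None:
    lines = []
    for sig in signatures:
        lines.append("\t".join([sig.name, sig.stage, *sig.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# clinical tables and response labels


def read_clinical(path, sep: str = "\t") -> ClinicalTable:
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
    return ClinicalTable(df)


def label_response(recist, benefit_months=None, mode: str = "dcb_ndb",
                   sd_months_min: float = 6.0):
    """Derive a clinical-benefit label from RECIST and benefit duration.

    ``dcb_ndb`` mode: CR/PR -> DCB; SD counts as DCB only when benefit
    exceeds ``sd_months_min`` months (strictly); PD -> NDB. SD without a
    benefit duration cannot be classified and yields ``None`` with a
    warning.

    ``crpr_pd`` mode is the surrogate used when benefit duration is
    unavailable: CR/PR -> DCB, PD -> NDB, SD -> ``None``.
    """
    if recist is None or (isinstance(recist, float) and np.isnan(recist)):
        return None
    if recist not in RECIST_LEVELS:
        raise ValueError(f"unknown RECIST category {recist!r}")
    if mode not in ("dcb_ndb", "crpr_pd"):
        raise ValueError(f"unknown mode {mode!r}")
    if recist in ("CR", "PR"):
        return "DCB"
    if recist == "PD":
        return "NDB"
    # SD
    if mode == "crpr_pd":
        return None
    missing = benefit_months is None or (
        isinstance(benefit_months, float) and np.isnan(benefit_months)
    )
    if missing:
        warnings.warn("SD without benefit duration cannot be classified")
        return None
    if benefit_months < 0:
        raise ValueError("benefit_months must be non-negative")
    return "DCB" if benefit_months > sd_months_min else "NDB"


# ---------------------------------------------------------------------------
# identifier harmonization


def harmonize_genes(x: ExpressionMatrix, signature: GeneSignature,
                    case_fold: bool = False):
    """Intersect a signature with a matrix's gene universe.

    Returns ``(matrix, signature, report)`` where the signature is reduced
    to genes present in the matrix (order preserved) and the report lists
    the signature genes that were absent. With ``case_fold`` identifiers are
    matched case-insensitively (matrix spelling wins).
    """
    if case_fold:
        lookup = {g.casefold(): g for g in x.genes}
        matched, missing = [], []
        for g in signature.genes:
            hit = lookup.get(g.casefold())
            (matched.append(hit) if hit is not None else missing.append(g))
    else:
        index = set(x.genes)
        matched = [g for g in signature.genes if g in index]
        missing = [g for g in signature.genes if g not in index]
    if not matched:
        raise ValueError(
            f"no overlap between matrix and signature {signature.name!r}"
        )
    report = {"missing": missing, "n_matched": len(matched)}
    out = GeneSignature(matched, stage=signature.stage, name=signature.name)
    return x, out, report
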