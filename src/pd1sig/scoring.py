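"""Rank-based single-sample signature scoring.

The signature score of a sample is the mean rank of the signature genes
within the sample's expression profile, restricted to a fixed background
gene universe and normalized to [0, 1]:

    score = (meanRank - (g+1)/2) / ((N - (g-1)/2) - (g+1)/2)

with ``N`` the background universe size, ``g`` the number of signature
genes used, and average (fractional) ranks for ties. The score is 0 when
the signature genes occupy the bottom ``g`` ranks, 1 when they occupy the
top ``g`` ranks, and is invariant to any strictly increasing per-sample
transform of expression (so TPM and log TPM give identical scores).

Also provides the background-universe constructor, housekeeping-gene
normalization, and the mean-expression comparator scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import ExpressionMatrix, GeneSignature

__all__ = [
    "BackgroundSet",
    "compute_background",
    "rank_score",
    "housekeeping_normalize",
    "mean_expression_score",
]


@dataclass(frozen=True)
class BackgroundSet:
    """The ranking universe: genes expressed above a mean-TPM threshold in a
    reference compendium."""

    genes: tuple[str, ...]
    source: str = "reference"
    min_mean_tpm: float = 1.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("background set is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in set(self.genes)


def compute_background(reference: ExpressionMatrix,
                       min_mean_tpm: float = 1.0,
                       source: str = "reference") -> BackgroundSet:
    """Genes whose across-sample mean TPM strictly exceeds the threshold."""
    if reference.unit != "TPM":
        raise ValueError("background reference must be in TPM")
    means = reference.values.mean(axis=1)
    genes = tuple(means.index[means > min_mean_tpm])
    if not genes:
        raise ValueError(
            f"no genes with mean TPM > {min_mean_tpm} in the reference"
        )
    return BackgroundSet(genes, source=source, min_mean_tpm=min_mean_tpm)


def rank_score(x: ExpressionMatrix, signature: GeneSignature,
               background: BackgroundSet | None = None) -> pd.DataFrame:
    """Normalized mean-rank signature score per sample.

    The ranking universe is the intersection of the matrix genes with the
    background set (all matrix genes when ``background`` is None — the
    portability default for datasets without a reference compendium).
    Returns a DataFrame indexed by sample with columns ``score``,
    ``n_signature_used`` and ``n_background_used``.
    """
    if background is None:
        universe = list(x.values.index)
    else:
        bg = set(background.genes)
        universe = [g for g in x.values.index if g in bg]
    n = len(universe)
    uni_set = set(universe)
    sig_used = [g for g in signature.genes if g in uni_set]
    g = len(sig_used)
    if g < 2:
        missing = [s for s in signature.genes if s not in uni_set]
        raise ValueError(
            f"fewer than 2 usable signature genes (missing from the ranking "
            f"universe: {missing})"
        )
    if n == g:
        raise ValueError(
            "ranking universe equals the signature; score is degenerate"
        )
    sub = x.values.loc[universe]
    ranks = sub.rank(axis=0, method="average")  # ascending, fractional ties
    mean_rank = ranks.loc[sig_used].mean(axis=0)
    lo = (g + 1) / 2.0
    hi = n - (g - 1) / 2.0
    score = (mean_rank - lo) / (hi - lo)
    out = pd.DataFrame(
        {
            "score": score,
            "n_signature_used": g,
            "n_background_used": n,
        }
    )
    out.index.name = "sample"
    return out


def housekeeping_normalize(x: ExpressionMatrix,
                           hk_genes: GeneSignature) -> ExpressionMatrix:
    """Subtract each sample's mean housekeeping expression on the
    log2(TPM+1) scale, removing between-sample depth/platform offsets."""
    logx = x.log2_tpm()
    present = [g for g in hk_genes.genes if g in logx.values.index]
    if not present:
        raise ValueError("no housekeeping genes present in the matrix")
    hk_mean = logx.values.loc[present].mean(axis=0)
    return ExpressionMatrix(logx.values.sub(hk_mean, axis=1), unit="log2TPM")


def mean_expression_score(x: ExpressionMatrix,
                          genes: GeneSignature) -> pd.DataFrame:
    """Comparator score: per-sample mean log2(TPM+1) of the gene set.

    Single-gene sets reduce to that gene's log expression. Missing genes
    are dropped (counted in ``n_missing``); an all-missing set is an error.
    """
    logx = x.log2_tpm()
    present = [g for g in genes.genes if g in logx.values.index]
    if not present:
        raise ValueError(f"no genes of {genes.name!r} present in the matrix")
    n_missing = len(genes.genes) - len(present)
    if n_missing:
        warnings.warn(
            f"{genes.name!r}: {n_missing} gene(s) missing from the matrix"
        )
    out = pd.DataFrame(
        {
            "score": logx.values.loc[present].mean(axis=0),
            "n_used": len(present),
            "n_missing": n_missing,
        }
    )
    out.index.name = "sample"
    return out
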