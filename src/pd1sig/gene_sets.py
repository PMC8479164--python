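"""Built-in gene sets: the published core of the PD-1hi CD8+ T-cell
signature and the comparator biomarker panels.

Only 14 of the 31 final signature genes were published by name (seven
T-cell-exhaustion genes and seven cell-cycle genes); ``PD1HI_CORE`` is that
named subset, not the full signature.
"""

from .io import GeneSignature

# Named subset of the final PD-1hi CD8+ T-cell signature: exhaustion program
# (checkpoints and the exhaustion transcription factor TOX) plus the
# proliferation/cell-cycle program.
PD1HI_EXHAUSTION = ("CTLA4", "PDCD1", "TOX", "SIRPG", "HAVCR2", "TIGIT",
                    "IGFLR1")
PD1HI_CELL_CYCLE = ("BARD1", "CENPE", "RAD51", "SMC2", "GINS2", "CLSPN",
                    "CCNF")


def pd1hi_core() -> GeneSignature:
    """The 14 published genes of the final signature (a subset of 31)."""
    return GeneSignature(
        list(PD1HI_EXHAUSTION) + list(PD1HI_CELL_CYCLE),
        stage="final",
        name="PD1hiCD8T_core14",
    )


def ifng6() -> GeneSignature:
    """Six-gene interferon-gamma response panel (mean-expression score)."""
    return GeneSignature(
        ["IFNG", "STAT1", "IDO1", "CXCL10", "CXCL9", "HLA-DRA"],
        name="IFNG6",
    )


def crma() -> GeneSignature:
    """CTLA-4-resistance MAGE-A panel (mean-expression score)."""
    return GeneSignature(
        ["MAGEA3", "MAGEA2", "MAGEA2B", "MAGEA12", "MAGEA6"],
        name="CRMA",
    )


def pdl1() -> GeneSignature:
    return GeneSignature(["CD274"], name="PDL1")


def pd1() -> GeneSignature:
    return GeneSignature(["PDCD1"], name="PD1")


def housekeeping15() -> GeneSignature:
    """Fifteen housekeeping genes used for cross-dataset normalization."""
    return GeneSignature(
        ["RPL38", "UBA52", "RPL4", "RPS29", "SLC25A3", "CLTC", "RPL37",
         "PSMA1", "RPL8", "PPP2CA", "TXNL1", "MMADHC", "PSMC1", "RPL13A",
         "MRFAP1"],
        name="housekeeping15",
    )
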