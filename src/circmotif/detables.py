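"""Differential-expression tables: signed DE score, FDR control, gene classes.

Input is a DESeq2-style per-gene table (gene_id, log2_fold_change, p_value,
adjusted_p_value).  The signed DE score, -log10(p) times the fold-change
direction, ranks genes from most confidently down-regulated (large negative)
to most confidently up-regulated (large positive) and is the quantity the
motif-scoring stage consumes.  Genes are classified down / up / notDE at a
Benjamini-Hochberg FDR threshold (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClassifyParams",
    "compute_de_score",
    "bh_adjust",
    "classify_genes",
    "read_de_table",
    "DOWN",
    "UP",
    "NOT_DE",
]

DOWN, UP, NOT_DE = "down", "up", "notDE"

P_FLOOR = 1e-300  # DESeq2 can emit p = 0; floored so -log10 stays finite

REQUIRED_COLUMNS = ("gene_id", "log2_fold_change", "p_value")

# DESeq2's native headers, remapped on read
DESEQ2_COLUMN_MAP = {
    "log2FoldChange": "log2_fold_change",
    "pvalue": "p_value",
    "padj": "adjusted_p_value",
}


@dataclass(frozen=True)
class ClassifyParams:
    """fdr_threshold: adjusted-p cutoff for calling a gene DE.

    ranking_mode selects the gene-ranking statistic used downstream:
    "signed_p" (the -log10(p) x direction score) or "fold_change" (raw
    log2FC, the convention for public knockdown compendia that provide no
    usable per-gene p-value ranking).
    """

    fdr_threshold: float = 0.1
    ranking_mode: str = "signed_p"

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.ranking_mode not in ("signed_p", "fold_change"):
            raise ValueError("ranking_mode must be 'signed_p' or 'fold_change'")


def compute_de_score(log2_fold_change, p_value, p_floor: float = P_FLOOR):
    """Signed DE score: -log10(p) x sign(log2FC).

    log2FC of exactly 0 gives score 0 (direction undefined).  Accepts scalars
    or arrays.  p is floored at ``p_floor`` before the log; p <= 0 after
    flooring is an error.
    """
    lfc = np.asarray(log2_fold_change, dtype=float)
    p = np.asarray(p_value, dtype=float)
    if np.any(p > 1) or np.any(p < 0) or np.any(np.isnan(p)):
        raise ValueError("p_value must lie in [0, 1]")
    p = np.maximum(p, p_floor)
    if np.any(p <= 0):
        raise ValueError("p_value non-positive after flooring")
    score = -np.log10(p) * np.sign(lfc)
    # -log10(1) = 0 -> avoid -0.0 leaking through
    score = score + 0.0
    if score.ndim == 0:
        return float(score)
    return score


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited DE table, remapping DESeq2-native headers."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=DESEQ2_COLUMN_MAP)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path} missing required column(s): {missing}")
    return df


def classify_genes(
    de: pd.DataFrame,
    params: ClassifyParams = ClassifyParams(),
    recompute_adjusted: bool = False,
) -> pd.DataFrame:
    """Attach de_score and de_class columns.

    down iff padj < threshold and log2FC < 0; up iff padj < threshold and
    log2FC > 0; notDE otherwise.  Adjusted p-values present in the table are
    used verbatim unless ``recompute_adjusted``; absent ones are computed by
    Benjamini-Hochberg from the raw p-values.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"DE table missing required column(s): {missing}")
    out = de.copy()
    if recompute_adjusted or "adjusted_p_value" not in out.columns:
        out["adjusted_p_value"] = bh_adjust(out["p_value"].to_numpy())
    out["de_score"] = compute_de_score(
        out["log2_fold_change"].to_numpy(), out["p_value"].to_numpy()
    )
    padj = out["adjusted_p_value"].to_numpy(dtype=float)
    lfc = out["log2_fold_change"].to_numpy(dtype=float)
    sig = padj < params.fdr_threshold
    cls = np.full(len(out), NOT_DE, dtype=object)
    cls[sig & (lfc < 0)] = DOWN
    cls[sig & (lfc > 0)] = UP
    out["de_class"] = cls
    return out


def class_counts(classified: pd.DataFrame) -> dict[str, int]:
    vc = classified["de_class"].value_counts()
    return {c: int(vc.get(c, 0)) for c in (DOWN, UP, NOT_DE)}
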