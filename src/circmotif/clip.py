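"""CLIP peak filtering, gene-level binding annotation, and enrichment statistics.

Peaks come from eCLIP-style experiments: genomic intervals per RNA-binding
protein (RBP) with a log2 fold-enrichment over a size-matched input control.
The standard stringency filter keeps peaks at least eightfold enriched
(linear scale, boundary inclusive) and at least 4 nt wide; a gene counts as
bound by an RBP when a surviving peak overlaps one of its annotated feature
intervals (3'UTRs by default) by at least 4 nt on the same strand.

Enrichment of a binary gene feature across DE classes uses the Pearson
chi-square test on the 2x2 table (uncorrected by default, Yates optional),
falling back to Fisher's exact test when a margin is zero.  Gene-set overlap
uses the one-sided hypergeometric (Fisher) tail.  All intervals are 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detables import DOWN, NOT_DE, UP

__all__ = [
    "BindingSite",
    "PeakFilterParams",
    "EnrichmentResult",
    "ConcordanceTable",
    "filter_peaks",
    "annotate_gene_binding",
    "contingency_enrichment",
    "set_overlap_fisher",
    "cross_concordance",
    "peak_motif_overlap",
    "sweep_overlaps",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingSite:
    """One CLIP peak (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    rbp: str
    log2_fold_enrichment: float
    neg_log10_p: float = 0.0
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakFilterParams:
    """min_fold_enrichment is on the LINEAR scale (8-fold == log2 of 3)."""

    min_fold_enrichment: float = 8.0
    min_peak_length: int = 4
    min_feature_overlap: int = 4

    def __post_init__(self) -> None:
        if min(self.min_fold_enrichment, self.min_peak_length, self.min_feature_overlap) < 1:
            raise ValueError("all filter parameters must be >= 1")


def filter_peaks(peaks: list[BindingSite], params: PeakFilterParams = PeakFilterParams()) -> list[BindingSite]:
    """Keep peaks with linear fold-enrichment >= threshold AND length >= minimum.

    Idempotent; per-RBP kept/dropped counts are logged.
    """
    min_log2 = np.log2(params.min_fold_enrichment)
    kept = [
        p
        for p in peaks
        if p.log2_fold_enrichment >= min_log2 and p.length >= params.min_peak_length
    ]
    by_rbp_in: dict[str, int] = {}
    by_rbp_out: dict[str, int] = {}
    for p in peaks:
        by_rbp_in[p.rbp] = by_rbp_in.get(p.rbp, 0) + 1
    for p in kept:
        by_rbp_out[p.rbp] = by_rbp_out.get(p.rbp, 0) + 1
    for rbp in sorted(by_rbp_in):
        log.info("filter_peaks: %s kept %d/%d", rbp, by_rbp_out.get(rbp, 0), by_rbp_in[rbp])
    return kept


def sweep_overlaps(
    a: list[tuple[int, int, int]], b: list[tuple[int, int, int]], min_overlap: int = 1
) -> list[tuple[int, int, int]]:
    """All (i, j, overlap) pairs between interval lists a and b on one sequence.

    Intervals are (start, end, idx), half-open.  Sorted two-pointer sweep;
    equivalent to the naive all-pairs comparison but O(n log n + hits).
    """
    a_sorted = sorted(a)
    b_sorted = sorted(b)
    out = []
    j0 = 0
    for (sa, ea, ia) in a_sorted:
        # b intervals ending at or before sa cannot overlap this or any later a
        while j0 < len(b_sorted) and b_sorted[j0][1] <= sa:
            j0 += 1
        j = j0
        while j < len(b_sorted) and b_sorted[j][0] < ea:
            sb, eb, ib = b_sorted[j]
            ov = min(ea, eb) - max(sa, sb)
            if ov >= min_overlap:
                out.append((ia, ib, ov))
            j += 1
    return out


def annotate_gene_binding(
    peaks: list[BindingSite],
    features: pd.DataFrame,
    params: PeakFilterParams = PeakFilterParams(),
) -> dict[str, set[str]]:
    """gene_id -> set of RBPs with a filtered peak overlapping a gene feature.

    *features* is a BED-like frame with columns chrom, start, end, gene_id,
    strand.  A gene is bound iff some peak overlaps one of its intervals by
    >= min_feature_overlap nt on the same chrom and strand.
    """
    for col in ("chrom", "start", "end", "gene_id", "strand"):
        if col not in features.columns:
            raise ValueError(f"features missing column {col!r}")
    bad = features.index[features["end"] <= features["start"]]
    if len(bad):
        raise ValueError(f"malformed feature interval (end <= start) at row {bad[0]}")
    bound: dict[str, set[str]] = {}
    feats_by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    rows = features.reset_index(drop=True)
    for i, row in rows.iterrows():
        feats_by_key.setdefault((row["chrom"], row["strand"]), []).append(
            (int(row["start"]), int(row["end"]), i)
        )
    peaks_by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for pi, p in enumerate(peaks):
        peaks_by_key.setdefault((p.chrom, p.strand), []).append((p.start, p.end, pi))
    for key, plist in peaks_by_key.items():
        flist = feats_by_key.get(key)
        if not flist:
            continue
        for pi, fi, _ov in sweep_overlaps(plist, flist, min_overlap=params.min_feature_overlap):
            gene = rows.at[fi, "gene_id"]
            bound.setdefault(gene, set()).add(peaks[pi].rbp)
    return bound


@dataclass
class EnrichmentResult:
    """2x2 association test result.

    contingency rows are groups, columns are (has feature, lacks feature).
    """

    contingency: np.ndarray
    statistic: float
    p_value: float
    test: str  # "chisq" | "fisher"
    correction: str = "none"
    group_percent: dict[str, float] = field(default_factory=dict)
    odds_ratio: float | None = None


def contingency_enrichment(
    group_a: set[str],
    group_b: set[str],
    has_feature: dict[str, bool],
    correction: str = "none",
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> EnrichmentResult:
    """Chi-square association between group membership and a binary feature.

    Pearson chi-square on the 2x2 table, 1 df, two-sided; Yates correction
    optional.  A zero margin makes the chi-square undefined, in which case
    Fisher's exact test is used instead (logged).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    if correction not in ("none", "yates"):
        raise ValueError("correction must be 'none' or 'yates'")
    a = sum(bool(has_feature.get(g, False)) for g in group_a)
    b = len(group_a) - a
    c = sum(bool(has_feature.get(g, False)) for g in group_b)
    d = len(group_b) - c
    table = np.array([[a, b], [c, d]], dtype=float)
    pct = {labels[0]: 100.0 * a / len(group_a), labels[1]: 100.0 * c / len(group_b)}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.info("contingency_enrichment: zero margin, falling back to Fisher")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return EnrichmentResult(table, float("nan"), float(p), "fisher",
                                correction, pct, float(odds))
    chi2, p, _, _ = stats.chi2_contingency(table, correction=(correction == "yates"))
    return EnrichmentResult(table, float(chi2), float(p), "chisq", correction, pct)


def set_overlap_fisher(set_a: set[str], set_b: set[str], universe: set[str]) -> EnrichmentResult:
    """One-sided (enrichment) Fisher test of |A ∩ B| against the hypergeometric null."""
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    table = np.array(
        [
            [k, len(set_a) - k],
            [len(set_b) - k, len(universe) - len(set_a) - len(set_b) + k],
        ],
        dtype=float,
    )
    odds, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(table, float(k), float(p), "fisher", "none", {}, float(odds))


@dataclass
class ConcordanceTable:
    """Cross-knockdown directional concordance.

    For each direction in experiment A (down/up), the counts and fractions of
    classes in experiment B, over the shared gene universe.
    """

    counts: pd.DataFrame  # index down/up (in A); columns down/up/notDE (in B)
    fractions: pd.DataFrame
    n_shared: int


def cross_concordance(de_a: pd.DataFrame, de_b: pd.DataFrame) -> ConcordanceTable:
    """How genes regulated in experiment A behave in experiment B.

    Both frames must carry de_class (see classify_genes).  Built only over
    genes present in both tables; empty intersection is an error.
    """
    for df, name in ((de_a, "A"), (de_b, "B")):
        if "de_class" not in df.columns:
            raise ValueError(f"experiment {name} lacks de_class (run classify_genes)")
    a = de_a.set_index("gene_id")["de_class"]
    b = de_b.set_index("gene_id")["de_class"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between experiments")
    counts = pd.DataFrame(0, index=[DOWN, UP], columns=[DOWN, UP, NOT_DE], dtype=int)
    ct = pd.crosstab(a.loc[shared], b.loc[shared])
    for r in (DOWN, UP):
        for c in (DOWN, UP, NOT_DE):
            if r in ct.index and c in ct.columns:
                counts.at[r, c] = int(ct.at[r, c])
    row_sums = counts.sum(axis=1).replace(0, np.nan)
    fractions = counts.div(row_sums, axis=0)
    return ConcordanceTable(counts=counts, fractions=fractions, n_shared=int(len(shared)))


def peak_motif_overlap(
    peaks: list[BindingSite],
    matches,
    min_overlap: int = 1,
) -> tuple[dict[str, float], dict[str, set[str]]]:
    """Per-RBP fraction of peaks overlapping >= 1 motif match (>= min_overlap nt).

    *matches* are MotifMatch objects on the same coordinate system
    (sequence_id == peak chrom).  Also returns, per RBP, the set of
    sequences (genes) where a peak and a motif match overlap — the
    co-occurrence flags consumed by downstream enrichment.
    """
    match_by_seq: dict[str, list[tuple[int, int, int]]] = {}
    for mi, m in enumerate(matches):
        match_by_seq.setdefault(m.sequence_id, []).append((m.start, m.end, mi))
    per_rbp_total: dict[str, int] = {}
    per_rbp_hit: dict[str, int] = {}
    co_genes: dict[str, set[str]] = {}
    peaks_by_seq: dict[str, list[tuple[int, int, int]]] = {}
    for pi, p in enumerate(peaks):
        per_rbp_total[p.rbp] = per_rbp_total.get(p.rbp, 0) + 1
        peaks_by_seq.setdefault(p.chrom, []).append((p.start, p.end, pi))
    for seq_id, plist in peaks_by_seq.items():
        mlist = match_by_seq.get(seq_id)
        if not mlist:
            continue
        hit_idx = {pi for pi, _mi, _ov in sweep_overlaps(plist, mlist, min_overlap=min_overlap)}
        for pi in hit_idx:
            rbp = peaks[pi].rbp
            per_rbp_hit[rbp] = per_rbp_hit.get(rbp, 0) + 1
            co_genes.setdefault(rbp, set()).add(seq_id)
    fractions = {
        rbp: per_rbp_hit.get(rbp, 0) / total for rbp, total in per_rbp_total.items()
    }
    return fractions, co_genes
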