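"""Expression-coupled k-mer scoring.

Every k-mer of the circular RNA is scored against a ranked differential-
expression list: genes are split into those whose 3'UTR contains the k-mer
(exact match, presence/absence) and those that do not, and the two groups'
signed DE scores are compared with a two-sided Wilcoxon rank-sum test.  The
motif score is -log10(p) signed positive when the k-mer group sits toward
up-regulated genes and negative when it sits toward down-regulated genes, so
the most negative scores flag motifs whose carriers drop on knockdown.

The statistic is rank-based, hence invariant to monotone transforms of the
DE score, and antisymmetric: negating every DE score flips every sign.  A
gene-label permutation null is provided for calibration.  The universe is
the set of genes present in both the DE table and the UTR collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqkmer import CircularSequence, enumerate_kmers, normalize_sequence

__all__ = [
    "MotifScore",
    "build_presence_index",
    "motif_score",
    "score_all_kmers",
    "permutation_null",
    "scores_to_frame",
]

EXACT_MAX_N = 50  # below this universe size use the exact rank-sum null


@dataclass
class MotifScore:
    kmer: str
    n_genes_with_motif: int
    score: float  # signed -log10(p); NaN when not scorable
    p_value: float
    rank: int | None = None
    na_reason: str | None = None

    @property
    def is_na(self) -> bool:
        return self.na_reason is not None


def build_presence_index(
    utrs: dict[str, str], kmers: set[str] | None = None, k: int | None = None
) -> dict[str, set[str]]:
    """kmer -> set of gene_ids whose UTR contains it (exact, >= 1 occurrence).

    When *kmers* is given only those are indexed (k inferred from them);
    otherwise every k-mer present in any UTR is indexed and *k* is required.
    """
    if kmers is not None:
        kmers = {normalize_sequence(km) for km in kmers}
        ks = {len(km) for km in kmers}
        if len(ks) != 1:
            raise ValueError("all k-mers must share one length")
        k = ks.pop()
    elif k is None:
        raise ValueError("either kmers or k must be given")
    index: dict[str, set[str]] = {km: set() for km in (kmers or ())}
    for gene, seq in utrs.items():
        s = seq  # callers normalise on ingestion
        seen = {s[i : i + k] for i in range(len(s) - k + 1)}
        if kmers is None:
            for km in seen:
                index.setdefault(km, set()).add(gene)
        else:
            for km in seen & kmers:
                index[km].add(gene)
    return index


def _rank_context(de: pd.DataFrame, genes: list[str]):
    """Precompute ranks of de_score over the universe, plus tie-corrected sigma terms."""
    sub = de.set_index("gene_id").loc[genes]
    scores = sub["de_score"].to_numpy(dtype=float)
    ranks = stats.rankdata(scores)
    N = len(scores)
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    gene_pos = {g: i for i, g in enumerate(genes)}
    return scores, ranks, N, tie_term, gene_pos


def _ranksum_signed(ranks: np.ndarray, N: int, tie_term: float, group_idx: np.ndarray,
                    scores: np.ndarray | None = None, exact_ok: bool = True):
    """Two-sided rank-sum p and direction for the group at *group_idx*.

    Normal approximation with tie correction; exact enumeration (scipy) for
    small untied universes.  Returns (p, direction) with direction +1 when
    the group's mean rank exceeds the complement's, -1 below, 0 at equality.
    """
    m = len(group_idx)
    n2 = N - m
    if m == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    R1 = float(ranks[group_idx].sum())
    U1 = R1 - m * (m + 1) / 2.0
    mu = m * n2 / 2.0
    direction = 0 if U1 == mu else (1 if U1 > mu else -1)
    if exact_ok and N < EXACT_MAX_N and tie_term == 0 and scores is not None:
        mask = np.zeros(N, dtype=bool)
        mask[group_idx] = True
        p = float(stats.mannwhitneyu(scores[mask], scores[~mask],
                                     alternative="two-sided", method="exact").pvalue)
        return p, direction
    var = m * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # all scores tied
        return 1.0, 0
    z = (U1 - mu) / math.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return max(p, 5e-324), direction


def motif_score(
    kmer: str,
    utrs: dict[str, str],
    de: pd.DataFrame,
    min_genes: int = 10,
    presence: dict[str, set[str]] | None = None,
) -> MotifScore:
    """Score one k-mer against the ranked DE list.

    The k-mer group is genes with >= 1 exact occurrence in their UTR
    (mismatch-free; the mismatch-tolerant consensus scan is a separate,
    later stage).  Groups smaller than ``min_genes`` are flagged NA.
    """
    kmer = normalize_sequence(kmer)
    genes = [g for g in de["gene_id"] if g in utrs]
    if not genes:
        raise ValueError("empty universe: no DE gene has a UTR")
    if presence is None:
        presence = build_presence_index(utrs, kmers={kmer})
    carriers = presence.get(kmer, set())
    scores, ranks, N, tie_term, gene_pos = _rank_context(de, genes)
    return _score_from_context(kmer, carriers, scores, ranks, N, tie_term, gene_pos, min_genes)


def _score_from_context(kmer, carriers, scores, ranks, N, tie_term, gene_pos, min_genes):
    group_idx = np.fromiter((gene_pos[g] for g in carriers if g in gene_pos), dtype=np.intp)
    m = len(group_idx)
    if m == 0:
        return MotifScore(kmer, 0, math.nan, math.nan, na_reason="no occurrences")
    if m < min_genes:
        return MotifScore(kmer, m, math.nan, math.nan,
                          na_reason=f"only {m} carrier genes (< {min_genes})")
    if m == N:
        return MotifScore(kmer, m, math.nan, math.nan, na_reason="all genes carry the k-mer")
    p, direction = _ranksum_signed(ranks, N, tie_term, group_idx, scores=scores)
    score = -math.log10(p) * direction
    return MotifScore(kmer, m, score + 0.0, p)


def score_all_kmers(
    circ: CircularSequence,
    k: int,
    utrs: dict[str, str],
    de: pd.DataFrame,
    min_genes: int = 10,
) -> list[MotifScore]:
    """One MotifScore per unique k-mer of the circular RNA.

    Sorted ascending by score (most negative first); NA-scored k-mers last,
    each carrying its reason.  Ranks are 1-based over scorable k-mers.
    """
    table = enumerate_kmers(circ, k)
    kmers = table.kmers()
    genes = [g for g in de["gene_id"] if g in utrs]
    if not genes:
        raise ValueError("empty universe: no DE gene has a UTR")
    presence = build_presence_index(utrs, kmers=set(kmers))
    scores_arr, ranks, N, tie_term, gene_pos = _rank_context(de, genes)
    results = [
        _score_from_context(km, presence[km], scores_arr, ranks, N, tie_term, gene_pos, min_genes)
        for km in kmers
    ]
    scored = sorted((r for r in results if not r.is_na), key=lambda r: (r.score, r.kmer))
    nas = sorted((r for r in results if r.is_na), key=lambda r: r.kmer)
    for i, r in enumerate(scored, start=1):
        r.rank = i
    return scored + nas


def permutation_null(
    kmer: str,
    utrs: dict[str, str],
    de: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_genes: int = 10,
    presence: dict[str, set[str]] | None = None,
) -> float:
    """Empirical two-sided p for one k-mer by gene-label permutation.

    DE-score assignments are permuted across genes (equivalently, random
    carrier sets of the observed size are drawn); the empirical p uses the
    add-one estimator (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1), so
    its minimum attainable value is 1/(n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    kmer = normalize_sequence(kmer)
    genes = [g for g in de["gene_id"] if g in utrs]
    if presence is None:
        presence = build_presence_index(utrs, kmers={kmer})
    carriers = presence.get(kmer, set())
    scores, ranks, N, tie_term, gene_pos = _rank_context(de, genes)
    group_idx = np.fromiter((gene_pos[g] for g in carriers if g in gene_pos), dtype=np.intp)
    m = len(group_idx)
    if m < min_genes or m == N:
        raise ValueError(f"carrier group size {m} not scorable over universe {N}")
    obs = abs(float(ranks[group_idx].sum()) - m * (N + 1) / 2.0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)[:m]
        stat = abs(float(ranks[perm].sum()) - m * (N + 1) / 2.0)
        if stat >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def scores_to_frame(scores: list[MotifScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kmer": [s.kmer for s in scores],
            "n_motif_genes": [s.n_genes_with_motif for s in scores],
            "score": [s.score for s in scores],
            "p_value": [s.p_value for s in scores],
            "rank": [s.rank for s in scores],
            "na_reason": [s.na_reason for s in scores],
        }
    )
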