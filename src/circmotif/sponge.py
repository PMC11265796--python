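"""miRNA-sponge negative control.

If a circular RNA worked by sponging a miRNA, that miRNA's targets (genes
carrying its 7-nt seed site in their 3'UTR) should drop when the circRNA is
depleted.  This module counts exact seed-site occurrences per gene, tests
each miRNA's target set for enrichment among down-regulated genes, and
compares motif scores between k-mers that are miRNA seed sites and those
that are not.  The verdict "no sponge evidence" is emitted iff no tested
miRNA site is significantly enriched in down-regulated genes after
Benjamini-Hochberg correction across miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clip import EnrichmentResult, contingency_enrichment
from .detables import DOWN, NOT_DE, UP, bh_adjust
from .scoring import MotifScore
from .seqkmer import normalize_sequence

__all__ = [
    "SeedSite",
    "GroupComparison",
    "count_seed_sites",
    "seed_enrichment",
    "compare_score_groups",
    "sponge_report",
]

SEED_LENGTH = 7


@dataclass(frozen=True)
class SeedSite:
    """A miRNA seed-complementary 7-mer (e.g. CAGUGCA for miR-148-3p)."""

    mirna_id: str
    site_7mer: str
    conserved: bool = False

    def __post_init__(self) -> None:
        site = normalize_sequence(self.site_7mer)
        if len(site) != SEED_LENGTH:
            raise ValueError(f"seed site must be {SEED_LENGTH} nt, got {len(site)}")
        object.__setattr__(self, "site_7mer", site)


@dataclass
class GroupComparison:
    """Rank-sum comparison of two score groups.

    effect_size is the rank-biserial magnitude |2*AUC - 1| in [0, 1].
    """

    statistic: float
    p_value: float
    effect_size: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def count_seed_sites(utrs: dict[str, str], site: SeedSite | str) -> dict[str, int]:
    """Exact occurrence count of the seed 7-mer per gene, overlaps included."""
    s = site.site_7mer if isinstance(site, SeedSite) else normalize_sequence(site)
    if len(s) != SEED_LENGTH:
        raise ValueError(f"seed site must be {SEED_LENGTH} nt")
    counts: dict[str, int] = {}
    for gene, seq in utrs.items():
        n = 0
        i = seq.find(s)
        while i != -1:
            n += 1
            i = seq.find(s, i + 1)  # overlapping occurrences count
        counts[gene] = n
    return counts


def seed_enrichment(classified: pd.DataFrame, counts: dict[str, int],
                    correction: str = "none") -> dict[str, EnrichmentResult]:
    """Seed-site presence (count >= 1) cross-tabulated across DE classes.

    Returns the down-vs-up and down-vs-notDE tests (delegating to the shared
    2x2 machinery, Fisher fallback on degenerate tables included).
    """
    cls = classified.set_index("gene_id")["de_class"]
    groups = {c: set(cls.index[cls == c]) for c in (DOWN, UP, NOT_DE)}
    has = {g: counts.get(g, 0) >= 1 for g in cls.index}
    out = {}
    out["down_vs_up"] = contingency_enrichment(groups[DOWN], groups[UP], has,
                                               correction=correction, labels=(DOWN, UP))
    out["down_vs_notDE"] = contingency_enrichment(groups[DOWN], groups[NOT_DE], has,
                                                  correction=correction, labels=(DOWN, NOT_DE))
    return out


def compare_score_groups(scores: list[MotifScore], is_mirna_7mer) -> GroupComparison:
    """Two-sided rank-sum between miRNA-seed k-mers and all other k-mers.

    is_mirna_7mer maps kmer -> bool (a callable or a set/dict).  NA-scored
    k-mers are excluded.  Effect size |2*AUC - 1| is 0 for identical
    distributions and 1 for full separation.
    """
    flag = is_mirna_7mer if callable(is_mirna_7mer) else (lambda km: km in is_mirna_7mer)
    a = np.array([s.score for s in scores if not s.is_na and flag(s.kmer)])
    b = np.array([s.score for s in scores if not s.is_na and not flag(s.kmer)])
    if a.size == 0 or b.size == 0:
        raise ValueError("both k-mer groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    auc = res.statistic / (a.size * b.size)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=float(abs(2.0 * auc - 1.0)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def sponge_report(
    classified: pd.DataFrame,
    utrs: dict[str, str],
    seeds: list[SeedSite],
    fdr_threshold: float = 0.1,
) -> dict:
    """Per-miRNA down-regulation enrichment with BH across miRNAs, plus verdict.

    A miRNA supports sponging when its seed-carrying genes are
    over-represented among down-regulated genes (down-vs-up table, odds in
    the down direction) at BH-adjusted p < fdr_threshold.  The verdict
    "no sponge evidence" holds iff no miRNA passes.
    """
    rows = []
    for seed in seeds:
        counts = count_seed_sites(utrs, seed)
        res = seed_enrichment(classified, counts)["down_vs_up"]
        (a, b), (c, d) = res.contingency
        # direction: seed carriers over-represented among down genes
        down_frac = a / (a + b) if a + b else 0.0
        up_frac = c / (c + d) if c + d else 0.0
        rows.append(
            {
                "mirna_id": seed.mirna_id,
                "site": seed.site_7mer,
                "pct_down_with_site": 100.0 * down_frac,
                "pct_up_with_site": 100.0 * up_frac,
                "enriched_in_down": down_frac > up_frac,
                "p_value": res.p_value,
                "test": res.test,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p_value"] = bh_adjust(table["p_value"].to_numpy())
        significant = table[(table["adjusted_p_value"] < fdr_threshold) & table["enriched_in_down"]]
        verdict = "sponge evidence" if len(significant) else "no sponge evidence"
    else:
        verdict = "no sponge evidence"
    return {"per_mirna": table, "verdict": verdict}
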