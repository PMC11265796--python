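"""CLIP peak filtering, interval overlap, contingency and concordance tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

from circmotif.clip import (
    BindingSite,
    PeakFilterParams,
    annotate_gene_binding,
    contingency_enrichment,
    cross_concordance,
    filter_peaks,
    peak_motif_overlap,
    set_overlap_fisher,
    sweep_overlaps,
)
from circmotif.detables import DOWN, NOT_DE, UP
from circmotif.seqkmer import MotifMatch


def peak(start=0, end=30, log2fe=4.0, rbp="RBP", chrom="chr1", strand="+"):
    return BindingSite(chrom=chrom, start=start, end=end, strand=strand, rbp=rbp,
                       log2_fold_enrichment=log2fe)


def closed_form_chi2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestFilterPeaks:
    def test_eightfold_boundary_is_inclusive(self):
        kept = filter_peaks([peak(end=10, log2fe=3.0)])  # 2^3 = exactly 8-fold
        assert len(kept) == 1

    def test_short_peak_dropped(self):
        assert filter_peaks([peak(end=3, log2fe=5.0)]) == []

    def test_below_eightfold_dropped_regardless_of_length(self):
        assert filter_peaks([peak(end=100, log2fe=math.log2(7.9))]) == []

    def test_idempotent(self, rng):
        peaks = [peak(start=i, end=i + int(rng.integers(2, 20)),
                      log2fe=float(rng.uniform(1, 6))) for i in range(50)]
        once = filter_peaks(peaks)
        assert filter_peaks(once) == once

    def test_empty_interval_rejected_at_construction(self):
        with pytest.raises(ValueError):
            peak(start=10, end=10)


class TestSweepOverlaps:
    def test_matches_naive_all_pairs_on_random_intervals(self, rng):
        for _ in range(50):
            a = [(int(s), int(s + rng.integers(1, 30)), i)
                 for i, s in enumerate(rng.integers(0, 200, size=20))]
            b = [(int(s), int(s + rng.integers(1, 30)), j)
                 for j, s in enumerate(rng.integers(0, 200, size=20))]
            naive = sorted(
                (ia, ib, min(ea, eb) - max(sa, sb))
                for sa, ea, ia in a
                for sb, eb, ib in b
                if min(ea, eb) - max(sa, sb) >= 3
            )
            assert sorted(sweep_overlaps(a, b, min_overlap=3)) == naive


class TestGeneBinding:
    def feats(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])

    def test_four_bp_overlap_boundary_binds(self):
        f = self.feats([("chr1", 116, 200, "geneA", "+")])
        bound = annotate_gene_binding([peak(100, 120)], f)
        assert bound == {"geneA": {"RBP"}}

    def test_three_bp_overlap_does_not_bind(self):
        f = self.feats([("chr1", 117, 200, "geneA", "+")])
        assert annotate_gene_binding([peak(100, 120)], f) == {}

    def test_opposite_strand_does_not_bind(self):
        f = self.feats([("chr1", 100, 200, "geneA", "-")])
        assert annotate_gene_binding([peak(100, 120)], f) == {}

    def test_malformed_feature_interval_reports_row(self):
        f = self.feats([("chr1", 200, 100, "geneA", "+")])
        with pytest.raises(ValueError, match="end <= start"):
            annotate_gene_binding([peak(100, 120)], f)


class TestContingency:
    def test_closed_form_chi_square(self):
        has = {f"d{i}": i < 30 for i in range(100)}
        has.update({f"u{i}": i < 10 for i in range(100)})
        res = contingency_enrichment(
            {f"d{i}" for i in range(100)}, {f"u{i}" for i in range(100)}, has
        )
        assert res.test == "chisq"
        assert res.statistic == pytest.approx(closed_form_chi2(30, 70, 10, 90), abs=1e-9)
        assert res.statistic == pytest.approx(12.5)

    def test_equal_proportions_give_zero_statistic(self):
        has = {f"d{i}": i < 20 for i in range(100)}
        has.update({f"u{i}": i < 20 for i in range(100)})
        res = contingency_enrichment(
            {f"d{i}" for i in range(100)}, {f"u{i}" for i in range(100)}, has
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_falls_back_to_fisher(self):
        has = {f"d{i}": False for i in range(10)}
        has.update({f"u{i}": False for i in range(10)})
        res = contingency_enrichment(
            {f"d{i}" for i in range(10)}, {f"u{i}" for i in range(10)}, has
        )
        assert res.test == "fisher" and res.p_value == pytest.approx(1.0)

    def test_random_tables_match_scipy_chi2(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(1, 60, size=4)
            has = {f"d{i}": i < a for i in range(a + b)}
            has.update({f"u{i}": i < c for i in range(c + d)})
            res = contingency_enrichment(
                {f"d{i}" for i in range(a + b)}, {f"u{i}" for i in range(c + d)}, has
            )
            assert res.statistic == pytest.approx(closed_form_chi2(a, b, c, d), abs=1e-9)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            contingency_enrichment({"x"}, {"x", "y"}, {})


class TestSetOverlap:
    def test_hypergeometric_tail_by_enumeration(self):
        U = {f"g{i}" for i in range(100)}
        A = {f"g{i}" for i in range(10)}
        B = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        res = set_overlap_fisher(A, B, U)
        # P(X >= 5) with N=100, K=10, n=10 by direct summation
        expected = sum(hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_identical_sets_reach_minimal_p_for_margins(self):
        U = {f"g{i}" for i in range(40)}
        A = {f"g{i}" for i in range(8)}
        res_eq = set_overlap_fisher(A, A, U)
        # any other placement of B's 8 members cannot give smaller tail p
        res_other = set_overlap_fisher(A, {f"g{i}" for i in range(4, 12)}, U)
        assert res_eq.p_value <= res_other.p_value

    def test_independent_overlap_gives_odds_near_one(self):
        U = {f"g{i}" for i in range(100)}
        A = {f"g{i}" for i in range(20)}
        B = {f"g{i}" for i in range(16, 36)}  # |A∩B| = 4 = 20*20/100
        res = set_overlap_fisher(A, B, U)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.05)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            set_overlap_fisher(set(), set(), set())


class TestConcordance:
    def de(self, classes):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(classes))], "de_class": classes}
        )

    def test_forced_full_reversal(self):
        a = self.de([DOWN] * 5 + [UP] * 3)
        b = self.de([UP] * 5 + [DOWN] * 3)
        t = cross_concordance(a, b)
        assert t.fractions.loc[DOWN].tolist() == [0.0, 1.0, 0.0]
        assert t.fractions.loc[UP].tolist() == [1.0, 0.0, 0.0]

    def test_independent_classes_match_marginals(self, rng):
        n = 4000
        cls_a = rng.choice([DOWN, UP, NOT_DE], size=n, p=[0.3, 0.3, 0.4])
        cls_b = rng.choice([DOWN, UP, NOT_DE], size=n, p=[0.2, 0.5, 0.3])
        t = cross_concordance(self.de(list(cls_a)), self.de(list(cls_b)))
        for row in (DOWN, UP):
            assert t.fractions.loc[row].to_numpy() == pytest.approx([0.2, 0.5, 0.3], abs=0.06)

    def test_row_fractions_sum_to_one(self, rng):
        cls = list(rng.choice([DOWN, UP, NOT_DE], size=200))
        t = cross_concordance(self.de(cls), self.de(list(rng.permutation(cls))))
        assert t.fractions.sum(axis=1).to_numpy() == pytest.approx([1.0, 1.0])

    def test_empty_intersection_rejected(self):
        a = self.de([DOWN])
        b = self.de([UP])
        b["gene_id"] = ["other"]
        with pytest.raises(ValueError):
            cross_concordance(a, b)


class TestPeakMotifOverlap:
    def test_one_nt_overlap_counts(self):
        frac, co = peak_motif_overlap([peak(100, 120)], [MotifMatch("chr1", 110, 121, 0)])
        assert frac == {"RBP": 1.0} and co == {"RBP": {"chr1"}}

    def test_half_open_adjacency_does_not_count(self):
        frac, _ = peak_motif_overlap([peak(100, 110)], [MotifMatch("chr1", 110, 121, 0)])
        assert frac == {"RBP": 0.0}

    def test_fraction_matches_naive_all_pairs(self, rng):
        peaks = [peak(int(s), int(s) + 20, chrom=f"c{int(rng.integers(3))}")
                 for s in rng.integers(0, 300, size=40)]
        matches = [MotifMatch(f"c{int(rng.integers(3))}", int(s), int(s) + 11, 0)
                   for s in rng.integers(0, 300, size=30)]
        frac, _ = peak_motif_overlap(peaks, matches)
        naive_hits = sum(
            any(p.chrom == m.sequence_id and min(p.end, m.end) - max(p.start, m.start) >= 1
                for m in matches)
            for p in peaks
        )
        assert frac["RBP"] == pytest.approx(naive_hits / len(peaks))
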