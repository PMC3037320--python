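"""Cluster assembly, failure counts, and the negative-binomial test."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_clusters
from wordcluster.cluster_core import (Cluster, DegenerateInputError,
                                      ElementSet, build_clusters,
                                      failures_element, failures_kmer,
                                      filter_significant, negbin_pvalue,
                                      success_prob_element)
from wordcluster.io_formats import Interval
from wordcluster.kmer_scan import Occurrence


def _occs(spans, seq_id="s", word="ATGC"):
    return [Occurrence(seq_id, s, e, word) for s, e in spans]


class TestBuildClusters:
    def test_distances_within_threshold_form_one_cluster(self):
        # consecutive distances 1, 2, 500: the first three copies cluster
        spans = [(0, 4), (4, 8), (9, 13), (512, 516)]
        clusters = build_clusters(_occs(spans), d_max=10)
        assert [(c.start, c.end, c.n) for c in clusters] == [(0, 13, 3)]

    def test_all_gaps_too_large_gives_no_clusters(self):
        spans = [(0, 4), (100, 104), (300, 304)]
        assert build_clusters(_occs(spans), d_max=10) == []

    def test_tie_at_dmax_is_inside(self):
        spans = [(0, 4), (13, 17)]  # distance 10
        assert len(build_clusters(_occs(spans), d_max=10)) == 1
        assert build_clusters(_occs(spans), d_max=9) == []

    def test_singletons_never_reported(self):
        clusters = build_clusters(_occs([(0, 4)]), d_max=10)
        assert clusters == []
        for c in build_clusters(_occs([(0, 4), (4, 8), (500, 504)]), d_max=5):
            assert c.n >= 2

    @given(
        starts=st.lists(st.integers(0, 300), min_size=0, max_size=12,
                        unique=True),
        d_max=st.integers(1, 50),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_exhaustive_enumeration(self, starts, d_max):
        spans = [(s * 5, s * 5 + 4) for s in sorted(starts)]
        got = [(c.start, c.end, c.n) for c in build_clusters(_occs(spans), d_max)]
        assert got == brute_force_clusters(spans, d_max)


class TestFailures:
    def test_abutting_copies_have_zero_failures(self):
        # the cluster spanning ATGCATGC: n=2, L_c=8, k=4
        c = Cluster("s", 0, 8, n=2)
        assert failures_kmer(c, k=4) == 0

    def test_one_intervening_base_is_one_failure(self):
        # the cluster spanning ATGCAATGC: n=2, L_c=9
        c = Cluster("s", 0, 9, n=2)
        assert failures_kmer(c, k=4) == 1

    def test_three_adjacent_copies(self):
        c = Cluster("s", 0, 12, n=3)
        assert failures_kmer(c, k=4) == 0

    def test_negative_failures_is_internal_error(self):
        with pytest.raises(RuntimeError, match="negative failure"):
            failures_kmer(Cluster("s", 0, 7, n=2), k=4)

    def test_element_abutting_elements_zero_failures(self):
        members = (Interval("s", 0, 300), Interval("s", 300, 600))
        c = Cluster("s", 0, 600, n=2, members=members)
        es = ElementSet(list(members))
        assert failures_element(c, es) == 0

    def test_element_partial_gap_rounds_up(self):
        # L_no = 250, L_mean = 300 -> ceiling = 1
        members = (Interval("s", 0, 300), Interval("s", 550, 850))
        c = Cluster("s", 0, 850, n=2, members=members)
        es = ElementSet(list(members))
        assert es.L_mean == 300
        assert failures_element(c, es) == 1

    def test_element_five_members_four_gaps(self):
        # 5 elements of 300 bp, gaps of 250 bp: L_no = 1000 -> ceil(10/3) = 4
        members = tuple(
            Interval("s", i * 550, i * 550 + 300) for i in range(5)
        )
        c = Cluster("s", 0, members[-1].end, n=5, members=members)
        es = ElementSet(list(members))
        assert c.length == 5 * 300 + 4 * 250
        assert failures_element(c, es) == 4


class TestSuccessProbElement:
    def test_direct_substitution(self):
        es = ElementSet([Interval("s", i * 1000, i * 1000 + 300)
                         for i in range(10)])
        assert success_prob_element(es, 3_000_000) == pytest.approx(0.001)

    def test_saturating_element_rejected(self):
        es = ElementSet([Interval("s", 0, 1000)])
        with pytest.raises(DegenerateInputError, match=">= 1"):
            success_prob_element(es, 1000)

    def test_empty_element_set_rejected(self):
        with pytest.raises(DegenerateInputError, match="empty"):
            ElementSet([])


class TestNegbinPvalue:
    @pytest.mark.parametrize(
        "n, n_f, p, expected",
        [
            (2, 0, 0.5, 0.5),          # r=1 geometric: CDF(0) = p
            (2, 1, 0.5, 0.75),         # 1 - (1-p)^(n_f+1)
            (3, 2, 0.25, 0.26171875),  # exhaustive sum over x = 0..2
        ],
    )
    def test_frozen_reference_values(self, n, n_f, p, expected):
        assert negbin_pvalue(n, n_f, p) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_nbinom(self):
        for n in range(2, 8):
            for n_f in (0, 1, 5, 40):
                for p in (0.01, 0.3, 0.9):
                    assert negbin_pvalue(n, n_f, p) == pytest.approx(
                        scipy.stats.nbinom.cdf(n_f, n - 1, p), rel=1e-10)

    def test_geometric_closed_form_at_n2(self):
        for n_f in range(0, 30):
            for p in (0.05, 0.5, 0.99):
                assert negbin_pvalue(2, n_f, p) == pytest.approx(
                    1 - (1 - p) ** (n_f + 1), abs=1e-12)

    def test_strictly_increasing_in_failures(self):
        vals = [negbin_pvalue(4, n_f, 0.2) for n_f in range(40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_pmf_sums_to_one(self):
        # CDF at a deep truncation point approaches 1
        assert negbin_pvalue(4, 3000, 0.05) == pytest.approx(1.0, abs=1e-9)

    def test_no_underflow_for_large_clusters(self):
        pv = negbin_pvalue(500, 100, 0.01)
        assert 0.0 < pv <= 1.0

    @pytest.mark.parametrize("n, n_f, p", [(1, 0, 0.5), (2, -1, 0.5),
                                           (2, 0, 0.0), (2, 0, 1.0)])
    def test_invalid_arguments_rejected(self, n, n_f, p):
        with pytest.raises(ValueError):
            negbin_pvalue(n, n_f, p)


class TestFilterSignificant:
    def _clusters(self, pvals):
        return [Cluster("s", i * 10, i * 10 + 8, n=2, p_value=pv)
                for i, pv in enumerate(pvals)]

    def test_alpha_one_is_identity(self):
        cs = self._clusters([0.5, 1e-9, 1.0])
        assert filter_significant(cs, 1.0) == cs

    def test_mixed_list_keeps_qualifying_subset_in_order(self):
        cs = self._clusters([1e-3, 1e-7, 0.9, 1e-6])
        kept = filter_significant(cs, 1e-5)
        assert kept == [cs[1], cs[3]]

    def test_alpha_below_everything_gives_empty(self):
        assert filter_significant(self._clusters([0.1, 0.2]), 1e-12) == []

    @pytest.mark.parametrize("alpha", [0.0, -1.0, 1.1])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            filter_significant([], alpha)
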