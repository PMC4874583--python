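import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisgraph import stats
from cisgraph.exceptions import ContractError, ParameterError

from conftest import make_sites


class TestPositionSummaries:
    @pytest.mark.parametrize("positions, expected", [
        ([100, 200, 300, 400], 250.0),
        ([100, 110, 400], 250.0),  # midpoint ignores interior skew
        ([500], 500.0),
    ])
    def test_average_position_is_span_midpoint(self, positions, expected):
        assert stats.average_position(make_sites(positions)) == expected

    @pytest.mark.parametrize("positions, expected", [
        ([100, 110, 400], 110.0),   # odd order: central site
        ([100, 200, 300, 400], 250.0),  # even order: mean of central two
        ([500], 500.0),
    ])
    def test_median_position(self, positions, expected):
        assert stats.median_position(make_sites(positions)) == expected

    def test_median_tracks_dense_side_of_skewed_layouts(self, rng):
        # directional: piling sites near the left end pulls the median
        # below the midpoint
        for _ in range(20):
            dense = sorted(int(p) for p in rng.integers(1, 100, size=9))
            positions = dense + [int(rng.integers(10_000, 20_000))]
            cis = make_sites(positions)
            assert stats.median_position(cis) < stats.average_position(cis)

    @pytest.mark.parametrize("positions, expected", [
        ([100, 150], 51),
        ([500], 1),       # a single base pair contains one site
        ([200, 200], 1),  # coincident duplicates
    ])
    def test_dimension_is_inclusive_span(self, positions, expected):
        assert stats.dimension(make_sites(positions)) == expected

    def test_dimension_exclusive_variant(self):
        assert stats.dimension(make_sites([100, 150]), span_exclusive=True) == 50

    def test_empty_members_rejected(self):
        for fn in (stats.average_position, stats.median_position,
                   stats.dimension):
            with pytest.raises(ContractError):
                fn([])


class TestEntropy:
    @pytest.mark.parametrize("counts, order, expected", [
        ({"A": 2, "B": 2}, 4, 1.0),        # uniform mixing is maximal
        ({"A": 4}, 4, 0.0),                # single label: no diversity
        ({"A": 3, "B": 1}, 4, 0.811278),   # -(0.75 lg 0.75 + 0.25 lg 0.25)/lg 2
    ])
    def test_within_cis_entropy(self, counts, order, expected):
        assert stats.cis_entropy(counts, order) == pytest.approx(
            expected, abs=1e-6)

    @pytest.mark.parametrize("counts, order, n_labels, expected", [
        ({"A": 2, "B": 2}, 4, 4, 0.5),   # 1 bit over log2(4) = 2 bits
        ({"A": 2, "B": 2}, 4, 2, 1.0),   # N = n reduces to cis_entropy
        ({"A": 4}, 4, 5, 0.0),
    ])
    def test_normalized_entropy(self, counts, order, n_labels, expected):
        assert stats.normalized_entropy(counts, order, n_labels) == \
            pytest.approx(expected, abs=1e-6)

    def test_count_sum_mismatch_rejected(self):
        with pytest.raises(ContractError):
            stats.cis_entropy({"A": 2}, 4)
        with pytest.raises(ContractError):
            stats.normalized_entropy({"A": 2}, 4, 3)

    def test_dataset_label_count_below_cis_count_rejected(self):
        with pytest.raises(ContractError):
            stats.normalized_entropy({"A": 2, "B": 2}, 4, 1)

    def test_log_base_invariance(self):
        # the normalisation cancels the log base: recompute in base 2
        counts, order = {"A": 5, "B": 2, "C": 1}, 8
        ps = [c / order for c in counts.values()]
        base2 = -sum(p * math.log2(p) for p in ps) / math.log2(len(ps))
        assert stats.cis_entropy(counts, order) == pytest.approx(base2,
                                                                 abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.integers(1, 50), min_size=1, max_size=8),
           st.integers(0, 5))
    def test_entropy_bounds_hold_over_random_count_vectors(self, counts,
                                                           extra_labels):
        order = sum(counts)
        cv = {f"L{i}": c for i, c in enumerate(counts)}
        n_dataset = len(cv) + extra_labels
        e = stats.cis_entropy(cv, order)
        ne = stats.normalized_entropy(cv, order, n_dataset)
        assert 0.0 <= ne <= e + 1e-12 and e <= 1.0
        if len(cv) > 1 and len(set(counts)) == 1:
            assert e == pytest.approx(1.0, abs=1e-12)  # maximal iff uniform
        if extra_labels == 0 or len(cv) == 1:
            assert ne == pytest.approx(e if len(cv) > 1 else 0.0, abs=1e-12)


class TestSignificance:
    def test_order_one_pvalue_matches_closed_form(self):
        m, g, d = 50, 10_000, 100
        expected = 1 - (1 - d / g) ** m
        assert stats.cis_pvalue(1, d, m, g) == pytest.approx(expected,
                                                             rel=1e-9)

    def test_certain_event_has_pvalue_one(self):
        assert stats.cis_pvalue(10, 1_000, 10, 1_000) == 1.0

    def test_monotone_in_order_and_dimension(self):
        m, g = 100, 10**6
        ps = [stats.cis_pvalue(o, 10_000, m, g) for o in range(1, 8)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        pd_ = [stats.cis_pvalue(5, d, m, g) for d in (100, 1_000, 10_000)]
        assert pd_ == sorted(pd_)

    def test_dimension_beyond_genome_rejected(self):
        with pytest.raises(ParameterError):
            stats.cis_pvalue(2, 2_000, 10, 1_000)

    def test_llr_zero_exactly_at_global_rate(self):
        # O/d == M/G: 100 sites on 1 Mb, 1 site in a 10 kb window
        assert stats.loglik_ratio(1, 10_000, 100, 10**6) == 0.0

    def test_llr_positive_for_any_clustered_case(self, rng):
        for _ in range(50):
            m, g = 200, 10**6
            o = int(rng.integers(2, 20))
            d = int(rng.integers(1, 5_000))
            if o / d != m / g:
                assert stats.loglik_ratio(o, d, m, g) > 0

    def test_llr_closed_form_value(self):
        # 2*(10*ln(10/0.1) - (10 - 0.1)) with expected count 0.1
        expected = 2 * (10 * math.log(100) - 9.9)
        assert stats.loglik_ratio(10, 1_000, 100, 10**6) == pytest.approx(
            expected, rel=1e-12)


class TestComputeStatistics:
    def test_full_record_on_small_cis(self):
        from cisgraph.graph import gap_scan_components

        sites = make_sites([100, 110, 400, 90_000],
                           labels=["A", "B", "A", "C"])
        cis = gap_scan_components(sites, 1_000)
        stats.compute_statistics(cis, genome_size=10**6)
        st0 = cis[0].stats
        assert st0.order == 3 and st0.dimension == 301
        assert st0.median_pos == 110 and st0.avg_pos == 250
        assert st0.label_counts == {"A": 2, "B": 1}
        assert st0.entropy == pytest.approx(0.918296, abs=1e-6)
        # N = 3 labels dataset-wide
        assert st0.norm_entropy == pytest.approx(
            -(2 / 3 * math.log(2 / 3) + 1 / 3 * math.log(1 / 3)) / math.log(3),
            abs=1e-9)
        assert cis[1].stats.entropy == 0.0 and cis[1].stats.dimension == 1

    def test_fdr_adds_bh_qvalues(self):
        from statsmodels.stats.multitest import multipletests

        from cisgraph.graph import gap_scan_components

        sites = make_sites([1, 2, 3, 500_000, 900_000, 900_010])
        cis = gap_scan_components(sites, 100)
        stats.compute_statistics(cis, genome_size=10**6, fdr=True)
        qs = multipletests([c.stats.p_value for c in cis], method="fdr_bh")[1]
        assert [c.stats.fdr_q for c in cis] == pytest.approx(list(qs))

    def test_per_chromosome_null_uses_local_density(self):
        from cisgraph.graph import gap_scan_components

        a = make_sites([1000, 1010], chrom="chr1")
        # chr2 is crowded: same cluster is less surprising there
        b = make_sites([1000, 1010] + list(range(2000, 100_001, 500)),
                       chrom="chr2", row_offset=10)
        cis = gap_scan_components(sorted(a + b, key=lambda s: s.sort_key), 100)
        stats.compute_statistics(cis, per_chromosome=True)
        p_chr1 = next(c.stats.p_value for c in cis if c.chrom == "chr1")
        p_chr2 = next(c.stats.p_value for c in cis
                      if c.chrom == "chr2" and c.order == 2)
        assert p_chr1 < p_chr2
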