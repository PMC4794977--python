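import numpy as np
import pandas as pd
import pytest

from autozyg.consensus_roh import (
    carrier_association,
    common_roh_groups,
    consensus_region,
    filter_recurrent,
    homozygosity_proportion_test,
    pool_overlapping,
)

from conftest import make_dataset
from oracles import interval_overlap_components


def _segments(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp",
                                       "end_bp", "n_snp", "length_kb"])


class TestPooling:
    def test_disjoint_segments_make_singleton_pools(self):
        segs = _segments([("a", 1, 100, 200, 10, 0.1),
                          ("b", 1, 300, 400, 10, 0.1)])
        pools = pool_overlapping(segs)
        assert [p.n_members for p in pools] == [1, 1]

    def test_transitive_chain_pools_together(self):
        # A-B and B-C overlap, A-C do not: single-linkage puts all three
        # in one pool whose strict intersection is empty
        segs = _segments([("a", 1, 0, 10, 5, 0.01),
                          ("b", 1, 8, 20, 5, 0.01),
                          ("c", 1, 18, 30, 5, 0.01)])
        pools = pool_overlapping(segs)
        assert len(pools) == 1
        assert pools[0].n_members == 3
        assert pools[0].flag == "non_consensus"

    def test_identical_segments_ten_samples(self):
        segs = _segments([(f"s{i}", 2, 500, 900, 20, 0.4) for i in range(10)])
        pools = pool_overlapping(segs)
        assert len(pools) == 1
        assert pools[0].n_distinct_samples == 10
        assert (pools[0].consensus_start_bp, pools[0].consensus_end_bp) == (500, 900)

    def test_matches_component_oracle_and_order_invariance(self, rng):
        starts = rng.integers(0, 5000, size=40)
        rows = [(f"s{i % 7}", 1, int(s), int(s + rng.integers(50, 900)), 5, 0.5)
                for i, s in enumerate(starts)]
        segs = _segments(rows)
        pools = pool_overlapping(segs)
        got = sorted(frozenset(zip(p.members["start_bp"], p.members["end_bp"]))
                     for p in pools)
        intervals = [(r[2], r[3]) for r in rows]
        expect = [frozenset(intervals[i] for i in comp)
                  for comp in interval_overlap_components(intervals)]
        assert got == sorted(expect)
        # permuted input yields the same pools
        shuffled = segs.sample(frac=1, random_state=1).reset_index(drop=True)
        pools2 = pool_overlapping(shuffled)
        got2 = sorted(frozenset(zip(p.members["start_bp"], p.members["end_bp"]))
                      for p in pools2)
        assert got == got2

    def test_every_segment_in_exactly_one_pool(self, rng):
        rows = [(f"s{i}", int(rng.integers(1, 4)), int(s), int(s + 100), 5, 0.1)
                for i, s in enumerate(rng.integers(0, 2000, size=30))]
        segs = _segments(rows)
        pools = pool_overlapping(segs)
        assert sum(p.n_members for p in pools) == len(segs)


class TestConsensusRegion:
    @pytest.mark.parametrize("start, end, printed_kb",
                             [(121016843, 121689105, 672),
                              (44969326, 45928700, 959)])
    def test_published_consensus_lengths(self, start, end, printed_kb):
        segs = _segments([("a", 3, start, end, 80, 0.0),
                          ("b", 3, start - 5000, end + 2000, 90, 0.0)])
        pools = pool_overlapping(segs)
        vmap = pd.DataFrame({"chrom": [3], "bp": [start + 1]})
        s, e, n, kb = consensus_region(pools[0], vmap)
        assert (s, e) == (start, end)
        assert int(kb) == printed_kb

    def test_identical_members_consensus_is_the_interval(self):
        segs = _segments([("a", 1, 100, 900, 9, 0.8), ("b", 1, 100, 900, 9, 0.8)])
        pools = pool_overlapping(segs)
        vmap = pd.DataFrame({"chrom": np.ones(20, int),
                             "bp": np.linspace(50, 1000, 20).astype(int)})
        s, e, n, kb = consensus_region(pools[0], vmap)
        assert (s, e) == (100, 900)
        assert n == int(((vmap.bp >= 100) & (vmap.bp <= 900)).sum())

    def test_non_consensus_pool_raises(self):
        segs = _segments([("a", 1, 0, 10, 5, 0.01), ("b", 1, 8, 20, 5, 0.01),
                          ("c", 1, 18, 30, 5, 0.01)])
        pool = pool_overlapping(segs)[0]
        with pytest.raises(ValueError, match="empty consensus"):
            consensus_region(pool, pd.DataFrame({"chrom": [1], "bp": [9]}))


class TestFilterRecurrent:
    def _pool_of(self, n_samples, kb):
        segs = _segments([(f"s{i}", 1, 1000, 1000 + int(kb * 1000) - 1, 80, kb)
                          for i in range(n_samples)])
        return pool_overlapping(segs)[0]

    def test_more_than_five_samples_boundary(self):
        assert filter_recurrent([self._pool_of(5, 600.0)]) == []
        assert len(filter_recurrent([self._pool_of(6, 600.0)])) == 1

    def test_minimum_length_boundary(self):
        assert filter_recurrent([self._pool_of(8, 499.9)]) == []
        assert len(filter_recurrent([self._pool_of(8, 500.0)])) == 1

    def test_subset_and_idempotent(self, rng):
        pools = [self._pool_of(int(n), float(kb))
                 for n, kb in zip(rng.integers(1, 12, 20),
                                  rng.uniform(100, 900, 20))]
        kept = filter_recurrent(pools)
        assert set(id(p) for p in kept) <= set(id(p) for p in pools)
        assert filter_recurrent(kept) == kept


class TestCommonGroups:
    def test_unique_segments_no_multimember_groups(self):
        segs = _segments([("a", 1, 0, 100, 80, 0.1), ("b", 1, 1, 100, 80, 0.1)])
        groups = common_roh_groups(segs)
        assert (groups["size"] == 1).all()

    def test_identical_coordinates_grouped(self):
        segs = _segments([(s, 1, 500, 1500, 80, 1.0) for s in "abc"]
                         + [("d", 1, 500, 1501, 80, 1.0)])
        groups = common_roh_groups(segs)
        assert sorted(groups["size"]) == [1, 3]

    def test_min_snp_criterion_applied(self):
        segs = _segments([(s, 1, 500, 1500, 74, 1.0) for s in "abc"])
        assert len(common_roh_groups(segs, min_snp=75)) == 0


class TestCarrierAssociation:
    @pytest.mark.parametrize("cases, controls, expected",
                             [(6, 15, 8.87), (10, 0, 6.70), (5, 11, 5.63),
                              (7, 0, 4.67), (6, 0, 4.00)])
    def test_published_carrier_chi2(self, cases, controls, expected):
        res = carrier_association(cases, controls, 649, 431)
        assert res.statistic == pytest.approx(expected, abs=0.01)

    def test_equal_proportions_zero(self):
        assert carrier_association(10, 10, 100, 100).statistic == 0.0

    def test_zero_marginal_untestable(self):
        assert carrier_association(0, 0, 50, 50).flag == "untestable"

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            carrier_association(10, 0, 5, 50)


class TestHomozygosityProportion:
    def _region_dataset(self, rng, case_hom_p, ctrl_hom_p, n_snp=40,
                        n_case=80, n_ctrl=80):
        hom_draws_case = rng.random((n_case, n_snp)) < case_hom_p
        hom_draws_ctrl = rng.random((n_ctrl, n_snp)) < ctrl_hom_p
        calls = np.where(np.vstack([hom_draws_case, hom_draws_ctrl]), 2, 1)
        pheno = np.array([1] * n_case + [0] * n_ctrl)
        return make_dataset(calls.astype(np.int8), spacing_bp=1000,
                            phenotype=pheno)

    def _pool_for(self, ds):
        lo, hi = int(ds.variants["bp"].min()), int(ds.variants["bp"].max())
        segs = _segments([("s0", 1, lo, hi, ds.n_variants, (hi - lo + 1) / 1000)])
        return pool_overlapping(segs)[0]

    def test_identical_distributions_centre_p(self, rng):
        ds = self._region_dataset(rng, 0.6, 0.6)
        ds.calls[80:] = ds.calls[:80]  # controls exactly mirror cases
        res = homozygosity_proportion_test(self._pool_for(ds), ds)
        assert res.p_value == pytest.approx(0.5)

    def test_case_enriched_region_detected_with_power(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(900 + seed)
            ds = self._region_dataset(rng, 0.75, 0.60)
            res = homozygosity_proportion_test(self._pool_for(ds), ds)
            hits += res.p_value < 0.05
        assert hits > 90

    def test_swapped_labels_reverse_direction(self):
        rng = np.random.default_rng(7)
        ds = self._region_dataset(rng, 0.75, 0.60)
        swapped = ds.copy()
        swapped.samples["phenotype"] = 1 - ds.samples["phenotype"]
        res = homozygosity_proportion_test(self._pool_for(swapped), swapped)
        assert res.p_value > 0.5

    def test_tiny_region_rejected(self, rng):
        ds = self._region_dataset(rng, 0.6, 0.6, n_snp=1)
        with pytest.raises(ValueError, match="2 SNPs"):
            homozygosity_proportion_test(self._pool_for(ds), ds)
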