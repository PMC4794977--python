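import numpy as np
import pandas as pd
import pytest

from autozyg.roh_burden import (
    L_AUTO_BP,
    burden_category_or,
    burden_t_tests,
    f_roh,
    individual_burden,
)
from autozyg.roh_detect import scan_roh
from autozyg.synthetic_data import SimConfig, simulate_genotypes


def _segments(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp",
                                       "end_bp", "n_snp", "length_kb"])


class TestIndividualBurden:
    def test_arithmetic(self):
        segs = _segments([("s1", 1, 1, 1_000_000, 80, 1000.0),
                          ("s1", 1, 2_000_000, 3_500_000, 90, 1500.0),
                          ("s1", 2, 1, 2_000_000, 120, 2000.0)])
        row = individual_burden(segs).iloc[0]
        assert row.n_roh == 3
        assert row.total_kb == 4500.0
        assert row.mean_kb == 1500.0

    def test_absent_samples_get_zeros(self):
        out = individual_burden(_segments([]), sample_ids=["a", "b"])
        assert (out["n_roh"] == 0).all()
        assert (out["f_roh"] == 0.0).all()
        assert (out["mean_kb"] == 0.0).all()

    def test_short_segments_excluded_by_criterion(self):
        segs = _segments([("s1", 1, 1, 900_000, 80, 900.0),
                          ("s1", 1, 1, 1_200_000, 80, 1200.0)])
        row = individual_burden(segs, min_kb=1000).iloc[0]
        assert row.n_roh == 1 and row.total_kb == 1200.0

    def test_matches_caller_output_exactly(self, small_cohort):
        ds, _ = small_cohort
        segs = scan_roh(ds)
        out = individual_burden(segs, sample_ids=ds.samples["id"])
        for _, r in out.iterrows():
            mine = segs[(segs["sample_id"] == r.sample_id)
                        & (segs["length_kb"] >= 1000)]
            assert r.n_roh == len(mine)
            assert r.total_kb == pytest.approx(mine["length_kb"].sum())


class TestFRoh:
    def test_no_segments_zero(self):
        assert f_roh([]) == (0.0, 0.0, 0.0)

    def test_whole_genome_is_one(self):
        overall, _, long_ = f_roh([L_AUTO_BP / 1000], l_auto_bp=L_AUTO_BP)
        assert overall == pytest.approx(1.0)
        assert long_ == overall

    def test_known_fraction(self):
        # 1% of the default denominator (26,776.08286 Mb * 1%) -> 0.01
        overall, _, _ = f_roh([26_776.08286])
        assert overall == pytest.approx(0.01)

    def test_short_long_partition(self):
        overall, short, long_ = f_roh([1000.0, 1400.0, 1500.0, 2500.0])
        assert overall == pytest.approx(short + long_)
        assert short == pytest.approx((1000 + 1400) * 1000 / L_AUTO_BP)
        assert long_ == pytest.approx((1500 + 2500) * 1000 / L_AUTO_BP)

    def test_monotone_in_added_segments_and_order_invariant(self, rng):
        lengths = list(rng.uniform(1000, 4000, size=10))
        totals = [f_roh(lengths[:k])[0] for k in range(len(lengths) + 1)]
        assert all(b >= a for a, b in zip(totals, totals[1:]))
        shuffled = list(rng.permutation(lengths))
        assert f_roh(shuffled)[0] == pytest.approx(f_roh(lengths)[0])

    def test_mean_f_roh_increases_with_inbreeding(self):
        means = []
        for fval in (0.0, 0.05, 0.1):
            cfg = SimConfig(n_cases=100, n_controls=100, n_snps=4000, n_chroms=2,
                            inbreeding_f=fval, snp_spacing_bp=3000, seed=41)
            ds, _ = simulate_genotypes(cfg)
            segs = scan_roh(ds)
            burden = individual_burden(segs, sample_ids=ds.samples["id"])
            means.append(burden["f_roh"].mean())
        assert means[0] < means[1] < means[2]


class TestBurdenTTests:
    def test_identical_distributions_null(self):
        burden = pd.DataFrame({"n_roh": [3, 4, 3, 4], "total_kb": [5e3] * 4,
                               "mean_kb": [1.5e3] * 4})
        res = burden_t_tests(burden, [1, 1, 0, 0])
        assert all(r.p_value == 1.0 for r in res.values())

    def test_power_against_total_length_shift(self, rng):
        # +500 kb case shift on a 1000-kb SD: detected in >90% of replicates
        hits = 0
        for _ in range(100):
            total = np.concatenate([rng.normal(23_000 + 500, 1000, 200),
                                    rng.normal(23_000, 1000, 200)])
            burden = pd.DataFrame({"n_roh": np.ones(400), "total_kb": total,
                                   "mean_kb": total})
            res = burden_t_tests(burden, [1] * 200 + [0] * 200)
            hits += res["total_kb"].p_value < 0.05
        assert hits > 90

    def test_permuted_labels_are_null_calibrated(self, rng):
        ps = []
        for _ in range(200):
            total = rng.normal(23_000, 1000, 100)
            labels = rng.permutation([1] * 50 + [0] * 50)
            burden = pd.DataFrame({"n_roh": np.ones(100), "total_kb": total,
                                   "mean_kb": total})
            ps.append(burden_t_tests(burden, labels)["total_kb"].p_value)
        frac = np.mean(np.array(ps) < 0.05)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_small_stratum_rejected(self):
        burden = pd.DataFrame({"n_roh": [1, 2, 3], "total_kb": [1.0, 2, 3],
                               "mean_kb": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            burden_t_tests(burden, [1, 0, 0])


class TestCategoryOr:
    def test_published_category_counts(self):
        # category counts realised through per-individual burden rows
        counts = [(204, 152), (145, 88), (170, 127), (130, 64)]
        n_roh, pheno = [], []
        for k, (ncase, nctrl) in enumerate(counts):
            n_roh += [k * 3 + 1] * (ncase + nctrl)   # 1, 4, 7, 10
            pheno += [1] * ncase + [0] * nctrl
        burden = pd.DataFrame({"n_roh": n_roh,
                               "total_kb": np.zeros(len(n_roh)),
                               "mean_kb": np.zeros(len(n_roh))})
        out = burden_category_or(burden, pheno, metric="n_roh",
                                 cutoffs=[2, 5, 8])
        assert out.loc[1, "odds_ratio"] == pytest.approx(1.228, abs=0.01)
        assert out.loc[2, "odds_ratio"] == pytest.approx(0.997, abs=0.01)
        assert (out.loc[1:, "cases"].to_numpy()
                == np.array([145, 170, 130])).all()

    def test_uniform_ratio_gives_unit_ors(self):
        burden = pd.DataFrame({"n_roh": np.repeat([1, 5, 9], 40),
                               "total_kb": np.zeros(120),
                               "mean_kb": np.zeros(120)})
        pheno = np.tile([1] * 20 + [0] * 20, 3)
        out = burden_category_or(burden, pheno, cutoffs=[3, 7])
        assert np.allclose(out["odds_ratio"].dropna(), 1.0)

    def test_quartile_cutoffs_balance_groups(self, rng):
        burden = pd.DataFrame({"n_roh": rng.integers(0, 40, 400),
                               "total_kb": np.zeros(400),
                               "mean_kb": np.zeros(400)})
        pheno = rng.integers(0, 2, 400)
        out = burden_category_or(burden, pheno, cutoffs="quartiles")
        sizes = (out["cases"] + out["controls"]).to_numpy()
        assert sizes.sum() == 400
        assert sizes.min() > 400 / 4 * 0.5

    def test_counts_partition_strata(self, rng):
        burden = pd.DataFrame({"n_roh": rng.integers(0, 30, 200),
                               "total_kb": rng.uniform(0, 4e4, 200),
                               "mean_kb": np.zeros(200)})
        pheno = np.array([1] * 120 + [0] * 80)
        out = burden_category_or(burden, pheno, metric="total_mb",
                                 cutoffs=[14.1, 19.4, 25.4])
        assert out["cases"].sum() == 120 and out["controls"].sum() == 80
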