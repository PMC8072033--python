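"""Differential-accessibility scores, permutation null, Bonferroni scheme."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from notchdose.diffaccess import (
    adjust_effective_bonferroni,
    call_accessibility,
    gaussian_weights,
    normalize_rpm,
    permutation_pvalue,
    permutation_stats,
    pooled_pvalues,
    smooth_profile,
    stage_pair_test,
    ts_dnun,
    ts_kn,
)
from notchdose.genomic_io import GenomicInterval, write_bed
from notchdose.synthetic import SimConfig, make_truth, simulate_dhs_profiles


def brute_ts_dnun(a, b, eps=None):
    """Spreadsheet-style per-bin evaluation of the unsmoothed score."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    diffs, welch = [], []
    for j in range(a.shape[1]):
        diffs.append((a[:, j].mean() - b[:, j].mean()) ** 2)
        welch.append(a[:, j].var(ddof=1) / len(a) + b[:, j].var(ddof=1) / len(b))
    if eps is None:
        eps = 0.5 * np.median(welch) + 1e-12
    return float(np.mean([d / (w + eps) for d, w in zip(diffs, welch)]))


def _profiles(rng, n_reps=3, n_bins=50, rate=2.0):
    return rng.poisson(rate, size=(n_reps, n_bins)).astype(float)


class TestNormalize:
    def test_count_to_rpm(self):
        assert normalize_rpm(np.array([5.0]), 1e6)[0] == 5.0
        assert normalize_rpm(np.array([3.0]), 2e6)[0] == 1.5

    def test_scale_invariance(self, rng):
        counts = rng.poisson(4, size=(3, 20)).astype(float)
        libs = np.array([1e6, 2e6, 5e5])
        np.testing.assert_allclose(
            normalize_rpm(counts, libs), normalize_rpm(2 * counts, 2 * libs)
        )

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            normalize_rpm(np.ones((2, 3)), np.array([1e6, 0.0]))


class TestSmoothing:
    def test_constant_profile_preserved_exactly(self):
        out = smooth_profile(np.full(100, 3.7), bandwidth_bp=150, bin_size=20)
        np.testing.assert_allclose(out, 3.7)

    def test_spike_becomes_symmetric_bump_with_conserved_mass(self):
        spike = np.zeros(200)
        spike[100] = 1.0
        out = smooth_profile(spike, bandwidth_bp=150, bin_size=20)
        assert out[100] == out.max()
        np.testing.assert_allclose(out[99], out[101], rtol=1e-10)
        assert out.sum() == pytest.approx(1.0, abs=0.02)  # interior spike

    def test_zero_bandwidth_limit_recovers_input(self, rng):
        x = rng.normal(size=60)
        out = smooth_profile(x, bandwidth_bp=1e-3, bin_size=20)
        np.testing.assert_allclose(out, x)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.ones(10), bandwidth_bp=0)


class TestTsDnun:
    def test_identical_conditions_score_zero(self, rng):
        a = _profiles(rng)
        assert ts_dnun(a, a.copy()) == 0.0

    def test_two_bin_hand_case(self):
        # bin 1 identical, bin 2 differs by 2 with zero replicate variance:
        # score = (1/2) * (0 + 4 / eps) with eps the absolute variance floor
        a = np.array([[1.0, 3.0], [1.0, 3.0]])
        b = np.array([[1.0, 1.0], [1.0, 1.0]])
        expected = 0.5 * (4.0 / 1e-12)
        assert ts_dnun(a, b) == pytest.approx(expected, rel=1e-9)
        assert ts_dnun(a, b) == pytest.approx(brute_ts_dnun(a, b), rel=1e-9)

    def test_agrees_with_brute_force_on_noise(self, rng):
        a, b = _profiles(rng), _profiles(rng, rate=3.0)
        assert ts_dnun(a, b) == pytest.approx(brute_ts_dnun(a, b), rel=1e-12)

    def test_joint_scale_identity(self, rng):
        # doubling the data equals doubling means and quadrupling variances
        a, b = _profiles(rng), _profiles(rng, rate=5.0)
        diffs = (a.mean(0) - b.mean(0)) ** 2 * 4.0
        welch = (a.var(0, ddof=1) / len(a) + b.var(0, ddof=1) / len(b)) * 4.0
        eps = 0.5 * np.median(welch) + 1e-12
        manual = np.mean(diffs / (welch + eps))
        assert ts_dnun(2 * a, 2 * b) == pytest.approx(manual, rel=1e-12)

    def test_label_exchange_symmetry(self, rng):
        a, b = _profiles(rng), _profiles(rng, rate=4.0)
        assert ts_dnun(a, b) == pytest.approx(ts_dnun(b, a), rel=1e-12)
        assert ts_kn(a, b) == pytest.approx(ts_kn(b, a), rel=1e-12)

    def test_single_replicate_rejected(self, rng):
        with pytest.raises(ValueError):
            ts_dnun(_profiles(rng, n_reps=1), _profiles(rng))


class TestTsKn:
    def test_identical_conditions_score_zero(self, rng):
        a = _profiles(rng)
        assert ts_kn(a, a.copy()) == 0.0

    def test_positional_shift_detected(self, rng):
        x = (np.arange(200) + 0.5) * 20
        bump1 = 5 * np.exp(-0.5 * ((x - 2000) / 300) ** 2)
        bump2 = 5 * np.exp(-0.5 * ((x - 2300) / 300) ** 2)
        a = rng.poisson(0.5 + bump1, size=(3, 200)).astype(float)
        b = rng.poisson(0.5 + bump2, size=(3, 200)).astype(float)
        null = rng.poisson(0.5 + bump1, size=(3, 200)).astype(float)
        assert ts_kn(a, b) > 10 * ts_kn(a, null)

    def test_zero_bandwidth_limit_equals_unsmoothed(self, rng):
        a, b = _profiles(rng), _profiles(rng, rate=3.0)
        assert ts_kn(a, b, bandwidth_bp=1e-3) == pytest.approx(ts_dnun(a, b), rel=1e-9)


class TestPermutation:
    def test_2v2_enumerates_six_assignments(self, rng):
        a = np.array([[5.0, 5.0], [6.0, 6.0]])
        b = np.array([[0.0, 0.0], [1.0, 1.0]])
        p, n_eval = permutation_pvalue(a, b)
        assert n_eval == 6
        # the label-swap complement always ties the identity, so the smallest
        # attainable p with 2v2 is 2/6
        assert p == pytest.approx(1 / 3)

    def test_identical_data_gives_p_one(self):
        a = np.array([[1.0, 2.0], [1.0, 2.0]])
        p, _ = permutation_pvalue(a, a.copy())
        assert p == 1.0

    def test_null_pvalues_uniform_at_tail(self):
        # 500 null regions, 3v3 exhaustive enumeration: P(p <= 0.1) = 0.1 +- 0.03
        config = SimConfig(n_regions=500, seed=21, n_background_genes=0)
        truth = make_truth(config, {"null": 500})
        pset = simulate_dhs_profiles(config, truth)
        rpm = pset.rpm()
        ia, ib = pset.sample_indices("LSK"), pset.sample_indices("DN1")
        pvals = np.array(
            [
                permutation_pvalue(rpm[ia, ri, :], rpm[ib, ri, :])[0]
                for ri in range(500)
            ]
        )
        assert abs((pvals <= 0.1).mean() - 0.10) <= 0.03

    def test_monte_carlo_path_with_add_one_estimator(self, rng):
        a = _profiles(rng, n_reps=5)
        b = _profiles(rng, n_reps=5, rate=6.0)
        p, n_eval = permutation_pvalue(a, b, max_perms=99, seed=0)
        assert n_eval == 100
        assert 1 / 100 <= p <= 1.0

    def test_observed_statistics_match_their_permutation_null(self):
        # on null regions, observed scores and pooled permutation scores are
        # draws from the same distribution (two-sample KS)
        config = SimConfig(n_regions=500, seed=22, n_background_genes=0)
        truth = make_truth(config, {"null": 500})
        pset = simulate_dhs_profiles(config, truth)
        rpm = pset.rpm()
        ia, ib = pset.sample_indices("LSK"), pset.sample_indices("DN1")
        rng = np.random.default_rng(1)
        obs, pool = [], []
        for ri in range(500):
            v, _ = permutation_stats(rpm[ia, ri, :], rpm[ib, ri, :], seed=rng)
            obs.append(v[0])
            pool.append(v[1:])
        ks = sps.ks_2samp(np.array(obs), np.concatenate(pool))
        assert ks.pvalue > 0.01

    def test_power_monotone_in_peak_amplitude(self):
        rates = []
        for amplitude in (0.0, 1.0, 2.5, 5.0):  # 0, 2x, 5x, 10x background
            config = SimConfig(
                n_regions=200, seed=23, peak_amplitude=amplitude, n_background_genes=0
            )
            truth = make_truth(config, {"low_I": 200})
            pset = simulate_dhs_profiles(config, truth)
            t = stage_pair_test(pset, "LSK", "DN1", statistic="dnun", seed=2)
            rates.append((t["p_perm"] <= 0.05).mean())
        for lo, hi in zip(rates, rates[1:]):
            assert hi >= lo - 0.03


class TestPooledPvalues:
    def test_empirical_tail_estimate(self):
        pool = np.arange(1, 100, dtype=float)
        p = pooled_pvalues(np.array([50.0]), pool)
        assert p[0] == pytest.approx((1 + 50) / 100)

    def test_tail_extension_below_pool_resolution(self, rng):
        pool = rng.exponential(1.0, size=5000)
        p = pooled_pvalues(np.array([pool.max() * 4]), pool)
        assert 0 < p[0] < 1 / 5001


def _diff_frame(pvals):
    return pd.DataFrame(
        {
            "region_id": [f"r{i}" for i in range(len(pvals))],
            "stage_a": "LSK",
            "stage_b": "DN1",
            "p_perm": pvals,
        }
    )


class TestEffectiveBonferroni:
    def test_plain_bonferroni_when_no_overlap(self):
        regions = [GenomicInterval("chr1", i * 10000, i * 10000 + 4000, id=f"r{i}") for i in range(5)]
        out = adjust_effective_bonferroni(_diff_frame([0.01] * 5), regions)
        np.testing.assert_allclose(out["p_adjusted"], 0.05)

    def test_worked_cluster_example(self):
        # two fully overlapping regions (p 0.01, 0.20) + one disjoint:
        # 2 clusters; the overlapping cluster is adjusted to 0.01 x 2 = 0.02
        regions = [
            GenomicInterval("chr1", 0, 4000, id="r0"),
            GenomicInterval("chr1", 0, 4000, id="r1"),
            GenomicInterval("chr1", 20000, 24000, id="r2"),
        ]
        out = adjust_effective_bonferroni(_diff_frame([0.01, 0.20, 0.30]), regions)
        out = out.set_index("region_id")
        assert out["cluster_id"].nunique() == 2
        cluster_p = out.loc[["r0", "r1"], "p_adjusted"].min()
        assert cluster_p == pytest.approx(0.02)

    def test_single_region_unchanged(self):
        regions = [GenomicInterval("chr1", 0, 4000, id="r0")]
        out = adjust_effective_bonferroni(_diff_frame([0.2]), regions)
        assert out["p_adjusted"].iloc[0] == pytest.approx(0.2)

    def test_never_decreases_p_and_order_invariant(self, rng):
        starts = rng.integers(0, 50000, size=20)
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 4000, id=f"r{i}")
            for i, s in enumerate(starts)
        ]
        pvals = rng.uniform(size=20)
        out = adjust_effective_bonferroni(_diff_frame(pvals), regions)
        assert (out["p_adjusted"] >= out["p_perm"] - 1e-15).all()
        perm = rng.permutation(20)
        shuffled = _diff_frame(pvals).iloc[perm].reset_index(drop=True)
        out2 = adjust_effective_bonferroni(shuffled, regions)
        merged = out.set_index("region_id")["p_adjusted"]
        merged2 = out2.set_index("region_id")["p_adjusted"]
        pd.testing.assert_series_equal(merged.sort_index(), merged2.sort_index())


class TestAccessibilityCalls:
    def test_hotspot_bed_mode(self, tmp_path, small_dataset):
        pset = small_dataset.profiles
        # hotspots covering the first two region midpoints only, all stages
        hot = [GenomicInterval(r.chrom, r.start, r.end) for r in pset.regions[:2]]
        bed = tmp_path / "hot.bed"
        write_bed(hot, bed)
        calls = call_accessibility(pset, hotspot_beds={s: bed for s in pset.stages})
        calls = calls.set_index(["region_id", "stage"])
        first = pset.regions[0].id
        last = pset.regions[-1].id
        assert calls.loc[(first, "LSK"), "accessible"]
        assert not calls.loc[(last, "LSK"), "accessible"]
        assert (calls["source"] == "hotspot_bed").all()

    def test_threshold_mode_separates_planted_peaks(self):
        config = SimConfig(n_regions=500, seed=24, n_background_genes=0)
        truth = make_truth(config, {"low_I": 100})
        pset = simulate_dhs_profiles(config, truth)
        calls = call_accessibility(pset).set_index(["region_id", "stage"])
        planted = [t.region_id for t in truth if t.true_class == "low_I"]
        nulls = [t.region_id for t in truth if t.true_class == "null"]
        planted_rate = np.mean([calls.loc[(r, "DN1"), "accessible"] for r in planted])
        null_rate = np.mean([calls.loc[(r, "DN1"), "accessible"] for r in nulls])
        assert planted_rate >= 0.99
        assert null_rate <= 0.01
        assert (calls["source"] == "threshold").all()
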