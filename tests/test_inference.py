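"""Count-data inference: summaries, bootstrap, regime calls, rate-ratio solver."""

import itertools

import numpy as np
import pytest

from organoise import (
    CountSample,
    RateConstants,
    bootstrap_uncertainty,
    classify_regime_from_counts,
    compare_to_reference,
    fano_fdt,
    fano_vs_mean_report,
    poisson_distribution,
    shifted_poisson_distribution,
    solve_k_denovo_ratio,
    summarize_counts,
)
from organoise.inference import SummaryStats
from organoise.synthetic import FixtureSpec, generate_counts


class TestSummarize:
    def test_constant_sample(self):
        s = summarize_counts(CountSample(np.array([2, 2, 2])))
        assert (s.mean, s.variance, s.fano) == (2.0, 0.0, 0.0)

    def test_hand_arithmetic(self, small_sample):
        s = summarize_counts(small_sample)
        assert (s.mean, s.variance, s.fano) == (2.0, 1.0, 0.5)

    def test_poisson_sample_fano_near_one(self, rng):
        counts = rng.poisson(3.0, size=10000)
        s = summarize_counts(CountSample(counts))
        assert abs(s.fano - 1.0) < 3 * np.sqrt(2 / 10000) * 1.5

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize_counts(CountSample(np.array([5])))
        with pytest.raises(ValueError):
            summarize_counts(CountSample(np.array([0, 0, 0])))

    def test_validation(self):
        with pytest.raises(ValueError):
            CountSample(np.array([1, -2]))
        with pytest.raises(ValueError):
            CountSample(np.array([1.5, 2.0]))
        with pytest.raises(ValueError):
            CountSample(np.array([], dtype=int))


class TestBootstrap:
    def test_constant_sample_has_zero_se(self):
        s = bootstrap_uncertainty(CountSample(np.array([2, 2, 2, 2])), 200, seed=1)
        assert s.se_mean == 0.0 and s.se_fano == 0.0

    def test_monte_carlo_converges_to_exhaustive_enumeration(self, small_sample):
        # n = 3: enumerate all 27 equally likely resamples exactly
        counts = np.array([1.0, 2.0, 3.0])
        means, fanos = [], []
        for idx in itertools.product(range(3), repeat=3):
            r = counts[list(idx)]
            means.append(r.mean())
            fanos.append(r.var(ddof=1) / r.mean())
        exact_se_mean = np.std(means)  # population std over the 27 outcomes
        exact_se_fano = np.std(fanos)
        s = bootstrap_uncertainty(small_sample, 40000, seed=7)
        assert s.se_mean == pytest.approx(exact_se_mean, rel=0.03)
        assert s.se_fano == pytest.approx(exact_se_fano, rel=0.03)

    def test_deterministic_given_seed(self, small_sample):
        a = bootstrap_uncertainty(small_sample, 500, seed=3)
        b = bootstrap_uncertainty(small_sample, 500, seed=3)
        assert (a.se_mean, a.se_fano, a.ci_fano) == (b.se_mean, b.se_fano, b.ci_fano)

    def test_se_fano_scale_at_experiment_size(self, rng):
        counts = rng.poisson(3.0, size=150)
        s = bootstrap_uncertainty(CountSample(counts), 1000, seed=5)
        assert 0.04 < s.se_fano < 0.25  # the reported error-bar magnitude scale

    def test_degenerate_resamples_counted(self):
        sample = CountSample(np.array([0, 0, 0, 0, 0, 3]))
        s = bootstrap_uncertainty(sample, 2000, seed=2)
        assert s.n_degenerate_resamples > 0
        assert np.isfinite(s.se_fano)


class TestRegimeCall:
    @staticmethod
    def _stats(fano, lo, hi):
        return SummaryStats(
            n_cells=150, mean=3.0, variance=fano * 3.0, fano=fano,
            se_mean=0.1, se_fano=0.1, ci_mean=(2.8, 3.2), ci_fano=(lo, hi),
            bootstrap_reps=1000, seed=0,
        )

    @pytest.mark.parametrize(
        "fano, lo, hi, expected",
        [
            (2.4, 2.0, 2.8, "fission_dominated"),
            (1.0, 0.9, 1.1, "denovo_dominated"),
            (0.5, 0.4, 0.6, "fission_fusion_balance"),
            (1.3, 0.5, 2.6, "indeterminate"),
        ],
    )
    def test_interval_rules(self, fano, lo, hi, expected):
        assert classify_regime_from_counts(self._stats(fano, lo, hi)).call == expected

    def test_interval_required(self):
        stats = summarize_counts(CountSample(np.array([1, 2, 3])))
        with pytest.raises(ValueError):
            classify_regime_from_counts(stats)


class TestSolveKDenovoRatio:
    def test_vacuole_case_gives_zero_exactly(self):
        assert solve_k_denovo_ratio(2.0, 0.5) == 0.0

    def test_worked_example(self):
        assert solve_k_denovo_ratio(3.0, 0.6) == pytest.approx(0.2)

    def test_fano_above_decay_free_bound_rejected(self):
        with pytest.raises(ValueError):
            solve_k_denovo_ratio(2.0, 1.0)

    @pytest.mark.parametrize("mean", [1.5, 2.0, 3.0, 5.0])
    @pytest.mark.parametrize("ratio", [0.0, 0.2, 1.0, 4.0])
    def test_inverts_decay_free_fano_formula(self, mean, ratio):
        # gamma = 0 rates realizing the ratio: k_denovo = ratio * k_fission * mean
        rc = RateConstants(k_denovo=ratio * mean, k_fission=1.0, k_fusion=1.0, gamma=0.0)
        fano = fano_fdt(rc, mean)
        assert solve_k_denovo_ratio(mean, fano) == pytest.approx(ratio, abs=1e-10)


class TestCompareToReference:
    def test_self_consistency_calibration(self, rng):
        # Poisson data vs Poisson reference from the sample mean: the
        # Monte-Carlo G-test should keep its nominal size
        rejections = 0
        for i in range(100):
            counts = rng.poisson(3.2, size=150)
            sample = CountSample(counts)
            ref = poisson_distribution(counts.mean())
            gof = compare_to_reference(sample, ref, n_null=199, seed=1000 + i)
            rejections += gof.p_value <= 0.05
        assert rejections <= 10

    def test_power_against_fission_dominated_counts(self):
        # over-dispersed mechanistic counts at the experimental sample size
        big = generate_counts(
            FixtureSpec("power", "ssa_single", 7.0, 2.4, n_cells=15000, seed=99)
        )
        rejections = 0
        for i in range(100):
            chunk = big.counts[i * 150:(i + 1) * 150]
            ref = poisson_distribution(chunk.mean())
            gof = compare_to_reference(CountSample(chunk), ref, n_null=199, seed=i)
            rejections += gof.p_value <= 0.05
        assert rejections >= 90

    def test_perfect_fit_degenerate_sample(self):
        gof = compare_to_reference(
            CountSample(np.array([1, 1, 1])), shifted_poisson_distribution(1.0),
            n_null=99, seed=0,
        )
        assert gof.statistic == pytest.approx(0.0, abs=1e-12)
        assert gof.p_value == 1.0

    def test_zero_counts_against_shifted_reference_warn(self):
        sample = CountSample(np.array([0, 1, 2, 2, 3]))
        with pytest.warns(UserWarning, match="support starts at 1"):
            compare_to_reference(sample, shifted_poisson_distribution(2.0),
                                 n_null=49, seed=0)


class TestFanoVsMeanReport:
    def test_fission_factor_deletion_scenario(self):
        # synthetic wild-type oleic vs fission-factor deletions: Fano ordering
        # follows the configured effects and vps1-like cells fall back to
        # de novo dominated statistics
        specs = [
            FixtureSpec("wild_type_oleic", "ssa_single", 7.0, 2.4, 300, seed=1),
            FixtureSpec("dnm1_oleic", "ssa_single", 6.3, 2.04, 300, seed=2),
            FixtureSpec("fis1_oleic", "ssa_single", 4.0, 1.68, 300, seed=3),
            FixtureSpec("vps1_oleic", "poisson", 1.75, 1.0, 300, seed=4),
        ]
        samples = [generate_counts(s) for s in specs]
        table = fano_vs_mean_report(samples, bootstrap_reps=500, seed=11)
        by_cond = table.set_index("condition")
        assert (
            by_cond.loc["wild_type_oleic", "fano"]
            > by_cond.loc["fis1_oleic", "fano"]
        )
        assert by_cond.loc["vps1_oleic", "regime"] == "denovo_dominated"
        assert table["mean"].is_monotonic_increasing

    def test_single_sample_table(self, rng):
        sample = CountSample(rng.poisson(3, 200))
        table = fano_vs_mean_report([sample], bootstrap_reps=200, seed=0)
        assert len(table) == 1

    def test_ploidy_doubling_keeps_poisson_fano(self, rng):
        hap = CountSample(rng.poisson(3.4, 5000), condition="haploid")
        dip = CountSample(rng.poisson(6.8, 5000), condition="diploid")
        table = fano_vs_mean_report([hap, dip], bootstrap_reps=400, seed=3)
        for _, row in table.iterrows():
            assert abs(row["fano"] - 1.0) < 3 * row["se_fano"]
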