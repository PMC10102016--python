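"""ROC neurometrics: AUROC against the rank-statistic oracle, the
weighted-ROC identity, d' calibration under null and Gaussian generators,
sliding-window peak localization, and modulation indices."""

import numpy as np
import pytest
from scipy import stats

from whisksel.neurometrics import (
    auroc,
    dprime_from_auroc,
    ei_ratio,
    fixed_window_dprime,
    modulation_index,
    population_series,
    prestim_rate,
    sliding_dprime,
)
from whisksel.spikes import BinnedCounts
from whisksel.synth import SynthConfig, simulate_population_counts


def make_binned(counts, window=(-0.1, 0.1), bin_s=0.005):
    counts = np.asarray(counts)
    return BinnedCounts(
        counts=counts,
        window=window,
        bin_s=bin_s,
        trial_index=np.arange(counts.shape[0]),
    )


class TestAuroc:
    def test_tie_convention(self):
        assert auroc([3], [3]) == 0.5

    def test_perfect_separation(self):
        assert auroc([0, 0], [1, 1]) == 1.0

    def test_matches_mann_whitney_on_random_integers(self, rng):
        for _ in range(50):
            a = rng.integers(0, 5, rng.integers(2, 20))
            b = rng.integers(0, 5, rng.integers(2, 20))
            u = stats.mannwhitneyu(b, a, alternative="two-sided").statistic
            assert auroc(a, b) == pytest.approx(u / (len(a) * len(b)), abs=1e-12)

    def test_weighted_duplication_identity(self, rng):
        # 5 copies at weight 1 == one sample at weight 5
        pre = rng.integers(0, 4, 30)
        post = rng.integers(0, 4, 6)
        dup = auroc(pre, np.repeat(post, 5))
        weighted = auroc(pre, post, weights1=np.full(6, 5.0))
        assert dup == pytest.approx(weighted, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([], [1])


class TestDPrimeFromAuroc:
    def test_chance_is_zero(self):
        assert dprime_from_auroc(0.5) == 0.0

    @pytest.mark.parametrize("a", [0.6, 0.75, 0.9])
    def test_antisymmetry(self, a):
        assert dprime_from_auroc(a) == pytest.approx(-dprime_from_auroc(1 - a))

    def test_clip_scales_with_evidence(self):
        assert dprime_from_auroc(1.0, n_per_class=10) < dprime_from_auroc(
            1.0, n_per_class=1000
        )

    def test_gaussian_identity_monte_carlo(self, rng):
        # equal-variance Gaussian: AUROC = Phi(d'/sqrt(2)), so estimated d'
        # approaches the true separation delta/sigma = 1
        x0 = rng.normal(0.0, 1.0, 20_000)
        x1 = rng.normal(1.0, 1.0, 20_000)
        d = dprime_from_auroc(auroc(x0, x1), n_per_class=20_000)
        assert d == pytest.approx(1.0, abs=0.05)


class TestFixedWindow:
    def test_all_zero_counts_chance(self):
        b = make_binned(np.zeros((20, 40), dtype=int))
        res = fixed_window_dprime(b)
        assert res.auroc[0] == 0.5 and res.dprime[0] == 0.0

    def test_null_calibration(self, rng):
        # identical-rate Poisson pre/post: mean d' across sessions ~ 0
        dprimes = []
        for _ in range(300):
            b = make_binned(rng.poisson(0.05, (50, 40)))
            dprimes.append(fixed_window_dprime(b).dprime[0])
        m = np.mean(dprimes)
        assert abs(m) < 3 * np.std(dprimes) / np.sqrt(len(dprimes))

    def test_monotone_in_rate_ratio(self, rng):
        pre = rng.poisson(0.05, (400, 20))
        d_vals = []
        for ratio in (1.5, 2.0, 3.0):
            post = rng.poisson(0.05 * ratio, (400, 20))
            b = make_binned(np.hstack([pre, post]))
            d_vals.append(fixed_window_dprime(b).dprime[0])
        assert d_vals[0] > 0
        assert d_vals == sorted(d_vals)

    def test_pooled_vs_summed_modes_differ_but_agree_in_sign(self, rng):
        pre = rng.poisson(0.05, (200, 20))
        post = rng.poisson(0.12, (200, 20))
        b = make_binned(np.hstack([pre, post]))
        d_pooled = fixed_window_dprime(b, pooled=True).dprime[0]
        d_summed = fixed_window_dprime(b, pooled=False).dprime[0]
        assert d_pooled > 0 and d_summed > 0


class TestSlidingWindow:
    def test_window_grid(self):
        b = make_binned(np.zeros((10, 40), dtype=int))
        res = sliding_dprime(b)
        assert res.window_start_s[0] == 0.0
        assert res.window_start_s[-1] == pytest.approx(0.08)
        assert len(res.window_start_s) == 17
        # all windows end at or before 100 ms post-stimulus
        assert (res.window_start_s + res.window_width_s <= 0.1 + 1e-9).all()

    def test_null_fluctuates_around_zero(self, rng):
        b = make_binned(rng.poisson(0.08, (300, 40)))
        res = sliding_dprime(b)
        assert np.abs(res.dprime).max() < 0.5

    def test_peak_near_generator_latency(self):
        # evoked transient peaking ~40-45 ms: the d' trace peaks in 35-50 ms
        cfg = SynthConfig(n_units=6, seed=31, excitatory_fraction=1.0)
        tgt, _, _ = simulate_population_counts(cfg, n_trials_per_stim=200)
        pop = make_binned(tgt.sum(axis=0))
        res = sliding_dprime(pop)
        assert 0.035 <= res.peak_time_s() <= 0.050


class TestPopulationSeries:
    def test_single_unit_identity(self, rng):
        b = make_binned(rng.poisson(0.1, (5, 40)))
        out = population_series([b])
        np.testing.assert_array_equal(out.counts, b.counts)

    def test_two_units_sum(self, rng):
        b1 = make_binned(rng.poisson(0.1, (5, 40)))
        b2 = make_binned(rng.poisson(0.2, (5, 40)))
        out = population_series([b1, b2])
        np.testing.assert_array_equal(out.counts, b1.counts + b2.counts)

    def test_poisson_additivity_of_means(self, rng):
        l1, l2 = 6.0, 10.0
        b1 = make_binned(rng.poisson(l1 * 0.005, (2000, 40)))
        b2 = make_binned(rng.poisson(l2 * 0.005, (2000, 40)))
        out = population_series([b1, b2])
        lam = (l1 + l2) * 0.005
        assert out.counts.mean() == pytest.approx(lam, abs=3 * np.sqrt(lam / 80_000))

    def test_trial_mismatch_rejected(self, rng):
        b1 = make_binned(rng.poisson(0.1, (5, 40)))
        b2 = make_binned(rng.poisson(0.1, (6, 40)))
        with pytest.raises(ValueError):
            population_series([b1, b2])

    def test_population_dprime_grows_with_informative_units(self, rng):
        # independently informative units: summed counts separate better
        def pop_dprime(n_units):
            pre = rng.poisson(0.04 * n_units, (200, 20))
            post = rng.poisson(0.055 * n_units, (200, 20))
            return fixed_window_dprime(make_binned(np.hstack([pre, post]))).dprime[0]

        assert pop_dprime(16) > pop_dprime(1)


class TestModulation:
    @pytest.mark.parametrize(
        "on,off,expected", [(5.0, 5.0, 0.0), (0.0, 4.0, -1.0), (3.0, 1.0, 0.5)]
    )
    def test_forced_by_formula(self, on, off, expected):
        assert modulation_index(on, off) == pytest.approx(expected)

    def test_zero_rates_undefined(self):
        assert np.isnan(modulation_index(0.0, 0.0))

    def test_ei_ratio(self):
        assert ei_ratio(-0.3, -0.3) == pytest.approx(1.0)
        assert ei_ratio(-0.2, -0.5) == pytest.approx(0.4)
        assert ei_ratio(0.0, -0.5) == 0.0
        with pytest.raises(ZeroDivisionError):
            ei_ratio(0.1, 0.0)

    def test_prestim_rate_units(self):
        counts = np.full((10, 40), 1)  # one spike per 5 ms bin -> 200 Hz
        assert prestim_rate(make_binned(counts)) == pytest.approx(200.0)
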