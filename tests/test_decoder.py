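"""Pseudo-ensemble reader: unit selection, feature arithmetic, the
reconstruction multiset property, the diagonal discriminant against a
closed-form oracle, and iteration behavior."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from whisksel.decoder import (
    CONDITIONS,
    fit_diagonal_lda,
    iterate_reader,
    reconstruct_trials,
    select_top_units,
    train_test_reader,
    trial_features,
)
from whisksel.spikes import BinnedCounts


def make_binned(counts):
    counts = np.asarray(counts)
    return BinnedCounts(
        counts=counts, window=(-0.1, 0.1), bin_s=0.005,
        trial_index=np.arange(counts.shape[0]),
    )


def make_unit_trials(rng, n_units, mu_t=5.0, mu_d=-5.0, sigma=1.0,
                     n_off=70, n_on=30, on_shift=0.0):
    units = {}
    for i in range(n_units):
        units[f"u{i:03d}"] = {
            ("target", "off"): rng.normal(mu_t, sigma, n_off),
            ("distractor", "off"): rng.normal(mu_d, sigma, n_off),
            ("target", "on"): rng.normal(mu_t + on_shift, sigma, n_on),
            ("distractor", "on"): rng.normal(mu_d + on_shift, sigma, n_on),
        }
    return units


class TestSelectTopUnits:
    def test_smaller_half_for_odd_counts(self):
        df = pd.DataFrame(
            {"unit_id": [f"u{i:03d}" for i in range(197)],
             "dprime_target": np.linspace(0, 2, 197)}
        )
        assert len(select_top_units(df, 0.5)) == 98

    def test_all_equal_ties_break_lexicographically(self):
        df = pd.DataFrame(
            {"unit_id": ["u3", "u1", "u2", "u0"], "dprime_target": [1.0] * 4}
        )
        assert list(select_top_units(df, 0.5)["unit_id"]) == ["u0", "u1"]

    def test_fraction_one_is_identity(self):
        df = pd.DataFrame({"unit_id": ["a", "b"], "dprime_target": [1.0, 2.0]})
        assert set(select_top_units(df, 1.0)["unit_id"]) == {"a", "b"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_top_units(pd.DataFrame(columns=["unit_id", "dprime_target"]))


class TestTrialFeatures:
    def test_equal_rates_give_zero(self):
        counts = np.ones((5, 40), dtype=int)  # uniform 200 Hz
        np.testing.assert_allclose(trial_features(make_binned(counts)), 0.0)

    def test_forced_by_arithmetic(self):
        counts = np.zeros((1, 40), dtype=int)
        counts[0, 20] = 2  # 2 spikes in the first 50 ms post, none at baseline
        assert trial_features(make_binned(counts))[0] == pytest.approx(40.0)

    def test_generator_feature_matches_kernel_average(self, rng):
        from whisksel.synth import SynthConfig, expected_epoch_means, simulate_population_counts

        cfg = SynthConfig(n_units=1, seed=13, excitatory_fraction=1.0)
        tgt, _, gt = simulate_population_counts(cfg, n_trials_per_stim=3000, seed=13)
        feats = trial_features(make_binned(tgt[0]))
        post, = expected_epoch_means(gt.iloc[0], "target", "off", cfg, [(0.0, 0.05)])
        pre, = expected_epoch_means(gt.iloc[0], "target", "off", cfg, [(-0.1, 0.0)])
        expected = post / 0.05 - pre / 0.1
        assert feats.mean() == pytest.approx(expected, abs=3 * feats.std() / np.sqrt(3000))


class TestReconstruction:
    def test_exact_duplication_at_half(self, rng):
        units = {"u0": {c: np.arange(35, dtype=float) + k for k, c in enumerate(CONDITIONS)}}
        ens = reconstruct_trials(units, rng)
        off = ens.features[("target", "off")][0]
        assert off.size == 70
        assert Counter(off) == {v: 2 for v in units["u0"][("target", "off")]}

    def test_partial_fill_sampled_without_replacement(self, rng):
        units = {"u0": {c: np.arange(50, dtype=float) for c in CONDITIONS}}
        ens = reconstruct_trials(units, rng)
        off = Counter(ens.features[("target", "off")][0])
        assert sum(off.values()) == 70
        # every reconstructed trial is an original; originals appear 1 or 2 times
        assert set(off) <= set(np.arange(50, dtype=float))
        assert set(off.values()) <= {1, 2}
        assert sum(v == 2 for v in off.values()) == 20

    def test_unit_missing_condition_excluded_with_warning(self, rng):
        units = make_unit_trials(rng, 2)
        units["u000"].pop(("target", "on"))
        with pytest.warns(UserWarning, match="u000"):
            ens = reconstruct_trials(units, rng)
        assert ens.unit_ids == ["u001"]

    def test_per_unit_shuffling_decorrelates(self, rng):
        units = make_unit_trials(rng, 2, sigma=5.0)
        units["u001"] = {c: v.copy() for c, v in units["u000"].items()}
        ens = reconstruct_trials(units, rng)
        a, b = ens.features[("target", "off")]
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.5


class TestReader:
    def test_separable_limit_zero_error(self, rng):
        units = make_unit_trials(rng, 98)
        ens = reconstruct_trials(units, rng)
        res = train_test_reader(ens, rng)
        assert res.error_off == 0.0
        assert res.error_on == 0.0

    def test_label_shuffle_chance_error(self, rng):
        # both classes from the same distribution: error ~ 0.5
        errs = []
        for _ in range(40):
            units = make_unit_trials(rng, 10, mu_t=0.0, mu_d=0.0)
            ens = reconstruct_trials(units, rng)
            errs.append(train_test_reader(ens, rng).error_off)
        assert np.mean(errs) == pytest.approx(0.5, abs=0.08)

    def test_decision_scores_match_naive_gaussian_oracle(self, rng):
        units = make_unit_trials(rng, 7, mu_t=1.0, mu_d=-0.5, sigma=2.0)
        ens = reconstruct_trials(units, rng)
        t = ens.features[("target", "off")][:, :40]
        d = ens.features[("distractor", "off")][:, :40]
        model = fit_diagonal_lda(t, d)
        x = ens.features[("target", "on")]
        got = model.decision_scores(x)
        # independent oracle: per-feature normal log-likelihoods, pooled
        # variance, equal priors
        mu_t, mu_d = t.mean(axis=1), d.mean(axis=1)
        var = (
            ((t - mu_t[:, None]) ** 2).sum(axis=1)
            + ((d - mu_d[:, None]) ** 2).sum(axis=1)
        ) / (t.shape[1] + d.shape[1] - 2)

        def loglik(x, mu):
            return -0.5 * ((x - mu[:, None]) ** 2 / var[:, None]).sum(axis=0)

        want = loglik(x, mu_t) - loglik(x, mu_d)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_zero_variance_feature_floored(self, rng):
        t = np.vstack([np.ones(40), rng.normal(1, 1, 40)])
        d = np.vstack([np.ones(40), rng.normal(-1, 1, 40)])
        with pytest.warns(UserWarning, match="flooring"):
            model = fit_diagonal_lda(t, d)
        assert np.all(model.pooled_var > 0)


class TestIterateReader:
    def test_single_iteration_matches_seed_chain(self, rng):
        units = make_unit_trials(rng, 5, mu_t=0.5, mu_d=-0.5)
        summary = iterate_reader(units, n_iter=1, seed=123)
        child = np.random.default_rng(123).integers(0, 2**31 - 1, size=1)[0]
        r = np.random.default_rng(int(child))
        ens = reconstruct_trials(units, r)
        res = train_test_reader(ens, r)
        assert vars(summary.mean) == vars(res)

    def test_no_opto_effect_null(self, rng):
        units = make_unit_trials(rng, 30, mu_t=0.6, mu_d=-0.6, on_shift=0.0)
        summary = iterate_reader(units, n_iter=50, seed=5)
        assert abs(summary.mean.error_on - summary.mean.error_off) < 0.05

    def test_mean_stable_across_disjoint_halves(self, rng):
        units = make_unit_trials(rng, 12, mu_t=0.25, mu_d=-0.25)
        a = iterate_reader(units, n_iter=100, seed=11)
        b = iterate_reader(units, n_iter=100, seed=12)
        sd = max(a.sd.error_off, b.sd.error_off) / np.sqrt(100)
        assert abs(a.mean.error_off - b.mean.error_off) < max(4 * sd, 0.02)
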