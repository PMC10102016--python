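"""Signal-detection behavior: log-linear rates, d'/criterion against an
inverse-normal oracle, engagement epochs against brute force, trial-count
gating, and the expert rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from whisksel import behavior, synth
from whisksel.behavior import (
    behavioral_dprime,
    criterion,
    engagement_epoch,
    expert_check,
    loglinear_rate,
    sdt_summary,
)


class TestLoglinearRate:
    @pytest.mark.parametrize(
        "n_resp,n_trials,expected",
        [(0, 10, 0.5 / 11), (10, 10, 10.5 / 11), (5, 10, 0.5)],
    )
    def test_forced_by_formula(self, n_resp, n_trials, expected):
        assert loglinear_rate(n_resp, n_trials) == pytest.approx(expected)

    def test_rejects_impossible_counts(self):
        with pytest.raises(ValueError):
            loglinear_rate(11, 10)
        with pytest.raises(ValueError):
            loglinear_rate(-1, 10)

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_strictly_interior_and_monotone(self, a, b):
        n = max(a, b)
        k = min(a, b)
        r = loglinear_rate(k, n)
        assert 0.0 < r < 1.0
        if k < n:
            assert loglinear_rate(k + 1, n) > r


class TestDPrimeAndCriterion:
    def test_equal_rates_give_zero(self):
        assert behavioral_dprime(0.5, 0.5) == 0.0
        assert criterion(0.5, 0.5) == 0.0

    def test_loglinear_extremes_match_inverse_normal_oracle(self):
        # corrected all-response vs no-response rates from 10 trials
        hi, lo = 10.5 / 11, 0.5 / 11
        expected = norm.ppf(hi) - norm.ppf(lo)
        assert behavioral_dprime(hi, lo) == pytest.approx(expected)
        assert behavioral_dprime(hi, lo) == pytest.approx(3.381, abs=5e-3)

    def test_criterion_symmetry_about_half(self):
        assert criterion(0.8, 0.2) == pytest.approx(0.0, abs=1e-12)

    @given(
        st.floats(0.01, 0.99), st.floats(0.01, 0.99)
    )
    def test_antisymmetry_and_oracle(self, a, b):
        assert behavioral_dprime(a, b) == pytest.approx(-behavioral_dprime(b, a))
        assert criterion(a, b) == pytest.approx(-0.5 * (norm.ppf(a) + norm.ppf(b)))
        assert criterion(a, b) == pytest.approx(-criterion(1 - a, 1 - b), abs=1e-9)

    def test_degenerate_rate_instructs_correction(self):
        with pytest.raises(ValueError, match="loglinear"):
            behavioral_dprime(1.0, 0.5)

    @given(st.floats(0.02, 0.98), st.floats(0.02, 0.98), st.floats(0.02, 0.98))
    def test_discrimination_identity(self, hr, far, cr):
        # Z(HR)-Z(FAR) == (Z(HR)-Z(CR)) - (Z(FAR)-Z(CR)) exactly
        lhs = behavioral_dprime(hr, far)
        rhs = behavioral_dprime(hr, cr) - behavioral_dprime(far, cr)
        assert lhs == pytest.approx(rhs, abs=1e-9)


def _brute_force_epoch(licks, min_dur, max_gap):
    best = None
    n = len(licks)
    for i in range(n):
        for j in range(i, n):
            seg = licks[i : j + 1]
            if len(seg) > 1 and np.max(np.diff(seg)) > max_gap:
                continue
            span = seg[-1] - seg[0]
            if span >= min_dur and (best is None or span > best[1] - best[0]):
                best = (seg[0], seg[-1])
    return best


class TestEngagementEpoch:
    def test_no_licks(self):
        assert engagement_epoch(np.array([])) is None

    def test_steady_licking_single_epoch(self):
        licks = np.arange(0.0, 1200.1, 30.0)
        assert engagement_epoch(licks) == (0.0, 1200.0)

    def test_gap_splits_and_longest_wins(self):
        # 8 min of licking, a 61 s gap, then 12 min: only the 12 min segment
        first = np.arange(0.0, 480.1, 30.0)
        second = np.arange(541.0, 541.0 + 720.1, 30.0)
        licks = np.concatenate([first, second])
        epoch = engagement_epoch(licks)
        assert epoch[0] == pytest.approx(541.0)
        assert epoch[1] == pytest.approx(second[-1])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            engagement_epoch(np.array([10.0, 5.0]))

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(20):
            licks = np.sort(rng.uniform(0, 300, rng.integers(2, 30)))
            got = engagement_epoch(licks, min_duration_s=60, max_gap_s=25)
            want = _brute_force_epoch(licks, 60, 25)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)


class TestSDTSummary:
    def test_rates_recover_generator_response_model(self):
        cfg = synth.SynthConfig(n_trials=400, n_units=1, seed=17)
        trials = synth.generate_trials(cfg, np.random.default_rng(cfg.seed))
        s = sdt_summary(trials, opto_condition="off", amplitude="large")
        rm = cfg.response_model
        for rate, p, n in [
            (s.hit_rate, rm.hit_large_off, s.n_target),
            (s.fa_rate, rm.fa_large_off, s.n_distractor),
            (s.catch_rate, rm.spont_off, s.n_catch),
        ]:
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(rate - p) < 3 * sd + 1.0 / n  # log-linear shift <= 1/n

    def test_few_catch_trials_flags_dependent_stats(self):
        import pandas as pd

        n_t, n_d, n_c = 20, 20, 4
        trials = pd.DataFrame(
            {
                "trial_index": range(n_t + n_d + n_c),
                "onset_time_s": np.arange(n_t + n_d + n_c) * 8.0,
                "stim_type": ["target"] * n_t + ["distractor"] * n_d
                + ["catch"] * n_c,
                "amplitude": ["large"] * (n_t + n_d) + ["none"] * n_c,
                "opto": "off",
                "outcome": ["hit"] * 15 + ["miss"] * 5 + ["fa"] * 8
                + ["cr"] * 12 + ["cw"] * n_c,
            }
        )
        s = sdt_summary(trials, opto_condition=None, amplitude=None)
        assert s.n_catch < 5
        assert "dprime_target" in s.unavailable
        assert np.isnan(s.dprime_target) and np.isnan(s.criterion_distractor)
        assert np.isfinite(s.dprime_discrimination)

    def test_degenerate_all_correct_session_finite(self):
        import pandas as pd

        trials = pd.DataFrame(
            {
                "trial_index": range(15),
                "onset_time_s": np.arange(15) * 8.0,
                "stim_type": ["target"] * 5 + ["distractor"] * 5 + ["catch"] * 5,
                "amplitude": ["large"] * 10 + ["none"] * 5,
                "opto": ["off"] * 15,
                "outcome": ["hit"] * 5 + ["cr"] * 5 + ["cw"] * 5,
            }
        )
        s = sdt_summary(trials, opto_condition="off")
        assert np.isfinite(s.dprime_target) and np.isfinite(s.dprime_discrimination)

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            sdt_summary(pd.DataFrame(columns=["stim_type", "outcome"]))


class TestExpertCheck:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([0.5, 1.2, 1.3, 1.4], (True, 3)),
            ([1.2, 0.9, 1.2, 1.3], (False, None)),
        ],
    )
    def test_forced_by_rule(self, seq, expected):
        assert expert_check(seq) == expected

    @settings(deadline=None)
    @given(st.lists(st.floats(0.0, 2.0), min_size=0, max_size=15))
    def test_matches_windowed_scan(self, seq):
        got = expert_check(seq, threshold=1.0, streak=3)
        runs = [
            i + 2
            for i in range(len(seq) - 2)
            if all(v > 1.0 for v in seq[i : i + 3])
        ]
        want = (True, runs[0]) if runs else (False, None)
        assert got == want
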