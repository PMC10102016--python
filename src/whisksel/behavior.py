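"""Behavioral signal-detection analysis for the Go/No-Go selection task.

Response rates per trial type with the log-linear correction, behavioral
d' and criterion from the inverse normal CDF, task-engagement epoch
extraction from the lick log, minimum-trial-count gating, and the
expert-performance criterion (discrimination d' > 1 on consecutive days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

OUTCOME_RESPONSE = {"hit", "fa", "spont"}
OUTCOME_NO_RESPONSE = {"miss", "cr", "cw"}

_STIM_OUTCOMES = {
    "target": ("hit", "miss"),
    "distractor": ("fa", "cr"),
    "catch": ("spont", "cw"),
}


def loglinear_rate(n_responses: int, n_trials: int) -> float:
    """Response rate with the log-linear correction.

    Adds one pseudo-trial split equally between responding and
    non-responding outcomes: ``(n_responses + 0.5) / (n_trials + 1)``.
    Strictly inside (0, 1) for any non-negative counts, which keeps every
    downstream Z transform finite.
    """
    if n_responses < 0 or n_trials < 0:
        raise ValueError("counts must be non-negative")
    if n_responses > n_trials:
        raise ValueError("n_responses cannot exceed n_trials")
    return (n_responses + 0.5) / (n_trials + 1.0)


def _z(rate: float) -> float:
    if not 0.0 < rate < 1.0:
        raise ValueError(
            f"rate {rate} must lie strictly in (0, 1); apply loglinear_rate first"
        )
    return float(norm.ppf(rate))


def behavioral_dprime(rate_a: float, rate_b: float) -> float:
    """Z(rate_a) - Z(rate_b): separation of two response rates in Z units.

    With (hit rate, catch rate) this is target-detection d'; with
    (FA rate, catch rate) distractor-detection d'; with (hit rate, FA rate)
    target-distractor discrimination d'.
    """
    return _z(rate_a) - _z(rate_b)


def criterion(rate_a: float, rate_b: float) -> float:
    """Response criterion c = -0.5 * (Z(rate_a) + Z(rate_b)).

    Lower c means a greater overall tendency to respond.
    """
    return -0.5 * (_z(rate_a) + _z(rate_b))


def engagement_epoch(
    lick_times_s: np.ndarray,
    min_duration_s: float = 600.0,
    max_gap_s: float = 60.0,
) -> tuple[float, float] | None:
    """Longest continuous task-engagement interval, or None.

    An engaged epoch is a run of licks with every inter-lick gap
    <= ``max_gap_s`` whose total span is >= ``min_duration_s``; of the
    qualifying runs, the longest is returned as ``(start_s, end_s)``.
    """
    licks = np.asarray(lick_times_s, dtype=float)
    if licks.size == 0:
        return None
    if np.any(np.diff(licks) < 0):
        raise ValueError("lick times must be sorted ascending")
    gaps = np.diff(licks)
    breaks = np.flatnonzero(gaps > max_gap_s)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [licks.size - 1]])
    best: tuple[float, float] | None = None
    for s, e in zip(starts, ends):
        span = licks[e] - licks[s]
        if span >= min_duration_s and (best is None or span > best[1] - best[0]):
            best = (float(licks[s]), float(licks[e]))
    return best


@dataclass
class SDTSummary:
    """Corrected rates and signal-detection statistics for one condition.

    Statistics whose trial types fail the minimum-count rule are NaN and
    listed in ``unavailable``.
    """

    hit_rate: float
    fa_rate: float
    catch_rate: float
    dprime_target: float
    dprime_distractor: float
    dprime_discrimination: float
    criterion_target: float
    criterion_distractor: float
    n_target: int
    n_distractor: int
    n_catch: int
    unavailable: tuple[str, ...] = ()


def _counts(trials: pd.DataFrame, stim: str) -> tuple[int, int]:
    resp_out, _ = _STIM_OUTCOMES[stim]
    sub = trials[(trials["stim_type"] == stim) & (trials["outcome"] != "abort")]
    return int((sub["outcome"] == resp_out).sum()), len(sub)


def sdt_summary(
    trials: pd.DataFrame,
    opto_condition: str | None = None,
    amplitude: str | None = "large",
    min_trials: int = 5,
) -> SDTSummary:
    """Per-condition behavioral rates and the five SDT statistics.

    Abort (lockout-lick) trials are excluded from all denominators and do
    not count toward the minimum-trial rule.  ``amplitude`` of None pools
    small and large stimuli (catch trials are always included regardless
    of the amplitude filter).  Any trial type with fewer than
    ``min_trials`` usable trials marks its dependent statistics NaN.
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    sel = trials
    if opto_condition is not None:
        sel = sel[sel["opto"] == opto_condition]
    if amplitude is not None:
        sel = sel[(sel["amplitude"] == amplitude) | (sel["stim_type"] == "catch")]
    if sel.empty:
        raise ValueError("no trials left after condition filtering")

    n_hit, n_t = _counts(sel, "target")
    n_fa, n_d = _counts(sel, "distractor")
    n_sp, n_c = _counts(sel, "catch")

    hr = loglinear_rate(n_hit, n_t) if n_t > 0 else np.nan
    far = loglinear_rate(n_fa, n_d) if n_d > 0 else np.nan
    cr = loglinear_rate(n_sp, n_c) if n_c > 0 else np.nan

    ok_t = n_t >= min_trials
    ok_d = n_d >= min_trials
    ok_c = n_c >= min_trials
    unavailable = []

    def gated(name: str, ok: bool, fn, *args):
        if ok and all(np.isfinite(a) for a in args):
            return fn(*args)
        unavailable.append(name)
        return np.nan

    dp_t = gated("dprime_target", ok_t and ok_c, behavioral_dprime, hr, cr)
    dp_d = gated("dprime_distractor", ok_d and ok_c, behavioral_dprime, far, cr)
    dp_x = gated("dprime_discrimination", ok_t and ok_d, behavioral_dprime, hr, far)
    c_t = gated("criterion_target", ok_t and ok_c, criterion, hr, cr)
    c_d = gated("criterion_distractor", ok_d and ok_c, criterion, far, cr)

    return SDTSummary(
        hit_rate=hr,
        fa_rate=far,
        catch_rate=cr,
        dprime_target=dp_t,
        dprime_distractor=dp_d,
        dprime_discrimination=dp_x,
        criterion_target=c_t,
        criterion_distractor=c_d,
        n_target=n_t,
        n_distractor=n_d,
        n_catch=n_c,
        unavailable=tuple(unavailable),
    )


def restrict_to_epoch(
    trials: pd.DataFrame, epoch: tuple[float, float] | None
) -> pd.DataFrame:
    """Trials whose stimulus onset falls inside the engagement epoch."""
    if epoch is None:
        return trials.iloc[0:0]
    start, end = epoch
    keep = (trials["onset_time_s"] >= start) & (trials["onset_time_s"] <= end)
    return trials[keep]


def expert_check(
    daily_dprime: np.ndarray, threshold: float = 1.0, streak: int = 3
) -> tuple[bool, int | None]:
    """Expert-performance rule: discrimination d' above ``threshold`` for
    ``streak`` consecutive days.

    Returns ``(is_expert, index_of_last_day_of_first_qualifying_run)``.
    """
    vals = np.asarray(daily_dprime, dtype=float)
    run = 0
    for i, v in enumerate(vals):
        run = run + 1 if v > threshold else 0
        if run >= streak:
            return True, i
    return False, None
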