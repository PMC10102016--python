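"""ROC-based stimulus-encoding statistics (neuronal d') and pre-stimulus
optogenetic modulation indices.

Neuronal d' is the ideal-observer separation between pre- and
post-stimulus spike-count distributions: d' = sqrt(2) * Z(AUROC), where
AUROC is the area under the ROC curve (equivalently the Mann-Whitney
probability that a random post-stimulus count exceeds a random
pre-stimulus count, ties counting one half).  Two window schemes are
provided: a fixed 100 ms pre vs 100 ms post comparison in which each
trial contributes two 50 ms epoch counts per class, and a sliding 20 ms
post-stimulus window (5 ms steps, 75% overlap) compared against the five
consecutive 20 ms windows tiling the last 100 ms of the pre-stimulus
period, with post samples weighted x5 to balance the pre-sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .spikes import BinnedCounts


def auroc(
    class0: np.ndarray,
    class1: np.ndarray,
    weights0: np.ndarray | None = None,
    weights1: np.ndarray | None = None,
) -> float:
    """Area under the ROC curve separating class1 from class0.

    Equals P(X1 > X0) + 0.5 * P(X1 = X0) under the (weighted) empirical
    distributions, i.e. the normalized Mann-Whitney U statistic.  Sample
    weights generalize this to weighted resampling schemes.
    """
    x0 = np.asarray(class0, dtype=float).ravel()
    x1 = np.asarray(class1, dtype=float).ravel()
    if x0.size == 0 or x1.size == 0:
        raise ValueError("both classes must be non-empty")
    w0 = np.ones(x0.size) if weights0 is None else np.asarray(weights0, dtype=float)
    w1 = np.ones(x1.size) if weights1 is None else np.asarray(weights1, dtype=float)
    if w0.shape != x0.shape or w1.shape != x1.shape:
        raise ValueError("weights must match their samples")
    if np.any(w0 < 0) or np.any(w1 < 0):
        raise ValueError("weights must be non-negative")
    order = np.argsort(x0, kind="stable")
    x0s, w0s = x0[order], w0[order]
    cum = np.concatenate([[0.0], np.cumsum(w0s)])
    lo = np.searchsorted(x0s, x1, side="left")
    hi = np.searchsorted(x0s, x1, side="right")
    w_below = cum[lo]
    w_equal = cum[hi] - cum[lo]
    total0 = cum[-1]
    total1 = float(np.sum(w1))
    if total0 <= 0 or total1 <= 0:
        raise ValueError("total weight must be positive in both classes")
    return float(np.sum(w1 * (w_below + 0.5 * w_equal)) / (total0 * total1))


def dprime_from_auroc(
    a: float, n_per_class: int | None = None, clip_eps: float | None = None
) -> float:
    """Convert AUROC to neuronal d' = sqrt(2) * Z(AUROC).

    Extreme AUROCs are clipped to keep d' finite: by default to
    ``[1/(4N), 1 - 1/(4N)]`` where N is the number of samples per class,
    so the bound tightens as evidence grows; pass ``clip_eps`` to
    override.  Antisymmetric: d'(a) = -d'(1 - a) and d'(0.5) = 0.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("AUROC must lie in [0, 1]")
    if clip_eps is None:
        clip_eps = 1.0 / (4.0 * n_per_class) if n_per_class else 1e-6
    a = float(np.clip(a, clip_eps, 1.0 - clip_eps))
    return float(np.sqrt(2.0) * norm.ppf(a))


@dataclass
class DPrimeSeries:
    """Per-window AUROC and d' for one unit or population."""

    window_start_s: np.ndarray  # post-stimulus window starts (s)
    window_width_s: float
    auroc: np.ndarray
    dprime: np.ndarray
    n_trials: int
    scope: str = "single_unit"  # or "population"
    kind: str = "fixed"  # or "sliding"

    def peak_time_s(self) -> float:
        """Center of the window with the largest d'."""
        i = int(np.argmax(self.dprime))
        return float(self.window_start_s[i] + self.window_width_s / 2.0)

    def mean_dprime(self, lo_s: float, hi_s: float) -> float:
        """Mean d' over windows starting within [lo_s, hi_s]."""
        sel = (self.window_start_s >= lo_s - 1e-9) & (
            self.window_start_s <= hi_s + 1e-9
        )
        if not sel.any():
            raise ValueError("no windows in the requested range")
        return float(self.dprime[sel].mean())


def _epoch_sums(binned: BinnedCounts, lo: float, hi: float, epoch_s: float) -> np.ndarray:
    """Per-trial spike counts in consecutive epochs tiling [lo, hi).

    Returns shape (n_trials, n_epochs).
    """
    n_epochs = int(round((hi - lo) / epoch_s))
    cols = []
    for k in range(n_epochs):
        seg = binned.window_slice(lo + k * epoch_s, lo + (k + 1) * epoch_s)
        cols.append(seg.sum(axis=1))
    return np.stack(cols, axis=1)


def fixed_window_dprime(
    binned: BinnedCounts,
    pre: tuple[float, float] = (-0.1, 0.0),
    post: tuple[float, float] = (0.0, 0.1),
    epoch_s: float = 0.05,
    pooled: bool = True,
    scope: str = "single_unit",
) -> DPrimeSeries:
    """Fixed-window neuronal d': 100 ms pre vs 100 ms post spike counts.

    With ``pooled`` (default) each trial contributes one sample per 50 ms
    epoch to each class (2N pre vs 2N post samples); with
    ``pooled=False`` epochs are summed into a single 100 ms count per
    trial per class.
    """
    if binned.window[0] > pre[0] + 1e-9 or binned.window[1] < post[1] - 1e-9:
        raise ValueError("binned window does not cover the pre/post analysis windows")
    span = epoch_s if pooled else (pre[1] - pre[0])
    pre_s = _epoch_sums(binned, pre[0], pre[1], span).ravel()
    post_s = _epoch_sums(binned, post[0], post[1], span).ravel()
    a = auroc(pre_s, post_s)
    d = dprime_from_auroc(a, n_per_class=pre_s.size)
    return DPrimeSeries(
        window_start_s=np.array([post[0]]),
        window_width_s=post[1] - post[0],
        auroc=np.array([a]),
        dprime=np.array([d]),
        n_trials=binned.n_trials,
        scope=scope,
        kind="fixed",
    )


def sliding_dprime(
    binned: BinnedCounts,
    width_s: float = 0.02,
    step_s: float = 0.005,
    post_max_s: float = 0.1,
    pre_span_s: float = 0.1,
    scope: str = "single_unit",
) -> DPrimeSeries:
    """Sliding-window neuronal d' over the first 100 ms post-stimulus.

    Each 20 ms post window (stepping 5 ms, ending at or before
    ``post_max_s``) is compared against the five consecutive 20 ms
    windows tiling the last ``pre_span_s`` before stimulus onset.  Every
    trial thus contributes five pre samples but one post sample; post
    samples carry weight 5 to compensate.
    """
    if binned.window[0] > -pre_span_s + 1e-9 or binned.window[1] < post_max_s - 1e-9:
        raise ValueError("binned window must cover the pre-stimulus span")
    pre_samples = _epoch_sums(binned, -pre_span_s, 0.0, width_s).ravel()
    n_pre_windows = int(round(pre_span_s / width_s))
    starts = np.arange(0.0, post_max_s - width_s + 1e-9, step_s)
    aurocs = np.empty(starts.size)
    dprimes = np.empty(starts.size)
    w1 = np.full(binned.n_trials, float(n_pre_windows))
    for i, s in enumerate(starts):
        post_samples = binned.window_slice(s, s + width_s).sum(axis=1)
        a = auroc(pre_samples, post_samples, weights1=w1)
        aurocs[i] = a
        dprimes[i] = dprime_from_auroc(a, n_per_class=pre_samples.size)
    return DPrimeSeries(
        window_start_s=starts,
        window_width_s=width_s,
        auroc=aurocs,
        dprime=dprimes,
        n_trials=binned.n_trials,
        scope=scope,
        kind="sliding",
    )


def population_series(units: list[BinnedCounts]) -> BinnedCounts:
    """Bin-wise sum of simultaneously recorded units (the population series)."""
    if not units:
        raise ValueError("need at least one unit")
    first = units[0]
    total = first.counts.copy()
    for b in units[1:]:
        if (
            b.counts.shape != first.counts.shape
            or b.window != first.window
            or not np.array_equal(b.trial_index, first.trial_index)
        ):
            raise ValueError("units must share trial alignment and windows")
        total = total + b.counts
    return BinnedCounts(total, first.window, first.bin_s, first.trial_index.copy())


def prestim_rate(binned: BinnedCounts, window: tuple[float, float] = (-0.1, 0.0)) -> float:
    """Trial-averaged spike rate (Hz) in a pre-stimulus window."""
    seg = binned.window_slice(*window)
    return float(seg.sum() / (binned.n_trials * seg.shape[1] * binned.bin_s))


def modulation_index(on_rate_hz: float, off_rate_hz: float) -> float:
    """Pre-stimulus optogenetic modulation index.

    MI = (on - off) / (on + off), in [-1, 1].  MI < 0 means the light
    (suppressing the projecting region) reduces spiking, i.e. that region
    normally drives the unit.  NaN when both rates are zero.
    """
    if on_rate_hz < 0 or off_rate_hz < 0:
        raise ValueError("rates must be non-negative")
    total = on_rate_hz + off_rate_hz
    if total == 0:
        return float("nan")
    return (on_rate_hz - off_rate_hz) / total


def ei_ratio(mean_mi_excitatory: float, mean_mi_inhibitory: float) -> float:
    """E/I modulation ratio: mean excitatory MI over mean inhibitory MI.

    Ratios near 1 indicate balanced drive onto both populations; ratios
    below 1 indicate preferential drive onto inhibitory neurons.
    """
    if mean_mi_inhibitory == 0:
        raise ZeroDivisionError("inhibitory mean MI is zero; ratio undefined")
    return mean_mi_excitatory / mean_mi_inhibitory
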