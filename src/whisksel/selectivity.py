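"""Single-unit stimulus selectivity: preferred vs unpreferred encoding
scatter, linear fits with 95% confidence intervals, and the
rotation-vs-shift contrast between light-off and light-on fits.

Each unit contributes a (preferred d', unpreferred d') pair — its
fixed-window neuronal d' for the stimulus contralateral to the recording
site and for the opposite-side (cross-hemispheric) stimulus.  The
across-population linear fit summarizes how strongly units couple the
two: a positive slope means units that encode their preferred stimulus
strongly also respond to the unpreferred one; a change in slope between
light conditions (disjoint CIs) is a "rotation" of the population
selectivity, while a change in intercept alone is a "shift".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .neurometrics import fixed_window_dprime
from .spikes import BinnedCounts


@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    confidence: float = 0.95
    # sufficient statistics for CIs of the fitted line at arbitrary x
    x_mean: float = 0.0
    sxx: float = 0.0
    resid_se: float = 0.0

    def height_ci(self, x0: float) -> tuple[float, float]:
        """CI for the fitted line's height at ``x0`` (narrowest at the
        data centroid, widening under extrapolation)."""
        h = self.slope * x0 + self.intercept
        if self.n < 3:
            raise ValueError("height CI needs n >= 3")
        tcrit = stats.t.ppf(0.5 + self.confidence / 2.0, self.n - 2)
        se = self.resid_se * np.sqrt(
            1.0 / self.n + (x0 - self.x_mean) ** 2 / self.sxx
        )
        return (h - tcrit * se, h + tcrit * se)


@dataclass
class SelectivityFit:
    """Population selectivity scatter and its linear fit for one condition."""

    units: pd.DataFrame  # unit_id, dprime_preferred, dprime_unpreferred
    condition: str
    fit: LinearFit


def unit_selectivity(
    binned_target: BinnedCounts,
    binned_distractor: BinnedCounts,
    hemisphere_alignment: str,
    min_trials: int = 5,
) -> tuple[float, float]:
    """(preferred d', unpreferred d') for one unit.

    Fixed-window d' is computed separately on target-stimulus and
    distractor-stimulus trials and mapped through the recording-side
    alignment: target-aligned units prefer target stimuli.
    """
    if hemisphere_alignment not in ("target", "distractor"):
        raise ValueError("hemisphere_alignment must be 'target' or 'distractor'")
    if binned_target.n_trials < min_trials or binned_distractor.n_trials < min_trials:
        raise ValueError(f"need at least {min_trials} trials of each stimulus")
    d_target = fixed_window_dprime(binned_target).dprime[0]
    d_distractor = fixed_window_dprime(binned_distractor).dprime[0]
    if hemisphere_alignment == "target":
        return d_target, d_distractor
    return d_distractor, d_target


def linear_fit_ci(
    x: np.ndarray, y: np.ndarray, confidence: float = 0.95
) -> LinearFit:
    """Ordinary least squares line with t-distribution confidence intervals.

    CIs use n - 2 degrees of freedom on the standard errors of the slope
    and intercept; an exact fit has zero-width intervals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x values are degenerate (zero variance)")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, x.size - 2)
    resid = y - (res.slope * x + res.intercept)
    resid_se = float(np.sqrt(np.sum(resid**2) / max(x.size - 2, 1)))
    return LinearFit(
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
        resid_se=resid_se,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        intercept_ci=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        n=int(x.size),
        confidence=confidence,
    )


def fit_selectivity(
    pairs: pd.DataFrame, condition: str, confidence: float = 0.95
) -> SelectivityFit:
    """Fit the unpreferred-on-preferred d' line for one condition.

    ``pairs`` needs columns ``unit_id``, ``dprime_preferred``,
    ``dprime_unpreferred``.
    """
    fit = linear_fit_ci(
        pairs["dprime_preferred"].to_numpy(),
        pairs["dprime_unpreferred"].to_numpy(),
        confidence,
    )
    return SelectivityFit(units=pairs.reset_index(drop=True), condition=condition, fit=fit)


def _disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[1] < b[0] or b[1] < a[0]


@dataclass
class GatingContrast:
    verdict: str  # rotation | shift | both | neither
    slope_cis: tuple[tuple[float, float], tuple[float, float]]
    intercept_cis: tuple[tuple[float, float], tuple[float, float]]
    displacements: pd.DataFrame  # per-unit paired d' displacement vectors


def gating_model_contrast(
    fit_off: SelectivityFit, fit_on: SelectivityFit
) -> GatingContrast:
    """Classify how the light changes population selectivity.

    "rotation": the slope 95% CIs of the two conditions are disjoint
    (selectivity coupling changed); "shift": the CIs of the fitted line's
    height are disjoint while the slope CIs overlap (uniform
    displacement); "both" when slope and height CIs are each disjoint;
    "neither" otherwise.  The displacement contrast is evaluated at the
    pooled preferred-d' centroid rather than at the x = 0 intercept, so a
    rotation about the population center does not masquerade as a shift.
    Units present in both conditions are paired by unit_id and their
    per-unit d' displacement vectors returned for plotting.
    """
    ids_off = set(fit_off.units["unit_id"])
    ids_on = set(fit_on.units["unit_id"])
    if not ids_off & ids_on:
        raise ValueError("the two fits share no units; population mismatch")
    slope_dis = _disjoint(fit_off.fit.slope_ci, fit_on.fit.slope_ci)
    pivot = 0.5 * (fit_off.fit.x_mean + fit_on.fit.x_mean)
    inter_dis = _disjoint(
        fit_off.fit.height_ci(pivot), fit_on.fit.height_ci(pivot)
    )
    if slope_dis and inter_dis:
        verdict = "both"
    elif slope_dis:
        verdict = "rotation"
    elif inter_dis:
        verdict = "shift"
    else:
        verdict = "neither"
    merged = fit_off.units.merge(
        fit_on.units, on="unit_id", suffixes=("_off", "_on")
    )
    merged["d_preferred"] = (
        merged["dprime_preferred_on"] - merged["dprime_preferred_off"]
    )
    merged["d_unpreferred"] = (
        merged["dprime_unpreferred_on"] - merged["dprime_unpreferred_off"]
    )
    return GatingContrast(
        verdict=verdict,
        slope_cis=(fit_off.fit.slope_ci, fit_on.fit.slope_ci),
        intercept_cis=(fit_off.fit.intercept_ci, fit_on.fit.intercept_ci),
        displacements=merged[
            ["unit_id", "d_preferred", "d_unpreferred"]
        ].reset_index(drop=True),
    )


def permutation_slope_test(
    fit_off: SelectivityFit,
    fit_on: SelectivityFit,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Optional stricter rotation test: permutation p-value for the
    slope difference between conditions (condition labels shuffled across
    the pooled units)."""
    x = np.concatenate(
        [
            fit_off.units["dprime_preferred"].to_numpy(),
            fit_on.units["dprime_preferred"].to_numpy(),
        ]
    )
    y = np.concatenate(
        [
            fit_off.units["dprime_unpreferred"].to_numpy(),
            fit_on.units["dprime_unpreferred"].to_numpy(),
        ]
    )
    n_off = len(fit_off.units)
    observed = abs(fit_on.fit.slope - fit_off.fit.slope)
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(x.size)
    for _ in range(n_perm):
        rng.shuffle(idx)
        a, b = idx[:n_off], idx[n_off:]
        s_a = stats.linregress(x[a], y[a]).slope
        s_b = stats.linregress(x[b], y[b]).slope
        if abs(s_b - s_a) >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)
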