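"""The "downstream reader" simulation: pseudo-ensemble construction with
trial-count equalization, diagonal-covariance linear-discriminant
training and testing, and iterated error decomposition.

Units recorded in different sessions are pooled into a pseudo-ensemble:
each unit's trial lists are equalized to 70 light-off and 30 light-on
trials per stimulus by whole-set duplication plus sampling without
replacement, and each unit's trial order is shuffled independently —
deliberately destroying within-session noise correlations.  A two-class
linear discriminant with a shared diagonal covariance (pooled
per-feature variance, equal priors) is trained on 40 + 40 light-off
trials and tested on the 30 + 30 light-off hold-outs and the 30 + 30
light-on trials, and the whole process is iterated with fresh
reconstructions and splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = [
    ("target", "off"),
    ("distractor", "off"),
    ("target", "on"),
    ("distractor", "on"),
]
DEFAULT_TRIAL_TARGETS = {"off": 70, "on": 30}


def select_top_units(
    unit_dprimes: pd.DataFrame, fraction: float = 0.5
) -> pd.DataFrame:
    """The units with the largest target-stimulus neuronal d'.

    Keeps ``floor(fraction * n)`` units (the smaller half for odd counts),
    breaking d' ties by unit_id for determinism.  Requires columns
    ``unit_id`` and ``dprime_target``.
    """
    if unit_dprimes.empty:
        raise ValueError("no units to select from")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = max(1, int(np.floor(fraction * len(unit_dprimes))))
    ranked = unit_dprimes.sort_values(
        ["dprime_target", "unit_id"], ascending=[False, True], kind="stable"
    )
    return ranked.head(n_keep).reset_index(drop=True)


def trial_features(
    binned,
    post_window: tuple[float, float] = (0.0, 0.05),
    baseline_window: tuple[float, float] = (-0.1, 0.0),
) -> np.ndarray:
    """Per-trial evoked-rate feature: baseline-subtracted spike rate (Hz).

    Feature = rate in the first 50 ms post-stimulus minus rate in the
    pre-stimulus baseline window, isolating the initial sensory response.
    """
    post = binned.window_slice(*post_window)
    base = binned.window_slice(*baseline_window)
    r_post = post.sum(axis=1) / (post.shape[1] * binned.bin_s)
    r_base = base.sum(axis=1) / (base.shape[1] * binned.bin_s)
    return r_post - r_base


def _equalize(values: np.ndarray, n_target: int, rng: np.random.Generator) -> np.ndarray:
    """Duplicate whole trial sets while they fit, then fill the remainder by
    sampling without replacement from the originals."""
    n = values.size
    if n == 0:
        raise ValueError("unit has no trials of a required kind")
    reps = n_target // n
    rem = n_target % n
    parts = [values] * reps
    if rem:
        parts.append(rng.choice(values, size=rem, replace=False))
    return np.concatenate(parts) if parts else np.empty(0, dtype=values.dtype)


@dataclass
class PseudoEnsemble:
    """Unit x trial feature matrices per (stimulus, light) condition.

    ``features[(stim, light)]`` has shape (n_units, n_trials) with each
    unit's trial order independently shuffled.
    """

    features: dict[tuple[str, str], np.ndarray]
    unit_ids: list[str]

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


def reconstruct_trials(
    unit_trials: dict[str, dict[tuple[str, str], np.ndarray]],
    rng: np.random.Generator,
    trial_targets: dict[str, int] | None = None,
) -> PseudoEnsemble:
    """Equalize trial counts across units and shuffle per-unit trial order.

    ``unit_trials`` maps unit_id -> {(stim, light): original feature
    values}.  Units missing any required condition are dropped with a
    warning.  Every reconstructed trial is one of the unit's original
    trials; originals appear floor(target/n) or ceil(target/n) times.
    """
    targets = DEFAULT_TRIAL_TARGETS if trial_targets is None else trial_targets
    kept: list[str] = []
    for uid in sorted(unit_trials):
        conds = unit_trials[uid]
        if all(
            (stim, light) in conds and conds[(stim, light)].size > 0
            for (stim, light) in CONDITIONS
        ):
            kept.append(uid)
        else:
            warnings.warn(f"unit {uid} lacks trials of a required kind; excluded",
                          stacklevel=2)
    if not kept:
        raise ValueError("no unit has trials of every required kind")
    features = {}
    for stim, light in CONDITIONS:
        n_target = targets[light]
        mat = np.empty((len(kept), n_target))
        for i, uid in enumerate(kept):
            vals = _equalize(
                np.asarray(unit_trials[uid][(stim, light)], dtype=float),
                n_target,
                rng,
            )
            rng.shuffle(vals)
            mat[i] = vals
        features[(stim, light)] = mat
    return PseudoEnsemble(features=features, unit_ids=kept)


@dataclass
class DiagonalLDA:
    """Two-class linear discriminant with shared diagonal covariance."""

    mean_target: np.ndarray
    mean_distractor: np.ndarray
    pooled_var: np.ndarray

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        """Log-likelihood-ratio scores (target minus distractor), equal priors.

        ``x`` has shape (n_units, n_trials); positive score -> target.
        """
        w = (self.mean_target - self.mean_distractor) / self.pooled_var
        mid = (self.mean_target + self.mean_distractor) / 2.0
        return w @ (x - mid[:, None])

    def predict_target(self, x: np.ndarray) -> np.ndarray:
        return self.decision_scores(x) > 0


def fit_diagonal_lda(
    train_target: np.ndarray,
    train_distractor: np.ndarray,
    var_floor: float = 1e-6,
) -> DiagonalLDA:
    """Fit class means and the pooled per-feature variance on training trials.

    Features with zero pooled variance are floored at ``var_floor`` with a
    warning (a degenerate feature would otherwise dominate the rule).
    """
    mu_t = train_target.mean(axis=1)
    mu_d = train_distractor.mean(axis=1)
    n_t, n_d = train_target.shape[1], train_distractor.shape[1]
    ss = ((train_target - mu_t[:, None]) ** 2).sum(axis=1) + (
        (train_distractor - mu_d[:, None]) ** 2
    ).sum(axis=1)
    var = ss / (n_t + n_d - 2)
    if np.any(var < var_floor):
        warnings.warn("zero pooled variance in some features; flooring", stacklevel=2)
        var = np.maximum(var, var_floor)
    return DiagonalLDA(mean_target=mu_t, mean_distractor=mu_d, pooled_var=var)


@dataclass
class DecoderResult:
    """Error rates for one train/test iteration (or a summary over many).

    ``fa_type`` is the misclassification of light-on distractor trials as
    target ("false alarms" of the reader); ``miss_type`` the converse.
    """

    error_off: float
    error_on: float
    fa_type: float
    miss_type: float


def train_test_reader(
    ensemble: PseudoEnsemble,
    rng: np.random.Generator,
    n_train: int = 40,
    var_floor: float = 1e-6,
) -> DecoderResult:
    """One reader iteration: train on light-off, test held-out off and on.

    ``n_train`` light-off trials per stimulus train the discriminant; the
    remaining light-off trials and all light-on trials are tested.
    """
    t_off = ensemble.features[("target", "off")]
    d_off = ensemble.features[("distractor", "off")]
    t_on = ensemble.features[("target", "on")]
    d_on = ensemble.features[("distractor", "on")]
    n_off = t_off.shape[1]
    if n_train >= n_off:
        raise ValueError("n_train must leave light-off hold-out trials")
    idx_t = rng.permutation(n_off)
    idx_d = rng.permutation(n_off)
    model = fit_diagonal_lda(
        t_off[:, idx_t[:n_train]], d_off[:, idx_d[:n_train]], var_floor
    )
    t_hold = t_off[:, idx_t[n_train:]]
    d_hold = d_off[:, idx_d[n_train:]]

    miss_off = float(np.mean(~model.predict_target(t_hold)))
    fa_off = float(np.mean(model.predict_target(d_hold)))
    miss_on = float(np.mean(~model.predict_target(t_on)))
    fa_on = float(np.mean(model.predict_target(d_on)))

    n_th, n_dh = t_hold.shape[1], d_hold.shape[1]
    err_off = (miss_off * n_th + fa_off * n_dh) / (n_th + n_dh)
    n_ton, n_don = t_on.shape[1], d_on.shape[1]
    err_on = (miss_on * n_ton + fa_on * n_don) / (n_ton + n_don)
    return DecoderResult(
        error_off=err_off, error_on=err_on, fa_type=fa_on, miss_type=miss_on
    )


@dataclass
class DecoderSummary:
    iterations: pd.DataFrame
    mean: DecoderResult
    sd: DecoderResult


def iterate_reader(
    unit_trials: dict[str, dict[tuple[str, str], np.ndarray]],
    n_iter: int = 1000,
    seed: int = 0,
    n_train: int = 40,
    trial_targets: dict[str, int] | None = None,
) -> DecoderSummary:
    """Iterate reconstruct -> shuffle -> train -> test, summarizing errors.

    A master seed spawns one independent child seed per iteration, so
    ``n_iter=1`` reproduces a single :func:`train_test_reader` call on the
    same seed chain.  Reports mean and standard deviation of each error
    rate over iterations.
    """
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_iter)
    rows = []
    for s in child_seeds:
        rng = np.random.default_rng(int(s))
        ens = reconstruct_trials(unit_trials, rng, trial_targets)
        res = train_test_reader(ens, rng, n_train)
        rows.append(vars(res))
    iters = pd.DataFrame(rows)
    mean = DecoderResult(**iters.mean().to_dict())
    sd = DecoderResult(**iters.std(ddof=0).to_dict())
    return DecoderSummary(iterations=iters, mean=mean, sd=sd)
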