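"""Whisker motion energy from ROI frame stacks or precomputed traces:
frame differencing, post-stimulus normalization, pre-stimulus-referenced
z-scoring, and high-motion trial exclusion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MotionTrace:
    """Per-frame motion energy for one ROI.

    ``frame_times_s`` are strictly increasing; motion energy is
    non-negative until normalization/z-scoring, after which it may go
    negative.  No constant frame rate is assumed — heterogeneous cameras
    are handled by carrying explicit frame times.
    """

    frame_times_s: np.ndarray
    energy: np.ndarray
    roi_id: str = "whisker"

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times_s, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.frame_times_s = t
        self.energy = np.asarray(self.energy, dtype=float)
        if self.energy.shape != t.shape:
            raise ValueError("energy and frame times must align")


def motion_energy(
    frames: np.ndarray, frame_times_s: np.ndarray, roi_id: str = "whisker"
) -> MotionTrace:
    """Motion energy of an ROI frame stack: summed squared frame difference.

    ``energy[f] = sum_pixels (I_f - I_{f-1})**2``; the first frame has no
    predecessor and is dropped, so the trace aligns to
    ``frame_times_s[1:]``.  Invariant to a constant intensity offset
    applied to all frames.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim < 2 or stack.shape[0] < 2:
        raise ValueError("need at least 2 frames of constant ROI geometry")
    diffs = np.diff(stack, axis=0)
    energy = (diffs**2).reshape(diffs.shape[0], -1).sum(axis=1)
    t = np.asarray(frame_times_s, dtype=float)
    if t.shape[0] != stack.shape[0]:
        raise ValueError("one frame time per frame required")
    return MotionTrace(frame_times_s=t[1:], energy=energy, roi_id=roi_id)


def align_trials(
    trace: MotionTrace,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-0.5, 1.2),
) -> pd.DataFrame:
    """Long-format per-trial segments of the trace.

    Columns: trial_index, rel_time_s (frame time minus stimulus onset),
    energy.
    """
    rows = []
    for row in trials.itertuples():
        rel = trace.frame_times_s - row.onset_time_s
        sel = (rel >= window[0]) & (rel <= window[1])
        rows.append(
            pd.DataFrame(
                {
                    "trial_index": row.trial_index,
                    "rel_time_s": rel[sel],
                    "energy": trace.energy[sel],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def normalize_post_stimulus(segments: pd.DataFrame) -> pd.DataFrame:
    """Subtract the immediately pre-stimulus frame value per trial.

    Post-stimulus frames (rel_time_s >= 0) get the energy of that trial's
    last pre-stimulus frame subtracted; trials with no pre-stimulus frame
    are flagged (``flag_no_prestim``) and left unnormalized.
    """
    out = segments.copy()
    out["energy_norm"] = np.nan
    out["flag_no_prestim"] = False
    for _, idx in out.groupby("trial_index").groups.items():
        seg = out.loc[idx]
        pre = seg[seg["rel_time_s"] < 0]
        post_mask = seg["rel_time_s"] >= 0
        if pre.empty:
            out.loc[idx, "flag_no_prestim"] = True
            continue
        ref = pre.sort_values("rel_time_s")["energy"].iloc[-1]
        out.loc[seg.index[post_mask], "energy_norm"] = (
            seg.loc[post_mask, "energy"] - ref
        )
    return out


def zscore_prestim(
    segments: pd.DataFrame, column: str = "energy"
) -> pd.DataFrame:
    """Z-score all frames using mean and SD of pre-stimulus frames only.

    Determining the session statistics from pre-stimulus data keeps
    post-stimulus motion inflation visible after standardization (it is
    measured against the pre-stimulus reference, not absorbed into sigma).
    """
    pre = segments.loc[segments["rel_time_s"] < 0, column]
    if len(pre) < 2:
        raise ValueError("need at least 2 pre-stimulus frames")
    mu, sd = pre.mean(), pre.std(ddof=0)
    if sd == 0:
        raise ValueError("pre-stimulus SD is zero; cannot z-score")
    out = segments.copy()
    out[column + "_z"] = (out[column] - mu) / sd
    return out


def exclude_high_motion_trials(
    segments: pd.DataFrame,
    pre_window_s: float = 0.5,
    fraction: float = 0.5,
) -> np.ndarray:
    """Retained trial indices after dropping the highest-motion trials.

    Trials are ranked by summed motion energy within ``pre_window_s``
    before stimulus onset and the top ``fraction`` dropped (ongoing
    whisking attenuates evoked responses).  Ties and the odd-count
    boundary resolve by trial_index, retaining ceil(n * (1 - fraction))
    trials.
    """
    pre = segments[
        (segments["rel_time_s"] < 0) & (segments["rel_time_s"] >= -pre_window_s)
    ]
    sums = pre.groupby("trial_index")["energy"].sum().reset_index()
    sums = sums.sort_values(["energy", "trial_index"], kind="stable")
    n_keep = int(np.ceil(len(sums) * (1.0 - fraction)))
    return np.sort(sums["trial_index"].to_numpy()[:n_keep])
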