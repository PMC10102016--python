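"""Spike-train preparation: trial-aligned binning, mask-noise filtering,
opto-tag cell-type classification, and alignment quality control."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

BIN_S = 0.005  # canonical analysis resolution


@dataclass
class BinnedCounts:
    """Trial-aligned spike counts in non-overlapping bins.

    ``counts`` has shape (n_trials, n_bins); bin b of trial t covers
    ``[onset + window[0] + b*bin_s, onset + window[0] + (b+1)*bin_s)``
    (half-open).  ``trial_index`` keeps the join key to the trial table.
    Counts are integers as binned; filtering makes them real-valued.
    """

    counts: np.ndarray
    window: tuple[float, float]
    bin_s: float
    trial_index: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_starts(self) -> np.ndarray:
        """Bin left edges in seconds relative to stimulus onset."""
        return self.window[0] + np.arange(self.n_bins) * self.bin_s

    def select(self, mask: np.ndarray) -> "BinnedCounts":
        return BinnedCounts(
            self.counts[mask], self.window, self.bin_s, self.trial_index[mask]
        )

    def window_slice(self, lo_s: float, hi_s: float) -> np.ndarray:
        """Counts restricted to bins whose spans lie within [lo_s, hi_s)."""
        starts = self.bin_starts
        keep = (starts >= lo_s - 1e-9) & (starts + self.bin_s <= hi_s + 1e-9)
        return self.counts[:, keep]


def bin_spikes(
    spike_times_s: np.ndarray,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-0.2, 0.2),
    bin_s: float = BIN_S,
) -> BinnedCounts:
    """Bin one unit's spike times into trial-aligned 5 ms (default) bins.

    Bins are half-open ``[edge, edge + bin_s)``, so a spike exactly on an
    edge falls in the later bin; the total count inside the window is
    conserved.  If ``bin_s`` does not divide the window evenly the window
    is truncated to whole bins with a warning.
    """
    pre, post = window
    if post <= pre:
        raise ValueError("window must satisfy post > pre")
    n_bins_f = (post - pre) / bin_s
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9:
        n_bins = int(np.floor(n_bins_f))
        warnings.warn(
            f"bin_s={bin_s} does not divide window {window}; truncating to "
            f"{n_bins} bins",
            stacklevel=2,
        )
    st = np.asarray(spike_times_s, dtype=float)
    onsets = trials["onset_time_s"].to_numpy()
    counts = np.zeros((len(onsets), n_bins), dtype=np.int64)
    edges = pre + np.arange(n_bins + 1) * bin_s
    for i, onset in enumerate(onsets):
        rel = st[(st >= onset + edges[0]) & (st < onset + edges[-1])] - onset
        # half-open [edge, edge+bin): searchsorted 'right' puts edge spikes later
        idx = np.searchsorted(edges, rel, side="right") - 1
        np.add.at(counts[i], idx, 1)
    return BinnedCounts(
        counts=counts,
        window=(pre, pre + n_bins * bin_s),
        bin_s=bin_s,
        trial_index=trials["trial_index"].to_numpy(),
    )


def _bandstop_sos(low: float, high: float, fs: float, order: int = 2) -> np.ndarray:
    return signal.butter(order, [low, high], btype="bandstop", fs=fs, output="sos")


def notch_filter_counts(
    series: np.ndarray, bin_s: float = BIN_S, order: int = 2
) -> np.ndarray:
    """Remove 10 and 20 Hz mask-light contamination from a count series.

    Two second-order Butterworth band-stop filters (9-11 Hz and 19-21 Hz)
    applied forward-and-backward (zero-phase).  DC gain is unity, so slow
    rate structure is preserved; works on 1-D series or (n_trials, n_bins)
    arrays filtered along the last axis.
    """
    x = np.asarray(series, dtype=float)
    fs = 1.0 / bin_s
    sos10 = _bandstop_sos(9.0, 11.0, fs, order)
    sos20 = _bandstop_sos(19.0, 21.0, fs, order)
    padlen = 3 * (2 * max(sos10.shape[0], sos20.shape[0]) + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"series length {x.shape[-1]} is shorter than the filter warm-up "
            f"({padlen + 1} samples); pad or use a longer window"
        )
    y = signal.sosfiltfilt(sos10, x, axis=-1)
    return signal.sosfiltfilt(sos20, y, axis=-1)


def classify_cell_type(
    rates_on_hz: np.ndarray,
    rates_off_hz: np.ndarray,
    alpha: float = 0.1,
) -> tuple[str, float]:
    """Opto-tagging call from per-trial mean rates in the light window.

    In VGAT-ChR2 tissue the light directly drives GABAergic interneurons,
    so units significantly enhanced on light-on trials are putative
    inhibitory and units significantly suppressed are putative excitatory
    (Welch two-sample t-test, p < ``alpha``); otherwise unclassified.
    Rates should already exclude the first and last 100 ms of the light
    waveform (see :func:`light_window_rates`).

    Returns ``(cell_type, p_value)``.
    """
    on = np.asarray(rates_on_hz, dtype=float)
    off = np.asarray(rates_off_hz, dtype=float)
    if on.size < 2 or off.size < 2:
        warnings.warn("fewer than 2 trials per light condition; unclassified",
                      stacklevel=2)
        return "unclassified", np.nan
    if np.allclose(on, on[0]) and np.allclose(off, off[0]) and on[0] == off[0]:
        return "unclassified", 1.0
    t, p = stats.ttest_ind(on, off, equal_var=False)
    if np.isnan(p) or p >= alpha:
        return "unclassified", float(p)
    return ("inhibitory" if on.mean() > off.mean() else "excitatory"), float(p)


def light_window_rates(
    binned: BinnedCounts,
    light_window: tuple[float, float],
    trim_s: float = 0.1,
) -> np.ndarray:
    """Per-trial mean firing rate (Hz) inside the light waveform, with the
    first and last ``trim_s`` of the waveform excluded."""
    lo, hi = light_window[0] + trim_s, light_window[1] - trim_s
    if hi <= lo:
        raise ValueError("light window shorter than twice the trim")
    counts = binned.window_slice(lo, hi)
    return counts.sum(axis=1) / (counts.shape[1] * binned.bin_s)


@dataclass
class AlignmentQC:
    passed: bool
    peak_ratio: float
    flags: tuple[str, ...] = ()


def alignment_qc(
    psth_hz: np.ndarray,
    bin_starts_s: np.ndarray,
    bin_s: float = BIN_S,
    threshold: float = 1.4,
    baseline_window_s: float = 0.1,
    peak_window_s: float = 0.05,
) -> AlignmentQC:
    """Principal-whisker alignment check on the multi-unit PSTH.

    Passes when the peak PSTH value within (0, ``peak_window_s``] after the
    preferred large-amplitude stimulus reaches at least ``threshold`` times
    the mean pre-stimulus baseline.
    """
    psth = np.asarray(psth_hz, dtype=float)
    t = np.asarray(bin_starts_s, dtype=float)
    base_sel = (t >= -baseline_window_s - 1e-9) & (t + bin_s <= 1e-9)
    post_sel = (t >= -1e-9) & (t + bin_s <= peak_window_s + 1e-9)
    if not base_sel.any() or not post_sel.any():
        raise ValueError("PSTH must cover the baseline and post-stimulus windows")
    baseline = psth[base_sel].mean()
    if baseline <= 0:
        return AlignmentQC(False, np.inf, ("baseline undefined",))
    ratio = float(psth[post_sel].max() / baseline)
    return AlignmentQC(ratio >= threshold, ratio)


@dataclass
class UnitRecord:
    """One sorted unit: spike times plus alignment metadata and the derived
    opto-tag cell-type call."""

    unit_id: str
    spike_times_s: np.ndarray
    hemisphere_alignment: str
    depth_um: float = np.nan
    cell_type: str = "unclassified"
    tag_p_value: float = np.nan
    qc: AlignmentQC | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times_s, dtype=float)
        if st.size and (np.any(np.diff(st) < 0) or st[0] < 0):
            raise ValueError("spike times must be sorted and non-negative")
        self.spike_times_s = st
        if self.hemisphere_alignment not in ("target", "distractor"):
            raise ValueError("hemisphere_alignment must be 'target' or 'distractor'")


def build_unit_records(spikes: pd.DataFrame, units: pd.DataFrame) -> list[UnitRecord]:
    """Assemble UnitRecords from the spikes and units tables."""
    grouped = dict(iter(spikes.groupby("unit_id")["spike_time_s"]))
    records = []
    for row in units.itertuples():
        st = grouped.get(row.unit_id, pd.Series(dtype=float)).to_numpy()
        records.append(
            UnitRecord(
                unit_id=row.unit_id,
                spike_times_s=np.sort(st),
                hemisphere_alignment=row.hemisphere_alignment,
                depth_um=getattr(row, "depth_um", np.nan),
            )
        )
    return records


def type_units(
    records: list[UnitRecord],
    trials: pd.DataFrame,
    window: tuple[float, float] = (-0.6, 0.8),
    alpha: float = 0.1,
    bin_s: float = BIN_S,
) -> pd.DataFrame:
    """Classify every unit from suppression (light-on vs light-off) trials.

    The light window is taken from the median per-trial triangular waveform
    bounds recorded in the trial table.  Mutates ``cell_type`` and
    ``tag_p_value`` on the records and returns a summary frame.
    """
    on_trials = trials[trials["opto"] == "on"]
    off_trials = trials[trials["opto"] == "off"]
    if on_trials.empty or off_trials.empty:
        raise ValueError("typing requires both light-on and light-off trials")
    light_lo = float(on_trials["opto_onset_s"].median())
    light_hi = float(on_trials["opto_offset_s"].median())
    rows = []
    for rec in records:
        b_on = bin_spikes(rec.spike_times_s, on_trials, window, bin_s)
        b_off = bin_spikes(rec.spike_times_s, off_trials, window, bin_s)
        r_on = light_window_rates(b_on, (light_lo, light_hi))
        r_off = light_window_rates(b_off, (light_lo, light_hi))
        rec.cell_type, rec.tag_p_value = classify_cell_type(r_on, r_off, alpha)
        rows.append(
            {
                "unit_id": rec.unit_id,
                "cell_type": rec.cell_type,
                "tag_p_value": rec.tag_p_value,
                "rate_on_hz": float(np.mean(r_on)),
                "rate_off_hz": float(np.mean(r_off)),
            }
        )
    return pd.DataFrame(rows)
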