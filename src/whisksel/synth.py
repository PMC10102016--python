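"""Synthetic session generator with known ground truth.

Emulates a head-fixed bilateral Go/No-Go whisker selective-detection
session: pseudo-random target / distractor / catch trials (20% catch),
a 200 ms post-stimulus lockout followed by a 1 s response window,
6-10.5 s inter-trial intervals, layer-5 units spiking as inhomogeneous
Poisson processes with stimulus-evoked transients (preferred-stimulus
latency ~40-45 ms, cross-hemispheric ~60-80 ms), triangular-waveform
optogenetic gain modulation that suppresses putative excitatory and
enhances putative inhibitory units, configurable across-unit coupling
between target and distractor evoked amplitudes (the selectivity
"slope"), and optional 10/20 Hz mask-light contamination of the firing
rates.

Every artifact (trial table, lick log, spike times, whisker motion
trace) is drawn from a single seeded generator, so identical
(config, seed) pairs reproduce byte-identical outputs, and the drawn
unit parameters are returned as a ground-truth table for
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats


class ConfigurationError(ValueError):
    """Raised when a synthesis configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseModel:
    """Per-trial-type lick probabilities within the response window.

    Separate probabilities for light-off and light-on (optogenetic
    suppression) trials; suppression of frontal cortex disinhibits
    responding, so the light-on defaults are uniformly higher.
    """

    hit_large_off: float = 0.94
    hit_small_off: float = 0.65
    fa_large_off: float = 0.37
    fa_small_off: float = 0.25
    spont_off: float = 0.29
    hit_large_on: float = 0.96
    hit_small_on: float = 0.70
    fa_large_on: float = 0.59
    fa_small_on: float = 0.40
    spont_on: float = 0.43
    p_abort: float = 0.03

    def response_probability(self, stim_type: str, amplitude: str, opto: str) -> float:
        on = opto == "on"
        if stim_type == "catch":
            return self.spont_on if on else self.spont_off
        small = amplitude == "small"
        if stim_type == "target":
            if on:
                return self.hit_small_on if small else self.hit_large_on
            return self.hit_small_off if small else self.hit_large_off
        if stim_type == "distractor":
            if on:
                return self.fa_small_on if small else self.fa_large_on
            return self.fa_small_off if small else self.fa_large_off
        raise ValueError(f"unknown stim_type {stim_type!r}")

    def validate(self) -> None:
        for name, value in vars(self).items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"ResponseModel.{name}={value} outside [0, 1]")


@dataclass(frozen=True)
class OptoConfig:
    """Triangular optogenetic waveform and per-cell-type gains.

    The light ramps from zero starting ``lead_s`` before the whisker
    stimulus, peaks ``peak_s`` after it, and decays back to zero over
    ``decay_s``.  A unit's firing rate is multiplied by
    ``1 + (gain - 1) * waveform(t)``; excitatory gains < 1 (suppressed
    by GABAergic activation), inhibitory gains > 1 (directly driven).
    """

    light_fraction: float = 1.0 / 3.0
    tag_fraction: float = 0.08
    lead_s: tuple[float, float] = (0.2, 0.5)
    peak_s: tuple[float, float] = (0.1, 0.2)
    decay_s: tuple[float, float] = (0.4, 0.6)
    excitatory_gain: float = 0.3
    inhibitory_gain: float = 2.5

    def validate(self) -> None:
        if not 0.0 <= self.light_fraction <= 1.0:
            raise ConfigurationError("light_fraction outside [0, 1]")
        if not 0.0 <= self.tag_fraction <= 1.0 - self.light_fraction:
            raise ConfigurationError("tag_fraction incompatible with light_fraction")
        if self.excitatory_gain < 0 or self.inhibitory_gain < 0:
            raise ConfigurationError("opto gains must be non-negative")


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of a synthetic session.

    Trial mixture defaults follow the task design (20% catch, the rest
    split evenly between target and distractor); unit parameters are in
    Hz and seconds.
    """

    n_trials: int = 300
    p_catch: float = 0.20
    p_target: float = 0.40
    p_distractor: float = 0.40
    p_large: float = 0.5
    lockout_s: float = 0.2
    response_window_s: float = 1.0
    iti_range_s: tuple[float, float] = (6.0, 10.5)
    response_model: ResponseModel = field(default_factory=ResponseModel)

    n_units: int = 12
    excitatory_fraction: float = 0.85
    alignment: str = "target"  # recording side: preferred stimulus identity
    # log-normal baseline rate distribution (log-mean of Hz, log-sd)
    baseline_log_mean: float = math.log(8.0)
    baseline_log_sd: float = 0.5
    # preferred-stimulus evoked amplitude distribution (Hz at kernel peak)
    amp_pref_log_mean: float = math.log(25.0)
    amp_pref_log_sd: float = 0.4
    # cross-hemispheric (unpreferred) evoked amplitudes: mean level plus a
    # linear coupling of configurable slope to the preferred amplitude
    amp_unpref_mean: float = 5.0
    selectivity_slope: float = 0.15
    selectivity_slope_on: float | None = None  # light-on coupling; None = same
    # fraction of each unit's preferred amplitude added to its unpreferred
    # amplitude on light-on trials (cross-hemispheric un-gating)
    opto_distractor_boost: float = 0.0
    small_amp_scale: float = 0.4
    latency_pref_s: tuple[float, float] = (0.040, 0.045)
    latency_unpref_s: tuple[float, float] = (0.060, 0.080)

    opto: OptoConfig = field(default_factory=OptoConfig)
    mask_depth_10: float = 0.0
    mask_depth_20: float = 0.0
    mask_lead_s: float = 0.6

    whisker_frame_hz: float = 35.6
    bin_s: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        probs = (self.p_catch, self.p_target, self.p_distractor, self.p_large)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("trial-type probabilities must lie in [0, 1]")
        if abs(self.p_catch + self.p_target + self.p_distractor - 1.0) > 1e-9:
            raise ConfigurationError(
                "p_catch + p_target + p_distractor must sum to 1"
            )
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be positive")
        if self.n_units < 1:
            raise ConfigurationError("n_units must be positive")
        if self.alignment not in ("target", "distractor"):
            raise ConfigurationError("alignment must be 'target' or 'distractor'")
        if self.mask_depth_10 < 0 or self.mask_depth_20 < 0:
            raise ConfigurationError("mask contamination depths must be >= 0")
        if self.bin_s <= 0:
            raise ConfigurationError("bin_s must be positive")
        self.response_model.validate()
        self.opto.validate()


@dataclass
class Session:
    """One generated session: the standard tables plus ground truth."""

    trials: pd.DataFrame
    licks: pd.DataFrame
    units: pd.DataFrame
    spikes: pd.DataFrame
    whisker: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SynthConfig


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def alpha_kernel(t_s: np.ndarray, peak_hz: float, latency_s: float) -> np.ndarray:
    """Evoked-rate kernel ``peak * (t/tau) * exp(1 - t/tau)``, zero for t <= 0.

    The kernel peaks at ``t = latency_s`` with value ``peak_hz``, rising
    smoothly from stimulus onset and decaying with the same time constant.
    """
    t = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / latency_s
    out[pos] = peak_hz * x * np.exp(1.0 - x)
    return out


def triangular_waveform(
    t_s: np.ndarray, onset_s: float, peak_time_s: float, offset_s: float
) -> np.ndarray:
    """Normalized triangular light waveform: 0 at onset, 1 at peak, 0 at offset."""
    if not onset_s < peak_time_s < offset_s:
        raise ValueError("waveform requires onset < peak < offset")
    t = np.asarray(t_s, dtype=float)
    up = np.clip((t - onset_s) / (peak_time_s - onset_s), 0.0, 1.0)
    down = np.clip((offset_s - t) / (offset_s - peak_time_s), 0.0, 1.0)
    return np.minimum(up, down)


def generate_spike_counts(
    rate_hz: np.ndarray, bin_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson spike counts per bin from a non-negative rate series (Hz)."""
    rate = np.asarray(rate_hz, dtype=float)
    if np.any(rate < 0):
        raise ValueError("firing rates must be non-negative")
    return rng.poisson(rate * bin_s)


def apply_opto_gain(
    rate_hz: np.ndarray, waveform: np.ndarray, gain: float
) -> np.ndarray:
    """Multiply a rate series by ``1 + (gain - 1) * waveform``; gain 1 is identity."""
    if gain < 0:
        raise ValueError("opto gain must be non-negative")
    w = np.asarray(waveform, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("waveform values must lie in [0, 1]")
    return np.asarray(rate_hz, dtype=float) * (1.0 + (gain - 1.0) * w)


def inject_mask_contamination(
    rate_hz: np.ndarray,
    bin_s: float,
    depth_10: float,
    depth_20: float,
    onset_times_s: np.ndarray,
    t0_s: float = 0.0,
) -> np.ndarray:
    """Superimpose 10 and 20 Hz sinusoidal rate modulation, phase-locked to
    each mask-light onset, on a rate series (applied before Poisson emission).

    From each onset until the next, the rate is multiplied by
    ``1 + depth_10*sin(2*pi*10*(t-onset)) + depth_20*sin(2*pi*20*(t-onset))``
    so the modulation phase re-locks at every onset.  Depth 0 is the identity.
    """
    if depth_10 < 0 or depth_20 < 0:
        raise ValueError("contamination depths must be >= 0")
    rate = np.asarray(rate_hz, dtype=float).copy()
    if depth_10 == 0 and depth_20 == 0:
        return rate
    onsets = np.sort(np.asarray(onset_times_s, dtype=float))
    if onsets.size == 0:
        return rate
    t = t0_s + (np.arange(rate.size) + 0.5) * bin_s
    # index of the most recent onset for each bin (-1 = before the first)
    idx = np.searchsorted(onsets, t, side="right") - 1
    valid = idx >= 0
    phase_t = t[valid] - onsets[idx[valid]]
    mod = (
        1.0
        + depth_10 * np.sin(2.0 * np.pi * 10.0 * phase_t)
        + depth_20 * np.sin(2.0 * np.pi * 20.0 * phase_t)
    )
    rate[valid] = np.maximum(rate[valid] * mod, 0.0)
    return rate


# ---------------------------------------------------------------------------
# unit parameter draws
# ---------------------------------------------------------------------------

def draw_unit_parameters(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-unit ground-truth parameters.

    The unpreferred (cross-hemispheric) evoked amplitude is coupled to the
    preferred amplitude with regression slope ``selectivity_slope``; the
    residual scatter is scaled so that the across-unit Pearson correlation
    equals the slope as well (residual sd = sd_pref * sqrt(1 - slope^2)).
    A distinct light-on coupling (``selectivity_slope_on``) reuses the same
    per-unit residual, so light-on/light-off pairs are linked within units.
    """
    n = config.n_units
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    amp_pref = rng.lognormal(config.amp_pref_log_mean, config.amp_pref_log_sd, n)
    resid = rng.normal(0.0, 1.0, n)

    mean_pref = math.exp(config.amp_pref_log_mean + config.amp_pref_log_sd**2 / 2.0)
    sd_pref = mean_pref * math.sqrt(math.expm1(config.amp_pref_log_sd**2))

    def couple(slope: float) -> np.ndarray:
        slope = float(np.clip(slope, -1.0, 1.0))
        sd_resid = sd_pref * math.sqrt(max(0.0, 1.0 - slope**2))
        return (
            config.amp_unpref_mean
            + slope * (amp_pref - mean_pref)
            + sd_resid * resid
        )

    slope_on = (
        config.selectivity_slope
        if config.selectivity_slope_on is None
        else config.selectivity_slope_on
    )
    amp_unpref_off = couple(config.selectivity_slope)
    amp_unpref_on = couple(slope_on) + config.opto_distractor_boost * amp_pref

    n_exc = int(round(config.excitatory_fraction * n))
    cell_type = np.array(["excitatory"] * n_exc + ["inhibitory"] * (n - n_exc))
    rng.shuffle(cell_type)
    gain = np.where(
        cell_type == "excitatory",
        config.opto.excitatory_gain,
        config.opto.inhibitory_gain,
    )
    lat_pref = rng.uniform(*config.latency_pref_s, n)
    lat_unpref = rng.uniform(*config.latency_unpref_s, n)
    return pd.DataFrame(
        {
            "unit_id": [f"u{i:03d}" for i in range(n)],
            "cell_type": cell_type,
            "baseline_hz": baseline,
            "amp_pref_hz": amp_pref,
            "amp_unpref_off_hz": amp_unpref_off,
            "amp_unpref_on_hz": amp_unpref_on,
            "latency_pref_s": lat_pref,
            "latency_unpref_s": lat_unpref,
            "opto_gain": gain,
            "depth_um": rng.uniform(500.0, 1000.0, n),
        }
    )


# ---------------------------------------------------------------------------
# trial structure
# ---------------------------------------------------------------------------

_OUTCOME_BY_STIM = {
    "target": ("hit", "miss"),
    "distractor": ("fa", "cr"),
    "catch": ("spont", "cw"),
}


def generate_trials(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the trial table: types, amplitudes, opto conditions, outcomes, times."""
    n = config.n_trials
    stim = rng.choice(
        ["target", "distractor", "catch"],
        size=n,
        p=[config.p_target, config.p_distractor, config.p_catch],
    )
    amplitude = np.where(
        stim == "catch",
        "none",
        np.where(rng.random(n) < config.p_large, "large", "small"),
    )
    u = rng.random(n)
    opto = np.where(
        u < config.opto.light_fraction,
        "on",
        np.where(u < config.opto.light_fraction + config.opto.tag_fraction, "tag", "off"),
    )

    itis = rng.uniform(*config.iti_range_s, n)
    onset = 5.0 + np.cumsum(itis)

    outcomes = []
    rts = []
    rm = config.response_model
    for i in range(n):
        abort = rng.random() < rm.p_abort
        p_resp = rm.response_probability(stim[i], amplitude[i], opto[i])
        responded = rng.random() < p_resp
        if abort:
            outcomes.append("abort")
            rts.append(rng.uniform(0.0, config.lockout_s))
        elif responded:
            outcomes.append(_OUTCOME_BY_STIM[stim[i]][0])
            rts.append(
                rng.uniform(
                    config.lockout_s, config.lockout_s + config.response_window_s
                )
            )
        else:
            outcomes.append(_OUTCOME_BY_STIM[stim[i]][1])
            rts.append(np.nan)

    # per-trial opto waveform parameters (light-on and tag trials)
    lead = rng.uniform(*config.opto.lead_s, n)
    peak = rng.uniform(*config.opto.peak_s, n)
    decay = rng.uniform(*config.opto.decay_s, n)
    lit = opto != "off"
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "onset_time_s": onset,
            "stim_type": stim,
            "amplitude": amplitude,
            "opto": opto,
            "outcome": outcomes,
            "response_time_s": rts,
            "opto_onset_s": np.where(lit, -lead, np.nan),
            "opto_peak_s": np.where(lit, peak, np.nan),
            "opto_offset_s": np.where(lit, peak + decay, np.nan),
            "mask_onset_s": -config.mask_lead_s,
        }
    )
    return trials


def generate_licks(
    trials: pd.DataFrame, config: SynthConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Lick-time log: the response lick plus a short consumption bout on hits."""
    times: list[float] = []
    for row in trials.itertuples():
        if not np.isfinite(row.response_time_s):
            continue
        t0 = row.onset_time_s + row.response_time_s
        times.append(t0)
        n_bout = 5 if row.outcome == "hit" else rng.integers(0, 3)
        for k in range(int(n_bout)):
            times.append(t0 + (k + 1) * 0.125 + rng.normal(0.0, 0.01))
    return pd.DataFrame({"lick_time_s": np.sort(np.asarray(times, dtype=float))})


# ---------------------------------------------------------------------------
# unit rate profiles and spike emission
# ---------------------------------------------------------------------------

def _trial_amplitudes(
    unit: pd.Series, trials: pd.DataFrame, config: SynthConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial evoked amplitude (Hz) and latency (s) for one unit."""
    n = len(trials)
    amp = np.zeros(n)
    lat = np.full(n, unit["latency_pref_s"])
    preferred_stim = config.alignment  # target-aligned cortex prefers target
    for i, row in enumerate(trials.itertuples()):
        if row.stim_type == "catch":
            continue
        scale = 1.0 if row.amplitude == "large" else config.small_amp_scale
        if row.stim_type == preferred_stim:
            amp[i] = unit["amp_pref_hz"] * scale
            lat[i] = unit["latency_pref_s"]
        else:
            key = "amp_unpref_on_hz" if row.opto == "on" else "amp_unpref_off_hz"
            amp[i] = unit[key] * scale
            lat[i] = unit["latency_unpref_s"]
    return amp, lat


def unit_rate_profile(
    unit: pd.Series,
    trials: pd.DataFrame,
    config: SynthConfig,
    t_bins_s: np.ndarray,
) -> np.ndarray:
    """Session-long firing-rate series (Hz) at bin centers for one unit.

    Baseline plus per-trial evoked kernels, with the triangular opto gain
    applied on light-on/tag trials and mask-light contamination overlaid
    (phase-locked to each trial's mask onset).  Floored at zero.
    """
    rate = np.full(t_bins_s.size, float(unit["baseline_hz"]))
    amp, lat = _trial_amplitudes(unit, trials, config)
    gain = float(unit["opto_gain"])
    for i, row in enumerate(trials.itertuples()):
        onset = row.onset_time_s
        lo = np.searchsorted(t_bins_s, onset - 1.0)
        hi = np.searchsorted(t_bins_s, onset + 1.5)
        tt = t_bins_s[lo:hi] - onset
        seg = rate[lo:hi]
        if amp[i] != 0.0:
            seg = seg + alpha_kernel(tt, amp[i], lat[i])
        if row.opto in ("on", "tag") and gain != 1.0:
            w = triangular_waveform(
                tt, row.opto_onset_s, row.opto_peak_s, row.opto_offset_s
            )
            seg = apply_opto_gain(seg, w, gain)
        rate[lo:hi] = seg
    if config.mask_depth_10 > 0 or config.mask_depth_20 > 0:
        mask_onsets = trials["onset_time_s"].to_numpy() + trials["mask_onset_s"].to_numpy()
        rate = inject_mask_contamination(
            rate,
            config.bin_s,
            config.mask_depth_10,
            config.mask_depth_20,
            mask_onsets,
            t0_s=t_bins_s[0] - config.bin_s / 2.0,
        )
    return np.maximum(rate, 0.0)


def _spike_times_from_counts(
    counts: np.ndarray, bin_edges_left: np.ndarray, bin_s: float, rng: np.random.Generator
) -> np.ndarray:
    lefts = np.repeat(bin_edges_left, counts)
    return np.sort(lefts + rng.uniform(0.0, bin_s, lefts.size))


def generate_whisker_trace(
    trials: pd.DataFrame, config: SynthConfig, rng: np.random.Generator, duration_s: float
) -> pd.DataFrame:
    """Motion-energy trace: positive baseline noise plus a post-stimulus ramp
    on response ("Go"-outcome) trials, sampled at the whisker frame rate."""
    frame_times = np.arange(0.0, duration_s, 1.0 / config.whisker_frame_hz)
    energy = np.abs(rng.normal(0.5, 0.15, frame_times.size))
    go = trials[trials["outcome"].isin(["hit", "fa", "spont"])]
    for row in go.itertuples():
        t = frame_times - row.onset_time_s
        ramp = np.clip((t - 0.05) / 0.25, 0.0, 1.0) * np.clip(
            (1.2 - t) / 0.4, 0.0, 1.0
        )
        energy += 3.0 * np.clip(ramp, 0.0, 1.0)
    return pd.DataFrame(
        {"frame_time_s": frame_times, "motion_energy": energy, "roi_id": "whisker"}
    )


def generate_session(config: SynthConfig) -> Session:
    """Generate one complete synthetic session from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    trials = generate_trials(config, rng)
    licks = generate_licks(trials, config, rng)
    gt = draw_unit_parameters(config, rng)

    duration = float(trials["onset_time_s"].iloc[-1] + 3.0)
    n_bins = int(math.ceil(duration / config.bin_s))
    lefts = np.arange(n_bins) * config.bin_s
    centers = lefts + config.bin_s / 2.0

    unit_ids = []
    spike_times = []
    for _, unit in gt.iterrows():
        rate = unit_rate_profile(unit, trials, config, centers)
        counts = generate_spike_counts(rate, config.bin_s, rng)
        st = _spike_times_from_counts(counts, lefts, config.bin_s, rng)
        spike_times.append(st)
        unit_ids.append(np.full(st.size, unit["unit_id"]))

    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(unit_ids) if unit_ids else [],
            "spike_time_s": np.concatenate(spike_times) if spike_times else [],
        }
    )
    units = pd.DataFrame(
        {
            "unit_id": gt["unit_id"],
            "hemisphere_alignment": config.alignment,
            "depth_um": gt["depth_um"],
        }
    )
    whisker = generate_whisker_trace(trials, config, rng, duration)
    return Session(
        trials=trials,
        licks=licks,
        units=units,
        spikes=spikes,
        whisker=whisker,
        ground_truth=gt,
        config=config,
    )


# ---------------------------------------------------------------------------
# light-weight peri-stimulus population simulator
# ---------------------------------------------------------------------------

def simulate_population_counts(
    config: SynthConfig,
    n_trials_per_stim: int,
    window_s: tuple[float, float] = (-0.1, 0.1),
    opto: str = "off",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Peri-stimulus spike-count arrays for a population, without building a
    full session timeline.

    Returns ``(counts_target, counts_distractor, ground_truth)`` where each
    counts array has shape (n_units, n_trials, n_bins) over ``window_s`` in
    ``config.bin_s`` bins, for large-amplitude stimuli under the requested
    light condition.  Statistically identical to windowing a full generated
    session, but orders of magnitude cheaper for population-level
    parameter-recovery studies.
    """
    config.validate()
    if opto not in ("off", "on"):
        raise ValueError("opto must be 'off' or 'on'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gt = draw_unit_parameters(config, rng)

    edges = np.arange(window_s[0], window_s[1] + config.bin_s / 2, config.bin_s)
    centers = edges[:-1] + config.bin_s / 2.0
    n_bins = centers.size

    # nominal mid-range opto waveform, shared across trials
    o = config.opto
    w = (
        triangular_waveform(
            centers,
            -np.mean(o.lead_s),
            np.mean(o.peak_s),
            np.mean(o.peak_s) + np.mean(o.decay_s),
        )
        if opto == "on"
        else None
    )

    out = {}
    for stim in ("target", "distractor"):
        counts = np.empty((config.n_units, n_trials_per_stim, n_bins), dtype=np.int64)
        for u in range(config.n_units):
            unit = gt.iloc[u]
            rate = _stim_rate_profile(unit, stim, opto, centers, config, w)
            lam = np.maximum(rate, 0.0) * config.bin_s
            counts[u] = rng.poisson(lam, size=(n_trials_per_stim, n_bins))
        out[stim] = counts
    return out["target"], out["distractor"], gt


def _stim_rate_profile(
    unit: pd.Series,
    stim: str,
    opto: str,
    t_s: np.ndarray,
    config: SynthConfig,
    waveform: np.ndarray | None,
) -> np.ndarray:
    """Trial-relative rate profile (Hz) for one unit / stimulus / light state."""
    preferred = stim == config.alignment
    if preferred:
        amp, lat = unit["amp_pref_hz"], unit["latency_pref_s"]
    else:
        key = "amp_unpref_on_hz" if opto == "on" else "amp_unpref_off_hz"
        amp, lat = unit[key], unit["latency_unpref_s"]
    rate = unit["baseline_hz"] + alpha_kernel(t_s, amp, lat)
    if opto == "on" and waveform is not None:
        rate = apply_opto_gain(rate, waveform, float(unit["opto_gain"]))
    return np.maximum(rate, 0.0)


# ---------------------------------------------------------------------------
# analytic expectations (sampling-free ground truth)
# ---------------------------------------------------------------------------

def _poisson_mixture_pmf(means: np.ndarray, kmax: int) -> np.ndarray:
    k = np.arange(kmax + 1)
    pmfs = np.stack([stats.poisson.pmf(k, m) for m in means])
    return pmfs.mean(axis=0)


def poisson_mixture_auroc(means0: np.ndarray, means1: np.ndarray) -> float:
    """Exact AUROC between two equal-weight mixtures of Poisson distributions.

    AUROC = P(X1 > X0) + 0.5 * P(X1 = X0), evaluated by direct pmf summation.
    Used as a sampling-free expectation for Poisson spike-count discrimination.
    """
    m0 = np.atleast_1d(np.asarray(means0, dtype=float))
    m1 = np.atleast_1d(np.asarray(means1, dtype=float))
    top = float(max(m0.max(), m1.max()))
    kmax = int(math.ceil(top + 10.0 * math.sqrt(top + 1.0) + 20.0))
    p0 = _poisson_mixture_pmf(m0, kmax)
    p1 = _poisson_mixture_pmf(m1, kmax)
    cdf0 = np.cumsum(p0)
    below = np.concatenate([[0.0], cdf0[:-1]])
    return float(np.sum(p1 * (below + 0.5 * p0)))


def expected_epoch_means(
    unit: pd.Series,
    stim: str,
    opto: str,
    config: SynthConfig,
    epochs: list[tuple[float, float]],
    dt_s: float = 5e-4,
) -> np.ndarray:
    """Expected spike count of one unit in each trial-relative epoch.

    Integrates the (floored) rate profile on a fine grid, including the
    nominal opto waveform on light-on trials — the exact mean of the
    Poisson counts the simulator emits for those epochs.
    """
    o = config.opto
    means = []
    for lo, hi in epochs:
        t = np.arange(lo + dt_s / 2.0, hi, dt_s)
        w = (
            triangular_waveform(
                t,
                -np.mean(o.lead_s),
                np.mean(o.peak_s),
                np.mean(o.peak_s) + np.mean(o.decay_s),
            )
            if opto == "on"
            else None
        )
        rate = _stim_rate_profile(unit, stim, opto, t, config, w)
        means.append(float(np.sum(rate) * dt_s))
    return np.asarray(means)


def expected_unit_dprime(
    unit: pd.Series, stim: str, opto: str, config: SynthConfig
) -> float:
    """Sampling-free expected fixed-window neuronal d-prime for one unit.

    Pre- and post-stimulus 100 ms windows are each split into two 50 ms
    epochs; the exact Poisson-mixture AUROC between the epoch-count
    distributions is converted to d' = sqrt(2) * Z(AUROC).
    """
    pre = expected_epoch_means(unit, stim, opto, config, [(-0.1, -0.05), (-0.05, 0.0)])
    post = expected_epoch_means(unit, stim, opto, config, [(0.0, 0.05), (0.05, 0.1)])
    a = poisson_mixture_auroc(pre, post)
    a = min(max(a, 1e-12), 1.0 - 1e-12)
    return float(math.sqrt(2.0) * stats.norm.ppf(a))


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
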