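"""Stage orchestration across sessions, cross-session summaries, and the
neurometric-psychometric delta correlation."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, decoder, motion, neurometrics, selectivity, spikes
from .io import SessionData, SessionManifest, load_session


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and session."""


@dataclass
class PipelineConfig:
    """Analysis parameters shared across stages (times in seconds)."""

    engagement_min_s: float = 600.0
    engagement_max_gap_s: float = 60.0
    min_trials: int = 5
    bin_s: float = 0.005
    align_window: tuple[float, float] = (-0.7, 0.9)
    tag_alpha: float = 0.1
    qc_threshold: float = 1.4
    decoder_n_iter: int = 1000
    decoder_top_fraction: float = 0.5
    delta_window: tuple[float, float] = (0.03, 0.08)  # sliding-window starts
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionResult:
    session_id: str
    engaged_epoch: tuple[float, float]
    trials: pd.DataFrame  # engaged trials only
    behavior_rows: pd.DataFrame
    units_typed: pd.DataFrame
    qc: spikes.AlignmentQC
    dprime_rows: pd.DataFrame
    modulation_rows: pd.DataFrame
    selectivity_pairs: dict[str, pd.DataFrame]  # light condition -> unit pairs
    unit_trials: dict[str, dict[tuple[str, str], np.ndarray]]
    whisker_rows: pd.DataFrame


def _engaged_trials(
    data: SessionData, cfg: PipelineConfig
) -> tuple[pd.DataFrame, tuple[float, float]]:
    epoch = behavior.engagement_epoch(
        data.licks["lick_time_s"].to_numpy(),
        min_duration_s=cfg.engagement_min_s,
        max_gap_s=cfg.engagement_max_gap_s,
    )
    if epoch is None:
        raise PipelineError(
            f"session {data.manifest.session_id}: no task-engaged epoch "
            f">= {cfg.engagement_min_s} s"
        )
    return behavior.restrict_to_epoch(data.trials, epoch), epoch


def behavior_stage(
    trials: pd.DataFrame, session_id: str, cfg: PipelineConfig
) -> pd.DataFrame:
    rows = []
    for opto in ("off", "on"):
        for amplitude in ("large", "small", None):
            try:
                summary = behavior.sdt_summary(
                    trials, opto_condition=opto, amplitude=amplitude,
                    min_trials=cfg.min_trials,
                )
            except ValueError:
                continue
            row = {"session_id": session_id, "opto": opto,
                   "amplitude": amplitude or "pooled"}
            row.update({k: v for k, v in vars(summary).items() if k != "unavailable"})
            row["unavailable"] = ";".join(summary.unavailable)
            rows.append(row)
    return pd.DataFrame(rows)


def _stim_trials(trials: pd.DataFrame, stim: str, opto: str) -> pd.DataFrame:
    sel = trials[
        (trials["stim_type"] == stim)
        & (trials["opto"] == opto)
        & (trials["outcome"] != "abort")
    ]
    if stim != "catch":
        sel = sel[sel["amplitude"] == "large"]
    return sel


def prep_stage(
    data: SessionData, trials: pd.DataFrame, cfg: PipelineConfig
) -> tuple[list[spikes.UnitRecord], pd.DataFrame, spikes.AlignmentQC]:
    records = spikes.build_unit_records(data.spikes, data.units)
    typed = spikes.type_units(
        records, trials, window=cfg.align_window, alpha=cfg.tag_alpha,
        bin_s=cfg.bin_s,
    )
    # alignment QC on the multi-unit PSTH for preferred large-amplitude stimuli
    preferred = data.manifest.hemisphere_alignment
    pref_trials = _stim_trials(trials, preferred, "off")
    mu = None
    for rec in records:
        b = spikes.bin_spikes(rec.spike_times_s, pref_trials, (-0.1, 0.05), cfg.bin_s)
        mu = b if mu is None else neurometrics.population_series([mu, b])
    psth = mu.counts.mean(axis=0) / cfg.bin_s
    qc = spikes.alignment_qc(
        psth, mu.bin_starts, cfg.bin_s, threshold=cfg.qc_threshold
    )
    return records, typed, qc


def neurometrics_stage(
    data: SessionData,
    trials: pd.DataFrame,
    records: list[spikes.UnitRecord],
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, dict]:
    """Per-unit and population d' series, modulation indices, and the raw
    per-condition material reused by the selectivity and decoder stages."""
    masked = data.manifest.masked
    sid = data.manifest.session_id
    dprime_rows = []
    pairs: dict[str, list[dict]] = {"off": [], "on": []}
    unit_trials: dict[str, dict[tuple[str, str], np.ndarray]] = {}

    for opto in ("off", "on"):
        for stim in ("target", "distractor"):
            tsel = _stim_trials(trials, stim, opto)
            if len(tsel) < cfg.min_trials:
                continue
            binned_units = []
            for rec in records:
                b = spikes.bin_spikes(rec.spike_times_s, tsel, (-0.2, 0.2), cfg.bin_s)
                if masked:
                    b = spikes.BinnedCounts(
                        spikes.notch_filter_counts(b.counts, cfg.bin_s),
                        b.window, b.bin_s, b.trial_index,
                    )
                binned_units.append(b)
            pop = neurometrics.population_series(binned_units)
            for scope_id, b, scope in [("population", pop, "population")] + [
                (rec.unit_id, bu, "single_unit")
                for rec, bu in zip(records, binned_units)
            ]:
                fixed = neurometrics.fixed_window_dprime(b, scope=scope)
                sliding = neurometrics.sliding_dprime(b, scope=scope)
                dprime_rows.append(
                    {
                        "session_id": sid, "scope": scope, "id": scope_id,
                        "stim_type": stim, "opto": opto, "kind": "fixed",
                        "window_start_ms": 0.0,
                        "auroc": fixed.auroc[0], "dprime": fixed.dprime[0],
                        "n_trials": b.n_trials,
                    }
                )
                for ws, a, d in zip(
                    sliding.window_start_s, sliding.auroc, sliding.dprime
                ):
                    dprime_rows.append(
                        {
                            "session_id": sid, "scope": scope, "id": scope_id,
                            "stim_type": stim, "opto": opto, "kind": "sliding",
                            "window_start_ms": ws * 1e3,
                            "auroc": a, "dprime": d, "n_trials": b.n_trials,
                        }
                    )
            # selectivity pairs and decoder features per unit
            align = data.manifest.hemisphere_alignment
            for rec, b in zip(records, binned_units):
                key = "preferred" if stim == align else "unpreferred"
                fixed = neurometrics.fixed_window_dprime(b)
                _append_pair(pairs[opto], rec.unit_id, key, fixed.dprime[0], stim)
                unit_trials.setdefault(rec.unit_id, {})[(stim, opto)] = (
                    decoder.trial_features(b)
                )

    pair_frames = {
        cond: _pairs_frame(rows) for cond, rows in pairs.items() if rows
    }

    # pre-stimulus modulation index per unit (last 100 ms, all trial types)
    mod_rows = []
    on_trials = trials[trials["opto"] == "on"]
    off_trials = trials[trials["opto"] == "off"]
    for rec in records:
        b_on = spikes.bin_spikes(rec.spike_times_s, on_trials, (-0.1, 0.0), cfg.bin_s)
        b_off = spikes.bin_spikes(rec.spike_times_s, off_trials, (-0.1, 0.0), cfg.bin_s)
        r_on = neurometrics.prestim_rate(b_on)
        r_off = neurometrics.prestim_rate(b_off)
        mod_rows.append(
            {
                "session_id": sid, "unit_id": rec.unit_id,
                "cell_type": rec.cell_type,
                "rate_on_hz": r_on, "rate_off_hz": r_off,
                "mi": neurometrics.modulation_index(r_on, r_off),
            }
        )
    return (
        pd.DataFrame(dprime_rows),
        pd.DataFrame(mod_rows),
        pair_frames,
        unit_trials,
    )


def _append_pair(rows: list, unit_id: str, key: str, dprime: float, stim: str) -> None:
    for row in rows:
        if row["unit_id"] == unit_id:
            row[f"dprime_{key}"] = dprime
            row[f"dprime_{stim}"] = dprime
            return
    rows.append({"unit_id": unit_id, f"dprime_{key}": dprime, f"dprime_{stim}": dprime})


def _pairs_frame(rows: list) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    need = {"dprime_preferred", "dprime_unpreferred"}
    if not need <= set(df.columns):
        return pd.DataFrame(columns=["unit_id", *sorted(need)])
    return df.dropna(subset=sorted(need)).reset_index(drop=True)


def whisker_stage(
    data: SessionData, trials: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    trace = motion.MotionTrace(
        frame_times_s=data.whisker["frame_time_s"].to_numpy(),
        energy=data.whisker["motion_energy"].to_numpy(),
    )
    segments = motion.align_trials(trace, trials)
    segments = motion.zscore_prestim(segments)
    segments = motion.normalize_post_stimulus(segments)
    retained = set(motion.exclude_high_motion_trials(segments))
    rows = []
    for trial_index, seg in segments.groupby("trial_index"):
        post = seg[seg["rel_time_s"] >= 0]
        rows.append(
            {
                "session_id": data.manifest.session_id,
                "trial_index": trial_index,
                "mean_post_energy_norm": post["energy_norm"].mean(),
                "flag_no_prestim": bool(seg["flag_no_prestim"].any()),
                "retained_low_motion": trial_index in retained,
            }
        )
    return pd.DataFrame(rows)


def analyze_session(data: SessionData, cfg: PipelineConfig) -> SessionResult:
    sid = data.manifest.session_id

    def run(stage, fn, *args):
        try:
            return fn(*args)
        except PipelineError:
            raise
        except Exception as exc:  # annotate with stage and session
            raise PipelineError(f"stage {stage} failed for session {sid}: {exc}") from exc

    trials, epoch = run("engagement", _engaged_trials, data, cfg)
    behavior_rows = run("behavior", behavior_stage, trials, sid, cfg)
    records, typed, qc = run("prep", prep_stage, data, trials, cfg)
    dprime_rows, mod_rows, pair_frames, unit_trials = run(
        "neurometrics", neurometrics_stage, data, trials, records, cfg
    )
    whisker_rows = run("whisker", whisker_stage, data, trials, cfg)
    typed = typed.assign(session_id=sid, qc_pass=qc.passed, qc_peak_ratio=qc.peak_ratio)
    return SessionResult(
        session_id=sid,
        engaged_epoch=epoch,
        trials=trials,
        behavior_rows=behavior_rows,
        units_typed=typed,
        qc=qc,
        dprime_rows=dprime_rows,
        modulation_rows=mod_rows,
        selectivity_pairs=pair_frames,
        unit_trials=unit_trials,
        whisker_rows=whisker_rows,
    )


# ---------------------------------------------------------------------------
# cross-session summaries
# ---------------------------------------------------------------------------

def pooled_selectivity(
    results: list[SessionResult],
) -> tuple[dict[str, selectivity.SelectivityFit], selectivity.GatingContrast | None]:
    """Pool unit selectivity pairs across sessions and fit per light condition."""
    fits = {}
    for cond in ("off", "on"):
        frames = [
            r.selectivity_pairs[cond].assign(
                unit_id=r.session_id + "/" + r.selectivity_pairs[cond]["unit_id"]
            )
            for r in results
            if cond in r.selectivity_pairs and not r.selectivity_pairs[cond].empty
        ]
        if not frames:
            continue
        pooled = pd.concat(frames, ignore_index=True)
        if len(pooled) >= 3:
            fits[cond] = selectivity.fit_selectivity(pooled, cond)
    contrast = None
    if "off" in fits and "on" in fits:
        contrast = selectivity.gating_model_contrast(fits["off"], fits["on"])
    return fits, contrast


def pooled_decoder(
    results: list[SessionResult],
    cfg: PipelineConfig,
    cell_type: str = "excitatory",
) -> decoder.DecoderSummary | None:
    """Pseudo-ensemble reader over excitatory units pooled across sessions."""
    rows = []
    unit_trials = {}
    for r in results:
        typed = r.units_typed.set_index("unit_id")["cell_type"]
        for uid, conds in r.unit_trials.items():
            if typed.get(uid) != cell_type:
                continue
            if any(
                c not in conds or conds[c].size == 0 for c in decoder.CONDITIONS
            ):
                continue
            pairs_off = r.selectivity_pairs.get("off")
            if pairs_off is None or uid not in set(pairs_off["unit_id"]):
                continue
            d_t = pairs_off.set_index("unit_id").loc[uid].get("dprime_target", np.nan)
            if not np.isfinite(d_t):
                continue
            key = f"{r.session_id}/{uid}"
            rows.append({"unit_id": key, "dprime_target": d_t})
            unit_trials[key] = conds
    if not rows:
        return None
    top = decoder.select_top_units(pd.DataFrame(rows), cfg.decoder_top_fraction)
    selected = {uid: unit_trials[uid] for uid in top["unit_id"]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return decoder.iterate_reader(
            selected, n_iter=cfg.decoder_n_iter, seed=cfg.seed
        )


@dataclass
class DeltaCorrelation:
    """Session-by-session coupling of encoding and behavioral changes."""

    measure: str
    pairs: pd.DataFrame  # session_id, delta_dprime, delta_behavior
    r_squared: float
    slope: float


def delta_correlation(
    results: list[SessionResult], cfg: PipelineConfig
) -> list[DeltaCorrelation]:
    """Correlate light-on minus light-off changes in distractor encoding
    with changes in each behavioral measure across sessions.

    The encoding delta is the session's population sliding-window d' for
    distractor stimuli averaged over the 30-100 ms post-stimulus span,
    light-on minus light-off.
    """
    measures = ["fa_rate", "catch_rate", "dprime_distractor", "criterion_distractor"]
    rows = []
    for r in results:
        d = r.dprime_rows
        sel = d[
            (d["scope"] == "population")
            & (d["stim_type"] == "distractor")
            & (d["kind"] == "sliding")
            & (d["window_start_ms"] >= cfg.delta_window[0] * 1e3 - 1e-6)
            & (d["window_start_ms"] <= cfg.delta_window[1] * 1e3 + 1e-6)
        ]
        by_opto = sel.groupby("opto")["dprime"].mean()
        if not {"on", "off"} <= set(by_opto.index):
            continue
        b = r.behavior_rows
        b_large = b[b["amplitude"] == "large"].set_index("opto")
        if not {"on", "off"} <= set(b_large.index):
            continue
        row = {
            "session_id": r.session_id,
            "delta_dprime": by_opto["on"] - by_opto["off"],
        }
        for m in measures:
            row[f"delta_{m}"] = b_large.loc["on", m] - b_large.loc["off", m]
        rows.append(row)
    frame = pd.DataFrame(rows)
    out = []
    for m in measures:
        col = f"delta_{m}"
        sub = frame.dropna(subset=["delta_dprime", col]) if not frame.empty else frame
        if len(sub) < 3:
            continue
        x = sub["delta_dprime"].to_numpy()
        y = sub[col].to_numpy()
        if np.ptp(x) == 0:
            warnings.warn(f"constant encoding delta; R^2 undefined for {m}",
                          stacklevel=2)
            continue
        res = stats.linregress(x, y)
        out.append(
            DeltaCorrelation(
                measure=m,
                pairs=sub[["session_id", "delta_dprime", col]].rename(
                    columns={col: "delta_behavior"}
                ),
                r_squared=float(res.rvalue**2),
                slope=float(res.slope),
            )
        )
    return out


def difference_report(
    rate_a_hz: float,
    rate_b_hz: float,
    suppressed_a_hz: float,
    suppressed_b_hz: float,
) -> dict[str, float]:
    """Group rate differences and their percent reduction under suppression.

    Returns the control difference (a - b), the suppressed difference
    (a' - b'), and 100 * (control - suppressed) / control.
    """
    for v in (rate_a_hz, rate_b_hz, suppressed_a_hz, suppressed_b_hz):
        if not np.isfinite(v):
            raise ValueError("rates must be finite")
    diff = rate_a_hz - rate_b_hz
    diff_sup = suppressed_a_hz - suppressed_b_hz
    if diff == 0:
        raise ZeroDivisionError("control groups are equal; percent reduction undefined")
    return {
        "difference_hz": diff,
        "suppressed_difference_hz": diff_sup,
        "percent_reduction": 100.0 * (diff - diff_sup) / diff,
    }


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(
    manifests: list[SessionManifest],
    cfg: PipelineConfig | None = None,
    out_dir: Path | None = None,
) -> dict:
    """Execute every stage over a set of sessions and write all outputs.

    Deterministic for fixed inputs and config; writes a provenance record
    (config hash and seed) alongside the stage CSVs when ``out_dir`` is
    given.
    """
    cfg = cfg or PipelineConfig()
    results = [analyze_session(load_session(m), cfg) for m in manifests]

    fits, contrast = pooled_selectivity(results)
    decoder_summary = pooled_decoder(results, cfg)
    deltas = delta_correlation(results, cfg)

    bundle = {
        "behavior": pd.concat([r.behavior_rows for r in results], ignore_index=True),
        "units_typed": pd.concat([r.units_typed for r in results], ignore_index=True),
        "dprime_series": pd.concat([r.dprime_rows for r in results], ignore_index=True),
        "modulation": pd.concat(
            [r.modulation_rows for r in results], ignore_index=True
        ),
        "whisker_trials": pd.concat(
            [r.whisker_rows for r in results], ignore_index=True
        ),
        "selectivity_fits": fits,
        "gating_contrast": contrast,
        "decoder": decoder_summary,
        "delta_correlations": deltas,
        "session_results": results,
    }
    if out_dir is not None:
        _write_outputs(bundle, manifests, cfg, Path(out_dir))
    return bundle


def _write_outputs(
    bundle: dict, manifests: list[SessionManifest], cfg: PipelineConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for name in ("behavior", "units_typed", "dprime_series", "modulation",
                 "whisker_trials"):
        bundle[name].to_csv(out / f"{name}.csv", index=False)
    fit_rows = []
    for cond, fit in bundle["selectivity_fits"].items():
        fit.units.assign(condition=cond).to_csv(
            out / f"selectivity_units_{cond}.csv", index=False
        )
        fit_rows.append(
            {
                "condition": cond, "slope": fit.fit.slope,
                "slope_ci_lo": fit.fit.slope_ci[0],
                "slope_ci_hi": fit.fit.slope_ci[1],
                "intercept": fit.fit.intercept,
                "intercept_ci_lo": fit.fit.intercept_ci[0],
                "intercept_ci_hi": fit.fit.intercept_ci[1],
                "n_units": fit.fit.n,
            }
        )
    if fit_rows:
        pd.DataFrame(fit_rows).to_csv(out / "selectivity_fits.csv", index=False)
    if bundle["decoder"] is not None:
        bundle["decoder"].iterations.to_csv(out / "decoder_results.csv", index=False)
        (out / "decoder_summary.json").write_text(
            json.dumps(
                {"mean": vars(bundle["decoder"].mean),
                 "sd": vars(bundle["decoder"].sd)},
                indent=2,
            )
            + "\n"
        )
    if bundle["delta_correlations"]:
        pd.DataFrame(
            [
                {"measure": d.measure, "r_squared": d.r_squared, "slope": d.slope,
                 "n_sessions": len(d.pairs)}
                for d in bundle["delta_correlations"]
            ]
        ).to_csv(out / "delta_correlation.csv", index=False)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    provenance = {
        "sessions": [m.session_id for m in manifests],
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "gating_verdict": (
            bundle["gating_contrast"].verdict if bundle["gating_contrast"] else None
        ),
    }
    (out / "run_log.json").write_text(json.dumps(provenance, indent=2) + "\n")
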