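"""Session file I/O: the package's delimited-text formats and the JSON
session manifest.

A session on disk is a directory of CSV tables —

- ``trials.csv``   one row per trial (see TRIAL_COLUMNS)
- ``licks.csv``    lick_time_s
- ``spikes.csv``   unit_id, spike_time_s
- ``units.csv``    unit_id, hemisphere_alignment, depth_um
- ``whisker.csv``  frame_time_s, motion_energy, roi_id

— plus a ``manifest.json`` naming the files, the recording-side
hemisphere alignment, and whether the session is flagged as mask-light
contaminated (which triggers band-stop filtering before neurometrics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .synth import Session

TRIAL_COLUMNS = [
    "trial_index",
    "onset_time_s",
    "stim_type",
    "amplitude",
    "opto",
    "outcome",
    "response_time_s",
    "opto_onset_s",
    "opto_peak_s",
    "opto_offset_s",
    "mask_onset_s",
]

_TABLE_FILES = {
    "trials": "trials.csv",
    "licks": "licks.csv",
    "spikes": "spikes.csv",
    "units": "units.csv",
    "whisker": "whisker.csv",
}


@dataclass
class SessionManifest:
    session_id: str
    root: Path
    files: dict[str, str] = field(
        default_factory=lambda: dict(_TABLE_FILES)
    )
    hemisphere_alignment: str = "target"
    masked: bool = False
    config_overrides: dict = field(default_factory=dict)

    def path(self, table: str) -> Path:
        return Path(self.root) / self.files[table]

    def validate(self) -> None:
        if self.hemisphere_alignment not in ("target", "distractor"):
            raise ValueError("hemisphere_alignment must be 'target' or 'distractor'")
        for table, name in self.files.items():
            p = self.path(table)
            if not p.exists():
                raise FileNotFoundError(
                    f"session {self.session_id}: missing {table} file {p}"
                )


@dataclass
class SessionData:
    """A loaded session bundle."""

    manifest: SessionManifest
    trials: pd.DataFrame
    licks: pd.DataFrame
    spikes: pd.DataFrame
    units: pd.DataFrame
    whisker: pd.DataFrame


def write_manifest(manifest: SessionManifest, path: Path | None = None) -> Path:
    path = Path(path) if path else Path(manifest.root) / "manifest.json"
    payload = {
        "session_id": manifest.session_id,
        "files": manifest.files,
        "hemisphere_alignment": manifest.hemisphere_alignment,
        "masked": manifest.masked,
        "config_overrides": manifest.config_overrides,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: Path) -> SessionManifest:
    path = Path(path)
    payload = json.loads(path.read_text())
    return SessionManifest(
        session_id=payload["session_id"],
        root=path.parent,
        files=payload.get("files", dict(_TABLE_FILES)),
        hemisphere_alignment=payload.get("hemisphere_alignment", "target"),
        masked=payload.get("masked", False),
        config_overrides=payload.get("config_overrides", {}),
    )


def write_session(
    session: Session, root: Path, session_id: str, masked: bool | None = None
) -> SessionManifest:
    """Write a generated session as the standard file bundle."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(root / "trials.csv", index=False)
    session.licks.to_csv(root / "licks.csv", index=False)
    session.spikes.to_csv(root / "spikes.csv", index=False)
    session.units.to_csv(root / "units.csv", index=False)
    session.whisker.to_csv(root / "whisker.csv", index=False)
    session.ground_truth.to_csv(root / "ground_truth.csv", index=False)
    if masked is None:
        masked = (
            session.config.mask_depth_10 > 0 or session.config.mask_depth_20 > 0
        )
    manifest = SessionManifest(
        session_id=session_id,
        root=root,
        hemisphere_alignment=session.config.alignment,
        masked=masked,
    )
    write_manifest(manifest)
    return manifest


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{table} is missing columns {missing}")


def load_session(manifest: SessionManifest) -> SessionData:
    manifest.validate()
    trials = pd.read_csv(manifest.path("trials"))
    _require_columns(
        trials,
        ["trial_index", "onset_time_s", "stim_type", "amplitude", "opto", "outcome"],
        "trials.csv",
    )
    if not trials["onset_time_s"].is_monotonic_increasing:
        raise ValueError("trial onset times must be strictly increasing")
    licks = pd.read_csv(manifest.path("licks"))
    _require_columns(licks, ["lick_time_s"], "licks.csv")
    spikes = pd.read_csv(manifest.path("spikes"))
    _require_columns(spikes, ["unit_id", "spike_time_s"], "spikes.csv")
    units = pd.read_csv(manifest.path("units"))
    _require_columns(units, ["unit_id", "hemisphere_alignment"], "units.csv")
    whisker = pd.read_csv(manifest.path("whisker"))
    _require_columns(whisker, ["frame_time_s", "motion_energy"], "whisker.csv")
    return SessionData(
        manifest=manifest,
        trials=trials,
        licks=licks,
        spikes=spikes,
        units=units,
        whisker=whisker,
    )
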