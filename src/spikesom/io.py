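"""Trial-CSV and cohort-manifest input/output.

A trial file is a wide CSV: ``time_s`` + the 32 registry channel columns
(+ optional marker columns ``heelL_z_mm, heelR_z_mm, wrist_y_mm``).  The
cohort manifest is a CSV with one row per trial holding the file path,
sampling rate, outcome metadata and (optionally) precomputed plant and
impact frames.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .channels import ChannelRegistry, build_channel_registry
from .preprocess import MarkerTraces, OutcomeRecord, RawTrial

MARKER_COLUMNS = ("heelL_z_mm", "heelR_z_mm", "wrist_y_mm")
MANIFEST_COLUMNS = ("player_id", "trial_id", "path", "sampling_rate", "blocked",
                    "ball_speed_kmh", "touched_block_and_slowed", "landed_out")


class TrialFormatError(ValueError):
    """Raised for malformed trial or manifest files."""


def write_trial_csv(trial: RawTrial, path: str | Path,
                    registry: Optional[ChannelRegistry] = None) -> Path:
    registry = registry or build_channel_registry()
    path = Path(path)
    t = np.arange(trial.n_frames) / trial.sampling_rate
    data = {"time_s": t}
    for k, name in enumerate(registry.names):
        data[name] = trial.frames[:, k]
    if trial.markers is not None:
        data["heelL_z_mm"] = trial.markers.heel_left_z
        data["heelR_z_mm"] = trial.markers.heel_right_z
        data["wrist_y_mm"] = trial.markers.wrist_y
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_trial_csv(path: str | Path, *, player_id: str, trial_id: str,
                   outcome: OutcomeRecord, sampling_rate: float = 180.0,
                   plant_frame: Optional[int] = None,
                   impact_frame: Optional[int] = None,
                   registry: Optional[ChannelRegistry] = None) -> RawTrial:
    registry = registry or build_channel_registry()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in registry.names if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing channel columns {missing[:5]}")
    for col in ["time_s"] + registry.names:
        if col in df.columns and not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float, np.number)))].index
            row = int(bad[0]) if len(bad) else -1
            raise TrialFormatError(f"{path}: non-numeric value in column {col!r}, row {row}")
    frames = df[registry.names].to_numpy(dtype=float)
    markers = None
    if all(c in df.columns for c in MARKER_COLUMNS):
        markers = MarkerTraces(
            heel_left_z=df["heelL_z_mm"].to_numpy(dtype=float),
            heel_right_z=df["heelR_z_mm"].to_numpy(dtype=float),
            wrist_y=df["wrist_y_mm"].to_numpy(dtype=float),
        )
    return RawTrial(player_id=player_id, trial_id=trial_id, frames=frames,
                    outcome=outcome, sampling_rate=sampling_rate, markers=markers,
                    plant_frame=plant_frame, impact_frame=impact_frame)


def write_cohort(trials: Sequence[RawTrial], manifest: pd.DataFrame,
                 out_dir: str | Path,
                 registry: Optional[ChannelRegistry] = None) -> Path:
    """Write every trial CSV plus ``manifest.csv`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {t.trial_id: t for t in trials}
    for _, row in manifest.iterrows():
        write_trial_csv(by_id[row["trial_id"]], out_dir / row["path"], registry)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return int(value)


def load_cohort(manifest_path: str | Path,
                registry: Optional[ChannelRegistry] = None) -> list[RawTrial]:
    """Read a manifest and all trial files it references."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{manifest_path}: missing manifest columns {missing}")
    base = manifest_path.parent
    trials = []
    for _, row in df.iterrows():
        outcome = OutcomeRecord(
            blocked=bool(int(row["blocked"])),
            ball_speed_kmh=float(row["ball_speed_kmh"]),
            touched_block_and_slowed=bool(int(row["touched_block_and_slowed"])),
            landed_out=bool(int(row["landed_out"])),
        )
        trial_path = base / str(row["path"])
        trials.append(read_trial_csv(
            trial_path, player_id=str(row["player_id"]), trial_id=str(row["trial_id"]),
            outcome=outcome, sampling_rate=float(row["sampling_rate"]),
            plant_frame=_opt_int(row.get("plant_frame")),
            impact_frame=_opt_int(row.get("impact_frame")),
            registry=registry))
    return trials
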