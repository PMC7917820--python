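"""Kinematic preprocessing: filtering, event detection, trimming and
time-normalisation of spike trials.

A raw trial is an F x 32 channel matrix sampled at 180 Hz plus optional
heel/wrist marker traces used to detect the plant phase (both feet on the
ground) and ball impact (abrupt wrist deceleration).  Preprocessing trims
each channel to the plant-to-impact window, computes angular velocities by
central differences at the original sampling rate, and linearly
interpolates both angle and velocity waveforms onto 101 points
(t = 0..100, i.e. percent of the movement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as _signal

from .channels import N_CHANNELS

#: number of time-normalised samples per trial (0..100 % of the movement)
N_NODES = 101

SUCCESSFUL = "successful"
FAULTY = "faulty"

# plant-phase detection defaults (the source description is verbal only)
GROUND_HEIGHT_MM = 30.0
GROUND_SPEED_MM_S = 50.0
#: minimum |wrist Y deceleration| (mm/s^2) for a trustworthy impact event
IMPACT_ACCEL_FLOOR_MM_S2 = 1000.0


class EventDetectionError(ValueError):
    """Raised when plant/impact events cannot be located in a trial."""


@dataclass(frozen=True)
class OutcomeRecord:
    """Spike outcome metadata used to label a trial successful or faulty."""

    blocked: bool = False
    ball_speed_kmh: float = 100.0
    touched_block_and_slowed: bool = False
    landed_out: bool = False

    def __post_init__(self) -> None:
        if self.ball_speed_kmh < 0:
            raise ValueError("ball_speed_kmh must be non-negative")


@dataclass
class MarkerTraces:
    """Auxiliary marker signals for event detection (heights in mm)."""

    heel_left_z: np.ndarray
    heel_right_z: np.ndarray
    wrist_y: np.ndarray


@dataclass
class RawTrial:
    """One spike trial: F x 32 channel matrix at ``sampling_rate`` Hz."""

    player_id: str
    trial_id: str
    frames: np.ndarray
    outcome: OutcomeRecord
    sampling_rate: float = 180.0
    markers: Optional[MarkerTraces] = None
    plant_frame: Optional[int] = None
    impact_frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != N_CHANNELS:
            raise ValueError(f"frames must be F x {N_CHANNELS}, got {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("trial must have at least 2 frames")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class PreprocessedTrial:
    """Time-normalised trial: 101 x 32 angle (psi) and velocity (phi) matrices."""

    player_id: str
    label: str
    psi: np.ndarray
    phi: np.ndarray
    events: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.psi.shape[0] != N_NODES or self.phi.shape[0] != N_NODES:
            raise ValueError(f"psi/phi must have exactly {N_NODES} rows")
        if self.psi.shape != self.phi.shape:
            raise ValueError("psi and phi must have identical shapes")
        if self.label not in (SUCCESSFUL, FAULTY):
            raise ValueError(f"label must be {SUCCESSFUL!r} or {FAULTY!r}")


def butterworth_lowpass(x: np.ndarray, sampling_rate: float, cutoff: float = 10.0,
                        order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    ``order`` is the *effective* order: an order/2 filter is applied
    forward and backward (dual pass), which doubles the order and cancels
    the phase lag — the standard smoothing convention for motion-capture
    kinematics.  Endpoint transients are suppressed by reflective padding
    of 3x the filter order.
    """
    x = np.asarray(x, dtype=float)
    if order < 2 or order % 2:
        raise ValueError("order must be an even integer >= 2")
    if not 0 < cutoff < sampling_rate / 2:
        raise ValueError(f"cutoff must lie in (0, Nyquist={sampling_rate / 2} Hz)")
    if x.shape[0] <= 3 * order:
        raise ValueError(f"signal too short for order-{order} zero-phase filtering "
                         f"(need > {3 * order} samples, got {x.shape[0]})")
    b, a = _signal.butter(order // 2, cutoff, btype="low", fs=sampling_rate)
    return _signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=3 * order)


def detect_events(raw: RawTrial,
                  ground_height_mm: float = GROUND_HEIGHT_MM,
                  ground_speed_mm_s: float = GROUND_SPEED_MM_S,
                  accel_floor_mm_s2: float = IMPACT_ACCEL_FLOOR_MM_S2) -> tuple[int, int]:
    """Locate the plant and ball-impact frames from heel/wrist markers.

    Plant = first frame where both heel heights drop below
    ``ground_height_mm`` while their vertical speed magnitude is below
    ``ground_speed_mm_s``.  Impact = frame of the global minimum of the
    wrist-marker Y acceleration (the largest abrupt deceleration); a
    minimum shallower than ``accel_floor_mm_s2`` is considered unreliable.
    """
    if raw.markers is None:
        raise EventDetectionError("trial has no marker traces; supply events in the manifest")
    if raw.n_frames < 10:
        raise EventDetectionError("too few frames for event detection")
    fs = raw.sampling_rate
    hl, hr = raw.markers.heel_left_z, raw.markers.heel_right_z
    vl = np.gradient(hl) * fs
    vr = np.gradient(hr) * fs
    on_ground = ((hl < ground_height_mm) & (hr < ground_height_mm)
                 & (np.abs(vl) < ground_speed_mm_s) & (np.abs(vr) < ground_speed_mm_s))
    if not on_ground.any():
        raise EventDetectionError("no plant phase: both heels never at rest below "
                                  f"{ground_height_mm} mm")
    plant = int(np.argmax(on_ground))

    wy = raw.markers.wrist_y
    acc = np.gradient(np.gradient(wy)) * fs * fs
    impact = int(np.argmin(acc))
    if acc[impact] > -accel_floor_mm_s2:
        raise EventDetectionError("impact detection unreliable: no abrupt wrist "
                                  "deceleration exceeds the magnitude floor")
    if impact <= plant:
        raise EventDetectionError(f"event order violation: impact frame {impact} "
                                  f"not after plant frame {plant}")
    return plant, impact


def time_normalize(series: np.ndarray, n_out: int = N_NODES) -> np.ndarray:
    """Linearly interpolate a (F,) or (F, k) series onto ``n_out`` equally
    spaced points, preserving the endpoints exactly."""
    series = np.asarray(series, dtype=float)
    n_in = series.shape[0]
    if n_in < 2:
        raise ValueError("need at least 2 frames to time-normalise")
    t_in = np.linspace(0.0, 1.0, n_in)
    t_out = np.linspace(0.0, 1.0, n_out)
    if series.ndim == 1:
        out = np.interp(t_out, t_in, series)
    else:
        out = np.column_stack([np.interp(t_out, t_in, series[:, k])
                               for k in range(series.shape[1])])
    # endpoints of linear interpolation are exact by construction
    out[0], out[-1] = series[0], series[-1]
    return out


def central_difference_velocity(x: np.ndarray, sampling_rate: float) -> np.ndarray:
    """First derivative by central differences (one-sided at the ends)."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for central differences")
    return np.gradient(x, axis=0) * sampling_rate


def classify_outcome(rec: OutcomeRecord, speed_threshold_kmh: float = 50.0) -> str:
    """Label a spike faulty iff any fault criterion holds: the attacker was
    blocked, ball speed below 50 km/h, the ball touched the block and
    slowed below 50 km/h, or the ball landed out of bounds."""
    faulty = (rec.blocked or rec.ball_speed_kmh < speed_threshold_kmh
              or rec.touched_block_and_slowed or rec.landed_out)
    return FAULTY if faulty else SUCCESSFUL


def preprocess_trial(raw: RawTrial,
                     plant_frame: Optional[int] = None,
                     impact_frame: Optional[int] = None,
                     filter_cutoff_hz: Optional[float] = 10.0,
                     filter_order: int = 4) -> PreprocessedTrial:
    """Full single-trial preprocessing.

    Pipeline: optional zero-phase low-pass filtering of every channel,
    trim to [plant, impact] inclusive, central-difference velocities at
    the source rate on the trimmed window, then time-normalisation of both
    angle and velocity waveforms to 101 points.  Events are taken from
    arguments, the trial's stored events, or marker-based detection, in
    that order.
    """
    if plant_frame is None:
        plant_frame = raw.plant_frame
    if impact_frame is None:
        impact_frame = raw.impact_frame
    if plant_frame is None or impact_frame is None:
        plant_frame, impact_frame = detect_events(raw)
    plant_frame, impact_frame = int(plant_frame), int(impact_frame)
    if not 0 <= plant_frame < impact_frame < raw.n_frames:
        raise ValueError(f"invalid event window [{plant_frame}, {impact_frame}] "
                         f"for a {raw.n_frames}-frame trial")

    frames = raw.frames
    if filter_cutoff_hz is not None:
        frames = butterworth_lowpass(frames, raw.sampling_rate, filter_cutoff_hz,
                                     filter_order)
    trimmed = frames[plant_frame:impact_frame + 1]
    if trimmed.shape[0] < 3:
        raise ValueError("plant-to-impact window too short")
    velocity = central_difference_velocity(trimmed, raw.sampling_rate)
    psi = time_normalize(trimmed)
    phi = time_normalize(velocity)
    label = classify_outcome(raw.outcome)
    return PreprocessedTrial(player_id=raw.player_id, label=label, psi=psi, phi=phi,
                             events=(plant_frame, impact_frame))


def condition_mean(trials: list[PreprocessedTrial]) -> PreprocessedTrial:
    """Element-wise mean of one player's trials sharing an outcome label."""
    if not trials:
        raise ValueError("cannot average an empty trial list")
    players = {t.player_id for t in trials}
    labels = {t.label for t in trials}
    if len(players) > 1:
        raise ValueError(f"mixed players in condition mean: {sorted(players)}")
    if len(labels) > 1:
        raise ValueError(f"mixed labels in condition mean: {sorted(labels)}")
    psi = np.mean([t.psi for t in trials], axis=0)
    phi = np.mean([t.phi for t in trials], axis=0)
    return PreprocessedTrial(player_id=trials[0].player_id, label=trials[0].label,
                             psi=psi, phi=phi, events=trials[0].events)


def condition_means(trials: list[PreprocessedTrial]) -> list[PreprocessedTrial]:
    """Per-player, per-label averages in stable (player, label) order.

    Players contribute one sequence per outcome label they actually have;
    a player with no faulty trial contributes a single successful mean.
    """
    keys: list[tuple[str, str]] = []
    groups: dict[tuple[str, str], list[PreprocessedTrial]] = {}
    for t in trials:
        key = (t.player_id, t.label)
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(t)
    ordered = sorted(keys, key=lambda k: (k[0], k[1] != SUCCESSFUL))
    return [condition_mean(groups[k]) for k in ordered]
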