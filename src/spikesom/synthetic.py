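"""Seeded synthetic spike-kinematics cohorts.

Real spike trials from the motion-capture study design this package
targets are not publicly deposited, so the generator emulates their
statistical structure: ten players, six spikes each, player-specific
smooth coordination patterns (between-player differences well above
trial-to-trial noise), one player who never faults, and a
successful-vs-faulty difference confined to the upper-limb angular
velocities inside the 35-45% and 76-100% windows of the normalised
movement.

Each player is a set of per-channel smooth base curves (random low-order
harmonics scaled to channel-appropriate ranges).  A trial evaluates the
curves at 180 Hz over a random movement duration, adds smooth
Gaussian-process noise, and — for faulty trials — an angle perturbation
whose time derivative is a cosine-tapered velocity bump on the effect
windows of the eight upper-limb channels, so angles and velocities stay
derivative-consistent through preprocessing.  Heel and wrist marker
traces are written so event detection recovers the scripted plant and
impact frames exactly, and the outcome metadata reproduces the requested
label under the fault classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .channels import ChannelRegistry, build_channel_registry
from .preprocess import FAULTY, SUCCESSFUL, MarkerTraces, OutcomeRecord, RawTrial


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort."""

    n_players: int = 10
    trials_per_player: int = 6
    fault_probability: float = 1.0 / 3.0
    no_fault_player_index: int = 1
    effect_windows: tuple[tuple[float, float], ...] = ((35.0, 45.0), (76.0, 100.0))
    #: velocity-bump amplitude on upper-limb channels, deg/s; None -> 3x the
    #: velocity SD implied by the smooth trial noise
    effect_amplitude: Optional[float] = None
    base_harmonics: int = 4
    trial_noise_sd_deg: float = 2.0
    trial_noise_sd_m: float = 0.02
    noise_fwhm_samples: float = 20.0
    angle_scale_deg: float = 12.0
    com_scale_m: float = 0.25
    #: pointwise correlation of trunk/neck/head channel deviations within a
    #: player (stacked segments tilt together)
    trunk_coupling: float = 0.8
    duration_range_frames: tuple[int, int] = (120, 200)
    pre_frames: int = 30
    post_frames: int = 10
    sampling_rate: float = 180.0
    taper_width_pct: float = 4.0
    blocked_prob: float = 0.3
    touched_prob: float = 0.1
    landed_out_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for w0, w1 in self.effect_windows:
            if not (0 <= w0 <= w1 <= 100):
                raise ValueError("effect windows must lie within [0, 100]")
        if not 0 <= self.fault_probability <= 1:
            raise ValueError("fault_probability must lie in [0, 1]")
        if self.effect_amplitude is not None and self.effect_amplitude < 0:
            raise ValueError("effect_amplitude must be non-negative")

    @property
    def noise_kernel_sd(self) -> float:
        """Gaussian smoothing kernel SD (samples) of the trial noise."""
        return self.noise_fwhm_samples / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def velocity_noise_sd(self) -> float:
        """SD (deg/s) of the angular-velocity noise implied by smooth
        angle noise: differentiating a Gaussian-kernel GP of SD sigma
        multiplies the SD by 1/(sqrt(2) * kernel_sd) per sample."""
        return (self.trial_noise_sd_deg * self.sampling_rate
                / (math.sqrt(2.0) * self.noise_kernel_sd))

    def resolved_effect_amplitude(self) -> float:
        if self.effect_amplitude is not None:
            return self.effect_amplitude
        return 3.0 * self.velocity_noise_sd()


@dataclass
class PlayerTemplate:
    """Per-channel smooth base curves b(tau) = offset + sum_h a_h sin(2 pi h tau + phi_h).

    Trunk/neck/head channels additionally mix in a shared harmonic curve
    (weight sqrt(trunk_coupling)), modelling the mechanical coupling of
    stacked axial segments within a player."""

    player_id: str
    offsets: np.ndarray   # (32,)
    amplitudes: np.ndarray  # (32, H)
    phases: np.ndarray      # (32, H)
    shared_amplitudes: np.ndarray  # (H,) trunk/head common curve
    shared_phases: np.ndarray      # (H,)
    trunk_mask: np.ndarray         # (32,) bool
    trunk_coupling: float = 0.8

    def evaluate(self, tau: np.ndarray) -> np.ndarray:
        """Evaluate all channels at curve parameter tau in [0, 1] -> (len(tau), 32)."""
        tau = np.asarray(tau, dtype=float)
        h = np.arange(1, self.amplitudes.shape[1] + 1)
        # (T, 32, H) phase argument
        arg = 2.0 * math.pi * tau[:, None, None] * h[None, None, :] + self.phases[None, :, :]
        own = (self.amplitudes[None, :, :] * np.sin(arg)).sum(axis=2)
        arg_s = 2.0 * math.pi * tau[:, None] * h[None, :] + self.shared_phases[None, :]
        shared = (self.shared_amplitudes[None, :] * np.sin(arg_s)).sum(axis=1)
        rho = self.trunk_coupling
        mix = np.where(self.trunk_mask, math.sqrt(max(1.0 - rho, 0.0)), 1.0)
        out = self.offsets[None, :] + own * mix[None, :]
        out[:, self.trunk_mask] += math.sqrt(rho) * shared[:, None]
        return out


def generate_player_template(seed, registry: Optional[ChannelRegistry] = None,
                             config: Optional[SyntheticConfig] = None,
                             player_id: str = "P") -> PlayerTemplate:
    """Draw one player's base curves; deterministic given the seed.

    Harmonic amplitudes fall off as 1/h and are scaled per channel kind
    (degrees for angles, metres for CoM coordinates), so distinct seeds
    give distinct, C1-smooth coordination patterns.
    """
    registry = registry or build_channel_registry()
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    n = len(registry)
    scales = np.array([config.angle_scale_deg if c.kind == "angle_deg"
                       else config.com_scale_m for c in registry.entries])
    H = config.base_harmonics
    h = np.arange(1, H + 1)
    amplitudes = scales[:, None] * rng.standard_normal((n, H)) / h[None, :]
    phases = rng.uniform(0.0, 2.0 * math.pi, size=(n, H))
    offsets = scales * rng.standard_normal(n)
    shared_amplitudes = config.angle_scale_deg * rng.standard_normal(H) / h
    shared_phases = rng.uniform(0.0, 2.0 * math.pi, size=H)
    trunk_mask = np.array([c.group == "trunk_head" for c in registry.entries])
    return PlayerTemplate(player_id=player_id, offsets=offsets,
                          amplitudes=amplitudes, phases=phases,
                          shared_amplitudes=shared_amplitudes,
                          shared_phases=shared_phases, trunk_mask=trunk_mask,
                          trunk_coupling=config.trunk_coupling)


def smooth_noise(n: int, sd: float, kernel_sd: float, rng: np.random.Generator,
                 columns: int = 1) -> np.ndarray:
    """Stationary smooth Gaussian noise: white noise convolved with a
    Gaussian kernel, rescaled so the marginal SD equals ``sd``."""
    half = max(int(math.ceil(4.0 * kernel_sd)), 1)
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / kernel_sd) ** 2)
    k /= math.sqrt((k ** 2).sum())  # unit output variance for unit white noise
    white = rng.standard_normal((n + 2 * half, columns))
    out = np.empty((n, columns))
    for c in range(columns):
        out[:, c] = np.convolve(white[:, c], k, mode="valid")
    return sd * out


def effect_profile(pct: np.ndarray, windows: Sequence[tuple[float, float]],
                   taper_width_pct: float = 4.0) -> np.ndarray:
    """Unit-amplitude velocity-bump shape over movement percentage.

    Each window ramps with a half-cosine of width ``taper_width_pct``
    centred on the window edge (so the taper extends taper/2 beyond the
    window, well inside the +/-5% confinement margin); a window ending at
    100% keeps full amplitude to the end of the movement.
    """
    pct = np.asarray(pct, dtype=float)
    g = np.zeros_like(pct)
    half = taper_width_pct / 2.0
    for w0, w1 in windows:
        up = np.clip((pct - (w0 - half)) / max(taper_width_pct, 1e-9), 0.0, 1.0)
        rise = 0.5 * (1.0 - np.cos(math.pi * up))
        if w1 >= 100.0:
            fall = np.ones_like(pct)
        else:
            down = np.clip(((w1 + half) - pct) / max(taper_width_pct, 1e-9), 0.0, 1.0)
            fall = 0.5 * (1.0 - np.cos(math.pi * down))
        g = np.maximum(g, rise * fall)
    return g


def _heel_trace(n_frames: int, plant: int, hold: int = 6) -> np.ndarray:
    """Heel height (mm): decelerating descent to just below the 30 mm
    ground threshold exactly at the plant frame, a short flat ground
    phase, then the jump."""
    f = np.arange(n_frames, dtype=float)
    h = np.empty(n_frames)
    pre = f < plant
    h[pre] = 30.0 + 90.0 * ((plant - f[pre]) / max(plant, 1)) ** 2
    ground = (f >= plant) & (f < plant + hold)
    h[ground] = 29.9
    rise = f >= plant + hold
    denom = max(n_frames - plant - hold, 1)
    h[rise] = 29.9 + 600.0 * ((f[rise] - plant - hold) / denom) ** 1.5
    return h


def _wrist_trace(n_frames: int, impact: int) -> np.ndarray:
    """Wrist Y position (mm): smoothly accelerating forward swing with a
    step drop in per-frame displacement at the impact frame, placing the
    global minimum of the second central difference exactly at impact."""
    d = np.empty(n_frames - 1)
    f = np.arange(n_frames - 1, dtype=float)
    pre = f < impact
    d[pre] = 2.0 + 48.0 * (f[pre] / max(impact, 1)) ** 2
    d[~pre] = -5.0
    return np.concatenate([[0.0], np.cumsum(d)])


def generate_trial(template: PlayerTemplate, outcome_label: str,
                   config: SyntheticConfig, rng: np.random.Generator,
                   trial_id: str = "T1") -> RawTrial:
    """Generate one raw trial consistent with the requested outcome label."""
    if outcome_label not in (SUCCESSFUL, FAULTY):
        raise ValueError(f"unknown outcome label {outcome_label!r}")
    lo, hi = config.duration_range_frames
    movement = int(rng.integers(lo, hi + 1))
    plant = config.pre_frames
    impact = plant + movement - 1
    n_frames = impact + 1 + config.post_frames
    fs = config.sampling_rate

    tau = np.arange(n_frames, dtype=float) / max(n_frames - 1, 1)
    angles = template.evaluate(tau)
    registry = build_channel_registry()
    noise_sd = np.array([config.trial_noise_sd_deg if c.kind == "angle_deg"
                         else config.trial_noise_sd_m for c in registry.entries])
    noise = smooth_noise(n_frames, 1.0, config.noise_kernel_sd, rng,
                         columns=len(registry) + 1)
    shared_noise = noise[:, -1]
    noise = noise[:, :-1]
    # trunk/head noise shares a common component, like the base curves
    trunk = np.array([c.group == "trunk_head" for c in registry.entries])
    rho = config.trunk_coupling
    noise[:, trunk] = (math.sqrt(max(1.0 - rho, 0.0)) * noise[:, trunk]
                       + math.sqrt(rho) * shared_noise[:, None])
    angles = angles + noise * noise_sd[None, :]

    if outcome_label == FAULTY:
        upper = registry.indices("upper")
        pct = (np.arange(n_frames) - plant) / max(movement - 1, 1) * 100.0
        bump = effect_profile(np.clip(pct, 0.0, 100.0), config.effect_windows,
                              config.taper_width_pct)
        bump[np.arange(n_frames) < plant] = 0.0
        bump[np.arange(n_frames) > impact] = 0.0
        # integrate the velocity bump so the angle derivative carries it
        extra = np.cumsum(config.resolved_effect_amplitude() * bump) / fs
        angles[:, upper] += extra[:, None]

    heel = _heel_trace(n_frames, plant)
    markers = MarkerTraces(heel_left_z=heel.copy(), heel_right_z=heel.copy(),
                           wrist_y=_wrist_trace(n_frames, impact))

    if outcome_label == FAULTY:
        outcome = OutcomeRecord(
            blocked=bool(rng.random() < config.blocked_prob),
            ball_speed_kmh=float(rng.uniform(25.0, 48.0)),
            touched_block_and_slowed=bool(rng.random() < config.touched_prob),
            landed_out=bool(rng.random() < config.landed_out_prob),
        )
    else:
        outcome = OutcomeRecord(blocked=False,
                                ball_speed_kmh=float(rng.uniform(60.0, 110.0)),
                                touched_block_and_slowed=False, landed_out=False)
    return RawTrial(player_id=template.player_id, trial_id=trial_id,
                    frames=angles, outcome=outcome, sampling_rate=fs,
                    markers=markers, plant_frame=plant, impact_frame=impact)


def generate_cohort(config: Optional[SyntheticConfig] = None
                    ) -> tuple[list[RawTrial], pd.DataFrame]:
    """Generate the full cohort plus its manifest table.

    Each player gets ``trials_per_player`` trials with faulty labels drawn
    at ``fault_probability``; the player at ``no_fault_player_index`` never
    faults, and every other player keeps at least one trial of each label
    (label vectors are redrawn otherwise).
    """
    config = config or SyntheticConfig()
    trials: list[RawTrial] = []
    rows = []
    for p in range(config.n_players):
        player_id = f"P{p + 1:02d}"
        template = generate_player_template(
            np.random.SeedSequence([config.seed, p]), config=config,
            player_id=player_id)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, p, 7919]))
        if p == config.no_fault_player_index:
            labels = [SUCCESSFUL] * config.trials_per_player
        else:
            draws = rng.random(config.trials_per_player) < config.fault_probability
            # with >= 2 trials, keep at least one of each label so every
            # player contributes both condition means
            while config.trials_per_player >= 2 and not (draws.any() and not draws.all()):
                draws = rng.random(config.trials_per_player) < config.fault_probability
            labels = [FAULTY if d else SUCCESSFUL for d in draws]
        for t, label in enumerate(labels):
            trial_id = f"{player_id}_T{t + 1}"
            trial = generate_trial(template, label, config, rng, trial_id=trial_id)
            trials.append(trial)
            rows.append({
                "player_id": player_id,
                "trial_id": trial_id,
                "path": f"{trial_id}.csv",
                "sampling_rate": trial.sampling_rate,
                "blocked": int(trial.outcome.blocked),
                "ball_speed_kmh": trial.outcome.ball_speed_kmh,
                "touched_block_and_slowed": int(trial.outcome.touched_block_and_slowed),
                "landed_out": int(trial.outcome.landed_out),
                "plant_frame": trial.plant_frame,
                "impact_frame": trial.impact_frame,
            })
    return trials, pd.DataFrame(rows)
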