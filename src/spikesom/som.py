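"""Self-organising map engine for coordination-pattern analysis.

The map is a 2D lattice (hexagonal by default) of weight vectors trained
on the pooled per-time-point kinematic state vectors of all movement
sequences.  After training, each 101-sample sequence is represented by
its best-matching-unit (BMU) trajectory across the lattice, and pairs of
sequences are compared by the summed squared lattice distance between
their BMU trajectories:

    D[i, j] = sum_t || BMU_i(t) - BMU_j(t) ||^2,   t = 0..100.

The U-matrix (per-unit mean weight distance to lattice neighbours)
summarises cluster structure on the map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .channels import ChannelRegistry
from .preprocess import SUCCESSFUL, PreprocessedTrial

MapScale = Literal["small", "normal", "big"]
_SCALE_FACTORS = {"small": 0.25, "normal": 1.0, "big": 4.0}

SegmentSubset = Literal["whole", "lower", "upper"]
SignalSet = Literal["both", "angles_only", "velocities_only"]


@dataclass
class SOMConfig:
    """Training configuration.  The defaults are the applied options of the
    sensitivity analysis: big map (4x base size), Gaussian neighbourhood,
    hexagonal lattice, sequential training."""

    map_scale: MapScale = "big"
    neighbourhood: str = "gaussian"
    lattice: str = "hexagonal"
    training: str = "sequential"
    phase1_epochs: int = 5
    phase2_epochs: int = 10
    phase1_alpha: tuple[float, float] = (0.5, 0.05)
    phase2_alpha: tuple[float, float] = (0.05, 0.01)
    phase1_sigma: Optional[tuple[float, float]] = None  # None -> max(rows, cols)/4 -> 1
    phase2_sigma: tuple[float, float] = (3.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.map_scale not in _SCALE_FACTORS:
            raise ValueError(f"unknown map_scale {self.map_scale!r}")
        if self.neighbourhood not in ("gaussian", "cutoff_gaussian", "bubble", "epanechikov"):
            raise ValueError(f"unknown neighbourhood {self.neighbourhood!r}")
        if self.lattice not in ("hexagonal", "rectangular"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.training not in ("sequential", "batch"):
            raise ValueError(f"unknown training type {self.training!r}")


@dataclass
class InputMatrix:
    """Range-normalised input sequences for SOM training.

    ``sequences`` is an (n, 101, d) array; every non-constant channel
    attains -1 and 1 somewhere in the pooled data.  The per-channel
    min/max of the raw data are stored so the transform can be inverted.
    """

    sequences: np.ndarray
    ids: list[str]
    channel_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    @property
    def n_sequences(self) -> int:
        return self.sequences.shape[0]

    @property
    def dim(self) -> int:
        return self.sequences.shape[2]

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant (zero-range) channels."""
        return self.maxs == self.mins

    def pooled(self) -> np.ndarray:
        """All time-point vectors stacked into an (n * 101, d) matrix."""
        return self.sequences.reshape(-1, self.dim)

    def invert(self, normalised: np.ndarray) -> np.ndarray:
        """Map normalised values back to the original units (constant
        channels return their constant value)."""
        span = np.where(self.degenerate, 1.0, self.maxs - self.mins)
        return (np.asarray(normalised) + 1.0) / 2.0 * span + self.mins


def normalize_range(raw_sequences: Sequence[np.ndarray], ids: Optional[list[str]] = None,
                    channel_names: Optional[list[str]] = None) -> InputMatrix:
    """Normalise each channel to [-1, 1] using the pooled min/max across
    all sequences and time points.  Constant channels map to 0."""
    arr = np.asarray(raw_sequences, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a list of equally-shaped (T, d) sequences")
    n, _, d = arr.shape
    mins = arr.min(axis=(0, 1))
    maxs = arr.max(axis=(0, 1))
    span = maxs - mins
    safe = np.where(span == 0, 1.0, span)
    norm = 2.0 * (arr - mins) / safe - 1.0
    norm[:, :, span == 0] = 0.0
    if ids is None:
        ids = [f"seq{i}" for i in range(n)]
    if channel_names is None:
        channel_names = [f"ch{k}" for k in range(d)]
    return InputMatrix(sequences=norm, ids=list(ids), channel_names=list(channel_names),
                       mins=mins, maxs=maxs)


def assemble_input_vectors(trials: Sequence[PreprocessedTrial], registry: ChannelRegistry,
                           subset: SegmentSubset = "whole",
                           signals: SignalSet = "both") -> InputMatrix:
    """Build the normalised SOM input from condition-mean trials.

    Each sequence concatenates the selected angle (psi) columns followed
    by the matching velocity (phi) columns, so the state dimension is
    2 x channels for coordination analyses and 1 x channels for ROM-only
    or velocity-only analyses.  Limb subsets exclude the CoM channels.
    """
    if subset not in ("whole", "lower", "upper"):
        raise ValueError(f"unknown segment subset {subset!r}")
    cols = registry.indices(subset)
    if signals == "both":
        raws, names = [], []
        for t in trials:
            raws.append(np.hstack([t.psi[:, cols], t.phi[:, cols]]))
        names = [registry.names[c] + "_psi" for c in cols] + \
                [registry.names[c] + "_phi" for c in cols]
    elif signals == "angles_only":
        raws = [t.psi[:, cols] for t in trials]
        names = [registry.names[c] + "_psi" for c in cols]
    elif signals == "velocities_only":
        raws = [t.phi[:, cols] for t in trials]
        names = [registry.names[c] + "_phi" for c in cols]
    else:
        raise ValueError(f"unknown signal set {signals!r}")
    ids = [sequence_id(t) for t in trials]
    return normalize_range(raws, ids=ids, channel_names=names)


def sequence_id(trial: PreprocessedTrial) -> str:
    suffix = "succ" if trial.label == SUCCESSFUL else "fault"
    return f"{trial.player_id}_{suffix}"


def default_grid(n_samples: int, data: Optional[np.ndarray] = None,
                 map_scale: MapScale = "big") -> tuple[int, int]:
    """Heuristic lattice dimensions.

    The base unit count is ceil(5 * sqrt(n_samples)) (n_samples = pooled
    time-point vectors), scaled by 1/4, 1 or 4; the side ratio follows
    sqrt(lambda1 / lambda2) of the two largest data covariance
    eigenvalues (square grid when the covariance is degenerate).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    units = _SCALE_FACTORS[map_scale] * math.ceil(5.0 * math.sqrt(n_samples))
    ratio = 1.0
    if data is not None:
        data = np.asarray(data, dtype=float)
        if data.ndim == 2 and data.shape[0] > 1 and data.shape[1] >= 2:
            eigvals = np.sort(np.linalg.eigvalsh(np.cov(data, rowvar=False)))[::-1]
            if eigvals[1] > 1e-12 * max(eigvals[0], 1.0):
                ratio = math.sqrt(eigvals[0] / eigvals[1])
    rows = max(1, round(math.sqrt(units * ratio)))
    cols = max(1, round(units / rows))
    return rows, cols


def lattice_coordinates(rows: int, cols: int, lattice: str = "hexagonal") -> np.ndarray:
    """Unit positions in map space with nearest-neighbour distance 1.

    Hexagonal: odd rows are offset by 0.5 and row spacing is sqrt(3)/2,
    so each interior unit has six equidistant neighbours."""
    r, c = np.divmod(np.arange(rows * cols), cols)
    if lattice == "hexagonal":
        x = c + 0.5 * (r % 2)
        y = r * (math.sqrt(3.0) / 2.0)
    elif lattice == "rectangular":
        x, y = c.astype(float), r.astype(float)
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    return np.column_stack([x, y]).astype(float)


@dataclass
class SOMGrid:
    """A lattice of prototype (weight) vectors."""

    rows: int
    cols: int
    weights: np.ndarray
    lattice: str = "hexagonal"
    lattice_xy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.rows * self.cols:
            raise ValueError("weights row count must equal rows * cols")
        if self.lattice_xy is None:
            self.lattice_xy = lattice_coordinates(self.rows, self.cols, self.lattice)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def lattice_sq_distances(self) -> np.ndarray:
        """(n_units, n_units) squared map-space distances."""
        diff = self.lattice_xy[:, None, :] - self.lattice_xy[None, :, :]
        return (diff ** 2).sum(axis=2)

    def neighbour_lists(self) -> list[np.ndarray]:
        """Indices of units at lattice distance 1 from each unit."""
        d2 = self.lattice_sq_distances()
        return [np.flatnonzero(np.abs(d2[u] - 1.0) < 1e-9) for u in range(self.n_units)]


def init_linear(data: np.ndarray, rows: int, cols: int,
                lattice: str = "hexagonal") -> SOMGrid:
    """Deterministic initialisation: weights span the plane of the first
    two principal components, linearly spaced over the lattice."""
    data = np.asarray(data, dtype=float)
    mean = data.mean(axis=0)
    centred = data - mean
    # SVD-based PCA; deterministic sign fix on the leading loadings
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    sd = s / math.sqrt(max(data.shape[0] - 1, 1))
    n_comp = min(2, vt.shape[0], data.shape[1])
    for k in range(n_comp):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] = -vt[k]
    grid_r = np.linspace(-1.0, 1.0, rows) if rows > 1 else np.zeros(1)
    grid_c = np.linspace(-1.0, 1.0, cols) if cols > 1 else np.zeros(1)
    rr, cc = np.meshgrid(grid_r, grid_c, indexing="ij")
    weights = np.tile(mean, (rows * cols, 1))
    axes = [cc.ravel(), rr.ravel()]  # columns follow PC1, rows PC2
    for k in range(n_comp):
        weights += np.outer(axes[k], sd[k] * vt[k])
    return SOMGrid(rows=rows, cols=cols, weights=weights, lattice=lattice)


def _neighbourhood(kind: str, lat_d2: np.ndarray, sigma: float) -> np.ndarray:
    if kind == "gaussian":
        return np.exp(-lat_d2 / (2.0 * sigma * sigma))
    if kind == "cutoff_gaussian":
        h = np.exp(-lat_d2 / (2.0 * sigma * sigma))
        h[lat_d2 > sigma * sigma] = 0.0
        return h
    if kind == "bubble":
        return (lat_d2 <= sigma * sigma).astype(float)
    if kind == "epanechikov":
        return np.maximum(0.0, 1.0 - lat_d2 / (sigma * sigma))
    raise ValueError(f"unknown neighbourhood {kind!r}")


def find_bmu(grid: SOMGrid, vector: np.ndarray) -> int:
    """Index of the unit with the smallest Euclidean weight distance
    (ties break toward the lowest unit index)."""
    vector = np.asarray(vector, dtype=float)
    d2 = ((grid.weights - vector) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def quantization_error(grid: SOMGrid, samples: np.ndarray) -> float:
    """Mean Euclidean distance from samples to their BMUs."""
    samples = np.asarray(samples, dtype=float)
    d2 = ((samples[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def train_sequential(grid: SOMGrid, inputs: InputMatrix, config: SOMConfig) -> SOMGrid:
    """Two-phase sequential (online) Kohonen training.

    Per step, the BMU c of a sample x is found and every unit j moves
    toward x by alpha(t) * h_cj(t), with h the neighbourhood kernel on
    lattice distance.  Phase 1 orders the map with a wide, shrinking
    radius and high learning rate; phase 2 fine-tunes with a narrow
    radius.  Sample order is reshuffled each pass with the config seed,
    so training is bit-reproducible.
    """
    X = inputs.pooled()
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")
    if X.shape[1] != grid.dim:
        raise ValueError(f"input dimension {X.shape[1]} != grid dimension {grid.dim}")
    if config.training == "batch":
        return _train_batch(grid, X, config)
    rng = np.random.default_rng(config.seed)
    weights = grid.weights.copy()
    lat_d2 = grid.lattice_sq_distances()
    sigma1 = config.phase1_sigma or (max(grid.rows, grid.cols) / 4.0, 1.0)
    phases = [(config.phase1_epochs, config.phase1_alpha, sigma1),
              (config.phase2_epochs, config.phase2_alpha, config.phase2_sigma)]
    n = X.shape[0]
    for epochs, (a0, a1), (s0, s1) in phases:
        total = max(epochs * n - 1, 1)
        step = 0
        for _ in range(epochs):
            order = rng.permutation(n)
            for idx in order:
                frac = step / total
                alpha = a0 + (a1 - a0) * frac
                sigma = max(s0 + (s1 - s0) * frac, 1e-3)
                x = X[idx]
                c = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
                h = _neighbourhood(config.neighbourhood, lat_d2[c], sigma)
                weights += (alpha * h)[:, None] * (x - weights)
                step += 1
    return SOMGrid(rows=grid.rows, cols=grid.cols, weights=weights,
                   lattice=grid.lattice, lattice_xy=grid.lattice_xy)


def _train_batch(grid: SOMGrid, X: np.ndarray, config: SOMConfig) -> SOMGrid:
    """Batch training: each epoch replaces every weight by the
    neighbourhood-weighted mean of the samples (Voronoi-mean update)."""
    weights = grid.weights.copy()
    lat_d2 = grid.lattice_sq_distances()
    sigma1 = config.phase1_sigma or (max(grid.rows, grid.cols) / 4.0, 1.0)
    schedule = (list(np.linspace(*sigma1, max(config.phase1_epochs, 1)))
                + list(np.linspace(*config.phase2_sigma, max(config.phase2_epochs, 1))))
    for sigma in schedule:
        d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
        bmus = d2.argmin(axis=1)
        H = _neighbourhood(config.neighbourhood, lat_d2, max(sigma, 1e-3))
        w_num = H[bmus].T @ X
        w_den = H[bmus].sum(axis=0)
        nonzero = w_den > 0
        weights[nonzero] = w_num[nonzero] / w_den[nonzero, None]
    return SOMGrid(rows=grid.rows, cols=grid.cols, weights=weights,
                   lattice=grid.lattice, lattice_xy=grid.lattice_xy)


def train_som(inputs: InputMatrix, config: Optional[SOMConfig] = None) -> SOMGrid:
    """Convenience wrapper: size the lattice, linearly initialise, train."""
    config = config or SOMConfig()
    X = inputs.pooled()
    rows, cols = default_grid(X.shape[0], X, config.map_scale)
    grid = init_linear(X, rows, cols, config.lattice)
    return train_sequential(grid, inputs, config)


@dataclass
class BMUTrajectory:
    """Time-ordered lattice positions of one sequence's BMUs."""

    sequence_id: str
    positions: np.ndarray   # (101, 2) lattice coordinates
    unit_indices: np.ndarray  # (101,) unit indices


def bmu_trajectory(grid: SOMGrid, sequence: np.ndarray,
                   sequence_id: str = "") -> BMUTrajectory:
    """BMU lattice position for every time point of a normalised sequence."""
    sequence = np.asarray(sequence, dtype=float)
    d2 = ((sequence[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=2)
    units = d2.argmin(axis=1)
    return BMUTrajectory(sequence_id=sequence_id,
                         positions=grid.lattice_xy[units].copy(),
                         unit_indices=units.astype(int))


@dataclass
class UMatrix:
    """Per-unit mean weight-space distance to lattice neighbours."""

    rows: int
    cols: int
    values: np.ndarray

    def as_grid(self) -> np.ndarray:
        return self.values.reshape(self.rows, self.cols)


def compute_umatrix(grid: SOMGrid) -> UMatrix:
    values = np.empty(grid.n_units)
    for u, nbrs in enumerate(grid.neighbour_lists()):
        if nbrs.size == 0:
            values[u] = 0.0
            continue
        diffs = grid.weights[nbrs] - grid.weights[u]
        values[u] = np.sqrt((diffs ** 2).sum(axis=1)).mean()
    return UMatrix(rows=grid.rows, cols=grid.cols, values=values)


def trajectory_distance(a: BMUTrajectory, b: BMUTrajectory,
                        grid: Optional[SOMGrid] = None,
                        space: str = "lattice") -> float:
    """Summed squared distance between two BMU trajectories.

    ``space='lattice'`` (default) compares lattice coordinates, so the
    value reflects map-space separation; ``space='weight'`` compares the
    BMU weight vectors instead (requires ``grid``).
    """
    if a.positions.shape[0] != b.positions.shape[0]:
        raise ValueError("trajectory length mismatch")
    if space == "lattice":
        return float(((a.positions - b.positions) ** 2).sum())
    if space == "weight":
        if grid is None:
            raise ValueError("weight-space distance requires the grid")
        wa, wb = grid.weights[a.unit_indices], grid.weights[b.unit_indices]
        return float(((wa - wb) ** 2).sum())
    raise ValueError(f"unknown space {space!r}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise BMU-trajectory distance matrix."""

    values: np.ndarray
    ids: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_distance_matrix(trajectories: Sequence[BMUTrajectory],
                             grid: Optional[SOMGrid] = None,
                             space: str = "lattice") -> DistanceMatrix:
    n = len(trajectories)
    if n < 2:
        raise ValueError("need at least 2 trajectories")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = trajectory_distance(trajectories[i], trajectories[j],
                                                    grid=grid, space=space)
    return DistanceMatrix(values=D, ids=[t.sequence_id for t in trajectories])
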