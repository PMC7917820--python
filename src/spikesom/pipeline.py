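"""End-to-end orchestration of the coordination analysis.

``run_analysis`` preprocesses a cohort, forms per-player condition means,
then runs nine SOM analyses ({coordination, ROM-only, velocity-only} x
{whole body, lower limb, upper limb}): range normalisation, SOM
training, BMU trajectories, the pairwise trajectory-distance matrix and
an average-linkage dendrogram.  Independently, a two-sample SPM compares
the group-averaged normalised velocity waveforms of successful vs faulty
condition means for each channel group.  All artifacts are serialised as
plain-text CSV/TSV/Newick/JSON and the run is deterministic under a
fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as sio
from .channels import ChannelRegistry, build_channel_registry
from .cluster import Dendrogram, agglomerate, dendrogram_to_newick
from .preprocess import (FAULTY, SUCCESSFUL, PreprocessedTrial, condition_means,
                         preprocess_trial)
from .som import (BMUTrajectory, DistanceMatrix, InputMatrix, SOMConfig, SOMGrid,
                  UMatrix, assemble_input_vectors, bmu_trajectory,
                  compute_umatrix, pairwise_distance_matrix, train_som)
from .spm import SPMResult, spm_ttest2

SIGNAL_SETS = ("both", "angles_only", "velocities_only")
SUBSETS = ("whole", "lower", "upper")


@dataclass
class SOMAnalysis:
    """Artifacts of one (signal set, segment subset) SOM analysis."""

    signals: str
    subset: str
    inputs: InputMatrix
    grid: SOMGrid
    umatrix: UMatrix
    trajectories: list[BMUTrajectory]
    distances: DistanceMatrix
    dendrogram: Dendrogram


@dataclass
class AnalysisBundle:
    """Everything one pipeline run produces."""

    analyses: dict[tuple[str, str], SOMAnalysis]
    spm: dict[str, SPMResult]
    seed: int
    config: dict
    condition_mean_ids: list[str] = field(default_factory=list)


def velocity_group_fields(means: list[PreprocessedTrial], registry: ChannelRegistry,
                          subset: str) -> tuple[np.ndarray, np.ndarray]:
    """Channel-averaged normalised velocity fields split by outcome label.

    Returns (successful, faulty) arrays of shape (players, 101): each row
    is the mean over the subset's channels of the [-1, 1]-normalised
    angular-velocity waveforms of one condition mean.
    """
    inputs = assemble_input_vectors(means, registry, subset=subset,
                                    signals="velocities_only")
    fields = inputs.sequences.mean(axis=2)
    labels = [t.label for t in means]
    a = fields[[i for i, l in enumerate(labels) if l == SUCCESSFUL]]
    b = fields[[i for i, l in enumerate(labels) if l == FAULTY]]
    return a, b


def run_analysis(manifest_path: str | Path,
                 out_dir: Optional[str | Path] = None,
                 som_config: Optional[SOMConfig] = None,
                 alpha: float = 0.05,
                 linkage: str = "average",
                 seed: int = 0,
                 signal_sets: tuple[str, ...] = SIGNAL_SETS,
                 subsets: tuple[str, ...] = SUBSETS,
                 filter_cutoff_hz: Optional[float] = 10.0) -> AnalysisBundle:
    """Run the full pipeline on a cohort manifest.

    Every SOM analysis derives its training seed deterministically from
    ``seed`` and its position, so two runs with the same inputs and seed
    produce byte-identical artifacts.
    """
    registry = build_channel_registry()
    som_config = som_config or SOMConfig()
    t0 = time.perf_counter()
    log: list[str] = []

    raws = sio.load_cohort(manifest_path, registry)
    if not raws:
        raise ValueError(f"manifest {manifest_path} lists no trials")
    trials = [preprocess_trial(r, filter_cutoff_hz=filter_cutoff_hz) for r in raws]
    means = condition_means(trials)
    both = {t.player_id for t in means if t.label == SUCCESSFUL} & \
           {t.player_id for t in means if t.label == FAULTY}
    if len(both) < 2:
        raise ValueError("degenerate cohort: need >= 2 players with both "
                         "successful and faulty condition means")
    log.append(f"preprocess: {len(trials)} trials -> {len(means)} condition means "
               f"({time.perf_counter() - t0:.2f}s)")

    analyses: dict[tuple[str, str], SOMAnalysis] = {}
    for idx, signals in enumerate(signal_sets):
        for jdx, subset in enumerate(subsets):
            t1 = time.perf_counter()
            inputs = assemble_input_vectors(means, registry, subset=subset,
                                            signals=signals)
            cfg = replace(som_config, seed=int(seed) * 100 + idx * 10 + jdx)
            grid = train_som(inputs, cfg)
            trajs = [bmu_trajectory(grid, inputs.sequences[i], inputs.ids[i])
                     for i in range(inputs.n_sequences)]
            dm = pairwise_distance_matrix(trajs)
            dend = agglomerate(dm, linkage=linkage)
            analyses[(signals, subset)] = SOMAnalysis(
                signals=signals, subset=subset, inputs=inputs, grid=grid,
                umatrix=compute_umatrix(grid), trajectories=trajs,
                distances=dm, dendrogram=dend)
            log.append(f"som {signals}/{subset}: grid {grid.rows}x{grid.cols}, "
                       f"d={inputs.dim} ({time.perf_counter() - t1:.2f}s)")

    spm_results: dict[str, SPMResult] = {}
    for subset in subsets:
        a, b = velocity_group_fields(means, registry, subset)
        spm_results[subset] = spm_ttest2(a, b, alpha=alpha)
        log.append(f"spm {subset}: threshold {spm_results[subset].threshold:.3f}, "
                   f"{len(spm_results[subset].clusters)} cluster(s)")

    config_echo = {
        "alpha": alpha, "linkage": linkage, "seed": int(seed),
        "filter_cutoff_hz": filter_cutoff_hz,
        "som": {"map_scale": som_config.map_scale,
                "neighbourhood": som_config.neighbourhood,
                "lattice": som_config.lattice,
                "training": som_config.training,
                "phase1_epochs": som_config.phase1_epochs,
                "phase2_epochs": som_config.phase2_epochs},
    }
    bundle = AnalysisBundle(analyses=analyses, spm=spm_results, seed=int(seed),
                            config=config_echo,
                            condition_mean_ids=[f"{m.player_id}_"
                                                f"{'succ' if m.label == SUCCESSFUL else 'fault'}"
                                                for m in means])
    if out_dir is not None:
        write_bundle(bundle, out_dir, log)
    return bundle


def write_bundle(bundle: AnalysisBundle, out_dir: str | Path,
                 log: Optional[list[str]] = None) -> None:
    """Serialise all artifacts; numeric files use repr-exact formatting so
    reruns with the same seed are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index: dict[str, dict] = {"analyses": {}, "spm": {}}
    for (signals, subset), an in bundle.analyses.items():
        sub = out / f"{signals}_{subset}"
        sub.mkdir(exist_ok=True)
        np.savetxt(sub / "umatrix.csv", an.umatrix.as_grid(), fmt="%.17g", delimiter=",")
        with open(sub / "bmu_trajectories.csv", "w") as fh:
            fh.write("sequence_id,t,x,y\n")
            for tr in an.trajectories:
                for t, (x, y) in enumerate(tr.positions):
                    fh.write(f"{tr.sequence_id},{t},{x!r},{y!r}\n")
        with open(sub / "distances.tsv", "w") as fh:
            fh.write("id\t" + "\t".join(an.distances.ids) + "\n")
            for i, row_id in enumerate(an.distances.ids):
                fh.write(row_id + "\t"
                         + "\t".join(repr(float(v)) for v in an.distances.values[i]) + "\n")
        (sub / "dendrogram.nwk").write_text(dendrogram_to_newick(an.dendrogram) + "\n")
        with open(sub / "merges.csv", "w") as fh:
            fh.write("left,right,height,count\n")
            for m in an.dendrogram.merges:
                fh.write(f"{m.left},{m.right},{m.height!r},{m.count}\n")
        index["analyses"][f"{signals}_{subset}"] = {
            "dir": f"{signals}_{subset}",
            "grid": [an.grid.rows, an.grid.cols],
            "dim": an.inputs.dim,
            "n_sequences": an.inputs.n_sequences,
        }
    for subset, res in bundle.spm.items():
        path = out / f"spm_{subset}.json"
        with open(path, "w") as fh:
            json.dump(res.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        index["spm"][subset] = path.name
    index["seed"] = bundle.seed
    index["config"] = bundle.config
    index["condition_means"] = bundle.condition_mean_ids
    index["config_hash"] = hashlib.sha256(
        json.dumps(bundle.config, sort_keys=True).encode()).hexdigest()[:16]
    with open(out / "bundle.json", "w") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if log:
        (out / "log.txt").write_text("\n".join(log) + "\n")
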