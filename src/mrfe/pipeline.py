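"""Iterative pose-prediction loop over pluggable MD backends.

Each iteration trains the encoder–decoder network on every MD-evaluated
pose, scores the remaining docked poses through its energetic and
geometric channels, selects the top poses per compound, sends the new
selections to the MD backend, and folds the results back into the training
set.  The loop terminates when it can no longer propose a top pose that
has not already been simulated.  LIE coefficients are frozen throughout —
the network predicts observables, never refits the regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

from . import ann
from .lie import LIEParams, ReplicaObservables, replica_dg
from .structures import MolecularComplex
from .voxel import GridSpec, VoxelMap, voxel_similarity, voxelize

__all__ = [
    "PoseRecord",
    "MDBackend",
    "CommandMDBackend",
    "IterationLog",
    "combine_scores",
    "iterate",
    "rank_poses",
]

SOURCE_DOCKING = "docking"
SOURCE_MD = "md-evaluated"


class MDBackend(Protocol):
    """Contract for MD engines: deterministic under a fixed seed."""

    def evaluate(
        self, pose: "PoseRecord"
    ) -> tuple[list[MolecularComplex], list[ReplicaObservables]]:
        ...


@dataclass
class PoseRecord:
    """One docked pose of one compound, possibly MD-evaluated."""

    compound_id: str
    pose_id: str
    complex: MolecularComplex
    source: str = SOURCE_DOCKING
    scores: Optional[tuple[float, float]] = None  # (energetic, geometric)
    lie_observed: Optional[np.ndarray] = None  # mean 5-vector over replicas
    replica_obs: list[ReplicaObservables] = field(default_factory=list)
    post_md: list[MolecularComplex] = field(default_factory=list)
    failed: bool = False

    def __post_init__(self):
        if self.source not in (SOURCE_DOCKING, SOURCE_MD):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == SOURCE_MD and self.lie_observed is None:
            raise ValueError("md-evaluated records must carry lie_observed")

    @property
    def evaluated(self) -> bool:
        return self.source == SOURCE_MD


@dataclass
class IterationLog:
    """Per-iteration record of the loop's selections and training size."""

    selections: list[list[tuple[str, str]]] = field(default_factory=list)
    new_per_iteration: list[int] = field(default_factory=list)
    training_sizes: list[int] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.selections)

    @property
    def productive_iterations(self) -> int:
        """Iterations that sent new poses to the MD backend.  The final
        confirming pass, which proposes nothing new, is not counted — this
        matches the usual reporting of 'converged after N iterations'."""
        return sum(1 for n in self.new_per_iteration if n > 0)


def combine_scores(
    energetic: Sequence[float],
    geometric: Sequence[float],
    method: str = "rank",
    weights: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Combine the two scoring channels into one pose ordering (lower =
    better).

    ``rank`` (default): each pose is ranked per channel (energetic
    ascending — lower ΔG wins; geometric descending — higher similarity
    wins) and the mean rank is returned; ties inherit the stable input
    order.  ``weighted``: weighted sum w_e·energetic − w_g·geometric.
    """
    e = np.asarray(energetic, dtype=float)
    g = np.asarray(geometric, dtype=float)
    if e.shape != g.shape:
        raise ValueError("channel length mismatch")
    if method == "rank":
        rank_e = np.empty(e.size)
        rank_e[np.argsort(e, kind="stable")] = np.arange(e.size)
        rank_g = np.empty(g.size)
        rank_g[np.argsort(-g, kind="stable")] = np.arange(g.size)
        return (rank_e + rank_g) / 2.0
    if method == "weighted":
        return weights[0] * e - weights[1] * g
    raise ValueError(f"unknown method {method!r}")


def _mark_evaluated(pose: PoseRecord, replicas, observables, grid: GridSpec) -> None:
    pose.replica_obs = list(observables)
    pose.post_md = list(replicas)
    pose.lie_observed = np.mean([o.as_vector() for o in observables], axis=0)
    pose.source = SOURCE_MD


def evaluate_pose(pose: PoseRecord, backend: MDBackend, grid: GridSpec) -> bool:
    """Run the backend on a pose; returns False (and flags it) on failure."""
    try:
        replicas, observables = backend.evaluate(pose)
    except Exception as exc:
        warnings.warn(f"backend failed on {pose.compound_id}:{pose.pose_id}: {exc}", stacklevel=2)
        pose.failed = True
        return False
    _mark_evaluated(pose, replicas, observables, grid)
    return True


def _training_examples(
    poses: Sequence[PoseRecord], input_maps: dict, grid: GridSpec
) -> tuple[list[ann.TrainingExample], list[VoxelMap]]:
    examples, references = [], []
    for pose in poses:
        if not pose.evaluated:
            continue
        key = (pose.compound_id, pose.pose_id)
        for comp, obs in zip(pose.post_md, pose.replica_obs):
            tmap = voxelize(comp, grid)
            examples.append(ann.TrainingExample(input_maps[key], tmap, obs.as_vector()))
            references.append(tmap)
    return examples, references


def iterate(
    pose_pool: Sequence[PoseRecord],
    backend: MDBackend,
    ann_config: dict,
    lie_params: LIEParams,
    select_n: int = 2,
    max_iters: int = 5,
    seed: int = 0,
    combine: str = "rank",
    combine_weights: tuple[float, float] = (1.0, 5.0),
    margin: float = 0.0,
) -> tuple[list[PoseRecord], IterationLog]:
    """Run the iterative dock → predict → simulate → retrain loop.

    ``ann_config`` carries: ``spec`` (NetworkSpec), ``grid`` (GridSpec for
    voxelization), and optional ``ga``/``cg``/``mix`` training settings.
    Each iteration (1) trains the network on all MD-evaluated poses,
    (2) scores every pose — evaluated poses from their observed replica
    energies, the rest from network predictions — (3) selects the top
    ``select_n`` per compound by combined score, (4) evaluates the
    selections that are new and enriches the training set.  Terminates
    when every selected pose has already been evaluated, or at
    ``max_iters``.  ``lie_params`` is frozen for the whole run.

    ``combine`` picks the channel-combination rule (see
    :func:`combine_scores`); ``combine_weights`` applies to the
    ``weighted`` rule, whose geometric weight is the energy bonus (kJ/mol)
    awarded per unit of map similarity.  ``margin`` sharpens the "new top
    pose" test: a not-yet-evaluated selection is sent to the backend only
    if its combined score beats the compound's best evaluated pose by more
    than ``margin`` (same units as the combined score), which keeps
    prediction noise from proposing marginal re-runs forever.
    """
    poses = list(pose_pool)
    if not poses:
        raise ValueError("empty pose pool")
    if not any(p.evaluated for p in poses):
        raise ValueError("initial training set is empty (no md-evaluated poses)")
    spec: ann.NetworkSpec = ann_config["spec"]
    grid: GridSpec = ann_config["grid"]
    ga_cfg = ann_config.get("ga")
    cg_cfg = ann_config.get("cg")
    mix = ann_config.get("mix", 1.0)

    input_maps = {(p.compound_id, p.pose_id): voxelize(p.complex, grid) for p in poses}
    compounds = sorted({p.compound_id for p in poses})
    log = IterationLog()

    for it in range(max_iters):
        examples, references = _training_examples(poses, input_maps, grid)
        # constant seed: retraining differs across iterations only through
        # the enriched data, not through fresh initialization noise
        weights, _ = ann.train(
            examples, spec, seed=seed, ga_config=ga_cfg, cg_config=cg_cfg, mix=mix
        )

        for pose in poses:
            if pose.failed:
                continue
            if pose.evaluated:
                energetic = float(
                    np.mean([replica_dg(o, lie_params) for o in pose.replica_obs])
                )
                own_map = voxelize(pose.post_md[0], grid)
                geometric = max(voxel_similarity(own_map, r) for r in references)
            else:
                energetic, geometric = ann.score_pose(
                    weights, spec, input_maps[(pose.compound_id, pose.pose_id)],
                    lie_params, references,
                )
            pose.scores = (energetic, geometric)

        selections: list[tuple[str, str]] = []
        new_selections: list[PoseRecord] = []
        for cid in compounds:
            group = [p for p in poses if p.compound_id == cid and not p.failed]
            if not group:
                continue
            combined = combine_scores(
                [p.scores[0] for p in group], [p.scores[1] for p in group],
                method=combine, weights=combine_weights,
            )
            order = np.argsort(combined, kind="stable")
            eval_scores = [combined[i] for i, p in enumerate(group) if p.evaluated]
            best_eval = min(eval_scores) if eval_scores else np.inf
            for idx in order[:select_n]:
                pose = group[int(idx)]
                selections.append((pose.compound_id, pose.pose_id))
                if not pose.evaluated and combined[int(idx)] < best_eval - margin:
                    new_selections.append(pose)

        log.selections.append(selections)
        log.new_per_iteration.append(len(new_selections))
        log.training_sizes.append(sum(1 for p in poses if p.evaluated))
        if not new_selections:
            log.converged = True
            break
        for pose in new_selections:
            evaluate_pose(pose, backend, grid)
    return poses, log


class CommandMDBackend:
    """MD backend that shells out to a user-supplied script.

    The script is called as ``script <pose.pdb> <output_dir>`` and must
    write ``replica_*.pdb`` end-state structures plus an
    ``observables.tsv`` with one whitespace row per replica
    (u_lig_coul u_lig_lj u_site_coul u_site_lj entropy_s).  This lets a
    real MD engine drive the loop without this package depending on it.
    """

    def __init__(self, command: str):
        self.command = command

    def evaluate(self, pose: PoseRecord):
        import subprocess
        import tempfile
        from pathlib import Path

        from .lie import ReplicaObservables
        from .structures import read_structure, write_structure

        with tempfile.TemporaryDirectory() as tmp:
            tmp_path = Path(tmp)
            pose_file = tmp_path / "pose.pdb"
            pose_file.write_text(write_structure(pose.complex))
            out_dir = tmp_path / "out"
            out_dir.mkdir()
            subprocess.run(
                [self.command, str(pose_file), str(out_dir)], check=True
            )
            replicas = [
                read_structure(p.read_text())
                for p in sorted(out_dir.glob("replica_*.pdb"))
            ]
            observables = []
            for line in (out_dir / "observables.tsv").read_text().splitlines():
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                vals = [float(v) for v in s.split()[:5]]
                observables.append(ReplicaObservables(*vals))
            if len(replicas) != len(observables) or not replicas:
                raise RuntimeError(
                    f"backend script wrote {len(replicas)} structures but "
                    f"{len(observables)} observable rows"
                )
            return replicas, observables


def rank_poses(
    poses: Sequence[PoseRecord],
    combine: str = "rank",
    combine_weights: tuple[float, float] = (1.0, 5.0),
) -> dict[str, list[PoseRecord]]:
    """Final per-compound ordering by combined score (best first)."""
    out: dict[str, list[PoseRecord]] = {}
    for cid in sorted({p.compound_id for p in poses}):
        group = [p for p in poses if p.compound_id == cid and not p.failed and p.scores]
        combined = combine_scores(
            [p.scores[0] for p in group], [p.scores[1] for p in group],
            method=combine, weights=combine_weights,
        )
        order = np.argsort(combined, kind="stable")
        out[cid] = [group[int(i)] for i in order]
    return out
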