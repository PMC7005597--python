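"""Glowworm swarm optimization over rigid-body pose space.

Each agent (glowworm) carries a ligand pose, a luciferin level that tracks
its recent fitness, and an adaptive vision range. At every step agents are
scored, luciferin is updated, each agent probabilistically moves a small
step toward a brighter visible neighbor, and vision ranges adapt toward a
target neighbor count. GSO keeps multiple basins populated simultaneously,
which suits the multi-funnel energy landscape of docking.

Pose space is SE(3); neighborhood distances mix translation (A) and
orientation (quaternion geodesic angle, weighted in A/rad) into one hybrid
metric. Fitness is "higher is better" throughout; energy-like scores are
negated by the scoring layer before they reach the engine.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import _quat
from .restraints import RestraintScorer, RestraintSet, DEFAULT_SATISFACTION_CUTOFF
from .scoring import (
    ScoringContext,
    bias_score,
    score_from_distance_matrix,
    score_pose,
    to_fitness,
)
from .structures import Pose, Structure, apply_pose_to_coords
from .swarms import Glowworm, Swarm


@dataclasses.dataclass
class GSOParams:
    """GSO control parameters.

    The luciferin dynamics (rho, gamma, l0), neighbor target n_t and range
    gain beta follow the standard GSO literature values; step sizes and the
    SE(3) metric weight are docking-specific (A and interpolation fraction).
    """

    rho: float = 0.4  # luciferin decay in (0,1)
    gamma: float = 0.6  # luciferin gain > 0
    l0: float = 5.0  # initial luciferin
    nt: int = 5  # target neighbor count
    beta: float = 0.08  # vision-range gain
    rs: float = 8.0  # max vision range (A-equivalent)
    r0: float = 8.0  # initial vision range <= rs
    translation_step: float = 0.5  # A per move
    rotation_step: float = 0.1  # slerp fraction per move in (0,1]
    steps: int = 100
    rotation_weight: float = 10.0  # A per radian in the hybrid metric

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0,1)")
        if self.gamma <= 0 or self.l0 < 0 or self.beta < 0:
            raise ValueError("invalid luciferin parameters")
        if not 0 < self.r0 <= self.rs:
            raise ValueError("need 0 < r0 <= rs")
        if not 0 < self.rotation_step <= 1:
            raise ValueError("rotation step must be in (0,1]")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")


@dataclasses.dataclass
class SwarmResult:
    swarm_id: int
    glowworms: list[Glowworm]
    best_index: int
    best_per_step: list[float]  # best-so-far fitness, length steps+1

    @property
    def best(self) -> Glowworm:
        return self.glowworms[self.best_index]


def luciferin_update(current: float, fitness: float, params: GSOParams) -> float:
    """l <- (1 - rho) * l + gamma * J.

    Luciferin is a decaying trace of fitness and may go negative on
    energy-like landscapes where every pose scores below zero; clamping it
    at zero would erase the brightness ordering there and freeze the swarm.
    """
    return (1.0 - params.rho) * current + params.gamma * fitness


def update_vision_range(current: float, n_neighbors: int, params: GSOParams) -> float:
    """r <- clamp(r + beta * (n_t - n_neighbors), 0, r_s)."""
    return min(params.rs, max(0.0, current + params.beta * (params.nt - n_neighbors)))


def pose_distance(a: Pose, b: Pose, rotation_weight: float) -> float:
    """Hybrid SE(3) metric: translation distance + weighted geodesic angle."""
    return float(
        np.linalg.norm(a.translation - b.translation)
        + rotation_weight * _quat.geodesic_angle(a.rotation, b.rotation)
    )


def _pairwise_pose_distances(worms: Sequence[Glowworm], w: float) -> np.ndarray:
    t = np.array([g.pose.translation for g in worms])
    q = np.array([g.pose.rotation for g in worms])
    dt = cdist(t, t)
    dots = np.clip(np.abs(q @ q.T), 0.0, 1.0)
    return dt + w * 2.0 * np.arccos(dots)


def select_neighbor(
    index: int,
    worms: Sequence[Glowworm],
    params: GSOParams,
    rng: np.random.Generator,
    distances: np.ndarray | None = None,
) -> int | None:
    """Pick a brighter glowworm within vision range, with probability
    proportional to the luciferin difference; None if none is visible."""
    me = worms[index]
    if distances is None:
        d = np.array(
            [pose_distance(me.pose, g.pose, params.rotation_weight) for g in worms]
        )
    else:
        d = distances[index]
    lum = np.array([g.luciferin for g in worms])
    mask = (d < me.vision_range) & (lum > me.luciferin)
    mask[index] = False
    ids = np.nonzero(mask)[0]
    if len(ids) == 0:
        return None
    weights = lum[ids] - me.luciferin
    return int(rng.choice(ids, p=weights / weights.sum()))


def move(glowworm: Glowworm, target: Glowworm, params: GSOParams) -> Pose:
    """Advance toward the target: a fixed-length translation step along the
    line to the target plus a slerp fraction of the orientation gap.

    The translation step is *not* capped at the gap: a mover closer than one
    step overshoots past its target, exactly as in the original glowworm
    algorithm. The resulting jitter around bright agents is the algorithm's
    local-search mechanism — it is what lets a cluster ratchet downhill past
    the best pose any agent started from.
    """
    gap = target.pose.translation - glowworm.pose.translation
    d = float(np.linalg.norm(gap))
    ang = _quat.geodesic_angle(glowworm.pose.rotation, target.pose.rotation)
    if d < 1e-12 and ang < 1e-12:
        return glowworm.pose
    if d < 1e-12:
        t_new = glowworm.pose.translation.copy()
    else:
        t_new = glowworm.pose.translation + params.translation_step * gap / d
    q_new = _quat.slerp(glowworm.pose.rotation, target.pose.rotation, params.rotation_step)
    return Pose(t_new, q_new)


Objective = Callable[[Pose], "float | tuple[float, float, float]"]


def run_gso(
    glowworms: Sequence[Glowworm],
    objective: Objective,
    params: GSOParams,
    rng: np.random.Generator,
) -> tuple[list[Glowworm], int, list[float]]:
    """Drive a population of glowworms over ``objective`` for params.steps.

    ``objective(pose)`` returns either a fitness or a (fitness, raw score,
    satisfied fraction) triple. An objective failure on a pose marks that
    glowworm with a -inf sentinel for the step and freezes it. Returns the
    final population, the best index and the best-so-far trajectory
    (length steps + 1, non-decreasing).
    """
    worms = list(glowworms)
    n = len(worms)
    best_so_far = -np.inf
    trajectory: list[float] = []
    stale = [True] * n  # only poses that moved need rescoring
    batch = getattr(objective, "batch", None)

    def evaluate() -> None:
        nonlocal best_so_far
        pending = [i for i in range(n) if stale[i]]
        if pending and batch is not None:
            fit, raw, sat = batch([worms[i].pose for i in pending])
            for k, i in enumerate(pending):
                g = worms[i]
                g.fitness, g.raw_score, g.satisfied = (
                    float(fit[k]),
                    float(raw[k]),
                    float(sat[k]),
                )
                stale[i] = False
        else:
            for i in pending:
                g = worms[i]
                try:
                    res = objective(g.pose)
                except Exception as exc:  # scoring failure -> sentinel
                    warnings.warn(
                        f"scoring failed for glowworm {g.id}: {exc}", stacklevel=2
                    )
                    g.fitness = -np.inf
                    stale[i] = False
                    continue
                if isinstance(res, tuple):
                    g.fitness, g.raw_score, g.satisfied = res
                else:
                    g.fitness = float(res)
                stale[i] = False
        finite = [g.fitness for g in worms if np.isfinite(g.fitness)]
        if finite:
            best_so_far = max(best_so_far, max(finite))
        trajectory.append(best_so_far)

    for _ in range(params.steps):
        evaluate()
        for g in worms:
            if np.isfinite(g.fitness):
                g.luciferin = luciferin_update(g.luciferin, g.fitness, params)
            else:
                # failed agents keep decaying so they stop attracting others
                g.luciferin = (1.0 - params.rho) * g.luciferin
        d = _pairwise_pose_distances(worms, params.rotation_weight)
        lum = np.array([g.luciferin for g in worms])
        ranges = np.array([g.vision_range for g in worms])
        visible = (d < ranges[:, None]) & (lum[None, :] > lum[:, None])
        np.fill_diagonal(visible, False)
        n_neighbors = visible.sum(axis=1)
        # snapshot targets before anyone moves: simultaneous update
        new_poses: list[Pose | None] = [None] * n
        for i, g in enumerate(worms):
            if not np.isfinite(g.fitness) or n_neighbors[i] == 0:
                continue
            ids = np.nonzero(visible[i])[0]
            weights = lum[ids] - lum[i]
            j = int(rng.choice(ids, p=weights / weights.sum()))
            new_poses[i] = move(g, worms[j], params)
        for i, g in enumerate(worms):
            if new_poses[i] is not None:
                g.pose = new_poses[i]
                g.moves += 1
                stale[i] = True
            g.vision_range = update_vision_range(g.vision_range, int(n_neighbors[i]), params)
    evaluate()
    finite_best = [
        (g.fitness, i) for i, g in enumerate(worms) if np.isfinite(g.fitness)
    ]
    best_index = max(finite_best)[1] if finite_best else 0
    return worms, best_index, trajectory


def make_docking_objective(
    context: ScoringContext,
    restraints: RestraintSet | None,
    satisfaction_cutoff: float = DEFAULT_SATISFACTION_CUTOFF,
) -> Objective:
    """Objective coupling the pair potential with the restraint bias (S3).

    At every evaluation the raw energy is converted to fitness and biased by
    the fraction of satisfied *active* restraints of the current pose.
    """
    ligand = context.ligand
    lig_coords = ligand.coords
    lig_center = ligand.centroid
    rec_coords = context.receptor.coords
    scorer = None
    if restraints is not None and len(restraints) > 0:
        scorer = RestraintScorer(
            restraints, context.receptor, ligand, cutoff=satisfaction_cutoff
        )

    # when every atom is typed, one distance matrix serves both the energy
    # and the restraint satisfaction
    fused = (
        scorer is not None
        and context._dense
        and len(context.lig_idx) == len(ligand)
        and len(context.rec_idx) == len(context.receptor)
        and np.array_equal(context.lig_idx, np.arange(len(ligand)))
        and np.array_equal(context.rec_idx, np.arange(len(context.receptor)))
    )

    if fused:

        def objective(pose: Pose) -> tuple[float, float, float]:
            coords = apply_pose_to_coords(lig_coords, lig_center, pose)
            d = cdist(coords, rec_coords)
            context.evaluations += 1
            raw = score_from_distance_matrix(context, d)
            fitness = to_fitness(raw)
            s = scorer.fraction_from_matrix(d)
            return bias_score(fitness, s), raw, s

        table = context.table
        edges = table.bin_edges
        cutoff = table.cutoff
        n_pairs = len(context.lig_idx) * len(context.rec_idx)

        def batch(poses: Sequence[Pose]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            w = len(poses)
            stack = np.empty((w, len(lig_coords), len(rec_coords)))
            for k, pose in enumerate(poses):
                coords = apply_pose_to_coords(lig_coords, lig_center, pose)
                stack[k] = cdist(coords, rec_coords)
            context.evaluations += w
            flat = stack.reshape(-1)
            idx = np.flatnonzero(flat < cutoff)
            raw = np.zeros(w)
            if len(idx):
                bins = np.searchsorted(edges, flat[idx], side="right")
                inside = bins < len(edges)
                contrib = context._pair_energies[
                    idx[inside] % n_pairs, bins[inside]
                ]
                raw = np.bincount(
                    idx[inside] // n_pairs, weights=contrib, minlength=w
                )
            fitness = -raw
            s = scorer.fraction_from_matrices(stack)
            biased = np.where(fitness >= 0, fitness * s, fitness * (2.0 - s))
            return biased, raw, s

        objective.batch = batch  # type: ignore[attr-defined]

    else:

        def objective(pose: Pose) -> tuple[float, float, float]:
            coords = apply_pose_to_coords(lig_coords, lig_center, pose)
            raw = score_pose(context, coords)
            fitness = to_fitness(raw)
            s = 1.0 if scorer is None else scorer.fraction(rec_coords, coords)
            return bias_score(fitness, s), raw, s

    return objective


def run_swarm(
    receptor: Structure,
    ligand: Structure,
    swarm: Swarm,
    context: ScoringContext,
    restraints: RestraintSet | None,
    params: GSOParams,
    rng: np.random.Generator,
    satisfaction_cutoff: float = DEFAULT_SATISFACTION_CUTOFF,
) -> SwarmResult:
    """Optimize one swarm's glowworms under the biased potential."""
    if not swarm.glowworms:
        raise ValueError("swarm has no glowworms; run init_glowworms first")
    objective = make_docking_objective(context, restraints, satisfaction_cutoff)
    worms, best_index, trajectory = run_gso(swarm.glowworms, objective, params, rng)
    return SwarmResult(
        swarm_id=swarm.id,
        glowworms=worms,
        best_index=best_index,
        best_per_step=trajectory,
    )
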