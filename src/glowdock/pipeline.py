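"""End-to-end orchestration: setup -> run -> evaluate for one docking case.

These helpers are the programmatic counterpart of the CLI subcommands and
are what the test-bench and the acceptance script drive. A single integer
seed fans out deterministically to per-stage and per-swarm generators
(documented splitting rule below), so results are reproducible and
independent of swarm execution order.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .evaluation import CaseResult, RankedModel, evaluate_case, rank_models
from .gso import GSOParams, SwarmResult, run_swarm
from .restraints import (
    DEFAULT_SATISFACTION_CUTOFF,
    RestraintSet,
)
from .scoring import ScoringContext, ScoringTable
from .structures import Structure
from .swarms import (
    DEFAULT_GLOWWORMS,
    DEFAULT_NUM_SWARMS,
    DEFAULT_SWARMS_PER_RESTRAINT,
    DEFAULT_JITTER_RADIUS,
    Swarm,
    default_surface_distance,
    filter_swarms_by_restraints,
    generate_swarm_centers,
    init_glowworms,
)

_SPLIT_MULTIPLIER = 0x9E3779B1  # golden-ratio hash constant
_SEED_MODULUS = 2**31


def split_seed(seed: int, stream: int) -> int:
    """Deterministic, order-independent sub-seed for stream ``stream``.

    ``sub = (seed + K * (stream + 1)) mod 2^31`` with a golden-ratio
    multiplier K, so per-swarm generators never depend on execution order.
    """
    return int((seed + _SPLIT_MULTIPLIER * (stream + 1)) % _SEED_MODULUS)


@dataclasses.dataclass
class SetupResult:
    swarms: list[Swarm]
    centers_generated: int
    centers_after_filter: int
    surface_distance: float


def setup_case(
    receptor: Structure,
    ligand: Structure,
    restraints: RestraintSet | None,
    seed: int,
    num_swarms: int = DEFAULT_NUM_SWARMS,
    glowworms_per_swarm: int = DEFAULT_GLOWWORMS,
    swarms_per_restraint: int = DEFAULT_SWARMS_PER_RESTRAINT,
    surface_distance: float | None = None,
    jitter_radius: float = DEFAULT_JITTER_RADIUS,
) -> SetupResult:
    """S1 + S2: place swarm centers, filter by receptor restraints, and
    initialize (pre-oriented) glowworm populations."""
    if restraints is not None:
        restraints.validate_against(receptor, ligand)
    if surface_distance is None:
        surface_distance = default_surface_distance(ligand)
    centers = generate_swarm_centers(
        receptor,
        num_swarms,
        surface_distance,
        rng=np.random.default_rng(split_seed(seed, 0)),
    )
    kept = filter_swarms_by_restraints(
        centers, receptor, restraints, swarms_per_restraint
    )
    swarms: list[Swarm] = []
    for sid in kept:
        swarm = Swarm(id=int(sid), center=centers[int(sid)])
        init_glowworms(
            swarm,
            ligand,
            n=glowworms_per_swarm,
            restraints=restraints,
            rng=np.random.default_rng(split_seed(seed, int(sid) + 1)),
            receptor=receptor,
            jitter_radius=jitter_radius,
        )
        swarms.append(swarm)
    return SetupResult(
        swarms=swarms,
        centers_generated=len(centers),
        centers_after_filter=len(kept),
        surface_distance=surface_distance,
    )


def run_case(
    receptor: Structure,
    ligand: Structure,
    swarms: Sequence[Swarm],
    table: ScoringTable,
    restraints: RestraintSet | None,
    params: GSOParams,
    seed: int,
    satisfaction_cutoff: float = DEFAULT_SATISFACTION_CUTOFF,
) -> list[SwarmResult]:
    """Run GSO in every swarm; per-swarm seeds derive from the swarm id, so
    execution order cannot change any result."""
    context = ScoringContext(receptor, ligand, table)
    results = []
    for swarm in swarms:
        rng = np.random.default_rng(split_seed(seed, 100000 + swarm.id))
        results.append(
            run_swarm(
                receptor,
                ligand,
                swarm,
                context,
                restraints,
                params,
                rng,
                satisfaction_cutoff=satisfaction_cutoff,
            )
        )
    return results


def dock_case(
    receptor: Structure,
    ligand: Structure,
    restraints: RestraintSet | None,
    table: ScoringTable,
    seed: int,
    params: GSOParams | None = None,
    **setup_kwargs,
) -> tuple[SetupResult, list[SwarmResult], list[RankedModel]]:
    """Full pipeline for one case: setup, optimize, global ranking."""
    if params is None:
        params = GSOParams()
    setup = setup_case(receptor, ligand, restraints, seed, **setup_kwargs)
    results = run_case(
        receptor, ligand, setup.swarms, table, restraints, params, seed
    )
    return setup, results, rank_models(results)


def dock_and_evaluate(
    label: str,
    receptor: Structure,
    ligand_native: Structure,
    restraints: RestraintSet | None,
    table: ScoringTable,
    seed: int,
    params: GSOParams | None = None,
    max_models: int | None = 50,
    **setup_kwargs,
) -> CaseResult:
    """Dock the (native-frame) ligand from scratch and CAPRI-classify the
    best-ranked models against the native complex."""
    _, _, models = dock_case(
        receptor, ligand_native, restraints, table, seed, params, **setup_kwargs
    )
    return evaluate_case(
        label, receptor, ligand_native, ligand_native, models, max_models=max_models
    )
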