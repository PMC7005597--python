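"""Swarm placement over the receptor surface and glowworm initialization.

A *swarm* is a sampling locus: a point a fixed distance outside the receptor
surface from which a population of glowworm agents (candidate ligand poses)
is optimized. Receptor-side restraints act before sampling by keeping only
the swarms nearest each restraint residue (S1); ligand-side restraints act
by pre-orienting each initial pose so a randomly chosen ligand restraint
faces a randomly chosen receptor anchor (S2). Both steps use active *and*
passive restraints — passivity only exempts a residue from the scoring bias.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree

from . import _quat
from .restraints import RestraintSet
from .structures import Pose, Structure

DEFAULT_NUM_SWARMS = 400
DEFAULT_SWARMS_PER_RESTRAINT = 10
DEFAULT_GLOWWORMS = 200
DEFAULT_JITTER_RADIUS = 2.0  # Angstrom
DEFAULT_SURFACE_MARGIN = 5.0  # added to the ligand bounding radius


@dataclasses.dataclass
class Glowworm:
    """One GSO agent: a ligand pose plus luciferin/vision state."""

    id: int
    pose: Pose
    luciferin: float
    vision_range: float
    fitness: float = -np.inf
    raw_score: float = 0.0
    satisfied: float = 1.0
    moves: int = 0


@dataclasses.dataclass
class Swarm:
    id: int
    center: np.ndarray
    glowworms: list[Glowworm] = dataclasses.field(default_factory=list)


def ligand_bounding_radius(ligand: Structure) -> float:
    return float(np.linalg.norm(ligand.coords - ligand.centroid, axis=1).max())


def default_surface_distance(ligand: Structure) -> float:
    """Swarm-center distance from the receptor surface: the ligand bounding
    radius plus a clearance margin, so initial poses start clash-free."""
    return ligand_bounding_radius(ligand) + DEFAULT_SURFACE_MARGIN


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit directions (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def generate_swarm_centers(
    receptor: Structure,
    num_swarms: int,
    surface_distance: float,
    rng: np.random.Generator | None = None,
    min_spacing: float | None = None,
    oversample: int = 4,
    tolerance: float = 0.5,
) -> np.ndarray:
    """Quasi-uniform swarm centers at ``surface_distance`` from the receptor.

    Directions from an enclosing-sphere spiral are projected iteratively to
    the offset surface (distance to the nearest heavy receptor atom equals
    ``surface_distance``), then pruned to a minimum inter-center spacing
    derived from the requested count. Returns an (n, 3) array; fewer than
    requested centers triggers a warning, not an error.
    """
    if num_swarms < 1:
        raise ValueError("num_swarms must be >= 1")
    heavy = receptor.coords[receptor.heavy_mask()]
    tree = cKDTree(heavy)
    center = heavy.mean(axis=0)
    radius = float(np.linalg.norm(heavy - center, axis=1).max()) + surface_distance
    pts = center + radius * _fibonacci_sphere(num_swarms * oversample)
    for _ in range(25):
        d, i = tree.query(pts)
        anchor = heavy[i]
        v = pts - anchor
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        pts = anchor + surface_distance * v / norms
        d_new, _ = tree.query(pts)
        if np.max(np.abs(d_new - surface_distance)) < 0.05:
            break
    d_final, _ = tree.query(pts)
    ok = np.abs(d_final - surface_distance) <= tolerance
    pts = pts[ok]
    if min_spacing is None:
        r_eff = float(np.mean(np.linalg.norm(pts - center, axis=1)))
        min_spacing = 0.8 * np.sqrt(4 * np.pi * r_eff**2 / num_swarms)
    kept: list[np.ndarray] = []
    for p in pts:
        if all(np.linalg.norm(p - q) >= min_spacing for q in kept):
            kept.append(p)
            if len(kept) == num_swarms:
                break
    if len(kept) < num_swarms:
        warnings.warn(
            f"placed {len(kept)} of {num_swarms} swarm centers at spacing "
            f"{min_spacing:.2f} A",
            stacklevel=2,
        )
    return np.array(kept)


def filter_swarms_by_restraints(
    centers: np.ndarray,
    receptor: Structure,
    restraints: RestraintSet | None,
    swarms_per_restraint: int = DEFAULT_SWARMS_PER_RESTRAINT,
) -> np.ndarray:
    """S1: keep, for each receptor restraint (active or passive), the
    ``swarms_per_restraint`` centers closest to its representative atom.

    Returns the sorted, de-duplicated original center indices; with no
    receptor restraints every center survives.
    """
    centers = np.asarray(centers)
    n = len(centers)
    if restraints is None:
        return np.arange(n)
    rec = restraints.receptor
    if not rec:
        return np.arange(n)
    keep: set[int] = set()
    k = min(swarms_per_restraint, n)
    for r in rec:
        anchor = receptor.coords[receptor.representative_atom_index(r.residue_key)]
        d = np.linalg.norm(centers - anchor, axis=1)
        nearest = np.argsort(d, kind="stable")[:k]
        keep.update(int(i) for i in nearest)
    return np.array(sorted(keep), dtype=int)


def random_point_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    if radius == 0:
        return np.zeros(3)
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        return np.zeros(3)
    return v / n * radius * rng.uniform() ** (1 / 3)


def preorient_ligand(
    pose: Pose,
    swarm_center: np.ndarray,
    receptor: Structure,
    ligand: Structure,
    restraints: RestraintSet,
    rng: np.random.Generator,
) -> Pose:
    """S2: replace the pose orientation using randomly drawn restraint pairs.

    A random ligand restraint is aligned to face a random receptor anchor
    (a receptor restraint residue, active or passive; with none, the
    receptor surface point nearest the swarm center stands in). The
    remaining degree of freedom — the spin about the facing axis — is fixed
    by a *second* randomly drawn restraint pair when both sides offer one,
    so that with informative restraints initial orientations start near the
    implied binding orientation; with only a single pair available the spin
    is uniform random. The translation is untouched.
    """
    lig_restraints = restraints.ligand
    if not lig_restraints:
        raise ValueError("pre-orientation requires at least one ligand restraint")
    rec_restraints = restraints.receptor
    center = np.asarray(swarm_center)

    def rec_anchor(index: int) -> np.ndarray:
        pick = rec_restraints[index]
        return receptor.coords[receptor.representative_atom_index(pick.residue_key)]

    if rec_restraints:
        r1 = int(rng.integers(len(rec_restraints)))
        anchor = rec_anchor(r1)
    else:
        heavy = receptor.coords[receptor.heavy_mask()]
        anchor = heavy[int(np.argmin(np.linalg.norm(heavy - center, axis=1)))]
    l1 = int(rng.integers(len(lig_restraints)))
    latom = ligand.coords[
        ligand.representative_atom_index(lig_restraints[l1].residue_key)
    ]
    v_lig = latom - ligand.centroid
    v_target = anchor - center
    if np.linalg.norm(v_lig) < 1e-9 or np.linalg.norm(v_target) < 1e-9:
        warnings.warn(
            "degenerate pre-orientation vector; keeping random orientation",
            stacklevel=2,
        )
        return pose
    q_align = _quat.align_vectors_quat(v_lig, v_target)
    axis = v_target / np.linalg.norm(v_target)

    spin_angle = None
    if len(rec_restraints) >= 2 and len(lig_restraints) >= 2:
        r2 = int(rng.integers(len(rec_restraints) - 1))
        r2 = r2 + 1 if r2 >= r1 else r2
        l2 = int(rng.integers(len(lig_restraints) - 1))
        l2 = l2 + 1 if l2 >= l1 else l2
        latom2 = ligand.coords[
            ligand.representative_atom_index(lig_restraints[l2].residue_key)
        ]
        v2 = _quat.rotate(q_align, latom2 - ligand.centroid)
        w2 = rec_anchor(r2) - center
        a = v2 - (v2 @ axis) * axis
        b = w2 - (w2 @ axis) * axis
        if np.linalg.norm(a) > 1e-6 and np.linalg.norm(b) > 1e-6:
            spin_angle = float(
                np.arctan2(axis @ np.cross(a, b), float(a @ b))
            )
    if spin_angle is None:
        spin_angle = float(rng.uniform(0.0, 2 * np.pi))
    spin = _quat.from_axis_angle(axis, spin_angle)
    return Pose(pose.translation, _quat.normalize(_quat.multiply(spin, q_align)))


def init_glowworms(
    swarm: Swarm,
    ligand: Structure,
    n: int = DEFAULT_GLOWWORMS,
    restraints: RestraintSet | None = None,
    rng: np.random.Generator | None = None,
    receptor: Structure | None = None,
    jitter_radius: float = DEFAULT_JITTER_RADIUS,
    luciferin0: float = 5.0,
    vision_range0: float | None = None,
) -> list[Glowworm]:
    """Populate a swarm with ``n`` glowworms (200 by default).

    Translations place the ligand centroid at the swarm center plus uniform
    jitter inside ``jitter_radius``; orientations are uniform over rotation
    space unless ligand restraints request pre-orientation.
    """
    if n < 1:
        raise ValueError("need at least one glowworm")
    if rng is None:
        rng = np.random.default_rng(0)
    if vision_range0 is None:
        vision_range0 = 4.0 * max(jitter_radius, 0.5)
    base = np.asarray(swarm.center) - ligand.centroid
    preorient = restraints is not None and len(restraints.ligand) > 0
    if preorient and receptor is None:
        raise ValueError("pre-orientation needs the receptor structure")
    worms: list[Glowworm] = []
    for i in range(n):
        pose = Pose(base + random_point_in_ball(rng, jitter_radius), _quat.random_unit(rng))
        if preorient:
            pose = preorient_ligand(
                pose, swarm.center, receptor, ligand, restraints, rng
            )
        worms.append(
            Glowworm(
                id=i,
                pose=pose,
                luciferin=luciferin0,
                vision_range=vision_range0,
            )
        )
    swarm.glowworms = worms
    return worms
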