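"""Synthetic rigid two-body complexes with known ground truth.

The generator builds two pseudo-protein bodies from reduced 5-atom residues
(N, CA, C, O, CB) on a jittered cubic lattice: a receptor slab carrying a
chiral, shallow binding cavity (an L-tetromino hole over a raised pedestal)
and a matching ligand block nested into it by construction, producing a
native complex with a known interface. This exercises every pipeline stage
— interface detection, scenarios, swarm setup, optimization, scoring and
CAPRI evaluation — without any external structure downloads. The geometry
is deliberately idealized: no real side chains, secondary structure or
sequence realism (see docs/methods.md for what that implies).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy.spatial.distance import cdist

from . import _quat
from .restraints import DEFAULT_INTERFACE_CUTOFF
from .scoring import ScoringContext, ScoringTable, score_pose
from .structures import Atom, Pose, ResidueKey, Structure, apply_pose

#: Residue alphabet of the toy globules; a small subset keeps the synthetic
#: scoring table compact while the restraint syntax stays realistic.
TOY_RESNAMES = ("ALA", "SER", "VAL", "LEU")
TOY_ATOMS = ("N", "CA", "C", "O", "CB")

MIN_CLASH_DISTANCE = 2.5  # A, hard lower bound between partners
MIN_NATIVE_CONTACTS = 3  # residue pairs at the interface cutoff

# local atom offsets from CA, kept within ~1.6 A so lattice spacing controls
# packing density
_TEMPLATE = {
    "N": np.array([-1.25, 0.65, 0.15]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.25, 0.65, -0.15]),
    "O": np.array([1.55, 1.35, 0.60]),
    "CB": np.array([-0.25, -1.05, -0.85]),
}


@dataclasses.dataclass
class ToyComplex:
    receptor: Structure
    ligand: Structure  # bound (native) frame
    native_contacts: list[tuple[ResidueKey, ResidueKey]]
    seed: int


# chiral L-tetromino: no in-plane rotational symmetry and a distinct mirror
# image, so the matching cavity admits exactly one insertion orientation
_L_CELLS = ((0, 0), (1, 0), (2, 0), (2, 1))


def _ligand_lattice(n: int, spacing: float) -> np.ndarray:
    """n points stacked in L-tetromino layers (a chiral block)."""
    pts = []
    for z in itertools.count():
        for ix, iy in _L_CELLS:
            pts.append([ix * spacing, iy * spacing, z * spacing])
            if len(pts) == n:
                return np.array(pts, dtype=float)


def _receptor_lattice(n_target: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Receptor CA points with a binding cavity, plus the cavity-center xy.

    A full bottom layer carries a ring layer with an L-tetromino hole, and a
    raised pedestal sits under the hole: a chiral, deliberately *shallow*
    cavity. The ligand block bottoms out on the pedestal at ring level, so
    most of its native contacts are lateral wall pairs — contacts that a
    pose hovering an Angstrom or two above the native placement still
    keeps, which makes near-native sampling detectable by fnat. The
    straight-in bound orientation is the only insertion that fits. The
    lattice side grows until the topology holds at least ``n_target``
    residues.
    """
    nx = 5
    while 2 * nx * nx - 4 < n_target:
        nx += 1
    o = (nx - 3) // 2
    hole = {(o + ix, o + iy) for ix, iy in _L_CELLS}
    pts = []
    for iy, ix in itertools.product(range(nx), range(nx)):
        pts.append([ix * spacing, iy * spacing, -spacing])  # floor layer
    for iy, ix in itertools.product(range(nx), range(nx)):
        if (ix, iy) not in hole:
            pts.append([ix * spacing, iy * spacing, 0.0])  # ring layer
    for ix, iy in sorted(hole):
        pts.append([ix * spacing, iy * spacing, -spacing + 2.2])  # pedestal
    center = np.array(
        [np.mean([o + ix for ix, _ in _L_CELLS]), np.mean([o + iy for _, iy in _L_CELLS])]
    ) * spacing
    return np.array(pts, dtype=float), center


def _build_globule(
    ca: np.ndarray,
    chain_id: str,
    rng: np.random.Generator,
    jitter: float = 0.25,
    start_resnum: int = 1,
    label: str = "",
) -> Structure:
    ca = ca + rng.uniform(-jitter, jitter, size=ca.shape)
    atoms: list[Atom] = []
    serial = 1
    for i, center in enumerate(ca):
        resname = TOY_RESNAMES[int(rng.integers(len(TOY_RESNAMES)))]
        for name in TOY_ATOMS:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    chain_id=chain_id,
                    residue_number=start_resnum + i,
                    insertion_code="",
                    residue_name=resname,
                    coordinates=center + _TEMPLATE[name],
                )
            )
            serial += 1
    return Structure(atoms, label=label)


def _native_contacts(
    receptor: Structure, ligand: Structure, cutoff: float
) -> list[tuple[ResidueKey, ResidueKey]]:
    d = cdist(receptor.coords, ligand.coords)
    rres = receptor.atom_to_residue_index()
    lres = ligand.atom_to_residue_index()
    rkeys = receptor.residue_keys()
    lkeys = ligand.residue_keys()
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    seen = set()
    for i, j in zip(*np.nonzero(d <= cutoff)):
        pair = (int(rres[i]), int(lres[j]))
        if pair not in seen:
            seen.add(pair)
            pairs.append((rkeys[pair[0]], lkeys[pair[1]]))
    return pairs


def _surrogate_energy(rec_coords: np.ndarray, lig_coords: np.ndarray) -> float:
    """Wiggle-free stand-in for the toy table: counts pairs per distance
    bin with the same weights the table is built from."""
    d = cdist(rec_coords, lig_coords).ravel()
    return float(
        70.0 * np.count_nonzero(d < 3.0)
        - 3.0 * np.count_nonzero((d >= 3.0) & (d < 4.5))
        - 0.2 * np.count_nonzero((d >= 4.5) & (d < 8.0))
        - 0.02 * np.count_nonzero((d >= 8.0) & (d < 15.0))
    )


def _refine_bound(
    receptor: Structure, lig_coords: np.ndarray, max_rounds: int = 60
) -> np.ndarray:
    """Greedy rigid-body descent of the surrogate energy (small translations
    and rotations about the ligand centroid), keeping the clash margin."""
    rec = receptor.coords
    best = lig_coords.copy()
    best_e = _surrogate_energy(rec, best)
    axes = np.eye(3)
    for _ in range(max_rounds):
        improved = False
        candidates = []
        for ax in axes:
            for sign in (1.0, -1.0):
                candidates.append(best + 0.2 * sign * ax)
        center = best.mean(axis=0)
        for ax in axes:
            for sign in (1.0, -1.0):
                q = _quat.from_axis_angle(ax, sign * np.deg2rad(2.0))
                candidates.append(_quat.rotate(q, best - center) + center)
        for cand in candidates:
            if cdist(rec, cand).min() < MIN_CLASH_DISTANCE + 0.4:
                continue
            e = _surrogate_energy(rec, cand)
            if e < best_e - 1e-9:
                best, best_e = cand, e
                improved = True
        if not improved:
            break
    return best


def generate_toy_complex(
    n_residues_receptor: int = 46,
    n_residues_ligand: int = 8,
    seed: int = 0,
) -> ToyComplex:
    """Deterministic synthetic bound complex with a constructed interface.

    The receptor carries a shallow binding cavity; the ligand block is
    lowered into it until just above the clash margin, so the bound pose
    contacts the cavity floor and walls and is the contact-richest rigid
    placement. The result must show at least three residue contacts at
    3.9 A and no inter-molecular heavy-atom distance below 2.5 A. A global
    random rotation and offset (shared by both partners) decorrelates seeds.
    """
    rng = np.random.default_rng(seed)
    rec_ca, cavity_xy = _receptor_lattice(n_residues_receptor, 5.0)
    receptor = _build_globule(rec_ca, "A", rng, label="toy_receptor")
    # slightly tighter ligand lattice widens the cavity clearance, so the
    # bound pose is reachable without sub-Angstrom lateral precision
    lig_ca = _ligand_lattice(n_residues_ligand, 5.0)
    ligand = _build_globule(lig_ca, "B", rng, start_resnum=1, label="toy_ligand")

    # center the ligand block over the cavity and lower it until just above
    # the clash margin
    rec_top = receptor.coords[:, 2].max()
    lig_xy = ligand.coords[:, :2].mean(axis=0)
    lig_bottom = ligand.coords[:, 2].min()
    shift_xy = cavity_xy - lig_xy

    placed = None
    for height in np.arange(6.0, -6.0, -0.1):
        dz = rec_top + height - lig_bottom
        coords = ligand.coords + np.array([shift_xy[0], shift_xy[1], dz])
        if cdist(receptor.coords, coords).min() < MIN_CLASH_DISTANCE + 0.55:
            break
        placed = ligand.with_coords(coords)
    if placed is None:  # pragma: no cover - construction is deterministic
        raise RuntimeError("could not construct a clash-free bound pose")
    placed = ligand.with_coords(_refine_bound(receptor, placed.coords))
    if len(_native_contacts(receptor, placed, DEFAULT_INTERFACE_CUTOFF)) < MIN_NATIVE_CONTACTS:
        raise RuntimeError("bound pose has too few native contacts")

    # shared random frame so seeds differ globally, not just in jitter
    q = _quat.random_unit(rng)
    offset = rng.uniform(-10.0, 10.0, size=3)
    origin = receptor.centroid

    def reframe(mol: Structure) -> Structure:
        return mol.with_coords(_quat.rotate(q, mol.coords - origin) + origin + offset)

    receptor = reframe(receptor)
    placed = reframe(placed)
    contacts = _native_contacts(receptor, placed, DEFAULT_INTERFACE_CUTOFF)
    assert len(contacts) >= MIN_NATIVE_CONTACTS
    assert cdist(receptor.coords, placed.coords).min() >= MIN_CLASH_DISTANCE
    return ToyComplex(
        receptor=receptor, ligand=placed, native_contacts=contacts, seed=seed
    )


@dataclasses.dataclass
class Decoy:
    pose: Pose
    translation_magnitude: float
    rotation_degrees: float


#: (translation A, rotation deg) pairs chosen to straddle the CAPRI class
#: boundaries: exact native, sub-Angstrom, borderline, unambiguous miss.
DEFAULT_PERTURBATION_SCHEDULE = ((0.0, 0.0), (1.0, 5.0), (5.0, 25.0), (20.0, 120.0))


def generate_decoy_set(
    complex_: ToyComplex,
    n_decoys: int,
    schedule=DEFAULT_PERTURBATION_SCHEDULE,
    seed: int = 0,
) -> list[Decoy]:
    """Ligand-pose decoys at controlled perturbation magnitudes.

    Cycles through the schedule; each decoy translates the bound ligand by
    the stated magnitude in a random direction and rotates it about a random
    axis through its centroid by the stated angle.
    """
    rng = np.random.default_rng(seed)
    decoys: list[Decoy] = []
    for k in range(n_decoys):
        mag, deg = schedule[k % len(schedule)]
        if mag == 0.0 and deg == 0.0:
            pose = Pose.identity()
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            axis = rng.normal(size=3)
            q = (
                _quat.IDENTITY.copy()
                if deg == 0.0
                else _quat.from_axis_angle(axis, np.deg2rad(deg))
            )
            pose = Pose(mag * direction, q)
        decoys.append(Decoy(pose=pose, translation_magnitude=mag, rotation_degrees=deg))
    return decoys


def generate_toy_scoring_table(
    seed: int = 0,
    complex_: ToyComplex | None = None,
    n_verification_poses: int = 30,
) -> ScoringTable:
    """Synthetic pair potential with its optimum at native-like contact.

    A firm but climbable repulsive wall below 3.0 A, an attractive well over
    the native contact distances (3.0-4.5 A) and a weak long-range tail to 15 A that
    gives distant swarms a gradient toward the receptor. Pair energies get a
    small seeded perturbation so the table is not perfectly uniform. When a
    complex is supplied, the construction is verified by sampling: the bound
    pose must score strictly below every rigid perturbation of >= 2 A.
    """
    rng = np.random.default_rng(seed)
    tokens = [(res, atom) for res in TOY_RESNAMES for atom in TOY_ATOMS]
    type_index = {tok: i for i, tok in enumerate(tokens)}
    t = len(tokens)
    edges = np.array([3.0, 4.5, 8.0, 15.0])
    base = np.array([70.0, -3.0, -0.2, -0.02])
    energies = np.empty((t, t, len(edges)))
    for i in range(t):
        for j in range(i, t):
            wiggle = 1.0 + 0.1 * rng.uniform(-1, 1, size=len(edges))
            energies[i, j] = energies[j, i] = base * wiggle
    # repulsion must stay repulsive
    energies[:, :, 0] = np.abs(energies[:, :, 0])
    if complex_ is not None:
        # contrastive wells: atom-type pairs seen in native contacts keep
        # the deep well; all other type pairs get a shallow one, so decoy
        # packings that pair different atom types score visibly worse
        d = cdist(complex_.receptor.coords, complex_.ligand.coords)
        native_type_pairs = set()
        rec_atoms = complex_.receptor.atoms
        lig_atoms = complex_.ligand.atoms
        for i, j in zip(*np.nonzero(d < edges[1])):
            ti_ = type_index[(rec_atoms[int(i)].residue_name, rec_atoms[int(i)].name)]
            tj_ = type_index[(lig_atoms[int(j)].residue_name, lig_atoms[int(j)].name)]
            native_type_pairs.add((ti_, tj_))
            native_type_pairs.add((tj_, ti_))
        for i in range(t):
            for j in range(t):
                if (i, j) not in native_type_pairs:
                    energies[i, j, 1] *= 0.25
    table = ScoringTable(
        type_index=type_index, bin_edges=edges, energies=energies, name="toy_dfire"
    )
    if complex_ is not None:
        _verify_bound_optimum(table, complex_, rng, n_verification_poses)
    return table


def _verify_bound_optimum(
    table: ScoringTable,
    complex_: ToyComplex,
    rng: np.random.Generator,
    n_poses: int,
) -> None:
    context = ScoringContext(complex_.receptor, complex_.ligand, table)
    bound = score_pose(context, complex_.ligand.coords)
    for _ in range(n_poses):
        mag = rng.uniform(2.0, 25.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        angle = rng.uniform(0, np.pi)
        pose = Pose(mag * direction, _quat.from_axis_angle(rng.normal(size=3), angle))
        perturbed = score_pose(context, apply_pose(complex_.ligand, pose))
        if bound >= perturbed:
            raise RuntimeError(
                "toy scoring table failed bound-optimum verification: "
                f"bound {bound:.3f} vs perturbed {perturbed:.3f}"
            )
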