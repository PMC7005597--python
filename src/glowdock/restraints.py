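"""Residue restraints: parsing, true-interface computation, restraint
scenarios and restraint-satisfaction of docking poses.

Restraints are residues the user believes to be at (or near) the binding
interface. *Active* restraints participate everywhere: swarm filtering,
ligand pre-orientation and the per-step scoring bias. *Passive* restraints
participate only in the setup steps (filtering and pre-orientation) and are
exempt from the scoring bias.

The *true interface* (TI) of a bound complex is the set of residues with any
atom within 3.9 A of the partner molecule — the LIGPLOT contact convention.
Scenario constructors degrade the TI in controlled ways (halves/quarters of
true residues padded with contiguous false-positive surface patches,
receptor-only variants, a single contacting pair, a single receptor residue)
to emulate incomplete or partially wrong experimental information.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structures import ResidueKey, Structure

DEFAULT_INTERFACE_CUTOFF = 3.9  # Angstrom, any-atom contact
#: Runtime cutoff for counting a restraint as satisfied during optimization.
#: Wider than the interface definition so that near-contact poses already
#: feel a restraint gradient (see docs/methods.md).
DEFAULT_SATISFACTION_CUTOFF = 10.0

SCENARIOS = (
    "TI",
    "TI_50",
    "TI_25",
    "TI_REC",
    "TI_REC_50",
    "TI_REC_25",
    "TI_SINGLE",
    "TI_ONE",
)

_LINE_RE = re.compile(
    r"^(?P<side>[RL])\s+(?P<chain>\S+)\.(?P<resname>[A-Za-z]{3})"
    r"(?P<resnum>-?\d+)(?P<icode>[A-Za-z]?)(?P<passive>\s+passive)?\s*$"
)


class RestraintError(ValueError):
    """Malformed restraint input or restraint/structure mismatch."""


@dataclasses.dataclass(frozen=True)
class Restraint:
    side: str  # "receptor" | "ligand"
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str | None = None
    mode: str = "active"  # "active" | "passive"

    def __post_init__(self):
        if self.side not in ("receptor", "ligand"):
            raise RestraintError(f"unknown restraint side: {self.side!r}")
        if self.mode not in ("active", "passive"):
            raise RestraintError(f"unknown restraint mode: {self.mode!r}")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_active(self) -> bool:
        return self.mode == "active"

    def to_line(self) -> str:
        side = "R" if self.side == "receptor" else "L"
        name = self.residue_name or "UNK"
        icode = self.insertion_code or ""
        suffix = " passive" if self.mode == "passive" else ""
        return f"{side} {self.chain_id}.{name}{self.residue_number}{icode}{suffix}"


class RestraintSet:
    """Active/passive residue restraints for both docking partners."""

    def __init__(
        self,
        restraints: Iterable[Restraint] = (),
        cutoff: float = DEFAULT_INTERFACE_CUTOFF,
    ):
        if cutoff <= 0:
            raise RestraintError("contact cutoff must be positive")
        self.cutoff = float(cutoff)
        self.restraints: list[Restraint] = []
        seen: set[tuple] = set()
        for r in restraints:
            ident = (r.side, r.residue_key)
            if ident in seen:
                raise RestraintError(f"duplicate restraint: {r.to_line()}")
            seen.add(ident)
            self.restraints.append(r)

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def side(self, side: str, active_only: bool = False) -> list[Restraint]:
        return [
            r
            for r in self.restraints
            if r.side == side and (r.is_active or not active_only)
        ]

    @property
    def receptor(self) -> list[Restraint]:
        return self.side("receptor")

    @property
    def ligand(self) -> list[Restraint]:
        return self.side("ligand")

    def residue_keys(self, side: str) -> set[ResidueKey]:
        return {r.residue_key for r in self.side(side)}

    def validate_against(self, receptor: Structure, ligand: Structure) -> None:
        """Every restraint residue must exist in its structure."""
        for r in self.restraints:
            mol = receptor if r.side == "receptor" else ligand
            if not mol.has_residue(r.residue_key):
                raise RestraintError(
                    f"restraint residue not found in {r.side}: {r.to_line()}"
                )
            if r.residue_name is not None:
                actual = mol.residue_name(r.residue_key)
                if actual != r.residue_name:
                    raise RestraintError(
                        f"residue name mismatch for {r.to_line()}: "
                        f"structure has {actual}"
                    )


def parse_restraints(path: str | Path) -> RestraintSet:
    """Parse the plain-text restraint dialect.

    One restraint per line: ``R|L <chain>.<resname><resnum>[icode] [passive]``
    e.g. ``R A.ARG131`` or ``L B.GLU45 passive``. ``#`` comments and blank
    lines are ignored.
    """
    path = Path(path)
    restraints: list[Restraint] = []
    seen: dict[tuple, int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINE_RE.match(line)
        if m is None:
            token = line.split()[0]
            if token not in ("R", "L"):
                raise RestraintError(
                    f"{path.name}:{lineno}: unknown side token {token!r}"
                )
            raise RestraintError(f"{path.name}:{lineno}: unparsable restraint {raw!r}")
        side = "receptor" if m.group("side") == "R" else "ligand"
        r = Restraint(
            side=side,
            chain_id=m.group("chain"),
            residue_number=int(m.group("resnum")),
            insertion_code=m.group("icode") or "",
            residue_name=m.group("resname").upper(),
            mode="passive" if m.group("passive") else "active",
        )
        ident = (r.side, r.residue_key)
        if ident in seen:
            raise RestraintError(
                f"{path.name}:{lineno}: duplicate restraint "
                f"(first defined on line {seen[ident]})"
            )
        seen[ident] = lineno
        restraints.append(r)
    return RestraintSet(restraints)


def write_restraints(
    rset: RestraintSet, path: str | Path, header: Sequence[str] = ()
) -> None:
    lines = [f"# {h}" for h in header]
    lines += [r.to_line() for r in rset]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# True interface
# ---------------------------------------------------------------------------


def _contact_residues(
    query: Structure, partner: Structure, cutoff: float
) -> list[ResidueKey]:
    """Residues of ``query`` with any atom within cutoff of any partner atom."""
    tree = cKDTree(partner.coords)
    hits = tree.query_ball_point(query.coords, r=cutoff)
    keys: list[ResidueKey] = []
    seen: set[ResidueKey] = set()
    for atom, found in zip(query.atoms, hits):
        if found and atom.residue_key not in seen:
            seen.add(atom.residue_key)
            keys.append(atom.residue_key)
    return keys


def compute_true_interface(
    receptor: Structure,
    ligand: Structure,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> RestraintSet:
    """True-interface restraints of a bound complex at ``cutoff`` (default 3.9 A).

    A residue belongs to the interface iff any of its atoms lies within the
    cutoff of any partner atom. All returned restraints are active.
    """
    restraints: list[Restraint] = []
    for side, mol, partner in (
        ("receptor", receptor, ligand),
        ("ligand", ligand, receptor),
    ):
        for key in _contact_residues(mol, partner, cutoff):
            restraints.append(
                Restraint(
                    side=side,
                    chain_id=key[0],
                    residue_number=key[1],
                    insertion_code=key[2],
                    residue_name=mol.residue_name(key),
                )
            )
    if not restraints:
        warnings.warn(
            f"no residue pair within {cutoff} A: empty true interface",
            stacklevel=2,
        )
    return RestraintSet(restraints, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Surface residues and contiguous patches
# ---------------------------------------------------------------------------


def surface_residues(
    structure: Structure,
    neighbor_radius: float = 10.0,
    burial_quantile: float = 0.25,
    max_neighbors: int | None = None,
) -> list[ResidueKey]:
    """Residues ranked most-exposed-first by a burial proxy.

    The proxy is the number of heavy atoms within ``neighbor_radius`` of the
    residue's representative atom (CB, CA for GLY): exposed residues have few
    neighbors. By default the threshold adapts so at least ``burial_quantile``
    of residues qualify (ties included); pass ``max_neighbors`` for a fixed
    threshold instead.
    """
    keys = structure.residue_keys()
    heavy = structure.coords[structure.heavy_mask()]
    tree = cKDTree(heavy)
    reps = np.array(
        [structure.coords[structure.representative_atom_index(k)] for k in keys]
    )
    counts = np.array([len(ix) for ix in tree.query_ball_point(reps, neighbor_radius)])
    if max_neighbors is None:
        order = np.sort(counts)
        k = max(1, int(np.ceil(burial_quantile * len(keys))))
        max_neighbors = int(order[k - 1])
    chosen = [
        (int(c), key) for c, key in zip(counts, keys) if c <= max_neighbors
    ]
    chosen.sort(key=lambda item: (item[0], keys.index(item[1])))
    return [key for _, key in chosen]


def residue_adjacency_connected(
    structure: Structure, keys: Sequence[ResidueKey], radius: float = 8.0
) -> bool:
    """Is the residue set connected under representative-atom adjacency?"""
    if not keys:
        return True
    reps = np.array(
        [structure.coords[structure.representative_atom_index(k)] for k in keys]
    )
    n = len(keys)
    adj = cdist(reps, reps) <= radius
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in np.nonzero(adj[i])[0]:
            if j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    return len(seen) == n


def grow_contiguous_patch(
    structure: Structure,
    seeds: Sequence[ResidueKey],
    target_size: int,
    pool: Sequence[ResidueKey],
    rng: np.random.Generator | None = None,
) -> list[ResidueKey]:
    """Greedily grow a contiguous residue patch from ``seeds``.

    At each step the pool residue whose representative atom is closest to the
    current patch is added, until ``target_size`` residues (seeds included)
    are reached. Ties are broken randomly when an rng is given, else by pool
    order.
    """
    patch = list(seeds)
    if target_size < len(patch):
        raise RestraintError("target size smaller than seed set")
    available = [k for k in pool if k not in set(patch)]
    rep = {
        k: structure.coords[structure.representative_atom_index(k)]
        for k in set(patch) | set(available)
    }
    while len(patch) < target_size:
        if not available:
            raise RestraintError(
                f"candidate pool exhausted: patch reached {len(patch)} of "
                f"{target_size} residues"
            )
        patch_xyz = np.array([rep[k] for k in patch])
        cand_xyz = np.array([rep[k] for k in available])
        dmin = cdist(cand_xyz, patch_xyz).min(axis=1)
        best = dmin.min()
        ties = np.nonzero(dmin <= best + 1e-9)[0]
        pick = int(ties[0] if rng is None else rng.choice(ties))
        patch.append(available.pop(pick))
    return patch


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------


def _keys_to_restraints(
    mol: Structure, side: str, keys: Iterable[ResidueKey]
) -> list[Restraint]:
    return [
        Restraint(
            side=side,
            chain_id=k[0],
            residue_number=k[1],
            insertion_code=k[2],
            residue_name=mol.residue_name(k),
        )
        for k in keys
    ]


def _block(shuffled: list, n_blocks: int, index: int) -> list:
    """index-th of n near-equal contiguous blocks of a shuffled list."""
    edges = np.linspace(0, len(shuffled), n_blocks + 1).astype(int)
    return shuffled[edges[index] : edges[index + 1]]


def _degraded_side(
    mol: Structure,
    side: str,
    ti_keys: list[ResidueKey],
    perm: np.ndarray,
    fraction_blocks: int,
    replicate: int,
    rng: np.random.Generator,
) -> list[Restraint]:
    """Retain one block of a seeded shuffle of the TI, pad with a contiguous
    false-positive surface patch up to the original TI size."""
    if replicate >= fraction_blocks:
        raise RestraintError(
            f"replicate index {replicate} out of range for 1/{fraction_blocks} scenario"
        )
    shuffled = [ti_keys[int(i)] for i in perm]
    retained = _block(shuffled, fraction_blocks, replicate)
    if not retained:
        raise RestraintError("true-interface side too small to subsample")
    n_false = len(ti_keys) - len(retained)
    ti_set = set(ti_keys)
    # every non-TI residue ranked most-exposed-first: small partners may
    # need more than the top surface quantile to fill the decoy patch
    pool = [
        k
        for k in surface_residues(mol, burial_quantile=1.0)
        if k not in ti_set
    ]
    patch = grow_contiguous_patch(
        mol, retained, len(retained) + n_false, pool, rng=rng
    )
    false_keys = [k for k in patch if k not in set(retained)]
    return _keys_to_restraints(mol, side, list(retained) + false_keys)


def closest_contact_pair(
    receptor: Structure, ligand: Structure, cutoff: float
) -> tuple[ResidueKey, ResidueKey]:
    """The receptor/ligand residue pair with the smallest inter-atomic
    distance, required to be a real contact (min distance <= cutoff)."""
    d = cdist(receptor.coords, ligand.coords)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] > cutoff:
        raise RestraintError("no receptor-ligand residue pair in contact")
    return receptor.atoms[int(i)].residue_key, ligand.atoms[int(j)].residue_key


def build_scenario(
    ti: RestraintSet,
    scenario: str,
    receptor: Structure,
    ligand: Structure,
    replicate: int = 0,
    rng: np.random.Generator | None = None,
) -> RestraintSet:
    """Construct one of the eight restraint scenarios from the true interface.

    TI passes the interface through unchanged; TI_50/TI_25 retain a half or a
    quarter of the TI per side (disjoint across replicates for equal
    generator seeds) padded to the original size with contiguous
    false-positive surface patches; TI_REC* restrict to the receptor side;
    TI_SINGLE is the single closest real-contact residue pair; TI_ONE is that
    pair's receptor residue alone.
    """
    if scenario not in SCENARIOS:
        raise RestraintError(f"unknown scenario: {scenario!r}")
    if len(ti) == 0:
        raise RestraintError("true interface is empty")
    if rng is None:
        rng = np.random.default_rng(0)

    rec_keys = [r.residue_key for r in ti.receptor]
    lig_keys = [r.residue_key for r in ti.ligand]

    if scenario == "TI":
        out = list(ti.restraints)
    elif scenario == "TI_REC":
        out = list(ti.receptor)
    elif scenario in ("TI_50", "TI_25"):
        blocks = 2 if scenario == "TI_50" else 4
        # both permutations are drawn before any patch-growth randomness, so
        # equal generator seeds give disjoint retained blocks across replicates
        perm_rec = rng.permutation(len(rec_keys))
        perm_lig = rng.permutation(len(lig_keys))
        out = _degraded_side(
            receptor, "receptor", rec_keys, perm_rec, blocks, replicate, rng
        )
        out += _degraded_side(ligand, "ligand", lig_keys, perm_lig, blocks, replicate, rng)
    elif scenario in ("TI_REC_50", "TI_REC_25"):
        blocks = 2 if scenario == "TI_REC_50" else 4
        perm_rec = rng.permutation(len(rec_keys))
        out = _degraded_side(
            receptor, "receptor", rec_keys, perm_rec, blocks, replicate, rng
        )
    elif scenario in ("TI_SINGLE", "TI_ONE"):
        rkey, lkey = closest_contact_pair(receptor, ligand, ti.cutoff)
        out = _keys_to_restraints(receptor, "receptor", [rkey])
        if scenario == "TI_SINGLE":
            out += _keys_to_restraints(ligand, "ligand", [lkey])
    return RestraintSet(out, cutoff=ti.cutoff)


# ---------------------------------------------------------------------------
# Satisfaction
# ---------------------------------------------------------------------------


class RestraintScorer:
    """Precompiled restraint-satisfaction evaluator for one receptor/ligand
    pair; used at every optimization step and for post-hoc filtering."""

    def __init__(
        self,
        restraints: RestraintSet,
        receptor: Structure,
        ligand: Structure,
        cutoff: float = DEFAULT_SATISFACTION_CUTOFF,
    ):
        restraints.validate_against(receptor, ligand)
        self.cutoff = float(cutoff)
        # concatenated atom indices per side with segment boundaries, so one
        # distance matrix per side covers all restraints of that side
        by_side: dict[str, list[np.ndarray]] = {"receptor": [], "ligand": []}
        for r in restraints:
            if not r.is_active:
                continue
            mol = receptor if r.side == "receptor" else ligand
            by_side[r.side].append(mol.residue_atom_indices(r.residue_key))
        self._segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for side, groups in by_side.items():
            if groups:
                starts = np.cumsum([0] + [len(g) for g in groups[:-1]])
                self._segments[side] = (np.concatenate(groups), starts)
        self._n_active = sum(len(v) for v in by_side.values())

    @property
    def n_active(self) -> int:
        return self._n_active

    def fraction(self, receptor_coords: np.ndarray, ligand_coords: np.ndarray) -> float:
        """Fraction of active restraints with any residue atom within the
        cutoff of any partner atom; 1.0 when there are no active restraints."""
        if self._n_active == 0:
            return 1.0
        satisfied = 0
        for side, (idx, starts) in self._segments.items():
            if side == "receptor":
                own, partner = receptor_coords[idx], ligand_coords
            else:
                own, partner = ligand_coords[idx], receptor_coords
            row_min = cdist(own, partner).min(axis=1)
            per_restraint = np.minimum.reduceat(row_min, starts)
            satisfied += int(np.count_nonzero(per_restraint <= self.cutoff))
        return satisfied / self._n_active

    def fraction_from_matrices(self, distances: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`fraction_from_matrix` over a (poses, ligand
        atom, receptor atom) distance stack."""
        w = distances.shape[0]
        if self._n_active == 0:
            return np.ones(w)
        satisfied = np.zeros(w)
        for side, (idx, starts) in self._segments.items():
            if side == "receptor":
                mins = distances[:, :, idx].min(axis=1)
            else:
                mins = distances[:, idx, :].min(axis=2)
            per_restraint = np.minimum.reduceat(mins, starts, axis=1)
            satisfied += (per_restraint <= self.cutoff).sum(axis=1)
        return satisfied / self._n_active

    def fraction_from_matrix(self, distances: np.ndarray) -> float:
        """Satisfaction from a precomputed (ligand atom, receptor atom)
        distance matrix covering *all* atoms of both molecules in order."""
        if self._n_active == 0:
            return 1.0
        satisfied = 0
        for side, (idx, starts) in self._segments.items():
            if side == "receptor":
                mins = distances[:, idx].min(axis=0)
            else:
                mins = distances[idx, :].min(axis=1)
            per_restraint = np.minimum.reduceat(mins, starts)
            satisfied += int(np.count_nonzero(per_restraint <= self.cutoff))
        return satisfied / self._n_active


def satisfied_fraction(
    restraints: RestraintSet,
    receptor: Structure,
    ligand: Structure,
    receptor_coords: np.ndarray,
    ligand_coords: np.ndarray,
    cutoff: float = DEFAULT_SATISFACTION_CUTOFF,
) -> float:
    """One-shot restraint satisfaction of a pose (active restraints only)."""
    return RestraintScorer(restraints, receptor, ligand, cutoff=cutoff).fraction(
        receptor_coords, ligand_coords
    )
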