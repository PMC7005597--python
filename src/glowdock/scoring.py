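"""Distance-binned atom-pair statistical potential and the restraint bias.

The potential is DFIRE-shaped: every (residue name, atom name) pair maps to
an atom type, and each receptor-ligand atom pair within the interaction
cutoff contributes the tabulated energy of its (type_i, type_j, distance
bin). Energies are consumed as a loadable text table — a published parameter
set can be converted into the documented format; a tiny synthetic table
ships with the fixtures for testing. Lower energy is better; the engine
works with fitness = -energy.

The information-driven bias multiplies fitness by the fraction ``s`` of
satisfied active restraints (sign-split so that ``s < 1`` strictly worsens
any nonzero fitness and ``s = 1`` is the identity).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structures import Structure


class ScoringTableError(ValueError):
    """Malformed scoring-table file."""


@dataclasses.dataclass
class ScoringTable:
    """Symmetric (type, type, distance-bin) energy table.

    ``bin_edges`` are the upper edges of the distance bins (the implicit
    lower edge of the first bin is 0); the last edge is the interaction
    cutoff. Pairs at or beyond the cutoff contribute nothing.
    """

    type_index: dict[tuple[str, str], int]
    bin_edges: np.ndarray
    energies: np.ndarray  # (T, T, K)
    name: str = "table"
    missing_entries: int = 0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ScoringTableError("bin edges must be strictly increasing")
        t = len(set(self.type_index.values()))
        k = len(self.bin_edges)
        if self.energies.shape != (t, t, k):
            raise ScoringTableError("energy array shape mismatch")
        if not np.allclose(self.energies, self.energies.transpose(1, 0, 2)):
            raise ScoringTableError("energy table must be symmetric in (i, j)")

    @property
    def cutoff(self) -> float:
        return float(self.bin_edges[-1])

    @property
    def n_types(self) -> int:
        return self.energies.shape[0]

    def atom_type(self, residue_name: str, atom_name: str) -> int | None:
        return self.type_index.get((residue_name, atom_name))


def load_scoring_table(path: str | Path) -> ScoringTable:
    """Load the text format::

        # comment
        name <label>
        bins <e1> <e2> ... <ek>
        <resname> <atomname> <resname> <atomname> <bin_index> <energy>
        ...

    The atom-type alphabet is the set of (resname, atomname) tokens that
    appear. Missing (i, j, bin) combinations default to 0 and are counted;
    rows with unparsable bin/energy fields are skipped and reported.
    """
    path = Path(path)
    name = path.stem
    edges: np.ndarray | None = None
    rows: list[tuple[str, str, str, str, int, float]] = []
    skipped = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "name":
            name = parts[1]
            continue
        if parts[0] == "bins":
            edges = np.array([float(x) for x in parts[1:]])
            if len(edges) == 0 or np.any(np.diff(edges) <= 0):
                raise ScoringTableError(
                    f"{path.name}:{lineno}: bin edges must be strictly increasing"
                )
            continue
        if len(parts) != 6:
            skipped += 1
            continue
        try:
            b = int(parts[4])
            e = float(parts[5])
        except ValueError:
            skipped += 1
            continue
        rows.append((parts[0].upper(), parts[1].upper(), parts[2].upper(), parts[3].upper(), b, e))
    if edges is None:
        raise ScoringTableError(f"{path.name}: missing 'bins' header line")
    tokens: list[tuple[str, str]] = []
    for r1, a1, r2, a2, _, _ in rows:
        for tok in ((r1, a1), (r2, a2)):
            if tok not in tokens:
                tokens.append(tok)
    type_index = {tok: i for i, tok in enumerate(tokens)}
    t, k = len(tokens), len(edges)
    energies = np.zeros((t, t, k))
    filled = np.zeros((t, t, k), dtype=bool)
    for r1, a1, r2, a2, b, e in rows:
        if not 0 <= b < k:
            skipped += 1
            continue
        i, j = type_index[(r1, a1)], type_index[(r2, a2)]
        energies[i, j, b] = e
        energies[j, i, b] = e
        filled[i, j, b] = filled[j, i, b] = True
    missing = int((~filled).sum())
    table = ScoringTable(
        type_index=type_index,
        bin_edges=edges,
        energies=energies,
        name=name,
        missing_entries=missing,
    )
    if skipped:
        table.skipped_rows = skipped  # type: ignore[attr-defined]
    return table


def write_scoring_table(table: ScoringTable, path: str | Path) -> None:
    """Emit the table in the loadable text format (upper triangle only)."""
    tokens = sorted(table.type_index, key=lambda t: table.type_index[t])
    lines = [f"name {table.name}", "bins " + " ".join(f"{e:g}" for e in table.bin_edges)]
    for i, (r1, a1) in enumerate(tokens):
        for j, (r2, a2) in enumerate(tokens):
            if j < i:
                continue
            for b in range(len(table.bin_edges)):
                e = table.energies[i, j, b]
                lines.append(f"{r1} {a1} {r2} {a2} {b} {e:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


class ScoringContext:
    """Typed atoms plus a receptor KD-tree for cutoff-limited pair scoring.

    Hydrogens and atoms without a table type are skipped (counted in
    ``skipped_receptor`` / ``skipped_ligand``). Ligand coordinates are
    supplied per pose; the receptor is fixed.
    """

    def __init__(self, receptor: Structure, ligand: Structure, table: ScoringTable):
        self.table = table
        self.receptor = receptor
        self.ligand = ligand

        def typed(mol: Structure) -> tuple[np.ndarray, np.ndarray, int]:
            idx, types = [], []
            skipped = 0
            for i, atom in enumerate(mol.atoms):
                if atom.is_hydrogen:
                    skipped += 1
                    continue
                t = table.atom_type(atom.residue_name, atom.name)
                if t is None:
                    skipped += 1
                    continue
                idx.append(i)
                types.append(t)
            return np.asarray(idx, dtype=int), np.asarray(types, dtype=int), skipped

        self.rec_idx, self.rec_types, self.skipped_receptor = typed(receptor)
        self.lig_idx, self.lig_types, self.skipped_ligand = typed(ligand)
        if len(self.rec_idx) == 0 or len(self.lig_idx) == 0:
            raise ScoringTableError("no typed atoms to score")
        self.rec_coords = receptor.coords[self.rec_idx]
        self._tree = cKDTree(self.rec_coords)
        # small systems: a vectorized full distance matrix beats per-atom
        # tree queries; large ones go through the KD tree
        self._dense = len(self.rec_idx) * len(self.lig_idx) <= 500_000
        if self._dense:
            # (L*R, K) energy lookup per fixed ligand/receptor atom pair
            self._pair_energies = np.ascontiguousarray(
                table.energies[self.lig_types][:, self.rec_types, :].reshape(
                    -1, len(table.bin_edges)
                )
            )
        self.evaluations = 0


def score_pose(context: ScoringContext, ligand_coords: np.ndarray) -> float:
    """Raw energy of one ligand placement (sum over receptor-ligand atom
    pairs with distance < cutoff, each binned by distance)."""
    if not np.all(np.isfinite(ligand_coords)):
        raise ValueError("non-finite ligand coordinates")
    context.evaluations += 1
    table = context.table
    edges = table.bin_edges
    cutoff = table.cutoff
    lig = np.asarray(ligand_coords)[context.lig_idx]
    if context._dense:
        return score_from_distance_matrix(context, cdist(lig, context.rec_coords))
    neighbors = context._tree.query_ball_point(lig, r=cutoff)
    total = 0.0
    for i, found in enumerate(neighbors):
        if not found:
            continue
        found = np.asarray(found, dtype=int)
        d = np.linalg.norm(context.rec_coords[found] - lig[i], axis=1)
        bins = np.searchsorted(edges, d, side="right")
        inside = bins < len(edges)
        if not np.any(inside):
            continue
        total += float(
            table.energies[
                context.lig_types[i], context.rec_types[found[inside]], bins[inside]
            ].sum()
        )
    return total


def score_from_distance_matrix(context: ScoringContext, distances: np.ndarray) -> float:
    """Raw energy from a precomputed (typed ligand atom, typed receptor
    atom) distance matrix; lets callers reuse one matrix for scoring and
    restraint satisfaction."""
    table = context.table
    edges = table.bin_edges
    d = distances.ravel()
    idx = np.flatnonzero(d < table.cutoff)
    if len(idx) == 0:
        return 0.0
    bins = np.searchsorted(edges, d[idx], side="right")
    inside = bins < len(edges)
    return float(context._pair_energies[idx[inside], bins[inside]].sum())


def to_fitness(raw_energy: float) -> float:
    """Fitness convention: higher is better, so energies are negated."""
    return -float(raw_energy)


def bias_score(fitness: float, satisfied_fraction: float) -> float:
    """Bias a fitness by the fraction ``s`` of satisfied active restraints.

    Multiplicative and sign-split: ``f*s`` for ``f >= 0`` and ``f*(2 - s)``
    for ``f < 0``, so full satisfaction is the identity and any ``s < 1``
    strictly worsens a nonzero fitness, continuously in ``s``.
    """
    s = satisfied_fraction
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"satisfied fraction outside [0, 1]: {s}")
    if fitness >= 0:
        return fitness * s
    return fitness * (2.0 - s)
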