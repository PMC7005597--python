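"""Atomic structures, fixed-column PDB I/O and rigid-body pose algebra.

A :class:`Structure` is an ordered list of atoms grouped into residues keyed
by ``(chain id, residue number, insertion code)``. A :class:`Pose` is a rigid
body transform of the ligand relative to its own centered frame: rotation
about the molecule's coordinate centroid followed by a translation. Rotating
about the centroid (rather than the file origin) keeps translation and
orientation parameters approximately decoupled for the optimizer.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _quat

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})

ResidueKey = tuple[str, int, str]


class PDBFormatError(ValueError):
    """Raised for unparsable or out-of-contract PDB content."""


@dataclasses.dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    coordinates: np.ndarray  # (3,) in Angstrom

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


class Structure:
    """Ordered atomic model; residues are contiguous runs of atoms."""

    def __init__(self, atoms: Sequence[Atom], label: str = ""):
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        self.atoms: list[Atom] = list(atoms)
        self.label = label
        self._coords = np.array([a.coordinates for a in self.atoms], dtype=float)
        if not np.all(np.isfinite(self._coords)):
            raise ValueError("non-finite coordinates")
        # residue grouping preserving first-appearance order
        self._residues: dict[ResidueKey, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            self._residues.setdefault(atom.residue_key, []).append(i)
        self._residue_index = {
            key: np.asarray(idx, dtype=int) for key, idx in self._residues.items()
        }

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterable[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order. Treat as read-only."""
        return self._coords

    @property
    def chain_ids(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    @property
    def centroid(self) -> np.ndarray:
        return self._coords.mean(axis=0)

    def residue_keys(self) -> list[ResidueKey]:
        return list(self._residue_index)

    def residue_atom_indices(self, key: ResidueKey) -> np.ndarray:
        return self._residue_index[key]

    def residue_name(self, key: ResidueKey) -> str:
        return self.atoms[int(self._residue_index[key][0])].residue_name

    def has_residue(self, key: ResidueKey) -> bool:
        return key in self._residue_index

    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def backbone_mask(self) -> np.ndarray:
        return np.array([a.is_backbone for a in self.atoms], dtype=bool)

    def atom_to_residue_index(self) -> np.ndarray:
        """Map atom index -> ordinal residue index (file order)."""
        order = {key: i for i, key in enumerate(self._residue_index)}
        return np.array([order[a.residue_key] for a in self.atoms], dtype=int)

    def representative_atom_index(self, key: ResidueKey) -> int:
        """CB if present, else CA, else the first atom of the residue."""
        idx = self._residue_index[key]
        names = {self.atoms[int(i)].name: int(i) for i in idx}
        if "CB" in names:
            return names["CB"]
        if "CA" in names:
            return names["CA"]
        return int(idx[0])

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self._coords.shape:
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            dataclasses.replace(a, coordinates=coords[i])
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, label=self.label if label is None else label)


@dataclasses.dataclass(frozen=True)
class Pose:
    """Rigid-body ligand transform: rotate about the centroid, then translate."""

    translation: np.ndarray  # (3,) Angstrom
    rotation: np.ndarray  # unit quaternion (w, x, y, z)

    def __post_init__(self):
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.zeros(3), _quat.IDENTITY.copy())

    def normalized(self) -> "Pose":
        return Pose(self.translation, _quat.normalize(self.rotation))

    def quaternion_norm(self) -> float:
        return float(np.linalg.norm(self.rotation))


def apply_pose(structure: Structure, pose: Pose) -> np.ndarray:
    """Transformed coordinates of ``structure`` under ``pose``.

    Rotation acts about the structure's coordinate centroid; the original
    structure is left untouched.
    """
    if abs(pose.quaternion_norm() - 1.0) > 1e-6:
        raise ValueError("pose rotation is not a unit quaternion")
    center = structure.centroid
    return apply_pose_to_coords(structure.coords, center, pose)


def apply_pose_to_coords(
    coords: np.ndarray, center: np.ndarray, pose: Pose
) -> np.ndarray:
    rotated = _quat.rotate(pose.rotation, coords - center)
    return rotated + center + pose.translation


def compose_poses(first: Pose, second: Pose) -> Pose:
    """Pose equivalent to applying ``first`` then ``second``.

    The second transform acts in the frame of the already-moved molecule
    (whose centroid has shifted by the first translation), which reduces to
    composing rotations and adding translations.
    """
    q = _quat.normalize(_quat.multiply(second.rotation, first.rotation))
    return Pose(first.translation + second.translation, q)


def invert_pose(pose: Pose) -> Pose:
    return Pose(-pose.translation, _quat.conjugate(_quat.normalize(pose.rotation)))


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed-column ATOM/HETATM records)
# ---------------------------------------------------------------------------


def _guess_element(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            # 4-char names starting with H digit (e.g. 1HB) are hydrogens
            return ch.upper()
    return "X"


def read_pdb(
    path: str | Path,
    include_hetatm: bool = False,
    include_waters: bool = False,
    label: str | None = None,
) -> Structure:
    """Parse the first MODEL of a PDB file into a :class:`Structure`.

    Only ATOM records are kept by default (``include_hetatm`` adds HETATM,
    ``include_waters`` additionally keeps water residues). Alternate
    locations other than blank or 'A' are dropped.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6]
            if record.startswith("ENDMDL"):
                break
            is_atom = record == "ATOM  " or record.rstrip() == "ATOM"
            is_het = record == "HETATM"
            if not (is_atom or is_het):
                continue
            if is_het and not include_hetatm:
                continue
            altloc = line[16:17]
            if altloc not in (" ", "A", ""):
                continue
            resname = line[17:20].strip()
            if resname in WATER_RESNAMES and not include_waters:
                continue
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = len(atoms) + 1
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBFormatError(
                    f"{path.name}: malformed coordinate field on line {lineno}"
                ) from exc
            name = line[12:16].strip()
            element = line[76:78].strip().upper() if len(line) >= 77 else ""
            if not element:
                element = _guess_element(name)
            try:
                resnum = int(line[22:26])
            except ValueError as exc:
                raise PDBFormatError(
                    f"{path.name}: malformed residue number on line {lineno}"
                ) from exc
            icode = line[26:27].strip()
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    chain_id=line[21:22].strip() or " ",
                    residue_number=resnum,
                    insertion_code=icode,
                    residue_name=resname,
                    coordinates=np.array([x, y, z]),
                )
            )
    if not atoms:
        raise PDBFormatError(f"{path.name}: no parsable ATOM record found")
    return Structure(atoms, label=label if label is not None else path.stem)


def write_pdb(
    structure: Structure,
    path: str | Path,
    coordinates: np.ndarray | None = None,
) -> None:
    """Write fixed-column ATOM records, a TER between chains, and END."""
    coords = structure.coords if coordinates is None else np.asarray(coordinates)
    if coords.shape[0] != len(structure):
        raise ValueError("coordinate array length must equal atom count")
    if np.any(np.abs(coords) >= 10000.0):
        raise PDBFormatError(
            "coordinate magnitude >= 10000 A overflows the PDB fixed-column format"
        )
    lines = []
    prev_chain = None
    serial = 0
    for atom, xyz in zip(structure.atoms, coords):
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        serial += 1
        name = atom.name
        # standard alignment: 1-3 char names start at column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            "ATOM  {serial:>5d} {name}{alt}{res:>3s} {chain}{num:>4d}{icode}   "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                serial=serial,
                name=name_field,
                alt=" ",
                res=atom.residue_name,
                chain=atom.chain_id if atom.chain_id.strip() else " ",
                num=atom.residue_number,
                icode=atom.insertion_code or " ",
                x=xyz[0],
                y=xyz[1],
                z=xyz[2],
                occ=1.0,
                b=0.0,
                el=atom.element[:2],
            )
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
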