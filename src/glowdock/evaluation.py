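"""Model ranking and CAPRI-style quality assessment against a native complex.

Quality of a docked model is measured by three standard quantities: fnat
(fraction of native inter-molecular residue contacts, 5 A any-atom,
reproduced by the model), l-RMSD (ligand backbone RMSD after superposing the
model receptor on the native receptor) and i-RMSD (backbone RMSD over native
interface residues, 10 A definition, after interface superposition). The
CAPRI tiers combine them into high / medium / acceptable / incorrect, and
the Top-N success rate is the percentage of cases with at least one
non-incorrect model among the N best-ranked models.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .restraints import RestraintScorer
from .structures import Pose, Structure, apply_pose
from .gso import SwarmResult

FNAT_CUTOFF = 5.0  # A, any-atom native contact
INTERFACE_CUTOFF = 10.0  # A, i-RMSD interface definition
DEFAULT_TOP_N = (1, 5, 10, 20, 50, 100)


@dataclasses.dataclass(frozen=True)
class QualityMetrics:
    fnat: float
    irmsd: float
    lrmsd: float

    @property
    def capri_class(self) -> str:
        return classify_capri(self.fnat, self.lrmsd, self.irmsd)


@dataclasses.dataclass
class RankedModel:
    """One model in the global ranking (identified by swarm and glowworm)."""

    swarm_id: int
    glowworm_id: int
    pose: Pose
    fitness: float
    raw_score: float = 0.0
    satisfied: float = 1.0
    metrics: QualityMetrics | None = None


@dataclasses.dataclass
class CaseResult:
    label: str
    models: list[RankedModel]

    def classes(self) -> list[str]:
        return [
            m.metrics.capri_class if m.metrics is not None else "incorrect"
            for m in self.models
        ]


def rank_models(
    results: Sequence[SwarmResult], top_k_per_swarm: int | None = None
) -> list[RankedModel]:
    """Merge swarm populations into one list sorted by descending biased
    fitness; ties break deterministically by (swarm id, glowworm id).

    ``top_k_per_swarm`` truncates each swarm to its k best agents before the
    merge; the default pools every glowworm globally.
    """
    models: list[RankedModel] = []
    for res in results:
        worms = sorted(res.glowworms, key=lambda g: (-g.fitness, g.id))
        if top_k_per_swarm is not None:
            worms = worms[:top_k_per_swarm]
        for g in worms:
            models.append(
                RankedModel(
                    swarm_id=res.swarm_id,
                    glowworm_id=g.id,
                    pose=g.pose,
                    fitness=g.fitness,
                    raw_score=g.raw_score,
                    satisfied=g.satisfied,
                )
            )
    models.sort(key=lambda m: (-m.fitness, m.swarm_id, m.glowworm_id))
    return models


# ---------------------------------------------------------------------------
# Contacts and RMSDs
# ---------------------------------------------------------------------------


def _residue_contact_pairs(
    rec_coords: np.ndarray,
    lig_coords: np.ndarray,
    rec_res: np.ndarray,
    lig_res: np.ndarray,
    cutoff: float,
) -> set[tuple[int, int]]:
    tree = cKDTree(lig_coords)
    pairs: set[tuple[int, int]] = set()
    for i, found in enumerate(tree.query_ball_point(rec_coords, r=cutoff)):
        for j in found:
            pairs.add((int(rec_res[i]), int(lig_res[int(j)])))
    return pairs


def compute_fnat(
    native_receptor: Structure,
    native_ligand: Structure,
    model_ligand_coords: np.ndarray,
    cutoff: float = FNAT_CUTOFF,
    model_receptor_coords: np.ndarray | None = None,
) -> float:
    """Fraction of native residue contacts preserved in the model.

    Atom correspondence between native and model is positional (same atom
    order); the model receptor defaults to the native receptor frame.
    """
    rec_res = native_receptor.atom_to_residue_index()
    lig_res = native_ligand.atom_to_residue_index()
    native_pairs = _residue_contact_pairs(
        native_receptor.coords, native_ligand.coords, rec_res, lig_res, cutoff
    )
    if not native_pairs:
        raise ValueError("native complex has no inter-molecular contacts")
    rec_coords = (
        native_receptor.coords
        if model_receptor_coords is None
        else np.asarray(model_receptor_coords)
    )
    model_pairs = _residue_contact_pairs(
        rec_coords, np.asarray(model_ligand_coords), rec_res, lig_res, cutoff
    )
    return len(native_pairs & model_pairs) / len(native_pairs)


def _superpose(
    reference: np.ndarray, mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares (Kabsch) fit of mobile onto reference.

    Returns (rotation matrix, mobile centroid, reference centroid): a mobile
    point x maps to R @ (x - cm) + cr.
    """
    cr = reference.mean(axis=0)
    cm = mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    return rot.as_matrix(), cm, cr


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def compute_lrmsd(
    native_receptor: Structure,
    native_ligand: Structure,
    model_receptor_coords: np.ndarray,
    model_ligand_coords: np.ndarray,
) -> float:
    """Ligand backbone RMSD after superposing the model receptor backbone
    onto the native receptor backbone."""
    bb_rec = native_receptor.backbone_mask()
    bb_lig = native_ligand.backbone_mask()
    R, cm, cr = _superpose(
        native_receptor.coords[bb_rec], np.asarray(model_receptor_coords)[bb_rec]
    )
    lig = (np.asarray(model_ligand_coords) - cm) @ R.T + cr
    return _rmsd(native_ligand.coords[bb_lig], lig[bb_lig])


def native_interface_atom_mask(
    native_receptor: Structure,
    native_ligand: Structure,
    cutoff: float = INTERFACE_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """Backbone-atom masks of the native 10 A interface residues, per side."""
    rtree = cKDTree(native_receptor.coords)
    ltree = cKDTree(native_ligand.coords)

    def side_mask(mol: Structure, partner_tree: cKDTree) -> np.ndarray:
        d, _ = partner_tree.query(mol.coords)
        res_idx = mol.atom_to_residue_index()
        contact_res = set(res_idx[d < cutoff].tolist())
        in_iface = np.array([r in contact_res for r in res_idx])
        return in_iface & mol.backbone_mask()

    return side_mask(native_receptor, ltree), side_mask(native_ligand, rtree)


def compute_irmsd(
    native_receptor: Structure,
    native_ligand: Structure,
    model_receptor_coords: np.ndarray,
    model_ligand_coords: np.ndarray,
    cutoff: float = INTERFACE_CUTOFF,
) -> float:
    """Backbone RMSD over native interface residues (both molecules) after
    superposition on exactly those atoms."""
    rmask, lmask = native_interface_atom_mask(native_receptor, native_ligand, cutoff)
    native = np.vstack(
        [native_receptor.coords[rmask], native_ligand.coords[lmask]]
    )
    model = np.vstack(
        [np.asarray(model_receptor_coords)[rmask], np.asarray(model_ligand_coords)[lmask]]
    )
    R, cm, cr = _superpose(native, model)
    fitted = (model - cm) @ R.T + cr
    return _rmsd(native, fitted)


def classify_capri(fnat: float, lrmsd: float, irmsd: float) -> str:
    """CAPRI quality tier from fnat / l-RMSD / i-RMSD."""
    if fnat >= 0.5 and (lrmsd <= 1.0 or irmsd <= 1.0):
        return "high"
    if fnat >= 0.3 and (lrmsd <= 5.0 or irmsd <= 2.0):
        return "medium"
    if fnat >= 0.1 and (lrmsd <= 10.0 or irmsd <= 4.0):
        return "acceptable"
    return "incorrect"


def evaluate_model(
    native_receptor: Structure,
    native_ligand: Structure,
    model_ligand_coords: np.ndarray,
    model_receptor_coords: np.ndarray | None = None,
) -> QualityMetrics:
    """All three CAPRI quantities for one model against the native complex."""
    rec = (
        native_receptor.coords
        if model_receptor_coords is None
        else np.asarray(model_receptor_coords)
    )
    return QualityMetrics(
        fnat=compute_fnat(
            native_receptor, native_ligand, model_ligand_coords,
            model_receptor_coords=rec,
        ),
        irmsd=compute_irmsd(native_receptor, native_ligand, rec, model_ligand_coords),
        lrmsd=compute_lrmsd(native_receptor, native_ligand, rec, model_ligand_coords),
    )


def evaluate_case(
    label: str,
    native_receptor: Structure,
    native_ligand: Structure,
    docking_ligand: Structure,
    models: Sequence[RankedModel],
    max_models: int | None = None,
) -> CaseResult:
    """Attach CAPRI metrics to the ``max_models`` best-ranked models."""
    out: list[RankedModel] = []
    for m in models if max_models is None else models[:max_models]:
        coords = apply_pose(docking_ligand, m.pose)
        m = dataclasses.replace(
            m, metrics=evaluate_model(native_receptor, native_ligand, coords)
        )
        out.append(m)
    return CaseResult(label=label, models=out)


def success_rate(
    cases: Sequence[CaseResult],
    top_n: Sequence[int] = DEFAULT_TOP_N,
) -> dict[int, float]:
    """Percentage (1 decimal) of cases with >= 1 non-incorrect model in the
    top N ranks; cases shorter than N use all available models."""
    if not cases:
        raise ValueError("no cases")
    rates: dict[int, float] = {}
    for n in top_n:
        hits = 0
        for case in cases:
            classes = case.classes()[:n]
            if any(c != "incorrect" for c in classes):
                hits += 1
        rates[n] = round(100.0 * hits / len(cases), 1)
    return rates


def post_filter(
    models: Sequence[RankedModel],
    scorer: RestraintScorer,
    threshold: float,
    receptor: Structure,
    ligand: Structure,
) -> list[RankedModel]:
    """A-posteriori baseline: keep models whose restraint satisfaction
    reaches ``threshold``, preserving relative order.

    This is the post-docking filter the a-priori protocol (swarm filtering,
    pre-orientation, bias) is contrasted against.
    """
    rec_coords = receptor.coords
    kept: list[RankedModel] = []
    for m in models:
        coords = apply_pose(ligand, m.pose)
        if scorer.fraction(rec_coords, coords) >= threshold:
            kept.append(m)
    return kept
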