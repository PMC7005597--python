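"""Restraint parsing, true interface, scenarios and satisfaction."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from glowdock.restraints import (
    Restraint,
    RestraintError,
    RestraintSet,
    build_scenario,
    compute_true_interface,
    grow_contiguous_patch,
    parse_restraints,
    residue_adjacency_connected,
    satisfied_fraction,
    surface_residues,
    write_restraints,
)
from glowdock.structures import Atom, Structure
from glowdock import _quat


def single_atom_residue(chain, num, xyz, name="CA", resname="GLY", serial=1):
    return Atom(serial, name, name[0], chain, num, "", resname, np.array(xyz, float))


def two_residue_pair(distance):
    rec = Structure([single_atom_residue("A", 1, (0, 0, 0))])
    lig = Structure([single_atom_residue("B", 1, (distance, 0, 0))])
    return rec, lig


class TestParsing:
    def test_basic_dialect(self, tmp_path):
        path = tmp_path / "r.txt"
        path.write_text("# comment\nR A.ARG131\nL B.GLU45 passive\n\n")
        rset = parse_restraints(path)
        assert len(rset.receptor) == 1 and len(rset.ligand) == 1
        rec = rset.receptor[0]
        assert (rec.chain_id, rec.residue_number, rec.residue_name) == ("A", 131, "ARG")
        assert rec.mode == "active"
        assert rset.ligand[0].mode == "passive"

    def test_duplicate_names_line(self, tmp_path):
        path = tmp_path / "dup.txt"
        path.write_text("R A.ARG131\nR A.ARG131\n")
        with pytest.raises(RestraintError, match="line 1"):
            parse_restraints(path)

    def test_unknown_side_token(self, tmp_path):
        path = tmp_path / "side.txt"
        path.write_text("X A.ARG131\n")
        with pytest.raises(RestraintError, match="side"):
            parse_restraints(path)

    def test_round_trip(self, tmp_path, toy_complex):
        ti = compute_true_interface(toy_complex.receptor, toy_complex.ligand)
        path = tmp_path / "ti.txt"
        write_restraints(ti, path, header=["scenario TI"])
        back = parse_restraints(path)
        assert {r.to_line() for r in back} == {r.to_line() for r in ti}

    def test_insertion_code_and_negative_number(self, tmp_path):
        path = tmp_path / "ic.txt"
        path.write_text("R A.SER-2A\n")
        r = parse_restraints(path).receptor[0]
        assert r.residue_number == -2 and r.insertion_code == "A"


class TestTrueInterface:
    def test_pair_inside_cutoff(self):
        rec, lig = two_residue_pair(3.8)
        ti = compute_true_interface(rec, lig)
        assert len(ti.receptor) == 1 and len(ti.ligand) == 1

    def test_pair_outside_cutoff(self):
        rec, lig = two_residue_pair(4.0)
        with pytest.warns(UserWarning):
            ti = compute_true_interface(rec, lig)
        assert len(ti) == 0

    def test_matches_brute_force_all_pairs(self, toy_complex):
        rec, lig = toy_complex.receptor, toy_complex.ligand
        ti = compute_true_interface(rec, lig)
        # O(N*M) oracle over every atom pair
        d = cdist(rec.coords, lig.coords)
        rres = rec.atom_to_residue_index()
        lres = lig.atom_to_residue_index()
        rec_expected = {
            rec.residue_keys()[k]
            for k in set(rres[np.nonzero((d <= 3.9).any(axis=1))[0]])
        }
        lig_expected = {
            lig.residue_keys()[k]
            for k in set(lres[np.nonzero((d <= 3.9).any(axis=0))[0]])
        }
        assert ti.residue_keys("receptor") == rec_expected
        assert ti.residue_keys("ligand") == lig_expected

    def test_symmetric_in_argument_order(self, toy_complex):
        a = compute_true_interface(toy_complex.receptor, toy_complex.ligand)
        b = compute_true_interface(toy_complex.ligand, toy_complex.receptor)
        assert a.residue_keys("receptor") == b.residue_keys("ligand")
        assert a.residue_keys("ligand") == b.residue_keys("receptor")

    def test_monotone_in_cutoff(self, toy_complex):
        small = compute_true_interface(toy_complex.receptor, toy_complex.ligand, 3.9)
        large = compute_true_interface(toy_complex.receptor, toy_complex.ligand, 5.0)
        for side in ("receptor", "ligand"):
            assert small.residue_keys(side) <= large.residue_keys(side)


class TestSurfaceAndPatch:
    def test_single_residue_is_surface(self):
        s = Structure([single_atom_residue("A", 1, (0, 0, 0))])
        assert surface_residues(s) == [("A", 1, "")]

    def test_buried_centroid_residue_excluded(self, rng):
        # dense synthetic globule: center residue has the most neighbors
        atoms = []
        serial = 1
        grid = np.arange(-2, 3) * 4.0
        num = 1
        for x in grid:
            for y in grid:
                for z in grid:
                    atoms.append(
                        single_atom_residue("A", num, (x, y, z), serial=serial)
                    )
                    num += 1
                    serial += 1
        s = Structure(atoms)
        center_key = s.atoms[len(atoms) // 2].residue_key
        assert np.allclose(s.coords[len(atoms) // 2], 0.0)
        assert center_key not in surface_residues(s)

    def test_surface_ranked_by_neighbor_count_oracle(self, toy_complex):
        rec = toy_complex.receptor
        surf = set(surface_residues(rec))
        counts = {}
        heavy = rec.coords[rec.heavy_mask()]
        for key in rec.residue_keys():
            rep = rec.coords[rec.representative_atom_index(key)]
            counts[key] = int((np.linalg.norm(heavy - rep, axis=1) <= 10.0).sum())
        worst_in = max(counts[k] for k in surf)
        best_out = min(
            (counts[k] for k in rec.residue_keys() if k not in surf), default=np.inf
        )
        assert worst_in <= best_out  # ties allowed on the threshold itself
        assert len(surf) >= 0.25 * len(rec.residue_keys())

    def test_patch_zero_growth(self, toy_complex):
        rec = toy_complex.receptor
        seeds = rec.residue_keys()[:3]
        assert grow_contiguous_patch(rec, seeds, 3, rec.residue_keys()) == seeds

    def test_patch_on_a_line_takes_consecutive_residues(self):
        atoms = [
            single_atom_residue("A", i + 1, (4.0 * i, 0, 0), serial=i + 1)
            for i in range(8)
        ]
        s = Structure(atoms)
        keys = s.residue_keys()
        patch = grow_contiguous_patch(s, [keys[0]], 3, keys[1:])
        assert patch == keys[:3]

    def test_patch_connected_under_adjacency(self, toy_complex, rng):
        rec = toy_complex.receptor
        pool = surface_residues(rec)
        patch = grow_contiguous_patch(rec, [pool[0]], 6, pool[1:], rng=rng)
        assert residue_adjacency_connected(rec, patch, radius=8.0)

    def test_pool_exhaustion_reports_achieved_size(self, toy_complex):
        rec = toy_complex.receptor
        keys = rec.residue_keys()
        with pytest.raises(RestraintError, match="3"):
            grow_contiguous_patch(rec, [keys[0]], 10, keys[1:3])


@pytest.fixture(scope="module")
def ti(toy_complex):
    return compute_true_interface(toy_complex.receptor, toy_complex.ligand)


class TestScenarios:

    def test_ti_identity(self, toy_complex, ti):
        out = build_scenario(
            ti, "TI", toy_complex.receptor, toy_complex.ligand, rng=np.random.default_rng(0)
        )
        assert {r.to_line() for r in out} == {r.to_line() for r in ti}

    @pytest.mark.parametrize("scenario,blocks", [("TI_50", 2), ("TI_25", 4)])
    def test_degraded_sizes_and_false_positives(
        self, toy_complex, ti, scenario, blocks
    ):
        rec, lig = toy_complex.receptor, toy_complex.ligand
        for replicate in range(blocks):
            out = build_scenario(
                ti, scenario, rec, lig, replicate, np.random.default_rng(7)
            )
            for side, mol in (("receptor", rec), ("ligand", lig)):
                ti_keys = ti.residue_keys(side)
                out_keys = out.residue_keys(side)
                assert len(out_keys) == len(ti_keys)  # size identity
                n_true = len(out_keys & ti_keys)
                assert n_true == len(_block_sizes(len(ti_keys), blocks)[replicate])
                # false positives never intersect the TI
                false = out_keys - ti_keys
                assert false.isdisjoint(ti_keys)
                assert len(false) == len(ti_keys) - n_true

    @pytest.mark.parametrize("scenario,blocks", [("TI_50", 2), ("TI_25", 4)])
    def test_replicates_have_disjoint_true_residues(
        self, toy_complex, ti, scenario, blocks
    ):
        rec, lig = toy_complex.receptor, toy_complex.ligand
        retained = []
        for replicate in range(blocks):
            out = build_scenario(
                ti, scenario, rec, lig, replicate, np.random.default_rng(7)
            )
            retained.append(out.residue_keys("receptor") & ti.residue_keys("receptor"))
        for i in range(blocks):
            for j in range(i + 1, blocks):
                assert retained[i].isdisjoint(retained[j])

    def test_receptor_only_variants_have_empty_ligand_side(self, toy_complex, ti):
        for scenario in ("TI_REC", "TI_REC_50", "TI_REC_25"):
            out = build_scenario(
                ti, scenario, toy_complex.receptor, toy_complex.ligand,
                rng=np.random.default_rng(3),
            )
            assert out.ligand == []
            assert len(out.receptor) > 0

    def test_ti_single_is_closest_real_contact_pair(self, toy_complex, ti):
        rec, lig = toy_complex.receptor, toy_complex.ligand
        out = build_scenario(ti, "TI_SINGLE", rec, lig, rng=np.random.default_rng(0))
        assert len(out.receptor) == 1 and len(out.ligand) == 1
        # oracle: brute-force closest atom pair
        d = cdist(rec.coords, lig.coords)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        assert out.receptor[0].residue_key == rec.atoms[i].residue_key
        assert out.ligand[0].residue_key == lig.atoms[j].residue_key
        assert d[i, j] <= ti.cutoff

    def test_ti_one_is_receptor_residue_of_ti_single(self, toy_complex, ti):
        rec, lig = toy_complex.receptor, toy_complex.ligand
        single = build_scenario(ti, "TI_SINGLE", rec, lig, rng=np.random.default_rng(0))
        one = build_scenario(ti, "TI_ONE", rec, lig, rng=np.random.default_rng(0))
        assert len(one) == 1
        assert one.receptor[0].residue_key == single.receptor[0].residue_key

    def test_empty_ti_rejected(self, toy_complex):
        with pytest.raises(RestraintError):
            build_scenario(
                RestraintSet(), "TI", toy_complex.receptor, toy_complex.ligand
            )


def _block_sizes(n, blocks):
    edges = np.linspace(0, n, blocks + 1).astype(int)
    return [list(range(edges[i], edges[i + 1])) for i in range(blocks)]


class TestSatisfaction:
    def test_full_and_zero_satisfaction(self, toy_complex, true_interface):
        rec, lig = toy_complex.receptor, toy_complex.ligand
        assert (
            satisfied_fraction(true_interface, rec, lig, rec.coords, lig.coords, 3.9)
            == 1.0
        )
        far = lig.coords + np.array([500.0, 0, 0])
        assert (
            satisfied_fraction(true_interface, rec, lig, rec.coords, far, 3.9) == 0.0
        )

    def test_partial_fraction_matches_brute_force(self, toy_complex, true_interface):
        rec, lig = toy_complex.receptor, toy_complex.ligand
        cutoff = 5.0
        axis = lig.centroid - rec.centroid
        axis /= np.linalg.norm(axis)

        def brute_force(coords):
            sat = total = 0
            for r in true_interface:
                if not r.is_active:
                    continue
                total += 1
                mol, own_coords, partner = (
                    (rec, rec.coords, coords)
                    if r.side == "receptor"
                    else (lig, coords, rec.coords)
                )
                idx = mol.residue_atom_indices(r.residue_key)
                if cdist(own_coords[idx], partner).min() <= cutoff:
                    sat += 1
            return sat / total

        # pull the ligand out along the dissociation axis until the oracle
        # reports a strictly partial satisfaction, then compare
        for h in np.arange(3.0, 20.0, 0.5):
            shifted = lig.coords + h * axis
            expected = brute_force(shifted)
            if 0.0 < expected < 1.0:
                break
        else:
            pytest.fail("no displacement splits the restraint set")
        got = satisfied_fraction(
            true_interface, rec, lig, rec.coords, shifted, cutoff
        )
        assert got == pytest.approx(expected)

    def test_zero_active_restraints_returns_one(self, toy_complex):
        rec, lig = toy_complex.receptor, toy_complex.ligand
        passive = RestraintSet(
            [
                Restraint(
                    side="receptor",
                    chain_id=k[0],
                    residue_number=k[1],
                    insertion_code=k[2],
                    mode="passive",
                )
                for k in rec.residue_keys()[:2]
            ]
        )
        assert (
            satisfied_fraction(passive, rec, lig, rec.coords, lig.coords, 3.9) == 1.0
        )

    def test_invariant_under_joint_rigid_transform(
        self, toy_complex, true_interface, rng
    ):
        rec, lig = toy_complex.receptor, toy_complex.ligand
        q = _quat.random_unit(rng)
        t = rng.uniform(-30, 30, 3)
        rec_t = _quat.rotate(q, rec.coords) + t
        lig_t = _quat.rotate(q, lig.coords) + t
        a = satisfied_fraction(true_interface, rec, lig, rec.coords, lig.coords, 3.9)
        b = satisfied_fraction(true_interface, rec, lig, rec_t, lig_t, 3.9)
        assert a == b

    def test_missing_restraint_residue_fails_at_construction(self, toy_complex):
        bogus = RestraintSet(
            [Restraint(side="receptor", chain_id="Z", residue_number=999)]
        )
        with pytest.raises(RestraintError, match="not found"):
            satisfied_fraction(
                bogus,
                toy_complex.receptor,
                toy_complex.ligand,
                toy_complex.receptor.coords,
                toy_complex.ligand.coords,
                3.9,
            )
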