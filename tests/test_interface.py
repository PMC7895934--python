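"""Contacts, buried SASA, interface residues, zinc sites."""

import math

import numpy as np
import pytest

from rascal.interface import (ContactCriteria, buried_sasa, enumerate_contacts,
                              find_zinc_sites, interface_report, sasa,
                              sphere_points)
from rascal.structio import AtomRecord, Selection, StructureModel
from rascal.synth import make_planted_complex, make_zinc_cage

CHAIN_A = Selection(chains=("A",))
CHAIN_B = Selection(chains=("B",))


def _atom(chain, res, name, elem, xyz, res_name="ALA"):
    return AtomRecord(chain, res, "", res_name, name, elem, np.array(xyz, float))


# ---------------------------------------------------------------------------
# brute-force oracle, independent of the package's chemistry dictionaries
# ---------------------------------------------------------------------------

_ORACLE_DONORS = {("SER", "OG"), ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"),
                  ("ARG", "NH2"), ("HIS", "ND1"), ("HIS", "NE2"), ("THR", "OG1")}
_ORACLE_ACCEPT = {("SER", "OG"), ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"),
                  ("GLU", "OE2"), ("THR", "OG1"), ("HIS", "ND1"), ("HIS", "NE2")}
_ORACLE_ANION = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_ORACLE_CATION = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
                  ("HIS", "ND1"), ("HIS", "NE2")}


def brute_force_contacts(model, chains=("A", "B")):
    """All-pairs double loop with its own typing tables (backbone included)."""
    atoms_a = [a for a in model.atoms()
               if a.chain_id == chains[0] and not a.is_hydrogen and not a.is_water]
    atoms_b = [a for a in model.atoms()
               if a.chain_id == chains[1] and not a.is_hydrogen and not a.is_water]
    out = []
    for a in atoms_a:
        for b in atoms_b:
            d = math.dist(a.coords, b.coords)
            ka, kb = (a.res_name, a.atom_name), (b.res_name, b.atom_name)
            da = ka in _ORACLE_DONORS or (a.atom_name == "N" and a.res_name != "PRO")
            db = kb in _ORACLE_DONORS or (b.atom_name == "N" and b.res_name != "PRO")
            aa = ka in _ORACLE_ACCEPT or a.atom_name in ("O", "OXT")
            ab = kb in _ORACLE_ACCEPT or b.atom_name in ("O", "OXT")
            if d <= 4.0 and ((ka in _ORACLE_ANION and kb in _ORACLE_CATION)
                             or (ka in _ORACLE_CATION and kb in _ORACLE_ANION)):
                out.append(("saltbridge", a.atom_key, b.atom_key))
            elif (d <= 3.5 and a.element in "NOS" and b.element in "NOS"
                  and ((da and ab) or (db and aa))):
                out.append(("hbond", a.atom_key, b.atom_key))
            elif d <= 3.9:
                out.append(("nonbonded", a.atom_key, b.atom_key))
    return sorted(out)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

class TestSasa:
    def test_isolated_sphere_closed_form(self):
        """Single carbon: area = 4π(1.70 + 1.40)² exactly (no occlusion)."""
        area = sasa([_atom("A", 1, "C", "C", (0, 0, 0))])[0]
        exact = 4 * math.pi * 3.10 ** 2
        assert abs(area - exact) / exact < 1e-9

    def test_distant_atoms_keep_isolated_areas(self):
        atoms = [_atom("A", 1, "C", "C", (0, 0, 0)),
                 _atom("A", 2, "C", "C", (100, 0, 0))]
        areas = sasa(atoms)
        exact = 4 * math.pi * 3.10 ** 2
        np.testing.assert_allclose(areas, exact, rtol=1e-9)

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_two_overlapping_spheres_match_cap_formula(self, d):
        """Equal spheres at separation d: exposed area = 2(4πR² − 2πRh) with
        cap height h = R − d/2; quadrature within 2% at 960 points."""
        atoms = [_atom("A", 1, "C", "C", (0, 0, 0)),
                 _atom("A", 2, "C", "C", (d, 0, 0))]
        total = sasa(atoms, n_points=960).sum()
        R = 3.10
        h = R - d / 2
        exact = 2 * (4 * math.pi * R ** 2 - 2 * math.pi * R * h)
        assert abs(total - exact) / exact < 0.02

    def test_quadrature_converges(self, planted):
        model, _ = planted
        a960 = sasa(model, n_points=960).sum()
        a4000 = sasa(model, n_points=4000).sum()
        assert abs(a960 - a4000) / a4000 < 0.02

    def test_point_set_is_deterministic_and_unit(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, sphere_points(960))
        with pytest.raises(ValueError):
            sphere_points(8)

    def test_unknown_element_requires_override(self):
        weird = [_atom("A", 1, "XX", "XX", (0, 0, 0))]
        with pytest.raises(KeyError):
            sasa(weird)
        area = sasa(weird, radius_overrides={"XX": 2.0})[0]
        assert np.isclose(area, 4 * math.pi * 3.4 ** 2, rtol=1e-9)

    def test_matches_independent_shrake_rupley(self, planted):
        """Cross-check against biotite's Shrake-Rupley with element radii."""
        biotite_struc = pytest.importorskip("biotite.structure")
        model, _ = planted
        atoms = list(model.atoms())
        arr = biotite_struc.AtomArray(len(atoms))
        arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
        arr.chain_id = np.array([a.chain_id for a in atoms])
        arr.res_id = np.array([a.res_seq for a in atoms])
        arr.res_name = np.array([a.res_name for a in atoms])
        arr.atom_name = np.array([a.atom_name for a in atoms])
        arr.element = np.array([a.element for a in atoms])
        theirs = biotite_struc.sasa(arr, probe_radius=1.4, point_number=960,
                                    vdw_radii="Single").sum()
        ours = sasa(model).sum()
        assert abs(ours - theirs) / theirs < 0.02


class TestBuriedSasa:
    def test_distant_partners_bury_nothing(self):
        atoms = [_atom("A", 1, "CA", "C", (0, 0, 0)),
                 _atom("A", 2, "CA", "C", (3, 0, 0)),
                 _atom("B", 1, "CA", "C", (100, 0, 0)),
                 _atom("B", 2, "CA", "C", (103, 0, 0))]
        model = StructureModel.from_atoms(atoms)
        buried = buried_sasa(model, CHAIN_A, CHAIN_B)
        assert buried == (0.0, 0.0)

    def test_planted_complex_buries_both_partners(self, planted):
        model, truth = planted
        ba, bb = buried_sasa(model, CHAIN_A, CHAIN_B)
        assert ba > 0 and bb > 0
        assert truth.buried_positive

    def test_burial_decreases_as_partners_separate(self, planted):
        model, _ = planted
        values = []
        for shift in (0.0, 3.0, 8.0, 50.0):
            moved = model.copy()
            for atom in moved.atoms():
                if atom.chain_id == "B":
                    atom.coords = atom.coords + np.array([0.0, shift, 0.0])
            values.append(sum(buried_sasa(moved, CHAIN_A, CHAIN_B)))
        assert all(x >= y - 1e-9 for x, y in zip(values, values[1:]))
        assert values[-1] == 0.0

    def test_overlapping_partners_rejected(self, planted):
        model, _ = planted
        with pytest.raises(ValueError, match="overlap"):
            buried_sasa(model, CHAIN_A, CHAIN_A)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

class TestContacts:
    def test_planted_counts_recovered_exactly(self, planted):
        model, truth = planted
        recs = enumerate_contacts(model, CHAIN_A, CHAIN_B)
        counts = {t: sum(r.type == t for r in recs)
                  for t in ("hbond", "saltbridge", "nonbonded")}
        nh, ns, nn = truth.counts()
        assert counts == {"hbond": nh, "saltbridge": ns, "nonbonded": nn}
        # and the planted pairs themselves are the ones reported
        planted_pairs = {((a[0], a[1]), (b[0], b[1]))
                         for a, b, _ in truth.hbonds + truth.saltbridges + truth.nonbonded}
        found_pairs = {((r.atom_a[0], r.atom_a[1]), (r.atom_b[0], r.atom_b[1]))
                       for r in recs}
        assert found_pairs == planted_pairs

    @pytest.mark.parametrize("seed", [1, 5, 9, 42])
    def test_equals_brute_force_oracle(self, seed):
        model, _ = make_planted_complex(2, 2, 3, seed=seed)
        recs = enumerate_contacts(model, CHAIN_A, CHAIN_B)
        ours = sorted((r.type,
                       (r.atom_a[0], r.atom_a[1], r.atom_a[2], r.atom_a[4], ""),
                       (r.atom_b[0], r.atom_b[1], r.atom_b[2], r.atom_b[4], ""))
                      for r in recs)
        assert ours == brute_force_contacts(model)

    def test_distant_partners_no_contacts(self):
        model, truth = make_planted_complex(0, 0, 0, seed=1)
        assert enumerate_contacts(model, CHAIN_A, CHAIN_B) == []
        assert truth.counts() == (0, 0, 0)
        # zero-contact scaffold keeps the chains >= 5 Å apart everywhere
        a = np.array([x.coords for x in model.atoms() if x.chain_id == "A"])
        b = np.array([x.coords for x in model.atoms() if x.chain_id == "B"])
        dmin = np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2))
        assert dmin >= 5.0

    def test_symmetric_in_partner_order(self, planted):
        model, _ = planted
        fwd = enumerate_contacts(model, CHAIN_A, CHAIN_B)
        rev = enumerate_contacts(model, CHAIN_B, CHAIN_A)
        key = lambda r: (r.type, tuple(sorted((r.atom_a, r.atom_b))))
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_salt_bridge_takes_precedence_over_hbond(self):
        """A charged N/O pair within 3.5 Å is a salt bridge, not an hbond."""
        atoms = [_atom("A", 1, "OD1", "O", (0, 0, 0), "ASP"),
                 _atom("B", 1, "NZ", "N", (3.0, 0, 0), "LYS")]
        recs = enumerate_contacts(StructureModel.from_atoms(atoms),
                                  CHAIN_A, CHAIN_B)
        assert [r.type for r in recs] == ["saltbridge"]

    def test_invariant_under_rigid_transform(self, planted):
        model, _ = planted
        theta = np.radians(72)
        R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        moved = model.transform(R, np.array([10.0, -4.0, 7.0]))
        a = enumerate_contacts(model, CHAIN_A, CHAIN_B)
        b = enumerate_contacts(moved, CHAIN_A, CHAIN_B)
        assert [(r.type, r.atom_a, r.atom_b) for r in a] == \
               [(r.type, r.atom_a, r.atom_b) for r in b]
        for ra, rb in zip(a, b):
            assert np.isclose(ra.distance, rb.distance, atol=1e-9)


class TestInterfaceReport:
    def test_distant_partners_give_empty_report(self):
        model, _ = make_planted_complex(0, 0, 0, seed=3)
        rep = interface_report(model, CHAIN_A, CHAIN_B)
        assert (rep.n_hbonds, rep.n_saltbridges, rep.n_nonbonded) == (0, 0, 0)
        assert rep.interface_residues_a == [] and rep.interface_residues_b == []
        assert rep.buried_sasa_a == 0.0 and rep.buried_sasa_b == 0.0

    def test_planted_participants_are_interface_residues(self, planted):
        model, truth = planted
        rep = interface_report(model, CHAIN_A, CHAIN_B)
        planted_a = {r for (_, r, _), _, _ in
                     truth.hbonds + truth.saltbridges + truth.nonbonded}
        got_a = {r for (_, r, _) in rep.interface_residues_a}
        assert planted_a <= got_a
        assert rep.n_hbonds == len(truth.hbonds)
        table = rep.contacts_table()
        assert len(table) == rep.n_hbonds + rep.n_saltbridges + rep.n_nonbonded


class TestZincSites:
    def test_no_metals_no_sites(self, planted):
        model, _ = planted
        assert find_zinc_sites(model) == []

    def test_tetrahedral_cys3his_cage(self):
        """Cys3His cage with ligand atoms at 2.3 Å: one site, 4 residues."""
        sites = find_zinc_sites(make_zinc_cage(n_cys=3, n_his=1, bond_length=2.3))
        assert len(sites) == 1
        site = sites[0]
        assert len(site.residues) == 4
        names = sorted(r[2] for r in site.residues)
        assert names == ["CYS", "CYS", "CYS", "HIS"]
        assert all(np.isclose(c[4], 2.3, atol=1e-9) for c in site.coordinating)

    def test_underligated_zinc_not_reported(self):
        sites = find_zinc_sites(make_zinc_cage(n_cys=2, n_his=0))
        assert sites == []

    def test_site_detection_rigid_invariant(self):
        cage = make_zinc_cage()
        theta = np.radians(117)
        R = np.array([[1, 0, 0], [0, np.cos(theta), -np.sin(theta)],
                      [0, np.sin(theta), np.cos(theta)]])
        moved = cage.transform(R, np.array([-3.0, 9.0, 1.0]))
        a, b = find_zinc_sites(cage), find_zinc_sites(moved)
        assert len(a) == len(b) == 1
        assert a[0].residues == b[0].residues
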