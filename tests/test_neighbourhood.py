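"""Hydrogen bonds, water classification, and contact counting."""

import numpy as np
import pytest

from eemcc.neighbourhood import (
    assign_hbonds,
    build_shells,
    classify_water,
    contact_table,
    per_molecule_contacts,
    switching_contacts,
    water_environment_counts,
)
from eemcc.synthetic import gen_solution_ensemble
from tests.conftest import make_topology, static_ensemble, water_atoms


def ion(idx, mol, element="O", charge=-0.8, mass=16.0, role="anion"):
    return (
        [{"element": element, "mass": mass, "charge": charge,
          "ua": idx, "monomer": idx, "molecule": mol}],
        {mol: role},
    )


class TestHBonds:
    def _system(self, q_a, q_b, r_a, r_b):
        """Water donor at origin-ish plus two acceptor ions."""
        atoms = water_atoms(0, 0, 0)
        sp = {0: "water"}
        for i, q in enumerate((q_a, q_b)):
            a, s = ion(1 + i, 1 + i, charge=q)
            atoms += a
            sp.update({1 + i: "anion"})
        top = make_topology(atoms, [(0, 1), (0, 2)], species=sp)
        h1 = np.array([5.76, 5.59, 5.0])  # first water hydrogen
        pos = np.array([
            [5.0, 5.0, 5.0], h1, [4.24, 5.59, 5.0],
            h1 + [r_a, 0.0, 0.0],
            h1 + [0.0, r_b, 0.0],
        ])
        ens = static_ensemble(pos, box=40.0)
        shells = build_shells(ens, top, cutoff=8.0)
        return top, ens, shells

    def test_most_negative_qdqa_over_r2_wins(self):
        # qD=+0.417; A: q=-0.8 at 2.0 A (score -0.0834) beats
        # B: q=-0.4 at 1.5 A (score -0.0741), despite B being closer
        top, ens, shells = self._system(-0.8, -0.4, 2.0, 1.5)
        hb = assign_hbonds(ens, shells, top)
        assert hb.assignments[0][1] == 1  # H atom 1 -> UA of acceptor A

    def test_single_negative_candidate_is_assigned(self):
        top, ens, shells = self._system(-0.8, +0.4, 2.0, 50.0)
        hb = assign_hbonds(ens, shells, top)
        assert hb.assignments[0][1] == 1

    def test_no_acceptor_when_all_products_positive(self):
        top, ens, shells = self._system(+0.5, +0.4, 2.0, 1.5)
        hb = assign_hbonds(ens, shells, top)
        assert 1 not in hb.assignments[0]


class TestClassifyWater:
    def _scene(self, extra_roles):
        """Water at centre surrounded by one UA per requested role."""
        atoms = water_atoms(0, 0, 0)
        bonds = [(0, 1), (0, 2)]
        sp = {0: "water"}
        offsets = [np.array([3.0, 0, 0]), np.array([-3.0, 0, 0]),
                   np.array([0, 3.0, 0]), np.array([0, -3.0, 0])]
        pos = [np.array([10.0, 10, 10]), np.array([10.76, 10.59, 10]),
               np.array([9.24, 10.59, 10])]
        for i, role in enumerate(extra_roles):
            a, _ = ion(1 + i, 1 + i, element="C", charge=0.1, role=role)
            atoms += a
            sp[1 + i] = role
            pos.append(np.array([10.0, 10, 10]) + offsets[i])
        top = make_topology(atoms, bonds, species=sp)
        ens = static_ensemble(np.array(pos), box=40.0)
        shells = build_shells(ens, top, cutoff=8.0)
        return classify_water(shells, top)[0][0]

    def test_one_protein_only_is_wp(self):
        assert self._scene(["protein"]) == "WP"

    def test_two_proteins_plus_counterion_is_wepp(self):
        assert self._scene(["protein", "protein", "cation"]) == "WEPP"

    def test_two_proteins_only_is_wpp(self):
        assert self._scene(["protein", "protein"]) == "WPP"

    def test_protein_plus_buffer_is_wep(self):
        assert self._scene(["protein", "buffer"]) == "WEP"

    def test_excipient_only_is_we(self):
        assert self._scene(["polyanion"]) == "WE"

    def test_waters_only_is_bulk(self):
        assert self._scene([]) == "bulk"

    def test_labels_partition_all_waters(self):
        ens, top = gen_solution_ensemble(n_waters=30, n_frames=4, seed=3)
        shells = build_shells(ens, top)
        labels = classify_water(shells, top)
        n_waters = len(top.molecules_of_species("water"))
        for lab_f in labels:
            assert len(lab_f) == n_waters
        counts = water_environment_counts(labels)
        assert counts.sum() == pytest.approx(n_waters)


class TestSwitchingContacts:
    def test_at_d0_full_contact(self):
        assert switching_contacts(np.array([5.0]), d0=5.0, r0=1.5) == 1.0

    def test_at_d0_plus_r0_half_contact(self):
        # removable singularity of (1-x^6)/(1-x^12) at x=1
        assert switching_contacts(np.array([6.5]), 5.0, 1.5) == pytest.approx(0.5)

    def test_far_pair_vanishes(self):
        assert switching_contacts(np.array([100.0]), 5.0, 1.5) < 1e-6

    def test_matches_rational_form_off_singularity(self):
        r = np.array([5.3, 5.9, 6.2, 7.4])
        x = (r - 5.0) / 1.5
        expected = ((1 - x**6) / (1 - x**12)).sum()
        assert switching_contacts(r, 5.0, 1.5) == pytest.approx(expected)


class TestContactTable:
    def _pair_system(self):
        a1, _ = ion(0, 0, role="cation", charge=1.0, element="Na", mass=23.0)
        a2, _ = ion(1, 1, role="anion", charge=-1.0, element="Cl", mass=35.5)
        top = make_topology(a1 + a2, [], species={0: "cation", 1: "anion"})
        pos = np.array([[10.0, 10, 10], [12.5, 10, 10]])
        return top, static_ensemble(pos, box=40.0)

    def test_single_pair_counts_once(self):
        top, ens = self._pair_system()
        shells = build_shells(ens, top)
        table = contact_table(ens, shells, top)
        assert table.loc["cation", "anion"] == pytest.approx(1.0)
        assert table.loc["anion", "cation"] == pytest.approx(1.0)
        assert table.loc["cation", "cation"] == 0.0

    def test_per_molecule_normalisation(self):
        top, ens = self._pair_system()
        shells = build_shells(ens, top)
        table = contact_table(ens, shells, top)
        norm = per_molecule_contacts(table, counts={"cation": 2, "anion": 1})
        assert norm.loc["cation", "anion"] == pytest.approx(0.5)
        assert norm.loc["anion", "cation"] == pytest.approx(1.0)

    def test_invariant_under_rigid_motion(self):
        ens, top = gen_solution_ensemble(n_waters=15, n_frames=2, seed=5)
        table = contact_table(ens, build_shells(ens, top), top)
        # rotate 90 degrees about the box centre plus a small translation
        c = ens.box[0] / 2
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = ens.positions - c
        moved = np.einsum("ij,fnj->fni", rot, moved) + c + 1.0
        ens2 = type(ens)(
            times=ens.times, box=ens.box, positions=moved,
            forces=ens.forces, pe=ens.pe, ke=ens.ke,
        )
        table2 = contact_table(ens2, build_shells(ens2, top), top)
        np.testing.assert_allclose(table.values, table2.values, atol=1e-12)
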