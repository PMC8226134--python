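"""Entropy ledger, binding decomposition and table consistency."""

import numpy as np
import pandas as pd
import pytest

from eemcc.assembly import (
    LedgerError,
    SpeciesState,
    assemble_ledger,
    average_formal_charge,
    binding_delta_g,
    check_free_energy_table,
    classwise_decomposition,
    group_standard_error,
)
from eemcc.data import reference_free_energy_decomposition
from eemcc.synthetic import gen_solution_ensemble, ion_set_topology
from eemcc.vibrational import vibrational_entropies
from tests.conftest import make_topology, water_atoms


def _water_top():
    return make_topology(water_atoms(0, 0, 0), [(0, 1), (0, 2)],
                         species={0: "water"})


class TestAssembleLedger:
    def test_water_carries_exactly_ua_components(self):
        top = _water_top()
        vib = {(0, "UA", "translation"): 50.0, (0, "UA", "rotation"): 10.0}
        topo = {("water", "UA", "orientational"): 14.0}
        ledger = assemble_ledger(vib, topo, top)
        assert ledger.declared_levels["water"] == ("UA",)
        assert ledger.total("water") == pytest.approx(74.0)

    def test_undeclared_level_is_error(self):
        top = _water_top()
        vib = {(0, "UA", "translation"): 50.0, (0, "M", "translation"): 5.0}
        with pytest.raises(LedgerError, match="outside its declared levels"):
            assemble_ledger(vib, {("water", "UA", "orientational"): 1.0}, top)

    def test_missing_declared_component_is_error(self):
        ens, top = gen_solution_ensemble(n_waters=5, n_frames=10, seed=0)
        vib = vibrational_entropies(ens, top)
        # drop the protein polymer-level entry
        proteins = set(int(m) for m in top.molecules_of_species("protein"))
        vib = {k: v for k, v in vib.items()
               if not (k[0] in proteins and k[1] == "P")}
        with pytest.raises(LedgerError, match="missing declared"):
            assemble_ledger(vib, {("water", "UA", "orientational"): 1.0}, top)

    def test_total_is_sum_of_components(self):
        top = _water_top()
        vib = {(0, "UA", "translation"): 50.0, (0, "UA", "rotation"): 10.0}
        topo = {("water", "UA", "orientational"): 14.0}
        ledger = assemble_ledger(vib, topo, top)
        assert ledger.total() == pytest.approx(sum(ledger.components.values()))


class TestBindingDeltaG:
    def _state(self, g, h, ts, n=1.0, n_w=0.0, gw=0.0, hw=0.0, tsw=0.0):
        return SpeciesState(g=g, h=h, ts=ts, n=n, n_w=n_w,
                            gw=gw, hw=hw, tsw=tsw)

    def test_identical_states_give_zero_everywhere(self):
        s = {"polyanion": self._state(-5.0, -8.0, -3.0, n=5, n_w=10.0,
                                      gw=-1.0, hw=-2.0, tsw=-1.0)}
        bulk = self._state(-1.5, -2.5, -1.0)
        df = binding_delta_g(s, s, bulk)
        np.testing.assert_allclose(df.values, 0.0, atol=1e-12)

    def test_hand_computed_two_species_example(self):
        bound = {
            "polyanion": self._state(-6.0, -8.0, -2.0, n=2, n_w=4.0,
                                     gw=-2.0, hw=-3.0, tsw=-1.0),
            "buffer": self._state(1.0, 0.5, -0.5, n=1, n_w=2.0,
                                  gw=-1.0, hw=-1.5, tsw=-0.5),
        }
        dilute = {
            "polyanion": self._state(-5.0, -6.0, -1.0, n=2, n_w=6.0,
                                     gw=-1.5, hw=-2.0, tsw=-0.5),
            "buffer": self._state(0.0, 0.0, 0.0, n=1, n_w=3.0,
                                  gw=-1.0, hw=-1.0, tsw=0.0),
        }
        bulk = self._state(-2.0, -3.0, -1.0)
        df = binding_delta_g(bound, dilute, bulk)
        # polyanion row: 2*(-6) - 2*(-5) = -2
        assert df.loc["polyanion", "dG"] == pytest.approx(-2.0)
        # its waters: 4*(-2) + (6-4)*(-2) - 6*(-1.5) = -3
        assert df.loc["W_polyanion", "dG"] == pytest.approx(-3.0)
        # buffer: 1*1 - 0 = 1; waters: 2*(-1) + 1*(-2) - 3*(-1) = -1
        assert df.loc["buffer", "dG"] == pytest.approx(1.0)
        assert df.loc["W_buffer", "dG"] == pytest.approx(-1.0)
        assert df.loc["Total", "dG"] == pytest.approx(-2 - 3 + 1 - 1)
        # dG = dH - TdS holds row-wise
        np.testing.assert_allclose(
            df["dG"].values, (df["dH"] - df["TdS"]).values, atol=1e-12
        )

    def test_antisymmetric_under_state_swap(self):
        rng = np.random.default_rng(3)
        def rand_state():
            g, ts = rng.normal(size=2)
            return self._state(g, g + ts, ts, n=2, n_w=float(rng.integers(1, 9)),
                               gw=rng.normal(), hw=rng.normal(),
                               tsw=rng.normal())
        bound = {"polyanion": rand_state(), "cation": rand_state()}
        dilute = {"polyanion": rand_state(), "cation": rand_state()}
        bulk = rand_state()
        fwd = binding_delta_g(bound, dilute, bulk)
        rev = binding_delta_g(dilute, bound, bulk)
        np.testing.assert_allclose(fwd.values, -rev.values, atol=1e-12)

    def test_negative_water_count_is_error(self):
        s = {"buffer": self._state(0, 0, 0, n_w=-1.0)}
        with pytest.raises(LedgerError, match="negative"):
            binding_delta_g(s, s, self._state(0, 0, 0))

    def test_species_missing_from_one_state_is_error(self):
        s = {"buffer": self._state(0, 0, 0)}
        with pytest.raises(LedgerError, match="missing"):
            binding_delta_g(s, {}, self._state(0, 0, 0))


class TestClasswiseDecomposition:
    def test_grouped_sums_match_brute_force(self):
        _, top = gen_solution_ensemble(n_waters=5, n_frames=2, seed=0)
        rng = np.random.default_rng(1)
        per_monomer = {
            int(m): tuple(rng.normal(size=3)) for m in top.units("monomer")
        }
        df = classwise_decomposition(per_monomer, top)
        for cls in df.index.drop("Total"):
            expected = np.sum(
                [v for m, v in per_monomer.items()
                 if top.monomer_class[m] == cls], axis=0
            )
            np.testing.assert_allclose(df.loc[cls].values, expected)
        np.testing.assert_allclose(
            df.loc["Total"].values, df.drop(index="Total").sum(axis=0).values
        )

    def test_single_class_total_equals_species_total(self):
        _, top = gen_solution_ensemble(n_waters=5, n_frames=2, seed=0)
        per_monomer = {int(m): (1.0, 2.0, 1.0) for m in top.units("monomer")
                       if top.monomer_class[int(m)] == "basic"}
        df = classwise_decomposition(per_monomer, top)
        assert df.loc["basic", "dH"] == pytest.approx(df.loc["Total", "dH"])


class TestGroupStandardError:
    def test_identical_group_means_give_zero(self):
        vals = np.array([1.0, 3.0, 1.0, 3.0])
        groups = np.array([0, 0, 1, 1])
        assert group_standard_error(vals, groups) == 0.0

    def test_two_group_means_zero_and_two_give_one(self):
        vals = np.array([0.0, 0.0, 2.0, 2.0])
        groups = np.array([0, 0, 1, 1])
        assert group_standard_error(vals, groups) == pytest.approx(1.0)

    def test_invariant_under_within_group_permutation(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=25)
        groups = np.repeat(np.arange(5), 5)
        se1 = group_standard_error(vals, groups)
        perm = vals.copy()
        perm[:5] = perm[:5][::-1]
        assert group_standard_error(perm, groups) == pytest.approx(se1)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError, match="2 groups"):
            group_standard_error(np.array([1.0, 2.0]), np.array([0, 0]))


class TestReferenceTables:
    def test_decomposition_components_sum_to_totals(self):
        # ten independently rounded rows can drift a couple of units
        # from the independently rounded Total (the published CIT dH
        # column does so by 2)
        ref = reference_free_energy_decomposition()
        for system in ("TPP", "CIT"):
            df = ref[[f"dG_{system}", f"dH_{system}", f"TdS_{system}"]]
            df = df.rename(columns=lambda c: c.split("_")[0])
            check_free_energy_table(df, decimals=0, slack=2.0)

    def test_mean_formal_charge_of_mixed_charge_ion_set(self):
        top = ion_set_topology([-4.0, -5.0, -5.0, -5.0, -5.0])
        assert average_formal_charge(top, "polyanion") == pytest.approx(-4.8)

    def test_missing_species_role_is_error(self):
        top = ion_set_topology([-1.0])
        with pytest.raises(ValueError, match="no molecules"):
            average_formal_charge(top, "buffer")
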