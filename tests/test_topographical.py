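"""Conformational and orientational topographical entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eemcc.constants import R_GAS
from eemcc.neighbourhood import accumulate_orientational_stats
from eemcc.synthetic import gen_dihedral_series, gen_water_shells
from eemcc.topographical import (
    build_conformer_distribution,
    conformational_entropy,
    find_conformers,
    hb_bias,
    orientational_entropy,
)


class TestFindConformers:
    def test_single_occupied_bin_gives_one_peak(self):
        peaks = find_conformers(np.full(100, 57.0))
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(45.0)  # centre of the [30, 60) bin

    def test_trimodal_series_recovers_three_peaks(self):
        ang = gen_dihedral_series(
            np.array([0.4, 0.35, 0.25]), n_frames=30000, seed=0
        )
        peaks = find_conformers(ang)
        assert len(peaks) == 3
        for target in (-60.0, 60.0, 180.0):
            d = np.abs(peaks - target) % 360.0
            assert np.minimum(d, 360.0 - d).min() <= 30.0

    def test_uniform_histogram_collapses_to_single_conformer(self):
        ang = np.linspace(-180.0, 179.9, 1200)
        with pytest.warns(UserWarning, match="single conformer"):
            peaks = find_conformers(ang)
        assert len(peaks) == 1

    def test_empty_series_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            find_conformers(np.array([]))

    def test_nearby_peaks_resolved_by_population(self):
        # bins at -15 and 45 are 60 degrees apart (allowed); bins at
        # -15 and 15 are 30 apart and can never both be strict peaks
        ang = np.concatenate([
            np.full(50, -10.0), np.full(30, 40.0), np.full(5, 100.0),
        ])
        peaks = find_conformers(ang)
        assert -15.0 in peaks and 45.0 in peaks


class TestConformationalEntropy:
    def test_single_state_zero(self):
        dist = build_conformer_distribution(np.full((1, 50), 10.0))
        assert conformational_entropy(dist) == 0.0

    def test_shannon_value_for_three_states(self):
        # exact occupancies 0.5/0.3/0.2 -> S/kB = 1.0297
        ang = np.concatenate([
            np.full(500, -60.0), np.full(300, 60.0), np.full(200, -180.0)
        ])
        dist = build_conformer_distribution(ang[None, :])
        expected = -(0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2))
        assert conformational_entropy(dist) / R_GAS == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(1.0297, abs=1e-4)

    def test_two_independent_uniform_dihedrals_give_ln9(self):
        # all 9 joint states equally occupied -> S/kB = ln 9
        centers = np.array([-60.0, 60.0, -180.0])
        a = np.repeat(centers, 3)
        b = np.tile(centers, 3)
        series = np.stack([np.tile(a, 40), np.tile(b, 40)])
        dist = build_conformer_distribution(series)
        assert dist.n_conf == 9
        assert conformational_entropy(dist) / R_GAS == pytest.approx(
            np.log(9.0), rel=1e-12
        )

    def test_weights_reshape_state_probabilities(self):
        ang = np.array([[-60.0, 60.0]])
        w = np.array([1.0, 3.0])
        dist = build_conformer_distribution(ang, weights=w)
        assert sorted(dist.state_probs.values()) == [0.25, 0.75]

    def test_entropy_bounded_by_ln_nconf(self):
        ang = gen_dihedral_series(np.array([0.6, 0.3, 0.1]),
                                  n_frames=5000, seed=1)
        dist = build_conformer_distribution(ang[None, :])
        assert conformational_entropy(dist) <= R_GAS * np.log(dist.n_conf) + 1e-9


class TestHBBias:
    def test_bulk_and_balanced_give_quarter(self):
        assert hb_bias(1.0, 1.0) == 0.25
        assert hb_bias(0.5, 0.5) == 0.25

    def test_donor_only_gives_zero(self):
        assert hb_bias(1.0, 0.0) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_symmetric_and_bounded(self, pd_, pa):
        assert hb_bias(pd_, pa) == pytest.approx(hb_bias(pa, pd_), abs=1e-15)
        assert 0.0 <= hb_bias(pd_, pa) <= 0.25 + 1e-15


class TestOrientationalEntropy:
    def test_bulk_limit_value(self):
        # 4 unbiased neighbours: Neff=4, p(HBav)=0.25,
        # S/kB = ln[(4 pi)^(3/2) /8] = 1.7171
        obs = gen_water_shells({"bulk": (4, 1.0, 1.0)}, n_frames=50,
                               n_waters=2, seed=0)
        s = orientational_entropy(accumulate_orientational_stats(obs))
        expected = np.log((4 * np.pi) ** 1.5 * 0.25 / 2)
        assert s / R_GAS == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.717, abs=1e-3)

    def test_fully_donor_biased_shell_is_dropped(self):
        obs = gen_water_shells({"bulk": (4, 1.0, 0.0)}, n_frames=50,
                               n_waters=2, seed=0)
        s, terms, dropped = orientational_entropy(
            accumulate_orientational_stats(obs), return_terms=True
        )
        assert s == 0.0 and len(terms) == 0 and dropped == pytest.approx(1.0)

    def test_alternative_exponent_grouping_is_constant_offset(self):
        obs = gen_water_shells({"bulk": (4, 1.0, 1.0)}, n_frames=50,
                               n_waters=2, seed=0)
        stats = accumulate_orientational_stats(obs)
        s1 = orientational_entropy(stats, exponent="neff_pi_3_2")
        s2 = orientational_entropy(stats, exponent="neff_3_2_pi_1_2")
        assert s1 - s2 == pytest.approx(R_GAS * np.log(np.pi), rel=1e-9)

    def test_bias_reduces_entropy_below_unbiased(self):
        unb = gen_water_shells({"a": (2, 1.0, 1.0), "b": (2, 1.0, 1.0)},
                               n_frames=400, n_waters=5, seed=1)
        bia = gen_water_shells({"a": (2, 1.0, 0.2), "b": (2, 0.2, 1.0)},
                               n_frames=400, n_waters=5, seed=1)
        s_unb = orientational_entropy(accumulate_orientational_stats(unb))
        s_bia = orientational_entropy(accumulate_orientational_stats(bia))
        assert s_bia < s_unb

    def test_recovered_probabilities_match_generator_within_3_sigma(self):
        pd_true = {"a": 0.7, "b": 0.3}
        pa_true = {"a": 0.25, "b": 0.75}
        n_frames, n_waters, n_events = 2000, 5, 2
        obs = gen_water_shells(
            {"a": (2, pd_true["a"], pa_true["a"]),
             "b": (2, pd_true["b"], pa_true["b"])},
            n_frames=n_frames, n_waters=n_waters, seed=7,
        )
        stats = accumulate_orientational_stats(obs)
        c = next(iter(stats.p_c))
        n_draws = n_frames * n_waters * n_events
        for lab in ("a", "b"):
            for got, true in ((stats.p_D[c][lab], pd_true[lab]),
                              (stats.p_A[c][lab], pa_true[lab])):
                sigma = np.sqrt(true * (1 - true) / n_draws)
                assert abs(got - true) < 3 * sigma + 1e-12
        # Neff from the recovered statistics matches the generator inputs
        phb = {lab: hb_bias(pd_true[lab], pa_true[lab]) for lab in ("a", "b")}
        neff_true = sum(phb[lab] * 2 for lab in phb) / 0.25
        _, terms, _ = orientational_entropy(stats, return_terms=True)
        assert terms[c].Neff == pytest.approx(neff_true, rel=0.05)
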