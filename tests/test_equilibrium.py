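"""Solver correctness: closed forms, conservation, oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given

from probesim import (
    CompetitionSystem,
    bisection_oracle,
    competition_cubic_coefficients,
    solve_competition,
    solve_one_to_one,
)
from probesim.assay import protein_for_target_fraction

from .conftest import concentrations, dissociation_constants

NM = 1e-9
UM = 1e-6


def assert_valid_state(state, system, rtol=1e-9):
    """Conservation and mass-action invariants every solve must satisfy."""
    for field in (
        state.free_protein,
        state.free_ligand,
        state.free_inhibitor,
        state.complex_pl,
        state.complex_pi,
    ):
        assert field >= 0.0
    assert state.p_total == pytest.approx(system.p_total, rel=rtol)
    assert state.l_total == pytest.approx(system.l_total, rel=rtol)
    assert state.i_total == pytest.approx(system.i_total, rel=rtol)
    if state.complex_pl > 0:
        assert state.free_protein * state.free_ligand / state.complex_pl == pytest.approx(
            system.kd_pl, rel=rtol
        )
    if state.complex_pi > 0:
        assert state.free_protein * state.free_inhibitor / state.complex_pi == pytest.approx(
            system.kd_pi, rel=rtol
        )


class TestOneToOne:
    def test_no_protein_means_no_complex(self):
        state = solve_one_to_one(0.0, 10 * NM, 100 * NM)
        assert state.complex_pl == 0.0
        assert state.fraction_ligand_bound() == 0.0

    def test_unit_symmetric_case_matches_quadratic_closed_form(self):
        # P0 = L0 = KD = 1: complex = (3 - sqrt(5)) / 2
        state = solve_one_to_one(1.0, 1.0, 1.0)
        assert state.complex_pl == pytest.approx((3 - math.sqrt(5)) / 2, rel=1e-12)
        assert state.free_protein == pytest.approx((math.sqrt(5) - 1) / 2, rel=1e-12)

    def test_baseline_scenario_fraction(self):
        # The protein load derived for a 0.7 baseline with a 100 nM probe
        state = solve_one_to_one(240.33 * NM, 10 * NM, 100 * NM)
        assert state.fraction_ligand_bound() == pytest.approx(0.700, abs=1e-3)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            solve_one_to_one(-1 * NM, 10 * NM, 100 * NM)

    @given(concentrations(), concentrations(), dissociation_constants())
    def test_state_invariants(self, p0, l0, kd):
        state = solve_one_to_one(p0, l0, kd)
        system = CompetitionSystem(p0, l0, 0.0, kd, 1.0)
        assert_valid_state(state, system)


class TestCubicCoefficients:
    def test_unit_system_hand_derived(self):
        system = CompetitionSystem(1.0, 1.0, 0.0, 1.0, 1.0)
        assert competition_cubic_coefficients(system) == (2.0, 0.0, -1.0)

    def test_unit_system_root_matches_quadratic_free_protein(self):
        # p^3 + 2p^2 - 1 has the golden-ratio root (sqrt(5)-1)/2 in [0, 1],
        # which is exactly the 1:1 free protein for P0 = L0 = KD = 1.
        p = (math.sqrt(5) - 1) / 2
        assert p**3 + 2 * p**2 - 1 == pytest.approx(0.0, abs=1e-12)
        assert solve_one_to_one(1.0, 1.0, 1.0).free_protein == pytest.approx(p, rel=1e-12)

    @given(concentrations(), concentrations(), dissociation_constants(),
           dissociation_constants())
    def test_inhibitor_free_cubic_recovers_one_to_one_root(self, p0, l0, kd_pl, kd_pi):
        system = CompetitionSystem(p0, l0, 0.0, kd_pl, kd_pi)
        a, b, c = competition_cubic_coefficients(system)
        p = solve_one_to_one(p0, l0, kd_pl).free_protein
        # residual scaled by the cubic's magnitude at p
        scale = max(abs(p**3), abs(a * p**2), abs(b * p), abs(c))
        assert ((p**3 + a * p**2 + b * p) + c) == pytest.approx(0.0, abs=1e-9 * scale)


class TestCompetition:
    @pytest.mark.parametrize(
        "p0, kd_pl, expected",
        [
            (240.33 * NM, 100 * NM, 0.181),
            (9.33 * NM, 1 * NM, 0.348),
        ],
    )
    def test_screening_scenarios(self, p0, kd_pl, expected):
        system = CompetitionSystem(p0, 10 * NM, 10 * UM, kd_pl, 1 * UM)
        fb = solve_competition(system).fraction_ligand_bound()
        assert fb == pytest.approx(expected, abs=1e-3)

    def test_without_inhibitor_reduces_to_one_to_one(self):
        system = CompetitionSystem(240.33 * NM, 10 * NM, 0.0, 100 * NM, 1 * UM)
        fb = solve_competition(system).fraction_ligand_bound()
        assert fb == pytest.approx(0.700, abs=1e-3)

    @given(concentrations(), concentrations(), concentrations(),
           dissociation_constants(), dissociation_constants())
    def test_state_invariants(self, p0, l0, i0, kd_pl, kd_pi):
        system = CompetitionSystem(p0, l0, i0, kd_pl, kd_pi)
        assert_valid_state(solve_competition(system), system)

    @given(concentrations(), concentrations(), concentrations(),
           dissociation_constants(), dissociation_constants())
    def test_oracle_equivalence(self, p0, l0, i0, kd_pl, kd_pi):
        system = CompetitionSystem(p0, l0, i0, kd_pl, kd_pi)
        fb = solve_competition(system).fraction_ligand_bound()
        fb_oracle = bisection_oracle(system).fraction_ligand_bound()
        assert fb == pytest.approx(fb_oracle, rel=1e-8, abs=1e-15)

    @given(concentrations(), concentrations(), concentrations(),
           dissociation_constants())
    def test_inert_inhibitor_reduces_to_one_to_one(self, p0, l0, i0, kd_pl):
        # KD_PI at a million times the inhibitor load: nothing binds
        system = CompetitionSystem(p0, l0, i0, kd_pl, max(1e6 * i0, 1e-3))
        fb = solve_competition(system).fraction_ligand_bound()
        fb_11 = solve_one_to_one(p0, l0, kd_pl).fraction_ligand_bound()
        assert fb == pytest.approx(fb_11, abs=1e-6)

    @given(concentrations(), concentrations(), concentrations(),
           dissociation_constants(), dissociation_constants())
    def test_swap_symmetry_is_exact(self, p0, l0, i0, kd_pl, kd_pi):
        system = CompetitionSystem(p0, l0, i0, kd_pl, kd_pi)
        state = solve_competition(system)
        swapped = solve_competition(system.swapped())
        assert state.complex_pl == swapped.complex_pi
        assert state.complex_pi == swapped.complex_pl
        assert state.free_protein == swapped.free_protein

    def test_excess_tight_inhibitor_strips_all_ligand(self):
        # P0 << I0 with KD_PI << I0: the competitor soaks up every protein
        system = CompetitionSystem(10 * NM, 10 * NM, 1e-3, 100 * NM, 1 * NM)
        assert solve_competition(system).fraction_ligand_bound() < 1e-3

    def test_zero_protein_gives_empty_state(self):
        state = solve_competition(CompetitionSystem(0.0, 10 * NM, 10 * UM, 100 * NM, 1 * UM))
        assert state.complex_pl == state.complex_pi == 0.0
        assert state.free_ligand == 10 * NM
        assert state.free_inhibitor == 10 * UM

    def test_no_probe_still_equilibrates_inhibitor(self):
        # l_total = 0: the P-I pair follows its own 1:1 equilibrium
        state = solve_competition(CompetitionSystem(1 * UM, 0.0, 1 * UM, 100 * NM, 1 * UM))
        expected = solve_one_to_one(1 * UM, 1 * UM, 1 * UM).complex_pl
        assert state.complex_pl == 0.0
        assert state.complex_pi == pytest.approx(expected, rel=1e-9)


class TestMonotonicity:
    """Directional responses of the readout on 10-point axes."""

    def test_fraction_bound_non_increasing_in_inhibitor_total(self):
        fbs = [
            solve_competition(
                CompetitionSystem(240.33 * NM, 10 * NM, i0, 100 * NM, 1 * UM)
            ).fraction_ligand_bound()
            for i0 in np.logspace(-9, -3, 10)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(fbs, fbs[1:]))

    def test_fraction_bound_non_increasing_in_ligand_kd_at_fixed_protein(self):
        fbs = [
            solve_competition(
                CompetitionSystem(240.33 * NM, 10 * NM, 10 * UM, kd, 1 * UM)
            ).fraction_ligand_bound()
            for kd in np.logspace(-10, -4, 10)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(fbs, fbs[1:]))

    def test_fraction_bound_non_decreasing_in_inhibitor_kd(self):
        fbs = [
            solve_competition(
                CompetitionSystem(240.33 * NM, 10 * NM, 10 * UM, 100 * NM, kd)
            ).fraction_ligand_bound()
            for kd in np.logspace(-10, -4, 10)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(fbs, fbs[1:]))


class TestBisectionOracle:
    def test_low_baseline_scenario(self):
        # protein derived for a 0.1 baseline with the 100 nM probe
        system = CompetitionSystem(12.111 * NM, 10 * NM, 10 * UM, 100 * NM, 1 * UM)
        fb = bisection_oracle(system).fraction_ligand_bound()
        assert fb == pytest.approx(0.011, abs=1e-3)

    def test_weak_probe_barely_responds(self):
        p0 = protein_for_target_fraction(10 * NM, 100 * UM, 0.7)
        system = CompetitionSystem(p0, 10 * NM, 10 * UM, 100 * UM, 1 * UM)
        fb = bisection_oracle(system).fraction_ligand_bound()
        assert 0.65 <= fb <= 0.70

    def test_rejects_non_positive_tolerance(self):
        system = CompetitionSystem(1.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            bisection_oracle(system, tolerance=0.0)


def test_arbitrary_precision_fallback_agrees_with_oracle():
    from probesim.equilibrium import _solve_mpmath, _state_from_free_protein

    system = CompetitionSystem(240.33 * NM, 10 * NM, 10 * UM, 100 * NM, 1 * UM)
    state = _state_from_free_protein(_solve_mpmath(system), system)
    fb_oracle = bisection_oracle(system).fraction_ligand_bound()
    assert state.fraction_ligand_bound() == pytest.approx(fb_oracle, rel=1e-10)
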