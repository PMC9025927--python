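"""Eckart potential, side-dependent kinetic energies, transmission, conductance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iontunnel import (
    EckartBarrier,
    MembraneSide,
    eckart_potential,
    kinetic_energy,
    log_transmission_approx,
    log_transmission_exact,
    membrane_conductance,
    per_um2_to_per_cm2,
    transmission_approx,
    transmission_exact,
    tunneling_probability,
    unitary_conductance,
)


class TestEckartPotential:
    def test_peak_is_barrier_height(self, barrier):
        assert eckart_potential(0.0, barrier) == barrier.height_G

    def test_falls_to_042_g_at_gate_length(self, barrier):
        # sech^2(1) = 0.41997...
        ratio = eckart_potential(barrier.gate_length_L, barrier) / barrier.height_G
        assert ratio == pytest.approx(0.42, abs=5e-4)

    def test_far_tail_is_negligible(self):
        b = EckartBarrier(height_G=1e-20, gate_length_L=1e-10)
        # direct high-precision: sech^2(10) = 8.2446e-9 -> 8.24e-29 J
        assert eckart_potential(10 * b.gate_length_L, b) < 1e-27
        assert eckart_potential(10 * b.gate_length_L, b) == pytest.approx(8.2446e-29, rel=1e-3)

    def test_even_in_x_and_vectorized(self, barrier):
        x = np.linspace(-5e-10, 5e-10, 41)
        u = eckart_potential(x, barrier)
        np.testing.assert_allclose(u, u[::-1], rtol=1e-12)
        assert u.max() == pytest.approx(barrier.height_G)

    def test_zero_length_is_undefined_off_origin(self):
        b = EckartBarrier(height_G=1e-20, gate_length_L=0.0)
        assert eckart_potential(0.0, b) == b.height_G
        with pytest.raises(ValueError):
            eckart_potential(1e-10, b)

    def test_no_overflow_for_huge_offsets(self, barrier):
        assert eckart_potential(1e-6, barrier) == 0.0


class TestKineticEnergy:
    def test_intracellular_is_thermal(self, kion, barrier, constants):
        e = kinetic_energy(kion, MembraneSide.INTRACELLULAR, 0.07, barrier, constants)
        # direct arithmetic: 1.5 x 1.38e-23 x 310
        assert e == pytest.approx(6.417e-21, rel=1e-9)

    def test_extracellular_sodium_at_resting_potential(self, na, barrier, constants):
        e = kinetic_energy(na, MembraneSide.EXTRACELLULAR, 0.073, barrier, constants)
        assert e == pytest.approx(1.8097e-20, rel=1e-9)

    def test_zero_potential_sides_agree(self, na, barrier, constants):
        e_out = kinetic_energy(na, MembraneSide.EXTRACELLULAR, 0.0, barrier, constants)
        e_in = kinetic_energy(na, MembraneSide.INTRACELLULAR, 0.0, barrier, constants)
        assert e_out == e_in

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_gate_location_divides_field_gain(self, na, constants, n):
        b = EckartBarrier(height_G=2e-20, gate_length_L=1e-10, gate_location_n=n)
        e = kinetic_energy(na, MembraneSide.EXTRACELLULAR, 0.073, b, constants)
        expected = na.charge_q * 0.073 / n + constants.thermal_energy
        assert e == pytest.approx(expected, rel=1e-12)

    def test_negative_potential_rejected(self, na, barrier, constants):
        with pytest.raises(ValueError):
            kinetic_energy(na, MembraneSide.EXTRACELLULAR, -0.01, barrier, constants)


class TestTransmission:
    def test_exact_zero_energy_gives_zero(self, na, barrier, constants):
        assert transmission_exact(na, barrier, 0.0, constants) == 0.0

    def test_exact_vanishing_barrier_is_tanh_squared(self, na, constants):
        # algebraic limit of the closed form: G -> 0 gives tanh^2(pi k L)
        b = EckartBarrier(height_G=1e-45, gate_length_L=1e-10)
        e_k = 6.417e-21
        k = math.sqrt(2 * na.mass_m * e_k) / constants.hbar
        expected = math.tanh(math.pi * k * b.gate_length_L) ** 2
        assert transmission_exact(na, b, e_k, constants) == pytest.approx(expected, rel=1e-9)

    def test_approx_over_barrier_clamps_to_one(self, na, barrier, constants):
        assert transmission_approx(na, barrier, barrier.height_G, constants) == 1.0
        assert transmission_approx(na, barrier, 2 * barrier.height_G, constants) == 1.0

    def test_approx_zero_length_gate_is_transparent(self, na, constants):
        b = EckartBarrier(height_G=2e-20, gate_length_L=0.0)
        assert transmission_approx(na, b, 1e-21, constants, warn=False) == 1.0

    def test_sodium_worked_exponent(self, na, barrier, constants):
        # direct arithmetic with the stored constants gives 101.15
        ln_t = log_transmission_approx(na, barrier, 6.417e-21, constants)
        assert -ln_t == pytest.approx(101.15, rel=1e-3)

    def test_exact_and_approx_agree_at_the_checkpoint(self, na, constants):
        # L = 0.5 angstrom, E_K = G = 1e-20 J: both cosh arguments ~82
        b = EckartBarrier(height_G=1e-20, gate_length_L=0.5e-10)
        ln_exact = log_transmission_exact(na, b, 1e-20, constants)
        ln_approx = log_transmission_approx(na, b, 1e-20, constants)
        assert abs(ln_exact - ln_approx) <= 1.0

    def test_no_overflow_in_deep_tunneling(self, na, constants):
        b = EckartBarrier(height_G=4e-20, gate_length_L=2e-10)
        t = transmission_exact(na, b, 1e-21, constants)
        assert 0.0 <= t < 1e-200  # cosh never overflows to inf/nan
        assert math.isfinite(log_transmission_exact(na, b, 1e-21, constants))

    def test_minus_one_retention_changes_little_here(self, na, barrier, constants):
        kept = log_transmission_exact(na, barrier, 6.417e-21, constants, drop_minus_one=False)
        dropped = log_transmission_exact(na, barrier, 6.417e-21, constants, drop_minus_one=True)
        assert kept != dropped
        assert abs(kept - dropped) < 0.5

    def test_warns_outside_validity_region(self, na, constants):
        b = EckartBarrier(height_G=1e-22, gate_length_L=1e-12)
        with pytest.warns(UserWarning, match="validity"):
            transmission_approx(na, b, 1e-23, constants)

    @settings(derandomize=True, max_examples=150)
    @given(
        g20=st.floats(1.0, 4.0),
        frac=st.floats(0.05, 0.95),
        l10=st.floats(0.5, 2.0),
        m26=st.floats(3.0, 7.0),
    )
    def test_log_agreement_within_one_on_validity_domain(self, g20, frac, l10, m26):
        """|ln T_exact - ln T_approx| <= 1 wherever both cosh arguments >= 3."""
        from iontunnel.constants import IonSpecies, ELEMENTARY_CHARGE, PhysicalConstants

        constants = PhysicalConstants()
        ion = IonSpecies("X", m26 * 1e-26, ELEMENTARY_CHARGE, 1, 0.0, 0.0)
        b = EckartBarrier(height_G=g20 * 1e-20, gate_length_L=l10 * 1e-10)
        e_k = frac * b.height_G
        a = 2 * math.pi * b.gate_length_L * math.sqrt(2 * ion.mass_m * e_k) / constants.hbar
        bb = 2 * math.pi * b.gate_length_L * math.sqrt(2 * ion.mass_m * b.height_G) / constants.hbar
        if min(a, bb) < 3.0:
            return
        diff = abs(log_transmission_exact(ion, b, e_k, constants)
                   - log_transmission_approx(ion, b, e_k, constants))
        assert diff <= 1.0

    @settings(derandomize=True, max_examples=100)
    @given(
        g20=st.floats(1.5, 4.0),
        l10=st.floats(0.3, 2.0),
        m26=st.floats(3.0, 7.0),
        e21=st.floats(1.0, 10.0),
    )
    def test_approx_monotonicity(self, g20, l10, m26, e21):
        """T_approx falls with G, L, m and rises with E_K below the barrier."""
        from iontunnel.constants import IonSpecies, ELEMENTARY_CHARGE, PhysicalConstants

        constants = PhysicalConstants()
        e_k = e21 * 1e-21
        if e_k >= g20 * 1e-20 * 0.98:
            return
        ion = IonSpecies("X", m26 * 1e-26, ELEMENTARY_CHARGE, 1, 0.0, 0.0)
        b = EckartBarrier(height_G=g20 * 1e-20, gate_length_L=l10 * 1e-10)
        base = log_transmission_approx(ion, b, e_k, constants, warn=False)
        assert log_transmission_approx(
            ion, EckartBarrier(b.height_G * 1.1, b.gate_length_L), e_k,
            constants, warn=False) < base
        assert log_transmission_approx(
            ion, EckartBarrier(b.height_G, b.gate_length_L * 1.1), e_k,
            constants, warn=False) < base
        heavier = IonSpecies("Y", ion.mass_m * 1.1, ELEMENTARY_CHARGE, 1, 0.0, 0.0)
        assert log_transmission_approx(heavier, b, e_k, constants, warn=False) < base
        assert log_transmission_approx(ion, b, e_k * 1.1, constants, warn=False) > base
        assert base <= 0.0


class TestTunnelingProbability:
    def test_zero_potential_equalizes_sides(self, na, barrier, constants):
        t_out = tunneling_probability(na, barrier, MembraneSide.EXTRACELLULAR, 0.0, constants)
        t_in = tunneling_probability(na, barrier, MembraneSide.INTRACELLULAR, 0.0, constants)
        assert t_out == t_in

    def test_extracellular_dominates_at_positive_potential(self, na, barrier, constants):
        t_out = tunneling_probability(na, barrier, MembraneSide.EXTRACELLULAR, 0.07, constants)
        t_in = tunneling_probability(na, barrier, MembraneSide.INTRACELLULAR, 0.07, constants)
        assert t_out > t_in

    def test_potassium_intracellular_worked_exponent(self, kion, constants):
        b = EckartBarrier(height_G=1e-20, gate_length_L=1e-10)
        from iontunnel import log_tunneling_probability

        ln_t = log_tunneling_probability(kion, b, MembraneSide.INTRACELLULAR, 0.0, constants)
        assert -ln_t == pytest.approx(42.92, rel=2e-3)

    def test_divalent_calcium_outruns_sodium_outside(self, na, ca, barrier, constants):
        t_ca = tunneling_probability(ca, barrier, MembraneSide.EXTRACELLULAR, 0.073, constants)
        t_na = tunneling_probability(na, barrier, MembraneSide.EXTRACELLULAR, 0.073, constants)
        assert t_ca > t_na


class TestConductance:
    def test_monovalent_quantum_of_conductance(self, na, constants):
        assert unitary_conductance(na, 1.0, constants) * 1e3 == pytest.approx(3.88e-2, rel=1e-3)

    def test_divalent_quantum_of_conductance(self, ca, constants):
        assert unitary_conductance(ca, 1.0, constants) * 1e3 == pytest.approx(15.52e-2, rel=1e-3)

    def test_divalent_to_monovalent_ratio_is_four(self, na, ca, constants):
        ratio = unitary_conductance(ca, 0.3, constants) / unitary_conductance(na, 0.3, constants)
        assert ratio == pytest.approx(4.0, rel=1e-12)

    def test_linearity_in_transmission(self, na, constants):
        assert unitary_conductance(na, 0.5, constants) == pytest.approx(
            0.5 * unitary_conductance(na, 1.0, constants), rel=1e-12)
        assert unitary_conductance(na, 0.0, constants) == 0.0

    def test_membrane_conductance_worked_value(self, na, constants):
        c_q = unitary_conductance(na, 1e-11, constants)
        assert membrane_conductance(c_q, 1e10) == pytest.approx(3.88e-3, rel=1e-3)

    def test_density_unit_equivalence(self):
        assert per_um2_to_per_cm2(1e2) == 1e10

    def test_zero_density_and_negative_density(self):
        assert membrane_conductance(1e-5, 0.0) == 0.0
        with pytest.raises(ValueError):
            membrane_conductance(1e-5, -1.0)

    def test_transmission_out_of_range_rejected(self, na, constants):
        with pytest.raises(ValueError):
            unitary_conductance(na, 1.5, constants)


class TestBarrierValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(height_G=-1e-20, gate_length_L=1e-10),
        dict(height_G=1e-20, gate_length_L=-1e-10),
        dict(height_G=1e-20, gate_length_L=1e-10, gate_location_n=5),
    ])
    def test_invalid_barriers_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EckartBarrier(**kwargs)
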