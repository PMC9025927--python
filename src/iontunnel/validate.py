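"""Validation suite: every printed worked example of the model, recomputed.

Each check recomputes one reference intermediate value from the package
and compares it at a stated tolerance.  The two threshold-chain numbers
carry a 2% band: the reference values were produced through intermediate
rounding (2-significant-figure hand-offs) that cannot be reconstructed
exactly and re-derivation lands ~1% away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .constants import PhysicalConstants, calcium, potassium, sodium
from .ghk import LeakProfile, classical_vm
from .synapse import (
    AxonGeometry,
    ThresholdSpec,
    cylinder_geometry,
    ions_per_channel,
    k_release_concentration,
    threshold_coefficient,
    threshold_tunneling,
)
from .tunneling import (
    EckartBarrier,
    MembraneSide,
    eckart_potential,
    kinetic_energy,
    log_tunneling_probability,
    unitary_conductance,
)

__all__ = ["ValidationCheck", "run_validation", "validation_table"]


@dataclass(frozen=True)
class ValidationCheck:
    """One row of the validation report."""

    name: str
    expected: float
    computed: float
    rel_dev: float
    tolerance: float
    passed: bool


def _check(name: str, expected: float, computed: float, tol: float) -> ValidationCheck:
    rel = abs(computed - expected) / abs(expected) if expected != 0 else abs(computed)
    return ValidationCheck(name, expected, computed, rel, tol, rel <= tol)


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def run_validation() -> list[ValidationCheck]:
    """Recompute all printed worked examples and compare at stated tolerances."""
    constants = PhysicalConstants()
    leak = LeakProfile()
    na, k = sodium(), potassium()
    checks: list[ValidationCheck] = []

    # resting basolateral potential from the classical closed form
    checks.append(_check("classical_Vm_V", 0.073, classical_vm(leak, constants).Vm, 5e-3))
    checks.append(_check("F_over_RT_per_V", 37.45, constants.f_over_rt, 1e-3))

    # conductance quanta q^2/h (in mS) for mono- and divalent ions
    checks.append(_check("q2_over_h_monovalent_mS", 3.88e-2,
                         unitary_conductance(na, 1.0, constants) * 1e3, 1e-3))
    checks.append(_check("q2_over_h_divalent_mS", 15.52e-2,
                         unitary_conductance(calcium(), 1.0, constants) * 1e3, 1e-3))

    # barrier shape: U(L)/U(0) = sech^2(1)
    barrier = EckartBarrier(height_G=1e-20, gate_length_L=1e-10)
    ratio = eckart_potential(1e-10, barrier) / eckart_potential(0.0, barrier)
    checks.append(_check("eckart_U(L)_over_G", 0.42, ratio, 1e-3))

    # kinetic energies at the gate
    e_intra = kinetic_energy(k, MembraneSide.INTRACELLULAR, 0.0, barrier, constants)
    checks.append(_check("thermal_energy_J", 6.42e-21, e_intra, 1e-3))
    e_extra = kinetic_energy(na, MembraneSide.EXTRACELLULAR, 0.073, barrier, constants)
    checks.append(_check("Na_extracellular_EK_J", 1.81e-20, e_extra, 1e-3))

    # worked tunneling exponents (exponential form)
    na_barrier = EckartBarrier(height_G=2e-20, gate_length_L=1e-10)
    ln_t = log_tunneling_probability(na, na_barrier, MembraneSide.INTRACELLULAR, 0.0, constants)
    checks.append(_check("Na_intracellular_exponent", 101.0, -ln_t, 5e-3))
    k_barrier = EckartBarrier(height_G=1e-20, gate_length_L=1e-10)
    ln_t_k = log_tunneling_probability(k, k_barrier, MembraneSide.INTRACELLULAR, 0.0, constants)
    checks.append(_check("K_intracellular_exponent", 43.0, -ln_t_k, 5e-3))

    # axon geometry chain
    geom = cylinder_geometry(AxonGeometry())
    checks.append(_check("axon_surface_um2", 314.0, geom.surface_area_um2, 1e-3))
    checks.append(_check("axon_intra_volume_um3", 78.5, geom.intra_volume_um3, 1e-3))
    checks.append(_check("axon_extra_volume_um3", 52.6, geom.extra_volume_um3, 1e-3))

    k_ap = k_release_concentration(1.37e6, geom.extra_volume_um3, constants)
    checks.append(_check("K_AP_mmol_per_L", 4.3e-2, k_ap, 1e-2))

    n_k = ions_per_channel(1.37e6 / geom.surface_area_um2, 100.0)
    checks.append(_check("NK_ions_per_channel", 44.0, float(n_k.rounded), 1e-12))

    # threshold chain (2% band: reference values carry intermediate rounding)
    spec = ThresholdSpec(Vm_threshold=0.055, threshold_density_D=1e8, leak=leak)
    coef = threshold_coefficient(spec, constants)
    checks.append(_check("threshold_coefficient_mmol_per_L", 9.64e-7, coef, 2e-2))
    t_thr = threshold_tunneling(spec, _round_sig(k_ap, 2), constants)
    checks.append(_check("T_Q_threshold", 2.24e-5, t_thr, 2e-2))

    # the minimum achievable tunneling fraction exceeds the threshold
    min_fraction = 1.0 / n_k.rounded
    checks.append(_check("min_fraction_1_over_NK", 2.27e-2, min_fraction, 5e-3))
    checks.append(_check("min_fraction_exceeds_threshold", 1.0,
                         1.0 if min_fraction > t_thr else 0.0, 1e-12))
    return checks


def validation_table(checks: list[ValidationCheck] | None = None) -> pd.DataFrame:
    """The validation report as a deterministic DataFrame."""
    checks = checks if checks is not None else run_validation()
    return pd.DataFrame([c.__dict__ for c in checks],
                        columns=["name", "expected", "computed", "rel_dev",
                                 "tolerance", "passed"])
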