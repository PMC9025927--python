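"""Eckart-barrier transmission and quantum conductance of closed channel gates.

The closed gate of a voltage-gated channel is modelled as a symmetric
Eckart barrier U(x) = G sech^2(x/L).  An ion of mass m and kinetic energy
E_K crosses it with the closed-form transmission

    T_Q = (cosh a - 1) / (cosh a + cosh b),
    a = 2 pi L sqrt(2 m E_K) / hbar,   b = 2 pi delta,

where delta = (1/2) sqrt(8 m G L^2 / hbar^2 - 1); dropping the -1 gives
b = 2 pi L sqrt(2 m G) / hbar and, with the large-argument cosh
approximation, the WKB-like exponential

    T_Q ~ exp[-(2 pi L sqrt(2 m) / hbar) (sqrt G - sqrt E_K)].

Extracellular ions gain q Vm / n crossing the membrane field before
hitting the gate (n = 1..4 indexes how deep into the pore the gate sits);
both sides carry the thermal (3/2) k_B T.  A transmitting channel carries
the conductance quantum (q^2/h) T_Q, and D such channels per unit area
give the areal quantum conductance.

All transmissions are evaluated in log space; cosh never overflows.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import IonSpecies, PhysicalConstants

__all__ = [
    "MembraneSide",
    "EckartBarrier",
    "eckart_potential",
    "kinetic_energy",
    "log_transmission_exact",
    "log_transmission_approx",
    "transmission_exact",
    "transmission_approx",
    "log_tunneling_probability",
    "tunneling_probability",
    "unitary_conductance",
    "membrane_conductance",
    "per_um2_to_per_cm2",
]

_LN2 = math.log(2.0)
#: Validity threshold for cosh x ~ e^x / 2 (holds for x >= 3).
COSH_APPROX_MIN_ARG = 3.0


class MembraneSide(enum.Enum):
    """Which compartment the tunneling ion starts from."""

    EXTRACELLULAR = "extracellular"
    INTRACELLULAR = "intracellular"


@dataclass(frozen=True)
class EckartBarrier:
    """Closed-gate barrier: height G (J), length L (m), location index n.

    L is the half-width at which the potential has fallen to
    sech^2(1) ~ 0.42 of its peak.  The location index n in {1,2,3,4}
    determines the fraction Vm/n of the membrane potential that
    accelerates extracellular ions before they reach the gate (n = 1:
    gate at the intracellular end, full drop available).
    """

    height_G: float
    gate_length_L: float
    gate_location_n: int = 1

    def __post_init__(self) -> None:
        if self.height_G <= 0:
            raise ValueError("barrier height_G must be positive")
        if self.gate_length_L < 0:
            raise ValueError("gate_length_L must be non-negative")
        if self.gate_location_n not in (1, 2, 3, 4):
            raise ValueError("gate_location_n must be one of 1, 2, 3, 4")


def _log_sech(u):
    # log sech(u) = -|u| + log 2 - log1p(exp(-2|u|)), overflow-free
    au = np.abs(u)
    return _LN2 - au - np.log1p(np.exp(-2.0 * au))


def eckart_potential(x, barrier: EckartBarrier):
    """Barrier energy U(x) = G sech^2(x/L) at ion position x (m).

    Even in x, peaks at G for x = 0, and decays to zero for |x| >> L.
    Accepts scalars or arrays.  A zero-length barrier has no defined
    shape away from the origin.
    """
    x = np.asarray(x, dtype=float)
    if barrier.gate_length_L == 0:
        if np.any(x != 0):
            raise ValueError("eckart_potential undefined for gate_length_L = 0 at x != 0")
        out = np.full_like(x, barrier.height_G)
        return out if out.ndim else float(out)
    u = x / barrier.gate_length_L
    out = barrier.height_G * np.exp(2.0 * _log_sech(u))
    return out if out.ndim else float(out)


def kinetic_energy(
    ion: IonSpecies,
    side: MembraneSide,
    Vm: float,
    barrier: EckartBarrier,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Total kinetic energy (J) of an ion arriving at the closed gate.

    Extracellular ions pick up q Vm / n from the membrane field on top of
    the thermal (3/2) k_B T; intracellular ions hit the gate before the
    field and carry only the thermal term.  Vm is the absolute (positive)
    membrane potential in volts.
    """
    if Vm < 0:
        raise ValueError("Vm must be the absolute (non-negative) membrane potential")
    e_thermal = constants.thermal_energy
    if side is MembraneSide.INTRACELLULAR:
        return e_thermal
    return ion.charge_q * Vm / barrier.gate_location_n + e_thermal


def _wave_args(mass: float, barrier: EckartBarrier, E_K: float,
               constants: PhysicalConstants, drop_minus_one: bool) -> tuple[float, float]:
    """Return the cosh arguments (a, b) of the exact transmission formula."""
    L = barrier.gate_length_L
    hbar = constants.hbar
    a = 2.0 * math.pi * L * math.sqrt(2.0 * mass * E_K) / hbar
    s = 8.0 * mass * barrier.height_G * L * L / (hbar * hbar)
    if drop_minus_one or s < 1.0:
        b = math.pi * math.sqrt(s)  # = 2 pi L sqrt(2 m G) / hbar
    else:
        b = math.pi * math.sqrt(s - 1.0)
    return a, b


def _log_coshm1(x: float) -> float:
    # log(cosh x - 1) = log 2 + 2 log sinh(x/2); -inf at x = 0
    h = 0.5 * x
    if h == 0.0:
        return -math.inf
    log_sinh = h + math.log1p(-math.exp(-2.0 * h)) - _LN2
    return _LN2 + 2.0 * log_sinh


def _log_cosh(x: float) -> float:
    return x + math.log1p(math.exp(-2.0 * x)) - _LN2


def log_transmission_exact(
    ion: IonSpecies,
    barrier: EckartBarrier,
    E_K: float,
    constants: PhysicalConstants = PhysicalConstants(),
    drop_minus_one: bool = True,
) -> float:
    """ln of the exact Eckart transmission (cosh a - 1)/(cosh a + cosh b).

    ``drop_minus_one`` controls the -1 under the square root in the
    barrier term; when retained it is only applied where
    8 m G L^2 / hbar^2 >= 1 (below that the argument would go negative).
    """
    if E_K < 0:
        raise ValueError("E_K must be non-negative")
    if E_K == 0.0:
        return -math.inf
    if barrier.gate_length_L == 0.0:
        return 0.0  # no barrier extent: numerator == denominator term
    a, b = _wave_args(ion.mass_m, barrier, E_K, constants, drop_minus_one)
    num = _log_coshm1(a)
    den = np.logaddexp(_log_cosh(a), _log_cosh(b))
    return float(num - den)


def log_transmission_approx(
    ion: IonSpecies,
    barrier: EckartBarrier,
    E_K: float,
    constants: PhysicalConstants = PhysicalConstants(),
    warn: bool = True,
) -> float:
    """ln of the exponential transmission, clamped to 0 over the barrier.

    ln T = -(2 pi L sqrt(2 m) / hbar) (sqrt G - sqrt E_K) for E_K < G,
    0 (T = 1) otherwise.  Emits a warning when either cosh argument of
    the parent formula is below 3, where the exponential approximation
    loses validity.
    """
    if E_K < 0:
        raise ValueError("E_K must be non-negative")
    if E_K == 0.0:
        return -math.inf
    a, b = _wave_args(ion.mass_m, barrier, E_K, constants, drop_minus_one=True)
    if warn and min(a, b) < COSH_APPROX_MIN_ARG:
        warnings.warn(
            "exponential transmission used outside its validity region "
            f"(cosh arguments {a:.3g}, {b:.3g} < {COSH_APPROX_MIN_ARG:g})",
            stacklevel=2,
        )
    return min(0.0, a - b)


def transmission_exact(
    ion: IonSpecies,
    barrier: EckartBarrier,
    E_K: float,
    constants: PhysicalConstants = PhysicalConstants(),
    drop_minus_one: bool = True,
) -> float:
    """Exact Eckart transmission probability in [0, 1]."""
    return math.exp(log_transmission_exact(ion, barrier, E_K, constants, drop_minus_one))


def transmission_approx(
    ion: IonSpecies,
    barrier: EckartBarrier,
    E_K: float,
    constants: PhysicalConstants = PhysicalConstants(),
    warn: bool = True,
) -> float:
    """Exponential (large-argument) transmission probability in (0, 1]."""
    return math.exp(log_transmission_approx(ion, barrier, E_K, constants, warn))


def log_tunneling_probability(
    ion: IonSpecies,
    barrier: EckartBarrier,
    side: MembraneSide,
    Vm: float,
    constants: PhysicalConstants = PhysicalConstants(),
    method: str = "approx",
    warn: bool = False,
) -> float:
    """ln T_Q for an ion from the given side at membrane potential Vm."""
    E_K = kinetic_energy(ion, side, Vm, barrier, constants)
    if method == "approx":
        return log_transmission_approx(ion, barrier, E_K, constants, warn=warn)
    if method == "exact":
        return log_transmission_exact(ion, barrier, E_K, constants)
    raise ValueError("method must be 'approx' or 'exact'")


def tunneling_probability(
    ion: IonSpecies,
    barrier: EckartBarrier,
    side: MembraneSide,
    Vm: float,
    constants: PhysicalConstants = PhysicalConstants(),
    method: str = "approx",
    warn: bool = False,
) -> float:
    """Side-dependent tunneling probability through the closed gate."""
    return math.exp(log_tunneling_probability(ion, barrier, side, Vm, constants, method, warn))


def unitary_conductance(
    ion: IonSpecies,
    T_Q: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Single-channel quantum conductance C_Q = (q^2/h) T_Q in siemens.

    At T_Q = 1 this is 3.88e-5 S (3.88e-2 mS) for monovalent ions and
    four times that for divalent ions.
    """
    if not 0.0 <= T_Q <= 1.0:
        raise ValueError("T_Q must lie in [0, 1]")
    return ion.charge_q**2 / constants.planck_h * T_Q


def membrane_conductance(C_Q: float, D: float) -> float:
    """Areal quantum conductance MC_Q = C_Q x D in mS/cm^2.

    C_Q is a single-channel conductance in siemens and D a channel
    density in channels/cm^2 (use :func:`per_um2_to_per_cm2` for
    densities quoted per square micrometre).
    """
    if D < 0:
        raise ValueError("channel density D must be non-negative")
    return C_Q * 1e3 * D


def per_um2_to_per_cm2(D_um2: float) -> float:
    """Convert channels/um^2 to channels/cm^2 (1 um^2 = 1e-8 cm^2)."""
    return D_um2 * 1e8
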