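"""Quantum-synapse machinery: K+ release geometry, threshold tunneling, and
the Bernoulli cascade of action-potential induction.

An action potential in one axon dumps N_AP potassium ions into the
extracellular space; in a demyelinated neighbour those ions strike the
exposed closed K channels and may tunnel through.  The chain is:

* cylinder geometry -> extracellular volume -> concentration rise [K]_AP,
* N_K = (ions per unit area) / (channels per unit area): K+ hits per channel,
* a threshold tunneling probability T_Q(Thr) from the GHK relation at the
  firing threshold potential, and
* the cascade P1 = 1-(1-T_Q)^N_K (one channel), P2 = 1-(1-P1)^D (one um^2
  patch of D channels), P3 = 1-(1-P2)^N (N patches of demyelinated area),
  which collapses to 1-P3 = (1-T_Q)^(N_K D N).

Complements are accumulated in log space so the cascade stays exact for
tunneling probabilities down to 1e-300.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd
from scipy.stats import binom

from .constants import IonSpecies, PhysicalConstants, potassium
from .ghk import LeakProfile, sweep_table_to_csv  # noqa: F401  (re-export for CSV emission)
from .tunneling import EckartBarrier, MembraneSide, log_tunneling_probability

__all__ = [
    "AxonGeometry",
    "SynapseField",
    "ThresholdSpec",
    "InductionProbabilities",
    "SynapseScenario",
    "cylinder_geometry",
    "k_release_concentration",
    "ions_per_channel",
    "threshold_coefficient",
    "threshold_tunneling",
    "bernoulli_pmf",
    "induction_probability",
    "sweep_induction",
]


@dataclass(frozen=True)
class AxonGeometry:
    """Cylindrical axon segment that releases K+ during an action potential.

    Defaults: radius 0.5 um, length 100 um (surface ~314 um^2,
    intracellular volume ~78.5 um^3), extracellular/intracellular volume
    ratio 0.67, 1.37e6 K+ ions released per action potential over that
    surface, and 100 channels/um^2.
    """

    radius_r: float = 0.5  # um
    length_Laxon: float = 100.0  # um
    extra_to_intra_ratio: float = 0.67
    N_AP_total: float = 1.37e6
    channel_density_Dum2: float = 100.0

    def __post_init__(self) -> None:
        if self.radius_r <= 0 or self.length_Laxon <= 0:
            raise ValueError("axon radius and length must be positive")
        if self.extra_to_intra_ratio <= 0:
            raise ValueError("extra_to_intra_ratio must be positive")
        if self.N_AP_total < 0:
            raise ValueError("N_AP_total must be non-negative")
        if self.channel_density_Dum2 < 0:
            raise ValueError("channel_density_Dum2 must be non-negative")


class CylinderGeometry(NamedTuple):
    surface_area_um2: float
    intra_volume_um3: float
    extra_volume_um3: float


@dataclass(frozen=True)
class SynapseField:
    """Derived quantities describing one quantum-synapse encounter."""

    K_release_conc: float  # mmol/L, the [K]_AP rise
    ions_per_channel_NK: float
    channels_per_area_Dum2: float
    area_count_Num2: float
    demyelinated_area_A: float  # um^2

    def __post_init__(self) -> None:
        for name in ("K_release_conc", "ions_per_channel_NK", "channels_per_area_Dum2",
                     "area_count_Num2", "demyelinated_area_A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not math.isclose(self.area_count_Num2, self.demyelinated_area_A, rel_tol=1e-12):
            raise ValueError("area_count_Num2 must equal demyelinated_area_A / 1 um^2")


@dataclass(frozen=True)
class ThresholdSpec:
    """Firing-threshold setting for the threshold-tunneling relation.

    ``Vm_threshold`` is the absolute depolarized potential at which an
    action potential fires (default 0.055 V, up from the 0.073 V resting
    value); ``threshold_density_D`` is the channel density substituted in
    the GHK threshold relation (default 1e8 /cm^2 = 1 channel/um^2: one
    channel per patch suffices).
    """

    Vm_threshold: float = 0.055
    threshold_density_D: float = 1e8  # channels/cm^2
    leak: LeakProfile = field(default_factory=LeakProfile)

    def __post_init__(self) -> None:
        if not 0 < self.Vm_threshold:
            raise ValueError("Vm_threshold must be positive")
        if self.threshold_density_D <= 0:
            raise ValueError("threshold_density_D must be positive")


@dataclass(frozen=True)
class InductionProbabilities:
    """The P1/P2/P3 cascade with log-space complements.

    ``log1m_p*`` hold ln(1-P*) exactly even when the probabilities
    underflow to 0 or saturate at 1.
    """

    P1: float
    P2: float
    P3: float
    log1m_p1: float
    log1m_p2: float
    log1m_p3: float


def cylinder_geometry(geom: AxonGeometry = AxonGeometry()) -> CylinderGeometry:
    """Lateral surface (2 pi r L), intracellular (pi r^2 L) and extracellular
    volumes of the axon segment, in um^2 / um^3."""
    surface = 2.0 * math.pi * geom.radius_r * geom.length_Laxon
    v_intra = math.pi * geom.radius_r**2 * geom.length_Laxon
    v_extra = geom.extra_to_intra_ratio * v_intra
    return CylinderGeometry(surface, v_intra, v_extra)


def k_release_concentration(
    N_AP: float,
    V_E: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Extracellular K+ concentration rise [K]_AP = N_AP / (N_A V_E), mmol/L.

    ``V_E`` is the extracellular volume in um^3 (1 um^3 = 1e-15 L).
    """
    if V_E <= 0:
        raise ValueError("extracellular volume V_E must be positive")
    if N_AP < 0:
        raise ValueError("N_AP must be non-negative")
    mol = N_AP / constants.avogadro_NA
    return mol / (V_E * 1e-15) * 1e3  # mol/L -> mmol/L


class IonsPerChannel(NamedTuple):
    rounded: int
    raw: float


def ions_per_channel(area_density_NAP: float, D: float) -> IonsPerChannel:
    """K+ hits per closed channel, N_K = (ions/um^2) / (channels/um^2).

    Returns both the nearest-integer count (used as the Bernoulli trial
    number) and the unrounded ratio.
    """
    if D <= 0:
        raise ValueError("channel density D must be positive")
    if area_density_NAP < 0:
        raise ValueError("area_density_NAP must be non-negative")
    raw = area_density_NAP / D
    return IonsPerChannel(rounded=int(round(raw)), raw=raw)


def threshold_coefficient(
    spec: ThresholdSpec = ThresholdSpec(),
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """The product T_Q(Thr) x [K]_AP implied by the GHK threshold relation.

    Solving S1 + [K]_AP (q^2/h) T_Q D = exp(-F Vm_thr/RT) S2 for the
    product gives (exp(-F Vm_thr/RT) S2 - S1) / ((q^2/h) D), in mmol/L.
    With the default leak profile and D = 1e8 /cm^2 this is ~9.7e-7.
    """
    leak = spec.leak
    rhs = math.exp(-constants.f_over_rt * spec.Vm_threshold) * leak.s2
    drive = rhs - leak.s1
    if drive <= 0:
        raise ValueError(
            "threshold potential is at or above the resting drive; "
            "no positive tunneling threshold exists")
    q = potassium().charge_q
    q2h_mS = q * q / constants.planck_h * 1e3  # conductance quantum in mS
    return drive / (q2h_mS * spec.threshold_density_D)


def threshold_tunneling(
    spec: ThresholdSpec = ThresholdSpec(),
    K_AP: float = 4.3e-2,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Threshold tunneling probability T_Q(Thr) = coefficient / [K]_AP."""
    if K_AP <= 0:
        raise ValueError("K_AP must be positive")
    return threshold_coefficient(spec, constants) / K_AP


def bernoulli_pmf(N: int, Z: int, P: float) -> float:
    """Probability of exactly Z successes in N independent trials.

    Log-space binomial mass; Z = 0 reduces to (1-P)^N.
    """
    if not 0 <= Z <= N:
        raise ValueError("require 0 <= Z <= N")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    return float(binom.pmf(Z, N, P))


def induction_probability(
    T_Q: float,
    N_K: float,
    D_um2: float,
    N_um2: float,
) -> InductionProbabilities:
    """The at-least-one cascade over channel hits, patch channels, and patches.

    P1 = 1-(1-T_Q)^N_K, P2 = 1-(1-P1)^D, P3 = 1-(1-P2)^N, accumulated as
    ln(1-P) so the chain is exact down to T_Q ~ 1e-300 and satisfies
    1-P3 = (1-T_Q)^(N_K D N) identically.
    """
    if not 0.0 <= T_Q <= 1.0:
        raise ValueError("T_Q must lie in [0, 1]")
    for name, v in (("N_K", N_K), ("D_um2", D_um2), ("N_um2", N_um2)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    log1m_t = math.log1p(-T_Q) if T_Q < 1.0 else -math.inf
    log1m_p1 = N_K * log1m_t
    log1m_p2 = D_um2 * log1m_p1
    log1m_p3 = N_um2 * log1m_p2
    p = [-math.expm1(x) if x > -math.inf else 1.0 for x in (log1m_p1, log1m_p2, log1m_p3)]
    # 0^0 = 1 convention: zero trials leave the complement at 1
    return InductionProbabilities(
        P1=p[0], P2=p[1], P3=p[2],
        log1m_p1=log1m_p1, log1m_p2=log1m_p2, log1m_p3=log1m_p3)


@dataclass(frozen=True)
class SynapseScenario:
    """Base point for the induction-probability sweeps.

    The standard setting is L = 1e-10 m, Vm = 0.07 V, N_K = 100,
    D = 100 channels/um^2 and N = 100 patches; the base barrier height
    defaults to 2.5e-20 J, the midpoint of the investigated
    (1-4)e-20 J range.  The tunneling probability is that of an
    extracellular K+ at the fixed Vm (Vm is an independent axis here,
    not solved self-consistently).
    """

    barrier: EckartBarrier = field(
        default_factory=lambda: EckartBarrier(height_G=2.5e-20, gate_length_L=1e-10))
    Vm: float = 0.07
    N_K: float = 100.0
    D_um2: float = 100.0
    N_um2: float = 100.0
    ion: IonSpecies = field(default_factory=potassium)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    transmission_mode: str = "approx"

    def tunneling(self, barrier: EckartBarrier | None = None, Vm: float | None = None) -> float:
        b = barrier if barrier is not None else self.barrier
        v = Vm if Vm is not None else self.Vm
        return math.exp(log_tunneling_probability(
            self.ion, b, MembraneSide.EXTRACELLULAR, v, self.constants,
            method=self.transmission_mode))


_SWEEP_AXES = ("G", "L", "Vm", "N_K", "D_um2", "N_um2")


def sweep_induction(
    base: SynapseScenario,
    axis: str,
    grid,
) -> pd.DataFrame:
    """AP-induction probabilities along one parameter axis.

    ``axis`` is one of G, L, Vm, N_K, D_um2, N_um2; all other parameters
    stay at the base setting.  Each row carries the barrier height, the
    extracellular K+ tunneling probability and the P1/P2/P3 cascade.
    """
    if axis not in _SWEEP_AXES:
        raise ValueError(f"axis must be one of {_SWEEP_AXES}")
    grid = [float(v) for v in grid]
    if not grid:
        raise ValueError("grid must be non-empty")

    rows = []
    for value in grid:
        barrier, vm = base.barrier, base.Vm
        n_k, d, n_patches = base.N_K, base.D_um2, base.N_um2
        if axis == "G":
            barrier = EckartBarrier(value, barrier.gate_length_L, barrier.gate_location_n)
        elif axis == "L":
            barrier = EckartBarrier(barrier.height_G, value, barrier.gate_location_n)
        elif axis == "Vm":
            vm = value
        elif axis == "N_K":
            n_k = value
        elif axis == "D_um2":
            d = value
        elif axis == "N_um2":
            n_patches = value
        t_q = base.tunneling(barrier=barrier, Vm=vm)
        probs = induction_probability(t_q, n_k, d, n_patches)
        rows.append({
            "axis": axis,
            "axis_value": value,
            "G_J": barrier.height_G,
            "T_Q": t_q,
            "P1": probs.P1,
            "P2": probs.P2,
            "P3": probs.P3,
        })
    return pd.DataFrame(rows, columns=["axis", "axis_value", "G_J", "T_Q", "P1", "P2", "P3"])
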