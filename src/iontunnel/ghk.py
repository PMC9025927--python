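"""Classical and quantum Goldman-Hodgkin-Katz solvers for the basolateral membrane.

The steady-state membrane potential of the inner-hair-cell basolateral
membrane satisfies, classically,

    S1 = exp(-F Vm / R T) S2,
    S1 = MC_Na [Na]_E + MC_K [K]_E,   S2 = MC_Na [Na]_I + MC_K [K]_I,

giving the closed form Vm = (RT/F) ln(S2/S1) (Vm is the absolute,
positive, inside-negative potential).  Quantum leak through closed
channels adds side-dependent conductance terms MC_Q [ion]; because the
extracellular tunneling probability depends on the very Vm being solved
for (the field accelerates the incoming ion), the monovalent and
divalent equations are transcendental and are solved by bracketed root
search over Vm in [0, 0.12] V.

Divalent (Ca) permeation enters through the quadratic-form relation

    (S1 - S2) + sqrt((S1+S2)^2 + 4 (S1 H2 + S2 H1 + H1 H2))
        = 2 exp(-F Vm / R T) (S2 + H2),

with H1 = MC_Q(Ca, E) [Ca]_E and H2 = MC_Q(Ca, I) [Ca]_I; intracellular
free calcium is tiny, so H2 = 0 by default.

All sums use mixed (mS/cm^2 x mmol/L) units; only like terms are
compared, so no conversion is needed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import IonSpecies, PhysicalConstants, default_ions
from .tunneling import (
    EckartBarrier,
    MembraneSide,
    log_tunneling_probability,
    membrane_conductance,
    unitary_conductance,
)

__all__ = [
    "LeakProfile",
    "QuantumGHKScenario",
    "VmSolution",
    "classical_vm",
    "quantum_vm_monovalent",
    "quantum_vm_divalent",
    "quantum_vm",
    "sweep_barrier_height",
    "sweep_table_to_csv",
    "VM_BRACKET",
    "DEFAULT_GATE_LENGTHS",
    "DEFAULT_GATE_LOCATIONS",
]

#: Search bracket for the absolute membrane potential (V).
VM_BRACKET = (0.0, 0.12)
#: Gate-length settings used by the standard sweeps (m).
DEFAULT_GATE_LENGTHS = (0.5e-10, 1.0e-10, 1.5e-10, 2.0e-10)
#: Gate-location settings used by the standard sweeps.
DEFAULT_GATE_LOCATIONS = (1, 2, 3, 4)

_REL_RESIDUAL_TOL = 1e-9
_XTOL = 1e-13
_MAXITER = 200


@dataclass(frozen=True)
class LeakProfile:
    """Classical leak conductances and ionic concentrations.

    Defaults describe the inner-hair-cell basolateral membrane at rest:
    K leak 0.5 mS/cm^2, Na leak 0.01 mS/cm^2 (100:2 ratio), perilymph
    and cytosol concentrations in mmol/L.  Intracellular Ca defaults to
    zero (free cytosolic calcium is negligible here).
    """

    MC_K: float = 0.5
    MC_Na: float = 0.01
    Na_out: float = 140.0
    Na_in: float = 15.0
    K_out: float = 5.0
    K_in: float = 120.0
    Ca_out: float = 1.4
    Ca_in: float = 0.0

    def __post_init__(self) -> None:
        for name in ("MC_K", "MC_Na", "Na_out", "Na_in", "K_out", "K_in", "Ca_out", "Ca_in"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def s1(self) -> float:
        """Extracellular weighted sum MC_Na [Na]_E + MC_K [K]_E."""
        return self.MC_Na * self.Na_out + self.MC_K * self.K_out

    @property
    def s2(self) -> float:
        """Intracellular weighted sum MC_Na [Na]_I + MC_K [K]_I."""
        return self.MC_Na * self.Na_in + self.MC_K * self.K_in


@dataclass(frozen=True)
class VmSolution:
    """A solved membrane potential (absolute value, volts).

    ``residual`` is the equation residual relative to the magnitude of
    its two sides; ``branch_note`` records boundary or multistability
    diagnostics ('' for a plain interior root).
    """

    Vm: float
    converged: bool
    residual: float
    branch_note: str = ""


@dataclass(frozen=True)
class QuantumGHKScenario:
    """One quantum-GHK solve: a single tunneling ion over the leak background.

    ``self_consistent=True`` (default) lets the extracellular kinetic
    energy track the Vm being solved for; with ``False`` the kinetic
    energy is frozen at ``frozen_vm`` (the classical resting potential
    unless given).
    """

    tunneling_ion: IonSpecies
    barrier: EckartBarrier
    channel_density_D: float = 1e10  # channels/cm^2
    leak: LeakProfile = field(default_factory=LeakProfile)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    transmission_mode: str = "approx"
    self_consistent: bool = True
    frozen_vm: float | None = None

    def __post_init__(self) -> None:
        if self.channel_density_D < 0:
            raise ValueError("channel_density_D must be non-negative")
        if self.transmission_mode not in ("approx", "exact"):
            raise ValueError("transmission_mode must be 'approx' or 'exact'")

    def quantum_mc(self, side: MembraneSide, Vm: float) -> float:
        """Areal quantum conductance MC_Q (mS/cm^2) of the tunneling ion."""
        if self.channel_density_D == 0.0:
            return 0.0
        if not self.self_consistent and side is MembraneSide.EXTRACELLULAR:
            Vm = self.frozen_vm if self.frozen_vm is not None else classical_vm(
                self.leak, self.constants).Vm
        t_q = math.exp(log_tunneling_probability(
            self.tunneling_ion, self.barrier, side, Vm, self.constants,
            method=self.transmission_mode))
        c_q = unitary_conductance(self.tunneling_ion, t_q, self.constants)
        return membrane_conductance(c_q, self.channel_density_D)


def classical_vm(
    leak: LeakProfile = LeakProfile(),
    constants: PhysicalConstants = PhysicalConstants(),
) -> VmSolution:
    """Closed-form classical GHK potential Vm = (RT/F) ln(S2/S1).

    With the default basolateral leak profile this gives 0.073 V.
    """
    s1, s2 = leak.s1, leak.s2
    if s1 <= 0 or s2 <= 0:
        raise ValueError("both weighted concentration sums must be positive")
    vm = math.log(s2 / s1) / constants.f_over_rt
    return VmSolution(Vm=vm, converged=True, residual=0.0, branch_note="classical")


def _solve_scalar(f, bracket: tuple[float, float], warm_start: float | None) -> tuple[float, str]:
    """Bracketed root search with optional warm-start window and branch scan."""
    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    note = ""
    # coarse scan for multiple sign changes (multistability diagnostics)
    grid = np.linspace(lo, hi, 49)
    vals = np.array([f(v) for v in grid])
    signs = np.sign(vals)
    changes = np.nonzero(np.diff(signs[signs != 0]))[0]
    n_changes = int(len(changes))
    if n_changes > 1:
        note = f"multistable:{n_changes}_sign_changes"
    if f_lo >= 0.0:
        # LHS already exceeds RHS at Vm = 0: no non-negative root remains
        return lo, (note + ";" if note else "") + "fully_depolarized"
    if f_hi < 0.0:
        return hi, (note + ";" if note else "") + "no_root_in_bracket"
    if warm_start is not None and n_changes <= 1:
        w_lo = max(lo, warm_start - 0.02)
        w_hi = min(hi, warm_start + 0.02)
        try:
            if f(w_lo) < 0.0 <= f(w_hi):
                root = brentq(f, w_lo, w_hi, xtol=_XTOL, maxiter=_MAXITER)
                return float(root), note
        except ValueError:
            pass
    if n_changes > 1 and warm_start is not None:
        # pick the sign-change interval closest to the warm start (branch continuity)
        idx = [i for i in range(len(grid) - 1) if vals[i] < 0.0 <= vals[i + 1]]
        if idx:
            i = min(idx, key=lambda j: abs(0.5 * (grid[j] + grid[j + 1]) - warm_start))
            root = brentq(f, grid[i], grid[i + 1], xtol=_XTOL, maxiter=_MAXITER)
            return float(root), note
    root = brentq(f, lo, hi, xtol=_XTOL, maxiter=_MAXITER)
    return float(root), note


def _finalize(vm: float, note: str, lhs_rhs) -> VmSolution:
    lhs, rhs = lhs_rhs(vm)
    scale = max(abs(lhs), abs(rhs), 1e-300)
    rel = abs(lhs - rhs) / scale
    boundary = "fully_depolarized" in note or "no_root" in note
    converged = boundary or rel < _REL_RESIDUAL_TOL
    return VmSolution(Vm=vm, converged=converged, residual=rel, branch_note=note)


def quantum_vm_monovalent(
    scenario: QuantumGHKScenario,
    warm_start: float | None = None,
) -> VmSolution:
    """Self-consistent quantum GHK potential for a monovalent tunneling ion.

    Solves S1 + MC_Q(E)(Vm) [ion]_E = exp(-F Vm/RT) (S2 + MC_Q(I) [ion]_I)
    for the absolute Vm.  If the left side exceeds the right even at
    Vm = 0 the membrane is reported fully depolarized at the boundary.
    """
    ion = scenario.tunneling_ion
    if ion.valence != 1:
        raise ValueError("quantum_vm_monovalent requires a monovalent tunneling ion")
    leak, constants = scenario.leak, scenario.constants
    s1, s2 = leak.s1, leak.s2
    mc_q_in = scenario.quantum_mc(MembraneSide.INTRACELLULAR, 0.0)

    def sides(vm: float) -> tuple[float, float]:
        lhs = s1 + scenario.quantum_mc(MembraneSide.EXTRACELLULAR, vm) * ion.conc_extracellular
        rhs = math.exp(-constants.f_over_rt * vm) * (s2 + mc_q_in * ion.conc_intracellular)
        return lhs, rhs

    vm, note = _solve_scalar(lambda v: sides(v)[0] - sides(v)[1], VM_BRACKET, warm_start)
    return _finalize(vm, note, sides)


def quantum_vm_divalent(
    scenario: QuantumGHKScenario,
    warm_start: float | None = None,
) -> VmSolution:
    """Self-consistent quantum GHK potential for a divalent (Ca) tunneling ion.

    Uses the quadratic-form relation with H1 = MC_Q(Ca,E) [Ca]_E and
    H2 = MC_Q(Ca,I) [Ca]_I; H2 vanishes with the default zero
    intracellular calcium.  With H1 = H2 = 0 the relation reduces
    algebraically to the classical closed form.
    """
    ion = scenario.tunneling_ion
    if ion.valence != 2:
        raise ValueError("quantum_vm_divalent requires a divalent tunneling ion")
    leak, constants = scenario.leak, scenario.constants
    s1, s2 = leak.s1, leak.s2
    h2 = scenario.quantum_mc(MembraneSide.INTRACELLULAR, 0.0) * ion.conc_intracellular

    def sides(vm: float) -> tuple[float, float]:
        h1 = scenario.quantum_mc(MembraneSide.EXTRACELLULAR, vm) * ion.conc_extracellular
        disc = (s1 + s2) ** 2 + 4.0 * (s1 * h2 + s2 * h1 + h1 * h2)
        assert disc >= 0.0, "discriminant cannot be negative for non-negative terms"
        lhs = (s1 - s2) + math.sqrt(disc)
        rhs = 2.0 * math.exp(-constants.f_over_rt * vm) * (s2 + h2)
        return lhs, rhs

    vm, note = _solve_scalar(lambda v: sides(v)[0] - sides(v)[1], VM_BRACKET, warm_start)
    return _finalize(vm, note, sides)


def quantum_vm(scenario: QuantumGHKScenario, warm_start: float | None = None) -> VmSolution:
    """Dispatch to the monovalent or divalent solver by ion valence."""
    if scenario.tunneling_ion.valence == 1:
        return quantum_vm_monovalent(scenario, warm_start)
    return quantum_vm_divalent(scenario, warm_start)


def sweep_barrier_height(
    scenario: QuantumGHKScenario,
    G_grid,
    sweep_axis: str = "gate_length",
    axis_values=None,
    ions: dict[str, IonSpecies] | None = None,
) -> pd.DataFrame:
    """Vm(G) curves for Na, K and Ca over a descending barrier-height grid.

    ``sweep_axis`` selects the curve family: 'gate_length' varies L over
    ``axis_values`` (default 0.5-2 angstrom) at the scenario's n, while
    'gate_location' varies n (default 1-4) at the scenario's L.  Each
    solve is warm-started from the previous (higher-G) root so curves
    follow the branch continuous with the classical resting state.
    Non-converged points are flagged in the table, never dropped.
    """
    G_grid = [float(g) for g in G_grid]
    if any(b > a for a, b in zip(G_grid, G_grid[1:])):
        raise ValueError("G_grid must be sorted in descending order")
    if sweep_axis == "gate_length":
        axis_values = tuple(axis_values) if axis_values is not None else DEFAULT_GATE_LENGTHS
    elif sweep_axis == "gate_location":
        axis_values = tuple(axis_values) if axis_values is not None else DEFAULT_GATE_LOCATIONS
    else:
        raise ValueError("sweep_axis must be 'gate_length' or 'gate_location'")
    ions = ions if ions is not None else default_ions()

    rows = []
    for ion_name, ion in ions.items():
        for value in axis_values:
            if sweep_axis == "gate_length":
                L, n = float(value), scenario.barrier.gate_location_n
            else:
                L, n = scenario.barrier.gate_length_L, int(value)
            prev_root: float | None = None
            for g in G_grid:
                barrier = EckartBarrier(height_G=g, gate_length_L=L, gate_location_n=n)
                sc = replace(scenario, tunneling_ion=ion, barrier=barrier)
                sol = quantum_vm(sc, warm_start=prev_root)
                prev_root = sol.Vm
                rows.append({
                    "ion": ion_name,
                    "G_J": g,
                    "L_m": L,
                    "n": n,
                    "D_per_cm2": scenario.channel_density_D,
                    "Vm_V": sol.Vm,
                    "converged": sol.converged,
                    "branch_note": sol.branch_note,
                })
    return pd.DataFrame(rows, columns=[
        "ion", "G_J", "L_m", "n", "D_per_cm2", "Vm_V", "converged", "branch_note"])


def sweep_table_to_csv(table: pd.DataFrame, path=None) -> str:
    """Serialize a sweep table with 10-significant-digit scientific floats."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: f"{v:.9e}")
    buf = io.StringIO()
    out.to_csv(buf, index=False)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
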