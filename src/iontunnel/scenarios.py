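"""Scenario files: schema, loading, and fixture generation for the standard sweeps.

A scenario is a small YAML/JSON document overriding the model's default
parameters.  Unknown keys are rejected with their path, magnitudes are
sanity-checked (a gate length in metres must be < 1e-8 m), and an empty
file yields the all-defaults scenario.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import PhysicalConstants
from .ghk import (
    DEFAULT_GATE_LENGTHS,
    DEFAULT_GATE_LOCATIONS,
    LeakProfile,
    QuantumGHKScenario,
)
from .synapse import AxonGeometry, SynapseScenario
from .tunneling import EckartBarrier, per_um2_to_per_cm2
from .constants import default_ions

__all__ = [
    "Scenario",
    "load_scenario",
    "scenario_from_dict",
    "make_scenarios",
    "default_g_grid",
    "FIGURE_SCENARIOS",
]

#: Barrier heights investigated by the standard sweeps (J), descending.
G_RANGE = (4e-20, 1e-20)

#: Curve-family values for the induction sweeps whose settings are not
#: fixed by the base point (representative physiological grids).
INDUCTION_FAMILIES = {
    "L": [0.5e-10, 1.0e-10, 1.5e-10, 2.0e-10],
    "Vm": [0.055, 0.060, 0.065, 0.070],
    "N_K": [44.0, 100.0, 500.0, 1000.0],
    "D_um2": [1.0, 10.0, 100.0, 1000.0],
    "N_um2": [1.0, 10.0, 100.0, 1000.0],
}


def default_g_grid(n_points: int = 50) -> list[float]:
    """Descending barrier-height grid spanning (4 -> 1) x 1e-20 J."""
    return list(np.linspace(G_RANGE[0], G_RANGE[1], n_points))


@dataclass(frozen=True)
class Scenario:
    """A fully validated parameter set for one sweep or solve.

    ``kind`` selects the engine: 'ghk' (membrane-potential sweep over G)
    or 'synapse' (AP-induction sweep).  Field groups mirror the model's
    parameter blocks; anything omitted in a file takes the default.
    """

    name: str = "default"
    kind: str = "ghk"
    barrier: EckartBarrier = field(
        default_factory=lambda: EckartBarrier(height_G=4e-20, gate_length_L=1e-10))
    leak: LeakProfile = field(default_factory=LeakProfile)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    geometry: AxonGeometry = field(default_factory=AxonGeometry)
    channel_density_per_cm2: float = 1e10
    transmission_mode: str = "approx"
    sweep_axis: str = "gate_length"
    g_grid: tuple = tuple(default_g_grid())
    axis_values: tuple | None = None
    axis_grid: tuple | None = None
    synapse_base: SynapseScenario = field(default_factory=SynapseScenario)
    synapse_axis: str = "G"
    output_path: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ghk", "synapse"):
            raise ValueError("kind must be 'ghk' or 'synapse'")
        if self.channel_density_per_cm2 < 0:
            raise ValueError("channel density must be non-negative")
        if len(self.g_grid) == 0:
            raise ValueError("g_grid must be non-empty")
        if any(b > a for a, b in zip(self.g_grid, self.g_grid[1:])):
            raise ValueError("g_grid must be sorted in descending order")
        if self.barrier.gate_length_L >= 1e-8:
            raise ValueError(
                "gate_length_L must be < 1e-8 m (gate lengths are of angstrom order; "
                "check the unit)")

    def ghk_scenario(self, ion_name: str = "Na") -> QuantumGHKScenario:
        return QuantumGHKScenario(
            tunneling_ion=default_ions()[ion_name],
            barrier=self.barrier,
            channel_density_D=self.channel_density_per_cm2,
            leak=self.leak,
            constants=self.constants,
            transmission_mode=self.transmission_mode,
        )


_SCHEMA = {
    "name": str,
    "kind": str,
    "transmission_mode": str,
    "sweep_axis": str,
    "output_path": str,
    "channel_density_per_um2": (int, float),
    "channel_density_per_cm2": (int, float),
    "g_grid": list,
    "axis_values": list,
    "axis_grid": list,
    "barrier": {"height_G": (int, float), "gate_length_L": (int, float),
                "gate_location_n": int},
    "leak": {k: (int, float) for k in
             ("MC_K", "MC_Na", "Na_out", "Na_in", "K_out", "K_in", "Ca_out", "Ca_in")},
    "constants": {k: (int, float) for k in
                  ("planck_h", "hbar", "boltzmann_kB", "faraday_F", "gas_R",
                   "avogadro_NA", "body_temperature_T")},
    "geometry": {k: (int, float) for k in
                 ("radius_r", "length_Laxon", "extra_to_intra_ratio",
                  "N_AP_total", "channel_density_Dum2")},
    "synapse": {"G": (int, float), "L": (int, float), "n": int,
                "Vm": (int, float), "N_K": (int, float), "D_um2": (int, float),
                "N_um2": (int, float), "axis": str},
}


def _check_keys(doc: dict, schema: dict, path: str = "") -> None:
    for key, val in doc.items():
        where = f"{path}{key}"
        if key not in schema:
            raise ValueError(f"unknown scenario key: '{where}'")
        expected = schema[key]
        if isinstance(expected, dict):
            if not isinstance(val, dict):
                raise ValueError(f"scenario key '{where}' must be a mapping")
            _check_keys(val, expected, where + ".")
        elif not isinstance(val, expected):
            raise ValueError(f"scenario key '{where}' has the wrong type")


def scenario_from_dict(doc: dict | None, name: str = "default") -> Scenario:
    """Build a validated Scenario from a (possibly empty) mapping."""
    doc = doc or {}
    if not isinstance(doc, dict):
        raise ValueError("scenario document must be a mapping")
    _check_keys(doc, _SCHEMA)

    barrier_doc = dict(doc.get("barrier", {}))
    barrier = EckartBarrier(
        height_G=float(barrier_doc.get("height_G", 4e-20)),
        gate_length_L=float(barrier_doc.get("gate_length_L", 1e-10)),
        gate_location_n=int(barrier_doc.get("gate_location_n", 1)),
    )
    leak = LeakProfile(**{k: float(v) for k, v in doc.get("leak", {}).items()})
    constants = PhysicalConstants(**{k: float(v) for k, v in doc.get("constants", {}).items()})
    geometry = AxonGeometry(**{k: float(v) for k, v in doc.get("geometry", {}).items()})

    if "channel_density_per_um2" in doc and "channel_density_per_cm2" in doc:
        raise ValueError("give channel density per um^2 or per cm^2, not both")
    if "channel_density_per_um2" in doc:
        density = per_um2_to_per_cm2(float(doc["channel_density_per_um2"]))
    else:
        density = float(doc.get("channel_density_per_cm2", 1e10))

    syn = dict(doc.get("synapse", {}))
    syn_barrier = EckartBarrier(
        height_G=float(syn.get("G", 2.5e-20)),
        gate_length_L=float(syn.get("L", 1e-10)),
        gate_location_n=int(syn.get("n", 1)),
    )
    synapse_base = SynapseScenario(
        barrier=syn_barrier,
        Vm=float(syn.get("Vm", 0.07)),
        N_K=float(syn.get("N_K", 100.0)),
        D_um2=float(syn.get("D_um2", 100.0)),
        N_um2=float(syn.get("N_um2", 100.0)),
        constants=constants,
        transmission_mode=str(doc.get("transmission_mode", "approx")),
    )

    g_grid = tuple(float(g) for g in doc.get("g_grid", default_g_grid()))
    axis_values = doc.get("axis_values")
    axis_grid = doc.get("axis_grid")
    return Scenario(
        name=str(doc.get("name", name)),
        kind=str(doc.get("kind", "ghk")),
        barrier=barrier,
        leak=leak,
        constants=constants,
        geometry=geometry,
        channel_density_per_cm2=density,
        transmission_mode=str(doc.get("transmission_mode", "approx")),
        sweep_axis=str(doc.get("sweep_axis", "gate_length")),
        g_grid=g_grid,
        axis_values=tuple(axis_values) if axis_values is not None else None,
        axis_grid=tuple(axis_grid) if axis_grid is not None else None,
        synapse_base=synapse_base,
        synapse_axis=str(syn.get("axis", "G")),
        output_path=str(doc.get("output_path", "")),
    )


def load_scenario(path) -> Scenario:
    """Load and validate a YAML or JSON scenario file.

    An empty file yields the all-defaults scenario; unknown keys and
    non-physical values are rejected with a descriptive error.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        doc = json.loads(text) if text.strip() else None
    else:
        doc = yaml.safe_load(text)
    return scenario_from_dict(doc, name=path.stem)


def scenario_to_dict(s: Scenario) -> dict:
    """Serialize a Scenario back to its document form (round-trips)."""
    doc = {
        "name": s.name,
        "kind": s.kind,
        "transmission_mode": s.transmission_mode,
        "sweep_axis": s.sweep_axis,
        "channel_density_per_cm2": s.channel_density_per_cm2,
        "g_grid": [float(g) for g in s.g_grid],
        "barrier": {
            "height_G": s.barrier.height_G,
            "gate_length_L": s.barrier.gate_length_L,
            "gate_location_n": s.barrier.gate_location_n,
        },
        "leak": {k: getattr(s.leak, k) for k in
                 ("MC_K", "MC_Na", "Na_out", "Na_in", "K_out", "K_in", "Ca_out", "Ca_in")},
        "synapse": {
            "G": s.synapse_base.barrier.height_G,
            "L": s.synapse_base.barrier.gate_length_L,
            "n": s.synapse_base.barrier.gate_location_n,
            "Vm": s.synapse_base.Vm,
            "N_K": s.synapse_base.N_K,
            "D_um2": s.synapse_base.D_um2,
            "N_um2": s.synapse_base.N_um2,
            "axis": s.synapse_axis,
        },
    }
    if s.axis_values is not None:
        doc["axis_values"] = [float(v) for v in s.axis_values]
    if s.axis_grid is not None:
        doc["axis_grid"] = [float(v) for v in s.axis_grid]
    if s.output_path:
        doc["output_path"] = s.output_path
    return doc


_HEADER = """\
# iontunnel scenario file.
# Energies in joules, lengths in metres, potentials in volts (absolute),
# conductances in mS/cm^2, concentrations in mmol/L, densities in
# channels/cm^2 unless the key says per um^2.
"""

#: The named sweep scenarios behind the standard membrane-potential and
#: induction-probability figures.
FIGURE_SCENARIOS = {
    "fig5": {"kind": "ghk", "sweep_axis": "gate_length"},
    "fig6": {"kind": "ghk", "sweep_axis": "gate_location"},
    "fig7": {"kind": "synapse", "synapse": {"axis": "L"}},
    "fig8": {"kind": "synapse", "synapse": {"axis": "Vm"}},
    "fig9": {"kind": "synapse", "synapse": {"axis": "N_K"}},
    "fig10": {"kind": "synapse", "synapse": {"axis": "D_um2"}},
    "fig11": {"kind": "synapse", "synapse": {"axis": "N_um2"}},
}


def make_scenarios(out_dir, n_points: int = 50) -> list[Path]:
    """Write the default fixture scenario files and return their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, overrides in FIGURE_SCENARIOS.items():
        base = scenario_from_dict(None, name=name)
        doc = scenario_to_dict(base)
        doc["name"] = name
        doc["kind"] = overrides["kind"]
        if "sweep_axis" in overrides:
            doc["sweep_axis"] = overrides["sweep_axis"]
        if "synapse" in overrides:
            doc["synapse"].update(overrides["synapse"])
        doc["g_grid"] = [float(g) for g in default_g_grid(n_points)]
        doc["output_path"] = f"{name}.csv"
        path = out_dir / f"{name}.yaml"
        with open(path, "w") as fh:
            fh.write(_HEADER)
            yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)
        paths.append(path)
    return paths
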