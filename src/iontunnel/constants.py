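"""Physical constants and ion definitions.

Constants default to the rounded values used throughout the source model
(e.g. h = 6.6e-34 J s, R = 8.31 J/(K mol)) so that worked examples
reproduce to the printed precision.  Note that the stored h and hbar are
each rounded independently and are therefore mutually inconsistent at the
fourth digit (h/2pi = 1.0504e-34 vs the stored 1.05e-34); each is used
where the model uses it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = [
    "ELEMENTARY_CHARGE",
    "PhysicalConstants",
    "IonSpecies",
    "sodium",
    "potassium",
    "calcium",
    "default_ions",
]

#: Elementary charge (C), rounded as in the model equations.
ELEMENTARY_CHARGE = 1.6e-19


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants at body temperature.

    All values strictly positive; defaults are the rounded values the
    model's worked examples were computed with.

    Attributes
    ----------
    planck_h : float
        Planck constant (J s).
    hbar : float
        Reduced Planck constant (J s).
    boltzmann_kB : float
        Boltzmann constant (J/K).
    faraday_F : float
        Faraday constant (C/mol).
    gas_R : float
        Molar gas constant (J/(K mol)).
    avogadro_NA : float
        Avogadro number (1/mol).
    body_temperature_T : float
        Absolute body temperature (K).
    """

    planck_h: float = 6.6e-34
    hbar: float = 1.05e-34
    boltzmann_kB: float = 1.38e-23
    faraday_F: float = 96485.33
    gas_R: float = 8.31
    avogadro_NA: float = 6.02e23
    body_temperature_T: float = 310.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")

    @property
    def thermal_energy(self) -> float:
        """Mean thermal kinetic energy (3/2) k_B T in joules."""
        return 1.5 * self.boltzmann_kB * self.body_temperature_T

    @property
    def f_over_rt(self) -> float:
        """F/(R T) in 1/V; ~37.45 V^-1 at 310 K."""
        return self.faraday_F / (self.gas_R * self.body_temperature_T)


@dataclass(frozen=True)
class IonSpecies:
    """One permeant ion with its compartment concentrations.

    The charge must equal ``valence * 1.6e-19 C``; concentrations are in
    mmol/L (extracellular = perilymph side, intracellular = cytosol).
    """

    name: str
    mass_m: float  # kg
    charge_q: float  # C
    valence: int
    conc_extracellular: float  # mmol/L
    conc_intracellular: float  # mmol/L

    def __post_init__(self) -> None:
        if self.mass_m <= 0:
            raise ValueError("ion mass must be positive")
        if self.valence not in (1, 2):
            raise ValueError("valence must be 1 or 2")
        expected_q = self.valence * ELEMENTARY_CHARGE
        if abs(self.charge_q - expected_q) > 1e-6 * expected_q:
            raise ValueError(
                f"charge_q must be valence x {ELEMENTARY_CHARGE} C "
                f"(expected {expected_q}, got {self.charge_q})"
            )
        if self.conc_extracellular < 0 or self.conc_intracellular < 0:
            raise ValueError("concentrations must be non-negative")


def sodium(**overrides) -> IonSpecies:
    """Na+ with inner-hair-cell basolateral concentrations (140/15 mmol/L)."""
    kw = dict(
        name="Na",
        mass_m=3.8e-26,
        charge_q=ELEMENTARY_CHARGE,
        valence=1,
        conc_extracellular=140.0,
        conc_intracellular=15.0,
    )
    kw.update(overrides)
    return IonSpecies(**kw)


def potassium(**overrides) -> IonSpecies:
    """K+ (mass 39 u) with perilymph/cytosol concentrations (5/120 mmol/L)."""
    kw = dict(
        name="K",
        mass_m=6.5e-26,
        charge_q=ELEMENTARY_CHARGE,
        valence=1,
        conc_extracellular=5.0,
        conc_intracellular=120.0,
    )
    kw.update(overrides)
    return IonSpecies(**kw)


def calcium(**overrides) -> IonSpecies:
    """Ca2+ (mass 40 u), 1.4 mmol/L outside; intracellular taken as 0.

    Free cytosolic calcium is orders of magnitude below the other ionic
    concentrations, so the divalent solver's intracellular quantum term
    defaults to zero.
    """
    kw = dict(
        name="Ca",
        mass_m=6.64e-26,
        charge_q=2 * ELEMENTARY_CHARGE,
        valence=2,
        conc_extracellular=1.4,
        conc_intracellular=0.0,
    )
    kw.update(overrides)
    return IonSpecies(**kw)


def default_ions() -> dict[str, IonSpecies]:
    """The three cations of the model keyed by name."""
    return {"Na": sodium(), "K": potassium(), "Ca": calcium()}
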