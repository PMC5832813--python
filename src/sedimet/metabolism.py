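"""Individual body mass and metabolic rate estimation with temperature scaling.

The chain is: size measurement (shell length in mm for bivalves, wet weight in
mg for the lugworm Arenicola marina) -> body mass M in mg ash-free dry weight
(AFDW) via a per-species power law -> individual metabolic rate I in mW, either
from the pure allometric law I = a*M^b (b defaulting to the classic 3/4) or
from a configurable ln-linear empirical respiration model with trait
covariates. Uncertainty rides along every step as 95% half-widths
(:mod:`sedimet.quantities`).

Temperature dependence follows the Boltzmann-Arrhenius factor
exp(-E/k * (1/T - 1/T_ref)) with activation energy E in eV and k Boltzmann's
constant in eV/K; the factor is 1 at the reference temperature by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .quantities import QuantityWithCI, propagate_delta

__all__ = [
    "BOLTZMANN_EV",
    "DEFAULT_ACTIVATION_ENERGY_EV",
    "DEFAULT_ENERGY_DENSITY_J_PER_MG",
    "DEFAULT_REFERENCE_TEMP_C",
    "J_PER_DAY_TO_MW",
    "SizeMetric",
    "SizeMeasurement",
    "MassConversionRule",
    "MetabolicModelSpec",
    "ArrheniusParams",
    "celsius_to_kelvin",
    "convert_size_to_mass",
    "metabolic_rate",
    "arrhenius_factor",
]

#: Boltzmann's constant, eV per kelvin.
BOLTZMANN_EV = 8.617e-5
#: Default mean activation energy of metabolic reactions, eV.
DEFAULT_ACTIVATION_ENERGY_EV = 0.65
#: Mean energy density of macrozoobenthic tissue, J per mg AFDW.
DEFAULT_ENERGY_DENSITY_J_PER_MG = 21.5
#: Experimental reference temperature, degrees Celsius.
DEFAULT_REFERENCE_TEMP_C = 18.0
#: Exact conversion factor from J/day to mW (1000 mJ/J over 86400 s/day).
J_PER_DAY_TO_MW = 1000.0 / 86400.0


class SizeMetric(str, Enum):
    shell_length_mm = "shell_length_mm"
    wet_weight_mg = "wet_weight_mg"


@dataclass(frozen=True)
class SizeMeasurement:
    """A homogeneous size class of one species, with measurement uncertainty."""

    species: str
    metric: SizeMetric
    size: QuantityWithCI

    def __post_init__(self) -> None:
        if not (self.size.value > 0):
            raise ValueError(f"size must be positive, got {self.size.value}")


@dataclass(frozen=True)
class MassConversionRule:
    """Per-species power law M (mg AFDW) = p * size^q.

    The species-specific coefficients are unpublished lab calibrations and are
    therefore configuration, not constants of this package.
    """

    species: str
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (self.p > 0):
            raise ValueError(f"coefficient p must be positive, got {self.p}")

    @classmethod
    def calibrate(cls, species: str, size: float, mass: float, q: float = 1.0) -> "MassConversionRule":
        """Solve p from a single (size, mass) pair at a fixed exponent q."""
        return cls(species=species, p=mass / size**q, q=q)


def convert_size_to_mass(m: SizeMeasurement, rule: MassConversionRule) -> QuantityWithCI:
    """Convert a size measurement to body mass (mg AFDW), propagating the CI."""
    if rule.species != m.species:
        raise ValueError(
            f"conversion rule is for {rule.species!r}, measurement is {m.species!r}"
        )
    return propagate_delta(lambda s: rule.p * s**rule.q, m.size)


@dataclass(frozen=True)
class MetabolicModelSpec:
    """Parameterisation of the individual metabolic-rate model.

    form='allometric' evaluates I = a * M^b directly in mW.

    form='ln_linear_empirical' evaluates ln(R) = sum(coefficient * term) over a
    configurable coefficient table whose recognised terms are 'intercept',
    'ln_mass' (ln of M in the table's mass units), 'inv_temperature' (1/T, K)
    and arbitrary 0/1 trait indicators supplied through ``traits``. The result
    is interpreted as energy use in J/day and converted to mW. The coefficient
    table is external input (an empirical respiration regression), never
    shipped here.
    """

    form: str = "allometric"
    a: float = 1.0
    b: float = 0.75
    coefficients: Mapping[str, float] = field(default_factory=dict)
    energy_density: float = DEFAULT_ENERGY_DENSITY_J_PER_MG
    output_units: str = "mW"

    def __post_init__(self) -> None:
        if self.form not in ("allometric", "ln_linear_empirical"):
            raise ValueError(f"unknown model form {self.form!r}")
        if not (self.a > 0):
            raise ValueError(f"normalization a must be positive, got {self.a}")
        if not (self.energy_density > 0):
            raise ValueError("energy_density must be positive")


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


def metabolic_rate(
    mass: QuantityWithCI,
    spec: MetabolicModelSpec,
    T: float | None = None,
    traits: Mapping[str, float] | None = None,
) -> QuantityWithCI:
    """Individual metabolic rate I (mW) from body mass (mg AFDW).

    ``T`` is the absolute temperature in kelvin, required by the ln-linear
    empirical form whenever its coefficient table contains an
    'inv_temperature' term.
    """
    if not (mass.value > 0):
        raise ValueError(f"mass must be positive, got {mass.value}")
    if spec.form == "allometric":
        return propagate_delta(lambda m: spec.a * m**spec.b, mass)

    coefs = dict(spec.coefficients)
    if not coefs:
        raise ValueError("ln_linear_empirical form requires a coefficient table")
    traits = dict(traits or {})
    known = {"intercept", "ln_mass", "inv_temperature", *traits}
    unknown = [t for t in coefs if t not in known]
    if unknown:
        raise ValueError(f"missing covariate for term {unknown[0]!r}")
    if "inv_temperature" in coefs and T is None:
        raise ValueError("coefficient table uses 1/T but no temperature given")

    def _rate(m: float) -> float:
        ln_r = 0.0
        for term, coef in coefs.items():
            if term == "intercept":
                ln_r += coef
            elif term == "ln_mass":
                ln_r += coef * math.log(m)
            elif term == "inv_temperature":
                if T is None:
                    raise ValueError("coefficient table uses 1/T but no temperature given")
                ln_r += coef / T
            elif term in traits:
                ln_r += coef * traits[term]
            else:
                raise ValueError(f"missing covariate for term {term!r}")
        return math.exp(ln_r) * J_PER_DAY_TO_MW

    return propagate_delta(_rate, mass)


@dataclass(frozen=True)
class ArrheniusParams:
    """Boltzmann-Arrhenius temperature response e^(-E/kT)."""

    E: float = DEFAULT_ACTIVATION_ENERGY_EV
    T: float = celsius_to_kelvin(DEFAULT_REFERENCE_TEMP_C)
    boltzmann_k: float = BOLTZMANN_EV

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError(f"absolute temperature must be positive, got {self.T}")


def arrhenius_factor(T_ref: float, T: float, E: float = DEFAULT_ACTIVATION_ENERGY_EV) -> float:
    """Multiplicative change in metabolic rate from T_ref to T (both kelvin).

    Returns exp(-E/k * (1/T - 1/T_ref)): exactly 1 at the reference
    temperature, strictly increasing in T for E > 0.
    """
    if not (T_ref > 0 and T > 0):
        raise ValueError(f"temperatures must be positive kelvin, got {T_ref}, {T}")
    return math.exp(-(E / BOLTZMANN_EV) * (1.0 / T - 1.0 / T_ref))
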