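"""Temperature projection of biota-mediated resuspension.

With fitted coefficients (c, d), resuspension under a temperature scenario is

    R_TOT(T) = c + d * I_TOT(T_ref) * f(T_ref -> T),

where f is the Boltzmann-Arrhenius factor exp(-E/k (1/T - 1/T_ref)). Only the
metabolic (biotic) term scales with temperature; the abiotic baseline c is
temperature-invariant by assumption, so cooling can never push the projection
below c. Temperatures are degrees Celsius at this interface; the activation
energy E is a visible scenario parameter (default 0.65 eV, the canonical
metabolic-theory value).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .metabolism import (
    DEFAULT_ACTIVATION_ENERGY_EV,
    DEFAULT_REFERENCE_TEMP_C,
    arrhenius_factor,
    celsius_to_kelvin,
)

__all__ = [
    "TemperatureScenario",
    "project_resuspension",
    "percent_metabolic_change",
    "scenario_table",
]


@dataclass(frozen=True)
class TemperatureScenario:
    """Reference and target water temperatures plus activation energy."""

    T_target: float  # degrees C
    T_ref: float = DEFAULT_REFERENCE_TEMP_C  # degrees C
    E: float = DEFAULT_ACTIVATION_ENERGY_EV  # eV
    label: str = ""

    def __post_init__(self) -> None:
        for t in (self.T_ref, self.T_target):
            if not (-5.0 <= t <= 45.0):
                raise ValueError(f"temperature {t} degrees C outside plausible range [-5, 45]")

    @property
    def factor(self) -> float:
        """Multiplicative metabolic factor relative to the reference temperature."""
        return arrhenius_factor(
            celsius_to_kelvin(self.T_ref), celsius_to_kelvin(self.T_target), self.E
        )


def percent_metabolic_change(scenario: TemperatureScenario) -> float:
    """Signed percent change in metabolic rate, 100*(factor - 1), unrounded."""
    return 100.0 * (scenario.factor - 1.0)


def project_resuspension(
    c: float,
    d: float,
    I_TOT: float,
    scenario: TemperatureScenario,
) -> float:
    """Projected R_TOT (g/m2) for a population whose metabolism at the
    reference temperature is ``I_TOT`` (mW/m2)."""
    return c + d * I_TOT * scenario.factor


def scenario_table(
    c: float,
    d: float,
    I_TOT: "pd.Series | float",
    scenarios: list[TemperatureScenario],
) -> pd.DataFrame:
    """One row per scenario: factor, rounded percent change, projected R_TOT.

    Percentages are rounded to whole percent for reporting; the raw factor is
    retained in the ``factor`` column.
    """
    rows = []
    itot = pd.Series(I_TOT) if not isinstance(I_TOT, pd.Series) else I_TOT
    for sc in scenarios:
        f = sc.factor
        rows.append(
            {
                "label": sc.label or f"{sc.T_target:g}C",
                "T_ref_C": sc.T_ref,
                "T_target_C": sc.T_target,
                "activation_energy_eV": sc.E,
                "factor": f,
                "metabolic_change_pct": round(percent_metabolic_change(sc)),
                "Rtot_mean_g_m2": float((c + d * itot * f).mean()),
            }
        )
    return pd.DataFrame(rows)
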