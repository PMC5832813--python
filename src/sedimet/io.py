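"""Dataset access, configuration and CSV serialisation.

The packaged dataset is the 32-treatment flume experiment table (species,
functional group, size, body mass, individual and population metabolic rate,
density, observed resuspension, all with 95% CIs); the source study deposited
no machine-readable data, so this transcription is the dataset of record for
the pipeline. Configuration (constants, per-species conversion rules,
temperature scenarios) is plain TOML.
"""

from __future__ import annotations

import hashlib
import tomllib
from importlib import resources
from pathlib import Path

import pandas as pd

from .metabolism import MassConversionRule, MetabolicModelSpec
from .population import (
    DEFAULT_CONTROL,
    ControlSpec,
    TABLE_SCHEMA,
    ValidationReport,
    assemble_treatment_table,
)
from .projection import TemperatureScenario
from .quantities import QuantityWithCI

__all__ = [
    "load_flume_experiment",
    "read_treatment_table",
    "write_treatment_table",
    "load_config",
    "fixture_checksum",
]

_FIXTURE = "flume_treatments.csv"
_DEFAULTS = "defaults.toml"


def _dataset_path(name: str) -> Path:
    return Path(str(resources.files("sedimet.datasets") / name))


def read_treatment_table(
    path: "Path | str",
    control: ControlSpec = DEFAULT_CONTROL,
    check: bool = True,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a treatment-table CSV (standard schema) and assemble it."""
    df = pd.read_csv(path)
    missing = [c for c in TABLE_SCHEMA if c not in df.columns and c != "functional_group"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return assemble_treatment_table(df, control=control, check=check)


def write_treatment_table(table: pd.DataFrame, path: "Path | str") -> None:
    """Write a treatment table with 6-significant-digit floats (diff-stable)."""
    cols = [c for c in TABLE_SCHEMA if c in table.columns] + [
        c for c in table.columns if c not in TABLE_SCHEMA
    ]
    table[cols].to_csv(path, index=False, float_format="%.6g")


def load_flume_experiment(
    control: ControlSpec = DEFAULT_CONTROL, check: bool = False
) -> tuple[pd.DataFrame, ValidationReport]:
    """The packaged 32-treatment flume dataset, assembled with R_BIO.

    ``check=True`` re-runs the N*I vs I_TOT consistency screen; the printed
    individual-rate column of the source table is internally inconsistent for
    several treatments (the stored I_TOT is authoritative), so checking flags
    those rows with warnings.
    """
    return read_treatment_table(_dataset_path(_FIXTURE), control=control, check=check)


def fixture_checksum() -> str:
    """SHA-256 of the packaged dataset, for provenance logging."""
    return hashlib.sha256(_dataset_path(_FIXTURE).read_bytes()).hexdigest()


def load_config(path: "Path | str | None" = None) -> dict:
    """Parse a TOML config into typed objects.

    Returns a dict with keys: constants (dict), control (ControlSpec),
    metabolic_model (MetabolicModelSpec), mass_conversion (dict of
    MassConversionRule by species), scenarios (list of TemperatureScenario).
    """
    p = _dataset_path(_DEFAULTS) if path is None else Path(path)
    with open(p, "rb") as fh:
        raw = tomllib.load(fh)

    constants = raw.get("constants", {})
    ref_t = constants.get("reference_temperature_c", 18.0)
    e = constants.get("activation_energy_ev", 0.65)

    ctl = raw.get("control", {})
    control = ControlSpec(
        mode=ctl.get("mode", "global_mean"),
        R_CONTROL=QuantityWithCI(ctl.get("value_g_m2", 32.25), ctl.get("ci95_g_m2", 0.0)),
    )

    mm = raw.get("metabolic_model", {})
    spec = MetabolicModelSpec(
        form=mm.get("form", "allometric"),
        a=mm.get("a", 1.0),
        b=mm.get("b", 0.75),
        coefficients=mm.get("coefficients", {}),
        energy_density=constants.get("energy_density_j_per_mg", 21.5),
    )

    rules = {
        sp: MassConversionRule(species=sp, p=v["p"], q=v["q"])
        for sp, v in raw.get("mass_conversion", {}).items()
    }

    scenarios = [
        TemperatureScenario(
            T_target=s["t_target_c"],
            T_ref=s.get("t_ref_c", ref_t),
            E=s.get("activation_energy_ev", e),
            label=s.get("label", ""),
        )
        for s in raw.get("scenarios", [])
    ]

    return {
        "constants": constants,
        "control": control,
        "metabolic_model": spec,
        "mass_conversion": rules,
        "scenarios": scenarios,
    }
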