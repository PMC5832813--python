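"""Model/Results facade over the resuspension-metabolism pipeline.

``ResuspensionScaling`` is built from a treatment table (one row per flume
treatment); ``fit`` returns a ``ScalingResults`` carrying estimates, t-based
95% CIs, p-values, fit statistics and, for stepwise fits, the selection
trace. Temperature projection and correlation diagnostics hang off the two
objects, in the style of statsmodels model classes.

    >>> from sedimet import ResuspensionScaling
    >>> model = ResuspensionScaling.from_fixture()
    >>> res = model.fit()            # R_TOT ~ I_TOT
    >>> res.c, res.d                 # abiotic baseline, per-mW slope
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .population import DEFAULT_CONTROL, ControlSpec, ValidationReport, assemble_treatment_table
from .projection import TemperatureScenario, scenario_table
from .regression import (
    FULL_GROUP_SPEC,
    RBIO_FULL_SPEC,
    SIMPLE_SPEC,
    ModelSpec,
    RegressionResult,
    StepwiseTrace,
    fit_linear_model,
    leverage_exclusion_refit,
    pearson_correlation,
    rbio_models,
    spearman_correlation,
    stepwise_select,
)

__all__ = ["ResuspensionScaling", "ScalingResults"]


class ResuspensionScaling:
    """Linear scaling of sediment resuspension with population metabolism."""

    def __init__(self, table: pd.DataFrame, control: ControlSpec = DEFAULT_CONTROL):
        self.control = control
        if "Rbio_g_mW" in table.columns:
            self.table, self.validation = table, ValidationReport(len(table), [], [])
        else:
            self.table, self.validation = assemble_treatment_table(
                table, control=control, check=False
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, control: ControlSpec = DEFAULT_CONTROL
    ) -> "ResuspensionScaling":
        return cls(df, control=control)

    @classmethod
    def from_csv(
        cls, path: "Path | str", control: ControlSpec = DEFAULT_CONTROL
    ) -> "ResuspensionScaling":
        from .io import read_treatment_table

        table, report = read_treatment_table(path, control=control)
        model = cls(table, control=control)
        model.validation = report
        return model

    @classmethod
    def from_fixture(cls, control: ControlSpec = DEFAULT_CONTROL) -> "ResuspensionScaling":
        """The packaged 32-treatment flume experiment."""
        from .io import load_flume_experiment

        table, report = load_flume_experiment(control=control)
        model = cls(table, control=control)
        model.validation = report
        return model

    # -- fitting ---------------------------------------------------------

    def fit(self, spec: ModelSpec = SIMPLE_SPEC) -> "ScalingResults":
        return ScalingResults(self, fit_linear_model(self.table, spec))

    def fit_stepwise(self, full_spec: ModelSpec = FULL_GROUP_SPEC) -> "ScalingResults":
        """Bidirectional AIC selection over the functional-group variants."""
        trace = stepwise_select(self.table, full_spec)
        return ScalingResults(self, fit_linear_model(self.table, trace.selected), trace=trace)

    def fit_rbio(self, full_spec: ModelSpec = RBIO_FULL_SPEC) -> "ScalingResults":
        """Per-milliwatt biotic effect vs density and body size."""
        trace, selected, canonical = rbio_models(self.table, full_spec)
        return ScalingResults(self, selected, trace=trace, canonical=canonical)

    def leverage_refit(self, k: int = 2) -> tuple["ScalingResults", pd.Index]:
        """Refit the simple model without the k highest-leverage treatments."""
        res, excluded = leverage_exclusion_refit(self.table, k)
        return ScalingResults(self, res), excluded

    # -- diagnostics -----------------------------------------------------

    def correlations(self) -> pd.DataFrame:
        """Pearson and Spearman correlations of R_TOT with I_TOT and density.

        Both coefficients are reported deliberately: on this dataset the
        product-moment and rank statistics differ noticeably (the relation is
        linear but the extreme treatments compress the ranks).
        """
        rows = []
        y = self.table["Rtot_g_m2"]
        for name, x in (
            ("Itot_mW_m2", self.table["Itot_mW_m2"]),
            ("density_ind_m2", self.table["density_ind_m2"]),
        ):
            pr, pp = pearson_correlation(x, y)
            sr, sp = spearman_correlation(x, y)
            rows.append(
                {
                    "predictor": name,
                    "pearson_r": pr,
                    "pearson_p": pp,
                    "spearman_rho": sr,
                    "spearman_p": sp,
                }
            )
        return pd.DataFrame(rows).set_index("predictor")


@dataclass
class ScalingResults:
    """Fit results plus the diagnostics and projections that derive from them."""

    model: ResuspensionScaling
    result: RegressionResult
    trace: StepwiseTrace | None = None
    canonical: dict[str, RegressionResult] | None = None

    # pass-through accessors, statsmodels-style
    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def pvalues(self) -> pd.Series:
        return self.result.pvalues

    def conf_int(self) -> pd.DataFrame:
        return self.result.conf_int

    @property
    def rsquared(self) -> float:
        return self.result.rsquared

    @property
    def rsquared_adj(self) -> float:
        return self.result.rsquared_adj

    @property
    def aic(self) -> float:
        return self.result.aic

    @property
    def nobs(self) -> int:
        return self.result.nobs

    @property
    def c(self) -> float:
        """Abiotic baseline: the fitted intercept (g/m2)."""
        return float(self.params.iloc[0])

    @property
    def d(self) -> float:
        """Biotic slope per mW/m2 of population metabolism."""
        name = "Itot_mW_m2"
        if name not in self.params.index:
            raise AttributeError(f"fitted model has no {name} term")
        return float(self.params[name])

    # -- projection ------------------------------------------------------

    def project(self, scenarios: list[TemperatureScenario]) -> pd.DataFrame:
        """Project mean R_TOT under temperature scenarios via the fitted (c, d).

        Only the biotic term d*I_TOT scales with the Boltzmann-Arrhenius
        factor; the abiotic baseline c is held fixed.
        """
        return scenario_table(self.c, self.d, self.model.table["Itot_mW_m2"], scenarios)

    def summary(self) -> str:
        lines = ["Resuspension-metabolism scaling (OLS)", "=" * 60]
        if self.trace is not None:
            lines.append("stepwise trace:")
            for spec, aic in self.trace.steps:
                mark = " <- selected" if spec == self.trace.selected else ""
                lines.append(f"  {spec.label():<55s} AIC={aic:8.3f}{mark}")
            lines.append("-" * 60)
        lines.extend(self.result.summary_lines())
        return "\n".join(lines)
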