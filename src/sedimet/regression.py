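"""Linear resuspension-metabolism models, AIC stepwise selection, diagnostics.

The central model is ordinary least squares of equilibrium resuspended
sediment on population metabolic rate,

    R_TOT = c + d * I_TOT  (+ functional-group terms),

where c is the abiotic baseline (g/m2) and d the biotic effect per mW of
population metabolism. Functional-group variants (interaction, additive,
none) are compared by bidirectional stepwise selection on AIC, using the
convention AIC = -2*logLik + 2*(p + 1): the residual variance counts as a
fitted parameter, as in R's ``AIC``/``stepAIC``. Also here: rank and
product-moment correlations and the high-leverage exclusion refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelSpec",
    "RegressionResult",
    "StepwiseTrace",
    "fit_linear_model",
    "stepwise_select",
    "spearman_correlation",
    "pearson_correlation",
    "leverage_exclusion_refit",
    "rbio_models",
    "SIMPLE_SPEC",
    "FULL_GROUP_SPEC",
    "RBIO_FULL_SPEC",
]

#: Categorical columns and their reference levels (treatment contrasts).
REFERENCE_LEVELS = {"functional_group": "deep"}


@dataclass(frozen=True)
class ModelSpec:
    """A linear model: response plus an ordered list of predictor terms.

    Terms are column names; ``a:b`` denotes an interaction (its main effects
    must be present). The intercept is always included. Categorical columns
    are coded as treatment contrasts against :data:`REFERENCE_LEVELS`.
    """

    response: str
    terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t in self.terms:
            if ":" in t:
                for part in t.split(":"):
                    if part not in self.terms:
                        raise ValueError(
                            f"interaction {t!r} requires main effect {part!r}"
                        )

    def formula(self) -> str:
        def render(col: str) -> str:
            if col in REFERENCE_LEVELS:
                return f"C({col}, Treatment('{REFERENCE_LEVELS[col]}'))"
            return f"Q('{col}')"

        rhs = ["1"] + [":".join(render(p) for p in t.split(":")) for t in self.terms]
        return f"Q('{self.response}') ~ {' + '.join(rhs)}"

    def drop(self, term: str) -> "ModelSpec":
        return ModelSpec(self.response, tuple(t for t in self.terms if t != term))

    def add(self, term: str) -> "ModelSpec":
        return ModelSpec(self.response, self.terms + (term,))

    def removable_terms(self) -> list[str]:
        """Terms whose removal keeps the hierarchy (interactions go first)."""
        return [
            t
            for t in self.terms
            if not any(":" in o and t != o and t in o.split(":") for o in self.terms)
        ]

    def label(self) -> str:
        if not self.terms:
            return f"{self.response} ~ 1"
        return f"{self.response} ~ {' + '.join(self.terms)}"


# Canonical specs for the two analyses (column names of the table schema).
SIMPLE_SPEC = ModelSpec("Rtot_g_m2", ("Itot_mW_m2",))
FULL_GROUP_SPEC = ModelSpec(
    "Rtot_g_m2",
    ("functional_group", "Itot_mW_m2", "functional_group:Itot_mW_m2"),
)
RBIO_FULL_SPEC = ModelSpec(
    "Rbio_g_mW",
    ("density_ind_m2", "mass_mg_afdw", "density_ind_m2:mass_mg_afdw"),
)


@dataclass
class RegressionResult:
    """OLS fit summary mirroring one column block of a model-comparison table."""

    spec: ModelSpec
    params: pd.Series
    conf_int: pd.DataFrame  # columns: ci_low, ci_high (t-based, 95%)
    pvalues: pd.Series
    nobs: int
    rsquared: float
    rsquared_adj: float
    fvalue: float
    f_pvalue: float
    aic: float
    loglik: float
    residuals: np.ndarray
    fittedvalues: np.ndarray

    @property
    def df_resid(self) -> int:
        return self.nobs - len(self.params)

    def to_frame(self) -> pd.DataFrame:
        """Per-term table: estimate, 95% CI bounds, p-value."""
        out = pd.DataFrame(
            {
                "estimate": self.params,
                "ci_low": self.conf_int["ci_low"],
                "ci_high": self.conf_int["ci_high"],
                "p": self.pvalues,
            }
        )
        out.index.name = "term"
        return out

    def summary_lines(self) -> list[str]:
        lines = [self.spec.label()]
        for term, row in self.to_frame().iterrows():
            lines.append(
                f"  {term:<40s} {row.estimate:10.3f}  "
                f"[{row.ci_low:8.3f}, {row.ci_high:8.3f}]  p={row.p:.3g}"
            )
        lines.append(
            f"  n={self.nobs}  R2={self.rsquared:.3f}/{self.rsquared_adj:.3f}  "
            f"F={self.fvalue:.3f} (p={self.f_pvalue:.3g})  AIC={self.aic:.3f}"
        )
        return lines


def _clean_term_name(name: str) -> str:
    """Undo patsy's Q()/C() decoration for readable coefficient names."""
    out = name
    for col, ref in REFERENCE_LEVELS.items():
        out = out.replace(f"C({col}, Treatment('{ref}'))", col)
    while "Q('" in out:
        i = out.index("Q('")
        j = out.index("')", i)
        out = out[:i] + out[i + 3 : j] + out[j + 2 :]
    return out


def fit_linear_model(table: pd.DataFrame, spec: ModelSpec) -> RegressionResult:
    """Ordinary least squares with t-based 95% CIs and the (p+1)-parameter AIC."""
    n = len(table)
    if n < len(spec.terms) + 2:
        raise ValueError(
            f"need at least {len(spec.terms) + 2} observations for {spec.label()!r}, got {n}"
        )
    model = smf.ols(spec.formula(), data=table)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        names = [_clean_term_name(c) for c in model.exog_names]
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {len(names)}); collinear terms among {names}"
        )
    # degenerate inputs (perfect fit, zero-variance response) hit log(0)/0-division
    # inside statsmodels' lazy statistics; the results are handled explicitly below
    with np.errstate(divide="ignore", invalid="ignore"):
        res = model.fit()
        res.llf, res.rsquared, res.rsquared_adj, res.fvalue, res.f_pvalue
    # a zero-variance response has nothing to explain: define R^2 = 0 there
    r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 0.0
    r2_adj = float(res.rsquared_adj) if np.isfinite(res.rsquared_adj) else 0.0
    rename = {c: _clean_term_name(c) for c in res.params.index}
    ci = res.conf_int(alpha=0.05).rename(index=rename)
    ci.columns = ["ci_low", "ci_high"]
    return RegressionResult(
        spec=spec,
        params=res.params.rename(index=rename),
        conf_int=ci,
        pvalues=res.pvalues.rename(index=rename),
        nobs=int(res.nobs),
        rsquared=r2,
        rsquared_adj=r2_adj,
        fvalue=float(res.fvalue) if res.df_model > 0 else float("nan"),
        f_pvalue=float(res.f_pvalue) if res.df_model > 0 else float("nan"),
        # -2 llf + 2 (p + 1): count the residual variance as a parameter
        aic=float(-2.0 * res.llf + 2.0 * (len(res.params) + 1)),
        loglik=float(res.llf),
        residuals=np.asarray(res.resid),
        fittedvalues=np.asarray(res.fittedvalues),
    )


@dataclass
class StepwiseTrace:
    """Visited models of a bidirectional stepwise run, in order."""

    steps: list[tuple[ModelSpec, float]]
    selected_index: int
    log: list[str] = field(default_factory=list)

    @property
    def selected(self) -> ModelSpec:
        return self.steps[self.selected_index][0]

    @property
    def aics(self) -> list[float]:
        return [a for _, a in self.steps]


def stepwise_select(table: pd.DataFrame, full_spec: ModelSpec) -> StepwiseTrace:
    """Bidirectional AIC stepwise starting from the full model.

    At every step the candidate moves are: drop any term whose removal keeps
    the model hierarchical (interactions before their main effects), or add
    back any dropped term whose main effects are present. The move with the
    lowest AIC is taken if it improves on the current model; the procedure is
    deterministic (ties broken by term order) and stops when no move improves.
    """
    current = full_spec
    current_aic = fit_linear_model(table, current).aic
    steps = [(current, current_aic)]
    log = [f"start: {current.label()}  AIC={current_aic:.3f}"]
    while True:
        candidates: list[tuple[float, str, ModelSpec]] = []
        for t in current.removable_terms():
            cand = current.drop(t)
            candidates.append((fit_linear_model(table, cand).aic, f"- {t}", cand))
        for t in full_spec.terms:
            if t in current.terms:
                continue
            if any(p not in current.terms for p in t.split(":") if p != t):
                continue
            cand = current.add(t)
            candidates.append((fit_linear_model(table, cand).aic, f"+ {t}", cand))
        if not candidates:
            break
        best_aic, move, best = min(candidates, key=lambda c: c[0])
        if best_aic >= current_aic:
            log.append(f"stop: no move improves AIC {current_aic:.3f}")
            break
        current, current_aic = best, best_aic
        steps.append((current, current_aic))
        log.append(f"{move}: {current.label()}  AIC={current_aic:.3f}")
    sel = int(np.argmin([a for _, a in steps]))
    return StepwiseTrace(steps=steps, selected_index=sel, log=log)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    r = stats.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def leverage_exclusion_refit(
    table: pd.DataFrame,
    k: int,
    spec: ModelSpec = SIMPLE_SPEC,
    by: str = "Itot_mW_m2",
) -> tuple[RegressionResult, pd.Index]:
    """Sensitivity refit after dropping the k rows with the largest predictor.

    The two highest-I_TOT treatments dominate the leverage of the simple fit;
    this checks that the positive scaling survives without them. Rows tied at
    the k-th largest value are all excluded, so the effective number dropped
    can exceed ``k`` (the excluded index is returned alongside the refit).
    """
    n = len(table)
    if not (0 <= k < n - 2):
        raise ValueError(f"k must satisfy 0 <= k < n - 2 = {n - 2}, got {k}")
    if k == 0:
        return fit_linear_model(table, spec), table.index[:0]
    threshold = np.sort(table[by].to_numpy())[-k]
    excluded = table.index[table[by] >= threshold]
    kept = table.drop(index=excluded)
    return fit_linear_model(kept, spec), excluded


def rbio_models(
    table: pd.DataFrame, full_spec: ModelSpec = RBIO_FULL_SPEC
) -> tuple[StepwiseTrace, RegressionResult, dict[str, RegressionResult]]:
    """Per-milliwatt effect vs density and body size.

    Fits the interaction, additive and intercept-only models of R_BIO on
    density and individual mass, runs the stepwise selection, and returns
    (trace, fit of the selected model, the three canonical fits). With no
    density/size signal the selected model is the intercept-only one, whose
    single estimate is the mean R_BIO (g per mW).
    """
    if full_spec.response not in table.columns:
        raise ValueError(f"table has no {full_spec.response!r} column")
    trace = stepwise_select(table, full_spec)
    canonical = {
        "interaction": fit_linear_model(table, full_spec),
        "additive": fit_linear_model(
            table, ModelSpec(full_spec.response, tuple(t for t in full_spec.terms if ":" not in t))
        ),
        "intercept_only": fit_linear_model(table, ModelSpec(full_spec.response, ())),
    }
    selected = fit_linear_model(table, trace.selected)
    return trace, selected, canonical
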