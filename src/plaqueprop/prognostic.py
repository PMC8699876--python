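"""Error-injected prognostic modelling of plaque progression.

A patient cohort carries a roster of biohumoral measurements (liver
enzymes, lipids, inflammation markers...), imaging-derived features and
a plaque-progression outcome.  Analytical laboratory error is emulated
by multiplying the biohumoral columns either by a fixed worst-case
factor (e.g. 1.13, a 13% analytical error) or by independent uniform
multipliers in [1−f, 1+f].  Univariate screening and a multivariate fit
are then compared across scenarios: for well-behaved data the set of
significant predictors should be stable, exactly so under the uniform
scenario (ordinary least squares is scale-equivariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import StatsError

__all__ = [
    "BIOHUMORAL_VARIABLES",
    "LIPIDOMIC_VARIABLES",
    "IMAGING_VARIABLES",
    "CohortTable",
    "ErrorScenario",
    "RegressionReport",
    "inject_error",
    "univariate_screen",
    "multivariate_fit",
    "compare_scenarios",
]

#: Biohumoral roster — the columns analytical error applies to.
BIOHUMORAL_VARIABLES = (
    "alanine",
    "alkaline",
    "aspartate",
    "gamma_gt",
    "creatinine",
    "uric_acid",
    "glucose",
    "triglycerides",
    "cholesterol",
    "ldl",
    "hdl",
    "reactive_protein",
    "interleukin_6",
    "leptin",
    "icam1",
    "vcam1",
)

LIPIDOMIC_VARIABLES = ("ce_18_3", "ce_20_3", "ce_20_4", "ps_38_6")

#: Imaging/simulation-derived per-patient features.
IMAGING_VARIABLES = ("baseline_plaque_burden", "min_ess", "max_ldl_concentration", "smartffr")

OutcomeKind = Literal["continuous", "binary"]


@dataclass(frozen=True)
class CohortTable:
    """A patient table plus the metadata the analysis needs."""

    data: pd.DataFrame
    biohumoral_columns: tuple[str, ...] = BIOHUMORAL_VARIABLES
    outcome_column: str = "plaque_progression"
    outcome_kind: OutcomeKind = "continuous"

    def __post_init__(self) -> None:
        missing = [c for c in self.biohumoral_columns if c not in self.data.columns]
        if missing:
            raise StatsError(f"biohumoral columns missing from table: {missing}")
        if self.outcome_column not in self.data.columns:
            raise StatsError(f"outcome column {self.outcome_column!r} missing")
        if self.data[self.outcome_column].isna().any():
            raise StatsError("outcome column contains missing values")
        object.__setattr__(self, "biohumoral_columns", tuple(self.biohumoral_columns))

    @property
    def n(self) -> int:
        return len(self.data)

    def predictors(self) -> list[str]:
        return [c for c in self.data.columns if c != self.outcome_column]


@dataclass(frozen=True)
class ErrorScenario:
    """Analytical-error injection scheme for the biohumoral columns.

    ``maximum`` multiplies every value by (1 + max_fraction) — the
    worst-case systematic error; ``random`` multiplies each cell by an
    independent uniform draw from [1 − max_fraction, 1 + max_fraction].
    """

    kind: Literal["none", "maximum", "random"] = "none"
    max_fraction: float = 0.13
    seed: int | None = None
    direction: Literal["increase", "decrease"] = "increase"
    per_column: bool = False  # one multiplier per column instead of per cell

    def __post_init__(self) -> None:
        if self.kind not in ("none", "maximum", "random"):
            raise StatsError(f"unknown scenario kind {self.kind!r}")
        if not (0.0 <= self.max_fraction < 1.0):
            raise StatsError("max_fraction must be in [0, 1)")


def inject_error(table: CohortTable, scenario: ErrorScenario) -> CohortTable:
    """Apply an analytical-error scenario to the biohumoral columns."""
    if scenario.kind == "none":
        return table
    df = table.data.copy()
    cols = list(table.biohumoral_columns)
    if scenario.kind == "maximum":
        factor = 1.0 + scenario.max_fraction
        if scenario.direction == "decrease":
            factor = 1.0 - scenario.max_fraction
        df[cols] = df[cols] * factor
    else:  # random
        rng = np.random.default_rng(scenario.seed)
        lo, hi = 1.0 - scenario.max_fraction, 1.0 + scenario.max_fraction
        if scenario.per_column:
            mult = rng.uniform(lo, hi, size=len(cols))
            df[cols] = df[cols] * mult
        else:
            mult = rng.uniform(lo, hi, size=(len(df), len(cols)))
            df[cols] = df[cols].to_numpy() * mult
    return replace(table, data=df)


@dataclass(frozen=True)
class RegressionReport:
    """Per-variable coefficient, Wald 95% CI, p-value and significance."""

    table: pd.DataFrame  # index: variable; columns: coef, ci_low, ci_high, p
    alpha: float = 0.05
    model: str = "linear"

    def significant(self) -> set[str]:
        return set(self.table.index[self.table["p"] < self.alpha])


def _fit_one(y: np.ndarray, x: pd.DataFrame, model: str):
    design = sm.add_constant(x, has_constant="add")
    if model == "linear":
        return sm.OLS(y, design).fit()
    if model == "logistic":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.Logit(y, design).fit(disp=0)
    raise StatsError(f"unknown model {model!r}")


def univariate_screen(
    table: CohortTable,
    variables: Sequence[str] | None = None,
    model: str | None = None,
    alpha: float = 0.05,
) -> RegressionReport:
    """Single-predictor regressions of the outcome on each variable.

    Ordinary least squares for a continuous outcome, logistic for a
    binary one (the default follows the table's ``outcome_kind``).
    Constant predictors are skipped with a warning.
    """
    if variables is None:
        variables = list(table.biohumoral_columns)
    if model is None:
        model = "linear" if table.outcome_kind == "continuous" else "logistic"
    y = table.data[table.outcome_column].to_numpy(dtype=float)
    if table.n <= 2:
        raise StatsError("need more observations than parameters")
    rows = {}
    for var in variables:
        x = table.data[[var]].astype(float)
        if float(x[var].std()) == 0.0:
            warnings.warn(f"skipping constant predictor {var!r}", stacklevel=2)
            continue
        fit = _fit_one(y, x, model)
        ci = fit.conf_int(alpha=0.05)
        rows[var] = {
            "coef": float(fit.params[var]),
            "ci_low": float(ci.loc[var, 0]),
            "ci_high": float(ci.loc[var, 1]),
            "p": float(fit.pvalues[var]),
        }
    return RegressionReport(pd.DataFrame.from_dict(rows, orient="index"), alpha, model)


def multivariate_fit(
    table: CohortTable,
    predictors: Sequence[str],
    model: str | None = None,
    alpha: float = 0.05,
) -> RegressionReport:
    """Joint fit over a fixed predictor list.

    Raises a rank-deficiency error naming the collinear columns if the
    design matrix is not full rank.
    """
    predictors = list(predictors)
    if table.n <= len(predictors) + 1:
        raise StatsError("need n > number of predictors + 1")
    if model is None:
        model = "linear" if table.outcome_kind == "continuous" else "logistic"
    x = table.data[predictors].astype(float)
    mat = sm.add_constant(x, has_constant="add").to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns by incremental rank growth
        collinear = []
        cols: list[np.ndarray] = [np.ones(len(x))]
        for name in predictors:
            candidate = np.column_stack(cols + [x[name].to_numpy()])
            if np.linalg.matrix_rank(candidate) == len(cols):
                collinear.append(name)
            else:
                cols.append(x[name].to_numpy())
        raise StatsError(f"rank-deficient design; collinear columns: {collinear}")
    y = table.data[table.outcome_column].to_numpy(dtype=float)
    fit = _fit_one(y, x, model)
    ci = fit.conf_int(alpha=0.05)
    rows = {
        var: {
            "coef": float(fit.params[var]),
            "ci_low": float(ci.loc[var, 0]),
            "ci_high": float(ci.loc[var, 1]),
            "p": float(fit.pvalues[var]),
        }
        for var in predictors
    }
    return RegressionReport(pd.DataFrame.from_dict(rows, orient="index"), alpha, model)


def compare_scenarios(reports: Mapping[str, RegressionReport]) -> pd.DataFrame:
    """Significance pattern across scenarios plus Jaccard overlaps.

    Returns a table with one row per variable and one boolean column per
    scenario; pairwise Jaccard overlaps of the significant sets are
    attached as ``DataFrame.attrs['jaccard']``.
    """
    if len(reports) < 2:
        raise StatsError("need at least two reports to compare")
    rosters = [tuple(r.table.index) for r in reports.values()]
    if len(set(rosters)) != 1:
        raise StatsError("reports cover different variable rosters")
    pattern = pd.DataFrame(
        {name: rep.table["p"] < rep.alpha for name, rep in reports.items()}
    )
    names = list(reports)
    jaccard = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = reports[a].significant(), reports[b].significant()
            union = sa | sb
            jaccard[(a, b)] = 1.0 if not union else len(sa & sb) / len(union)
    pattern.attrs["jaccard"] = jaccard
    return pattern
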