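"""Clinical/functional outcome statistics and stepwise regression.

The clinical question behind these helpers: which easily measured
outcomes (side-to-side thigh girth difference, KT-1000 laxity
difference, hop-distance ratio, Tegner activity score) track the extent
of knee degeneration summarized by a whole-organ MRI (WORM) total?
Pairwise association uses two-tailed Pearson correlation; prediction
uses bidirectional stepwise ordinary least squares (forward selection
by smallest partial-F p-value below ``alpha_enter``, backward
elimination of any included term whose p-value rises above
``alpha_remove``).

Correlations are reported as the signed coefficient r together with r²;
the two are never conflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, ConfigurationError

__all__ = [
    "SubjectOutcomes",
    "RegressionResult",
    "pearson",
    "summarize_cohort",
    "stepwise_regression",
    "correlate_outcomes",
    "load_table1",
]

OUTCOME_FIELDS = ("girth_delta", "laxity_delta", "hop_ratio", "tegner", "worms_total")


@dataclass
class SubjectOutcomes:
    """Per-subject clinical, functional and imaging outcomes.

    ``girth_delta`` — thigh circumference 6 cm above the joint line,
    index minus contralateral, cm (0.5 cm resolution).
    ``laxity_delta`` — KT-1000 anterior laxity difference from the
    contralateral limb, mm.  ``hop_ratio`` — (index / contralateral) x
    100, percent.  ``tegner`` — ordinal 0-10 activity grade.
    ``worms_total`` — summed whole-organ MRI degeneration score.
    """

    subject_id: str
    group: str
    girth_delta: float
    laxity_delta: float
    hop_ratio: float
    tegner: int
    worms_total: float
    age: float = np.nan
    bmi: float = np.nan
    follow_up: float = np.nan

    def __post_init__(self) -> None:
        if self.hop_ratio <= 0:
            raise ConfigurationError("hop_ratio must be positive")
        if not 0 <= self.tegner <= 10:
            raise ConfigurationError("tegner score outside its ordinal range")
        if self.worms_total < 0:
            raise ConfigurationError("worms_total must be nonnegative")


@dataclass
class RegressionResult:
    selected_predictors: list
    intercept: float
    coefficients: dict
    p_values: dict
    steps: list = field(default_factory=list)


def pearson(x, y) -> dict:
    """Product-moment correlation with a two-tailed t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ConfigurationError("pearson needs at least 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConfigurationError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_two_tailed": float(p), "n": int(x.size)}


def summarize_cohort(table: pd.DataFrame, by: str = "group", decimals: int = 1) -> pd.DataFrame:
    """Group means and sample SDs (n-1 denominator) of the numeric columns.

    Returns a frame indexed by group with a two-level column index
    (field, statistic); values rounded to ``decimals`` for reporting.
    """
    numeric = table.select_dtypes(include=[np.number]).columns
    if table.groupby(by).size().min() < 2:
        raise ConfigurationError("every group needs at least 2 subjects")
    agg = table.groupby(by)[list(numeric)].agg(["mean", lambda s: s.std(ddof=1)])
    agg.columns = pd.MultiIndex.from_tuples(
        [(f, "mean" if s == "mean" else "sd") for f, s in agg.columns]
    )
    return agg.round(decimals)


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    y,
    candidates: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> RegressionResult:
    """Bidirectional stepwise OLS over named candidate predictors.

    Forward step: among excluded candidates, add the one with the
    smallest coefficient p-value in the augmented model if it is below
    ``alpha_enter`` (ties broken alphabetically).  Backward step: drop
    the included term with the largest p-value above ``alpha_remove``.
    ``alpha_remove >= alpha_enter`` guarantees termination.  A full step
    log is returned.
    """
    if alpha_remove < alpha_enter:
        raise ConfigurationError("alpha_remove must be >= alpha_enter")
    y = np.asarray(y, dtype=float)
    if candidates.shape[0] != y.size:
        raise ConfigurationError("y and candidates must have equal length")
    if y.size <= candidates.shape[1] + 1:
        raise ConfigurationError("need n > number of candidates + 1")
    corr = candidates.corr().abs()
    for i, a in enumerate(corr.columns):
        for b in corr.columns[i + 1 :]:
            if corr.loc[a, b] > 0.9999:
                raise CollinearityError(f"candidates {a!r} and {b!r} are collinear")

    included: list[str] = []
    steps: list[dict] = []
    while True:
        changed = False
        excluded = sorted(c for c in candidates.columns if c not in included)
        if excluded:
            pvals = {}
            for c in excluded:
                fit = _ols(y, candidates[included + [c]])
                pvals[c] = float(fit.pvalues[c])
            best = min(sorted(pvals), key=lambda c: pvals[c])  # alphabetical tie-break
            if pvals[best] < alpha_enter:
                included.append(best)
                steps.append({"action": "add", "term": best, "p": pvals[best]})
                changed = True
        if included:
            fit = _ols(y, candidates[included])
            worst = max(sorted(included), key=lambda c: float(fit.pvalues[c]))
            p_worst = float(fit.pvalues[worst])
            if p_worst > alpha_remove:
                included.remove(worst)
                steps.append({"action": "remove", "term": worst, "p": p_worst})
                changed = True
        if not changed:
            break

    if included:
        fit = _ols(y, candidates[included])
        intercept = float(fit.params["const"])
        coefs = {c: float(fit.params[c]) for c in included}
        pvs = {c: float(fit.pvalues[c]) for c in included}
    else:
        intercept = float(np.mean(y))
        coefs, pvs = {}, {}
    return RegressionResult(
        selected_predictors=list(included),
        intercept=intercept,
        coefficients=coefs,
        p_values=pvs,
        steps=steps,
    )


def correlate_outcomes(
    table: pd.DataFrame, score_field: str = "worms_total", fields=None
) -> pd.DataFrame:
    """Pearson correlation of each outcome against the degeneration score.

    Missing values are dropped pairwise and the pair count reported; no
    multiplicity adjustment is applied.
    """
    if fields is None:
        fields = [
            c
            for c in table.select_dtypes(include=[np.number]).columns
            if c != score_field
        ]
    rows = []
    for f in fields:
        res = pearson(table[f], table[score_field])
        rows.append(
            {
                "field": f,
                "r": res["r"],
                "r_squared": res["r"] ** 2,
                "p_two_tailed": res["p_two_tailed"],
                "n": res["n"],
            }
        )
    return pd.DataFrame(rows).set_index("field")


def load_table1() -> pd.DataFrame:
    """The packaged study-cohort demographics/outcomes table.

    Columns: sex, group, age, index_limb, bmi, follow_up_years, tegner,
    kt1000_delta_mm, hop_ratio_pct.  One control subject has no recorded
    follow-up year (empty cell -> NaN).
    """
    with resources.files("hopwave.data").joinpath("table1_cohort.csv").open() as fh:
        return pd.read_csv(fh)
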