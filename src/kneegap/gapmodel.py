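"""Statistical pipeline for the joint-gap model.

Organised statsmodels-style: :class:`JointGapModel` is built from a
DataFrame of per-knee measurements and ``fit()`` returns a
:class:`JointGapResults` carrying estimates, 95 % confidence intervals,
p-values, residual diagnostics and a summary table.  Module-level helpers
cover the rest of the analysis workflow: group descriptives with t-tests,
Pearson correlation of the eight canonical variables, backward-stepwise
term selection with a collinearity screen, prediction metrics, and seeded
k-fold cross-validation with best-fold selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import CollinearityError, ParameterError

__all__ = [
    "CANONICAL_VARIABLES",
    "DEFAULT_TERMS",
    "BORDER_VARIABLES",
    "JointGapModel",
    "JointGapResults",
    "ResidualDiagnostics",
    "CVResult",
    "Metrics",
    "fit_ols",
    "describe_and_compare",
    "pearson_matrix",
    "backward_stepwise",
    "metrics",
    "kfold_cv",
    "residual_diagnostics",
]

#: The eight per-knee measurements, all in millimetres.
CANONICAL_VARIABLES = (
    "x",
    "y",
    "z",
    "w",
    "tibial_cut",
    "femoral_cut",
    "post_condyle",
    "joint_gap",
)

#: Osteophyte trapezoid borders (mutually correlated in practice).
BORDER_VARIABLES = ("x", "y", "z", "w")

#: Terms of the final published gap equation.
DEFAULT_TERMS = ("y", "tibial_cut", "femoral_cut", "post_condyle")

RESPONSE = "joint_gap"


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame.from_records(records)


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise :class:`CollinearityError` naming an offending term if the
    design matrix (with intercept) is rank deficient."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # identify a column whose removal does not drop the rank
    for j, name in enumerate(X.columns):
        sub = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            raise CollinearityError(
                f"design matrix is rank deficient; term {name!r} is "
                "collinear with the others",
                term=str(name),
            )
    raise CollinearityError("design matrix is rank deficient")


class JointGapModel:
    """Ordinary least squares model of the joint gap on chosen predictors.

    Parameters
    ----------
    data:
        Per-knee measurements; must contain the response and every term.
    terms:
        Predictor columns; defaults to the four terms of the published
        equation (y, tibial_cut, femoral_cut, post_condyle).
    response:
        Response column, default ``joint_gap``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        terms: Sequence[str] = DEFAULT_TERMS,
        response: str = RESPONSE,
    ):
        data = _as_dataframe(data)
        terms = tuple(terms)
        missing = [c for c in (*terms, response) if c not in data.columns]
        if missing:
            raise ParameterError(f"data is missing columns {missing}")
        if len(set(terms)) != len(terms):
            dupes = sorted({t for t in terms if list(terms).count(t) > 1})
            raise CollinearityError(
                f"duplicated predictor column(s) {dupes}", term=dupes[0]
            )
        n = len(data)
        if n <= len(terms) + 1:
            raise ParameterError(
                f"need more than {len(terms) + 1} observations to fit "
                f"{len(terms)} terms, got {n}"
            )
        X = data.loc[:, list(terms)].astype(float)
        if not np.isfinite(X.to_numpy()).all():
            raise ParameterError("non-finite predictor values")
        _check_full_rank(sm.add_constant(X, has_constant="add"))
        self.data = data
        self.terms = terms
        self.response = response

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        terms: Sequence[str] = DEFAULT_TERMS,
        response: str = RESPONSE,
    ) -> "JointGapModel":
        return cls(data, terms=terms, response=response)

    def fit(self) -> "JointGapResults":
        X = sm.add_constant(self.data.loc[:, list(self.terms)].astype(float),
                            has_constant="add")
        y = self.data[self.response].astype(float)
        res = sm.OLS(y, X).fit()
        return JointGapResults(self, res)


class JointGapResults:
    """Fitted joint-gap model: estimates, 95 % CIs, p-values, diagnostics."""

    def __init__(self, model: JointGapModel, sm_results):
        self.model = model
        self.sm_results = sm_results

    @property
    def params(self) -> pd.Series:
        return self.sm_results.params

    @property
    def pvalues(self) -> pd.Series:
        return self.sm_results.pvalues

    @property
    def conf_int_95(self) -> pd.DataFrame:
        ci = self.sm_results.conf_int(alpha=0.05)
        ci.columns = ["ci_low", "ci_high"]
        return ci

    @property
    def resid(self) -> pd.Series:
        return self.sm_results.resid

    @property
    def fittedvalues(self) -> pd.Series:
        return self.sm_results.fittedvalues

    @property
    def resid_sd(self) -> float:
        """Residual standard deviation (root mean squared residual error)."""
        return float(np.sqrt(self.sm_results.mse_resid))

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(
            _as_dataframe(data).loc[:, list(self.model.terms)].astype(float),
            has_constant="add",
        )
        return np.asarray(self.sm_results.predict(X))

    def coefficient_table(self) -> pd.DataFrame:
        """Per-term estimate, 95 % CI and p-value."""
        tab = pd.DataFrame(
            {
                "estimate": self.params,
                "ci_low": self.conf_int_95["ci_low"],
                "ci_high": self.conf_int_95["ci_high"],
                "p_value": self.pvalues,
            }
        )
        tab.index.name = "term"
        return tab

    def diagnostics(self) -> "ResidualDiagnostics":
        return residual_diagnostics(self)

    def summary(self):
        """statsmodels summary table for the fit."""
        return self.sm_results.summary()


def fit_ols(
    records,
    response: str = RESPONSE,
    terms: Sequence[str] = DEFAULT_TERMS,
) -> JointGapResults:
    """Fit an OLS joint-gap model; convenience wrapper around
    :class:`JointGapModel`."""
    return JointGapModel(_as_dataframe(records), terms=terms, response=response).fit()


# ---------------------------------------------------------------------------
# descriptives and correlation
# ---------------------------------------------------------------------------


def describe_and_compare(
    train, test, variables: Sequence[str] = CANONICAL_VARIABLES
) -> pd.DataFrame:
    """Per-variable mean ± SD in two groups plus a Student t-test p-value.

    The equal-variance (Student) two-sample t-test is used.  Variables with
    zero variance in both groups get an undefined p-value (NaN) and a
    ``zero-variance`` flag instead of a hard error.
    """
    train, test = _as_dataframe(train), _as_dataframe(test)
    if len(train) == 0 or len(test) == 0:
        raise ParameterError("both groups must be nonempty")
    rows = []
    for v in variables:
        a = train[v].astype(float).to_numpy()
        b = test[v].astype(float).to_numpy()
        flag = ""
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # the pooled variance is zero, so the statistic is undefined
            t_stat, p, flag = np.nan, np.nan, "zero-variance"
        else:
            with np.errstate(all="ignore"):
                t_stat, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "variable": v,
                "train_mean": a.mean(),
                "train_sd": a.std(ddof=1) if len(a) > 1 else np.nan,
                "test_mean": b.mean(),
                "test_sd": b.std(ddof=1) if len(b) > 1 else np.nan,
                "t_stat": t_stat,
                "p_value": p,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def pearson_matrix(
    records, variables: Sequence[str] = CANONICAL_VARIABLES
) -> pd.DataFrame:
    """Pearson correlation matrix of the canonical variables.

    Requires n >= 3.  Constant columns produce undefined (NaN) entries and
    a warning naming them.
    """
    df = _as_dataframe(records).loc[:, list(variables)].astype(float)
    if len(df) < 3:
        raise ParameterError(f"need at least 3 records, got {len(df)}")
    constant = [c for c in df.columns if np.ptp(df[c].to_numpy()) == 0]
    if constant:
        warnings.warn(
            f"constant column(s) {constant}: correlation undefined (NaN)",
            stacklevel=2,
        )
    return df.corr(method="pearson")


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------


def backward_stepwise(
    records,
    candidates: Sequence[str] = ("x", "y", "z", "w", "tibial_cut", "femoral_cut", "post_condyle"),
    response: str = RESPONSE,
    vif_threshold: float = 10.0,
    alpha: float = 0.05,
) -> list[str]:
    """Backward-stepwise term selection with a border collinearity screen.

    The osteophyte borders x, y, z, w are strongly inter-correlated, so
    they are screened first: if the variance inflation factor within the
    border block exceeds ``vif_threshold``, only the border most correlated
    (in absolute value) with the response is kept.  The survivors then go
    through ordinary backward elimination, removing the highest-p term
    until every remaining term has p < ``alpha``.  An empty selection is
    returned with a warning when nothing survives.
    """
    df = _as_dataframe(records)
    candidates = list(candidates)
    borders = [c for c in candidates if c in BORDER_VARIABLES]

    selected = list(candidates)
    if len(borders) >= 2:
        Xb = sm.add_constant(df.loc[:, borders].astype(float), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vifs = [
                variance_inflation_factor(Xb.to_numpy(), j + 1)
                for j in range(len(borders))
            ]
        if max(vifs) > vif_threshold:
            resp = df[response].astype(float)
            corr = {
                b: abs(np.corrcoef(df[b].astype(float), resp)[0, 1]) for b in borders
            }
            keep = max(corr, key=corr.get)
            selected = [c for c in candidates if c not in borders or c == keep]

    while selected:
        res = fit_ols(df, response=response, terms=selected)
        pvals = res.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        selected.remove(worst)
    if not selected:
        warnings.warn(
            "backward stepwise removed every candidate; no term reaches "
            f"p < {alpha}",
            stacklevel=2,
        )
    return selected


# ---------------------------------------------------------------------------
# prediction metrics and cross-validation
# ---------------------------------------------------------------------------


class Metrics(NamedTuple):
    r_squared: float
    rmse: float
    mae: float


def metrics(observed, predicted) -> Metrics:
    """R², RMSE and MAE of predictions against observations.

    R² = 1 - SS_res/SS_tot and may be negative on held-out data.  With
    zero-variance observations R² is undefined (NaN, with a warning).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ParameterError(
            f"observed and predicted must be equal-length 1-D, got "
            f"{obs.shape} and {pred.shape}"
        )
    if obs.size == 0:
        raise ParameterError("empty input")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("observed values are constant; R² undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return Metrics(r2, rmse, mae)


@dataclass
class CVResult:
    """Per-fold cross-validation metrics with the selected best fold.

    ``fold_metrics`` has one row per fold (1-based ``fold`` index) with
    held-out r_squared, rmse and mae; ``assignments`` maps each record to
    its fold; ``best_fold`` is the fold with the highest held-out R²
    (ties broken by lowest RMSE); ``summary`` holds mean ± SD per metric.
    """

    fold_metrics: pd.DataFrame
    assignments: np.ndarray
    best_fold: int
    summary: pd.DataFrame
    terms: tuple[str, ...] = DEFAULT_TERMS


def kfold_cv(
    records,
    k: int = 10,
    *,
    seed: int,
    terms: Sequence[str] = DEFAULT_TERMS,
    response: str = RESPONSE,
) -> CVResult:
    """Seeded k-fold cross-validation of the OLS joint-gap model.

    Records are shuffled with a seeded generator and split into k
    near-equal folds (sizes differ by at most one).  Each fold is held out
    once; the model is fitted on the remaining k-1 folds and scored on the
    held-out fold.  Reproducibility is bit-exact for a fixed seed.
    """
    df = _as_dataframe(records).reset_index(drop=True)
    n = len(df)
    if k < 2:
        raise ParameterError(f"k must be at least 2, got {k}")
    if n < 2 * k:
        raise ParameterError(f"need at least 2k={2 * k} records for k={k}, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    assignments = np.empty(n, dtype=int)
    rows = []
    for i, hold in enumerate(folds, start=1):
        assignments[hold] = i
        train_idx = np.setdiff1d(order, hold, assume_unique=True)
        res = fit_ols(df.iloc[train_idx], response=response, terms=terms)
        pred = res.predict(df.iloc[hold])
        m = metrics(df.iloc[hold][response].to_numpy(dtype=float), pred)
        rows.append({"fold": i, "r_squared": m.r_squared, "rmse": m.rmse, "mae": m.mae})
    fold_metrics = pd.DataFrame(rows).set_index("fold")

    # best fold: highest held-out R², ties broken by lowest RMSE; metrics
    # are compared at 1e-12 resolution so numerically identical folds tie
    # and resolve to the earliest fold
    ranked = fold_metrics.round(12).sort_values(
        by=["r_squared", "rmse"], ascending=[False, True], kind="stable"
    )
    best_fold = int(ranked.index[0])

    summary = pd.DataFrame(
        {"mean": fold_metrics.mean(), "sd": fold_metrics.std(ddof=1)}
    )
    return CVResult(
        fold_metrics=fold_metrics,
        assignments=assignments,
        best_fold=best_fold,
        summary=summary,
        terms=tuple(terms),
    )


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ResidualDiagnostics:
    """Pass/warn flags for the linear-regression assumptions.

    ``trend_flag`` warns when residuals show curvature against fitted
    values (quadratic-term test); ``normality_flag`` is a Shapiro-Wilk
    check ('insufficient-n' below 8 residuals); ``leverage_flag`` warns
    when an influential outlier (Cook's distance > 1) is present.
    ``n_high_leverage`` counts points whose hat value exceeds 2(p+1)/n.
    """

    trend_flag: str
    trend_p: float
    normality_flag: str
    normality_p: float
    leverage_flag: str
    n_high_leverage: int
    max_cooks_distance: float

    def all_pass(self) -> bool:
        return (
            self.trend_flag == "pass"
            and self.normality_flag == "pass"
            and self.leverage_flag == "pass"
        )


def residual_diagnostics(results: JointGapResults, alpha: float = 0.05) -> ResidualDiagnostics:
    """Diagnostics on a fitted model's residuals (never raises)."""
    resid = np.asarray(results.resid, dtype=float)
    fitted = np.asarray(results.fittedvalues, dtype=float)
    n = resid.size
    p_terms = len(results.model.terms)

    # curvature of residual vs fitted: OLS residuals are orthogonal to the
    # fitted values by construction, so test the quadratic component
    if n >= p_terms + 4 and np.ptp(fitted) > 0:
        F = np.column_stack([np.ones(n), fitted, fitted**2])
        quad = sm.OLS(resid, F).fit()
        trend_p = float(quad.pvalues[2])
    else:
        trend_p = float("nan")
    trend_flag = "warn" if (trend_p == trend_p and trend_p < alpha) else "pass"

    if n < 8:
        normality_flag, normality_p = "insufficient-n", float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p = float(sps.shapiro(resid).pvalue)
        normality_flag = "warn" if normality_p < alpha else "pass"

    influence = results.sm_results.get_influence()
    hat = influence.hat_matrix_diag
    threshold = 2.0 * (p_terms + 1) / n
    n_high = int(np.sum(hat > threshold))
    cooks = influence.cooks_distance[0]
    max_cooks = float(np.max(cooks)) if cooks.size else 0.0
    leverage_flag = "warn" if max_cooks > 1.0 else "pass"

    return ResidualDiagnostics(
        trend_flag=trend_flag,
        trend_p=trend_p,
        normality_flag=normality_flag,
        normality_p=normality_p,
        leverage_flag=leverage_flag,
        n_high_leverage=n_high,
        max_cooks_distance=max_cooks,
    )
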