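"""Gene-specific cognitive composite derivation.

For each genetic group an L1-penalized (LASSO) logistic regression of
carrier status on the z-scored test battery is fitted with stratified
10-fold cross-validation over a descending penalty grid; the penalty
minimizing mean cross-validated binomial deviance is chosen (a one-SE rule
is available).  Tests with strictly negative coefficients — carriers worse
than controls — form the composite; positive-coefficient tests are excluded.
Two composites are built per gene: an unweighted average of the selected
z-scores, and a weighted average with weights proportional to the absolute
regression coefficients.

Penalty parameterization follows the glmnet convention: the objective is
the mean negative log-likelihood plus
lambda * ||beta||_1, with predictors standardized internally and
coefficients reported back on the z-score scale.  The all-zero penalty
bound is lambda_max = max_j |<x_j, y - ybar>| / n.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .battery import DEFAULT_BATTERY, TestBattery

logger = logging.getLogger(__name__)

#: Coefficients smaller than this magnitude are treated as exactly zero.
ZERO_TOL = 1e-8


class CompositeError(ValueError):
    """Composite cannot be formed (e.g. no negative coefficients)."""


class FitError(ValueError):
    """Penalized fit preconditions violated."""


@dataclass
class PenalizedFit:
    """One gene's L1-penalized logistic model over the battery z-scores."""

    gene: str
    coefficients: dict[str, float]  # every battery test; zero if unselected
    intercept: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray  # mean held-out binomial deviance per lambda
    cv_deviance_se: np.ndarray
    chosen_lambda: float
    fold_seed: int
    n_cases: int
    n_controls: int


@dataclass
class CompositeDefinition:
    """Selected tests and their weights for one gene and mode."""

    gene: str
    mode: str  # "average" | "weighted"
    tests: list[str]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.mode not in ("average", "weighted"):
            raise ValueError(f"unknown composite mode {self.mode!r}")
        if not self.tests:
            raise CompositeError(f"{self.gene}: composite has no tests")
        w = np.array([self.weights[t] for t in self.tests])
        if (w <= 0).any():
            raise ValueError(f"{self.gene}: weights must be > 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.gene}: weights must sum to 1 (got {w.sum()})")

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "mode": self.mode,
            "tests": list(self.tests),
            "weights": {t: self.weights[t] for t in self.tests},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompositeDefinition":
        return cls(gene=d["gene"], mode=d["mode"], tests=list(d["tests"]), weights=dict(d["weights"]))


def _complete_cases(z: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    y = np.asarray(labels, dtype=float)
    if len(y) != len(z):
        raise FitError("labels length does not match z table")
    keep = z.notna().all(axis=1).to_numpy()
    X = z.to_numpy(dtype=float)[keep]
    return X, y[keep], z.index[keep]


def lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero (standardized X)."""
    n = len(y)
    return float(np.max(np.abs(X_std.T @ (y - y.mean()))) / n)


def _fit_l1(X_std: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Single L1 logistic fit at glmnet-scale penalty lam (standardized X)."""
    n = len(y)
    C = 1.0 / max(n * lam, 1e-12)
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=C,
        solver="liblinear",
        tol=1e-8,
        max_iter=5000,
        fit_intercept=True,
        random_state=0,  # liblinear permutes coordinates internally
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_std, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean binomial deviance (-2 * mean log-likelihood) of linear predictor eta."""
    # numerically stable: log(1+exp(eta)) - y*eta
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(-2.0 * ll.mean())


def default_lambda_grid(lmax: float, n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down ``decades`` decades."""
    return lmax * np.logspace(0.0, -decades, n_lambda)


def fit_penalized_logistic(
    z: pd.DataFrame,
    labels: Sequence[int] | np.ndarray | pd.Series,
    folds: int = 10,
    seed: int = 0,
    gene: str = "",
    n_lambda: int = 100,
    lambda_decades: float = 4.0,
    lambda_rule: str = "min",
) -> PenalizedFit:
    """Cross-validated LASSO logistic regression of carrier status on z-scores.

    Participants with any missing z are excluded (complete-case analysis).
    Predictors are standardized internally; coefficients are reported on the
    original z-score scale.

    Parameters
    ----------
    lambda_rule
        "min" (default): penalty minimizing mean CV binomial deviance;
        "1se": largest penalty within one standard error of that minimum.
    """
    if lambda_rule not in ("min", "1se"):
        raise FitError(f"unknown lambda_rule {lambda_rule!r}")
    X, y, _ = _complete_cases(z, labels)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases == 0 and n_controls == 0:
        raise FitError("empty complete-case set after excluding missing data")
    if n_cases < folds or n_controls < folds:
        raise FitError(
            f"need >= {folds} cases and controls after complete-case exclusion "
            f"(got {n_cases} cases, {n_controls} controls)"
        )
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if (sd <= 0).any():
        const = [z.columns[j] for j in np.flatnonzero(sd <= 0)]
        raise FitError(f"constant predictor column(s): {const}")
    Xs = (X - mu) / sd

    grid = default_lambda_grid(lambda_max(Xs, y), n_lambda, lambda_decades)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.empty((folds, len(grid)))
    for f, (tr, te) in enumerate(skf.split(Xs, y)):
        for k, lam in enumerate(grid):
            beta, b0 = _fit_l1(Xs[tr], y[tr], lam)
            dev[f, k] = _binomial_deviance(y[te], Xs[te] @ beta + b0)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    k_min = int(np.argmin(mean_dev))
    if lambda_rule == "1se":
        thresh = mean_dev[k_min] + se_dev[k_min]
        k_chosen = int(np.min(np.flatnonzero(mean_dev <= thresh)))  # grid descends
    else:
        k_chosen = k_min
    chosen = float(grid[k_chosen])

    beta_s, b0_s = _fit_l1(Xs, y, chosen)
    beta = beta_s / sd
    intercept = b0_s - float(beta_s @ (mu / sd))
    coefs = {
        col: (0.0 if abs(b) < ZERO_TOL else float(b)) for col, b in zip(z.columns, beta)
    }
    return PenalizedFit(
        gene=gene,
        coefficients=coefs,
        intercept=intercept,
        lambda_grid=grid,
        cv_deviance=mean_dev,
        cv_deviance_se=se_dev,
        chosen_lambda=chosen,
        fold_seed=seed,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def fit_at_lambda(
    z: pd.DataFrame, labels, lam: float, gene: str = ""
) -> dict[str, float]:
    """Full-data L1 logistic coefficients (z-score scale) at one penalty."""
    X, y, _ = _complete_cases(z, labels)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / sd
    beta_s, _ = _fit_l1(Xs, y, lam)
    beta = beta_s / sd
    return {col: (0.0 if abs(b) < ZERO_TOL else float(b)) for col, b in zip(z.columns, beta)}


def select_tests(fit: PenalizedFit, battery: TestBattery = DEFAULT_BATTERY) -> list[str]:
    """Tests with strictly negative coefficients, in battery order.

    Positive coefficients indicate better performance in carriers and are
    excluded; coefficients below the zero tolerance count as zero.
    """
    order = [t for t in battery.ids if t in fit.coefficients]
    extra = [t for t in fit.coefficients if t not in battery.ids]
    selected = [t for t in order + sorted(extra) if fit.coefficients[t] < -ZERO_TOL]
    if not selected:
        raise CompositeError(
            f"{fit.gene or 'fit'}: no tests with negative coefficients; composite is empty"
        )
    return selected


def derive_weights(fit: PenalizedFit, battery: TestBattery = DEFAULT_BATTERY) -> CompositeDefinition:
    """Weighted composite: weight_i = |coef_i| / sum_j |coef_j| over selected tests."""
    tests = select_tests(fit, battery)
    mags = np.array([abs(fit.coefficients[t]) for t in tests])
    w = mags / mags.sum()
    return CompositeDefinition(
        gene=fit.gene, mode="weighted", tests=tests, weights={t: float(x) for t, x in zip(tests, w)}
    )


def average_definition(fit: PenalizedFit, battery: TestBattery = DEFAULT_BATTERY) -> CompositeDefinition:
    """Unweighted-average composite over the selected tests."""
    tests = select_tests(fit, battery)
    w = 1.0 / len(tests)
    return CompositeDefinition(
        gene=fit.gene, mode="average", tests=tests, weights={t: w for t in tests}
    )


def weights_from_coefficients(
    coefficients: Mapping[str, float],
    gene: str = "",
    mode: str = "weighted",
    battery: TestBattery = DEFAULT_BATTERY,
) -> CompositeDefinition:
    """Apply the selection and weight rules to an externally supplied
    coefficient map (e.g. a published table)."""
    fit = PenalizedFit(
        gene=gene,
        coefficients=dict(coefficients),
        intercept=0.0,
        lambda_grid=np.array([]),
        cv_deviance=np.array([]),
        cv_deviance_se=np.array([]),
        chosen_lambda=np.nan,
        fold_seed=0,
        n_cases=0,
        n_controls=0,
    )
    return derive_weights(fit, battery) if mode == "weighted" else average_definition(fit, battery)


def compute_composite(
    z: pd.DataFrame, definition: CompositeDefinition, missing: str = "strict"
) -> pd.Series:
    """Per-participant composite: sum_i weight_i * z_i.

    missing="strict" (default): any missing included test gives a missing
    composite.  missing="renormalize": weights are renormalized over the
    tests available for that participant (flagged in the series name).
    """
    unknown = [t for t in definition.tests if t not in z.columns]
    if unknown:
        raise CompositeError(f"{definition.gene}: z table lacks required tests: {unknown}")
    if missing not in ("strict", "renormalize"):
        raise ValueError(f"unknown missing policy {missing!r}")
    sub = z[definition.tests]
    w = np.array([definition.weights[t] for t in definition.tests])
    vals = sub.to_numpy(dtype=float)
    mask = np.isnan(vals)
    if missing == "strict":
        out = vals @ w
        out[mask.any(axis=1)] = np.nan
    else:
        wt = np.where(mask, 0.0, w[None, :])
        denom = wt.sum(axis=1)
        out = np.where(denom > 0, np.nansum(vals * wt, axis=1) / denom, np.nan)
    name = f"{definition.gene}_{definition.mode}" + ("_renorm" if missing == "renormalize" else "")
    return pd.Series(out, index=z.index, name=name)


# ---------------------------------------------------------------------------
# Published (GENFI-Cog) coefficient fixture

def published_coefficients() -> pd.DataFrame:
    """Published per-gene coefficients/weights as a tidy frame
    (gene, test, coefficient, printed_weight, excluded)."""
    with resources.files("ftdcog.data").joinpath("published_coefficients.json").open() as fh:
        raw = json.load(fh)
    rows = [
        {"gene": gene, **entry} for gene, entries in raw["genes"].items() for entry in entries
    ]
    return pd.DataFrame(rows, columns=["gene", "test", "coefficient", "printed_weight", "excluded"])


def published_definitions(mode: str = "weighted") -> dict[str, CompositeDefinition]:
    """Composite definitions rebuilt from the published coefficient table."""
    table = published_coefficients()
    out: dict[str, CompositeDefinition] = {}
    for gene, grp in table.groupby("gene", sort=False):
        coefs = dict(zip(grp["test"], grp["coefficient"]))
        out[gene] = weights_from_coefficients(coefs, gene=gene, mode=mode)
    return out


def coefficient_table(
    fits: Mapping[str, PenalizedFit], battery: TestBattery = DEFAULT_BATTERY
) -> pd.DataFrame:
    """Tidy per-gene coefficient/weight table for fitted models (nonzero
    coefficients only; positive ones flagged as excluded)."""
    rows = []
    for gene, fit in fits.items():
        try:
            weights = derive_weights(fit, battery).weights
        except CompositeError:
            weights = {}
        for t in battery.ids:
            c = fit.coefficients.get(t, 0.0)
            if c == 0.0:
                continue
            rows.append(
                {
                    "gene": gene,
                    "test": t,
                    "coefficient": c,
                    "weight": weights.get(t, np.nan),
                    "excluded_positive": c > 0,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "test", "coefficient", "weight", "excluded_positive"])
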