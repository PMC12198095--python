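"""Internal-consistency (McDonald's omega) for the 11 learning items.

Omega is the one-factor reliability coefficient

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta)

computed from a standardized single-factor solution.  The factor model is
fitted by minimum-residual (ordinary least squares on the off-diagonal
correlations) factoring of the weighted Pearson correlation matrix of the
raw binary items, with analytic gradient.  A tetrachoric variant would
give higher loadings for binary items; the Pearson choice matches common
general-purpose omega implementations and is exposed as the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .survey_io import ITEMS, SurveyTable

logger = logging.getLogger(__name__)

HEYWOOD_FLOOR = 1e-6


@dataclass
class OmegaResult:
    omega: float
    loadings: np.ndarray
    uniquenesses: np.ndarray
    n_used: int
    converged: bool
    heywood: bool = False

    def __post_init__(self):
        if self.converged and np.isfinite(self.omega):
            lam, theta = self.loadings.sum(), self.uniquenesses.sum()
            assert abs(self.omega - lam ** 2 / (lam ** 2 + theta)) < 1e-10


@dataclass
class OmegaSummary:
    mean: float
    ci_low: float
    ci_high: float
    min: float
    max: float
    min_label: str
    max_label: str
    n: int
    ci_available: bool = True


def weighted_corr(items: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of complete-case item columns."""
    X = np.asarray(items, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mean = w @ X
    Xc = X - mean
    cov = (Xc * w[:, None]).T @ Xc
    sd = np.sqrt(np.diag(cov))
    if (sd == 0).any():
        zero = [i for i, s in enumerate(sd) if s == 0]
        raise ValueError(f"zero-variance item column(s) at index {zero}")
    return cov / np.outer(sd, sd)


def _minres_objective(lam: np.ndarray, R: np.ndarray):
    resid = R - np.outer(lam, lam)
    np.fill_diagonal(resid, 0.0)
    f = 0.5 * np.sum(resid ** 2)
    grad = -2.0 * resid @ lam
    return f, grad


def fit_one_factor(
    items: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Minimum-residual one-factor fit on the weighted correlation matrix.

    Returns ``(loadings, uniquenesses, converged, heywood)`` on the
    standardized scale.  Negative uniquenesses (Heywood cases) are
    truncated at a small floor and flagged.
    """
    X = np.asarray(items, dtype=float)
    n = len(X)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    R = weighted_corr(X, w)
    p = R.shape[0]

    # start from the first principal component scaled to unit communality
    eigval, eigvec = np.linalg.eigh(R)
    lam0 = eigvec[:, -1] * np.sqrt(max(eigval[-1], 0.0))
    if lam0.sum() < 0:
        lam0 = -lam0

    res = optimize.minimize(
        _minres_objective, lam0, args=(R,), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    lam = res.x
    if lam.sum() < 0:
        lam = -lam
    theta = 1.0 - lam ** 2
    heywood = bool((theta < 0).any())
    theta = np.maximum(theta, HEYWOOD_FLOOR)
    converged = bool(res.success or res.status == 0 or np.max(np.abs(res.jac)) < 1e-4)
    return lam, theta, converged, heywood


def mcdonalds_omega(items: np.ndarray, weights: np.ndarray | None = None) -> OmegaResult:
    """McDonald's omega from the standardized one-factor solution."""
    lam, theta, converged, heywood = fit_one_factor(items, weights)
    if not converged:
        return OmegaResult(np.nan, lam, theta, len(np.asarray(items)), False, heywood)
    s = lam.sum()
    omega = s ** 2 / (s ** 2 + theta.sum())
    return OmegaResult(float(omega), lam, theta, len(np.asarray(items)), True, heywood)


def omega_by_stratum(
    table: SurveyTable, stratifier: str, min_n: int = 100
) -> dict[str, OmegaResult]:
    """Omega computed separately per level of a categorical field.

    Rows with any missing item are dropped (complete-case); strata smaller
    than ``min_n`` complete cases are omitted with a log entry.
    """
    frame = table.children
    if stratifier not in frame.columns:
        raise KeyError(f"stratifier {stratifier!r} not in schema")
    out: dict[str, OmegaResult] = {}
    for level, sub in frame.groupby(stratifier, observed=True, dropna=True):
        complete = sub.dropna(subset=ITEMS)
        if len(complete) < min_n:
            logger.info("stratum %r omitted: %d < %d complete cases",
                        level, len(complete), min_n)
            continue
        out[str(level)] = mcdonalds_omega(
            complete[ITEMS].to_numpy(float), complete["child_weight"].to_numpy(float)
        )
    return out


def omega_by_country(table: SurveyTable, min_n: int = 100) -> dict[str, OmegaResult]:
    return omega_by_stratum(table, "country_code", min_n=min_n)


def summarize_omegas(values, labels=None) -> OmegaSummary:
    """Cross-survey summary: mean with a t-based 95% CI, labelled min/max."""
    v = np.asarray(values, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(len(v))]
    if len(v) == 0:
        raise ValueError("no omega values to summarize")
    mean = float(v.mean())
    imin, imax = int(np.argmin(v)), int(np.argmax(v))
    if len(v) >= 2:
        half = stats.t.ppf(0.975, len(v) - 1) * v.std(ddof=1) / np.sqrt(len(v))
        ci = (mean - half, mean + half)
        available = True
    else:
        ci = (np.nan, np.nan)
        available = False
    return OmegaSummary(
        mean=mean, ci_low=float(ci[0]), ci_high=float(ci[1]),
        min=float(v[imin]), max=float(v[imax]),
        min_label=str(labels[imin]), max_label=str(labels[imax]),
        n=len(v), ci_available=available,
    )
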