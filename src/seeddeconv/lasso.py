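"""L1-penalized estimation of per-seed-family effects.

The off-target model treats each pool's Z score as the sum of an on-target
component and additive contributions from the pool's seed families:

    Z = X beta + Y

with X the binary pool x family membership matrix, beta the family effect
sizes (Z-score units) and Y the residual on-target component.  beta is
estimated by the lasso in its *unscaled* form

    beta_hat = argmin ||Z - X beta||^2 + lambda * sum_j |beta_j|

Note the residual sum of squares is NOT divided by n and the penalty is the
plain L1 norm; the default ``lambda = 0.001`` is only meaningful under this
convention.  Solvers that use the (1/2n)*RSS convention (e.g. scikit-learn)
need ``alpha = lambda / (2n)`` to match.

The problem is solved by cyclic coordinate descent with exact
soft-threshold updates.  For a binary membership column j with member rows
M_j and partial residual r, the coordinate minimizer is

    beta_j = S(sum_{i in M_j} (r_i + beta_j), lambda/2) / |M_j|

where S(a, t) = sign(a) * max(|a| - t, 0).  Columns are visited in
lexicographic seed order, which makes the solution path deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NonFiniteInput
from .seedlib import MembershipMatrix

logger = logging.getLogger(__name__)


def soft_threshold(a: float, t: float) -> float:
    """sign(a) * max(|a| - t, 0)."""
    return np.sign(a) * max(abs(a) - t, 0.0)


@dataclass
class LassoFit:
    """Solution of the penalized family-effect model.

    ``residuals`` is Y = Z - X beta_hat, the corrected on-target component
    before any selection filtering.
    """

    seeds: list[str]
    beta: np.ndarray
    lambda_: float
    n_iter: int
    converged: bool
    residuals: np.ndarray
    pool_ids: list[str]

    @property
    def beta_series(self) -> pd.Series:
        return pd.Series(self.beta, index=self.seeds, name="beta")

    def objective(self, z: np.ndarray, X: MembershipMatrix) -> float:
        resid = z - X.matrix @ self.beta
        return float(resid @ resid + self.lambda_ * np.abs(self.beta).sum())


def fit_lasso(
    z,
    X: MembershipMatrix,
    lambda_: float = 0.001,
    *,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> LassoFit:
    """Cyclic coordinate descent for the unscaled lasso (no intercept,
    no standardization).

    Converged when the largest absolute coefficient change in a full sweep
    drops below ``tol`` (default 1e-6) or after ``max_iter`` sweeps; a
    non-converged fit is returned with ``converged=False`` and a warning.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise NonFiniteInput("z contains non-finite values")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    if z.shape != (n,):
        raise ValueError(f"z has shape {z.shape}, expected ({n},)")

    members = X.member_index_arrays()
    sizes = X.family_sizes().astype(float)
    beta = np.zeros(p)
    r = z.copy()  # residual z - X beta, maintained incrementally
    half_lam = lambda_ / 2.0

    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            m = members[j]
            if m.size == 0:
                continue
            a = r[m].sum() + sizes[j] * beta[j]
            new = soft_threshold(a, half_lam) / sizes[j]
            delta = new - beta[j]
            if delta != 0.0:
                r[m] -= delta
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_iter} sweeps",
            RuntimeWarning,
            stacklevel=2,
        )
    return LassoFit(
        seeds=list(X.seeds),
        beta=beta,
        lambda_=lambda_,
        n_iter=n_iter,
        converged=converged,
        residuals=r,
        pool_ids=list(X.pool_ids),
    )


def kkt_violation(fit: LassoFit, z, X: MembershipMatrix) -> float:
    """Largest violation of the lasso stationarity conditions.

    At an exact solution, g_j = 2 * x_j'(z - X beta_hat) satisfies
    |g_j| <= lambda where beta_j = 0 and g_j = lambda * sign(beta_j)
    otherwise.  Returns the max absolute slack (0 at an exact optimum).
    """
    z = np.asarray(z, dtype=float)
    g = 2.0 * (X.matrix.T @ (z - X.matrix @ fit.beta))
    viol = np.where(
        fit.beta == 0.0,
        np.maximum(np.abs(g) - fit.lambda_, 0.0),
        np.abs(g - fit.lambda_ * np.sign(fit.beta)),
    )
    # families with zero members carry no constraint
    viol[X.family_sizes() == 0] = 0.0
    return float(viol.max(initial=0.0))


def select_by_strength(fit: LassoFit, strength_cutoff: float = 1.0) -> set[str]:
    """Seeds whose |beta_hat| strictly exceeds the cutoff.

    A negative coefficient means the family lowers Z scores (e.g. a toxic
    off-target in a viability screen) and vice versa; the sign is kept in
    ``fit.beta``.
    """
    if strength_cutoff <= 0:
        raise ValueError("strength cutoff must be positive")
    mask = np.abs(fit.beta) > strength_cutoff
    return {fit.seeds[j] for j in np.nonzero(mask)[0]}


def correct_z(
    z,
    X: MembershipMatrix,
    fit: LassoFit,
    significant: set[str] | None = None,
    *,
    subtract_all: bool = False,
) -> np.ndarray:
    """Corrected Z scores: y_i = z_i - sum_{j in significant} x_ij beta_j.

    With ``subtract_all=True`` the full X beta_hat is removed (the model's
    unfiltered residual Y), regardless of ``significant``.
    """
    z = np.asarray(z, dtype=float)
    if subtract_all:
        return z - X.matrix @ fit.beta
    significant = significant or set()
    unknown = significant - set(fit.seeds)
    if unknown:
        raise ValueError(f"seeds not in fit: {sorted(unknown)[:5]}")
    beta = np.where(
        np.isin(np.asarray(fit.seeds, dtype=object), sorted(significant)),
        fit.beta,
        0.0,
    )
    return z - X.matrix @ beta
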