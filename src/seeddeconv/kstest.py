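"""Kolmogorov-Smirnov confirmation of seed-family effects.

A candidate family is confirmed when the empirical distribution of its
members' Z scores,

    F_Ns(z) = (1/Ns) * sum_i I[Z_i <= z],

differs from a comparison distribution F(z) by a large supremum gap

    D = sup_z | F_Ns(z) - F(z) |.

Two comparison modes are supported:

* ``two_sample`` (default): F is the ECDF of the non-member pools.
* ``vs_all``: F is the ECDF of the full screen population (members
  included), the one-sample form with the population standing in for the
  reference distribution.

Both ECDFs are right-continuous step functions, so the supremum is attained
at an observed value and is evaluated exactly on the pooled sample points.
P-values come from the asymptotic Kolmogorov distribution at
sqrt(n1*n2/(n1+n2)) * D.
"""

from __future__ import annotations

import numpy as np
from scipy.special import kolmogorov

from .errors import DegenerateSplit, NonFiniteInput

_P_FLOOR = 1e-300  # keep p in (0, 1]


def ks_pvalue(d: float, n1: int, n2: int) -> float:
    """Asymptotic two-sample KS p-value at effective size n1*n2/(n1+n2)."""
    en = n1 * n2 / (n1 + n2)
    p = float(kolmogorov(np.sqrt(en) * d))
    return min(max(p, _P_FLOOR), 1.0)


def _ecdf_gap(sample1: np.ndarray, sample2: np.ndarray) -> float:
    """Exact sup_z |ECDF1 - ECDF2| for two sorted samples."""
    grid = np.concatenate([sample1, sample2])
    f1 = np.searchsorted(sample1, grid, side="right") / sample1.size
    f2 = np.searchsorted(sample2, grid, side="right") / sample2.size
    return float(np.abs(f1 - f2).max())


def ks_family_test(z, members, mode: str = "two_sample") -> tuple[float, float]:
    """KS statistic D and asymptotic p-value for one seed family.

    Parameters
    ----------
    z : array-like
        Z scores of all pools (the *original* screen scores, not residuals).
    members : array-like
        Integer row indices or a boolean mask selecting the family's pools;
        must be a proper nonempty subset of the screen.
    mode : {"two_sample", "vs_all"}
        Comparison population (see module docstring).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise NonFiniteInput("z contains non-finite values")
    members = np.asarray(members)
    mask = np.zeros(z.size, dtype=bool)
    if members.dtype == bool:
        if members.size != z.size:
            raise ValueError("boolean mask length mismatch")
        mask = members
    elif members.size:
        mask[members.astype(np.intp)] = True
    n1 = int(mask.sum())
    if n1 == 0 or n1 == z.size:
        raise DegenerateSplit(f"family has {n1} of {z.size} pools")

    fam = np.sort(z[mask])
    if mode == "two_sample":
        other = np.sort(z[~mask])
    elif mode == "vs_all":
        other = np.sort(z)
    else:
        raise ValueError(f"mode must be 'two_sample' or 'vs_all', got {mode!r}")
    d = _ecdf_gap(fam, other)
    return d, ks_pvalue(d, n1, other.size)
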