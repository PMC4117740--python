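import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

import seeddeconv as sd
from seeddeconv.seedlib import SeedFamilyIndex, build_membership_matrix

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


def make_membership(assignments: dict, pool_order):
    """Membership matrix from an explicit seed -> member pools mapping."""
    index = SeedFamilyIndex(
        seed_start=2, families={s: set(m) for s, m in assignments.items()}
    )
    return build_membership_matrix(index, pool_order)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated screen: 600 pools, one injected family of 15."""
    cfg = sd.SimulationConfig(
        rng_seed=11,
        n_genes=600,
        n_offtarget_families=1,
        beta_true=(-3.0,),
        family_sizes=(15,),
        frac_ontarget_genes=0.0,
    )
    return sd.simulate_screen(cfg)


@pytest.fixture(scope="session")
def small_screen_z(small_sim):
    """The small screen normalized to Z scores (normal-scale MAD)."""
    table = sd.robust_z_by_batch(small_sim.screen, scale="normal")
    return table[table["z"].notna()].reset_index(drop=True)


def grid_minimize_lasso(z, X_dense, lam, n_pass=6, grid=21):
    """Independent dense-grid minimizer of ||z - Xb||^2 + lam*sum|b|.

    Iteratively refines a per-coordinate grid around the incumbent optimum;
    precision after 6 passes is ~1e-5 on ranges of a few units.  Only
    practical for <= 3 coefficients — which is the point: it shares nothing
    with the coordinate-descent solver it checks.
    """
    import itertools

    p = X_dense.shape[1]
    span = np.abs(z).max() + 1.0
    lo = np.full(p, -span)
    hi = np.full(p, span)
    best_pt = np.zeros(p)
    for _ in range(n_pass):
        axes = [np.linspace(lo[j], hi[j], grid) for j in range(p)]
        best_val = np.inf
        for pt in itertools.product(*axes):
            b = np.asarray(pt)
            val = ((z - X_dense @ b) ** 2).sum() + lam * np.abs(b).sum()
            if val < best_val:
                best_val, best_pt = val, b
        step = (hi - lo) / (grid - 1)
        lo, hi = best_pt - step, best_pt + step
    return best_pt


def brute_force_ks_d(sample1, sample2):
    """O(n^2) supremum of |ECDF1 - ECDF2| over every observed point."""
    x = np.asarray(sample1, float)
    y = np.asarray(sample2, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        gap = abs((x <= t).mean() - (y <= t).mean())
        best = max(best, gap)
    return best
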