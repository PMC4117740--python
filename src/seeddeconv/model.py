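"""The screen deconvolution model and its results object.

:class:`ScreenDeconvolution` bundles a screen's Z scores with the seed-family
membership matrix; :meth:`ScreenDeconvolution.fit` runs the full pipeline —
lasso estimation of family effects, effect-size selection (|beta| > strength
cutoff), KS confirmation of the selected families, and subtraction of the
confirmed effects from each member pool's Z score — and returns a
:class:`DeconvolutionResults` carrying the per-family diagnostics, the
corrected scores and a text ``summary()``.

Typical use::

    from seeddeconv import ScreenDeconvolution

    model = ScreenDeconvolution.from_screen(screen_df, oligos=oligos)
    res = model.fit()                 # lambda=0.001, strength=1, p<0.05
    print(res.summary())
    res.pool_table()                  # corrected Z per pool
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSplit, EmptyTable, MissingColumn
from .kstest import ks_family_test
from .lasso import LassoFit, correct_z, fit_lasso, select_by_strength
from .screen_io import robust_z_by_batch
from .seedlib import MembershipMatrix, build_family_index, build_membership_matrix


@dataclass
class FamilyTestResult:
    """Diagnostics for one seed family."""

    seed: str
    beta: float
    n_members: int
    ks_D: float
    p_value: float
    selected_by_strength: bool
    significant: bool


class ScreenDeconvolution:
    """Off-target deconvolution model for one RNAi screen.

    Parameters
    ----------
    z : array-like
        Per-pool Z scores, aligned with ``membership`` rows.
    membership : MembershipMatrix
        Binary pool x seed-family design matrix.
    gene_ids : sequence of str, optional
        Per-pool gene identifiers, carried through to outputs.
    """

    def __init__(self, z, membership: MembershipMatrix, gene_ids=None):
        self.z = np.asarray(z, dtype=float)
        self.membership = membership
        if self.z.shape[0] != membership.shape[0]:
            raise ValueError("z and membership row counts differ")
        self.pool_ids = list(membership.pool_ids)
        self.gene_ids = list(gene_ids) if gene_ids is not None else [""] * len(self.pool_ids)
        if len(self.gene_ids) != len(self.pool_ids):
            raise ValueError("gene_ids length mismatch")

    @classmethod
    def from_screen(
        cls,
        screen: pd.DataFrame,
        *,
        oligos=None,
        membership: MembershipMatrix | None = None,
        seed_start: int = 2,
        mad_scale: str = "raw",
    ) -> "ScreenDeconvolution":
        """Build the model from a screen table plus library annotation.

        Uses the table's ``z`` column when present (precomputed scores are
        consumed as supplied); otherwise computes batch-aware robust Z from
        ``response``.  Membership comes either ready-made or from ``oligos``
        at the given seed window.
        """
        if "pool_id" not in screen.columns:
            raise MissingColumn("screen table needs a pool_id column")
        if "z" in screen.columns and screen["z"].notna().all():
            table = screen
        elif "response" in screen.columns:
            table = robust_z_by_batch(screen, scale=mad_scale)
            table = table[table["z"].notna()].reset_index(drop=True)
        else:
            raise MissingColumn("screen table needs a z or response column")
        if table.empty:
            raise EmptyTable("no scored pools")

        pool_order = table["pool_id"].astype(str).tolist()
        if membership is None:
            if oligos is None:
                raise ValueError("supply either oligos or a membership matrix")
            index = build_family_index(oligos, seed_start=seed_start)
            membership = build_membership_matrix(index, pool_order)
        elif list(membership.pool_ids) != pool_order:
            raise ValueError("membership rows must follow the screen table order")
        gene_ids = (
            table["gene_id"].astype(str).tolist() if "gene_id" in table.columns else None
        )
        return cls(table["z"].to_numpy(dtype=float), membership, gene_ids=gene_ids)

    def fit(
        self,
        lambda_: float = 0.001,
        strength: float = 1.0,
        significance: float = 0.05,
        *,
        ks_mode: str = "two_sample",
        test_all_families: bool = False,
        correct_all: bool = False,
        min_ks_family_size: int = 2,
        tol: float = 1e-6,
        max_iter: int = 1000,
    ) -> "DeconvolutionResults":
        """Run the deconvolution pipeline.

        Defaults are the tool's standard operating point: penalty
        ``lambda_=0.001`` (unscaled objective), effect-size cutoff
        ``|beta| > 1`` and KS significance ``p < 0.05``.  Families smaller
        than ``min_ks_family_size`` stay in the lasso but are never
        KS-tested (their ECDF is degenerate) and hence never confirmed.
        With ``correct_all=True`` the correction subtracts the full
        ``X beta_hat`` instead of only the confirmed families.
        """
        if strength <= 0:
            raise ValueError("strength cutoff must be positive")
        if not 0 < significance <= 1:
            raise ValueError("significance must be in (0, 1]")
        fit = fit_lasso(self.z, self.membership, lambda_, tol=tol, max_iter=max_iter)
        selected = select_by_strength(fit, strength)

        sizes = self.membership.family_sizes()
        families: list[FamilyTestResult] = []
        for j, seed in enumerate(fit.seeds):
            is_selected = seed in selected
            d = p = np.nan
            if (is_selected or test_all_families) and sizes[j] >= min_ks_family_size:
                try:
                    d, p = ks_family_test(
                        self.z, self.membership.column_members(j), mode=ks_mode
                    )
                except DegenerateSplit:
                    pass
            families.append(
                FamilyTestResult(
                    seed=seed,
                    beta=float(fit.beta[j]),
                    n_members=int(sizes[j]),
                    ks_D=d,
                    p_value=p,
                    selected_by_strength=is_selected,
                    significant=bool(is_selected and np.isfinite(p) and p < significance),
                )
            )
        significant = {f.seed for f in families if f.significant}
        corrected = correct_z(
            self.z, self.membership, fit, significant, subtract_all=correct_all
        )
        params = {
            "lambda": lambda_,
            "strength_cutoff": strength,
            "significance_cutoff": significance,
            "ks_mode": ks_mode,
            "min_ks_family_size": min_ks_family_size,
            "correct_all": correct_all,
        }
        return DeconvolutionResults(
            model=self,
            lasso_fit=fit,
            families=families,
            corrected=corrected,
            params=params,
        )


@dataclass
class DeconvolutionResults:
    """Fitted family effects, confirmation tests and corrected Z scores."""

    model: ScreenDeconvolution
    lasso_fit: LassoFit
    families: list[FamilyTestResult]
    corrected: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def significant_seeds(self) -> set[str]:
        return {f.seed for f in self.families if f.significant}

    @property
    def selected_seeds(self) -> set[str]:
        return {f.seed for f in self.families if f.selected_by_strength}

    @property
    def corrected_z(self) -> pd.Series:
        return pd.Series(self.corrected, index=self.model.pool_ids, name="z_corrected")

    @property
    def offtarget_pools(self) -> dict[str, list[str]]:
        """Member pools of each confirmed off-target family."""
        out: dict[str, list[str]] = {}
        seed_to_col = {s: j for j, s in enumerate(self.model.membership.seeds)}
        for seed in sorted(self.significant_seeds):
            rows = self.model.membership.column_members(seed_to_col[seed])
            out[seed] = [self.model.pool_ids[i] for i in rows]
        return out

    def family_table(self) -> pd.DataFrame:
        """Per-family results with a BH-adjusted p column over the tested set."""
        df = pd.DataFrame(
            {
                "seed": [f.seed for f in self.families],
                "beta": [f.beta for f in self.families],
                "ks_D": [f.ks_D for f in self.families],
                "p_value": [f.p_value for f in self.families],
                "n_pools": [f.n_members for f in self.families],
                "selected": [f.selected_by_strength for f in self.families],
                "significant": [f.significant for f in self.families],
            }
        )
        df["p_adjusted_bh"] = np.nan
        tested = df["p_value"].notna()
        if tested.any():
            df.loc[tested, "p_adjusted_bh"] = multipletests(
                df.loc[tested, "p_value"], method="fdr_bh"
            )[1]
        return df[
            ["seed", "beta", "ks_D", "p_value", "p_adjusted_bh", "n_pools",
             "selected", "significant"]
        ]

    def pool_table(self) -> pd.DataFrame:
        """Per-pool original and corrected Z with the confirmed seeds hit."""
        seeds_per_pool: dict[str, list[str]] = {p: [] for p in self.model.pool_ids}
        for seed, pools in self.offtarget_pools.items():
            for p in pools:
                seeds_per_pool[p].append(seed)
        return pd.DataFrame(
            {
                "pool_id": self.model.pool_ids,
                "gene_id": self.model.gene_ids,
                "z_original": self.model.z,
                "z_corrected": self.corrected,
                "offtarget_seeds": [
                    ";".join(sorted(seeds_per_pool[p])) for p in self.model.pool_ids
                ],
            }
        )

    def volcano_frame(self) -> pd.DataFrame:
        """(beta, -log10 p) per tested family — effect strength vs significance."""
        df = self.family_table()
        df = df[df["p_value"].notna()].copy()
        df["neg_log10_p"] = -np.log10(df["p_value"])
        return df[["seed", "beta", "neg_log10_p", "n_pools", "significant"]]

    def plot_volcano(self, ax=None):
        """Scatter of family effect size against KS significance."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.volcano_frame()
        colors = np.where(df["significant"], "crimson", "grey")
        ax.scatter(df["beta"], df["neg_log10_p"], s=12, c=colors, alpha=0.7)
        ax.axvline(self.params.get("strength_cutoff", 1.0), ls="--", lw=0.8, c="k")
        ax.axvline(-self.params.get("strength_cutoff", 1.0), ls="--", lw=0.8, c="k")
        ax.set_xlabel("estimated seed-family effect (Z units)")
        ax.set_ylabel("-log10 KS p-value")
        return ax

    def summary(self) -> str:
        """Plain-text overview in the style of a regression results table."""
        buf = io.StringIO()
        n, p = self.model.membership.shape
        w = 58
        buf.write("Seed-family off-target deconvolution\n")
        buf.write("=" * w + "\n")
        rows = [
            ("pools (n)", n),
            ("seed families (p)", p),
            ("lambda", self.params.get("lambda")),
            ("strength cutoff (|beta| >)", self.params.get("strength_cutoff")),
            ("significance cutoff (p <)", self.params.get("significance_cutoff")),
            ("KS mode", self.params.get("ks_mode")),
            ("solver sweeps", self.lasso_fit.n_iter),
            ("converged", self.lasso_fit.converged),
            ("families selected by strength", len(self.selected_seeds)),
            ("families confirmed by KS", len(self.significant_seeds)),
            ("pools in confirmed families",
             sum(len(v) for v in self.offtarget_pools.values())),
        ]
        for name, val in rows:
            buf.write(f"{name:<38}{val!s:>20}\n")
        buf.write("-" * w + "\n")
        sig = [f for f in self.families if f.significant]
        if sig:
            buf.write(f"{'seed':<10}{'beta':>10}{'ks_D':>10}{'p':>12}{'pools':>8}\n")
            for f in sorted(sig, key=lambda f: f.p_value):
                buf.write(
                    f"{f.seed:<10}{f.beta:>10.3f}{f.ks_D:>10.3f}"
                    f"{f.p_value:>12.3g}{f.n_members:>8d}\n"
                )
        else:
            buf.write("no confirmed off-target families\n")
        buf.write("=" * w + "\n")
        return buf.getvalue()

    def to_csv_dir(self, outdir) -> dict[str, str]:
        """Write the three standard outputs; returns {name: path}."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, df in (
            ("families", self.family_table()),
            ("pools", self.pool_table()),
            ("volcano", self.volcano_frame()),
        ):
            path = os.path.join(outdir, f"{name}.csv")
            df.to_csv(path, index=False, float_format="%.9g")
            paths[name] = path
        return paths


def deconvolve(
    screen: pd.DataFrame,
    *,
    oligos=None,
    membership: MembershipMatrix | None = None,
    seed_start: int = 2,
    mad_scale: str = "raw",
    **fit_kwargs,
) -> DeconvolutionResults:
    """One-shot pipeline: build :class:`ScreenDeconvolution` and fit it."""
    model = ScreenDeconvolution.from_screen(
        screen,
        oligos=oligos,
        membership=membership,
        seed_start=seed_start,
        mad_scale=mad_scale,
    )
    return model.fit(**fit_kwargs)
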