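"""Synthetic genome-wide RNAi screens with known ground truth.

The generator emulates the data model of an arrayed one-gene/one-well
siRNA screen: each gene is targeted by a pool of (by default) four
independent 19-mer guide oligos; a minority of seed families carry additive
phenotype shifts (the off-target signal to be recovered); a fraction of
genes carry genuine on-target effects; measurements acquire batch-level
shifts and Gaussian noise:

    raw_i = batch_shift(b_i) + ontarget(gene_i) + sum_j x_ij * beta_true_j + eps_i

with eps_i ~ Normal(0, noise_sd).  Injected family seeds are written into
exactly one oligo of each designated member pool at ``inject_window_start``
and scrubbed from every other oligo, so realized family sizes match the
configuration exactly and the truth table is exact.

Commercial libraries use far fewer distinct seeds than the 4096 possible
(design constraints concentrate seed usage: a genome-wide collection shows
roughly one seed family per ten pools, with a strongly skewed family-size
distribution).  The generator reproduces this by drawing each oligo's seed
window from a library *vocabulary* of ``n_library_seeds`` distinct 6-mers
(default ``n_genes // 10``) with lognormal usage weights; the remaining
19-mer positions are uniform random bases.  This keeps the simulated
design matrix in the n >> p regime of real screens.

Raw values (not Z scores) are emitted, so batch normalization is exercised
by downstream analysis.  All randomness flows from ``rng_seed``; identical
configurations reproduce identical screens byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigInvalid, MissingTruth
from .seedlib import SEED_LENGTH, OligoRecord

_BASES = np.array(list("ACGU"))
OLIGO_LENGTH = 19


@dataclass
class SimulationConfig:
    """Study conditions for one simulated screen.

    ``beta_true`` and ``family_sizes`` have one entry per injected
    off-target family (effects in raw phenotype units; with unit noise SD
    and normal-scaled robust Z they are recovered on their own scale).
    ``rng_seed`` is mandatory — there is no implicit seeding.
    """

    rng_seed: int
    n_genes: int = 2000
    oligos_per_pool: int = 4
    n_offtarget_families: int = 3
    beta_true: tuple = (-3.0, -3.0, -3.0)
    family_sizes: tuple = (30, 30, 30)
    frac_ontarget_genes: float = 0.05
    ontarget_effect_dist: tuple = (-2.0, 0.5)  # (mean, sd)
    noise_sd: float = 1.0
    n_batches: int = 4
    batch_shift_sd: float = 0.25
    seed_alphabet_bias: tuple | None = None  # per-base frequencies (A,C,G,U)
    inject_window_start: int = 2
    library_window_start: int = 2
    n_library_seeds: int | None = None  # default: n_genes // 10, min 20
    # lognormal skew of seed usage; 0.94 reproduces the mean/median family
    # size ratio (~42/27) of a genome-wide commercial siRNA library
    seed_usage_sigma: float = 0.94
    # clipping of usage weights, in sigmas around the median (None = none).
    # The floor drops the sparse tail of 2-7-pool families — a genome-scale
    # phenomenon a few-thousand-pool simulation cannot support family-level
    # inference on; the cap keeps any single family below ~10% of the
    # screen, as in real libraries where the largest families hold 1-2%.
    seed_usage_floor_sigma: float | None = 1.0
    seed_usage_cap_sigma: float | None = 2.0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.oligos_per_pool <= 0 or self.n_batches <= 0:
            raise ConfigInvalid("counts must be positive")
        if not 0 <= self.frac_ontarget_genes <= 1:
            raise ConfigInvalid("frac_ontarget_genes must be in [0, 1]")
        if self.n_offtarget_families != len(self.beta_true) or (
            self.n_offtarget_families != len(self.family_sizes)
        ):
            raise ConfigInvalid(
                "beta_true and family_sizes need one entry per injected family"
            )
        if any(s <= 0 for s in self.family_sizes):
            raise ConfigInvalid("family sizes must be positive")
        if sum(self.family_sizes) > self.n_genes:
            raise ConfigInvalid("injected families exceed the pool count")
        if not 1 <= self.inject_window_start <= 14:
            raise ConfigInvalid("inject_window_start must be in 1..14")
        if not 1 <= self.library_window_start <= 14:
            raise ConfigInvalid("library_window_start must be in 1..14")
        if self.n_library_seeds is not None and self.n_library_seeds <= 0:
            raise ConfigInvalid("n_library_seeds must be positive")
        if self.seed_usage_sigma < 0:
            raise ConfigInvalid("seed_usage_sigma must be >= 0")
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise ConfigInvalid("noise SDs must be >= 0")
        if self.seed_alphabet_bias is not None:
            p = np.asarray(self.seed_alphabet_bias, dtype=float)
            if p.shape != (4,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ConfigInvalid("seed_alphabet_bias must be 4 frequencies summing to 1")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated screen."""

    families: pd.DataFrame      # seed, beta_true, n_pools
    family_members: dict        # seed -> list of pool_ids
    ontarget: pd.DataFrame      # gene_id, effect (every gene; 0 if unaffected)
    batch_shifts: dict          # batch label -> shift


@dataclass
class SimulatedScreen:
    config: SimulationConfig
    oligos: list = field(default_factory=list)
    screen: pd.DataFrame = None
    truth: SimulationTruth = None


def _random_windows(rng, n: int, bias) -> np.ndarray:
    p = None if bias is None else np.asarray(bias, dtype=float)
    return rng.choice(4, size=(n, SEED_LENGTH), p=p)


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate oligos, raw phenotypes and truth tables for one screen."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_genes
    k = config.oligos_per_pool
    bias = config.seed_alphabet_bias

    pool_ids = [f"POOL{i:05d}" for i in range(n)]
    gene_ids = [f"GENE{i:05d}" for i in range(n)]

    # base-4 codes for every oligo; letters materialized at the end
    codes = rng.choice(4, size=(n, k, OLIGO_LENGTH), p=None if bias is None else np.asarray(bias))

    # distinct 6-mers for the injected families and the library vocabulary
    n_off = config.n_offtarget_families
    vocab_size = config.n_library_seeds or max(20, n // 10)
    distinct = rng.choice(4**SEED_LENGTH, size=vocab_size + n_off, replace=False)

    def _int_to_code(v: int) -> list[int]:
        return [(v // 4 ** (SEED_LENGTH - 1 - i)) % 4 for i in range(SEED_LENGTH)]

    injected_codes = [tuple(_int_to_code(v)) for v in distinct[:n_off]]
    injected_set = set(injected_codes)
    vocab_codes = np.array([_int_to_code(v) for v in distinct[n_off:]])

    # skewed seed usage: every oligo's library window carries a vocabulary
    # seed drawn with (floored) lognormal weights
    log_w = rng.normal(0.0, config.seed_usage_sigma, size=vocab_size)
    lo = (None if config.seed_usage_floor_sigma is None
          else -config.seed_usage_floor_sigma * config.seed_usage_sigma)
    hi = (None if config.seed_usage_cap_sigma is None
          else config.seed_usage_cap_sigma * config.seed_usage_sigma)
    weights = np.exp(np.clip(log_w, lo, hi))
    weights /= weights.sum()
    lw0 = config.library_window_start - 1
    usage = rng.choice(vocab_size, size=(n, k), p=weights)
    codes[:, :, lw0 : lw0 + SEED_LENGTH] = vocab_codes[usage]

    # designated member pools, disjoint across families
    all_members = rng.choice(n, size=sum(config.family_sizes), replace=False)
    member_lists: list[np.ndarray] = []
    offset = 0
    for size in config.family_sizes:
        member_lists.append(np.sort(all_members[offset : offset + size]))
        offset += size

    # write each injected seed into oligo 0 of its member pools
    w0 = config.inject_window_start - 1
    for fam, rows in zip(injected_codes, member_lists):
        codes[rows, 0, w0 : w0 + SEED_LENGTH] = np.asarray(fam)

    # realized family sizes must be exact: the vocabulary excludes injected
    # seeds, so collisions can only arise when injecting at a decoy window;
    # resample any accidental carrier there
    if w0 != lw0:
        designated = {(r, 0) for rows in member_lists for r in rows}
        windows = codes[:, :, w0 : w0 + SEED_LENGTH]
        for i in range(n):
            for j in range(k):
                if (i, j) in designated:
                    continue
                while tuple(windows[i, j]) in injected_set:
                    codes[i, j, w0 : w0 + SEED_LENGTH] = _random_windows(rng, 1, bias)[0]

    oligos = [
        OligoRecord(
            pool_id=pool_ids[i],
            gene_id=gene_ids[i],
            sequence="".join(_BASES[codes[i, j]]),
        )
        for i in range(n)
        for j in range(k)
    ]

    # on-target effects: drawn once per affected gene, shared by the pool
    n_on = int(round(config.frac_ontarget_genes * n))
    ontarget = np.zeros(n)
    on_rows = np.sort(rng.choice(n, size=n_on, replace=False)) if n_on else np.array([], int)
    if n_on:
        mean, sd = config.ontarget_effect_dist
        ontarget[on_rows] = rng.normal(mean, sd, size=n_on)

    # contiguous batches (plate blocks) with shared shifts
    batch_idx = np.minimum(
        (np.arange(n) * config.n_batches) // n, config.n_batches - 1
    )
    batch_labels = [f"B{b + 1}" for b in batch_idx]
    shifts = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches)

    offtarget = np.zeros(n)
    for beta, rows in zip(config.beta_true, member_lists):
        offtarget[rows] += beta

    raw = (
        shifts[batch_idx]
        + ontarget
        + offtarget
        + rng.normal(0.0, config.noise_sd, size=n)
    )

    screen = pd.DataFrame(
        {
            "pool_id": pool_ids,
            "gene_id": gene_ids,
            "response": raw,
            "batch": batch_labels,
        }
    )
    seeds = ["".join(_BASES[list(c)]) for c in injected_codes]
    truth = SimulationTruth(
        families=pd.DataFrame(
            {
                "seed": seeds,
                "beta_true": list(config.beta_true),
                "n_pools": list(config.family_sizes),
            }
        ),
        family_members={
            seed: [pool_ids[i] for i in rows]
            for seed, rows in zip(seeds, member_lists)
        },
        ontarget=pd.DataFrame({"gene_id": gene_ids, "effect": ontarget}),
        batch_shifts={f"B{b + 1}": float(shifts[b]) for b in range(config.n_batches)},
    )
    return SimulatedScreen(config=config, oligos=oligos, screen=screen, truth=truth)


def retest_truth(
    sim: SimulatedScreen, *, direction: str = "negative"
) -> dict[str, bool]:
    """Per-pool confirmation labels mimicking an individual-oligo retest.

    A pool is a *true* hit when its gene carries a genuine on-target effect
    in the phenotype direction of interest; pools whose score comes only
    from seed effects or noise do not reconfirm.
    """
    sign = -1.0 if direction == "negative" else 1.0
    effects = sim.truth.ontarget["effect"].to_numpy()
    return {
        pool: bool(sign * effects[i] > 0)
        for i, pool in enumerate(sim.screen["pool_id"])
    }


def evaluate_fpr(
    result,
    retest_truth: dict[str, bool],
    top_k: int,
    *,
    use_corrected: bool = True,
    direction: str = "negative",
) -> float:
    """False-positive rate among the top-k pools of a hit ranking.

    Pools are ranked by corrected (default) or original Z, most extreme
    first in ``direction``; the FPR is the fraction of the top k whose
    retest truth is False.
    """
    scores = result.corrected_z if use_corrected else pd.Series(
        result.model.z, index=result.model.pool_ids
    )
    ranked = scores.sort_values(ascending=(direction == "negative"))
    top = ranked.index[:top_k]
    missing = [p for p in top if p not in retest_truth]
    if missing:
        raise MissingTruth(f"no retest truth for {missing[:5]}")
    confirmed = np.array([retest_truth[p] for p in top])
    return float(1.0 - confirmed.mean())


def write_simulated(sim: SimulatedScreen, outdir) -> dict[str, str]:
    """Write library, screen and truth CSVs in the package's standard formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    lib = pd.DataFrame(
        {
            "pool_id": [o.pool_id for o in sim.oligos],
            "gene_id": [o.gene_id for o in sim.oligos],
            "oligo_seq": [o.sequence for o in sim.oligos],
        }
    )
    paths["library"] = str(out / "library.csv")
    lib.to_csv(paths["library"], index=False)

    paths["screen"] = str(out / "screen.csv")
    sim.screen.to_csv(paths["screen"], index=False, float_format="%.9g")

    paths["truth_families"] = str(out / "truth_families.csv")
    sim.truth.families.to_csv(paths["truth_families"], index=False, float_format="%.9g")

    paths["truth_ontarget"] = str(out / "truth_ontarget.csv")
    sim.truth.ontarget.to_csv(paths["truth_ontarget"], index=False, float_format="%.9g")
    return paths
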