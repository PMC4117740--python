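# Methods

## Model and procedure

A pooled arrayed RNAi screen yields one quantitative phenotype per siRNA
pool. seeddeconv decomposes these scores into gene-level on-target effects
and seed-family off-target effects with the linear model

    Z = Xβ + Y ,

where `Z` is the vector of per-pool robust Z scores, `X` the binary
pool × seed-family membership matrix, `β` the per-family off-target effect
sizes (Z-score units) and `Y` the residual on-target component. The
pipeline is:

1. **Normalization** (`screen_io`). Raw phenotypes are converted to robust
   Z scores within experimental batches: `Z = (x − median)/MAD` with the
   *raw* median absolute deviation `MAD = medianᵢ|xᵢ − median|`. Tables
   that already carry Z scores (reporter screens, ANOVA-derived scores)
   are consumed as supplied and never recomputed.
2. **Annotation** (`seedlib`). Each oligo's seed is the 6-mer at guide
   positions `seed_start … seed_start+5` (1-based, 5′→3′), default 2–7.
   Sense-strand library files are reverse-complemented via an explicit
   per-file strand declaration; there is no auto-detection. A pool belongs
   to a family if any of its oligos carries the seed — membership is an
   indicator, so duplicated seeds inside a pool count once.
3. **Estimation** (`lasso`). `β̂ = argmin ‖Z − Xβ‖² + λ‖β‖₁` in the
   *unscaled* penalty convention; the default `λ = 0.001` is only
   meaningful in this convention (solvers using `(1/2n)·RSS` need
   `α = λ/2n`). Cyclic coordinate descent with exact soft-threshold
   updates, no intercept, no column standardization (Z is centered by
   construction and X is binary). Update order is lexicographic in the
   seed string; convergence when the largest coefficient change in a sweep
   falls below 1e-6, capped at 1000 sweeps (a non-converged fit is
   returned flagged, with a warning). These choices make fits
   deterministic across platforms and row orderings.
4. **Selection and confirmation** (`model`). Families with `|β̂|` strictly
   greater than the strength cutoff (default 1, in Z units) are candidate
   off-target families. Each candidate of size ≥ 2 is tested by a
   two-sample Kolmogorov–Smirnov comparison of its members' *original* Z
   scores against the non-members (`vs_all` mode compares against the
   pooled population ECDF instead). ECDFs are right-continuous step
   functions and the supremum gap D is evaluated exactly over the observed
   points; p-values use the asymptotic Kolmogorov distribution at
   `√(n₁n₂/(n₁+n₂))·D`, floored at 1e-300 so p ∈ (0, 1]. Families are
   *significant* when selected by strength **and** `p <` the significance
   cutoff (default 0.05). No multiple-testing correction is applied in the
   main pipeline; a BH-adjusted column is emitted for user discretion.
5. **Correction**. `yᵢ = zᵢ − Σ_{j significant} x_ij β̂_j`. Pools in no
   significant family keep their original score exactly; an option
   subtracts the full `Xβ̂` (the model's unfiltered residual). Subtracting
   only confirmed families avoids injecting noise from the many near-zero
   coefficients.
6. **Window scan** (`seedscan`). To verify which 6-mer window carries the
   phenotype association, families are rebuilt at every window start 1–14
   and every family of size ≥ 2 is KS-tested; Benjamini–Hochberg
   adjustment is applied within each window and families with `q < FDR`
   (default 5%) are counted. The scan reports family size beside q because
   the KS test's sensitivity grows with family size; no size correction is
   applied in the scan — the penalized regression is the defense against
   size-driven hits.
7. **miRNA matching** (`mirna`). Detected seeds are matched by exact
   string equality to the seeds (mature positions 2–7) of a user-supplied
   miRNA table (miRBase-style FASTA or name/sequence CSV). The miRNA seed
   window is anchored at mature position 2 regardless of the screen's
   window, with an option to mirror the screen window. No miRNA database
   is bundled.

## Parameters

| parameter | default | units / range | role |
|---|---|---|---|
| `lambda_` | 0.001 | unscaled-penalty units | L1 penalty; near-least-squares at screen scale, the method's standard operating point |
| `strength` | 1.0 | Z-score units, > 0 | minimum `|β̂|` for a candidate family |
| `significance` | 0.05 | p-value | KS confirmation cutoff |
| `seed_start` | 2 | 1–14 | seed window start on the guide strand |
| `mad_scale` | `"raw"` | `raw`/`normal` | raw MAD per the defining formula; `normal` multiplies by 1.4826 for normal-consistent scale |
| `min_ks_family_size` | 2 | pools | below this the ECDF is degenerate; such families stay in the lasso but are never confirmed |

## The synthetic-data generator

`synthetic.simulate_screen` emulates an arrayed one-gene/one-well screen:

    rawᵢ = batch_shift(bᵢ) + ontarget(geneᵢ) + Σⱼ x_ij·β_trueⱼ + εᵢ ,
    εᵢ ~ N(0, noise_sd) ,

with pools of four random 19-mer guides, contiguous batch blocks with
shared N(0, 0.25) shifts, a fraction (default 5%) of genes carrying
N(−2, 0.5) on-target effects drawn once per gene, and a configurable set
of injected off-target families whose seeds are written into exactly one
oligo of each designated member pool (and scrubbed elsewhere), so realized
family sizes equal the configuration exactly.

Seed windows are drawn from a library *vocabulary* of `n_genes/10`
distinct 6-mers with lognormal usage weights (σ = 0.94, reproducing the
mean/median family-size ratio ≈ 42/27 of a genome-wide commercial
library), clipped at −1σ and +2σ. The clipping is deliberate: the floor
removes the sparse tail of 2–7-pool families, which at desk scale cannot
support family-level inference and whose extreme order statistics
otherwise dominate the method's false-positive behavior, and the cap keeps
any single family below ~10% of the screen. A genome-wide library's tail
is real, and on real data occasional very small families *will* pass both
filters by chance — significant families with few member pools deserve
skepticism, and the emitted family sizes exist precisely so users can
apply it. Passing the simulation studies therefore demonstrates
calibration and recovery over the well-populated family regime, not
robustness to the sparse tail, nor to spatial plate effects, guide-position
effects or non-Gaussian phenotype noise, none of which are modeled.

Simulation studies (tests and the acceptance script) normalize the raw
values with the normal-consistency MAD factor: with unit-SD Gaussian
noise this makes Z units coincide with the generative effect units, so
recovered `β̂` is directly comparable to `β_true`. Raw MAD remains the
package default for user data.

Study conditions are 2000-pool screens and 20 replicates per experiment:
large enough for the n ≫ p regime of real screens (~200 families, median
size ~26) while keeping the whole suite's runtime in minutes. The null and
single-family-recovery studies use pure noise (no on-target effects); the
false-positive-rate study uses the full defaults — three 30-pool families
at β = −3 contaminating the top ranks, with on-target genes as the ground
truth a retest would confirm. The window-scan study injects twelve
16-pool families (ten at β = −1.5, two at −2.5) at window 2: whole
families are detectable but their four-way splits at neighboring windows
mostly fall below the per-window BH threshold, reproducing the
max-at-window-2 localization with bleed-through confined to windows 1–3.
Uniformly large, strong families would invert that pattern (each family
contributes four detectable subfamilies to the flanking windows).

## Numerical and degenerate-input choices

- Even-length medians use the midpoint convention.
- A batch with zero MAD cannot be scored: it is flagged and excluded
  rather than silently normalized; an all-degenerate table is an error.
- DNA-alphabet input (T) is silently normalized to RNA (U); any other
  character is an error signaling a malformed file.
- KS ties are handled exactly by evaluating the step functions at observed
  values; `D ∈ [0, 1]` by construction.
- Boundary coefficients with `|β̂|` exactly equal to the strength cutoff
  are excluded (strict inequality).
- CSV outputs serialize floats at 9 significant digits, making repeated
  runs byte-identical.

## Design decisions taken where the design was open

- The constraint form (`subject to |β| < s`) and the Lagrangian λ form are
  equivalent formulations; only the λ form is implemented and `s` is not
  exposed, since no usable `s` default exists.
- KS confirmation defaults to the two-sample family-vs-complement test;
  the one-sample-vs-population variant is exposed as `ks_mode="vs_all"`
  rather than silently merged.
- Only lasso-selected families are KS-tested by default
  (`test_all_families=True` tests every family of size ≥ 2).
- KS uses original Z scores, not post-lasso residuals.
- The positional scan annotates one seed per oligo per window and uses
  pool-level membership at every window.
- FDR control in the scan is Benjamini–Hochberg, the field default.
- The CLI never downloads anything: named libraries resolve to bundled
  annotation files (only a small synthetic demo cache ships; commercial
  library annotations are proprietary) and their absence is an input
  error.

## Known limitations

- The model is additive and pool-level; per-oligo phenotypes and
  non-additive seed interactions are out of scope.
- λ is a user parameter; no cross-validated selection is provided.
- Small significant families (few member pools) are enriched for false
  positives on real data; see the generator discussion above.
- Spatial (plate-position) correction is not implemented — only
  batch-median normalization.
- shRNA hairpins must be supplied as processed guide sequences; no
  Dicer-site prediction is attempted.
- Full-length transcript complementarity search (identifying *which*
  transcripts a seed family silences) is out of scope.
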