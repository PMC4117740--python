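# seeddeconv

Detection, quantification and removal of seed-driven (miRNA-mimic)
off-target effects from genome-wide RNAi screens.

## The problem

Arrayed siRNA screens assay one gene per well with a pool of (typically
four) 19-mer siRNA duplexes. Each guide strand carries a 6-nucleotide
**seed** (positions 2–7, read 5′→3′) that can silence hundreds of
unintended transcripts through miRNA-style partial complementarity. All
pools sharing a seed — a **seed family** — therefore drift coherently
toward a spurious phenotype, producing false-positive "hits" that survive
conventional hit-calling. Over the 4⁶ = 4096 possible seeds, a genome-wide
library realizes about 4000 families, so seed-driven structure is both
pervasive and statistically detectable.

## The model

Per-pool phenotype scores are robust Z scores,
`Z = (x − median) / MAD` with `MAD = medianᵢ|xᵢ − median|`, computed within
experimental batches. Each score is modeled as an on-target component plus
additive seed-family off-target effects:

    Z = Xβ + Y

where `X` is the binary pool × family membership matrix (`x_ij = 1` iff
pool *i* contains an oligo of family *j*), `β` the family effect sizes and
`Y` the residual on-target component. `β` is estimated by the lasso in
unscaled form,

    β̂ = argmin ‖Z − Xβ‖² + λ‖β‖₁ ,    λ = 0.001 by default,

solved by deterministic cyclic coordinate descent (no intercept, no
standardization). Families with `|β̂| > 1` (Z-score units) are candidate
off-target families; each is then confirmed by a two-sample
Kolmogorov–Smirnov test of its members' original Z scores against the rest
of the screen (`p < 0.05` by default). Confirmed effects are subtracted to
give corrected scores `yᵢ = zᵢ − Σ_j x_ij β̂_j`, and detected seeds can be
matched against annotated miRNAs sharing the seed. A positional scan
(KS tests per family at every 6-mer window start 1–14, BH-FDR per window)
verifies which window carries the association.

## Worked example

```python
import seeddeconv as sd

# a synthetic 2000-pool screen: three 30-pool families carry a -3 shift,
# 5% of genes have genuine on-target effects (-2 ± 0.5), unit noise
sim = sd.simulate_screen(sd.SimulationConfig(rng_seed=1))
table = sd.robust_z_by_batch(sim.screen, scale="normal")

model = sd.ScreenDeconvolution.from_screen(table, oligos=sim.oligos)
res = model.fit()            # lambda=0.001, strength 1, significance 0.05
print(res.summary())
```

```
Seed-family off-target deconvolution
==========================================================
pools (n)                                             2000
seed families (p)                                      203
lambda                                               0.001
strength cutoff (|beta| >)                             1.0
significance cutoff (p <)                             0.05
KS mode                                         two_sample
solver sweeps                                           18
converged                                             True
families selected by strength                            4
families confirmed by KS                                 4
pools in confirmed families                            103
----------------------------------------------------------
seed            beta      ks_D           p   pools
UUAUAA        -2.812     0.885    1.59e-20      30
CUAGGU        -2.535     0.779    5.14e-16      30
AGAAUG        -2.517     0.732    3.39e-14      30
AGGGUG        -1.079     0.462     0.00809      13
==========================================================
```

The three injected families (UUAUAA, CUAGGU, AGAAUG) are recovered with
negative effects; the fourth is a borderline small vocabulary family.
`res.pool_table()` carries the
corrected Z per pool and `res.offtarget_pools` the members of each
confirmed family. On this class of simulation the top-20 false-positive
rate drops from ~63% with original scores to ~11% with corrected scores
(see the reproduction script below).

The same pipeline is available from a shell:

```bash
seeddeconv simulate --seed 1 --out-dir demo/
seeddeconv run --input demo/screen.csv --library demo/library.csv \
    --mad-scale normal --out-dir demo/out/
```

which writes `families.csv`, `pools.csv`, `volcano.csv`, a JSON run
manifest and a log. `seeddeconv scan` runs the seed-window scan,
`seeddeconv match` links detected seeds to a user-supplied miRNA table
(miRBase-style FASTA or CSV), and `seeddeconv annotate` builds reusable
seed-family caches from library annotation files.

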