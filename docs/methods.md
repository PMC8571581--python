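# Methods

## Model

### Life cycle and fitness

Social groups are founded by `l` cells; each founder grows a clonal
lineage of `m` cells, so the mature group holds `n = lm` cells and
whole-group relatedness (the chance that two members, sampled with
replacement, share a founder) is `1/l`. At maturity each cell becomes a
sterile helper or a pure reproductive. Helpers produce a public good;
a reproductive's fecundity is `1 − ε + εP` with `P` the realized helper
fraction of the whole group and `ε ∈ [0, 1]` the essentiality of
cooperation (`1 − ε` is baseline fecundity without any help). All
offspring disperse into one global pool and compete to found the next
generation's groups; generations do not overlap.

### Analytical layer: two extreme mechanisms

The heritable trait is the target helper proportion `q`. A fully
**random** lineage realizes Binomial(m, q) helpers; a fully
**coordinated** lineage hits `q` exactly at a flat fecundity cost
`θ`. The expected fitness of a focal founder against residents at `Q`:

- random: `w_FR(q,Q) = (1−q)(1−ε + εq/l + ε(l−1)Q/l − εq/lm)`. The
  final term is not an ad hoc penalty: writing the focal lineage's
  helper count as `k ~ Binomial(m, q)` and taking
  `E[(1 − k/m)(1 − ε + εP)]` produces exactly this expression — the
  negative covariance between a lineage's reproductive fraction
  `1 − k/m` and its own contribution to the group helper fraction `P`
  is what the `εq/lm` term captures. The test suite enforces the
  identity to 1e−12 against direct enumeration rather than trusting
  the algebra.
- coordinated: `w_FC(q,Q) = (1−θ)(1−q)(1−ε + εq/l + ε(l−1)Q/l)`,
  independent of `m` (no sampling noise).

Both are concave quadratics in `q`, so each mechanism has a unique
symmetric ESS:

```
q_FR* = 0                       if ε ≤ lm/(lm + m − 1)
        (m−1 − lm(1−ε)/ε)/(lm+m−2)   otherwise
q_FC* = 0                       if ε ≤ l/(l+1)
        (1 − l(1−ε)/ε)/(l+1)    otherwise
```

The closed forms are the accelerated path; `ess_numeric` finds the same
equilibrium as the root of `best_response(q) − q` (Brent's method; the
map is linear in `q` so the root is unique, and plain best-response
iteration is avoided because its contraction factor exceeds 1 for
large `l`). The suite requires agreement to 1e−8 across
`l ∈ {1,2,4,8}`, `m ∈ {2,5,25,125}` and a 0.05-step essentiality grid.
At the threshold exactly, `q* = 0` (the interior formula is continuous
there). The degenerate lone cell `(l, m) = (1, 1)` has `q* = 0`: a
helper with no one to help earns nothing.

### Invasion analysis

A rare mutant using the other mechanism invades when its fitness at the
resident equilibrium exceeds the resident's. At a monomorphic resident
target `q` the comparison reduces to the closed condition

```
random invades coordinated  ⇔  ε ≤ θlm / (θlm(1−q_FC*) + q_FC*)
coordinated invades random  ⇔  ε > θlm / (θlm(1−q_FR*) + q_FR*)
```

Both the closed inequality and the direct fitness comparison are
computed and must agree; a disagreement raises rather than returning a
silently chosen answer.

**Tie handling.** Exact fitness ties (within 1e−12) count as invasion
by the *random* specializer and never by the coordinated one. The
asymmetry is deliberate: the random mechanism carries no coordination
machinery, so at fitness parity the simpler phenotype-noise strategy is
treated as the default that displaces costly signaling. This makes the
boundary statement exact — at `θlm = 1` and `ε = 1` the two mechanisms
tie at the coordinated ESS, and with ties going to random, `θlm ≥ 1`
is precisely the regime where random specialization invades at every
essentiality and is never invaded. One can show the tie rule cannot
create mutual invadability in resident-target mode: the invasion margin
`w_FR − w_FC` at a resident target `q` is `(1−q)[θ(1−ε+εq) − εq/lm]`,
linear in `q`, and its sign pattern across `q_FR* ≤ q_FC*` admits at
most one direction of invasion (the property suite sweeps this).

`classify_region` supports two mutant conventions: `resident_q`
(the mutant copies the resident's ESS target, so only the mechanism
differs) and `mutant_optimal_q` (the mutant plays its own best response
to the resident; this enlarges both invasion sets and opens a
mutual-invasion region). A cell where both ESS are zero is classified
`no_division_of_labor` with no invasion evaluated — the invasion
conditions presuppose a resident that actually makes helpers.

`phase_grid` evaluates the classification over an `(ε, n)` grid at
fixed `l` and flags (never rounds) group sizes not divisible by `l`.

## Individual-based layer

The coordination level `s ∈ [0, 1]` becomes a second heritable trait,
interpolating between the analytical extremes.

- **Network.** Each cell opens a one-way observation link to each
  groupmate independently with probability equal to its *own* `s`
  (the receiver pays to observe; the sender is passive). The
  `own_lineage` scope variant restricts candidate senders to
  clone-mates.
- **Sequential resolution.** All cells start as intended
  reproductives. Cells are visited exactly once, in a uniformly random
  order per group; the visited cell becomes an intended helper iff the
  intended-helper fraction among its observed senders, at visit time,
  is strictly below its target `q`. Ties go to reproductive, which
  makes `q = 0` produce zero helpers under full coordination. A cell
  observing nobody falls back to a Bernoulli(q) coin flip — the
  continuous limit of `s → 0`, which is exactly the random mechanism.
  A config knob allows extra passes; one pass is the default and
  already yields the defining behavior: in a clonal group at `s = 1`
  the realized `P` lands within `1/n` of `q` for every target and
  visit order (helpers accumulate until the observed fraction reaches
  the target, i.e. the count stops at ⌈q(n−1)⌉).
- **Fecundity.** `w = (1 − cost(s))(1 − h)(1 − ε + εP)` per cell, with
  `P` over the whole group of `n` cells and `h = 1` for helpers (their
  fecundity is 0 regardless of `s`). The default cost is the
  decelerating `cost(s) = θ(1 − e^{−5s})`: the machinery is expensive
  to establish and cheap to extend, and its `s = 1` value
  `θ(1 − e^{−5}) ≈ 0.993 θ` keeps the fully coordinated simulation
  comparable to the analytical cost `θ`. The `linear` and
  `accelerating` alternatives are anchored to the same endpoints
  (`cost(0) = 0`, `cost(1) = θ(1 − e^{−5})`) so the three shapes
  differ only in curvature.
- **Selection and mutation.** Next-generation founders are a
  multinomial sample over all cells of the population weighted by
  fecundity (global competition makes parents' group membership
  irrelevant), randomly placed into groups. Each trait of each founder
  mutates independently with probability `p_mut = 0.01` by a
  Normal(0, 0.1) step clamped to [0, 1]. A zero total fecundity (every
  cell a helper) is an error, not a silent restart.

### Defaults and scales

`SimConfig` defaults mirror the reference study conditions: target
population ~10⁴ cells (realized as `⌊10⁴/(lm)⌋` groups), 10⁵
generations, 10 replicates, summaries over the trailing 10% of
generations, `init_q = 0.5`, `init_s = 0` (coordination must evolve de
novo). The `desk` preset (2000 cells, 2×10⁴ generations, 5 replicates)
is the package's working scale: at `ε = 1, n ≈ 20` the random control
converges to its analytic ESS within a few thousand generations and the
relatedness contrast between `l = 1` and `l = 8` is already an order of
magnitude in evolved helping, so the reduced scale preserves the
qualitative results while keeping the full test suite to minutes. The
`paper` preset exposes the full scale on demand.

The relatedness comparison is run at `n = 24` (`l = 1, m = 24` vs
`l = 8, m = 3`): group size must be a multiple of the founder number,
and 24 is the smallest size near 20 divisible by both settings, keeping
group size constant across the contrast.

### Randomness and determinism

One master seed; per-replicate streams are spawned with numpy's
`SeedSequence`, so adding replicates never reshuffles earlier ones and
identical `(config, seed)` reproduce trajectories bit for bit. The
variance comparison between evolved `s` and evolved `P` across
replicates is reported (ratio plus two-sided F p-value with
`r−1, r−1` degrees of freedom), never asserted: with `θ ≪ 0.1`,
selection on `s` is much weaker than on `q`, so drift spreads the
evolved coordination level far more than the helper fraction, and a
zero variance in either trait is flagged degenerate rather than tested.

## What the generator does and does not emulate

All inputs are generated internally; the model is deliberately generic
rather than species-specific. Real microbial groups have spatial
structure, density-dependent switching, signal deception, overlapping
generations, and helpers that retain partial fecundity — none of which
are modeled here. Passing tests therefore show internal consistency of
the theory and its simulation at the stated conditions, not predictions
calibrated to any particular organism.

## Known limitations

- The sequential one-pass resolution is one faithful reading of
  "sampled one individual at a time"; other stopping rules (iterate to
  a fixed point) would strengthen coordination at intermediate `s`.
  The `resolution_passes` knob exists for exploring this.
- The pure-numpy inner loop costs ~1 ms per generation at desk scale;
  full-scale runs (10⁴ cells × 10⁵ generations × 10 replicates) are
  supported but take hours per parameter point.
- Whether helpers would pay the coordination cost is moot here (their
  fecundity is zero) but would matter for partially sterile helpers.
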