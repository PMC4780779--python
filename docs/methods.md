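# Methods

This document describes the statistical model, the data-processing
conventions, the synthetic-data generator, and the numerical choices made by
`nichelimits`. Everything stated here about behaviour is enforced by the test
suite; nothing here reports empirical results beyond what the tests and the
validation script compute.

## Scientific setting

Grasses with C4 photosynthesis are concentrated in warm, open and often dry
environments, while their C3 relatives extend into cooler climates. A
long-standing question is whether this sorting reflects shifts in the
*limits* of the climatic niche — e.g. a warmer cold-edge or a drier dry-edge —
rather than shifts in niche centres. Because photosynthetic pathway is
phylogenetically clustered (C4 arose in a limited number of clades), any
C3/C4 comparison across species must account for relatedness: treating
related species as independent samples badly overstates the evidence.

`nichelimits` implements this comparison end to end: from occurrence records
and climate grids, through per-species trimmed niche limits and a composite
("working") phylogeny, to a phylogenetic generalized least squares (PGLS)
contrast of C3 versus C4 limit means under several residual correlation
structures.

## Trimmed niche limits

For each species and climate variable, occurrence records are annotated by
nearest-cell lookup in a regular longitude/latitude grid (ESRI ASCII format,
half-open cells `[x, x+cs) × [y, y+cs)`, row 0 northernmost). Records with
impossible coordinates or unknown photosynthetic state are dropped and
counted; a missing mandatory column is a fatal error.

The *trimmed extremes* of a species' values drop `k = floor(f·n)` records
from each tail (default `f = 0.05`) and report the remaining minimum and
maximum. This is a rank-based rule: with fewer than 20 records nothing is
trimmed. As `n` grows the trimmed limits converge to the 5% and 95%
quantiles of the *attainable* value distribution — deliberately inside the
true niche interval — which is the robustness/bias trade-off accepted in
exchange for insensitivity to single bad records. Species need at least 6
usable records per variable (configurable; the per-variable rule is the
default, a whole-record rule is available).

Aridity-index values are additionally classifiable into the UNEP categories
(hyper-arid < 0.03 ≤ arid < 0.2 ≤ semi-arid < 0.5 ≤ dry-subhumid < 0.65 ≤
humid; boundaries low-inclusive on the wetter class), temperatures into 5 °C
bins, and an 18 °C coldest-quarter threshold flags tropical climates.

## Working phylogenies

Sequence data rarely cover all species with occurrence data. The package
builds working trees by:

1. **Collapse**: a resolved source tree of sequenced species is collapsed to
   named backbone clades. Each clade node keeps the branch subtending the
   most recent common ancestor of its sampled members (its *stem*); sampled
   terminals keep their lengths. Non-monophyletic clades are a fatal error
   naming the intruding taxa. A clade with a single sampled member gets stem
   0 (there is no internal branch to inherit).
2. **Graft**: unsequenced species are attached as new terminals inside their
   assigned clade under one of three branch-length schemes:
   - **1 — equal**: *every* branch in the working tree is set to 1
     (topology-only information);
   - **2 — global mean**: grafted terminals get the mean terminal length of
     the source tree; existing lengths are kept;
   - **3 — clade mean**: grafted terminals get the mean length of their
     clade's sampled terminals; existing lengths are kept. If a clade has no
     sampled terminal the run fails unless the global-mean fallback is
     requested explicitly.

Because all three schemes are heuristics, the analysis runs under each
requested scheme and the report merges rows whose best model, significance
verdict and effect sign agree — disagreement across schemes is surfaced, not
averaged away.

## The PGLS contrast

For each clade scope × variable × extreme, the model is

    y = β0 + β1·1[C4] + ε,   ε ~ N(0, σ² C(θ))

fitted by generalized least squares via Cholesky factorisation (no explicit
matrix inverse). `β0` is the C3 mean limit, `β0 + β1` the C4 mean, and the
two-sided test of `β1 = 0` uses the unbiased residual scale
`eᵀC⁻¹e/(n − p)` with `n − 2` degrees of freedom, which makes the statistic
exactly t-distributed when `C` is correct.

Five residual correlation families are fitted:

| family | structure | parameter |
|---|---|---|
| none | identity (ordinary least squares) | — |
| Brownian | shared-path covariance `V` from the tree | — |
| Pagel | off-diagonals of `V` scaled by λ | λ ∈ [0, 1] |
| Grafen | `1 − h^ρ` with node height `h = (n_desc − 1)/(n − 1)` | ρ ∈ (10⁻³, 10] |
| ACDC | branch from depth `d₁` to `d₂` stretched to `(T/ln g)(g^{d₂/T} − g^{d₁/T})` | g ∈ [0.01, 100] |

`g = 1` recovers Brownian motion; `g < 1` decelerates evolution toward the
present, `g > 1` accelerates it. ρ and g are profiled on a log scale for
conditioning. Profiling uses a 5-point coarse grid followed by bounded
scalar minimisation on the bracketing interval (`xatol = 10⁻⁶` of the search
range); optima at a parameter boundary are flagged.

Model choice is by AIC with `k = 3` (β0, β1, σ²) or `k = 4` (plus θ); ties
break toward fewer parameters, then a fixed family order. A row's
*agreement* flag is true when every model within ΔAIC ≤ 10 of the best
agrees with it on significance at α and on the sign of β1. The maximum
likelihood criterion is the default (REML is available); AIC comparison
across correlation families uses a common fixed-effects design, where ML is
the standard choice. p-values are reported per row without multiple-testing
correction, matching the conventional contrast-table presentation; the
report footer says so.

## Synthetic-data generator

The generator is a first-class module that emulates the study design, with
every generated quantity recorded in a truth file so end-to-end tests can
score the pipeline against known answers.

- **Phylogeny**: a Yule (pure-birth) tree of the "sequenced" species (root
  split at t = 0, exponential waits with rate `k·birth_rate` while `k`
  lineages are active, and a final `Exp(n·rate)` stretch), which is
  ultrametric by construction. It is partitioned into monophyletic backbone
  clades of at most `clade_size_max` tips; additional "unsequenced" species
  are assigned to clades at random and grafted with the clade-mean scheme to
  form the generating tree.
- **States**: C4 is painted onto `n_transitions` disjoint clades of the
  generating tree, everything else is C3. The predictor is therefore
  phylogenetically clustered — the regime in which ordinary least squares is
  anticonservative and PGLS is needed. A draw is accepted only if the
  minimum number of state changes on the tree (unit-cost parsimony, computed
  by an internal dynamic program and cross-checked in the tests by an
  independent implementation) equals `n_transitions`; because the collapsed
  working tree is a star of backbone clades, the partition guarantees at
  least `2·n_transitions + 1` clades so this is realisable.
- **Limit traits**: species' niche-interval endpoints are drawn from the
  PGLS generating model itself (Brownian by default) on the generating tree.
  The warm-quarter upper limit carries the injected C4 shift of +1.61 °C —
  the magnitude of the headline warm-limit contrast in the motivating study
  system — with the residual scale σ set by an *analytic power rule*:
  the exact noncentral-t power of the GLS test on this tree and state
  pattern is solved for the noncentrality that achieves a 0.97 target, and
  σ follows from `σ = |β1|/(ncp·√c₁₁)`. The 0.97 target is chosen a
  priori to leave margin for the trim attenuation (the trimmed maximum
  under-shoots the interval end by roughly `(k+1)/(n+1)` of the interval)
  and grid discretisation, so realised end-to-end power stays above the 0.9
  acceptance floor. Aridity-index traits carry no effect and a small tip
  standard deviation (0.15).
- **Geometry**: the warm-quarter temperature (MTWQ) increases with latitude
  on the emitted grid and the cold-quarter temperature (MTCQ) decreases with
  it, so each species' latitude band implies both temperature intervals;
  the aridity index varies with longitude, independently. MTCQ limits are
  therefore affine images of the MTWQ limit traits with a known slope, which
  fixes their implied β1 (in particular, the MTCQ lower limit inherits an
  effect of `−slope·1.61`). Zero-effect responses — MTWQ lower limit, MTCQ
  upper limit, and both AI limits — provide the false-positive yardstick.
- **Occurrences**: each species receives `n_records` (default 80) points
  uniformly over the grid cells inside its (latitude-band × longitude-band)
  eligibility region, jittered within cells. The attainable per-variable
  intervals actually realised on the grid are stored in the truth file.

What the generator does **not** emulate: spatial abundance structure or
sampling bias (occurrences are uniform over eligible cells), climate
covariance between temperature and aridity (axes are orthogonal by design),
measurement error in the grids (noise is optional and off by default in
scenarios), non-ultrametric source trees, and state-dependent
diversification. These omissions are intentional: the generator exists to
validate the estimator and the pipeline plumbing, not to simulate
biogeography.

### Study conditions (fixed defaults)

Scenario defaults are the package's chosen study conditions, selected once
and justified here rather than revisited per run: 40 sequenced + 40 grafted
species (emulating roughly half the taxa lacking sequences), 4 C3→C4
transitions, clades of ≤ 8, 80 records per species, MTWQ limit means 18/28 °C
with the +1.61 shift on the upper limit, MTCQ spanning 0–22 °C, AI limit
means 0.4/1.6, power target 0.97, α = 0.05, a 100×100 grid of 0.3° cells.
Validation studies use 200-tip trees with 1000 replicates (type-I error,
recovery, λ recovery), 200 replicates for model selection, and 100 scenario
bundles for end-to-end calibration — sizes at which binomial noise on the
checked rates is small relative to the acceptance bands, while a full run
stays within a couple of minutes on one CPU.

## Numerical choices

- All GLS solves go through `scipy.linalg.cho_factor`/`cho_solve`; the
  log-determinant comes from the Cholesky diagonal. A non-positive-definite
  or numerically singular structure (diagonal ratio < 10⁻¹²) raises a typed
  error, and a family that fails inside the model suite is recorded and
  skipped rather than aborting the suite.
- Tree covariance construction is vectorised: an edge-by-tip incidence
  matrix `B` and per-edge depths give `V = (B·len)ᵀB`, the ACDC transform
  by per-edge stretched lengths, and Grafen heights from a tip-count MRCA
  matrix. The same arrays are reused across all replicates on a tree.
- The quadratic form `eᵀC⁻¹e` is floored at 10⁻³⁰⁰ to keep the profiled
  log-likelihood finite on degenerate (zero-residual) inputs.
- Noncentral-t tail probabilities in the power rule fall back to their
  limiting values (1 and 0) when scipy underflows to NaN deep in the tails.
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  identical configuration and seed reproduce every file byte-for-byte.

## Limitations

- The trimmed limit estimates the 5%/95% attainable quantiles, not the true
  niche edge; with strong spatial aggregation of records the bias can be
  larger than the `(k+1)/(n+1)` rank argument suggests.
- Working phylogenies built by collapse-and-graft understate uncertainty:
  grafted placements are treated as known, and branch-length schemes are
  heuristics. Running all schemes and reporting disagreement mitigates but
  does not remove this.
- The t-test is exact only when the correlation structure is correct; after
  data-driven selection of θ and family, p-values are mildly optimistic (the
  end-to-end false-positive check bounds this empirically at α + 0.03).
- Grafen and ACDC structures are recomputed from topology and depths on the
  *working* tree; on equal-branch trees the Grafen transform depends only on
  topology, which is the intended behaviour but means scheme 1 carries no
  branch-length signal at all.
- The species-mean contrast ignores within-species variance of the limit
  estimates (heteroscedasticity from unequal record counts is not modelled).
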