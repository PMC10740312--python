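# Methods

This note documents the model implemented by `icongems`, the numerical
choices behind it, what the synthetic data generator does and does not
emulate, and the known limitations.

## 1. Template model and irreversible split

A genome-scale model's flux bounds carry units (mmol/gDW/h) that are
incommensurate with expression units, so predictions are made on a
*template* model that keeps stoichiometry and reversibility but discards
bound magnitudes. Each reaction's bounds map to

    L̂ = 0 if L ≥ 0, else −T        Û = T if U > 0, else 0

with `T` a "largest number" that must dominate every expression-derived
cap. Default: `T = max(1000, 10 × max expression value)`; it is a scale
parameter, not an uptake rate.

Carbon handling: an exchange reaction is a *carbon exchange* when its
single exchanged metabolite's formula contains elemental carbon (element
tokenizer — `Ca`, `Cl`, `Co` are not carbon). In the **DC** (determined
carbon source) template only the user-named exchange(s) get lower bound
−T and all other carbon exchanges are closed for uptake; in **AC** (all
possible carbon sources) every carbon exchange opens at −T. Two open
points were decided as follows: non-carbon nutrient exchanges (O₂, NH₄⁺,
phosphate, …) simply follow the template rule, so a previously open uptake
stays open at −T; and biomass bounds are templated like any other reaction
(the bound rule makes no exception).

Reversible reactions (L̂ < 0 < Û) split into a forward column and a
negated backward column, both bounded [0, T]; backward-only reactions
(Û ≤ 0) become a single negated column rather than a pair. Columns are
ordered [irreversible | reversible-forward | reversible-backward]. Folding
a split solution back reports forward − backward per reaction. On small
fixtures the suite verifies that the split preserves the LP optimum and
the vertex set of the flux polytope.

## 2. Expression caps and the q-transform

Per-condition caps follow the E-flux idea with `f(g) = g`: a reaction's
cap is its GPR rule evaluated on the condition's expression values with
**AND → min** (an enzyme complex is limited by its scarcest subunit) and
**OR → sum** (isoenzymes add capacity). Empty-GPR columns keep the bound
T. Genes present in the model but absent from the expression table are
dropped from their parent node — neither +∞ into a min nor 0 into a sum is
defensible — and a reaction whose whole tree is unmeasured is treated as
unmapped (bound T).

The objective works on `q_j = 1 + v̄_j / M_j`. `M_j` is taken as the
maximum over *all conditions in the supplied matrix* of the GPR-evaluated
cap for column j; with `v̄_j ≤ f ≤ M_j` this puts `q_j ∈ [1, 2]` for every
feasible flux, so all objective terms are positive and comparable across
reactions. Columns with `M_j = 0` keep `q = 1`, are excluded from the
objective, and carry no flux anyway (`f = 0`). Forward/backward siblings
share f and M.

## 3. The pair set R

Each co-expression edge (gene a, gene b) is lifted to every unordered pair
of distinct mapped columns (i, j) with a on i and b on j. Sibling pairs of
one reversible reaction are excluded — rewarding simultaneous forward and
backward flux would fight the complementarity constraint — as are
self-pairs and unmapped or M = 0 columns. The expansion is over split
columns, so a single gene edge can contribute several pairs.

## 4. Solving the quadratic program

The objective Σ q_i q_j is an indefinite quadratic and the complementarity
constraint `v̄_a v̄_b = 0` per reversible pair is bilinear; the program is
NP-hard in general. The per-pair encoding is used instead of the aggregate
sum-of-products form: since all terms are nonnegative the two are
equivalent, and per-pair constraints branch cleanly. The solver:

1. computes `z*` and an optimizer by LP (HiGHS), canceling any two-way
   flow on sibling pairs (this changes neither steady state nor net
   fluxes);
2. enumerates the complementarity disjunctions (which side of each open
   reversible pair may carry flux) when 2^p fits the branch budget
   (default 64), otherwise explores the E-flux sign pattern and its
   single-pair flips;
3. within each branch runs local optimization (trust-region with exact
   gradient/Hessian) from multiple starts: the E-flux point, the LP
   vertex maximizing the linear objective part, the biomass vertex, and
   seeded random-objective vertices (10 starts by default, seed 0);
4. keeps the best point that passes a full feasibility audit (steady-state
   residual ≤ 1e-6 relative, bounds, complementarity ≤ 1e-6, biomass pin).

Because the folded E-flux optimizer is always a candidate, the returned
objective never falls below the E-flux solution's value. The status is
reported as `heuristic` — local certificates only — or `degenerate` when R
is empty, in which case any biomass-pinned feasible point is returned with
objective 0. On fixtures with one free flux dimension the solver matches a
1e-3-resolution grid search to < 1e-4 relative gap (tested).

α defaults to 1 (biomass pinned to the full E-flux optimum); lower values
trade growth for co-activation.

## 5. Two-stage flexibility (FVA)

Stage 2 maximizes and minimizes each reaction's net flux subject to the
full stage-1 system plus `Σ q_i q_j ≥ Z*(1 − 1e-6)` (a relative pin;
absolute pins are brittle in floating point) and the biomass constraint.
With R empty the quadratic pin is vacuous and the ranges are exact LP
values; otherwise stage 2 inherits the heuristic solver, starting from the
stage-1 point (always feasible), so reported ranges are inner
approximations. Flexibility is `F_i = |v_max − v_min|` per *original*
reaction (net flux, not split columns). Subsystem flexibility is the
arithmetic mean F over member reactions, min–max normalized to [0, 1]
over the whole subsystems × conditions matrix; an all-equal matrix
normalizes to 0 with a warning. Whether stage 2 should re-impose the full
q-system or only the linear constraints was open; the full system is
imposed.

## 6. Co-expression network construction

Cleaning: duplicate gene rows are averaged; genes with any missing value
are dropped; per-gene outliers are winsorized at median ± 5·MAD (a
conservative, deterministic rule; the raw table is never silently
modified — every action is logged). Correlation is Pearson across
conditions; constant rows get correlation 0 with a warning (never an
edge). At N = 2 conditions every defined correlation is ±1 and the
network is degenerate, which the code flags.

Binarization places an edge where `r ≥ t` on the *signed* correlation —
thresholds are reported on a (0, 1) scale and negative co-expression is
not treated as co-activation; an absolute-value mode exists behind a flag.
Equality counts as an edge.

Threshold selection scans a grid (default 0.50…0.99 step 0.01) and
records, per candidate: the scale-free topology fit R² (log–log regression
of the degree distribution; ≤ 10 distinct degrees are fitted exactly,
more are pooled into 10 logarithmic bins), mean connectivity 2E/V, and
the cluster count. Clusters are connected components with ≥ 2 nodes — a
deterministic stand-in for spectral cluster counting, which is available
behind a flag (near-zero Laplacian eigenvalues). Among candidates with
R² ≥ 0.5 the one maximizing the cluster count wins; ties break toward the
*smallest* threshold, since higher thresholds discard network
information. If nothing reaches R² ≥ 0.5 the max-R² candidate is returned
with a prominent warning.

Utilities: random rewiring removes round(fraction·E) edges and inserts
the same number uniformly among the non-edges of the original graph
(node and edge counts conserved exactly; removed edges cannot reappear);
STRING import keeps combined scores strictly greater than 900 by default;
TOM similarity is `(l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with unit
diagonal; modules come from average-linkage clustering of 1 − TOM with a
maxclust or height cut, labeled ME1… by decreasing size.

## 7. Accuracy scoring

Measured fluxes map onto model reactions through user-supplied entries:
*chain* entries (a measured conversion realized as sequential model
reactions) score the minimum **absolute** net flux along the chain — a
reversible intermediate running backward still carries the pathway —
and *parallel* entries (several model reactions sharing the measured
substrates/products) score the **signed** sum, each step oriented toward
the measured product via an optional `-` prefix. The mapping file is
user-supplied by design: automatic pathway search between substrate and
product would silently change results on ambiguous networks.

Agreement is the uncentered Pearson correlation (dot product over the
product of Euclidean norms — the only reading of the formula that yields
a correlation). It is invariant to positive rescaling of either vector,
which is what makes unit-free template predictions comparable to measured
fluxes; zero vectors raise rather than returning 0. Any plotting-style
rescaling of predictions (`‖v_m‖/‖v_p‖`) never affects the score.

Module concordance compares, per detected module and condition, the mean
expression of module genes against the mean |net flux| of reactions whose
GPR cites at least one module gene, both row-wise min–max normalized; the
per-module Pearson correlation of the two patterns is the concordance
score.

## 8. Synthetic data: what it emulates and what it does not

`gen_toy_model` builds a substrate exchange feeding `n_pathways` parallel
chains of `pathway_length` reactions converging on a biomass reaction;
every internal reaction carries a unique gene and the last pathway's last
step is reversible, so the split, the complementarity constraint and the
GPR machinery are always exercised. `gen_expression` drives each gene
block with a shared latent standard-normal condition profile plus
independent Gaussian noise, scaling the latent so the expected
within-block Pearson correlation equals `block_correlation` (default 0.9;
exactly 1 at `noise_sd = 0`); per-gene positive affine maps then set
realistic heterogeneous magnitudes without touching any correlation.
Defaults: 8 conditions, noise_sd 0.3.

This emulates exactly the structure the network construction assumes —
correlated gene groups across conditions — and nothing else: no count
noise, no library-size or batch effects, no nonlinear co-regulation.
Passing tests therefore demonstrate correctness of the machinery on
block-correlated data, not performance on real transcriptomes.

The **route-recovery experiment** co-expresses pathway 1's genes with the
biomass gene and scales the biomass gene's expression to 0.8× so the
biomass cap — not either pathway — is the E-flux bottleneck; both
pathways can then carry the whole optimum and only the co-expression
objective breaks the tie. Recovery means ≥ 95% of z* routed through
pathway 1 and uncentered correlation ≈ 1 with the target route.

The **robustness experiment** (accuracy vs number of conditions N) uses a
paired subsampled-dataset design: each replicate draws one dataset with
max(N) conditions and builds the network from its first N conditions
while the expression caps and the condition of interest stay fixed, so
accuracy differences across N reflect network quality alone. The toy
binarization threshold is 0.5, placed well between the null correlation
(~0) and the within-block correlation (0.9): true edges are then detected
reliably at every N and the dominant error mode is spurious
between-block edges, whose probability falls steeply with N — the
mechanism that makes few-condition networks unreliable. Accuracies are
averaged over 40 replicate draws (seeded from one master seed, fully
deterministic). With this design the mean curve is non-decreasing over
N ∈ {3, 5, 10, 20}; at N = 2 every correlation is ±1 and the network
carries no information.

## 9. Numerical conventions

- Feasibility tolerances: steady-state residual ≤ 1e-6 relative, bound
  violations ≤ 1e-9, per-pair complementarity ≤ 1e-6 relative, biomass
  pin ≤ 1e-6 relative.
- All randomness (multistart vertices, generators, rewiring) flows from
  explicit integer seeds; default 0.
- Degenerate inputs: empty R → degenerate solve with objective 0;
  all-equal normalization ranges → 0 with a warning; empty grids, zero
  vectors, unknown ids → errors, never silent defaults.
- Problem sizes: the shipped experiments use 5–9 reaction toys, 5–13
  genes, 2–20 conditions; the branch oracle scans 10,001 grid points.

## 10. Known limitations

- The quadratic solver is heuristic at scale: global optimality is not
  certified, and stage-2 FVA ranges are inner approximations when R is
  nonempty. A global nonconvex-QP backend could be slotted in behind the
  same interface.
- Branch enumeration is exponential in the number of open reversible
  pairs and falls back to a sign-pattern neighborhood beyond the budget.
- The network is binary and linear-correlation based; soft-threshold
  (weighted) networks and nonlinear association measures are out of
  scope, as are GO/KEGG enrichment of modules and probe-to-gene mapping.
- Chains in the accuracy mapping assume the user oriented steps
  consistently; the package does not infer pathway orientation.
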