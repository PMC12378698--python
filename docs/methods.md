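# Methods

## The multiplex model

A multiplex lexical network is a pair `(V, {G_1 … G_M})`: one node universe
`V` (word labels, case-folded and whitespace-trimmed at ingestion) and `M ≥ 2`
undirected layers over that universe, each carrying one relation type.
Nodes absent from a layer's edge list are isolates in that layer.  There are
no interlayer links: this is a multiplex of replica nodes, not a general
multilayer network.  Edge lists may carry an integer weight (e.g. elicitation
counts for free associations); the filter keeps an edge iff
`weight > min_weight` (strictly greater), and unweighted rows bypass the
filter entirely.

### Largest viable cluster

A node set `S ⊆ V` is *viable* when the subgraph induced by `S` is connected
in every layer.  The largest viable cluster (LVC) is a maximum-size viable
set.  We compute it by **partition refinement**: start with `V` as a single
candidate cell; repeatedly split every cell into the connected components of
its induced subgraph, layer by layer, until no cell splits; return the
largest final cell.  Two facts make this exact rather than heuristic:
every final cell is viable (it is a single component in each layer's induced
subgraph), and every viable set is contained in exactly one final cell (a
set connected within itself cannot straddle two components of any induced
subgraph that contains it).  The largest final cell is therefore the global
maximum.  We preferred this over the superficially similar
"intersect the per-layer largest components and iterate" procedure, which
can return the empty set when the per-layer giants do not overlap even
though a smaller joint core exists; an exhaustive-enumeration oracle
(`brute_force_viable_cluster`, for ≤ 12 nodes) confirms exactness on random
instances in the test suite.

Ties everywhere (largest component, largest cell, the oracle) break to the
lexicographically smallest sorted member list, so outputs are
bit-reproducible.  Isolated nodes count as size-1 components, which makes
extending layers with universe isolates harmless.  The single-layer analogue
of the LVC used by the null models is the layer's largest connected
component (LCC).

### Shortest paths

All walk reconstruction runs on the unweighted **aggregate** graph (the
union of layer edge sets), the simplest reading of "multiplex shortest
paths" in which a path may mix link types freely; restricting connectivity
to one layer is exactly what the single-layer null models do.  When several
shortest paths exist we return the single deterministic one produced by
breadth-first search expanding neighbors in lexicographic order, rather than
averaging over all shortest paths — determinism makes every downstream
feature bit-reproducible.  Disconnected pairs are a first-class outcome
(`None`), distinct from the error raised for nodes not in the graph.

## From fluency list to features

Responses are matched to the lexicon after case-folding and trimming; a
non-exact response matches a *unique* lexicon entry at Damerau edit distance
1 (one substitution, adjacent transposition, insertion or deletion — the
standard typo model) and is flagged as a typo; ambiguous or more distant
responses are out-of-vocabulary (OOV).  OOV responses are excluded from the
walk (consecutive in-lexicon neighbors are paired across them) but stay in
the denominator of the typo fraction.  Repeated responses are kept: revisits
are participant behavior.

The collective walk concatenates the per-pair shortest paths; a junction
node shared by consecutive paths is counted once.  Conventions for the 17
measures:

- *coverage per response* counts **nodes** per path, endpoints included
  (mean over consecutive pairs); *distance from the category identifier*
  counts **edges**.
- The LVC-access entry coding marks a walk node 1 iff it is inside the LVC
  and its predecessor is outside; the walk's first node has no predecessor
  and is coded 1 iff it is in the LVC (treated as entering from outside).
- All entropies are binary Shannon entropies in bits, hence in [0, 1].
- Permanence statistics are maximal-run lengths of the walk's LVC-membership
  coding; a symbol with no runs scores 0.
- *Norm 1* is max permanence divided by the number of responses; *Norm 2*
  is the **mean** 1-run length divided by the number of responses (the
  natural "average permanence" counterpart of Norm 1; no other reading
  yields a distinct measure).
- A response disconnected from the category contributes nothing to the
  category-distance numerator while the denominator stays the number of
  responses (the printed formula divides the summed lengths by the response
  count); the same responses are skipped in the mean LVC-access count from
  the category.  A category absent from the graph leaves both category
  measures missing, with a warning.
- Fewer than two usable responses make the walk degenerate: path-dependent
  measures become missing values (NaN); response-only measures are still
  computed.  Missing values are imputed with the cohort median before any
  model fitting.

## Prediction pipeline

Feature ranking is either correlation-based (descending |Pearson r| with
the target, ties by name) or importance-based from a gradient-boosted tree
ensemble with squared-error loss (500 trees, depth 6, learning rate 0.05,
fixed seed — hyperparameters are fixed and recorded for reproducibility,
not tuned).  Model search evaluates ranking prefixes by forward addition,
then prunes the winner by backward elimination, scoring every candidate
subset by LOOCV mean squared error of an L2-regularized linear model on
standardized features.  Backward elimination stops when no single removal
lowers the MSE; increases below `1e−9 · var(y)` count as ties so redundant
copies are still eliminated, and among trajectory subsets within that
tolerance of the minimum the smallest wins.  With `method="auto"` both
ranking routes run and the lower-MSE one is kept.

Inside LOOCV the scaler (per-feature mean and standard deviation) is fit on
the n−1 training rows of each fold only; the held-out row is transformed,
never fit — the deployed model's scaler, by contrast, is fit on all rows,
matching how it will be applied to new data.  Features that are constant
within a training fold are dropped for that fold.  The default ridge
strength is λ = 1.0 on standardized features, with λ = 0 (plain least
squares) exposed; an unregularized singular design is an error instructing
a nonzero λ.  The fitted coefficients on standardized features equal the
closed form `(XᵀX + λI)⁻¹ Xᵀ(y − ȳ)` with intercept `ȳ`; the test suite
checks this against an independent linear-algebra oracle.

Reported per subset: LOOCV MSE, the Pearson correlation between held-out
predictions and actual scores with its two-sided t-approximation p-value,
and `r_squared`, which is that correlation squared (an in-sample F-based R²
would differ; we label the one we compute).  Feature selection is performed
once on all data — matching the single selected subsets the workflow
reports — not re-nested per fold.

Deployable models store the selected subset, scaler parameters,
coefficients, the training-feature medians (for imputation at predict
time), and the in-sample prediction range.  New predictions are reported
raw, rescaled to [0, 1] by that range (clipped), and ×100 for display:
100 is "the highest prediction seen in training", a relative benchmark.
A degenerate range (min = max) pins the unit score at 0.5 with a warning.

Single-layer null models rebuild the features with connectivity restricted
to one layer and the layer's LCC substituted for the LVC, holding the
multiplex-selected feature subset fixed so the comparison isolates the
network substrate, and compare Pearson correlations.

## Synthetic data: what it emulates and what it does not

`generate_multiplex` plants a core that is connected in every layer (random
spanning tree plus extra core edges at `p_core` per layer) inside an
otherwise sparse random multiplex (`p_periphery` per layer for every other
pair).  Defaults — 120 nodes, 4 layers, core 30, `p_core = 0.12`,
`p_periphery = 0.01` — give a four-layer lexicon miniature with a viable
core of about a quarter of the nodes and a sparse periphery, a size at
which every pipeline stage runs in seconds.  The planted core is viable by
construction, so the LVC contains it unless the periphery happens to form a
larger joint structure (essentially never at these densities; a 100-spec
property test checks containment).

`generate_fluency_list` produces responses as a random walk on the
aggregate that, at each step, picks uniformly among LVC neighbors with
probability `lvc_bias` (when any exist) and uniformly among all neighbors
otherwise, avoiding the immediately preceding response when possible.  Core
occupancy of the resulting lists is strictly increasing in `lvc_bias`,
which is the handle the recovery tests use.  Because consecutive responses
are graph neighbors, per-pair shortest paths are short and coverage per
response is nearly constant — real participants skip across the lexicon,
so this generator under-exercises long-path coverage variation.  Real
response lists also carry typos, frequency effects, and proper-name OOVs
that the generator does not emulate (typo handling is unit-tested
directly).  Passing tests on these cohorts therefore demonstrates that the
machinery — LVC detection, walk reconstruction, selection, LOOCV, scoring —
is correct and leakage-free, not that any particular empirical effect size
will hold on real lexical data.

`generate_cohort` draws per participant `lvc_bias ~ U(0,1)` and list length
`~ U{10..40}` (roughly a 2-minute task's yield), computes features through
the real pipeline, and sets the trait to a linear combination of z-scored
features plus Gaussian noise (a heavier-tailed option is deliberately out
of scope; Gaussian noise keeps the planted R² interpretable).  Because walk
features are correlated with each other, a fixed noise sd cannot pin the
population R²; `target_r2` instead derives the noise sd from the realized
planted-signal sd, so a requested R² = 0.4 yields LOOCV correlations near
√0.4 ≈ 0.632 at n = 300.  The default cohort size, 479 participants,
mirrors the scale of the study populations this tool targets.

## Problem sizes and budgets used in the checks

The test suite and the acceptance script use: 200 random multiplexes of
≤ 10 nodes for the exhaustive-oracle comparison; cohorts of n = 300 over 20
seeds for planted-R² recovery (CFS ranking + forward selection — backward
elimination is exercised at smaller n, where its O(k²) LOOCV sweeps are
cheap); n = 150 with 200 target permutations for the null-band check;
n = 120 over 20 seeds for the multiplex-vs-single-layer comparison; and 100
lists per bias level for the monotonicity sweep.  These sizes give stable
pass/fail behavior for the stochastic checks while keeping a full run in
minutes on one CPU.

## Known limitations

- The LVC refinement is exact but quadratic-ish in naive cost; it is
  comfortable at the tens-of-thousands-of-nodes scale of real lexicons but
  has no incremental update path.
- One deterministic shortest path per pair means path-level measures ignore
  path multiplicity; an averaging variant would need an explicit rule the
  source literature does not provide.
- Shortest paths are aggregate-level; layer-switch costs or layer-constrained
  multiplex distances are not modeled (the single-layer nulls are the only
  layer-restricted variant).
- Phonological similarity is modeled only as an edge list supplied by the
  user; the package does no phonemic transcription.
- No multiple-testing correction across targets is applied; targets are
  modeled independently.
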