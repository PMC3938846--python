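# Methods

## Model and assumptions

The central object is a signed digraph over gene symbols: edges are
activating (+1) or inhibiting (−1), and an activating and an inhibiting
edge may coexist between the same ordered pair (regulator databases report
both modes for some factors). Dynamics are Boolean and synchronous: all
genes update simultaneously, so every state has exactly one successor and
the attractors of the finite map — fixed points and cycles — are identified
with stable cell phenotypes. The update rule is inhibitor-dominant:

    next(x) = (OR over activators of x, vacuously true when x has
               inhibitors but no activators)  AND  NOT (OR over inhibitors)

The literature does not fix a unique Boolean function per gene, and core
membership can depend on the choice, so the rule is a strategy option
rather than a hard-coded truth. Two conventions for a gene with *no*
regulators are provided:

* `hold` — an unregulated gene keeps its value (it acts as a constant
  input). This is the default for plain attractor analysis.
* `decay` — an unregulated gene falls to 0 (expression requires an active
  regulator). This is the default *inside contextualization*
  (`PruningConfig.update_rule`), for a structural reason: under `hold`,
  deleting a gene's last regulator freezes the gene and thereby preserves
  any fixed point, so the edgeless network is perfectly consistent with any
  pair of observed states and pruning degenerates to "delete everything".
  Under `decay`, removing a needed activator has an observable dynamical
  consequence, and the planted feedback circuits become necessary to hold
  an ON state. On networks where every gene is regulated the two rules
  coincide, so all fixed-point guarantees of the synthetic generator are
  rule-independent.

States are encoded as integers (bit *i* = value of the *i*-th gene in
lexicographic order), which makes attractor representations canonical
(cycles rotate to start at the minimal code) and all outputs reproducible.

## Attractor computation

Exhaustive mode builds the full successor table (vectorized over all 2^n
codes), peels transient states by repeated in-degree-zero removal, groups
the remaining states into cycles, and assigns basins by path-following.
The default cap is 20 genes (~10^6 states, well under a minute on one CPU);
contextualized cores in this problem class are an order of magnitude
smaller. Sampled mode follows explicit start states and is the fallback
above the cap. No symbolic (BDD/SAT) machinery is used — at these sizes the
explicit map is faster and simpler to verify against a brute-force oracle.

Missing-value prediction (`complete_partial_state`) enumerates the fixed
points consistent with the known entries of a partial state; it requires at
least one known and one unknown gene.

## Circuit enumeration

Elementary circuits are enumerated with Johnson's blocking/unblocking
algorithm on the unsigned support graph (self-loops handled separately);
each node cycle is then expanded into one circuit per combination of
available hop signs, so parallel opposite-sign arcs contribute both a
positive and a negative circuit — the downstream sampler needs them
distinguished. A circuit's sign is the product of its edge signs; positive
circuits (even number of inhibitions) are the ones linked to
multistationarity. When a maximum length is requested the implementation
switches to a plain bounded DFS, because Johnson's unblocking is only
correct for unbounded search. Enumeration warns past 10^5 circuits; counts
grow combinatorially with density.

## Contextualization (EDA pruning)

Candidates are bit-masks over the prior's edge list (pruning only removes
edges; the gene set is fixed). The fitness of a candidate is the
consistency between its exhaustive attractor set and the two observed
states: for each observed state, the best per-gene agreement over
attractors (fixed points compared directly; cycles summarized by per-gene
time-average rounded to the nearer value, exact 0.5 averages earning half
credit), averaged over the two states. The score is 1.0 when both observed
states are fixed points. In principle a cyclic attractor whose rounded
profile matches an observed state everywhere without ties could also reach
agreement 1.0; this does not arise in the planted benchmarks and the
forward implication (fixed points ⇒ 1.0) always holds. Equal-consistency
candidates are ranked by parsimony (fewer edges), since pruning seeks a
minimal consistent explanation.

Each generation: sample `population_size` candidates from the per-edge keep
probabilities; rank; take the `elite_fraction` best *after deduplication*
(so a single genotype cannot monopolize the frequency estimates); estimate
(a) the fraction of elites containing each positive circuit intact and
(b) each edge's inclusion frequency; set the target probability of an edge
to `circuit_weight · max(circuit frequencies over positive circuits
containing it) + (1 − circuit_weight) · edge frequency`. An edge on no
positive circuit takes its own edge frequency as the circuit term —
otherwise required non-circuit edges (e.g. chains feeding target genes)
would be permanently capped at `1 − circuit_weight` and could never fixate.
The sampling distribution moves toward the target with `learning_rate`
(incremental PBIL-style update) and is clamped to
`[min_keep_prob, max_keep_prob]` so no edge is irreversibly lost. If the
best-ever candidate has not improved for `stagnation_restart` generations
the distribution resets to `init_keep_prob` (the best-ever is retained);
direct resampling without smoothing, deduplication and restarts was
observed to fixate on local optima long before the planted optimum on
benchmarks of ~12 edges.

Defaults: population 200, elite fraction 0.2, 80 generations (generation 0
plus 80 resampling rounds; `generations=0` evaluates only the initial
population), circuit weight 0.5, initial keep probability 0.5, clamps
[0.02, 0.98], learning rate 0.25, restart after 12 stagnant generations,
stop on a perfect score. On the planted 8-node/12-edge benchmark a run
takes well under a second; identical config + seed gives bit-identical
results.

The **stability core** of the result is the set of strongly connected
components of the best network with ≥ 2 genes or a self-loop; their union
is the feedback structure that maintains the two states.

## Omics filters

* Differential expression: direction is a pure fold-change predicate —
  `up` iff mean log2 difference ≥ log2 *k* against *both* references
  (inclusive; default *k* = 2), `down` symmetrically. A Welch two-sided
  t-test per reference accompanies each call (reported p-value = max of the
  two; a pooled-reference mode exists); significance filtering is a
  separate step so that noise-free data (where the t statistic is
  undefined) still yields the planted calls. No multiple-testing
  correction is applied by default, matching the plain p < 0.05 convention
  of threshold-based microarray screens; fold changes are differences of
  log2 means (log2 ratio of geometric means, the RMA-scale convention).
* Coverage filter: a CpG site survives only with total count ≥ `min_cov`
  (default 10, inclusive) in *every* cell type — an intersection filter, so
  promoter means are always computed on a common site set.
* Promoter level: unweighted mean frequency over surviving CpGs within
  ±`window_bp` of the TSS (default 1000, boundary inclusive, symmetric;
  an upstream-only option exists). TSS coordinates follow BED: 0-based,
  minus-strand TSS = `end − 1`. Genes with no covered site are undefined
  and excluded (not imputed) from differential calls, with a skip report.
* Differential methylation: gain/loss ≥ `delta` (default 0.05, inclusive)
  vs both references. Promoter classes: > 0.70 hypermethylated, < 0.10
  low, both strict.
* Binarization (`midrange` default): a gene is ON in a cell type iff its
  mean there strictly exceeds the midpoint of its min/max means across
  cell types; constant genes are OFF everywhere. `reference_fold` instead
  requires ≥ 2-fold above the lowest cell type.

Inclusive thresholds are implemented with a 1e-9 tolerance so that exact
boundary values (2.00-fold, 5.0% delta) are never lost to float rounding;
the strict promoter-class bounds use plain comparisons.

## Synthetic data

The generators emulate the three-lineage triplicate design.

* Expression: per-gene Gaussian baseline (mean 7, sd 1.5 on the log2
  scale, typical of normalized arrays), planted modules shifted ±2 log2
  units in the target lineage, i.i.d. Gaussian sample noise (default
  σ = 0.25, a realistic replicate scatter at which 4-fold effects are
  comfortably but not trivially detectable with 3 replicates).
* Methylation: promoters on one synthetic chromosome spaced 4 kb apart (so
  ±1 kb windows never overlap and truth labels stay unambiguous), Poisson
  CpG counts per promoter, negative-binomial coverage (mean 30,
  dispersion 5 — over-dispersed like real capture data, exercising the 10×
  filter non-trivially), plus a configurable fraction of deliberately
  under-covered sites. Class levels default to the structural-like
  (0.8/0.8/0.1) vs TF-like (0.05 everywhere) dichotomy with an
  intermediate background. `exact_counts=True` replaces binomial draws by
  rounded expectations — the methylation analogue of zero expression noise
  — for exact-recovery checks.
* Prior networks: disjoint positive activation circuits (two 3-cycles by
  default) plus peripheral chain genes, with the two target states setting
  the circuits in antiphase and chain values propagated. Spurious edges are
  sampled from candidates *verified individually* to destroy at least one
  target fixed point (inhibiting chords within a circuit, activating
  cross-circuit edges); purely cross-circuit inhibitions are not used
  because, with the circuits in antiphase, their source is OFF exactly when
  their target's circuit is ON, so they never disturb either state. The
  generator re-verifies the construction with the exhaustive attractor
  machinery and regenerates on failure.

What the generators do **not** emulate: probe-level microarray effects,
bisulfite conversion error, read-level data, correlated replicate noise,
overlapping promoters, and genuine regulatory priors with hub structure.
Passing the recovery benchmarks therefore demonstrates correctness of the
filters and the search under the stated noise models, not performance on
any particular real dataset.

## Numerical and design choices

* Floats are serialized with 6 significant digits; all outputs are TSV/SIF
  /JSON, so identical runs are byte-identical (the determinism contract is
  tested end to end, including re-running a pipeline from its manifest).
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields recorded in the run manifest.
* Midpoint ties in binarization resolve to OFF; time-average ties in
  cyclic-attractor comparison earn half credit; elite ranking ties resolve
  by edge count, then sampling order.
* The exhaustive attractor cap (20 genes) and every EDA hyperparameter are
  configuration, not constants.

## Known limitations

* Exhaustive attractor computation is exponential in gene count; the
  contextualization stage requires it and therefore inherits the cap.
* The consistency score compares attractors gene-wise and cannot express
  preferences among multiple perfectly consistent subnetworks beyond
  parsimony.
* Recovering a specific published core requires the corresponding
  proprietary interaction database as the prior; the package ships only
  the machinery and synthetic benchmarks.
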