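# Methods

This note documents the models implemented in `sirenet`, the assumptions
behind them, the parameters that matter, and the design choices made where
the design was genuinely open.

## Signed networks and file format

All networks are directed graphs with edge signs in {+1, −1}; no other edge
attributes exist at this layer (weights are a separate, later annotation).
The SIF dialect is three-column (`source relation target`), tab-preferred and
whitespace-tolerant, with `1`/`activates` and `-1`/`inhibits` accepted on
read and `1`/`-1` emitted on write — interoperable with the causal-reasoning
and logic-modeling tool family that consumes signed SIF.  Because plain SIF
cannot express isolated nodes, the writer appends a `#nodes:` comment line
listing them, and the parser reads it back; the round trip is therefore the
identity on (nodes, edges), which a property test checks over random
networks.  Dual regulation (A→B and A⊣B) occurs in curated resources and is
allowed, with a warning.

## mRNA network construction

The three construction steps are pure table joins against user-supplied TSV
snapshots of the composition, pathway-annotation and interaction databases.
No live database client exists: snapshots pin the analysis to a dataset
version, where a live query would silently drift.

Choices worth recording:

- **Complex handling.**  A complex or family node with mapped members fans
  out into one gene node per member, each inheriting all incident edges with
  signs; with zero mapped members the node and its edges are dropped.  Both
  behaviors are needed in practice (a kinase family resolves to subunits; an
  obligate heterodimer absent from the mapping must go).  Plain protein nodes
  without a mapping raise an error instead, listing every offender, with a
  per-node `droppable` override.
- **Filter order.**  Pathway filtering runs before interaction matching.
  The initial/final nodes are whitelisted through the annotation filter so
  that a stimulus absent from the pathway tables cannot disconnect the
  network trivially.
- **Path pruning.**  After interaction matching, nodes not on any directed
  path from an initial to a final node are removed (reachable-from-inputs ∩
  co-reachable-to-outputs).  The restriction is node-wise with induced edges,
  which makes it idempotent: every surviving node lies on a path made
  entirely of surviving nodes.
- **Defaults.**  Initial nodes default to the upstream stimuli BDNF, IGF1,
  HRAS/NRAS/KRAS, PIK3CA/PIK3CG and CAMK2A, final node EIF4E — the boundary
  of the translation-control cascade this package was built around; both are
  plain parameters.

## Expression preprocessing and differential expression

Quality control keeps nuclei with ≥ 500 expressed genes (inclusive) and a
flagged-gene (mitochondrial/ribosomal) UMI fraction strictly below 5 %.
Normalization is total-count scaling to `scale` (default 10⁴, the common
single-cell convention) followed by `log(1+x)` (natural log); cells with zero
totals stay zero.

Differential expression is a per-gene two-sided Welch t-test on the
log-normalized values, case vs. control within one cell type; the reported
log2FC is the difference of group means on the log scale.  An ε = 10⁻⁹ floor
on the squared standard error guards zero-variance genes (the
Welch–Satterthwaite df falls back to the pooled df when both variances
vanish); at least two cells per condition are required.  A moderated
(empirical-Bayes) test would shrink variances and change p-values slightly;
the plain Welch test was chosen because the pipeline's behavior is driven by
the thresholds, not the moderation, and it keeps the statistical model fully
explicit.

DEG calling uses strict inequalities — |log2FC| > 0.3 **and** p < 0.05 — and
assigns direction sign(log2FC), else 0.  No multiple-testing correction is
applied by default (the raw-p filter is the operating convention here);
Benjamini–Hochberg is available behind `correct="bh"`.  Discretization
restricts directions to network nodes, with absent genes at 0 — this ternary
vector is exactly what the ILP consumes.

The two-group Wilcoxon helper uses exact enumeration for untied samples up to
n = 50 per group and the mid-rank normal approximation otherwise, returning
p = 1 for degenerate all-equal input.

## Causal subnetwork inference (ILP)

The objective is a weighted sum of measurement mismatch (α per unit of
|x_j − c_j|) and node activity (β per active sign variable).  Defaults
α = 1, β = 0.1 (ratio 0.1, inside the recommended 0.03–0.5 band; a ratio
outside the band warns).  The constraint set — exclusive decomposition,
cause-needed, sign-consistent propagation — follows the established
causal-reasoning ILP family; the objective alone does not determine it, so
this is the module's largest inferred component and is mirrored exactly in
the brute-force oracle used for verification.

- **Input semantics.**  An input with direction v may take state 0 or v: it
  is an available cause exempt from the cause-needed constraint, not a forced
  state, and it pays β when active.  This is the only reading under which an
  upregulated measurement behind a pure inhibitor is left unexplained at cost
  α (empty network) rather than α + β.
- **Mismatch linearization.**  With c fixed in {−1, 0, +1} and binary sign
  variables, |x − c| is itself linear (e.g. 1 − x⁺ + x⁻ for c = +1), so no
  auxiliary variables are needed.
- **Cycles.**  Permitted, with no loop-breaking constraints: two nodes in a
  positive loop may sustain each other.  The enumeration oracle uses the same
  local feasibility rule, so the two routes agree by construction on this
  point and are compared on 100 random instances in the tests.
- **Used edges.**  Reported as every sign-consistent edge between two active
  nodes, recomputed from the optimal states.  This is deterministic, whereas
  the solver's edge variables are free to take several equivalent values at
  the optimum.
- **Multiplicity.**  Alternate optima exist in general; the solver's optimum
  is reported (HiGHS is deterministic for a fixed instance), and the oracle
  returns the full optimal set for small instances.

Solved with `scipy.optimize.milp` (HiGHS).  One ILP is solved per cell type;
shared modules across cell types are extracted afterwards by intersecting
node states and used-edge sets, rather than by a joint multi-cell-type ILP,
matching the per-cell-type reading of the inference problem.

## Probabilistic logic model (DBN)

The update propagates expected values (mean field); the full state
distribution is never sampled.  Closure holds structurally: the activation
factor is a convex combination of [0,1] values, the inhibition factor lies in
[0,1] because inhibiting weights sum to at most 1.

- **Inhibitor-only nodes** use basal activation 1 in the first factor;
  otherwise they would be identically 0 and unfittable.
- **Parentless nodes** keep their current value (they are either clamped
  inputs or free initial conditions).
- **Steady state** is synchronous iteration until max |ΔX| < 10⁻⁶ (at most
  1000 iterations); acyclic networks converge exactly within longest-path
  iterations, cyclic ones may oscillate and return a non-converged flag.
- **Two-condition semantics.**  Control and case are two clamped steady-state
  problems sharing one weight set — the steady-state convention of the logic
  modeling family this extends.  A one-step-transition mode (case = one
  synchronous update from the control state) is available via
  `transition_mode="one_step"`.
- **Constraint handling.**  Weights are optimized through an unconstrained
  parameterization: per-target softmax over activating logits (sum exactly
  1), softmax over (l+1) inhibiting logits whose slack entry absorbs the
  unassigned inhibition mass (sum ≤ 1).  Invariants hold by construction at
  every iterate; no projection step can fail.  A single activator is forced
  to weight 1 and contributes no parameter.
- **Optimization.**  Multi-start L-BFGS-B with finite-difference gradients,
  default 20 restarts, objective tolerance 10⁻⁸, max 2000 iterations.
  Restart seeds are spawned from the master seed by index, so the best-of-n
  objective is nonincreasing in n with the same master seed.  Node values
  initialize from N(0.5, 0.1) truncated to [0, 1], fixed per restart so each
  restart's objective is deterministic.

Targets for fitting real data are per-condition mean expression min–max
scaled to [0, 1] across the two conditions (equal means map to 0.5).  For
simulation-based recovery checks the raw per-condition means are used
directly (`condition_means`): the simulator already emits activities on
[0, 1], and the min–max rescale deliberately discards the magnitude
information that recovery would be measured against.

## Sub-pathway scoring

SSP multiplies, over the nodes after the route's input, the on-path incoming
edge weight, ×100.  The per-node factor is the *single* on-path weight, not
the node's full activating fan-in sum: with fan-in sums every activated
node's factor would be 1 by the total-probability constraint and SSP would
be uninformative; a `full_fan_in` flag provides the sum-based variant.  AISP
scales each factor by the upstream node's log2 fold change, absolute value by
default (the index measures dysregulation magnitude; signed mode is a flag).
A missing fold change counts as 0 — no dysregulation evidence extinguishes
the route.  Pattern calling is the edge-weight rule: a route is active when
every edge on it has weight strictly above the threshold (default 0.2); it is
monotone in the threshold.

The packaged core network is the first neighborhood of the EIF4EBP1–EIF4E
pair: 6 nodes, 7 edges, with the four canonical routes I–IV.  In the 6-node
network alone, singleton activators are forced to weight 1 by total
probability; the full network gives those nodes additional activators, so
tests and the acceptance script attach an auxiliary activator to absorb the
remaining activating mass when an on-path activating weight below 1 is
required.

## Evidence-channel combination

The combination is the published prior-corrected noisy-OR: subtract the
random-expectation prior p = 0.041 from each nonzero channel (rescaled by
1 − p, floored at 0), take 1 − ∏(1 − s′), restore the prior once, cap at
0.999.  The formula was verified against all homology-free rows of the
packaged evidence table before adoption (agreement within ±0.001; the capped
rows confirm the 0.999 ceiling).  A single channel exactly at the prior
contributes nothing, leaving the restored prior itself (0.041) as the floor
value.  Pairs with a nonzero homology channel are not recomputable from the
per-channel table — homology discounts the coexpression and text-mining
channels in a way the table does not record — so validation falls back to
their printed combined scores.  Matching of network edges to score rows is
undirected and sign-blind: reliability concerns whether an interaction
exists, not its direction.

## Synthetic data

The simulator emulates a two-condition, multi-cell-type experiment at the
point where the models consume it: post-normalization activities on [0, 1].
Per condition, network-gene means are the quasi-steady state of a known
weighted network under that condition's clamps; cell values add Gaussian
noise (default sd 0.05) truncated at 0; filler genes are drawn identically in
both conditions.  One master seed spawns per-component child sequences.

Default study conditions used in the tests: 100 cells per condition per cell
type, noise sd 0.05 for detection checks and 0.01 for weight recovery,
control/case input clamps 0.2/0.9.  Problem sizes for the heavier checks:
ILP-vs-oracle equivalence on 100 random networks of up to 8 nodes and 12
edges; closure on 10⁵ random weight/state draws; weight recovery on the
3-edge fan-in motif over 30 replicates with 20 restarts each; end-to-end
chain recovery over 10 simulation seeds; null calibration on 1000 genes with
50 cells per group.

What passing does and does not show: the generator has no dropout, no count
noise, no batch structure and no cell-type heterogeneity beyond labels, so
the tests demonstrate correctness of the estimators under their own model
assumptions — not robustness to the full messiness of real single-nucleus
data.

## Known limitations

- The ILP's constraint set is the standard causal-reasoning one, but other
  constraint families (e.g. acyclicity-enforced variants) would yield
  different subnetworks on cyclic networks; an optional loop-breaking layer
  is deliberately not enabled by default because the objective contains no
  loop terms.
- Finite-difference gradients make fitting cost scale linearly in the number
  of free weights; large networks would benefit from analytic gradients.
- Weight identifiability depends on the clamp design; with a single
  measured node and two conditions only two degrees of freedom are
  identified.  The recovery tests use identifiable designs on purpose.
- The AISP definition leaves open which node's fold change scales a step and
  how signs combine; both choices are exposed as flags, with
  upstream-node/absolute as defaults.
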