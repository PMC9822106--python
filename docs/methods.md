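# Methods

This note documents the models implemented in `icnlearn`, the parameters
that matter, the synthetic-data conditions under which the package is
validated, and the numerical and design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Causal models and separation

The causal currency is the discrete **causal Bayesian network** (CBN): a
DAG over variables plus one conditional probability table per node, the
joint factorising as ∏ᵢ P(Xᵢ | pa(Xᵢ)). Conditional independence is read
off the structure with d-separation. When some variables are unmeasured,
the measured margin is represented by a **maximal ancestral graph**
(MAG): `X --> Y` for causation, `X <-> Y` for latent confounding, with
the ancestrality constraints (no directed cycle; no bidirected edge
between ancestrally related nodes) and maximality (every non-adjacent
pair is m-separable). Selection bias is assumed absent throughout, so
undirected (tail–tail) edges never occur and the corresponding
orientation rules are omitted.

Both d- and m-separation are implemented by one reachability walk over
(node, entered-with-arrowhead) states: an intermediate node passes the
walk if it is a non-collider outside the conditioning set, or a collider
in the ancestors of the conditioning set. The test suite checks this
implementation against a literal path-enumeration oracle on every graph
family used.

**Latent projection** maps a DAG with a latent set onto its measured
MAG. Adjacency is decided by the inducing-path criterion (every
non-endpoint vertex latent or a collider, every collider an ancestor of
an endpoint), which guarantees maximality by construction; marks follow
ancestry in the generating DAG.

**Equivalence classes.** A PAG summarises the Markov equivalence class
of a MAG: invariant tails/arrows are kept, class-variant endpoints
become circles. Two independent routes compute classes: the product
route runs FCI with a perfect separation oracle; the brute-force route
(`equivalence_class` / `brute_force_pag`) enumerates all orientations of
the skeleton over {-->, <--, <->} with ancestrality pruning and keeps
those whose unshielded-collider pattern and full m-separation
fingerprint match. The two routes are compared on 200 random DAGs (5–7
nodes, 0–2 planted latent confounders) in both the test suite and the
acceptance script.

## Structure search

**GES** follows Chickering's two-phase greedy equivalence search with
Insert/Delete operators, validity conditions (clique and blocking
checks), and conversion PDAG → DAG (Dor–Tarsi) → CPDAG (v-structures
plus Meek closure) after each step. Scorers only need local score
differences, which lets a d-separation oracle act as a scorer (+1 for
dependence, −1 for independence) alongside the data scorers (discrete
BIC, Gaussian BIC). Ties break lexicographically, making the search
deterministic.

**FCI** runs a PC-style adjacency search with growing conditioning sets
drawn from current adjacencies, a possible-d-sep removal stage, collider
orientation from separating sets, and Zhang's orientation rules R1–R4
and R8–R10 (R5–R7 concern selection bias and are omitted). Separating
sets used for orientation are chosen by the **max-p rule**: among all
separating candidates, the one with the largest p-value. With a perfect
oracle this is equivalent to the first separator found; on finite data
it protects collider orientation from barely-over-threshold independence
verdicts on weak long-range dependences, a failure mode we observed on
planted cohorts (a marginal two-hop dependence with p just above α would
otherwise certify a false collider).

**GFCI** feeds the GES skeleton to the FCI phase as its initial
adjacency set; FCI may delete from it but never adds. With oracle score
and test, GFCI's output equals the brute-force class summary on the full
200-graph suite.

Prior knowledge enters as forbidden pairs (never adjacent, in any
phase) and required edges (adjacency never removed; orientation remains
data driven).

## Conditional-independence tests and scores

* **G² test** (discrete): likelihood-ratio statistic against chi-square
  with (|X|−1)(|Y|−1)·∏|Zᵢ| degrees of freedom; strata with empty
  margins are dropped from the dof; a fully degenerate table returns
  independence with a flag. Type-I error is verified by simulation to
  track α.
* **Fisher-z** (continuous): partial correlation from the inverse
  correlation matrix, statistic √(n−|Z|−3)·atanh(r). The population
  pipeline default is the discrete stack (scores are discretized before
  search); the continuous stack is provided and tested because either
  can be used on score matrices directly.
* **Context-specific test**: restrict rows to Z = z and run the marginal
  G² on the subset. The restricted test falls back to the population
  test (with a flag) when it cannot carry information: fewer than
  max(30, 10% of n) rows, or when the context effectively pins X or Y
  (fewer than 30 off-modal rows). The absolute 30-row floor alone proved
  insufficient at cohort scale — a 224-row context produced a false
  independence verdict that deleted a planted edge, and a context that
  nearly fixes a variable (641/644 rows at one level in one observed
  case) can never attest to its dependences. α defaults to 0.01
  everywhere and is configurable.
* **Discrete BIC**: log-likelihood − pd·(k/2)·ln n with
  k = (arity−1)·∏(parent arities) and penalty discount pd = 1.0 by
  default; exactly decomposable.
* **Instance-specific family score**: rows whose candidate-parent
  configuration equals the instance's configuration form a dedicated
  block scored as one BDeu-smoothed multinomial (equivalent sample size
  1); the remaining rows are scored at the granularity of a fixed
  reference parent superset (the population parents during iGES
  pruning); a BIC-style penalty of pd·(arity−1)/2·ln n is charged per
  realized block. Candidate parent sets therefore differ only in how far
  the instance's context is merged, so removing a parent pays off
  exactly when the node is independent of it *within the instance's
  context*. A literal two-block rule that re-scores the complement at
  candidate granularity cannot prefer the pruned parent set — dropping a
  context-irrelevant parent would lose likelihood in every other
  context — which is why the fixed reference granularity is used. An
  instance context matching zero rows reduces to the population BIC.

## Individualized search

iGES runs population GES, takes the deterministic consistent extension
of the CPDAG as reference DAG, and greedily prunes each node's parents:
at each step the removal with the largest instance-score gain is
applied; re-insertion is never attempted. A node whose full population
parent context matches no rows is left untouched. iGFCI then runs the
FCI phase with the context-specific test, conditioning values read from
the instance, starting from the iGES adjacencies. On context-free
generators the instance-specific output coincides with the population
output; on cohorts with planted context-specific structure the
instance's PAG drops exactly the context-irrelevant adjacencies.

## Bootstrap consensus

Cohort level: 50 bootstrap resamples of 90% of the tumors drawn with
replacement; a directed edge is retained iff its frequency is strictly
above 0.2 (an inclusive flag is available, since "at least" and "more
than" both appear as conventions); if both orientations of a pair pass
the threshold the pair is conflicted and neither is entered. Tumor
level: 20 resamples at 90%, retention at ≥ 3 of 20 ("more than two").
Only fully directed (tail–arrow) edges count toward retention; `o->` and
`<->` endpoints are tallied in the provenance but never retained, so an
ICN is a set of unambiguous causal claims. Per-bootstrap seeds derive
from the master seed via a counter (a spawned seed sequence) and appear
in the manifest.

## Downstream analytics

**Edge vectors and clustering.** Tumors become binary vectors over the
sorted union of ICN edges. Consensus clustering is Monti-style:
repeated 80% item subsampling, agglomerative average-linkage clustering,
co-clustering frequencies among co-sampled pairs. The binary distance is
**Hamming** (matching): for subtype patterns the absence of an edge is
exactly as informative as its presence, and Jaccard — which ignores
shared absences — collapses whenever one subtype's networks are sparse
(two nearly empty vectors share no 1s and look maximally distant).
Euclidean distance is used for continuous score matrices; Jaccard
remains available behind the metric flag. The number of clusters is
chosen by the CDF delta-area criterion: area under the empirical CDF of
the consensus values per k, relative increase Δ(k), and k\* = the
largest k with Δ(k) above a threshold (default 0.1). The concrete rule
was fixed by validating on planted partitions (well-separated Gaussian
blocks select k = 2; four planted binary blocks select k = 4); the
criterion as usually described — stop where the curve flattens — leaves
the concrete cutoff open.

**Markov boundaries.** For a target module, the boundary is parents ∪
children ∪ other parents of children over the fully directed consensus
edges. Predictive validation: k-fold (default 10) cross-validated ridge
regression with internal penalty selection, reported as the squared
Pearson correlation between out-of-fold predictions and observations.
On linear-Gaussian cohorts the boundary predictors match the
all-predictors R² and dominate random same-size predictor sets.

**Correlation screen.** Pearson correlations are computed for
inter-category module pairs only; intra-category pairs are excluded
because co-expression within one cell population would confound the
communication signal.

## Enrichment scoring

GSVA settings follow the method's published defaults: Gaussian-kernel
ECDF with bandwidth sd/4 per gene (continuous expression), τ = 1
weighting of the symmetric rank statistic |p/2 − rank|, and the
magnitude-difference ("max.diff") enrichment statistic; all are exposed
as flags. Gene matching is exact string match; unmatched signature genes
are logged and skipped, and a module with no matched genes is an error.
Scores are expected to fall in roughly −3..3 — a soft check that only
warns. Discretization uses inclusive nearest-rank quantiles with ties to
the lower bracket, so n divisible by 4 with distinct values splits
exactly 25/50/25; a constant column maps to the middle level with a
warning.

## Synthetic-data conditions

The generators define the conditions under which the pipeline is
validated; passing tests show recovery under these conditions, not on
real tumors.

* `random_dag` / `random_cbn`: Erdős–Rényi DAGs over a random
  topological order; Dirichlet CPT rows redrawn until every parent level
  shifts the child by total variation ≥ 0.15 (the faithfulness guard;
  small enough to be realistic, large enough for desk-scale power).
* `mixture_cbn`: child distributions as additive per-parent mixtures
  (0.9/m weight per parent, 0.1 uniform floor), giving every parent a
  guaranteed effect in every context even for 3+ parents, where a
  row-wise rejection guard becomes infeasible.
* `plant_latents`: root confounders with two measured children each.
* `csi_cohort`: the pooled-cohort test bed. The backbone is built from
  one collider motif (w₁, w₂ → u → v) per discriminating edge, chained
  head to tail — the collider at u makes the u → v orientation
  identifiable from observational data, which a consensus of *directed*
  edges requires — plus background children up to the requested node
  count. Each subtype keeps or drops each discriminating edge according
  to its index bits (cycled over the edges so subtypes differ in several
  edges when more edges than bits are requested); dropping u → v
  replaces v's CPT, in that subtype's rows, by the parent-averaged
  distribution shrunk halfway to uniform — still independent of u and
  identical across all subtypes lacking the edge, but distinguishable
  enough from the intact family that the subtype indicator's own
  influence is detectable, which the instance-specific pruning relies
  on. The subtype indicator is a measured variable, making the planted
  heterogeneity literally context-specific structure. Default effect
  scale 0.30.
* `synth_bulk_cohort`: standard-normal module activities; module genes
  load with weights 1.0 → 0.5 plus Gaussian noise (default sd 0.5);
  background genes are pure noise. It emulates signature-driven bulk
  expression, not count noise, dropout, or library-size variation.
* `linear_gaussian_cohort`: linear SEM with ±[0.6, 1.2] weights for the
  Markov-boundary validation.

Problem sizes used in the validation runs — 5–7 node graphs for the
200-graph oracle suite, 8–16 node cohorts with 2,000 tumors per subtype
(1,500 for the four-subtype clustering run), 200-sample bulk cohorts —
were chosen as the smallest scales at which the statistical effects are
comfortably identifiable.

## Known limitations

* iGFCI operates on discrete variables only; mixed continuous/discrete
  context tests are out of scope.
* The context-specific test trades power for specificity: contexts
  covering under 10% of the cohort fall back to population verdicts, so
  structure specific to very rare contexts is invisible at desk scale.
* Brute-force enumeration (the oracle) is exponential in edge count and
  is intended for graphs of at most ~8 nodes.
* The greedy searches inherit the usual local-optimum caveats of GES;
  determinism is guaranteed, global optimality is not.
* Consensus clustering's delta-area rule, like all its published
  variants, is a heuristic; the full area/delta curves are returned so a
  user can inspect the elbow directly.
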