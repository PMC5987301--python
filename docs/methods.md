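# Methods

## Model class and semantics

An input–output asynchronous Boolean network (IO ABN) is a triple of maps
over Boolean vectors: an update function `f : {0,1}^p × {0,1}^n → {0,1}^n`,
an output function `h : {0,1}^n → {0,1}^q` (outputs read state variables
only, never inputs), and the asynchronous update discipline: from state
`x` under input `u`, every coordinate `i` with `f_i(u,x) ≠ x_i` yields one
successor `x ⊕ e_i`. The dynamics under a fixed input are therefore a
digraph with `2^n` vertices and at most `n·2^n` arcs, stored sparsely
(boolean CSR); rule evaluation is vectorized over the whole state space,
so building a transition graph is a handful of numpy passes rather than a
per-state loop. Synchronous or mixed schedules and multivalued logic are
out of scope.

States are indexed lexicographically with the left-most (first-declared)
variable most significant; internally indices are 0-based, every printed
report uses the 1-based convention plus the bit string. Enumerating a
state space above `n = 24` (configurable cap) is refused with a resource
error rather than attempted.

## Module analysis

Attractors are terminal SCCs of the per-input transition graph, computed
with `scipy.sparse.csgraph.connected_components(connection="strong")`;
components are relabelled by ascending minimal state so every report and
every downstream enumeration is deterministic. Each attractor is cut by
output value into *same-output attractor sets* `A_{uα}^i`, enumerated per
input profile (ascending), then per attractor (ascending minimal state),
then per output value (ascending) — the flat index this induces is the
running superscript used in printed labels such as `A112` (in labels,
decimal 1 = logical 0). Reachability closures are plain sparse frontier
BFS; "basin" always means the *weak* basin (backward closure: some
trajectory reaches the target), because under asynchronous dynamics the
strict basin is almost always empty and weak basins of different
attractors may legitimately overlap.

## Interconnection

A wiring maps every input of every module to an output of another module
(identity interconnection; a non-identity glue function can always be
expressed as an explicit intermediate module, which is why it is not a
separate feature). Two equivalent constructions of the closed network are
implemented and tested against each other: substitution of output
expressions into input symbols (rule composition), and the gated
Kronecker composition of the per-input graphs with diagonal
output-indicator matrices. The composite state index is module-major
(first module most significant), which makes the Kronecker formula an
adjacency identity rather than a permutation of one. For more than two
modules the Kronecker term of the moving module is taken over all output
assignments of the fixed modules; for full graphs of three or more
modules the rule-composition route is used directly.

## Asymptotic graph

Vertices are all products of one same-output attractor set per module.
For an arc, exactly one module moves: its new input profile is read off
the wired outputs of the other modules' labels, and the arc exists iff
the forward closure of the moving set (memoized per module, input and
source set — the dominant cost of the construction) meets the target set
in that input's graph. Self-arcs (including a set re-reaching itself
under a changed input) are recorded but ignored for SCC purposes; they
never affect terminality. `π` expands vertices back to composite states
with deduplication, because attractor sets of one module under different
inputs may coincide as state sets.

Terminal SCCs of this graph locate every attractor of the interconnection
(tested as a zero-miss property over hundreds of random schemes); they
may also contain rare spurious ones. A singleton terminal SCC is
certified non-spurious without any oracle; a non-singleton one is matched
against the attractors of the full graph (small systems) or of the cross
graph via `π(R) ⊆ Q`, and reported as `undecided` — never silently
guessed — when no oracle is available. The `accuracy` of a matched
prediction is `|π(R)|/|Q| ∈ (0,1]`.

## Cross graph

Per module, each state is labelled with its tuple of per-input SCC ids;
grouping equal tuples gives the coarsest partition finer than every
per-input SCC decomposition (the meet in the partition lattice, computed
in one `np.unique(axis=0)` pass instead of pairwise lattice operations),
and blocks are further cut by output value. Per-input graphs are
projected onto these blocks (inter-block arcs only; intra-block arcs are
SCC-internal by construction and carry no condensation information), and
the same Kronecker composition used for full graphs is applied at block
level. The SCC decomposition of the result is in bijection with that of
the full graph and its terminal SCCs expand to exactly the attractors —
the package's exactness oracle. Expansion of very large attractors is
optional (off above a size threshold) since only sizes are usually
needed; distinct cross vertices expand to disjoint state sets, so sizes
are products summed without materialization.

## Probabilistic layer

Incidence weights over a module's L same-output attractor sets come in
four modes: `uniform` (1/L), `uniform_per_input` (uniform within each
input profile, averaged over profiles), `basin` (weak-basin sizes
normalized over all L sets), and `basin_per_input` (weak-basin sizes
normalized within each input profile, averaged over profiles), plus
explicit user vectors validated to sum to one (tolerance 1e-9). The two
per-input variants exist because incidence mass can meaningfully be
assigned either to the module's sets at large or conditionally on the
operating input; both are legitimate priors and the shipped reproductions
exercise both (the yeast tables pin the per-input readings, the mammalian
weights the global one).

A vertex of the asymptotic graph first chooses which module updates. The
effective probability `ϱ̄_A` is 0 if no outgoing non-self arc changes the
first module's set, 1 if none changes the second module's, `ϱ_A`
otherwise; a vertex with no outgoing non-self arc becomes absorbing with
a self-loop of probability 1. The chosen module then switches to a
reachable attractor set `k` with probability `w_k / Σ_{j∈J} w_j` over the
reachable sets J of the new input profile — J is defined by set-level
reachability (some state of the source set), mirroring the arc rule.
Self-loops produced when the source set is itself reachable are kept;
they are harmless to absorption. Rows sum to one by construction and this
is asserted throughout.

Condensing over the SCCs of the asymptotic graph gives an absorbing
chain: inter-component probabilities are summed and each transient row is
then renormalized to one (raw sums over multi-vertex components are not
stochastic; for singleton components the renormalization is a no-op).
Components are ordered transient-first into the canonical form
`[[Q,R],[0,I_r]]`; `(I−Q)X = R` is solved densely below 2,000 transient
components and sparsely above (identical results to tolerance). Relative
probabilities combine each absorbing component's own incidence mass with
the absorbed transient mass and sum to one (asserted at 1e-9). The update
probability must be strictly inside (0,1) when a transient component's
only exits would otherwise get zero mass; this is detected and reported.

## Random network generator

The generator emulates random regulatory modules with tunable mean
connectivity `K_mean ∈ [1, n+p]`: each output depends on one uniformly
chosen state variable; each update rule draws `k_i ~ Binomial(n+p,
K_mean/(n+p))` (so `k_i = 0`, a constant rule, is possible and the
constant is drawn uniformly — the natural completion of the stated
range); rows draw uniform `k_i`-subsets, and the whole subset assignment
is regenerated until every input column is used (regenerating all rows,
not only offending ones, since partial regeneration changes the
distribution). If the drawn `k_i` cannot cover the inputs at all, or
after 1,000 failed subset draws, the `k_i` are redrawn — without this
guard the prescribed loop cannot terminate on unlucky draws. Functions
are then sampled uniformly among those depending essentially on *all*
declared arguments: by table enumeration up to arity 4 (65,536 tables),
by rejection above (degenerate tables are exponentially rare there), so
the realized essential-dependency matrix equals the drawn wiring diagram
exactly (tested). Outputs are identity or negation, equiprobably.

What this emulates — and does not: random NK-style modules probe the
*method* (no missed attractors, exact cross-graph recovery, stochastic
row sums) across connectivity regimes; they do not emulate the degree
heterogeneity, canalizing functions or signed monotone structure of real
regulatory networks, so passing the random suite says nothing about any
particular biological network beyond the theorems it instantiates. The
shipped biological models cover that side.

The comparison harness records, per random interconnection: graph sizes,
attractor counts, spurious counts, accuracies and per-stage wall-clock
times (reported for information; no expected durations exist in the
package). The default test suite runs it at 200 schemes with modules of
dimension at most 5 — sizes chosen so the brute-force full-graph oracle
stays exact — and a 100-replicate (10,2,2) configuration remains an
opt-in script via the CLI.

## Shipped models

The catalog holds the toy worked examples, the seven-variable circadian
clock (input: transcription shutdown at mitosis; output BMAL), the
eight-variable yeast cell-size module (chaperone competition for Ydj1,
output folded Cln3), the ten-variable mammalian cell-cycle module
(Faure et al. 2006 logical rules with cyclin E additionally gated by the
clock input) and the eleven-variable budding-yeast cell-cycle module
(Li et al. 2004 threshold network written out as Boolean rules: equal
±1 weights, threshold at zero, value kept on zero net input except for
the five self-degrading nodes, START driven by the external input). The
two `example4_*` modules are synthetic constructions (marked so in their
files) that realize the documented two-block / all-singleton meet
partition structure exactly. Every model is validated in the test suite
against its documented attractor inventory (state strings, sizes, output
cuts) — for the yeast module this pins all eleven fixed points and the
four-decimal basin-weight table, which uniquely constrains the dynamics
for every quantity the package computes from it.

## Numerical and degeneracy choices

* Determinism everywhere: component and block orders follow minimal
  state indices; all randomness flows through one seeded
  `numpy.random.Generator`.
* Hand-written models may contain degenerate rules (a declared variable
  that is not essential); only the random generator enforces
  non-degeneracy, since biological rule sets legitimately contain
  constant-like dependencies.
* Rule syntax is deliberately minimal (`!`, `&`, `|`, literals,
  parentheses); richer operators are rejected at parse time.
* Conjunctions/disjunctions are kept flat internally so that structural
  equality coincides with associativity, making parse → serialize →
  parse the identity.
* `(I−Q)` singularity cannot occur for a proper absorbing chain and is
  asserted with diagnostics rather than handled.

## Known limitations

* The transient block count of the mammalian cell-cycle module — and
  hence the cross-graph vertex count of the mammalian interconnection —
  depends on rule details that leave no trace in any attractor-level
  quantity; with the rules shipped here the output-refined meet has 448
  blocks (cross graph 57,344 vertices). All attractor-level mammalian
  results (18-vertex asymptotic graph, attractor sizes 120 and 13,552,
  relative probabilities 1/3 and 2/3 independent of `ϱ_A`) are exact.
* The probabilistic layer covers two-module schemes; the asymptotic and
  cross graphs themselves generalize to any module count.
* Spuriousness certificates beyond the singleton rule are out of scope;
  a non-singleton terminal SCC needs a cross- or full-graph oracle.
* Hierarchical-transition-graph compression of the cross graph and
  stable-motif-style analysis of very large modules are not implemented.
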