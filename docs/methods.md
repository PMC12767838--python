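# Methods

This note records the models implemented in `grnlogic`, the conventions
and numerical choices behind them, and what the test suite does and does
not establish.

## Rule representation

A rule is a complete mapping table over the alphabet `M = {0..m-1}`:
arity `k`, base `m`, and `m^k` outputs. Row order is mixed-radix with the
**first** variable most significant: `index(x) = Σ_i x_i · m^(k-i)`.
Nothing in the common text formats pins this down, so the convention is
fixed once here and enforced by every parser and writer (coordinate rows
in the truth-table format are validated against it). Variable indices in
all public APIs are 1-based, matching how layers and weights are usually
written in the modelling literature.

External-input genes (referenced but never defined) carry no rule; they
hold their state during simulation and are never clamped, pruned or
counted as core.

## Canalization peeling

`nested_canalization` peels greedily: at each layer, the canalizing value
set of an unused variable is the maximal set of values that force the
output on the current residual domain; the layer variable is the one with
the largest such set, ties broken by lowest index. Canalizing sets are
kept proper subsets of `M`: when *every* value of a variable is forcing
(the residual depends on that variable alone), the largest value is
dropped and its branch lands in the residual, which then either peels
further or ends constant. For `m = 2` this reproduces the classical
nested-canalizing chain — singleton canalizing/canalized values ending in
a constant residual — and the five-layer (x2, x5, x3, x1, x4) chain of
the ADD worked example. The returned object carries the residual
(constant or table) so the peel can be replayed exactly; the round trip
is property-tested.

The subset search is exhaustive over values per variable, which is cheap
for `m ≤ 4`; the number of candidate subsets grows as `2^m`, a documented
practical limit.

## Quine–McCluskey minimization

Implicant positions hold a single value or a full wildcard — partial
value subsets are not implicant positions, which keeps the lattice finite
and matches the assertion form `{r: C}` of multi-valued DNF. Merging is
the m-way generalization of the classic pairwise rule: m implicants
identical except at one position whose values jointly exhaust `M`
collapse to a wildcard. Level-by-level merging from the minterms
generates every homogeneous pattern, and anything that ever merges is
non-prime; this is checked exhaustively against a brute-force
maximal-pattern search for all 256 Boolean rules at `k = 3` and for
random ternary rules.

Covers are essential implicants (sole coverers of some minterm) plus an
exact minimum completion found by branch-and-bound set cover, with
deterministic tie-breaks: fewest implicants, then most total wildcards,
then lexicographic pattern order. Exact search is used up to 24 candidate
implicants; beyond that a greedy completion is used and a warning issued
(minimum-DNF search is NP-complete, so some cutoff is unavoidable).
Downstream measures always use these deterministic covers `Q_s` —
essential-only covers can be incomplete, so the completion is part of the
definition here.

Printed clause order is a house rule chosen to match the worked example's
published expression: descending literal count, then ascending
lexicographic with the wildcard sorting before values. Simplified tables
list outputs in descending order with the same clause order inside each.

## Order parameters

Sensitivity and per-edge activity are computed exactly (Python
`Fraction`s) by complete enumeration; report display rounds to 4 decimal
places but internal values stay rational.

Effectiveness averaging: when a state is covered by several cover
implicants, its contribution is averaged over those implicants. This
reading reproduces all five published edge values of the ADD example
(exactly 7/48, 73/96, 5/16, 7/48, 7/16, summing to `E_input = 173/96`)
and guarantees `E_input = Σ_i E_i` identically; the alternative reading
(averaging over all of `Q_s` rather than the covering implicants) does
not reproduce them.

## Polynomial and threshold conversions

Boolean rules get the unique real multilinear interpolating polynomial
via a Möbius (inclusion–exclusion) transform over subcubes, with integer
coefficients. Multi-valued rules get a Reed–Muller-style algebraic normal
form over `Z_m`: per-variable exponents up to `m-1`, coefficients from
per-axis inverse-Vandermonde transforms, terms combined with the
generalized XOR (addition mod m). The two branches are distinct algebras
and are kept separate deliberately. Unique interpolation over `Z_m`
requires `m` prime; composite bases raise an informative error rather
than returning a non-unique expansion.

Threshold and dominant witnesses are posed as linear feasibility
problems: strict separation is encoded with a margin of 1, the float LP
solution (HiGHS) is scaled by 10^6 and rounded to exact rationals, and
the witness is verified by re-evaluating the entire table. The margin
makes the rounding safe by construction; a solver failure is reported as
an `UNDETERMINED` sentinel, distinct from proven infeasibility. The step
function is parameterized by `m-1` strictly increasing cut points with
`Θ(z) = #{t_j < z}`. Threshold search proceeds order by order
(interaction monomials are products of distinct variables up to the
requested order); for Boolean rules an order-`k` form always exists
because the interpolating polynomial itself is a valid score, but for
`m > 2` multilinear monomials cannot interpolate every table, so `None`
at `max_order = k` is a legitimate verdict.

Boolean-to-multi-valued embedding maps the two Boolean levels to chosen
target levels and binarizes intermediate input values to the nearer
corner, with midpoints going down ("floor") by default.

## Networks

Expression-built tables order regulators by first appearance in the
expression text; influence-free regulators (e.g. `B = X or not X`) are
kept, because dropping them is a reduction step, not a parsing step. The
ADD fixture hard-codes the alphabetical input order in which the worked
example states its numbers. The threshold-model parser (activation /
repression edge lists) switches a gene on when active activators
outnumber active repressors; ties go to 0 by default, with an optional
retain-state mode that adds the gene itself as an input (common in
cell-cycle threshold models). The mode is recorded in network metadata.
An arity cap of 16 (override available) guards against accidental
`2^k` table blow-ups when parsing.

## Reduction pipeline

Clamping fixes genes whose rule is constant or whose regulators are all
fixed, substituting values downstream (arity shrinks, new constants can
appear, iterate to fixed point). Pruning removes, round by round, genes
that regulate nothing non-static; round-1 removals are terminal genes,
later removals relay genes. A self-regulating gene is a length-1
feedback loop and survives pruning. FFL decoupling substitutes an
intermediary's rule into a target (`f_S(P, f_I(P))`) when the
intermediary's regulators lie inside `P`, the target is regulated by a
subset of `P ∪ {I}`, shares at least one direct predecessor edge with the
intermediary, and is not itself a predecessor (that last condition keeps
feedback pairs intact — substituting through a cycle would alter the
dynamics, not simplify them). Influence-free regulators of the rewritten
target are then dropped. Iterating clamp/prune/decouple to a fixed point
yields the dynamic core; genes removed once decoupling starts rewiring
are labelled peripheral, first-pass removals keep their static /
terminal / relay labels. Both pipelines are idempotent by construction
and by test. The generalized predecessor scan is bounded at `|P| ≤ 6`
for tractability.

## Feedback loops

SCC decomposition plus Johnson's algorithm (via networkx) inside each
true SCC; no heuristics, with a configurable cycle cap (default 10^6)
that truncates with a warning. Cycles are rotation-normalized (smallest
node first) and named `SCC<i>.<j>` with SCCs indexed by smallest member
name. Edge "activity" — named but not defined in the source literature —
is formalized here as the flip-influence probability under uniform
contexts, i.e. exactly the per-variable term of the sensitivity sum;
cross-module equality is tested.

## Dynamics

Synchronous update is deterministic; asynchronous modes draw from a
seeded generator (uniform node choice, or the fast variant that draws
only among genes whose update would change something). Derrida damage
co-evolves a random state and a perturbed twin (`ceil(fraction·n)`
distinct genes redrawn uniformly among the other `m-1` values) under the
*same* node-choice schedule in asynchronous runs — uncoupled schedules
would conflate update noise with damage. The fast asynchronous mode is
excluded from damage runs because its updatable sets differ between
twins, making a shared schedule ill-defined. The horizon default is 500
synchronous steps; results echo all parameters and the seed.

Percolation embeds rules into square (4-neighbor), honeycomb
(3-neighbor, brick-wall parity) or triangular (6-neighbor) lattices with
periodic horizontal and open vertical boundaries; stability is "value
unchanged over the observation window after the transient", clusters are
connected stable sets under lattice adjacency, and spanning is tested
top-to-bottom. Boundary conventions are a package choice; none is
canonical in the literature.

Preference analysis pools attractor states (weighted by basin hits),
tabulates each regulator's value distribution conditioned on the target's
value, row-normalizes, multiplies by a weight matrix (identity by
default — the natural choice when no dominant-form interaction matrix is
supplied), and sums over regulators. Per-state scores are the diagonal
of the summed matrix; a row whose maximum sits off-diagonal is reported
as a preferred transition `u -> v`. This scoring is a documented house
interpretation: the published description fixes the normalization and the
matrix product but not the aggregation.

## Synthetic data: what the generators emulate

`random_function` draws from the four paradigm classes: uniform tables;
nested-canalizing rules built layer by layer (`Layer` nested layers,
`CanNum` canalizing values per layer, residual filled uniformly);
threshold rules from nonzero integer weights in ±5 with cut points at
midpoints of realized sums; dominant rules from continuous weights
(strict argmax almost surely). `generate_kauffman` wires each of `N`
genes to `K` distinct regulators drawn uniformly without self-edges.
These are the standard homogeneous random ensembles of discrete-network
theory. They do not emulate degree heterogeneity, correlated rules,
or the motif enrichment of real GRNs — so passing dynamics tests shows
the algorithms are correct on the stated ensembles, not that real
networks behave this way.

The canalization-stability check runs 3-valued Kauffman ensembles
(`K = 4`, `N = 60`, `CanNum = 2`, damage horizon 30, 40 networks × 5
replicates per depth, fixed seed scheme) and asserts that mean final
damage does not increase with canalizing depth 1 → 2 → 3. The network
size and replicate counts are the package's test-scale choice; the
effect is strong at this scale (mean D ≈ 0.23 / 0.07 / 0.05) and the
check is deterministic given the seeds. It is a qualitative ordering
check, not a reproduction of any published curve.

## Known limitations

- Exhaustive enumeration in measures/minimization is exponential in `k`;
  the QM pipeline is practical to roughly `k ≈ 12` (Boolean) and the
  arity cap defaults to 16.
- Multi-valued polynomial interpolation requires prime `m`.
- Exact cover search hands over to greedy above 24 candidate implicants.
- The FFL scan considers predecessor sets up to size 6.
- Attractor *enumeration* is out of scope (sampling only); heuristic
  cycle sampling for very large SCCs is likewise not provided.
- One `m` per system: heterogeneous per-gene bases are unsupported.
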