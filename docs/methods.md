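# Methods

## The coupling model

`phylotable` treats a comparative dataset as a single object: an ordered set
of rooted trees plus one character matrix, bound by a bijection between tree
tips and table rows. The invariant maintained after construction and after
every operation is

1. `set(table labels) == tip set of every tree`,
2. exactly one row per tip, and
3. row order equal to the first tree's tip traversal order.

All trees in one object share a single tip sample: matching intersects the
table's labels with the tip sets of *all* trees and prunes every tree to
that intersection. Partial tree/data matching and multiple matrices per
object are deliberately unsupported; they would make "which taxa does this
object contain?" ambiguous.

Every operation returns a new object; nothing mutates in place. This trades
some speed against the by-reference update semantics of high-performance
table engines, in exchange for referential transparency (`pull` hands out
copies for the same reason).

### Matching

Label-column auto-selection counts, for each column, how many of its values
(compared as strings, case-sensitively) occur among the **first** tree's tip
labels, and picks the column with the most matches, leftmost on ties (a
`TiedColumnsWarning` lists the tied candidates — deterministic and
order-stable). Comparison is exact: no whitespace trimming and no
underscore/space folding, consistent with the literal Newick labels. Rows
whose label matches no tip are dropped; duplicate-label rows keep the first
occurrence (deterministic and reportable) and are counted separately in the
`MatchReport`. Fewer than two shared taxa is an error — one-tip trees are
not well defined for any downstream use here.

Rows are canonicalized to the first tree's tip order at match time and after
every coupled operation, which makes `extract_vector` output order
deterministic. Whether to preserve data order instead was a genuinely open
choice; tree order was chosen because the tree is the fixed frame of
reference for comparative methods.

### Queries and detachment

`query` follows three-stage rows/columns/groups semantics: a row filter, a
column selection/derivation or aggregation, and optional grouping applied
before the column stage. The result contract is bijection-preserving: while
every output row derives from exactly one source row (pure filter, per-row
derivation, per-group head/tail), the taxon-label column is implicitly
retained, the trees are pruned to the surviving taxa, and the result stays
coupled. An aggregation collapses rows, so no row↔taxon bijection remains:
the result detaches from the trees and is returned as a plain `TraitTable`
with a `DetachedTableWarning` — a warning rather than an error, since the
weakest consistent reading of "row changes affect the corresponding taxa"
is that taxon-coupling simply no longer applies. A `group_by` combined with
a per-row derivation (grouping that collapses nothing) is rejected: the
grouping would have no observable effect on a coupled result and is almost
always a mistaken attempt at aggregation.

String predicates and column expressions are evaluated by the pandas query/
eval engine (comparisons `== != < <= > >=`, `&`, `|`, parentheses, quoted
string literals); callables receiving the DataFrame are accepted wherever an
expression is. A filter leaving fewer than two taxa is an error, mirroring
the matching rule.

The cumulative `dropped_tips_total` / `dropped_rows_total` counters start at
zero on construction (the match step's removals are in the `MatchReport`
instead) and count taxa removed by **any** later coupled operation —
explicit `drop_taxa` calls and coupled row filters alike — so the summary's
"changes since construction" line reflects everything that happened to the
object.

## Trees

### Newick dialect

Bare and single-quoted labels are accepted; quoted labels are stored without
the quotes; underscores are **never** translated to spaces (some ecosystems
do this silently, which breaks exact-name matching). Internal node labels
are parsed and re-written but ignored by coupling logic. Trees without
branch lengths are legal. On output, labels containing `( ) , : ;` or
spaces are single-quoted, and branch lengths are printed with a configurable
number of significant digits (default 6); re-parsing reproduces the tree up
to that rounding. NEXUS, PhyloXML and extended-Newick annotations are out of
scope. Parsing and serialization are delegated to dendropy.

### Pruning

`prune_to` removes tips and suppresses the resulting single-child nodes,
summing merged edge lengths. A collapsed chain above the root is handled the
same way: the accumulated length survives as the new root's own edge length,
so total tree depth is conserved. Consequently `path_length_to_root`
includes the root's edge length when one is present — with that convention,
every retained tip's root-to-tip path length is exactly conserved by
pruning, which is the property the test suite checks (to 1e-9 relative
tolerance) against a brute-force oracle that deletes tips one at a time and
suppresses degree-2 nodes after each deletion. Pruning below two tips is an
error. The implementation is a single postorder pass building the pruned
tree (O(n)), chosen after the generic batch pruning path proved quadratic
on 10⁴-tip trees.

### Simulation

`simulate_tree` builds a random binary topology by recursive uniform
bipartition (each left-subtree size uniform on 1..size−1), assigns labels
`t1..tn` in random order, and draws branch lengths i.i.d. uniform on (0,1).
It reproduces the *contract* of the classic `rtree` simulator — random
topology, uniform branch lengths, n labeled tips, deterministic under a
seed — without claiming distributional identity with any particular
implementation. Construction is iterative (explicit stack) so unbalanced
topologies at large n cannot hit recursion limits.

## Character typing

No formula for discrete/continuous detection is universal; the rule here is
the distinct-value-ratio heuristic: non-numeric columns are discrete, and a
numeric column with `n_distinct / n_non_missing < cutoff` is discrete,
otherwise continuous. The cutoff defaults to 0.1 and is exposed as a
parameter. Strict typing is deliberate: a column of numeric-looking strings
("1.5") is discrete unless the column already parses as numeric — silent
coercion is how mixed-type columns sneak through. An all-missing column is
an error (naming the column when detected table-wide).

`force_names` fills invalid column names positionally with `V1..Vk`,
designates the first unique-string column as labels, and synthesizes
`taxon_1..taxon_n` when no column qualifies; it is idempotent.

## Synthetic fixtures and what they do (not) show

`generate_benchmark_data` emulates a standard matching benchmark: a
simulated tree of `n` tips and a matrix whose rows cover
`round(match_fraction × n)` tips (default 0.9), drawn as a uniform random
subset, with `n_discrete` (default 50) categorical columns sampled uniformly
from the states `A..E` and `n_continuous` (default 50) standard-normal
columns. The state alphabet and the normal distribution are documented
stand-ins; the protocol fixes only the column counts and the coverage
fraction. The tests exercise matching, pruning and querying at sizes 10–100
and a 10,000-tip smoke test; the default suite does not exercise trees at
the 10⁵–10⁶ tip scale, real (messy) taxon-name conventions, or missing-data
patterns beyond isolated cells — passing tests show the coupling semantics
are correct, not that any particular real dataset will match cleanly.

The timing harness (`run_benchmark`) reports median and lower/upper-quartile
wall times (ms) for matching, the coupled filter (which includes tree
pruning), the coupled filter+grouped sum/mean aggregation, and the same
filter+aggregation on the bare table as a baseline. Absolute values are
hardware-dependent and carry no acceptance weight; the only asserted
relation is the soft ordering that the coupled path is not faster than the
bare-table baseline.

## Numerical and edge-case choices

- Branch-length round-trip tolerance is `10^(−precision+1)` relative, for
  `precision` significant digits on output.
- Tree equality in tests compares canonical signatures: the sorted list of
  (sorted tip set below node, edge length) over all nodes — exact for
  rooted trees, insensitive to child rotation.
- Merged edge lengths: `None + None = None`; otherwise missing lengths count
  as 0 in a sum, so partially-length-annotated trees prune without error.
- `drop_taxa({})` is the identity; `peek` never mutates; `apply_external`
  propagates exceptions unmodified, annotated with the 1-based tree index.
- Problem sizes in the test suite (1000 oracle trees at ≤50 tips, 200
  randomized operation chains, 500 round-trips, one 10,000-tip smoke test)
  keep a full run under ten seconds on one CPU while covering every code
  path; the acceptance script uses 500 oracle trees and the same chain and
  round-trip counts.

## Known limitations

- One character matrix per object; all trees forced to a common tip sample;
  no partial matching.
- No NEXUS/PhyloXML, no rerooting or branch-length transforms, no
  comparative-method models — `apply_external` only delivers `(tree, table)`
  to caller-supplied functions.
- Ordinal/meristic characters and polymorphic state strings ("A/B") are not
  modeled; they classify as discrete.
- The in-memory table is a pandas DataFrame; datasets beyond available RAM
  are out of scope.
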