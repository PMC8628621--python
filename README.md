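# phylotable

Coupled phylogeny/trait-table data wrangling for comparative analyses.

Phylogenetic comparative work keeps two objects in play: a tree (or a set of
trees) and a character matrix with one row per taxon. Kept separate, they
drift apart — a filtered table no longer lines up with the tree's tips, a
pruned tree orphans table rows, and every downstream model fit silently
inherits the mismatch. `phylotable` matches trees and table by taxon name
**once**, then maintains the coupling invariant through every subsequent
operation:

> the set of taxon labels in the table equals the tip set of every tree,
> with exactly one row per tip, rows ordered by the first tree's tip order.

Dropping taxa prunes both sides; filtering rows prunes the trees to the
surviving taxa; grouped aggregations that collapse rows (so no row↔taxon
bijection remains) return a plain table detached from the trees, with a
warning. Matching is case-sensitive exact string equality — no trimming, no
underscore/space folding — and Newick labels are read literally, so what you
see in the file is what gets matched.

It is intended for evolutionary biologists preparing data for comparative
methods (trait-evolution models, phylogenetic regressions), where the
input contract is typically "a tree plus a named vector per trait".

## What it does

- **Newick I/O** — single- and multi-tree files, quoted labels, polytomies,
  optional branch lengths (`parse_newick`, `write_newick`).
- **Tree operations** — pruning with unifurcation suppression that conserves
  every retained tip's root-to-tip path length (`prune_to`,
  `path_length_to_root`), and random tree simulation (`simulate_tree`:
  uniform random topology, U(0,1) branch lengths).
- **Matching** — `match` scores each table column by how many of its values
  occur among the first tree's tip labels, picks the best (leftmost on
  ties), intersects with every tree's tip set, prunes trees, drops unmatched
  and duplicate rows, and reports exactly what changed (`MatchReport`).
- **Coupled queries** — `query(ctd, where=..., select=..., group_by=...,
  head=..., aggregate=...)` with three-stage rows/columns/groups semantics;
  results stay coupled while each output row derives from one source row.
- **Extraction** — `extract_vector` (named vectors keyed by tip label, in
  tip order), `pull` (independent copies of table or trees),
  `apply_external(ctd, fn)` to hand `(tree, table)` to any other package's
  function, once per tree.
- **Character tools** — discrete/continuous detection (non-numeric columns
  are discrete; numeric columns are discrete when the distinct-value ratio
  falls below a cutoff, default 0.1), type filtering, name checking/forcing.
- **Fixtures and benchmarking** — a generator for random trees plus trait
  matrices covering a configurable fraction of tips (defaults: 50 discrete
  + 50 continuous characters, 90% tip coverage), and a timing harness.

## Worked example

```python
import pandas as pd
import phylotable as pt

tree = pt.parse_newick("((sp1:1,sp2:1):1,((sp3:1,sp4:1):1,(sp5:1,sp6:1):1):1);")[0]
traits = pd.DataFrame({
    "species":  ["sp1", "sp2", "sp3", "sp4", "sp5", "sp6", "sp7"],
    "island":   ["Cuba", "Cuba", "Hispaniola", "Hispaniola",
                 "PuertoRico", "PuertoRico", "Jamaica"],
    "ecomorph": ["trunk", "crown", "trunk", "crown", "trunk", "crown", "twig"],
    "SVL":      [3.5, 4.0, 2.5, 5.0, 1.5, 2.0, 2.2],
})

ctd, report = pt.match(tree, traits)
print(report)
# MatchReport(label_column='species', n_matched=6, n_tips_dropped=0,
#             n_rows_dropped=1, n_duplicate_rows_dropped=0,
#             per_tree_tips_dropped=[0])
```

The matcher picked `species` on its own (6 of its values are tip labels),
kept the 6 shared taxa, and dropped the one row (`sp7`) with no tip. The
summary counts characters by detected type:

```python
print(pt.summarize(ctd))
# Coupled tree/data object
#   taxa:        6
#   trees:       1
#   characters:  2 discrete, 1 continuous
#   missing:     0 cell(s)
#   changes:     0 tip(s), 0 row(s) dropped since construction
```

Filtering rows prunes the trees in the same step — here to the two Cuban
taxa, with a derived column computed per row:

```python
cuba = pt.query(ctd, where='island == "Cuba"', select={"Index": "SVL * 2"})
print(cuba.trees[0].as_newick())
# (sp1:1,sp2:1):1;
```

(The `:1` after the parenthesis is the collapsed root chain kept as the new
root's edge, so both tips keep their original depth of 2.) Named vectors
come out keyed by tip label, in tip order — exactly what trait-evolution
functions expect:

```python
print(pt.extract_vector(ctd, "SVL"))
# species
# sp1    3.5
# sp2    4.0
# sp3    2.5
# sp4    5.0
# sp5    1.5
# sp6    2.0
# Name: SVL, dtype: float64
```

A grouped aggregation such as
`pt.query(ctd, aggregate={"m": ("SVL", "mean")}, group_by="island")`
collapses rows, so it returns a plain table and warns that the result is
detached from the trees.

The same operations are available from a shell via the `phylotable` CLI
(`match`, `filter`, `extract`, `summary`, `simulate`, `benchmark`); exit
code 2 signals a validation/matching error and 3 a parse error.

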