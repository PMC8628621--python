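"""Synthetic benchmark fixtures: random trees plus random character matrices.

The generator reproduces a standard benchmarking protocol for tree/table
matching: simulate a random tree, then build a character matrix whose rows
cover a fixed fraction of the tips (default 90%, a uniform random subset),
with a block of discrete characters (states drawn uniformly from "A".."E")
and a block of continuous characters (standard-normal draws). Defaults are
50 discrete + 50 continuous characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TableValidationError
from .newick import Phylogeny
from .table import TraitTable
from .tree_ops import simulate_tree

__all__ = ["BenchmarkConfig", "generate_benchmark_data"]

_DISCRETE_STATES = ("A", "B", "C", "D", "E")


@dataclass
class BenchmarkConfig:
    """Parameters of the fixture generator and benchmark harness.

    tree_sizes : tip counts to benchmark (each >= 2)
    n_discrete / n_continuous : characters of each type in the matrix
    match_fraction : fraction of tips with a table row, in (0, 1]
    replicates : timing repeats per operation
    seed : base seed for all randomness
    """

    tree_sizes: list[int] = field(default_factory=lambda: [10, 40, 100])
    n_discrete: int = 50
    n_continuous: int = 50
    match_fraction: float = 0.9
    replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if any(s < 2 for s in self.tree_sizes):
            raise ValueError("all tree sizes must be >= 2")
        if not (0 < self.match_fraction <= 1):
            raise ValueError(f"match_fraction must be in (0, 1], got {self.match_fraction}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_discrete < 0 or self.n_continuous < 0:
            raise ValueError("character counts must be >= 0")


def generate_benchmark_data(
    n_tips: int,
    cfg: BenchmarkConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[Phylogeny, TraitTable]:
    """Simulate a tree and a matching character matrix.

    The table has ``round(match_fraction * n_tips)`` rows labeling a uniform
    random subset of the tips (column "species"), ``n_discrete`` columns
    "Disc1".. with uniform states from {"A".."E"}, and ``n_continuous``
    columns "Cont1".. with standard-normal draws. Deterministic given the
    seed.
    """
    cfg = cfg or BenchmarkConfig()
    if seed is None:
        seed = cfg.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_tips < 3:
        raise TableValidationError(
            f"need n_tips >= 3 so the matched subset has >= 2 taxa, got {n_tips}"
        )
    tree = simulate_tree(n_tips, rng)
    n_rows = round(cfg.match_fraction * n_tips)
    if n_rows < 2:
        raise TableValidationError(
            f"match_fraction {cfg.match_fraction} of {n_tips} tips leaves "
            f"{n_rows} rows; need at least 2"
        )
    chosen = rng.choice(tree.tip_labels, size=n_rows, replace=False)
    data = {"species": chosen}
    if cfg.n_discrete:
        states = rng.choice(_DISCRETE_STATES, size=(n_rows, cfg.n_discrete))
        for j in range(cfg.n_discrete):
            data[f"Disc{j + 1}"] = states[:, j]
    if cfg.n_continuous:
        values = rng.standard_normal((n_rows, cfg.n_continuous))
        for j in range(cfg.n_continuous):
            data[f"Cont{j + 1}"] = values[:, j]
    table = TraitTable(pd.DataFrame(data), label_column="species")
    return tree, table
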