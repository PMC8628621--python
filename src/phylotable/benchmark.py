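"""Timing harness for the match and query operations.

For each tree size the harness times (a) coupled-object construction
(matching), (b) the coupled filter step (rows where one discrete character
equals a level, which also prunes the trees), (c) the filter + grouped
sum/mean aggregation run through the coupled object, and (d) the same
filter + aggregation on the bare table as a baseline. Absolute timings are
hardware-dependent and reported for inspection only (median and lower/upper
quartiles, in milliseconds).
"""

from __future__ import annotations

import time
import warnings

import numpy as np
import pandas as pd

from .coupling import match, query
from .errors import DetachedTableWarning, QueryError
from .fixtures import BenchmarkConfig, generate_benchmark_data

__all__ = ["run_benchmark"]

_FILTER = 'Disc1 == "A"'
_AGGREGATE = {"sum_Cont2": ("Cont2", "sum"), "mean_Cont3": ("Cont3", "mean")}
_GROUP = "Disc10"


def _time(fn, replicates: int) -> dict[str, float]:
    samples = []
    for _ in range(replicates):
        t0 = time.perf_counter()
        fn()
        samples.append((time.perf_counter() - t0) * 1000.0)
    q1, med, q3 = np.percentile(samples, [25, 50, 75])
    return {"median_ms": med, "q1_ms": q1, "q3_ms": q3}


def run_benchmark(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Run the timing protocol; returns one row per (operation, tree size)
    with median and quartile times in ms."""
    if cfg.replicates < 2:
        raise ValueError("benchmarking needs at least 2 replicates")
    rows = []
    for size in cfg.tree_sizes:
        tree, table = generate_benchmark_data(size, cfg, seed=cfg.seed)
        ctd, _ = match(tree, table)
        df = ctd.table.data

        def coupled_filter():
            try:
                query(ctd, where=_FILTER)
            except QueryError:
                pass  # tiny sizes can leave <2 taxa; timing still meaningful

        def coupled_filter_aggregate():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DetachedTableWarning)
                query(ctd, where=_FILTER, aggregate=_AGGREGATE, group_by=_GROUP)

        def table_filter_aggregate():
            sub = df.query(_FILTER)
            sub.groupby(_GROUP, sort=False).agg(
                sum_Cont2=("Cont2", "sum"), mean_Cont3=("Cont3", "mean")
            )

        ops = {
            "match": lambda: match(tree, table),
            "coupled_filter": coupled_filter,
            "coupled_filter_aggregate": coupled_filter_aggregate,
            "table_filter_aggregate": table_filter_aggregate,
        }
        for name, fn in ops.items():
            stats = _time(fn, cfg.replicates)
            rows.append({"operation": name, "n_tips": size, **stats,
                         "replicates": cfg.replicates})
    return pd.DataFrame(rows)
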