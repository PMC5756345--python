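"""Pan-cancer aggregation: driver ∩ DEG intersection, cross-condition
sharing, FDR comparison, and benchmark-overlap arithmetic."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dea import DEGTable

__all__ = [
    "ConditionDriverResult",
    "SharedDriverMatrix",
    "intersect_driver_degs",
    "shared_driver_matrix",
    "fdr_comparison",
    "percentage",
    "benchmark_overlap",
]


@dataclass
class ConditionDriverResult:
    """Driver-DEG intersection for one condition (cancer type)."""

    condition_id: str
    degs: set[str]
    driver_degs: set[str]
    pct_of_network_drivers: float


@dataclass
class SharedDriverMatrix:
    """Pairwise counts of driver DEGs shared between conditions."""

    condition_ids: list[str]
    matrix: pd.DataFrame


def percentage(numerator: int, denominator: int, mode: str = "round1") -> float:
    """``100 * numerator / denominator`` under one of two printing conventions.

    ``round1`` rounds to one decimal; ``truncate_int`` truncates towards zero
    to a whole percent.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    value = 100.0 * numerator / denominator
    if mode == "round1":
        return round(value, 1)
    if mode == "truncate_int":
        return float(math.floor(value))
    raise ValueError(f"unknown rounding mode {mode!r}")


def intersect_driver_degs(
    drivers: set[str],
    deg_table: DEGTable,
    rounding: str = "round1",
) -> ConditionDriverResult:
    """Condition-specific driver DEGs: flagged DEGs that are network drivers.

    The percentage is relative to the size of the network-driver set; with
    an empty driver set the intersection is empty and the percentage is
    reported as 0 with a warning.
    """
    degs = deg_table.degs
    driver_degs = degs & drivers
    if not drivers:
        warnings.warn("empty network-driver set; percentage undefined, reported as 0",
                      stacklevel=2)
        pct = 0.0
    else:
        pct = percentage(len(driver_degs), len(drivers), mode=rounding)
    return ConditionDriverResult(
        condition_id=deg_table.condition_id,
        degs=degs,
        driver_degs=driver_degs,
        pct_of_network_drivers=pct,
    )


def shared_driver_matrix(results: Iterable[ConditionDriverResult]) -> SharedDriverMatrix:
    """Symmetric matrix of pairwise shared driver-DEG counts.

    The diagonal holds each condition's own driver-DEG count.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one condition")
    ids = [r.condition_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate condition ids")
    n = len(results)
    mat = np.zeros((n, n), dtype=int)
    for i, a in enumerate(results):
        for j, b in enumerate(results):
            mat[i, j] = len(a.driver_degs & b.driver_degs)
    return SharedDriverMatrix(
        condition_ids=ids,
        matrix=pd.DataFrame(mat, index=ids, columns=ids),
    )


def fdr_comparison(deg_table: DEGTable, driver_degs: set[str]) -> pd.DataFrame:
    """Summarise the FDR distribution of all DEGs vs the driver-DEG subset.

    Rows ``all_degs`` and ``driver_degs``; columns n, mean, median, q1, q3.
    """
    unknown = driver_degs - deg_table.genes
    if unknown:
        raise ValueError(
            f"driver DEGs absent from the DEG table: {sorted(unknown)[:5]}"
        )
    df = deg_table.df
    all_fdr = df.loc[df["is_deg"], "fdr"].to_numpy()
    groups = {"all_degs": all_fdr}
    if driver_degs:
        groups["driver_degs"] = df.loc[df["gene"].isin(driver_degs), "fdr"].to_numpy()
    else:
        warnings.warn("empty driver-DEG set; summarising DEGs only", stacklevel=2)
    rows = []
    for name, values in groups.items():
        if values.size:
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            rows.append(
                {"group": name, "n": values.size, "mean": values.mean(),
                 "median": med, "q1": q1, "q3": q3}
            )
        else:
            rows.append({"group": name, "n": 0, "mean": np.nan, "median": np.nan,
                         "q1": np.nan, "q3": np.nan})
    return pd.DataFrame(rows)


def benchmark_overlap(
    driver_degs: set[str],
    tool_gene_sets: Mapping[str, Iterable[str]],
    min_tools: int = 2,
) -> set[str]:
    """Driver DEGs found by at least ``min_tools`` of the given tool gene sets."""
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    if not tool_gene_sets:
        raise ValueError("empty tool gene-set mapping")
    sets = {name: set(genes) for name, genes in tool_gene_sets.items()}
    return {
        g for g in driver_degs
        if sum(g in s for s in sets.values()) >= min_tools
    }
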