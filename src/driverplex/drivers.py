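"""Driver-gene criterion and multiplex (multi-layer) aggregation.

A gene is a candidate driver in pathway *P* and layer *N* when its observed
within-pathway degree exceeds the equal-edge-probability expectation.  Two
forms of the comparison are provided:

* ``literal`` — ``di_P / k > di_E`` with ``di_E = di_N * k / m``, the
  inequality exactly as printed in the source method.  Note the two sides
  are on different scales (the left is normalised by pathway size, the
  right is not), so this form can only ever fire when ``k**2 < m``.
* ``unnormalized`` — ``di_P > di_E``, i.e. both sides on the raw degree
  scale; equivalent to comparing the densities ``di_P/k > di_N/m``.

Multiplex aggregation then calls a gene a network driver when the criterion
holds in at least ``min_layers`` layers (default 2).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .centrality import CentralityRecord

__all__ = [
    "DriverCall",
    "MultiplexDriverResult",
    "evaluate_criterion",
    "make_calls",
    "layer_driver_set",
    "multiplex_drivers",
    "venn_region_counts",
]

CRITERION_MODES = ("literal", "unnormalized")
AGGREGATION_MODES = ("per_gene", "per_pathway")


@dataclass(frozen=True)
class DriverCall:
    """Criterion verdict for one (gene, pathway, layer) centrality record."""

    gene: str
    pathway_id: str
    layer_name: str
    passes: bool
    criterion_mode: str


@dataclass
class MultiplexDriverResult:
    """Per-layer driver sets and the multi-layer aggregated driver set."""

    per_layer_sets: dict[str, set[str]]
    driver_genes: set[str]
    min_layers: int
    aggregation_mode: str


def evaluate_criterion(record: CentralityRecord, mode: str = "literal") -> bool:
    """Strict-inequality driver verdict for one record.

    Zero within-pathway degree can never pass (strict inequality at zero).
    """
    if mode not in CRITERION_MODES:
        raise ValueError(f"unknown criterion mode {mode!r}")
    if record.di_p == 0:
        return False
    if mode == "literal":
        return record.di_p / record.k > record.di_e
    return record.di_p > record.di_e


def make_calls(
    records: Iterable[CentralityRecord], mode: str = "literal"
) -> list[DriverCall]:
    """Evaluate the criterion on every record, preserving record order."""
    return [
        DriverCall(
            gene=r.gene,
            pathway_id=r.pathway_id,
            layer_name=r.layer_name,
            passes=evaluate_criterion(r, mode),
            criterion_mode=mode,
        )
        for r in records
    ]


def _check_single_mode(calls: list[DriverCall]) -> None:
    modes = {c.criterion_mode for c in calls}
    if len(modes) > 1:
        raise ValueError(f"calls mix criterion modes: {sorted(modes)}")


def layer_driver_set(calls: Iterable[DriverCall], layer_name: str) -> set[str]:
    """Genes passing the criterion in at least one pathway of the named layer."""
    calls = list(calls)
    _check_single_mode(calls)
    known = {c.layer_name for c in calls}
    if layer_name not in known:
        raise KeyError(f"unknown layer {layer_name!r}; calls cover {sorted(known)}")
    return {c.gene for c in calls if c.layer_name == layer_name and c.passes}


def multiplex_drivers(
    calls: Iterable[DriverCall],
    min_layers: int = 2,
    aggregation: str = "per_gene",
) -> MultiplexDriverResult:
    """Aggregate per-layer verdicts into a multiplex driver set.

    ``per_gene`` (default): a gene qualifies when it passes in at least
    ``min_layers`` distinct layers, in any pathways.  ``per_pathway``
    (stricter): some single pathway must pass in at least ``min_layers``
    layers.
    """
    if min_layers < 1:
        raise ValueError("min_layers must be >= 1")
    if aggregation not in AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation mode {aggregation!r}")
    calls = list(calls)
    _check_single_mode(calls)
    layer_names = sorted({c.layer_name for c in calls})
    per_layer: dict[str, set[str]] = {name: set() for name in layer_names}
    for c in calls:
        if c.passes:
            per_layer[c.layer_name].add(c.gene)

    if min_layers > len(layer_names):
        warnings.warn(
            f"min_layers={min_layers} exceeds the {len(layer_names)} available "
            "layer(s); driver set is empty",
            stacklevel=2,
        )
        return MultiplexDriverResult(per_layer, set(), min_layers, aggregation)

    drivers: set[str] = set()
    if aggregation == "per_gene":
        layer_count: dict[str, set[str]] = defaultdict(set)
        for c in calls:
            if c.passes:
                layer_count[c.gene].add(c.layer_name)
        drivers = {g for g, layers in layer_count.items() if len(layers) >= min_layers}
    else:
        pathway_layers: dict[tuple[str, str], set[str]] = defaultdict(set)
        for c in calls:
            if c.passes:
                pathway_layers[(c.gene, c.pathway_id)].add(c.layer_name)
        drivers = {
            gene
            for (gene, _pid), layers in pathway_layers.items()
            if len(layers) >= min_layers
        }
    return MultiplexDriverResult(per_layer, drivers, min_layers, aggregation)


def venn_region_counts(
    per_layer_sets: Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], int]:
    """Count genes in every exclusive region of the per-layer driver sets.

    A region is identified by the sorted tuple of layer names whose sets
    contain the gene, and every gene of the union falls in exactly one
    region; all non-empty layer combinations are reported, including
    zero-count ones.
    """
    if not per_layer_sets:
        raise ValueError("need at least one layer")
    sets = {name: set(genes) for name, genes in per_layer_sets.items()}
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[combo] = 0
    union = set().union(*sets.values())
    for gene in union:
        signature = tuple(sorted(n for n in names if gene in sets[n]))
        counts[signature] += 1
    return counts
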