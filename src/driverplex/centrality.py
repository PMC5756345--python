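"""Degree-centrality quantities per (gene, pathway, layer).

For gene *i* in an interaction layer *N* with *m* nodes and a pathway *P*
with *k* genes, three quantities are computed:

* ``di_N`` — degree of *i* in the whole layer,
* ``di_P`` — degree of *i* restricted to neighbours that are members of *P*,
* ``di_E`` — the expected within-pathway degree under the equal
  edge-probability null, ``di_E = di_N * k / m`` (from ``di_N/m = di_E/k``).

A gene absent from a layer has ``di_N = di_P = di_E = 0``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Collection, Iterable, Optional

import pandas as pd

from .datatypes import GeneSetCollection, MultiplexNetwork, NetworkLayer

__all__ = [
    "CentralityRecord",
    "degree_in_network",
    "degree_in_pathway",
    "expected_degree",
    "build_centrality_records",
    "records_to_frame",
]


@dataclass(frozen=True)
class CentralityRecord:
    """Observed and expected degree centrality of one gene in one pathway and layer."""

    gene: str
    pathway_id: str
    layer_name: str
    di_n: int
    di_p: int
    di_e: float
    k: int
    m: int


def degree_in_network(gene: str, layer: NetworkLayer) -> int:
    """Number of distinct neighbours of ``gene`` in the layer (0 if absent)."""
    if gene not in layer.graph:
        return 0
    return layer.graph.degree(gene)


def degree_in_pathway(gene: str, pathway: Collection[str], layer: NetworkLayer) -> int:
    """Number of distinct neighbours of ``gene`` that are members of ``pathway``.

    The gene itself is never counted.  The gene may or may not belong to the
    pathway; membership of the *neighbours* is what matters.
    """
    if len(pathway) == 0:
        raise ValueError("empty pathway")
    if gene not in layer.graph:
        return 0
    members = set(pathway)
    members.discard(gene)
    return sum(1 for nb in layer.graph.neighbors(gene) if nb in members)


def expected_degree(di_n: int, k: int, m: int) -> float:
    """Expected within-pathway degree ``di_N * k / m`` under the uniform-edge null."""
    if m < 1:
        raise ValueError("layer node count m must be >= 1")
    if k < 1:
        raise ValueError("pathway size k must be >= 1")
    if di_n < 0:
        raise ValueError("di_N must be non-negative")
    return di_n * k / m


def build_centrality_records(
    multiplex: MultiplexNetwork,
    pathways: GeneSetCollection,
    gene_filter: Optional[Iterable[str]] = None,
    k_mode: str = "annotated",
) -> list[CentralityRecord]:
    """One record per (pathway, gene, layer) for every pathway member gene.

    Parameters
    ----------
    gene_filter
        If given, only pathway members in this set get records (e.g. restrict
        the analysis to differentially expressed genes).
    k_mode
        ``"annotated"`` (default) takes ``k`` as the number of genes annotated
        to the pathway; ``"in_layer"`` restricts ``k`` to pathway members
        present in the layer (floored at 1 to keep ``di_E`` defined).

    Records are ordered lexicographically by (pathway, gene, layer).
    """
    if k_mode not in ("annotated", "in_layer"):
        raise ValueError(f"unknown k_mode {k_mode!r}")
    filt = set(gene_filter) if gene_filter is not None else None
    records: list[CentralityRecord] = []
    for pid in sorted(pathways.pathway_ids):
        members = pathways.sets[pid]
        member_set = set(members)
        for gene in sorted(members):
            if filt is not None and gene not in filt:
                continue
            for layer_name in sorted(multiplex.layer_names):
                layer = multiplex[layer_name]
                m = layer.n_nodes
                if k_mode == "annotated":
                    k = len(members)
                else:
                    k = max(1, len(member_set & layer.nodes))
                di_n = degree_in_network(gene, layer)
                di_p = degree_in_pathway(gene, member_set, layer)
                di_e = expected_degree(di_n, k, max(m, 1))
                records.append(
                    CentralityRecord(
                        gene=gene,
                        pathway_id=pid,
                        layer_name=layer_name,
                        di_n=di_n,
                        di_p=di_p,
                        di_e=di_e,
                        k=k,
                        m=max(m, 1),
                    )
                )
    return records


def records_to_frame(records: Iterable[CentralityRecord]) -> pd.DataFrame:
    """Tabulate records with columns gene, pathway, layer, di_N, di_P, di_E, k, m."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(
        rows, columns=["gene", "pathway_id", "layer_name", "di_n", "di_p", "di_e", "k", "m"]
    )
    return df.rename(
        columns={
            "pathway_id": "pathway",
            "layer_name": "layer",
            "di_n": "di_N",
            "di_p": "di_P",
            "di_e": "di_E",
        }
    )
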