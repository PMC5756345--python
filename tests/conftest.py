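"""Shared fixtures: the documented toy network instance, random-instance
helpers, and a session-scoped synthetic bundle."""

from __future__ import annotations

import numpy as np
import pytest

from driverplex.centrality import CentralityRecord
from driverplex.datatypes import GeneSetCollection, NetworkLayer
from driverplex.simulate import SimulationConfig, generate_study

TOY_EDGES = [("G1", "G2"), ("G1", "G3"), ("G1", "G4"), ("G2", "G3"), ("G5", "G6")]
TOY_PATHWAY = ["G1", "G2", "G3", "G7"]


@pytest.fixture
def toy_layer() -> NetworkLayer:
    """Six-node layer: edges G1-G2, G1-G3, G1-G4, G2-G3, G5-G6."""
    return NetworkLayer.from_edges("L1", TOY_EDGES)


@pytest.fixture
def toy_pathway() -> list[str]:
    return list(TOY_PATHWAY)


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    return GeneSetCollection(sets={"P": list(TOY_PATHWAY)}, source_name="toy")


def random_layer(rng: np.random.Generator, n_nodes: int, p: float, name: str = "L") -> NetworkLayer:
    """Erdős–Rényi layer over genes g0..g{n-1} (upper-cased at ingest)."""
    genes = [f"N{i:03d}" for i in range(n_nodes)]
    iu, ju = np.triu_indices(n_nodes, k=1)
    mask = rng.random(iu.size) < p
    edges = [(genes[a], genes[b]) for a, b in zip(iu[mask], ju[mask])]
    return NetworkLayer.from_edges(name, edges, extra_nodes=genes)


def brute_force_degrees(
    edges: list[tuple[str, str]], gene: str, pathway: set[str] | None = None
) -> int:
    """Independent degree oracle: scan the raw edge list, count distinct
    partners (optionally restricted to pathway members other than the gene)."""
    partners: set[str] = set()
    for a, b in edges:
        if a == b:
            continue
        if a == gene:
            partners.add(b)
        elif b == gene:
            partners.add(a)
    if pathway is not None:
        partners &= set(pathway) - {gene}
    return len(partners)


def bh_oracle(p_values) -> np.ndarray:
    """Direct Benjamini–Hochberg step-up: adj_(i) = min_{j>=i} p_(j)*n/j, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def make_record(gene="G", pathway="P", layer="L", di_n=0, di_p=0, k=1, m=1) -> CentralityRecord:
    return CentralityRecord(
        gene=gene, pathway_id=pathway, layer_name=layer,
        di_n=di_n, di_p=di_p, di_e=di_n * k / m, k=k, m=m,
    )


@pytest.fixture(scope="session")
def sparse_bundle(tmp_path_factory) -> dict:
    """Planted bundle in the regime where the literal criterion is informative."""
    out = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig.sparse_pathway_regime(seed=7)
    bundle = generate_study(config, out, overwrite=True)
    bundle["dir"] = out
    bundle["config"] = config
    return bundle
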