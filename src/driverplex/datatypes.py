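"""Core data containers shared across the pipeline.

The containers are deliberately thin wrappers around the field-standard
in-memory objects: gene sets are plain ``dict`` of lists, interaction layers
wrap a :class:`networkx.Graph`, expression data wraps a pandas DataFrame.
Validation happens at construction so downstream code can assume the
invariants (unique identifiers, non-negative counts, no self-loops).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOUR = "tumour"

#: accepted spellings for the two sample classes (case-insensitive)
_LABEL_ALIASES = {
    "normal": NORMAL,
    "tumour": TUMOUR,
    "tumor": TUMOUR,
    "tumoural": TUMOUR,
}


def normalize_class_label(raw: str) -> str:
    """Map a raw class label onto the ``{normal, tumour}`` vocabulary.

    Labels are case-insensitive; common spelling variants of "tumour" are
    accepted.  Any other value raises ``ValueError`` rather than silently
    creating a third class.
    """
    key = str(raw).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(
            f"unknown sample class {raw!r}; expected one of "
            f"{sorted(set(_LABEL_ALIASES))}"
        )
    return _LABEL_ALIASES[key]


@dataclass
class GeneSetCollection:
    """Named pathways, each an ordered list of unique gene symbols."""

    sets: dict[str, list[str]]
    source_name: str = ""

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("gene-set collection is empty")
        for pid, genes in self.sets.items():
            if not pid:
                raise ValueError("empty pathway id")
            if not genes:
                raise ValueError(f"pathway {pid!r} has no genes")
            if any(not g for g in genes):
                raise ValueError(f"pathway {pid!r} contains an empty gene symbol")
            if len(set(genes)) != len(genes):
                raise ValueError(f"pathway {pid!r} contains duplicate gene symbols")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def size(self, pathway_id: str) -> int:
        return len(self.sets[pathway_id])

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


@dataclass
class NetworkLayer:
    """One undirected interaction layer (e.g. physical interaction).

    Edges are unweighted and deduplicated regardless of pair order;
    self-loops are dropped at construction with a counted warning.
    """

    layer_name: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if not self.layer_name:
            raise ValueError("layer_name must be non-empty")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            warnings.warn(
                f"layer {self.layer_name!r}: dropped {len(loops)} self-loop(s)",
                stacklevel=2,
            )
            self.graph.remove_edges_from(loops)

    @classmethod
    def from_edges(
        cls,
        layer_name: str,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "NetworkLayer":
        g: nx.Graph = nx.Graph()
        n_loops = 0
        for a, b in edges:
            if a == b:
                n_loops += 1
                g.add_node(a)  # endpoint still counts towards the node universe
                continue
            g.add_edge(a, b)
        g.add_nodes_from(extra_nodes)
        if n_loops:
            warnings.warn(
                f"layer {layer_name!r}: dropped {n_loops} self-loop(s)",
                stacklevel=2,
            )
        return cls(layer_name=layer_name, graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        """Layer size ``m``: the endpoint union as read from the source."""
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkLayer):
            return NotImplemented
        return (
            self.layer_name == other.layer_name
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


@dataclass
class MultiplexNetwork:
    """A set of named interaction layers over a shared gene universe."""

    layers: dict[str, NetworkLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("multiplex network needs at least one layer")
        for name, layer in self.layers.items():
            if name != layer.layer_name:
                raise ValueError(
                    f"layer key {name!r} does not match layer_name "
                    f"{layer.layer_name!r}"
                )

    @classmethod
    def from_layers(cls, layers: Iterable[NetworkLayer]) -> "MultiplexNetwork":
        out: dict[str, NetworkLayer] = {}
        for layer in layers:
            if layer.layer_name in out:
                raise ValueError(f"duplicate layer name {layer.layer_name!r}")
            out[layer.layer_name] = layer
        return cls(layers=out)

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> NetworkLayer:
        return self.layers[name]

    def __iter__(self) -> Iterator[NetworkLayer]:
        return iter(self.layers.values())


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of non-negative counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count matrix contains non-numeric cells")
        if np.isnan(values).any():
            raise ValueError("count matrix contains missing values")
        if (values < 0).any():
            raise ValueError("count matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class SampleLabels:
    """Mapping of sample id to class label (normal / tumour)."""

    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate sample ids in labels")
        normalized = self.labels.map(normalize_class_label)
        self.labels = normalized

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SampleLabels":
        return cls(labels=pd.Series(dict(mapping), dtype=object))

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)

    def samples_of(self, klass: str) -> list[str]:
        klass = normalize_class_label(klass)
        return list(self.labels.index[self.labels == klass])

    def class_counts(self) -> dict[str, int]:
        return {
            NORMAL: int((self.labels == NORMAL).sum()),
            TUMOUR: int((self.labels == TUMOUR).sum()),
        }

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleLabels):
            return NotImplemented
        return self.labels.sort_index().equals(other.labels.sort_index())
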