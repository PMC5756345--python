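"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: GMT gene sets, two/three-column edge-list TSV, SIF,
gene-by-sample count TSV, two-column sample-label TSV, and TSV/JSON result
tables.  Gene symbols are upper-cased at ingest because pathway and network
sources disagree on symbol case.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    NetworkLayer,
    SampleLabels,
    normalize_class_label,
)

__all__ = [
    "read_gene_sets",
    "write_gene_sets",
    "read_network_layer",
    "write_network_layer",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "write_gene_list",
    "read_gene_list",
    "write_json",
]


def read_gene_sets(path: str | Path, format: str = "gmt") -> GeneSetCollection:
    """Read a gene-set collection.

    GMT lines are ``id<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    genes within a line are collapsed with a warning; duplicate pathway ids
    are an error.
    """
    if format != "gmt":
        raise ValueError(f"unsupported gene-set format {format!r}")
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} "
                    "field(s); expected id, description and at least one gene"
                )
            pid = fields[0].strip()
            if pid in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate pathway id {pid!r}")
            genes: list[str] = []
            seen: set[str] = set()
            n_dup = 0
            for raw in fields[2:]:
                sym = raw.strip().upper()
                if not sym:
                    continue
                if sym in seen:
                    n_dup += 1
                    continue
                seen.add(sym)
                genes.append(sym)
            if n_dup:
                warnings.warn(
                    f"{path.name}:{lineno}: pathway {pid!r} had {n_dup} "
                    "duplicate gene symbol(s); collapsed",
                    stacklevel=2,
                )
            if not genes:
                raise ValueError(f"{path.name}:{lineno}: pathway {pid!r} has no genes")
            sets[pid] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, source_name=path.stem)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid, genes in collection.sets.items():
            desc = collection.source_name or pid
            fh.write("\t".join([pid, desc, *genes]) + "\n")


def read_network_layer(
    path: str | Path, format: str = "edge_tsv", layer_name: str = "network"
) -> NetworkLayer:
    """Read one undirected interaction layer.

    ``edge_tsv`` rows are ``geneA geneB [weight]`` (whitespace separated;
    weights are ignored — the method uses unweighted degree).  ``sif`` rows
    are ``A relation B [B2 ...]`` and fan out to one edge per target.
    Self-loops are dropped with a counted warning; edges are deduplicated
    regardless of pair order.
    """
    if format not in ("edge_tsv", "sif"):
        raise ValueError(f"unsupported network format {format!r}")
    path = Path(path)
    edges: list[tuple[str, str]] = []
    endpoints: set[str] = set()
    n_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = [t.upper() for t in line.split()]
            n_rows += 1
            if format == "edge_tsv":
                if len(tokens) < 2:
                    raise ValueError(
                        f"{path.name}:{lineno}: expected at least 2 columns, "
                        f"got {len(tokens)}"
                    )
                pairs = [(tokens[0], tokens[1])]
            else:  # sif
                if len(tokens) < 3:
                    raise ValueError(
                        f"{path.name}:{lineno}: SIF row needs "
                        "'source relation target [target ...]'"
                    )
                src = tokens[0]
                pairs = [(src, tgt) for tgt in tokens[2:]]
            for a, b in pairs:
                endpoints.update((a, b))
                edges.append((a, b))
    if n_rows == 0:
        raise ValueError(f"{path}: empty network file")
    return NetworkLayer.from_edges(layer_name, edges, extra_nodes=endpoints)


def write_network_layer(layer: NetworkLayer, path: str | Path) -> None:
    """Write a layer as a sorted two-column edge TSV (isolated nodes as self-ref comments are not emitted)."""
    path = Path(path)
    rows = sorted(tuple(sorted(e)) for e in layer.edges)
    with path.open("w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample count TSV (header row of sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path.name}: non-numeric count column(s): {non_numeric[:5]}")
    return ExpressionMatrix(counts=df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene")


def read_labels(path: str | Path) -> SampleLabels:
    """Read a two-column ``sample<TAB>class`` table (header optional)."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path.name}:{lineno}: expected 2 columns")
            sample, klass = fields[0].strip(), fields[1].strip()
            if lineno == 1 and klass.lower() in ("class", "label", "group"):
                continue  # header row
            rows.append((sample, normalize_class_label(klass)))
    if not rows:
        raise ValueError(f"{path}: no sample labels found")
    samples = [s for s, _ in rows]
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample ids")
    return SampleLabels(labels=pd.Series(dict(rows), dtype=object))


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample\tclass\n")
        for sample, klass in labels.labels.items():
            fh.write(f"{sample}\t{klass}\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path: str | Path) -> set[str]:
    return {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
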