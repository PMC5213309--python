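"""Readers and writers for the external formats the pipeline touches.

Tab-separated files use a fixed dialect (UTF-8, tab delimiter, no quoting,
first row header) so fixtures stay bit-exact; gene identifiers are opaque,
case-sensitive strings.  Readers reject malformed input with line-numbered
errors rather than silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "TermAnnotation",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "write_annotations",
    "write_network",
]


@dataclass
class GeneSetCollection:
    """Ordered map set name -> (description, gene list).

    Gene lists are non-empty and duplicate-free within a set; the insertion
    order of sets is preserved (it is the GMT file order on read).
    """

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes_of(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class TermAnnotation:
    """Map term_id -> (term name, annotated gene set).  Flat — no ontology DAG."""

    terms: dict[str, tuple[str, set[str]]]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def genes_of(self, term_id: str) -> set[str]:
        return self.terms[term_id][1]

    def name_of(self, term_id: str) -> str:
        return self.terms[term_id][0]


# ---------------------------------------------------------------- counts TSV


def read_counts(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: line 1: header needs >= 2 tab-separated fields")
        sample_ids = header[1:]
        _reject_duplicates(sample_ids, f"{path}: line 1: duplicate sample id")
        n_fields = len(header)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_fields} fields, got {len(fields)}"
                )
            gene = fields[0]
            if gene in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
            gene_ids.append(gene)
    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    if np.allclose(values.to_numpy() % 1.0, 0.0):
        values = values.astype(np.int64)
        scale = "counts"
    else:
        scale = "log2cpm"
    return ExpressionMatrix(values, scale=scale)


def write_counts(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values
    if matrix.scale == "counts":
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def _reject_duplicates(items, prefix: str) -> None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            raise ValueError(f"{prefix} {it!r}")
        seen.add(it)


# ------------------------------------------------------------- sample sheet


def read_sample_sheet(path) -> SampleDesign:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in tab.columns:
        raise ValueError(f"{path}: sample sheet needs a 'sample' column")
    return SampleDesign(tab.set_index("sample"))


def write_sample_sheet(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------- GMT


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a set are dropped with a logged warning; a line
    with fewer than three fields is a parse error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(fields[2:]))
            if len(genes) != len(fields) - 2:
                logger.warning(
                    "%s: line %d: set %r had duplicate genes; deduplicated",
                    path, lineno, name,
                )
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# -------------------------------------------------------------- annotations


def read_annotations(path) -> TermAnnotation:
    """Read a flat term annotation TSV: columns term_id, term_name, gene."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"term_id", "term_name", "gene"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {sorted(missing)}")
    terms: dict[str, tuple[str, set[str]]] = {}
    for tid, sub in tab.groupby("term_id", sort=False):
        names = sub["term_name"].unique()
        if len(names) > 1:
            raise ValueError(f"{path}: term {tid!r} has conflicting names {list(names)}")
        terms[tid] = (names[0], set(sub["gene"]))
    return TermAnnotation(terms)


def write_annotations(annotation: TermAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\tgene\n")
        for tid, (name, genes) in annotation.terms.items():
            for g in sorted(genes):
                fh.write(f"{tid}\t{name}\t{g}\n")


# ------------------------------------------------------------------ network


def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Serialize a gene network with its node/edge attributes.

    ``graphml`` keeps all attributes; ``edgelist`` writes a TSV with columns
    gene_a, gene_b, r.
    """
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tr\n")
            for a, b, data in sorted(network.edges(data=True)):
                fh.write(f"{a}\t{b}\t{data.get('r', float('nan')):.6g}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")
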