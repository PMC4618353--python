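"""Readers and writers for the tab-separated tables and the Newick tree.

Every table is TSV with a header row; numeric values are written with 12
significant digits so that write(read(x)) round-trips losslessly at that
precision. Missing values are rejected (absence must be encoded as 0.0
upstream).
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, validate_annotation, validate_samples

FLOAT_FORMAT = "%.12g"


def read_expression_matrix(path, transform: str = "raw") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header of sample ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        sample_ids = header[1:]
        seen: dict[str, int] = {}
        for s in sample_ids:
            seen[s] = seen.get(s, 0) + 1
        dups = [s for s, k in seen.items() if k > 1]
        if dups:
            raise ValueError(f"duplicated sample ids in header: {', '.join(dups)}")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        gene_seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {n_cols}"
                )
            gene = fields[0]
            if gene in gene_seen:
                raise ValueError(f"{path}: line {lineno}: duplicated gene id {gene!r}")
            gene_seen.add(gene)
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno} ({gene}): {exc}") from None
            gene_ids.append(gene)
    data = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(data, transform=transform)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")


def read_samples(path, species: Sequence[str] | None = None) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species": str})
    return validate_samples(samples, species=species)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_annotation(path, species: Sequence[str] | None = None) -> pd.DataFrame:
    annotation = pd.read_csv(path, sep="\t")
    return validate_annotation(annotation, species=species)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def validate_tree(tree: dendropy.Tree, species: Sequence[str]) -> dendropy.Tree:
    """Check tip set and branch lengths of a phylogeny."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    expected = set(species)
    missing = expected - tips
    extra = tips - expected
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing tips: {sorted(missing)}")
        if extra:
            parts.append(f"unexpected tips: {sorted(extra)}")
        raise ValueError("tree does not match species set; " + "; ".join(parts))
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        if edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
        total += edge.length
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    return tree


def read_tree(path, species: Sequence[str]) -> dendropy.Tree:
    """Read a Newick tree whose tips must exactly equal the species set."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return validate_tree(tree, species)


def tree_from_newick(newick: str, species: Sequence[str]) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return validate_tree(tree, species)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
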