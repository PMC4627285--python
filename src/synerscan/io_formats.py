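"""Readers and writers for every on-disk artifact.

Formats: tab-separated expression and design tables, GMT gene-set
collections, results TSVs, and the CDT/GTR pair consumed by Java TreeView.
All writers are deterministic — identical inputs produce byte-identical
files (fixed field order, ``str(float)`` shortest-round-trip numbers for
TSVs, 6-decimal fixed point for CDT/GTR, ``\\n`` line endings).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .containers import (
    DESIGN_COLUMNS,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    SampleDesign,
)

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import ClusterTree


def _fmt(x: float) -> str:
    """Shortest round-trip decimal representation."""
    return repr(float(x))


def read_expression(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a genes-in-rows TSV: first column gene IDs, header sample IDs."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty data section")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        # Python's float() is round-trip exact for repr output, unlike
        # pandas' fast path
        def parse(cell: object, _col: str = col) -> float:
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                gene = df.index[df[_col].isna()][0]
                raise FormatError(
                    f"{path}: missing value at gene {gene!r}, sample {_col!r}"
                )
            try:
                return float(cell)
            except ValueError:
                gene = df.index[df[_col] == cell][0]
                raise FormatError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {_col!r}"
                ) from None

        numeric[col] = df[col].map(parse)
    return ExpressionMatrix(numeric, scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        values = matrix.values.to_numpy()
        for gid, row in zip(matrix.gene_ids, values):
            fh.write(gid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_design(path: str | Path) -> SampleDesign:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise")
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\t" + "\t".join(DESIGN_COLUMNS) + "\n")
        for sid, row in design.table.iterrows():
            fields = [str(sid)] + [str(row[c]) for c in DESIGN_COLUMNS]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line — name, description, members."""
    path = Path(path)
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3"
                )
            name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: {len(members) - len(deduped)} duplicate "
                    f"member(s) in set {name!r} removed"
                )
            if name in collection:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            collection.add(name, deduped, desc)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + list(members)) + "\n")


def write_cdt_gtr(
    matrix: ExpressionMatrix, tree: "ClusterTree", out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write the TreeView-compatible CDT/GTR pair for a gene clustering.

    The CDT reorders genes to the tree's leaf order and carries the standard
    GID/ORF/NAME/GWEIGHT columns plus an EWEIGHT row; the GTR lists one line
    per merge (``NODEkX  child  child  similarity``) with node identifiers
    following the ``NODEkX`` / ``GENEiX`` convention so Java TreeView can
    load the pair. ``GENEiX`` numbers refer to the matrix's original row
    order, as produced by Cluster 3.0.
    """
    out_prefix = Path(out_prefix)
    if tree.n_leaves != matrix.n_genes or list(tree.leaf_names) != matrix.gene_ids:
        raise ValueError("tree was not built over this matrix's genes (ID mismatch)")

    def node_name(idx: int) -> str:
        if idx < tree.n_leaves:
            return f"GENE{idx}X"
        return f"NODE{idx - tree.n_leaves + 1}X"

    gtr_path = out_prefix.with_suffix(".gtr")
    with open(gtr_path, "w", newline="\n") as fh:
        for t, merge in enumerate(tree.merges):
            similarity = 1.0 - merge.distance
            fh.write(
                f"NODE{t + 1}X\t{node_name(merge.left)}\t{node_name(merge.right)}\t"
                f"{similarity:.6f}\n"
            )

    cdt_path = out_prefix.with_suffix(".cdt")
    values = matrix.values.to_numpy()
    with open(cdt_path, "w", newline="\n") as fh:
        fh.write("GID\tORF\tNAME\tGWEIGHT\t" + "\t".join(matrix.sample_ids) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t1.000000" * matrix.n_samples + "\n")
        for leaf in tree.leaf_order:
            gid = matrix.gene_ids[leaf]
            row = values[leaf]
            fh.write(
                f"GENE{leaf}X\t{gid}\t{gid}\t1.000000\t"
                + "\t".join(f"{v:.6f}" for v in row)
                + "\n"
            )
    return cdt_path, gtr_path


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Deterministic TSV writer: shortest-round-trip floats, LF endings."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        cols = list(df.columns)
        header = ([index_label] if index_label is not None else []) + [str(c) for c in cols]
        fh.write("\t".join(header) + "\n")
        for idx, row in df.iterrows():
            fields = [str(idx)] if index_label is not None else []
            for c in cols:
                v = row[c]
                if isinstance(v, (float, np.floating)):
                    fields.append(_fmt(v))
                elif isinstance(v, (bool, np.bool_)):
                    fields.append("True" if v else "False")
                else:
                    fields.append(str(v))
            fh.write("\t".join(fields) + "\n")


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for g in genes:
            fh.write(g + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write each named results table as ``<out_dir>/<name>.tsv``.

    Tables indexed by gene or set IDs are written with their index as the
    first column. Empty tables produce a header-only file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        index_label = df.index.name if df.index.name else None
        write_table(df, path, index_label=index_label)
        paths[name] = path
    return paths
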