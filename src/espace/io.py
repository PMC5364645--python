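"""Reading and writing expression matrices, hub lists and edge lists."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .core import Edge
from .data import ExpressionMatrix, HubSet
from .netgen import NetworkStructure

__all__ = [
    "ParseError",
    "read_expression",
    "read_hub_list",
    "write_expression",
    "write_edges",
    "read_edges",
    "write_graphml",
    "read_graphml_edges",
    "write_performance",
]

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("gene_a", "gene_b", "partial_correlation", "hub_adjacent")


class ParseError(ValueError):
    """A delimited input file could not be interpreted."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: file is empty")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows/columns")
    return df


def read_expression(path: str | Path, orientation: str = "genes-in-columns") -> ExpressionMatrix:
    """Read a delimited expression table as samples x genes.

    The first column holds row identifiers and the header line column
    identifiers.  With ``orientation='genes-in-rows'`` the table is
    transposed after reading.  Missing, duplicate-gene and non-numeric
    cells raise :class:`ParseError` with the offending location.
    """
    if orientation not in ("genes-in-columns", "genes-in-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = _read_table(path)
    if orientation == "genes-in-columns":
        # pandas silently renames duplicate header entries; check the raw header
        sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
        with Path(path).open() as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dupes = [g for g in set(header) if header.count(g) > 1]
        if dupes:
            raise ParseError(f"{path}: duplicate gene identifier(s): {sorted(dupes)}")
    if orientation == "genes-in-rows":
        df = df.T
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ParseError(f"{path}: duplicate gene identifier(s): {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ParseError(f"{path}: non-numeric value {df.loc[row, col]!r} "
                             f"at row {row!r}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        row, col = next(zip(*df.isna().values.nonzero()))
        raise ParseError(f"{path}: missing value at row {df.index[row]!r}, "
                         f"column {df.columns[col]!r}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate gene identifier(s): {dupes}")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=tuple(str(c) for c in df.columns),
        sample_ids=tuple(str(r) for r in df.index),
    )


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(X.values, index=list(X.sample_ids), columns=list(X.gene_ids))
    df.to_csv(path, sep="\t")


def read_hub_list(path: str | Path, gene_ids: Sequence[str]) -> HubSet:
    """One hub identifier per line; '#' starts a comment.

    Identifiers absent from ``gene_ids`` are logged as warnings, not
    errors — prior hub knowledge routinely covers genes that were not
    measured.  Duplicates collapse to a single index.
    """
    path = Path(path)
    ids = []
    for line in path.read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            ids.append(token)
    hubs, unmatched = HubSet.from_ids(ids, gene_ids)
    for u in unmatched:
        logger.warning("hub identifier %r not present in the expression matrix", u)
    return hubs


def write_edges(edges: Iterable[Edge], path: str | Path) -> None:
    """TSV edge list with full-precision partial correlations."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.rho!r}\t{int(e.hub_adjacent)}\n")


def read_edges(path: str | Path) -> list[Edge]:
    df = _read_table_no_index(path)
    missing = set(EDGE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(Edge(str(row["gene_a"]), str(row["gene_b"]),
                        float(row["partial_correlation"]),
                        bool(int(row.get("hub_adjacent", 0)))))
    return out


def _read_table_no_index(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_graphml(edges: Iterable[Edge], path: str | Path,
                  gene_ids: Sequence[str] | None = None) -> None:
    g = nx.Graph()
    if gene_ids is not None:
        g.add_nodes_from(gene_ids)
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b, partial_correlation=e.rho,
                   hub_adjacent=int(e.hub_adjacent))
    nx.write_graphml(g, path)


def read_graphml_edges(path: str | Path) -> list[Edge]:
    g = nx.read_graphml(path)
    out = []
    for a, b, attrs in g.edges(data=True):
        out.append(Edge(str(a), str(b), float(attrs.get("partial_correlation", 0.0)),
                        bool(int(attrs.get("hub_adjacent", 0)))))
    return out


def write_network_tsv(net: NetworkStructure, path: str | Path) -> None:
    """Two-column TSV edge list of node indices."""
    with Path(path).open("w") as fh:
        fh.write("node_a\tnode_b\n")
        for i, j in sorted(net.edges):
            fh.write(f"{i}\t{j}\n")


def read_network_tsv(path: str | Path, p: int) -> NetworkStructure:
    df = _read_table_no_index(path)
    edges = frozenset((int(a), int(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]))
    return NetworkStructure(p=p, edges=edges)


def write_performance(report, path: str | Path) -> None:
    """One-row TSV of the five recovery measures."""
    d = report.as_dict()
    with Path(path).open("w") as fh:
        fh.write("\t".join(d.keys()) + "\n")
        fh.write("\t".join(f"{v!r}" for v in d.values()) + "\n")
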