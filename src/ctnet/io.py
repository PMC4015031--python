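"""Reading and writing delimited tables, edge lists, and GraphML."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .noise import RegulatoryNetwork
from .normalization import META_COLUMNS, CtTable, ExpressionMatrix
from .regulation import PerturbationMatrix


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, newline="") as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in ("\t", ",", ";")}
    best = max(counts, key=counts.get)
    return best if counts[best] else "\t"


def read_ct_table(path, sep: str | None = None, id_column: str = "cell_id") -> CtTable:
    """Read a cells-as-rows Ct table with metadata columns.

    Expects columns ``cell_id``, ``time_h``, ``replicate``, optionally
    ``treatment``, then one column per assay.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep))
    if id_column not in df.columns:
        raise ValueError(f"missing {id_column!r} column")
    df = df.set_index(id_column)
    df.index.name = None
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df[meta_cols].copy()
    values = df.drop(columns=meta_cols).astype(float)
    return CtTable(values, meta)


def write_ct_table(ct: CtTable, path, sep: str = "\t") -> None:
    out = pd.concat([ct.cell_meta, ct.values], axis=1)
    out.to_csv(path, sep=sep, index_label="cell_id")


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    out = pd.concat([expr.cell_meta, expr.expr], axis=1)
    out.to_csv(path, sep=sep, index_label="cell_id")


def read_expression(path, sep: str | None = None, scale_factor: float = 1.0) -> ExpressionMatrix:
    """Read a normalized expression table written by :func:`write_expression`."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep)).set_index("cell_id")
    df.index.name = None
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df[meta_cols].copy()
    expr = df.drop(columns=meta_cols).astype(float)
    detected = expr / scale_factor >= 0.5
    return ExpressionMatrix(expr, detected, meta, scale_factor)


def read_network(path, sep: str | None = None) -> RegulatoryNetwork:
    """Read a 3-column (source, target, sign) edge list."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path, sep))
    if not {"source", "target", "sign"}.issubset(df.columns):
        df = pd.read_csv(path, sep=_sniff_sep(path, sep), header=None, names=["source", "target", "sign"])
    df["sign"] = df["sign"].astype(int)
    nodes = sorted(set(df["source"]) | set(df["target"]))
    return RegulatoryNetwork(nodes, df)


def write_network(net: RegulatoryNetwork, path, sep: str = "\t") -> None:
    net.edges.to_csv(path, sep=sep, index=False)


def write_graphml(graph_or_net, path) -> None:
    g = graph_or_net.to_networkx() if hasattr(graph_or_net, "to_networkx") else graph_or_net
    nx.write_graphml(g, path)


def read_motif_table(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path, sep), index_col=0).astype(float)


def read_perturbation_matrix(path, tau: float = 1.0, sep: str | None = None) -> PerturbationMatrix:
    path = Path(path)
    return PerturbationMatrix(pd.read_csv(path, sep=_sniff_sep(path, sep), index_col=0).astype(float), tau)
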