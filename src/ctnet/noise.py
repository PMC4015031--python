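"""Expression noise strength and its relation to regulatory-network topology.

Noise strength is the Fano-type statistic eta = variance / mean of a gene's
expression across single cells at one time point, computed over all cells
(undetected zeros included, since on/off heterogeneity is part of the
cell-to-cell variability).  Genes are placed into upstream / midstream /
downstream layers of a directed regulatory network by their activating edge
ratio, and noise levels are compared across layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .normalization import ExpressionMatrix

LAYERS = ("upstream", "midstream", "downstream")
#: activating edge-ratio demarcations: r > 4 (or no regulators) -> upstream,
#: r < 0.5 -> downstream, boundaries inclusive to midstream
UPSTREAM_RATIO = 4.0
DOWNSTREAM_RATIO = 0.5


@dataclass
class RegulatoryNetwork:
    """Directed signed gene-regulatory network.

    ``edges`` has columns ``source``, ``target``, ``sign`` (+1 activating,
    -1 inhibiting).  ``nodes`` may include isolated genes.
    """

    nodes: list
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"source", "target", "sign"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edges must have columns {sorted(required)}")
        if not set(self.edges["sign"].unique()) <= {1, -1}:
            raise ValueError("edge signs must be +1 or -1")
        known = set(self.nodes)
        endpoints = set(self.edges["source"]) | set(self.edges["target"])
        if not endpoints <= known:
            raise ValueError(f"edges reference unknown nodes: {sorted(endpoints - known)[:5]}")

    def activating_degrees(self) -> pd.DataFrame:
        """Out/in degree per node counting activating (+1) edges only."""
        act = self.edges[self.edges["sign"] == 1]
        out_deg = act["source"].value_counts()
        in_deg = act["target"].value_counts()
        df = pd.DataFrame(index=pd.Index(self.nodes, name="gene"))
        df["out_activating"] = out_deg.reindex(df.index).fillna(0).astype(int)
        df["in_activating"] = in_deg.reindex(df.index).fillna(0).astype(int)
        with np.errstate(divide="ignore", invalid="ignore"):
            df["edge_ratio"] = df["out_activating"] / df["in_activating"]
        return df

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, sign=int(row.sign))
        return g


@dataclass
class NoiseTable:
    """Noise strength eta (genes x time) and its per-gene z-scaled version."""

    eta: pd.DataFrame
    z: pd.DataFrame


def noise_strength(expr: ExpressionMatrix) -> NoiseTable:
    """eta_g(t) = sample variance / mean of unit-scale expression at t.

    All cells enter, including undetected zeros.  Zero mean leaves eta
    undefined (NaN).  The z table standardises each gene's eta across the
    time course (rows with zero SD stay NaN).
    """
    unit = expr.unit_scale()
    meta = expr.cell_meta
    times = np.sort(meta["time_h"].unique())
    eta = pd.DataFrame(index=unit.columns, columns=times, dtype=float)
    for t in times:
        sub = unit.loc[meta["time_h"] == t]
        if len(sub) < 2:
            raise ValueError(f"time point {t} has a single cell; variance undefined")
        mean = sub.mean(axis=0)
        var = sub.var(axis=0, ddof=1)
        eta[t] = (var / mean).where(mean > 0)
    mu = eta.mean(axis=1)
    sd = eta.std(axis=1, ddof=1)
    z = eta.sub(mu, axis=0).div(sd.where(sd > 0), axis=0)
    return NoiseTable(eta, z)


def classify_layers(net: RegulatoryNetwork) -> pd.Series:
    """Layer labels from the activating edge ratio r = out / in.

    No activating regulators or r > 4 -> upstream; r < 0.5 -> downstream;
    anything else (boundary values included) -> midstream.
    """
    deg = net.activating_degrees()
    labels = pd.Series("midstream", index=deg.index, name="layer")
    r = deg["edge_ratio"]
    labels[(deg["in_activating"] == 0) | (r > UPSTREAM_RATIO)] = "upstream"
    labels[(deg["in_activating"] > 0) & (r < DOWNSTREAM_RATIO)] = "downstream"
    return labels


def layer_noise_test(
    noise: NoiseTable,
    net: RegulatoryNetwork,
    greater: str = "downstream",
    lesser: str = "upstream",
) -> dict:
    """One-sided Mann-Whitney comparison of per-gene mean noise across layers.

    Each gene is summarised by its mean eta over the time course; the test
    asks whether ``greater``-layer genes are stochastically noisier than
    ``lesser``-layer genes.  The report also carries all pairwise layer
    comparisons and per-layer medians.
    """
    layers = classify_layers(net)
    summary = noise.eta.mean(axis=1)
    common = summary.index.intersection(layers.index)
    layers = layers.loc[common]
    summary = summary.loc[common]
    groups = {lay: summary[layers == lay].dropna().to_numpy() for lay in LAYERS}

    def one(a: str, b: str) -> dict:
        x, y = groups[a], groups[b]
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"need >= 2 genes in layers {a} and {b}")
        # exact null distribution is affordable for gene-panel sized groups
        tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if tie_free and max(len(x), len(y)) <= 25 else "auto"
        u, p = stats.mannwhitneyu(x, y, alternative="greater", method=method)
        return {"U": float(u), "p": float(p), "n": (len(x), len(y))}

    report = {
        "comparison": f"{greater} > {lesser}",
        **one(greater, lesser),
        "medians": {lay: float(np.median(g)) if len(g) else float("nan") for lay, g in groups.items()},
        "pairwise": {
            f"{a} > {b}": one(a, b)
            for a in LAYERS
            for b in LAYERS
            if a != b and len(groups[a]) >= 2 and len(groups[b]) >= 2
        },
    }
    return report


def cluster_noise_heatmap(noise: NoiseTable) -> dict:
    """Average-linkage (Euclidean) clustering of z-scaled noise rows.

    Rows containing undefined eta are excluded and reported.  Leaf order is
    deterministic: genes are pre-sorted by name so distance ties break
    alphabetically.
    """
    z = noise.z.dropna(axis=0, how="any")
    excluded = sorted(set(noise.z.index) - set(z.index))
    z = z.sort_index()
    if len(z) < 2:
        raise ValueError("need at least 2 well-defined genes to cluster")
    link = hierarchy.linkage(pdist(z.to_numpy(), metric="euclidean"), method="average")
    order = hierarchy.leaves_list(link)
    return {
        "genes": list(z.index),
        "linkage": link,
        "leaf_order": [z.index[i] for i in order],
        "excluded": excluded,
    }
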