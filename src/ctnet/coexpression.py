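"""Time-resolved signed Spearman co-expression networks and module detection.

At each time point, all gene pairs are tested for Spearman rank correlation
across single cells; Benjamini-Hochberg control is applied within the time
point.  Significant edges (signed by the correlation) define a network whose
rewiring across the time course is the object of interest.  Modules are cut
from average-linkage clustering of 1 - TOM, where TOM (topological overlap)
rewards genes that share neighbours as well as a direct edge, and hinge
genes are the carriers of negative edges between modules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .noise import noise_strength
from .normalization import ExpressionMatrix

DEFAULT_FDR = 0.05
DEFAULT_PVAL = 0.01
_EXACT_N_MAX = 9  # below this sample size, tie-free pairs get an exact permutation p


@lru_cache(maxsize=None)
def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted |rho| null distribution over all rank permutations (tie-free)."""
    base = np.arange(n, dtype=float)
    rhos = []
    for perm in itertools.permutations(range(n)):
        rhos.append(abs(np.corrcoef(base, np.asarray(perm, dtype=float))[0, 1]))
    return np.sort(np.asarray(rhos))


def _exact_p(rho: float, n: int) -> float:
    null = _exact_rho_null(n)
    # two-sided: fraction of permutations at least as extreme (with float slack)
    return float((null >= abs(rho) - 1e-12).mean())


@dataclass
class TimeNetwork:
    """Correlation network at one time point."""

    time_h: float
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_cells: int
    excluded: list = field(default_factory=list)

    def edges(self, criterion: str = "q", threshold: float | None = None) -> pd.DataFrame:
        """Significant signed edges: criterion 'q' (FDR < 0.05) or 'p' (< 0.01)."""
        if criterion == "q":
            sig = self.q.to_numpy() < (DEFAULT_FDR if threshold is None else threshold)
        elif criterion == "p":
            sig = self.p.to_numpy() < (DEFAULT_PVAL if threshold is None else threshold)
        else:
            raise ValueError("criterion must be 'q' or 'p'")
        genes = list(self.rho.columns)
        rows = []
        r = self.rho.to_numpy()
        pm = self.p.to_numpy()
        qm = self.q.to_numpy()
        for i, j in zip(*np.triu_indices(len(genes), k=1)):
            if sig[i, j]:
                rows.append(
                    {
                        "source": genes[i],
                        "target": genes[j],
                        "rho": r[i, j],
                        "p": pm[i, j],
                        "q": qm[i, j],
                        "sign": 1 if r[i, j] > 0 else -1,
                    }
                )
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q", "sign"])


@dataclass
class TimeNetworkSet:
    """Per-time-point Spearman networks over a shared gene panel."""

    networks: dict[float, TimeNetwork]

    def __getitem__(self, time_h) -> TimeNetwork:
        return self.networks[time_h]

    @property
    def time_points(self) -> list[float]:
        return sorted(self.networks)


def spearman_pair(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and its two-sided p.

    The p-value uses the t approximation except for tie-free samples below
    n = 9, where the exact permutation tail is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n < _EXACT_N_MAX and tie_free:
        return rho, _exact_p(rho, n)
    return rho, _t_approx_p(np.array([[rho]]), n)[0, 0]


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho_c * np.sqrt((n - 2) / (1 - rho_c**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def spearman_networks(
    expr: ExpressionMatrix,
    fdr: float = DEFAULT_FDR,
) -> TimeNetworkSet:
    """Per-time-point Spearman correlation matrices with BH-adjusted q-values.

    Genes with zero variance at a time point cannot be ranked informatively;
    they are excluded there and reported.  BH runs within each time point
    over all retained gene pairs.
    """
    meta = expr.cell_meta
    unit = expr.unit_scale()
    networks = {}
    for t in np.sort(meta["time_h"].unique()):
        sub = unit.loc[meta["time_h"] == t]
        n = len(sub)
        if n < 4:
            raise ValueError(f"time point {t}: fewer than 4 cells")
        sd = sub.std(axis=0)
        excluded = list(sd.index[sd == 0])
        sub = sub.loc[:, sd > 0]
        genes = list(sub.columns)
        ranks = stats.rankdata(sub.to_numpy(), axis=0)
        rho = np.corrcoef(ranks, rowvar=False)
        np.fill_diagonal(rho, 1.0)
        p = _t_approx_p(rho, n)
        if n < _EXACT_N_MAX:
            for i, j in zip(*np.triu_indices(len(genes), k=1)):
                _, p[i, j] = spearman_pair(sub.iloc[:, i], sub.iloc[:, j])
                p[j, i] = p[i, j]
        np.fill_diagonal(p, 0.0)

        iu = np.triu_indices(len(genes), k=1)
        q = np.zeros_like(p)
        if iu[0].size:
            qvals = stats.false_discovery_control(p[iu], method="bh")
            q[iu] = qvals
            q[(iu[1], iu[0])] = qvals
        rho_df = pd.DataFrame(rho, index=genes, columns=genes)
        networks[float(t)] = TimeNetwork(
            float(t),
            rho_df,
            pd.DataFrame(p, index=genes, columns=genes),
            pd.DataFrame(q, index=genes, columns=genes),
            n,
            excluded,
        )
    return TimeNetworkSet(networks)


def count_edges(nets: TimeNetworkSet, criterion: str = "q") -> pd.DataFrame:
    """Number of significant positive / negative edges per time point."""
    rows = []
    for t in nets.time_points:
        e = nets[t].edges(criterion)
        rows.append(
            {
                "time_h": t,
                "n_pos": int((e["sign"] == 1).sum()) if len(e) else 0,
                "n_neg": int((e["sign"] == -1).sum()) if len(e) else 0,
            }
        )
    return pd.DataFrame(rows).set_index("time_h")


def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric [0, 1] adjacency.

    omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k the row sums and unit diagonal.  High overlap means two genes share
    neighbours even if their direct edge is weak.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.diag(a).any():
        raise ValueError("adjacency diagonal must be zero")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    omega = (shared + a) / denom
    np.fill_diagonal(omega, 1.0)
    return omega


@dataclass
class ModuleAssignment:
    """Gene -> module id mapping from TOM-based clustering."""

    modules: pd.Series
    unassigned: list
    time_h: float
    n_modules: int
    linkage: np.ndarray | None = None

    def genes_in(self, module_id: int) -> list:
        return list(self.modules.index[self.modules == module_id])


def detect_modules(
    nets: TimeNetworkSet,
    time_h: float,
    n_modules: int = 2,
    criterion: str = "q",
    min_component_size: int = 3,
    signed: bool = False,
) -> ModuleAssignment:
    """Cut TOM-dissimilarity clustering of the significant correlation adjacency.

    Adjacency on edges significant at the chosen criterion is |rho| by
    default, or the signed variant (1 + rho) / 2 (anticorrelated genes get
    low adjacency instead of high) with ``signed=True``; zero elsewhere.
    Genes with no significant edge, and genes in connected components
    smaller than ``min_component_size`` (isolated edge pairs from
    borderline correlations, too small to constitute a module), are left
    unassigned and reported.  Module ids are ordered by module size
    (1 = largest), ties by first gene name.
    """
    net = nets[time_h]
    rho = net.rho.to_numpy()
    if criterion == "q":
        sig = net.q.to_numpy() < DEFAULT_FDR
    else:
        sig = net.p.to_numpy() < DEFAULT_PVAL
    weight = (1.0 + rho) / 2.0 if signed else np.abs(rho)
    a = np.where(sig, weight, 0.0)
    np.fill_diagonal(a, 0.0)
    genes = np.asarray(net.rho.columns)
    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components(a > 0, directed=False)
    comp_sizes = np.bincount(comp)
    connected = (a.sum(axis=1) > 0) & (comp_sizes[comp] >= min_component_size)
    unassigned = list(genes[~connected])
    sub = a[np.ix_(connected, connected)]
    sub_genes = genes[connected]
    if connected.sum() < n_modules:
        raise ValueError("fewer connected genes than requested modules")
    omega = tom(sub)
    diss = 1.0 - omega
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    # deepen the cut until n_modules branches of module size appear; loose
    # small branches (below min_component_size genes) are left unassigned,
    # mirroring the grey-module convention of weighted-network analysis
    raw = None
    for k in range(n_modules, len(sub_genes) + 1):
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
        big = [m for m in np.unique(labels) if (labels == m).sum() >= min_component_size]
        if len(big) >= n_modules:
            raw = labels
            big_set = set(
                sorted(big, key=lambda m: (-(labels == m).sum(), sorted(sub_genes[labels == m])[0]))[
                    :n_modules
                ]
            )
            break
    if raw is None:
        raise ValueError("could not resolve the requested number of modules")
    in_module = np.isin(raw, list(big_set))
    unassigned += list(sub_genes[~in_module])
    sub_genes = sub_genes[in_module]
    raw = raw[in_module]
    # stable relabel: 1 = largest module, ties by alphabetically first member
    order = sorted(
        np.unique(raw),
        key=lambda m: (-(raw == m).sum(), sorted(sub_genes[raw == m])[0]),
    )
    relabel = {m: i + 1 for i, m in enumerate(order)}
    modules = pd.Series([relabel[m] for m in raw], index=sub_genes, name="module")
    return ModuleAssignment(modules, sorted(unassigned), time_h, n_modules, link)


def module_trajectories(expr: ExpressionMatrix, modules: ModuleAssignment) -> dict:
    """Per-module mean expression and mean noise strength over time.

    Module expression at t is the mean over member genes of the per-gene mean
    expression (all cells); module noise is the mean of per-gene eta.
    """
    unit = expr.unit_scale()
    meta = expr.cell_meta
    times = np.sort(meta["time_h"].unique())
    eta = noise_strength(expr).eta
    mean_rows, noise_rows = {}, {}
    for m in sorted(modules.modules.unique()):
        genes = modules.genes_in(m)
        if not genes:
            raise ValueError(f"module {m} is empty")
        mean_rows[m] = [unit.loc[meta["time_h"] == t, genes].to_numpy().mean() for t in times]
        noise_rows[m] = eta.loc[genes].mean(axis=0).to_numpy()
    return {
        "mean_expression": pd.DataFrame(mean_rows, index=times).T,
        "mean_noise": pd.DataFrame(noise_rows, index=times).T,
    }


def hinge_genes(
    nets: TimeNetworkSet,
    modules: ModuleAssignment,
    time_h: float,
    criterion: str = "q",
) -> pd.DataFrame:
    """Rank genes by negative edges crossing module boundaries.

    A hinge gene anchors the antagonism between modules: it carries
    significant negative correlations to the opposite module.  Ranking is by
    the count of such incident cross-module negative edges, ties broken by
    the summed |rho| of those edges, then by gene name.
    """
    edges = nets[time_h].edges(criterion)
    neg = edges[edges["sign"] == -1]
    mod = modules.modules
    counts: dict[str, int] = {}
    weights: dict[str, float] = {}
    for row in neg.itertuples(index=False):
        ms = mod.get(row.source)
        mt = mod.get(row.target)
        if ms is None or mt is None or ms == mt:
            continue
        for g in (row.source, row.target):
            counts[g] = counts.get(g, 0) + 1
            weights[g] = weights.get(g, 0.0) + abs(row.rho)
    if not counts:
        return pd.DataFrame(columns=["gene", "n_cross_negative", "sum_abs_rho"])
    df = pd.DataFrame(
        {
            "gene": list(counts),
            "n_cross_negative": [counts[g] for g in counts],
            "sum_abs_rho": [weights[g] for g in counts],
        }
    )
    df = df.sort_values(
        ["n_cross_negative", "sum_abs_rho", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df
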