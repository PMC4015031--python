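"""Synthetic single-cell qPCR study generator with known ground truth.

The generator emulates a time-course single-cell qPCR design: per gene, a
time-varying detection probability (Bernoulli dropout, independent of level
by default) and a time-varying mean expression on the normalized unit
scale; detected expression is Normal around the mean plus a contribution
from a per-cell latent factor shared by module members (inducing the
gene-gene correlations that module detection must recover); undetected
reactions are censored at Ct = 40.  Expression is simulated on the unit
scale and mapped back to Ct through the exact inverse of the normalization
map, so normalization round-trips the truth.  A layered directed network, a
knockdown perturbation matrix and a motif posterior table with one enriched
motif complete the study inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noise import RegulatoryNetwork, classify_layers
from .normalization import CENSORED_VALUE, CtTable, expression_to_ct
from .regulation import PerturbationMatrix

DEFAULT_TIME_POINTS = (0.0, 1.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0)
# detected expression support on the unit scale: the floor sits half a PCR
# cycle inside the detection boundary (corrected Ct 35.5) so that censoring
# never lands exactly on the cutoff after reference correction
EXPR_MIN, EXPR_MAX = 0.5625, 5.0


@dataclass
class GeneSpec:
    """Ground-truth parameters of one simulated gene.

    ``detect_prob`` and ``mean_expr`` carry one entry per time point;
    ``loadings`` maps latent-factor id -> weight (a gene in one module has a
    single entry; a hinge gene carries opposite-sign weights on two
    factors).
    """

    name: str
    detection_class: str
    detect_prob: np.ndarray
    mean_expr: np.ndarray
    expr_sd: float
    module_id: int | None = None
    factor_loading: float = 0.0
    loadings: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.detect_prob = np.asarray(self.detect_prob, dtype=float)
        self.mean_expr = np.asarray(self.mean_expr, dtype=float)
        if self.detect_prob.shape != self.mean_expr.shape:
            raise ValueError(f"{self.name}: detect_prob and mean_expr lengths differ")
        if ((self.detect_prob < 0) | (self.detect_prob > 1)).any():
            raise ValueError(f"{self.name}: detect_prob outside [0, 1]")
        if self.expr_sd <= 0:
            raise ValueError(f"{self.name}: expr_sd must be positive")
        if not self.loadings and self.module_id is not None and self.factor_loading:
            self.loadings = {self.module_id: self.factor_loading}


@dataclass
class SyntheticTruth:
    """Complete, seed-reproducible description of a simulated study."""

    genes: list[GeneSpec]
    time_points_h: np.ndarray
    n_cells_per_time: int = 120
    n_replicates: int = 3
    ref_gene: str = "GAPDH"
    ref_gene_mean_ct: float = 15.0
    ref_gene_sd: float = 0.25
    latent_factor_sd: float = 1.0
    network: RegulatoryNetwork | None = None
    perturbation_truth: PerturbationMatrix | None = None
    motif_truth: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_points_h = np.asarray(self.time_points_h, dtype=float)
        if (np.diff(self.time_points_h) <= 0).any():
            raise ValueError("time points must be strictly increasing")
        if self.n_cells_per_time < 2:
            raise ValueError("need at least 2 cells per time point")
        for g in self.genes:
            if g.detect_prob.size != self.time_points_h.size:
                raise ValueError(f"{g.name}: parameter vectors do not match time points")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def module_genes(self, module_id: int) -> list[str]:
        return [g.name for g in self.genes if g.module_id == module_id]


# ---------------------------------------------------------------------------
# trajectory templates for the five detection-dynamics classes

_TEMPLATES = {
    "ubiquitous": dict(p=[0.97] * 8, m=[1.6, 1.6, 1.7, 1.7, 1.8, 1.8, 1.7, 1.7]),
    "activated": dict(
        p=[0.15, 0.20, 0.45, 0.60, 0.75, 0.85, 0.90, 0.95],
        m=[0.9, 1.1, 1.4, 1.7, 2.0, 2.2, 2.3, 2.4],
    ),
    "deactivated": dict(
        p=[0.95, 0.90, 0.85, 0.75, 0.60, 0.45, 0.20, 0.15],
        m=[2.4, 2.3, 2.2, 2.0, 1.7, 1.4, 1.1, 0.9],
    ),
    "transient": dict(
        p=[0.20, 0.30, 0.70, 0.90, 0.70, 0.45, 0.30, 0.20],
        m=[0.9, 1.2, 1.8, 2.2, 1.8, 1.4, 1.2, 0.9],
    ),
    "variable": dict(
        p=[0.50, 0.35, 0.60, 0.40, 0.55, 0.45, 0.60, 0.50],
        m=[1.2, 1.0, 1.3, 1.1, 1.2, 1.1, 1.3, 1.2],
    ),
}


def make_truth(
    n_cells_per_time: int = 120,
    n_replicates: int = 3,
    time_points_h=DEFAULT_TIME_POINTS,
    class_counts: dict[str, int] | None = None,
    module_loading: float = 0.5,
    expr_sd: float = 0.4,
    latent_factor_sd: float = 1.0,
    include_hinge: bool = True,
    jitter: float = 0.02,
    seed: int = 0,
) -> SyntheticTruth:
    """Default 45-gene study design.

    Classes default to 16 ubiquitous / 11 activated / 7 deactivated /
    5 transient / 6 variable.  Module 1 holds 10 activated genes (latent
    factor 1), module 2 holds 8 ubiquitous low-expression genes (factor 2);
    one ubiquitous hinge gene (HINGE1) loads negatively on factor 1 and
    positively on factor 2, and SPI1 is included as the ubiquitous QC
    anchor.  Small per-gene jitter keeps trajectories distinct without
    blurring class boundaries.
    """
    if class_counts is None:
        class_counts = {
            "ubiquitous": 16,
            "activated": 11,
            "deactivated": 7,
            "transient": 5,
            "variable": 6,
        }
    rng = np.random.default_rng(seed)
    time_points_h = np.asarray(time_points_h, dtype=float)
    nt = time_points_h.size
    genes: list[GeneSpec] = []

    def add(name, cls, module=None, loading=0.0, loadings=None, mean_override=None, p_override=None):
        tpl = _TEMPLATES[cls]
        p = np.interp(
            np.linspace(0, 7, nt),
            np.arange(8),
            np.asarray(p_override if p_override is not None else tpl["p"], dtype=float),
        )
        m = np.interp(
            np.linspace(0, 7, nt), np.arange(8), np.asarray(tpl["m"], dtype=float)
        )
        p = np.clip(p + rng.normal(0, jitter, nt), 0.0, 1.0)
        if cls == "ubiquitous":
            p = np.clip(p, 0.9, 1.0)
        m = np.clip(m + rng.normal(0, jitter, nt), 0.7, 3.2)
        if mean_override is not None:
            m = np.asarray(mean_override, dtype=float)
        genes.append(
            GeneSpec(
                name,
                cls,
                p,
                m,
                expr_sd,
                module_id=module,
                factor_loading=loading,
                loadings=loadings or {},
            )
        )

    counts = dict(class_counts)
    idx = 1

    # module 1: activated genes sharing latent factor 1; their promoters switch
    # on fast, so by the module-detection time point most cells express them
    fast_on = [0.20, 0.35, 0.60, 0.80, 0.92, 0.95, 0.96, 0.97]
    n_mod1 = min(10, counts.get("activated", 0))
    for _ in range(n_mod1):
        add(f"TF{idx:02d}", "activated", module=1, loading=module_loading, p_override=fast_on)
        idx += 1
    counts["activated"] = counts.get("activated", 0) - n_mod1

    # module 2: ubiquitous, steadily low expression, latent factor 2
    n_mod2 = min(8, counts.get("ubiquitous", 0) - 2)  # keep room for SPI1 + hinge
    low = [0.95, 0.95, 0.95, 0.95, 1.0, 1.0, 1.0, 1.0]
    for _ in range(n_mod2):
        add(
            f"TF{idx:02d}",
            "ubiquitous",
            module=2,
            loading=module_loading,
            mean_override=np.interp(np.linspace(0, 7, nt), np.arange(8), low),
        )
        idx += 1
    counts["ubiquitous"] = counts.get("ubiquitous", 0) - n_mod2

    if include_hinge and counts.get("ubiquitous", 0) > 1:
        add(
            "HINGE1",
            "ubiquitous",
            module=2,
            loadings={1: -module_loading, 2: module_loading},
        )
        counts["ubiquitous"] -= 1
    if counts.get("ubiquitous", 0) > 0:
        add("SPI1", "ubiquitous")
        counts["ubiquitous"] -= 1

    for cls in ("ubiquitous", "activated", "deactivated", "transient", "variable"):
        for _ in range(max(0, counts.get(cls, 0))):
            add(f"TF{idx:02d}", cls)
            idx += 1

    names = [g.name for g in genes]
    net = generate_network(
        len(names),
        (0.2, 0.4, 0.4),
        seed=int(rng.integers(2**31)),
        node_names=names,
    )
    pert = generate_perturbation_matrix(net, seed=int(rng.integers(2**31)))
    return SyntheticTruth(
        genes,
        time_points_h,
        n_cells_per_time,
        n_replicates,
        latent_factor_sd=latent_factor_sd,
        network=net,
        perturbation_truth=pert,
        motif_truth={"AP1": 5.0},
        seed=seed,
    )


def generate_ct_table(truth: SyntheticTruth, treatment: str = "PMA") -> CtTable:
    """Draw a censored Ct table from the ground truth.

    Per cell and gene: with probability detect_prob[t] the gene is detected
    and its unit-scale expression is mean_expr[t] + sum_f loading_f z_cf +
    Normal(0, expr_sd), clamped to (0.5, 5.0]; the cell's latent factors
    z_cf are Normal(0, latent_factor_sd).  Detected expression is mapped to
    Ct via the inverse normalization map plus the cell's reference-gene
    offset from the cohort median; undetected reactions read Ct = 40.
    Deterministic in (parameters, seed).
    """
    rng = np.random.default_rng(truth.seed)
    times = truth.time_points_h
    n_per = truth.n_cells_per_time
    n_cells = n_per * times.size
    factor_ids = sorted({f for g in truth.genes for f in g.loadings})

    ref_ct = rng.normal(truth.ref_gene_mean_ct, truth.ref_gene_sd, n_cells)
    delta_ref = ref_ct - np.median(ref_ct)

    cell_ids, time_col, rep_col = [], [], []
    for ti, t in enumerate(times):
        for i in range(n_per):
            cell_ids.append(f"t{int(t):03d}h_r{i % truth.n_replicates + 1}_c{i:03d}")
            time_col.append(t)
            rep_col.append(f"r{i % truth.n_replicates + 1}")
    time_col = np.asarray(time_col)

    z = rng.normal(0.0, truth.latent_factor_sd, (n_cells, max(len(factor_ids), 1)))
    fidx = {f: i for i, f in enumerate(factor_ids)}

    ct = np.full((n_cells, len(truth.genes)), CENSORED_VALUE)
    for gi, g in enumerate(truth.genes):
        p = np.interp(time_col, times, g.detect_prob)
        mu = np.interp(time_col, times, g.mean_expr)
        detected = rng.random(n_cells) < p
        e = mu + rng.normal(0.0, g.expr_sd, n_cells)
        for f, w in g.loadings.items():
            e = e + w * z[:, fidx[f]]
        e = np.clip(e, EXPR_MIN, EXPR_MAX)
        raw = expression_to_ct(e) + delta_ref
        ct[detected, gi] = raw[detected]
    # physical floor: a Ct cannot be negative (astronomically rare with the
    # default reference spread; breaks the exact round-trip only at the clamp)
    ct = np.maximum(ct, 1e-3)

    values = pd.DataFrame(ct, index=cell_ids, columns=truth.gene_names)
    values[truth.ref_gene] = ref_ct
    meta = pd.DataFrame(
        {"time_h": time_col, "replicate": rep_col, "treatment": treatment},
        index=cell_ids,
    )
    return CtTable(values, meta)


def generate_network(
    n_genes: int,
    layer_fractions: tuple[float, float, float],
    seed: int,
    node_names: list[str] | None = None,
    inhibitory_fraction: float = 0.2,
) -> RegulatoryNetwork:
    """Layered directed signed network with exact layer fractions.

    ``layer_fractions`` = (upstream, midstream, downstream) proportions;
    counts are apportioned by largest remainder.  Upstream nodes have no
    activating regulators; midstream nodes get equal activating in/out
    degree (edge ratio 1); downstream nodes only receive.  Extra inhibitory
    edges are sprinkled in (they do not enter the edge-ratio rule).
    Re-classifying the result recovers the requested fractions exactly.
    """
    fr = np.asarray(layer_fractions, dtype=float)
    if fr.size != 3 or abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
        raise ValueError("layer fractions must be 3 nonnegative proportions summing to 1")
    raw = fr * n_genes
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(rem)[::-1][: n_genes - counts.sum()]:
        counts[i] += 1
    n_up, n_mid, n_down = (int(c) for c in counts)
    if (n_mid or n_down) and n_up == 0:
        raise ValueError("midstream/downstream nodes need at least one upstream source")
    if n_mid == 1 and n_down == 0:
        raise ValueError("a lone midstream node with no downstream targets is infeasible")
    if node_names is not None:
        if len(node_names) != n_genes:
            raise ValueError("node_names length must equal n_genes")
        names = list(node_names)
    else:
        names = [f"G{i:02d}" for i in range(n_genes)]
    rng = np.random.default_rng(seed)
    up = names[:n_up]
    mid = names[n_up : n_up + n_mid]
    down = names[n_up + n_mid :]

    # construction keeps each layer's activating edge ratio provably in range:
    # upstream nodes receive nothing (in = 0); each midstream node gets one
    # regulator and one target (r = 1, or r = 0.5 in the ring fallback);
    # downstream nodes only receive (r = 0)
    edges = []
    for g in mid:
        edges.append((up[rng.integers(n_up)], g, 1))
        if down:
            edges.append((g, down[rng.integers(len(down))], 1))
    if mid and not down:
        for i, g in enumerate(mid):
            edges.append((g, mid[(i + 1) % len(mid)], 1))
    for g in down:
        edges.append((up[rng.integers(n_up)], g, 1))
    # upstream fan-out goes to downstream only, so midstream ratios stay put
    for g in up:
        if down:
            edges.append((g, down[rng.integers(len(down))], 1))
    edges = sorted(set(edges))

    # inhibitory edges carry no layer information; add a sprinkle anywhere
    n_inhib = int(round(inhibitory_fraction * len(edges)))
    existing = {(s, t) for s, t, _ in edges}
    attempts = 0
    while n_inhib > 0 and attempts < 50 * n_inhib:
        s, t = (names[i] for i in rng.integers(n_genes, size=2))
        attempts += 1
        if s != t and (s, t) not in existing:
            edges.append((s, t, -1))
            existing.add((s, t))
            n_inhib -= 1

    df = pd.DataFrame(edges, columns=["source", "target", "sign"])
    net = RegulatoryNetwork(names, df)
    got = classify_layers(net).value_counts()
    want = {"upstream": n_up, "midstream": n_mid, "downstream": n_down}
    for lay, n in want.items():
        if int(got.get(lay, 0)) != n:
            raise RuntimeError(f"layer construction failed: {lay} {got.get(lay, 0)} != {n}")
    return net


def generate_perturbation_matrix(
    net: RegulatoryNetwork, seed: int, tau: float = 1.0, noise_sd: float = 0.2
) -> PerturbationMatrix:
    """Knockdown response scores consistent with the network's edges.

    True edges get |effect| >= tau with the edge's sign; non-edges get
    sub-threshold Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    nodes = list(net.nodes)
    eff = rng.normal(0.0, noise_sd, (len(nodes), len(nodes)))
    eff = np.clip(eff, -0.9 * tau, 0.9 * tau)
    df = pd.DataFrame(eff, index=nodes, columns=nodes)
    np.fill_diagonal(df.values, 0.0)
    for row in net.edges.itertuples(index=False):
        df.loc[row.source, row.target] = row.sign * (tau + abs(rng.normal(0.5, 0.3)))
    return PerturbationMatrix(df, tau)


def generate_motif_table(
    genes,
    motifs,
    module_genes,
    enriched_motif: str,
    base_rate: float = 0.5,
    enrichment: float = 5.0,
    seed: int = 0,
    dispersion: float = 0.7,
) -> pd.DataFrame:
    """Motif posterior-count table with one motif enriched in one gene set.

    Counts are nonnegative reals (sums of posterior binding probabilities)
    drawn from a Gamma with mean ``base_rate`` (times ``enrichment`` for the
    module x enriched-motif block) and variance = dispersion x mean;
    dispersion < 1 makes the counts under-dispersed relative to Poisson, as
    posterior sums empirically are.
    """
    if enriched_motif not in motifs:
        raise ValueError(f"{enriched_motif!r} not among motifs")
    if base_rate <= 0 or enrichment < 1:
        raise ValueError("need base_rate > 0 and enrichment >= 1")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    motifs = list(motifs)
    module_set = set(module_genes)
    mean = np.full((len(genes), len(motifs)), base_rate)
    j = motifs.index(enriched_motif)
    for i, g in enumerate(genes):
        if g in module_set:
            mean[i, j] *= enrichment
    scale = dispersion
    shape = mean / scale
    counts = rng.gamma(shape, scale)
    return pd.DataFrame(counts, index=genes, columns=motifs)
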