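"""Module-level regulatory integration: knockdown edge balance and motif
enrichment by a Poisson tail over summed binding-site posteriors.

A knockdown (RNAi) perturbation matrix gives directed regulator -> responder
edges; counting, per co-expression module, how many edges leave the module's
genes (targets) versus enter them (targeting) places the module in the
regulatory hierarchy.  Motif enrichment compares the summed a-posteriori
binding-site count of a motif over module promoters against a Poisson rate
calibrated on background promoters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ModuleAssignment
from .noise import RegulatoryNetwork


@dataclass
class PerturbationMatrix:
    """Knockdown response scores (regulator rows x responder columns).

    An edge regulator -> responder is called when |effect| >= tau; its sign
    is the sign of the effect.  The diagonal (self-knockdown) is never an
    edge.
    """

    effect: pd.DataFrame
    tau: float = 1.0

    def derive_edges(self) -> pd.DataFrame:
        rows = []
        for reg in self.effect.index:
            for res in self.effect.columns:
                if reg == res:
                    continue
                v = self.effect.loc[reg, res]
                if abs(v) >= self.tau:
                    rows.append({"source": reg, "target": res, "sign": 1 if v > 0 else -1})
        return pd.DataFrame(rows, columns=["source", "target", "sign"])

    def to_network(self) -> RegulatoryNetwork:
        nodes = sorted(set(self.effect.index) | set(self.effect.columns))
        return RegulatoryNetwork(nodes, self.derive_edges())


def module_edge_balance(
    net: RegulatoryNetwork | PerturbationMatrix,
    modules: ModuleAssignment,
    sign_test: bool = True,
) -> pd.DataFrame:
    """Targets vs targeting edge counts per module.

    n_targets(M) sums the out-degree of module genes (edges the module
    exerts); n_targeting(M) sums their in-degree (edges acting on the
    module).  The optional two-sided sign test asks whether per-gene
    (out - in) differences within the module lean one way.  Module genes
    absent from the network are reported and skipped.
    """
    if isinstance(net, PerturbationMatrix):
        net = net.to_network()
    out_deg = net.edges["source"].value_counts()
    in_deg = net.edges["target"].value_counts()
    known = set(net.nodes)
    rows = []
    for m in sorted(modules.modules.unique()):
        genes = modules.genes_in(m)
        missing = [g for g in genes if g not in known]
        present = [g for g in genes if g in known]
        outs = np.array([int(out_deg.get(g, 0)) for g in present])
        ins = np.array([int(in_deg.get(g, 0)) for g in present])
        row = {
            "module": m,
            "n_targets": int(outs.sum()),
            "n_targeting": int(ins.sum()),
            "n_genes": len(present),
            "missing": missing,
        }
        if sign_test:
            diff = outs - ins
            n_pos, n_neg = int((diff > 0).sum()), int((diff < 0).sum())
            if n_pos + n_neg:
                row["sign_test_p"] = float(
                    stats.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue
                )
            else:
                row["sign_test_p"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")


def poisson_tail(observed: float, rate: float) -> float:
    """Upper tail P(X >= ceil(observed)) for X ~ Poisson(rate).

    Non-integer observed counts (sums of posterior probabilities) are
    rounded up before taking the tail, which can only make the p-value
    smaller than any interpolation and is the stricter convention.
    observed = 0 returns exactly 1.
    """
    if rate <= 0:
        raise ValueError("Poisson rate must be positive")
    if observed < 0:
        raise ValueError("observed count must be nonnegative")
    k = math.ceil(observed)
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, rate))


def poisson_tail_continuous(observed: float, rate: float) -> float:
    """Continuity-free alternative: regularized upper gamma Q(observed, rate).

    Interpolates the Poisson survival function in the observed count, for
    use when the posterior sums should not be rounded.
    """
    if rate <= 0:
        raise ValueError("Poisson rate must be positive")
    if observed <= 0:
        return 1.0
    from scipy.special import gammainc

    return float(gammainc(observed, rate))


def motif_enrichment(
    table: pd.DataFrame,
    module_genes,
    motif: str,
    background_genes=None,
    allow_overlap: bool = False,
) -> dict:
    """Poisson-tail over-representation of one motif in module promoters.

    ``table`` is promoters (genes) x motifs with nonnegative a-posteriori
    binding-site counts.  observed = summed module counts for the motif;
    the null rate lambda = module size x mean per-promoter count over the
    background (all profiled non-module genes unless given explicitly).
    """
    if motif not in table.columns:
        raise ValueError(f"motif {motif!r} not in table")
    module_genes = [g for g in module_genes if g in table.index]
    if background_genes is None:
        background_genes = [g for g in table.index if g not in set(module_genes)]
    else:
        background_genes = [g for g in background_genes if g in table.index]
        overlap = set(background_genes) & set(module_genes)
        if overlap and not allow_overlap:
            raise ValueError(f"module and background overlap: {sorted(overlap)[:5]}")
    if not background_genes:
        raise ValueError("empty background gene set")
    if (table < 0).to_numpy().any():
        raise ValueError("motif counts must be nonnegative")

    observed = float(table.loc[module_genes, motif].sum())
    background_mean = float(table.loc[background_genes, motif].mean())
    if background_mean <= 0:
        return {
            "motif": motif,
            "observed": observed,
            "lambda": 0.0,
            "p": float("nan"),
            "flag": "zero background mean",
        }
    lam = len(module_genes) * background_mean
    return {
        "motif": motif,
        "observed": observed,
        "lambda": lam,
        "p": poisson_tail(observed, lam),
        "n_module": len(module_genes),
        "n_background": len(background_genes),
    }


def motif_enrichment_all(
    table: pd.DataFrame,
    module_genes,
    background_genes=None,
) -> pd.DataFrame:
    """Run :func:`motif_enrichment` for every motif, BH-adjusted across motifs."""
    rows = [motif_enrichment(table, module_genes, m, background_genes) for m in table.columns]
    df = pd.DataFrame(rows).set_index("motif")
    ok = df["p"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = stats.false_discovery_control(df.loc[ok, "p"].to_numpy(), method="bh")
    return df
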