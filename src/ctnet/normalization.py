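"""Ct-table ingestion, censoring, reference-gene normalization, and cell QC.

Single-cell qPCR reports a cycle-threshold (Ct) value per cell and assay;
low Ct means high transcript abundance and failed reactions are censored to
Ct = 40.  This module turns a censored Ct table into a normalized expression
matrix on a unit scale where the detection cutoff sits at 0.5, applies the
two-gene viability filter, and subsamples a fixed number of cells per time
point so that every downstream statistic sees a balanced design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CENSOR_CT = 36.0
CENSORED_VALUE = 40.0
#: slope of the affine inverse-normalization map e = (40 - Ct') / 8, the unique
#: affine map sending the censored value (40) to 0 and the cutoff (36) to 0.5
INVERSE_SLOPE = 8.0
DETECTION_THRESHOLD = 0.5

META_COLUMNS = ("time_h", "replicate", "treatment")


@dataclass
class CtTable:
    """Raw (censored) Ct values for cells x assays plus per-cell metadata.

    ``values`` rows are cells, columns are assays (genes plus the reference
    gene).  ``cell_meta`` is indexed like ``values`` and carries ``time_h``,
    ``replicate`` and ``treatment`` columns.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.cell_meta.index):
            raise ValueError("values and cell_meta must share the same cell index")
        for col in ("time_h", "replicate"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column {col!r}")
        if "treatment" not in self.cell_meta.columns:
            self.cell_meta = self.cell_meta.assign(treatment="none")
        vals = self.values.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("negative Ct values are not physical")

    @property
    def assay_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def subset(self, cell_ids) -> "CtTable":
        return CtTable(self.values.loc[cell_ids], self.cell_meta.loc[cell_ids])


@dataclass
class ExpressionMatrix:
    """Normalized expression (cells x genes) with detection calls.

    Expression lives on the unit scale e in [0, 5] by default (``scale_factor``
    = 1) where e >= 0.5 marks a detected transcript; ``scale_factor`` = 10
    reproduces the x10 display convention (cutoff at 5).  e = 0 exactly where
    the underlying Ct was censored.
    """

    expr: pd.DataFrame
    detected: pd.DataFrame
    cell_meta: pd.DataFrame
    scale_factor: float = 1.0
    invalid_cells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.cell_meta.index):
            raise ValueError("expr and cell_meta must share the same cell index")
        if self.expr.shape != self.detected.shape:
            raise ValueError("expr and detected shapes differ")

    @property
    def genes(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def time_points(self) -> np.ndarray:
        return np.sort(self.cell_meta["time_h"].unique())

    def at_time(self, time_h) -> "ExpressionMatrix":
        mask = self.cell_meta["time_h"] == time_h
        return ExpressionMatrix(
            self.expr.loc[mask],
            self.detected.loc[mask],
            self.cell_meta.loc[mask],
            self.scale_factor,
        )

    def unit_scale(self) -> pd.DataFrame:
        """Expression on the unit scale regardless of display scale."""
        return self.expr / self.scale_factor


def censor_ct(values):
    """Censor unreliable Ct measurements: entries above 36 are set to 40.

    Accepts a DataFrame or ndarray and returns the same type; entries <= 36
    are passed through unchanged.
    """
    if isinstance(values, pd.DataFrame):
        return values.where(values <= CENSOR_CT, CENSORED_VALUE)
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("Ct values must be finite")
    return np.where(arr > CENSOR_CT, CENSORED_VALUE, arr)


def inverse_normalize(corrected_ct, scale_factor: float = 1.0):
    """Map corrected Ct to the unit expression scale: e = (40 - Ct') / 8.

    Ct' = 36 maps to 0.5 (or 5 with ``scale_factor`` = 10) and the censored
    value 40 maps to 0.
    """
    return (CENSORED_VALUE - np.asarray(corrected_ct, dtype=float)) / INVERSE_SLOPE * scale_factor


def expression_to_ct(expr, scale_factor: float = 1.0):
    """Inverse of :func:`inverse_normalize`: corrected Ct = 40 - 8 e."""
    return CENSORED_VALUE - INVERSE_SLOPE * np.asarray(expr, dtype=float) / scale_factor


def normalize(ct: CtTable, ref_gene: str = "GAPDH", scale_factor: float = 1.0) -> ExpressionMatrix:
    """Reference-correct and inverse-normalize a censored Ct table.

    Each cell's Ct values are shifted by that cell's reference-gene deviation
    from the cohort median reference Ct, re-censored (corrected Ct > 36 set
    back to 40), and mapped to expression e = (40 - Ct') / 8.  Cells whose
    reference gene itself failed (Ct = 40) cannot be normalized; they are
    dropped and listed in ``invalid_cells``.
    """
    if ref_gene not in ct.values.columns:
        raise ValueError(f"reference gene {ref_gene!r} not in assay columns")
    ref = ct.values[ref_gene]
    invalid = list(ct.values.index[ref >= CENSORED_VALUE])
    keep = ct.values.index.difference(invalid, sort=False)
    values = ct.values.loc[keep]
    meta = ct.cell_meta.loc[keep]
    ref = ref.loc[keep]

    delta = ref - ref.median()
    genes = values.drop(columns=[ref_gene])
    corrected = genes.sub(delta, axis=0)
    censored_mask = genes >= CENSORED_VALUE
    # censored measurements stay censored; correction may also push a weak
    # signal past the cutoff, in which case it is censored too
    corrected = corrected.where(corrected <= CENSOR_CT, CENSORED_VALUE)
    corrected = corrected.where(~censored_mask, CENSORED_VALUE)

    expr = (CENSORED_VALUE - corrected) / INVERSE_SLOPE
    detected = expr >= DETECTION_THRESHOLD
    expr = expr * scale_factor
    return ExpressionMatrix(expr, detected, meta.copy(), scale_factor, invalid)


def qc_filter(
    ct: CtTable,
    ref_gene: str = "GAPDH",
    anchor_gene: str = "SPI1",
    k_sd: float = 2.0,
) -> tuple[CtTable, dict]:
    """Drop cells whose reference or anchor gene Ct is a >k_sd-SD outlier.

    Cells deviating more than ``k_sd`` sample standard deviations from the
    cohort mean Ct of either gene are deemed unviable.  Returns the filtered
    table and a report dict with removed cell ids and the offending gene(s).
    """
    for g in (ref_gene, anchor_gene):
        if g not in ct.values.columns:
            raise ValueError(f"QC gene {g!r} not in assay columns")
    if ct.n_cells < 3:
        raise ValueError("need at least 3 cells to estimate a standard deviation")

    reasons: dict[str, list[str]] = {}
    for g in (ref_gene, anchor_gene):
        col = ct.values[g]
        mu, sd = col.mean(), col.std(ddof=1)
        if sd == 0 or math.isinf(k_sd):
            continue
        out = col.index[(col - mu).abs() > k_sd * sd]
        for cell in out:
            reasons.setdefault(cell, []).append(g)

    removed = sorted(reasons)
    keep = [c for c in ct.values.index if c not in reasons]
    report = {
        "n_input": ct.n_cells,
        "n_removed": len(removed),
        "removed": {c: reasons[c] for c in removed},
        "k_sd": k_sd,
    }
    return ct.subset(keep), report


def subsample_cells(ct: CtTable, n_per_time: int, seed: int) -> CtTable:
    """Randomly fix ``n_per_time`` cells per time point (without replacement)."""
    rng = np.random.default_rng(seed)
    chosen: list = []
    for t in np.sort(ct.cell_meta["time_h"].unique()):
        ids = ct.cell_meta.index[ct.cell_meta["time_h"] == t]
        if len(ids) < n_per_time:
            raise ValueError(f"time point {t}: only {len(ids)} cells, need {n_per_time}")
        pick = rng.choice(len(ids), size=n_per_time, replace=False)
        chosen.extend(ids[np.sort(pick)])
    return ct.subset(chosen)


def ddct_fold_change(ct_target: float, ct_ref: float, ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative quantification by the 2^-ddCt method."""
    ddct = (ct_target - ct_ref) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
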