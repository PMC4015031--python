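"""Detection dynamics: per-gene detection fractions, trajectory classes,
and the promoter activation/enhancement rate decomposition.

A gene's expression can rise because more cells switch the promoter on
(detection fraction grows: *promoter activation*) or because cells that
already express it express more (mean detected expression grows:
*promoter enhancement*).  Splitting the temporal change into these two
per-hour rates distinguishes all-or-nothing switching from graded output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .normalization import DETECTION_THRESHOLD, ExpressionMatrix

TRAJECTORY_CLASSES = ("ubiquitous", "activated", "deactivated", "transient", "variable")

#: centroid-rule thresholds used to name k-means clusters; the class names
#: are field conventions, the numeric cutoffs are this package's defaults
CLASS_RULES = {"ubiquitous_min": 0.9, "monotone_delta": 0.25, "transient_bump": 0.15}


@dataclass
class DetectionProfiles:
    """Per-gene detection fraction and detected-cell mean over time.

    ``f`` and ``mean_detected`` are genes x time DataFrames; entries of
    ``mean_detected`` are NaN (undefined) where no cell detected the gene.
    """

    f: pd.DataFrame
    mean_detected: pd.DataFrame
    n_cells: pd.Series
    class_labels: pd.Series | None = None

    @property
    def time_points(self) -> np.ndarray:
        return self.f.columns.to_numpy(dtype=float)


def detection_profiles(expr: ExpressionMatrix) -> DetectionProfiles:
    """Exact detection fractions and detected-cell means per gene per time."""
    meta = expr.cell_meta
    unit = expr.unit_scale()
    times = np.sort(meta["time_h"].unique())
    f = pd.DataFrame(index=expr.genes, columns=times, dtype=float)
    m = pd.DataFrame(index=expr.genes, columns=times, dtype=float)
    n_cells = pd.Series(index=times, dtype=int)
    for t in times:
        sub = unit.loc[meta["time_h"] == t]
        det = expr.detected.loc[meta["time_h"] == t]
        n_cells[t] = len(sub)
        f[t] = det.mean(axis=0)
        m[t] = sub.where(det).mean(axis=0)  # NaN where nothing detected
    return DetectionProfiles(f, m, n_cells)


def _name_cluster(centroid: np.ndarray, rules=CLASS_RULES) -> str:
    """Map a k-means centroid trajectory to one of the five class names."""
    lo, hi = centroid[0], centroid[-1]
    interior_max = centroid[1:-1].max() if centroid.size > 2 else -np.inf
    if centroid.min() >= rules["ubiquitous_min"]:
        return "ubiquitous"
    diffs = np.diff(centroid)
    if hi - lo >= rules["monotone_delta"] and (diffs >= -0.1).all():
        return "activated"
    if lo - hi >= rules["monotone_delta"] and (diffs <= 0.1).all():
        return "deactivated"
    if interior_max - max(lo, hi) >= rules["transient_bump"]:
        return "transient"
    return "variable"


def classify_trajectories(
    profiles: DetectionProfiles, k: int = 5, seed: int = 0, rules=CLASS_RULES
) -> pd.Series:
    """k-means clustering of detection-fraction trajectories, named by rule.

    Trajectories (the rows of ``profiles.f``) are clustered with 50 random
    restarts at a fixed seed; each cluster centroid is then mapped to one of
    the five dynamic classes (ubiquitous / activated / deactivated /
    transient / variable).  Returns gene -> class label; labels are also
    stored on ``profiles.class_labels``.
    """
    X = profiles.f.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError("more clusters than genes")
    km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(X)
    names = [_name_cluster(c, rules) for c in km.cluster_centers_]
    labels = pd.Series([names[i] for i in km.labels_], index=profiles.f.index, name="class")
    profiles.class_labels = labels
    return labels


def rates(profiles: DetectionProfiles) -> pd.DataFrame:
    """Per-interval promoter activation and enhancement rates.

    For each adjacent pair of time points (t_i, t_{i+1}), dt hours apart:

    - activation rate a = 100 * (f_{i+1} - f_i) / dt, in percentage points
      of cells per hour (signed);
    - enhancement rate h = (m_{i+1} / m_i)^(1/dt), the per-hour fold change
      of mean detected expression, NaN when either endpoint mean is
      undefined or zero.

    Interval lengths are the true spacings of the sampling design; they are
    never assumed uniform.
    """
    times = profiles.time_points
    if times.size < 2:
        raise ValueError("need at least two time points")
    rows = []
    for i in range(times.size - 1):
        t0, t1 = times[i], times[i + 1]
        dt = float(t1 - t0)
        if dt <= 0:
            raise ValueError("time points must be strictly increasing")
        f0, f1 = profiles.f.iloc[:, i], profiles.f.iloc[:, i + 1]
        m0, m1 = profiles.mean_detected.iloc[:, i], profiles.mean_detected.iloc[:, i + 1]
        a = 100.0 * (f1 - f0) / dt
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = m1 / m0
            h = np.where((m0 > 0) & (m1 > 0), ratio ** (1.0 / dt), np.nan)
        for gene in profiles.f.index:
            rows.append(
                {
                    "gene": gene,
                    "t_start_h": t0,
                    "t_end_h": t1,
                    "activation_rate": a[gene],
                    "enhancement_rate": h[profiles.f.index.get_loc(gene)],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class KDEResult:
    """Gaussian kernel density on a regular grid (integrates to ~1)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    point_mass: bool = False
    location: float | None = None


def kde_density(values, bandwidth="scott", n_grid: int = 512) -> KDEResult:
    """Gaussian KDE evaluated on a grid spanning the data +/- 3 bandwidths.

    Scott's rule by default; a float selects a fixed bandwidth (in data
    units).  Zero-variance input has no density and is returned as a flagged
    point mass at the common value.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("KDE needs at least 2 finite values")
    if x.std() == 0:
        return KDEResult(np.array([x[0]]), np.array([np.inf]), 0.0, point_mass=True, location=float(x[0]))
    if isinstance(bandwidth, (int, float)):
        kde = stats.gaussian_kde(x, bw_method=bandwidth / x.std(ddof=1))
    else:
        kde = stats.gaussian_kde(x, bw_method=bandwidth)
    bw = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    return KDEResult(grid, kde(grid), bw)
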