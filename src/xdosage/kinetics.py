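"""Per-gene reactivation (XCR) and upregulation-erasure (XCD) kinetics.

Each gene's noisy per-cell signal — the Mus/(Mus+Cast) allelic ratio for
reactivation, or the active-allele normalized expression for upregulation
erasure — is smoothed along pseudotime with local polynomial regression
(loess: tricube weights, degree 2) and evaluated on a common equally
spaced pseudotime grid.  Genes are then clustered on their fitted curves
with k-means and the clusters are *named* from curve shape alone, so the
class labels do not depend on k-means cluster indexing:

* XCR (k=5): the cluster already at/above ratio 0.15 at the start of the
  grid is the escapee class; the remaining clusters are ordered by their
  half-reactivation pseudotime into early / intermediate / late /
  very_late.
* XCD (k=3): clusters are named decreased / stable / increased by applying
  the 25% expression-change rule to the fitted cluster-mean start and end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .core import AllelicCountMatrix
from .dosage import classify_expression_change

logger = logging.getLogger(__name__)

XCR_NAMES = ("early", "intermediate", "late", "very_late")
ESCAPEE_THRESHOLD = 0.15


# ---------------------------------------------------------------------------
# loess
# ---------------------------------------------------------------------------

def loess(x, y, grid, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at ``grid``.

    At each grid point the nearest ``span`` fraction of the data is fit by
    weighted least squares with tricube weights.  Degree-2 local fits are
    the classic loess default; linear data is reproduced exactly for any
    span.  Falls back to lower degree at grid points where the local
    design is rank-deficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("pseudotime must cover > 1 distinct value")
    n = x.size
    r = max(int(np.ceil(span * n)), degree + 2)
    r = min(r, n)
    fitted = np.empty(grid.size)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.partition(d, r - 1)[r - 1]
        if h == 0:
            h = max(d.max(), 1.0) * 1e-9
        w = np.clip(1 - (d / (h * 1.0000001)) ** 3, 0, None) ** 3
        use = w > 0
        xu = x[use] - g
        wu = w[use]
        for deg in range(degree, -1, -1):
            V = np.vander(xu, deg + 1, increasing=True)
            Vw = V * wu[:, None]
            beta, _, rank, _ = np.linalg.lstsq(Vw.T @ V, Vw.T @ y[use],
                                               rcond=None)
            if rank == deg + 1:
                fitted[i] = beta[0]
                break
        else:  # pragma: no cover - all-zero weights cannot happen (h > 0)
            fitted[i] = np.average(y[use], weights=wu)
    return fitted


def fit_pseudotime_curve(values, pseudotime, span: float = 0.75,
                         n_grid: int = 100, degree: int = 2,
                         clip: tuple | None = None,
                         min_cells: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Smooth per-cell values along pseudotime onto an equal-interval grid.

    NaN values (cells without signal for this gene) are dropped before
    fitting; fewer than ``min_cells`` informative cells raises ValueError
    (table-level callers skip and log).  ``clip`` bounds the fitted values,
    e.g. (0, 1) for allelic ratios.  Returns (grid, fitted).
    """
    values = np.asarray(values, dtype=float)
    pseudotime = np.asarray(pseudotime, dtype=float)
    ok = np.isfinite(values) & np.isfinite(pseudotime)
    values, pseudotime = values[ok], pseudotime[ok]
    if values.size < min_cells:
        raise ValueError(f"only {values.size} cells with defined values "
                         f"(minimum {min_cells})")
    grid = np.linspace(pseudotime.min(), pseudotime.max(), n_grid)
    fitted = loess(pseudotime, values, grid, span=span, degree=degree)
    if clip is not None:
        fitted = np.clip(fitted, *clip)
    return grid, fitted


# ---------------------------------------------------------------------------
# profile construction from an allelic matrix
# ---------------------------------------------------------------------------

def xcr_ratio_profiles(m: AllelicCountMatrix, pseudotime: pd.DataFrame,
                       genes=None, span: float = 0.75, n_grid: int = 100,
                       min_cells: int = 20) -> pd.DataFrame:
    """Per-gene smoothed Mus/(Mus+Cast) allelic-ratio curves (XCR mode).

    The per-cell ratio uses raw allelic counts (the per-cell library
    divisor cancels in the ratio); cells with zero allelic reads for a gene
    are missing for that gene's fit.  Genes with too few informative cells
    are skipped and logged.  Returns genes x grid fitted ratios in [0, 1].
    """
    genes = m.features if genes is None else pd.Index(genes)
    pt = pseudotime.loc[m.samples, "pseudotime"].to_numpy(dtype=float)
    mus = m.counts_mus.loc[genes].to_numpy(dtype=float)
    cast = m.counts_cast.loc[genes].to_numpy(dtype=float)
    total = mus + cast
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, mus / total, np.nan)
    return _fit_profile_table(ratio, pt, genes, span, n_grid, clip=(0.0, 1.0),
                              min_cells=min_cells)


def xcd_expression_profiles(m: AllelicCountMatrix, pseudotime: pd.DataFrame,
                            genes=None, allele: str = "cast",
                            span: float = 0.75, n_grid: int = 100,
                            min_cells: int = 20) -> pd.DataFrame:
    """Per-gene smoothed active-allele expression curves (XCD mode).

    Uses linear normalized expression of ``allele``; entries flagged by the
    missing-data convention are excluded from the fit.
    """
    genes = m.features if genes is None else pd.Index(genes)
    pt = pseudotime.loc[m.samples, "pseudotime"].to_numpy(dtype=float)
    vals = m.layer(allele, normalized=True, linear=True)
    vals = vals.where(m.usable_mask()).loc[genes].to_numpy(dtype=float)
    return _fit_profile_table(vals, pt, genes, span, n_grid, clip=None,
                              min_cells=min_cells)


def _fit_profile_table(values, pt, genes, span, n_grid, clip, min_cells):
    grid = np.linspace(pt.min(), pt.max(), n_grid)
    rows, kept = [], []
    n_skipped = 0
    for i, gene in enumerate(genes):
        try:
            _, fitted = fit_pseudotime_curve(values[i], pt, span=span,
                                             n_grid=n_grid, clip=clip,
                                             min_cells=min_cells)
        except ValueError:
            n_skipped += 1
            continue
        rows.append(fitted)
        kept.append(gene)
    if n_skipped:
        logger.warning("profiles: %d genes skipped (< %d informative cells)",
                       n_skipped, min_cells)
    return pd.DataFrame(rows, index=pd.Index(kept, name="feature_id"),
                        columns=grid)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class KineticsClassification:
    """K-means clustering of fitted curves plus shape-derived class names."""

    classes: pd.Series        # feature -> class name
    cluster_labels: pd.Series  # feature -> cluster id
    cluster_names: pd.Series   # cluster id -> class name
    centers: pd.DataFrame      # cluster id x grid


def _kmeans_curves(profiles: pd.DataFrame, k: int, seed: int):
    if profiles.isna().any().any():
        raise ValueError("profiles contain missing fitted values")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of genes {len(profiles)}")
    km = KMeans(n_clusters=k, n_init=25, random_state=seed)
    with warnings.catch_warnings():
        # duplicate profiles raise our own degeneracy error below
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        labels = km.fit_predict(profiles.to_numpy())
    centers = km.cluster_centers_
    if np.unique(labels).size < k or \
            np.unique(np.round(centers, 9), axis=0).shape[0] < k:
        raise ValueError(
            f"degenerate input: fewer than k={k} distinct clusters; reduce k "
            "or check that the profiles are not (near-)identical")
    return (pd.Series(labels, index=profiles.index, name="cluster_id"),
            pd.DataFrame(centers, columns=profiles.columns))


def half_activation_time(curve: np.ndarray, grid=None) -> float:
    """First grid point where the curve reaches (start + end) / 2.

    Ties break to the earliest grid point.  Index returned when ``grid``
    is None.
    """
    curve = np.asarray(curve, dtype=float)
    half = (curve[0] + curve[-1]) / 2
    idx = int(np.argmax(curve >= half))
    return idx if grid is None else float(np.asarray(grid)[idx])


def classify_xcr_kinetics(profiles: pd.DataFrame, k: int = 5, seed: int = 0,
                          escapee_threshold: float = ESCAPEE_THRESHOLD
                          ) -> KineticsClassification:
    """Classify fitted allelic-ratio curves into reactivation classes.

    K-means (default k=5) on the curves; clusters whose fitted ratio at the
    start of the grid is already >= ``escapee_threshold`` are escapees, the
    rest are named early/intermediate/late/very_late by increasing
    half-reactivation pseudotime.
    """
    labels, centers = _kmeans_curves(profiles, k, seed)
    start = centers.iloc[:, 0].to_numpy()
    names = pd.Series(index=centers.index, dtype=object)
    escapee = start >= escapee_threshold
    names[escapee] = "escapee"
    rest = centers.index[~escapee]
    half = {cid: half_activation_time(centers.loc[cid].to_numpy())
            for cid in rest}
    for rank, cid in enumerate(sorted(rest, key=lambda c: (half[c], c))):
        names[cid] = XCR_NAMES[min(rank, len(XCR_NAMES) - 1)]
    classes = labels.map(names)
    classes.name = "xcr_class"
    return KineticsClassification(classes, labels, names.rename("class"), centers)


def classify_xcd_kinetics(profiles: pd.DataFrame, k: int = 3, seed: int = 0,
                          threshold: float = 0.25) -> KineticsClassification:
    """Classify fitted active-allele expression curves by start-vs-end change.

    Cluster means are named with the 25% rule: end >= 1.25x start ->
    'increased', end <= 0.75x start -> 'decreased', else 'stable'.
    """
    labels, centers = _kmeans_curves(profiles, k, seed)
    rename = {"up": "increased", "down": "decreased", "stable": "stable"}
    names = pd.Series(
        {cid: rename[classify_expression_change(
            float(centers.loc[cid].iloc[0]), float(centers.loc[cid].iloc[-1]),
            threshold)]
         for cid in centers.index}, dtype=object)
    classes = labels.map(names)
    classes.name = "xcd_class"
    return KineticsClassification(classes, labels, names.rename("class"), centers)
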