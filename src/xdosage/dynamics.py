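"""Allelic chromatin-accessibility dynamics across reprogramming timepoints.

Works on the allelic ratio r = mus / (mus + cast) of read counts summed
within each timepoint group.  r in [0, 0.15) is Cast-monoallelic
accessibility, [0.15, 0.85] biallelic, (0.85, 1] Mus-monoallelic.  Regions
are clustered by their ratio trajectory over the timepoints, clusters are
assigned to kinetic categories by when their mean trajectory first enters
the biallelic band, and per-region opening times are estimated with a
log-linked Gaussian GLM of ratio on reprogramming day.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans

from .core import AllelicCountMatrix

logger = logging.getLogger(__name__)

#: canonical isolation timepoints, in reprogramming order
TIMEPOINTS = ("d0", "d8", "d9", "d10", "d12", "iPSC")
#: numeric day encoding for the opening-time GLM; iPSC day is a convention
DAY_MAP = {"d0": 0.0, "d8": 8.0, "d9": 9.0, "d10": 10.0, "d12": 12.0, "iPSC": 16.0}

LOWER, UPPER = 0.15, 0.85

#: first biallelic timepoint index -> kinetic category
CROSSING_CATEGORIES = {1: "early", 2: "intermediate", 3: "late", 4: "very_late",
                       5: "very_late"}


def allelic_ratio(mus, cast):
    """Maternal fraction mus / (mus + cast); undefined (error) at 0 reads."""
    mus = np.asarray(mus, dtype=float)
    cast = np.asarray(cast, dtype=float)
    total = mus + cast
    if np.any(total <= 0):
        raise ValueError("allelic ratio undefined where mus + cast == 0")
    return mus / total


def classify_accessibility_state(ratio):
    """Map ratios to {'cast_mono', 'biallelic', 'mus_mono'}.

    The band boundaries 0.15 and 0.85 belong to the biallelic state.
    Scalar in, scalar out; array in, object array out.
    """
    arr = np.asarray(ratio, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("ratio outside [0, 1]")
    out = np.where(arr < LOWER, "cast_mono",
                   np.where(arr > UPPER, "mus_mono", "biallelic"))
    return out.item() if np.isscalar(ratio) else out


def group_allelic_ratios(m: AllelicCountMatrix, groups: pd.Series,
                         order=None) -> pd.DataFrame:
    """Features x groups allelic-ratio table from group-summed raw counts.

    Ratios are NaN where a group has no allelic reads for a feature.
    ``order`` fixes the column order (default: first appearance).
    """
    groups = groups.reindex(m.samples)
    order = list(order) if order is not None else list(dict.fromkeys(groups))
    out = {}
    for label in order:
        cols = list(groups.index[groups == label])
        mus = m.counts_mus[cols].sum(axis=1).astype(float)
        cast = m.counts_cast[cols].sum(axis=1).astype(float)
        total = mus + cast
        with np.errstate(invalid="ignore", divide="ignore"):
            out[label] = np.where(total > 0, mus / total, np.nan)
    return pd.DataFrame(out, index=m.features)


def filter_informative_regions(m: AllelicCountMatrix, groups: pd.Series,
                               min_total_per_group: int = 9) -> pd.Index:
    """Regions with >= min_total_per_group allelic reads in EVERY group."""
    groups = groups.reindex(m.samples)
    keep = pd.Series(True, index=m.features)
    for label, cols in groups.groupby(groups).groups.items():
        s = (m.counts_mus[list(cols)].sum(axis=1)
             + m.counts_cast[list(cols)].sum(axis=1))
        keep &= s >= min_total_per_group
    return m.features[keep]


def cluster_ratio_trajectories(trajectories: pd.DataFrame, k: int = 10,
                               seed: int = 0, n_init: int = 25
                               ) -> tuple[pd.Series, pd.DataFrame]:
    """K-means on ratio trajectories (rows = features, columns = timepoints).

    Euclidean distance on the raw ratio vectors (already bounded and
    commensurate), k-means++ starts, deterministic given ``seed``.  Returns
    (feature -> cluster_id, cluster mean trajectories).
    """
    if trajectories.isna().any().any():
        raise ValueError("trajectories contain missing ratios")
    if k > len(trajectories):
        raise ValueError(f"k={k} exceeds number of features {len(trajectories)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = pd.Series(km.fit_predict(trajectories.to_numpy()),
                       index=trajectories.index, name="cluster_id")
    centers = pd.DataFrame(km.cluster_centers_, columns=trajectories.columns)
    centers.index.name = "cluster_id"
    return labels, centers


def assign_categories(cluster_means: pd.DataFrame,
                      opening_threshold: float = LOWER,
                      upper: float = UPPER) -> pd.Series:
    """Name clusters by their mean-trajectory dynamics.

    Rules, applied in order to each cluster's mean Mus ratio trajectory:
    starts Mus-monoallelic (> upper) -> 'mus_mono_to_bi'; never leaves the
    Cast-mono band -> 'cast_monoallelic'; starts at/above the opening
    threshold -> 'escapee' (biallelic throughout); otherwise the first
    timepoint at which it enters the biallelic band names it (2nd
    timepoint = 'early', then 'intermediate', 'late', 'very_late').
    """
    names = {}
    for cid, row in cluster_means.iterrows():
        traj = row.to_numpy(dtype=float)
        if traj[0] > upper:
            names[cid] = "mus_mono_to_bi"
        elif np.all(traj < opening_threshold):
            names[cid] = "cast_monoallelic"
        elif traj[0] >= opening_threshold:
            names[cid] = "escapee"
        else:
            first = int(np.argmax(traj >= opening_threshold))
            names[cid] = CROSSING_CATEGORIES[min(first, max(CROSSING_CATEGORIES))]
    return pd.Series(names, name="category")


def categorize_regions(trajectories: pd.DataFrame, k: int = 10, seed: int = 0
                       ) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Cluster trajectories and propagate cluster categories to regions.

    Returns (region -> category, cluster -> category, cluster means).
    """
    labels, centers = cluster_ratio_trajectories(trajectories, k=k, seed=seed)
    cluster_cat = assign_categories(centers)
    region_cat = labels.map(cluster_cat)
    region_cat.name = "category"
    return region_cat, cluster_cat, centers


def distance_to_nearest_biallelic(features: pd.DataFrame,
                                  reference: pd.DataFrame) -> pd.Series:
    """Genomic distance (bp) from each feature to the nearest reference region.

    Both frames need chrom/start/end columns (0-based half-open).  The
    distance is the gap between closest edges on the same chromosome, 0 for
    any overlap; features on a chromosome with no reference regions get NaN
    (logged).
    """
    out = pd.Series(np.nan, index=features.index, dtype=float)
    for chrom, qsub in features.groupby("chrom"):
        ref = reference[reference["chrom"] == chrom]
        if ref.empty:
            logger.warning("no reference regions on %s (%d features)",
                           chrom, len(qsub))
            continue
        starts = np.sort(ref["start"].to_numpy())
        ends = np.sort(ref["end"].to_numpy())
        qs = qsub["start"].to_numpy()
        qe = qsub["end"].to_numpy()
        # gap to nearest region entirely to the right / left; sorted-edge
        # trick: the nearest right gap uses the smallest ref start >= query
        # end, the nearest left gap the largest ref end <= query start
        i = np.searchsorted(starts, qe, side="left")
        right = np.where(i < len(starts), starts[np.minimum(i, len(starts) - 1)] - qe,
                         np.inf)
        j = np.searchsorted(ends, qs, side="right")
        left = np.where(j > 0, qs - ends[np.maximum(j - 1, 0)], np.inf)
        d = np.maximum(np.minimum(left, right), 0.0)
        # any overlap -> 0: a region overlaps iff some ref has start < qe
        # and end > qs
        k = np.searchsorted(starts, qe, side="left")  # refs with start < qe
        kk = np.searchsorted(ends, qs, side="right")  # refs with end <= qs
        d = np.where(k > kk, 0.0, d)
        out.loc[qsub.index] = d
    return out


def estimate_opening_time(trajectories: pd.DataFrame,
                          day_map: dict = DAY_MAP,
                          threshold: float = LOWER) -> pd.Series:
    """Per-region chromatin opening time from a log-linked Gaussian GLM.

    Fits ratio ~ exp(b0 + b1 * day) per region and reports the day at which
    the fitted curve crosses the opening threshold: 0 if already open at
    day 0, NaN (logged) if the fit fails or the curve never reaches the
    threshold within the observed day range.
    """
    days = np.array([day_map[c] for c in trajectories.columns], dtype=float)
    X = sm.add_constant(days)
    max_day = days.max()
    out = pd.Series(np.nan, index=trajectories.index, dtype=float)
    n_skipped = 0
    for fid, row in trajectories.iterrows():
        y = row.to_numpy(dtype=float)
        if np.isnan(y).any():
            n_skipped += 1
            continue
        try:
            fit = sm.GLM(y, X, family=sm.families.Gaussian(
                sm.families.links.Log())).fit()
            b0, b1 = fit.params
        except Exception:
            n_skipped += 1
            continue
        if np.exp(b0) >= threshold:
            out.loc[fid] = 0.0
        elif b1 > 0:
            day = (np.log(threshold) - b0) / b1
            out.loc[fid] = day if day <= max_day else np.nan
    if n_skipped:
        logger.warning("opening time: %d regions skipped (missing data or "
                       "non-convergent fit)", n_skipped)
    return out.rename("opening_time")


def mean_opening_time_by_class(opening_time: pd.Series,
                               annotation: pd.DataFrame) -> pd.Series:
    """Mean opening time per regulatory class (enhancer vs promoter ...)."""
    reg = annotation.loc[opening_time.index, "reg_class"]
    return opening_time.groupby(reg).mean()
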