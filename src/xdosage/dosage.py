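"""X-to-autosome dosage statistics.

The core quantity throughout is the X/A ratio: the median signal of
X-linked features divided by the median signal of autosomal features, on
one parental allele.  A value of ~0.5 per allele (or ~1 when each X allele
is compared against single autosomal alleles) indicates no dosage
compensation beyond ploidy; the upregulated active X (XCU) shows X/A > 1
on its allele, and the inactive X shows X/A ~ 0.

Medians and folds are computed on the linear normalized scale (de-logged
library-normalized values): a fold of medians of log-transformed values
would not equal the fold in accessibility/expression.  Rank-sum p-values
are invariant to the monotone log either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (AllelicCountMatrix, AllelicDataError, AUTOSOMES,
                   autosomal_features, x_features)

logger = logging.getLogger(__name__)


@dataclass
class DosageSummary:
    """Per-group, per-allele X-vs-autosome dosage summary."""

    allele: str
    group: str | None
    x_median: float
    autosome_median: float
    fold_change: float
    p_value: float
    n_x: int
    n_autosomal: int


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null for small untied samples and the normal
    approximation otherwise; returns (U statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def _masked_group_mean(m: AllelicCountMatrix, allele: str,
                       samples) -> pd.Series:
    """Per-feature mean of linear normalized values over ``samples``,
    honouring the missing/informative masks (masked entries are excluded
    from the mean; features masked everywhere come back NaN)."""
    vals = m.layer(allele, normalized=True, linear=True)[samples]
    mask = m.usable_mask()[samples]
    vals = vals.where(mask)
    return vals.mean(axis=1)


def x_autosome_fold(m: AllelicCountMatrix, allele: str = "cast",
                    samples=None, group: str | None = None,
                    per_chromosome_median: bool = False) -> DosageSummary:
    """Fold change of median X-linked vs autosomal normalized signal.

    Feature values are averaged over the selected samples, the fold is the
    median over X-linked features divided by the autosomal median (pooled
    across autosomes by default; ``per_chromosome_median`` uses the median
    of the 19 per-autosome medians instead), and the p-value is a two-sided
    rank-sum test between the two feature-level distributions.
    """
    if samples is None:
        samples = list(m.samples)
    if len(samples) == 0:
        raise ValueError("no samples selected")
    ann = m.annotation.loc[m.features]
    vals = _masked_group_mean(m, allele, samples)
    xv = vals.loc[x_features(ann)].dropna()
    av = vals.loc[autosomal_features(ann)].dropna()
    if xv.empty or av.empty:
        raise AllelicDataError("no X-linked or no autosomal features after filtering")
    if per_chromosome_median:
        per_chrom = av.groupby(ann.loc[av.index, "chrom"]).median()
        a_med = float(per_chrom.median())
    else:
        a_med = float(av.median())
    x_med = float(xv.median())
    _, p = rank_sum_test(xv, av)
    return DosageSummary(allele=allele, group=group, x_median=x_med,
                         autosome_median=a_med,
                         fold_change=x_med / a_med, p_value=p,
                         n_x=len(xv), n_autosomal=len(av))


def x_autosome_ratio_per_cell(m: AllelicCountMatrix, allele: str = "mus",
                              statistic: str = "median") -> pd.Series:
    """Per-cell ratio of X-linked to autosomal allelic expression.

    For each cell only expressed genes are retained (allelic read sum > 0
    for that gene in that cell); the ratio is statistic(X genes) /
    statistic(autosomal genes) of the linear normalized allele values.
    ``statistic`` is "median" (default) or "mean".  Cells with no expressed
    autosomal genes yield NaN and are logged.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    ann = m.annotation.loc[m.features]
    expressed = (m.counts_mus + m.counts_cast) > 0
    vals = m.layer(allele, normalized=True, linear=True).where(expressed)
    xi = x_features(ann)
    ai = autosomal_features(ann)
    agg = getattr(vals.loc[xi], statistic)(axis=0)
    agg_a = getattr(vals.loc[ai], statistic)(axis=0)
    # a cell whose X allele is fully silenced has no expressed X genes:
    # its X-side statistic is an empty median -> report ratio 0, not NaN
    agg = agg.fillna(0.0)
    ratio = agg / agg_a
    n_bad = int(agg_a.isna().sum())
    if n_bad:
        logger.warning("%d cells with no expressed autosomal genes", n_bad)
    ratio.name = f"x_{allele}_over_autosomes"
    return ratio


def chromosome_autosome_trajectory(m: AllelicCountMatrix, chrom: str,
                                   allele: str, groups: pd.Series) -> pd.Series:
    """Per-group median(chrom) / median(other autosomes) ratio series.

    ``groups`` maps sample -> group label; group order follows first
    appearance.  When ``chrom`` is an autosome it is excluded from its own
    denominator, giving the control series used to judge the X trajectory.
    """
    ann = m.annotation.loc[m.features]
    if chrom != "chrX" and chrom not in AUTOSOMES:
        raise ValueError(f"unknown chromosome {chrom!r}")
    num_feats = ann.index[ann["chrom"] == chrom]
    den_feats = autosomal_features(
        ann, exclude_chrom=chrom if chrom in AUTOSOMES else None)
    groups = groups.reindex(m.samples)
    order = list(dict.fromkeys(groups))
    if len(order) < 2:
        raise ValueError("trajectory requires >= 2 groups")
    out = {}
    for label in order:
        cols = list(groups.index[groups == label])
        vals = _masked_group_mean(m, allele, cols)
        num = vals.loc[num_feats].dropna()
        den = vals.loc[den_feats].dropna()
        out[label] = float(num.median() / den.median())
    return pd.Series(out, name=f"{chrom}_{allele}")


def classify_expression_change(expr_start: float, expr_end: float,
                               threshold: float = 0.25) -> str:
    """Classify a start->end expression change as 'up', 'down' or 'stable'.

    A change of exactly ``threshold`` (default 25%) counts as up/down.
    """
    if expr_start <= 0:
        raise ValueError("expr_start must be > 0")
    if expr_end >= expr_start * (1 + threshold):
        return "up"
    if expr_end <= expr_start * (1 - threshold):
        return "down"
    return "stable"


def classify_allelic_bias(mus_expr: float, cast_expr: float,
                          threshold: float = 0.25) -> str:
    """Classify allelic expression as mus_biased / cast_biased / balanced.

    Biased toward the larger allele when the relative difference
    |mus - cast| / max(mus, cast) reaches ``threshold``.
    """
    if mus_expr < 0 or cast_expr < 0:
        raise ValueError("expression values must be >= 0")
    if mus_expr == 0 and cast_expr == 0:
        raise ValueError("both alleles zero: bias undefined")
    hi = max(mus_expr, cast_expr)
    if abs(mus_expr - cast_expr) / hi >= threshold:
        return "mus_biased" if mus_expr > cast_expr else "cast_biased"
    return "balanced"
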