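"""Synthetic allelic count datasets with full ground truth.

Generates data with the statistical structure the analysis modules assume —
diploid biallelic autosomes, an inactive X allele silenced except for
escapees, an active X allele carrying a configurable upregulation factor,
class-wise reactivation of the inactive allele along pseudotime or discrete
timepoints, concurrent erasure of active-X upregulation, X-loss (XO) cells
— with per-allele counts drawn from the two-state (telegraph) transcription
model (direct Beta-then-Poisson sampling).  Every generator is
bit-reproducible given (config, seed) and returns the generative truth.

Two deliberate design choices (see docs/methods.md):

* Upregulation (``xa_fold``) acts on the burst frequency k_on — the
  mechanistic claim under study — with the per-gene multiplier solved so
  that the *mean* expression scales exactly by ``xa_fold``; a k_syn mode
  exists to test whether the pipeline can distinguish mechanisms.
* Feature-level baseline parameters are drawn by stratified
  (scrambled-quantile) lognormal sampling: identical marginals to i.i.d.
  draws, but the feature-set median — the denominator of every recovery
  statistic — is stabilized, as is standard in parameter-recovery designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .core import AllelicCountMatrix, AUTOSOMES

TIMEPOINTS = ("d0", "d8", "d9", "d10", "d12", "iPSC")
CHRX_LENGTH = 171_000_000

#: Cast-allele Xa enhancement along the ATAC timecourse, as a fraction of
#: (xa_fold - 1) remaining: present through d9, decaying at d10/d12, gone
#: in iPSCs.
XA_DECAY_FRACTION = {"d0": 1.0, "d8": 1.0, "d9": 1.0, "d10": 2 / 3,
                     "d12": 1 / 3, "iPSC": 0.0}

ATAC_CATEGORY_FRACTIONS = {
    "early": 0.20, "intermediate": 0.15, "late": 0.20, "very_late": 0.15,
    "escapee": 0.15, "mus_mono_to_bi": 0.10, "cast_monoallelic": 0.05}
ATAC_OPENING_TIMEPOINT = {"early": "d8", "intermediate": "d9", "late": "d10",
                          "very_late": "d12"}
#: planted genomic offset (bp) from the nearest day-0 biallelic (escapee)
#: region, per opening class — earlier-opening regions sit closer
ATAC_DISTANCE_RANGE = {"early": (5e3, 5e4), "intermediate": (5e4, 3e5),
                       "late": (3e5, 1.5e6), "very_late": (1.5e6, 5e6)}


@dataclass
class SimulationConfig:
    """Shared knobs for all generators; defaults are the study conditions.

    Burst parameter distributions are (median, lognormal sigma) pairs in
    units of the mRNA degradation rate.  ``xa_fold`` is the fold by which
    the active-X allele's mean signal exceeds one autosomal allele.
    """

    # scRNA-seq shape
    n_cells: int = 500
    n_autosomal_features: int = 2000
    n_x_features: int = 300
    # ATAC shape
    n_samples_per_group: int = 2
    n_autosomal_regions: int = 50_000
    n_x_regions: int = 5_000

    fraction_escapees: float = 0.10
    xa_fold: float = 1.33
    xa_allele: str = "cast"
    #: state of the non-upregulated X allele: "silenced" (reactivating),
    #: "absent" (male / XO) or "active" (XX pluripotent, no XCI)
    other_x: str = "silenced"
    xa_mechanism: str = "k_on"        # or "k_syn"

    # reprogramming dynamics (pseudotime units, 0..pseudotime_max)
    pseudotime_max: float = 100.0
    reactivation_schedule: dict = field(default_factory=lambda: {
        "early": 25.0, "intermediate": 45.0, "late": 65.0, "very_late": 85.0})
    reactivation_slope: float = 4.0
    silenced_multiplier: float = 0.01
    xa_decay_midpoint: float = 45.0
    xa_decay_slope: float = 8.0

    # telegraph-model parameter distributions (median, lognormal sigma).
    # Expression-oriented generators draw (mean expression, k_on, k_off)
    # and derive k_syn; the pure burst generator draws (k_on, k_off,
    # burst size) and derives k_syn — in each case the quantity whose
    # feature-set median the downstream estimator uses is sampled directly
    # (and hence quantile-stratified).
    kon_dist: tuple = (1.0, 0.4)
    koff_dist: tuple = (10.0, 0.4)
    mean_expression_dist: tuple = (45.0, 0.7)
    burst_size_dist: tuple = (15.0, 0.5)

    # ATAC intensity model
    atac_mean_reads: float = 30.0
    atac_region_sigma: float = 0.5
    atac_closed_multiplier: float = 0.02
    atac_category_fractions: dict = field(
        default_factory=lambda: dict(ATAC_CATEGORY_FRACTIONS))

    # technical noise
    depth_sigma: float = 0.3
    assignable_fraction: float = 0.10

    #: stratified (scrambled-quantile) feature-parameter sampling pins the
    #: feature-set medians that recovery statistics divide by; switch to
    #: plain i.i.d. draws for calibration experiments, where rank-based
    #: p-values require exchangeable samples
    stratified: bool = True

    # XO
    xo_fraction: float = 0.5
    xo_lost_allele: str = "random"    # "mus", "cast" or "random"

    #: scRNA snapshot mode: None simulates the full reprogramming
    #: trajectory; "C0" places every cell in the somatic state (Xi
    #: silenced, full xa_fold), "C5" in the pluripotent end state
    #: (Xi reactivated, upregulation erased)
    snapshot: str | None = None

    def validate(self) -> "SimulationConfig":
        if self.xa_fold <= 0:
            raise ValueError("xa_fold must be > 0")
        if not 0 <= self.fraction_escapees <= 1:
            raise ValueError("fraction_escapees must be in [0, 1]")
        if not 0 <= self.xo_fraction <= 1:
            raise ValueError("xo_fraction must be in [0, 1]")
        if self.xa_allele not in ("mus", "cast"):
            raise ValueError("xa_allele must be 'mus' or 'cast'")
        if self.other_x not in ("silenced", "absent", "active"):
            raise ValueError("other_x must be silenced/absent/active")
        if self.xa_mechanism not in ("k_on", "k_syn"):
            raise ValueError("xa_mechanism must be 'k_on' or 'k_syn'")
        if self.snapshot not in (None, "C0", "C5"):
            raise ValueError("snapshot must be None, 'C0' or 'C5'")
        if not 0 < self.assignable_fraction <= 1:
            raise ValueError("assignable_fraction must be in (0, 1]")
        for t in self.reactivation_schedule.values():
            if not 0 <= t <= self.pseudotime_max:
                raise ValueError("schedule times must lie in the pseudotime range")
        return self


@dataclass
class GroundTruth:
    """Generative truth: per-feature classes, per-cell states, parameters."""

    features: pd.DataFrame
    cells: pd.DataFrame | None
    burst_params: pd.DataFrame | None
    config: SimulationConfig


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _lognormal(rng, median: float, sigma: float, n: int,
               stratified: bool = True) -> np.ndarray:
    """Lognormal draws, by default via scrambled stratified quantiles
    (identical marginal, stable sample median)."""
    if not stratified:
        return median * np.exp(sigma * rng.standard_normal(n))
    u = (rng.permutation(n) + rng.uniform(size=n)) / n
    return median * np.exp(sigma * ndtri(np.clip(u, 1e-12, 1 - 1e-12)))


def _draw_expression_params(rng, cfg: SimulationConfig, *group_sizes) -> pd.DataFrame:
    """Telegraph parameters with the mean expression sampled directly.

    Stratification is applied within each feature group (autosomal genes,
    X-linked genes) separately so every group's parameter medians are
    pinned at the distribution medians.
    """
    parts = []
    for n in group_sizes:
        mean = _lognormal(rng, *cfg.mean_expression_dist, n, cfg.stratified)
        k_on = _lognormal(rng, *cfg.kon_dist, n, cfg.stratified)
        k_off = _lognormal(rng, *cfg.koff_dist, n, cfg.stratified)
        parts.append(pd.DataFrame({"k_on": k_on, "k_off": k_off,
                                   "k_syn": mean * (k_on + k_off) / k_on,
                                   "mean_expression": mean}))
    return pd.concat(parts, ignore_index=True)


def _draw_burst_params(rng, cfg: SimulationConfig, *group_sizes) -> pd.DataFrame:
    """Telegraph parameters with the burst size sampled directly,
    stratified within each feature group."""
    parts = []
    for n in group_sizes:
        k_on = _lognormal(rng, *cfg.kon_dist, n, cfg.stratified)
        k_off = _lognormal(rng, *cfg.koff_dist, n, cfg.stratified)
        size = _lognormal(rng, *cfg.burst_size_dist, n, cfg.stratified)
        parts.append(pd.DataFrame({"k_on": k_on, "k_off": k_off,
                                   "k_syn": size * k_off}))
    return pd.concat(parts, ignore_index=True)


def _kon_multiplier_for_mean_fold(fold, k_on, k_off):
    """k_on multiplier g such that the Poisson-beta mean scales by ``fold``.

    mean = k_syn*k_on/(k_on+k_off); solving for g in mean(g*k_on) =
    fold*mean(k_on) gives g = fold*k_off / (k_on + k_off - fold*k_on).
    Degenerate draws (fold*k_on close to k_on + k_off) fall back to a plain
    multiplier.
    """
    fold = np.asarray(fold, dtype=float)
    denom = k_on + k_off - fold * k_on
    safe = denom > 0.05 * k_off
    return np.where(safe, fold * k_off / np.where(safe, denom, 1.0), fold)


def _telegraph_counts(rng, k_on, k_off, intensity):
    """Beta-then-Poisson draws; all arguments broadcastable."""
    k_on, k_off, intensity = np.broadcast_arrays(
        np.maximum(k_on, 1e-8), np.maximum(k_off, 1e-8), intensity)
    p = rng.beta(k_on, k_off)
    return rng.poisson(intensity * p)


def _with_unassignable(rng, mus, cast, fraction):
    """Total layer = allelic reads plus Poisson unassignable reads."""
    extra = rng.poisson((mus + cast) * (1.0 / fraction - 1.0))
    return mus + cast + extra


def _gene_annotation(rng, cfg, x_classes: pd.Series) -> pd.DataFrame:
    n_auto = cfg.n_autosomal_features
    ids = [f"gene_{i:05d}" for i in range(n_auto + len(x_classes))]
    chroms = [AUTOSOMES[i % len(AUTOSOMES)] for i in range(n_auto)] \
        + ["chrX"] * len(x_classes)
    lengths = np.round(_lognormal(rng, 2000.0, 0.5, len(ids))).astype(int)
    starts = np.concatenate([
        100_000 * (1 + np.arange(n_auto) // len(AUTOSOMES)),
        100_000 * (1 + np.arange(len(x_classes)))])
    cat = ["autosomal"] * n_auto + [
        "escapee" if c == "escapee" else "x_linked" for c in x_classes]
    return pd.DataFrame({
        "chrom": chroms, "start": starts, "end": starts + lengths,
        "category": cat, "reg_class": "unknown",
        "snp_count": 4 + rng.poisson(6, size=len(ids))},
        index=pd.Index(ids, name="feature_id"))


def _assign_classes(rng, n: int, fractions: dict) -> pd.Series:
    names = list(fractions)
    counts = np.floor(np.array([fractions[c] for c in names]) * n).astype(int)
    counts[0] += n - counts.sum()
    labels = np.repeat(names, counts)
    return pd.Series(rng.permutation(labels))


def _x_class_fractions(cfg: SimulationConfig) -> dict:
    rest = (1.0 - cfg.fraction_escapees) / len(cfg.reactivation_schedule)
    out = {"escapee": cfg.fraction_escapees}
    out.update({c: rest for c in cfg.reactivation_schedule})
    return out


# ---------------------------------------------------------------------------
# scRNA-seq reprogramming
# ---------------------------------------------------------------------------

def simulate_reprogramming_scrna(config: SimulationConfig | None = None,
                                 seed: int = 0):
    """Single cells along a reprogramming pseudotime, genes x cells.

    The inactive-X (Mus) allele's k_on is scaled by a logistic reactivation
    factor centred at each gene's class time; the active-X (Cast) allele
    carries ``xa_fold`` decaying to 1 around the erasure midpoint; escapees
    are biallelic throughout; autosomes are biallelic with independent
    per-allele telegraph draws.  Returns (matrix, pseudotime frame, truth).
    """
    cfg = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(seed)
    n_cells, n_x, n_auto = cfg.n_cells, cfg.n_x_features, cfg.n_autosomal_features

    if cfg.snapshot is None:
        pt = np.sort((rng.permutation(n_cells) + rng.uniform(size=n_cells))
                     / n_cells * cfg.pseudotime_max)
        group = [f"C{g}" for g in
                 np.minimum((pt / cfg.pseudotime_max * 6).astype(int), 5)]
    else:
        pt = np.full(n_cells, 0.0 if cfg.snapshot == "C0"
                     else cfg.pseudotime_max)
        group = [cfg.snapshot] * n_cells
    cells = pd.DataFrame(
        {"pseudotime": pt, "group_label": group, "x_state": "XX"},
        index=pd.Index([f"cell_{i:04d}" for i in range(n_cells)],
                       name="sample_id"))

    x_classes = _assign_classes(rng, n_x, _x_class_fractions(cfg))
    ann = _gene_annotation(rng, cfg, x_classes)
    genes = ann.index
    params = _draw_expression_params(rng, cfg, n_auto, n_x)
    params.index = genes
    kon = params["k_on"].to_numpy()[:, None]
    koff = params["k_off"].to_numpy()[:, None]
    ksyn = params["k_syn"].to_numpy()[:, None]

    is_x = (ann["chrom"] == "chrX").to_numpy()
    class_time = np.full(len(genes), np.nan)
    for cls, t in cfg.reactivation_schedule.items():
        class_time[np.concatenate([np.zeros(n_auto, bool),
                                   (x_classes == cls).to_numpy()])] = t
    escapee = np.concatenate([np.zeros(n_auto, bool),
                              (x_classes == "escapee").to_numpy()])

    # inactive-X allele multiplier on k_on: silenced baseline rising
    # logistically at the gene's class time; escapees stay at 1
    react = np.ones((len(genes), n_cells))
    sched = is_x & ~escapee
    if cfg.snapshot is None:
        react[sched] = cfg.silenced_multiplier + (1 - cfg.silenced_multiplier) \
            * expit((pt[None, :] - class_time[sched, None])
                    / cfg.reactivation_slope)
        # active-X allele fold decaying to 1 as reactivation proceeds
        fold_t = 1.0 + (cfg.xa_fold - 1.0) * expit(
            (cfg.xa_decay_midpoint - pt) / cfg.xa_decay_slope)
    elif cfg.snapshot == "C0":
        react[sched] = cfg.silenced_multiplier
        fold_t = np.full(n_cells, cfg.xa_fold)
    else:  # C5: reactivated, upregulation erased
        fold_t = np.ones(n_cells)
    xa = np.ones((len(genes), n_cells))
    if cfg.xa_mechanism == "k_on":
        xa[is_x] = _kon_multiplier_for_mean_fold(
            fold_t[None, :], kon[is_x], koff[is_x])
    else:
        xa[is_x] = np.broadcast_to(fold_t, (is_x.sum(), n_cells))

    depth = np.exp(rng.normal(0.0, cfg.depth_sigma, size=n_cells))[None, :]

    mult = {"mus": react, "cast": np.ones_like(react)}
    mult[cfg.xa_allele] = xa
    if cfg.other_x == "active":
        other = "mus" if cfg.xa_allele == "cast" else "cast"
        mult[other] = np.ones_like(react)

    def draw(allele):
        m = mult[allele]
        if cfg.xa_mechanism == "k_syn" and np.shares_memory(m, xa):
            return _telegraph_counts(rng, kon, koff, ksyn * m * depth)
        return _telegraph_counts(rng, kon * m, koff, ksyn * depth)

    mus = draw("mus")
    cast = draw("cast")
    other_allele = "mus" if cfg.xa_allele == "cast" else "cast"
    if cfg.other_x == "absent":
        (mus if other_allele == "mus" else cast)[is_x] = 0
    total = _with_unassignable(rng, mus, cast, cfg.assignable_fraction)

    m = AllelicCountMatrix(
        counts_mus=pd.DataFrame(mus, index=genes, columns=cells.index),
        counts_cast=pd.DataFrame(cast, index=genes, columns=cells.index),
        counts_total=pd.DataFrame(total, index=genes, columns=cells.index),
        annotation=ann).validate()
    feat = pd.DataFrame({
        "kinetic_class": ["autosomal"] * n_auto + x_classes.tolist(),
        "chrom": ann["chrom"].to_numpy(),
        "schedule_time": class_time}, index=genes)
    return m, cells[["pseudotime", "group_label"]], \
        GroundTruth(feat, cells, params, cfg)


# ---------------------------------------------------------------------------
# bulk allelic ATAC timecourse
# ---------------------------------------------------------------------------

def _x_region_coordinates(rng, categories: pd.Series) -> np.ndarray:
    """chrX starts with planted distance-to-escapee structure."""
    n = len(categories)
    esc = categories.isin(["escapee", "mus_mono_to_bi"]).to_numpy()
    starts = np.zeros(n)
    anchors = np.sort(rng.uniform(1e6, CHRX_LENGTH - 1e6, size=max(esc.sum(), 1)))
    starts[esc] = anchors[:esc.sum()] if esc.any() else 0
    for cls, (lo, hi) in ATAC_DISTANCE_RANGE.items():
        idx = (categories == cls).to_numpy()
        if not idx.any():
            continue
        base = rng.choice(anchors, size=idx.sum())
        off = rng.uniform(lo, hi, size=idx.sum()) \
            * rng.choice([-1.0, 1.0], size=idx.sum())
        starts[idx] = np.clip(base + off, 1000, CHRX_LENGTH - 1000)
    rest = (categories == "cast_monoallelic").to_numpy()
    starts[rest] = rng.uniform(1e4, CHRX_LENGTH - 1e4, size=rest.sum())
    return np.round(starts).astype(int)


def simulate_atac_timepoints(config: SimulationConfig | None = None,
                             seed: int = 0, timepoints=TIMEPOINTS):
    """Allelic ATAC counts, regions x (timepoint x replicate) samples.

    Per X region, the Mus (inactive) allele steps from a closed baseline to
    open at its category's timepoint; the Cast (active) allele carries the
    ``xa_fold`` enhancement at d0, decaying from d10 and gone in iPSCs;
    autosomes are biallelic throughout.  Counts are depth-scaled Poisson
    draws around lognormal region baselines.  Returns (matrix, truth).
    """
    cfg = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(seed)
    timepoints = list(timepoints)
    n_auto, n_x = cfg.n_autosomal_regions, cfg.n_x_regions

    categories = _assign_classes(rng, n_x, cfg.atac_category_fractions)
    ids = [f"region_{i:06d}" for i in range(n_auto + n_x)]
    chroms = [AUTOSOMES[i % len(AUTOSOMES)] for i in range(n_auto)] \
        + ["chrX"] * n_x
    starts = np.concatenate([
        50_000 * (1 + np.arange(n_auto) // len(AUTOSOMES)),
        _x_region_coordinates(rng, categories)])
    cat_col = ["autosomal"] * n_auto + [
        "escapee" if c == "escapee" else "x_linked" for c in categories]
    reg_class = np.where(
        np.array(chroms) == "chrX",
        rng.choice(["enhancer", "promoter"], size=len(ids)), "other")
    ann = pd.DataFrame({
        "chrom": chroms, "start": starts, "end": starts + 500,
        "category": cat_col, "reg_class": reg_class},
        index=pd.Index(ids, name="feature_id"))

    base = np.concatenate([
        _lognormal(rng, cfg.atac_mean_reads, cfg.atac_region_sigma,
                   n_auto, cfg.stratified),
        _lognormal(rng, cfg.atac_mean_reads, cfg.atac_region_sigma,
                   n_x, cfg.stratified)])[:, None]
    is_x = np.array(chroms) == "chrX"
    tp_index = {t: i for i, t in enumerate(TIMEPOINTS)}
    open_at = np.full(len(ids), np.nan)
    for cls, tp in ATAC_OPENING_TIMEPOINT.items():
        open_at[np.concatenate([np.zeros(n_auto, bool),
                                (categories == cls).to_numpy()])] = tp_index[tp]
    esc = np.concatenate([np.zeros(n_auto, bool),
                          (categories == "escapee").to_numpy()])
    mus2bi = np.concatenate([np.zeros(n_auto, bool),
                             (categories == "mus_mono_to_bi").to_numpy()])
    cast_only = np.concatenate([np.zeros(n_auto, bool),
                                (categories == "cast_monoallelic").to_numpy()])

    samples, mus_cols, cast_cols = [], [], []
    closed = cfg.atac_closed_multiplier
    for tp in timepoints:
        ti = tp_index[tp]
        fold = 1.0 + (cfg.xa_fold - 1.0) * XA_DECAY_FRACTION[tp]
        # inactive-allele multiplier per region at this timepoint
        mus_mult = np.ones(len(ids))
        sched = is_x & ~esc & ~mus2bi & ~cast_only
        mus_mult[sched] = np.where(np.asarray(open_at)[sched] <= ti, 1.0, closed)
        mus_mult[cast_only] = closed
        cast_mult = np.ones(len(ids))
        cast_mult[is_x] = fold
        # mus-mono-to-bi: accessible from Mus at d0, Cast opens at d10
        cast_mult[mus2bi] = np.where(ti >= tp_index["d10"], 1.0, closed)
        mus_mult[mus2bi] = 1.0
        if cfg.xa_allele == "mus":
            mus_mult, cast_mult = cast_mult, mus_mult
        if cfg.other_x == "absent":
            (mus_mult if cfg.xa_allele == "cast" else cast_mult)[is_x] = 0.0
        elif cfg.other_x == "active":
            (mus_mult if cfg.xa_allele == "cast" else cast_mult)[is_x] = 1.0
        for rep in range(cfg.n_samples_per_group):
            depth = np.exp(rng.normal(0.0, cfg.depth_sigma))
            samples.append(f"{tp}_rep{rep + 1}")
            mus_cols.append(rng.poisson(base[:, 0] * mus_mult * depth))
            cast_cols.append(rng.poisson(base[:, 0] * cast_mult * depth))

    mus = np.column_stack(mus_cols)
    cast = np.column_stack(cast_cols)
    total = _with_unassignable(rng, mus, cast, cfg.assignable_fraction)
    m = AllelicCountMatrix(
        counts_mus=pd.DataFrame(mus, index=ann.index, columns=samples),
        counts_cast=pd.DataFrame(cast, index=ann.index, columns=samples),
        counts_total=pd.DataFrame(total, index=ann.index, columns=samples),
        annotation=ann).validate()
    feat = pd.DataFrame({
        "category": ["autosomal"] * n_auto + categories.tolist(),
        "chrom": ann["chrom"].to_numpy(),
        "opening_timepoint": [
            TIMEPOINTS[int(t)] if np.isfinite(t) else ""
            for t in open_at]}, index=ann.index)
    return m, GroundTruth(feat, None, None, cfg)


def atac_groups(m: AllelicCountMatrix) -> pd.Series:
    """Sample -> timepoint label for matrices from simulate_atac_timepoints."""
    return pd.Series({s: s.rsplit("_rep", 1)[0] for s in m.samples},
                     name="group_label").reindex(m.samples)


# ---------------------------------------------------------------------------
# XO iPSCs
# ---------------------------------------------------------------------------

def simulate_xo_ipscs(config: SimulationConfig | None = None, seed: int = 0):
    """XX iPSCs plus XO cells that lost one X chromosome.

    XX cells express both X alleles at autosomal levels (no XCI, no XCU);
    XO cells have every X-linked count of the lost allele at zero —
    escapees included, matching the loss of biallelic escapee expression
    used to call X loss — and the retained allele upregulated by
    ``xa_fold``.  Returns (matrix, truth).
    """
    cfg = (config or SimulationConfig()).validate()
    if cfg.xo_fraction <= 0:
        raise ValueError("xo_fraction must be > 0 for the XO simulation")
    rng = np.random.default_rng(seed)
    n_cells, n_auto, n_x = cfg.n_cells, cfg.n_autosomal_features, cfg.n_x_features

    is_xo = rng.permutation(n_cells) < int(round(cfg.xo_fraction * n_cells))
    if cfg.xo_lost_allele == "random":
        lost = np.where(rng.uniform(size=n_cells) < 0.5, "mus", "cast")
    else:
        lost = np.full(n_cells, cfg.xo_lost_allele)
    state = np.where(is_xo, np.char.add("XO_", np.char.add(lost, "_lost")), "XX")
    cells = pd.DataFrame(
        {"pseudotime": 0.0, "group_label": np.where(is_xo, "XO", "XX"),
         "x_state": state},
        index=pd.Index([f"cell_{i:04d}" for i in range(n_cells)],
                       name="sample_id"))

    x_classes = pd.Series(["escapee"] * int(cfg.fraction_escapees * n_x)
                          + ["late"] * (n_x - int(cfg.fraction_escapees * n_x)))
    ann = _gene_annotation(rng, cfg, x_classes)
    genes = ann.index
    params = _draw_expression_params(rng, cfg, n_auto, n_x)
    params.index = genes
    kon = params["k_on"].to_numpy()[:, None]
    koff = params["k_off"].to_numpy()[:, None]
    ksyn = params["k_syn"].to_numpy()[:, None]
    is_x = (ann["chrom"] == "chrX").to_numpy()
    depth = np.exp(rng.normal(0.0, cfg.depth_sigma, size=n_cells))[None, :]

    counts = {}
    for allele in ("mus", "cast"):
        mult = np.ones((len(genes), n_cells))
        retained_xo = is_xo & (lost != allele)
        up = _kon_multiplier_for_mean_fold(cfg.xa_fold, kon[is_x], koff[is_x]) \
            if cfg.xa_mechanism == "k_on" else np.full((is_x.sum(), 1), cfg.xa_fold)
        mult[np.ix_(is_x, retained_xo)] = np.broadcast_to(
            up, (is_x.sum(), retained_xo.sum()))
        if cfg.xa_mechanism == "k_syn":
            c = _telegraph_counts(rng, kon, koff, ksyn * mult * depth)
        else:
            c = _telegraph_counts(rng, kon * mult, koff, ksyn * depth)
        c[np.ix_(is_x, is_xo & (lost == allele))] = 0
        counts[allele] = c
    total = _with_unassignable(rng, counts["mus"], counts["cast"],
                               cfg.assignable_fraction)
    m = AllelicCountMatrix(
        counts_mus=pd.DataFrame(counts["mus"], index=genes, columns=cells.index),
        counts_cast=pd.DataFrame(counts["cast"], index=genes, columns=cells.index),
        counts_total=pd.DataFrame(total, index=genes, columns=cells.index),
        annotation=ann).validate()
    feat = pd.DataFrame({"kinetic_class": ["autosomal"] * n_auto
                         + x_classes.tolist(),
                         "chrom": ann["chrom"].to_numpy()}, index=genes)
    return m, GroundTruth(feat, cells, params, cfg)


# ---------------------------------------------------------------------------
# pure Poisson-beta burst experiment (no technical noise)
# ---------------------------------------------------------------------------

def simulate_burst_dataset(n_autosomal: int = 1500, n_x: int = 300,
                           n_cells: int = 1000, kon_fold_x: float = 1.0,
                           size_fold_x: float = 1.0, seed: int = 0,
                           config: SimulationConfig | None = None):
    """Genes x cells counts drawn straight from the Poisson-beta model.

    X-linked genes have k_on multiplied by ``kon_fold_x`` and burst size
    (via k_syn) by ``size_fold_x``; no depth variation or unassignable
    reads, so each gene's marginal is exactly Poisson-beta at its
    generative parameters.  Returns (counts frame, truth params frame,
    x gene index, autosomal gene index).
    """
    cfg = config or SimulationConfig(kon_dist=(0.8, 0.5),
                                     koff_dist=(10.0, 0.5),
                                     burst_size_dist=(15.0, 0.5))
    rng = np.random.default_rng(seed)
    n = n_autosomal + n_x
    params = _draw_burst_params(rng, cfg, n_autosomal, n_x)
    params.index = pd.Index(
        [f"gene_{i:05d}" for i in range(n)], name="feature_id")
    is_x = np.arange(n) >= n_autosomal
    params["chrom"] = np.where(is_x, "chrX", "autosome")
    params.loc[is_x, "k_on"] *= kon_fold_x
    params.loc[is_x, "k_syn"] *= size_fold_x
    counts = _telegraph_counts(
        rng, params["k_on"].to_numpy()[:, None],
        params["k_off"].to_numpy()[:, None],
        params["k_syn"].to_numpy()[:, None] * np.ones((1, n_cells)))
    frame = pd.DataFrame(counts, index=params.index,
                         columns=[f"cell_{i:04d}" for i in range(n_cells)])
    return frame, params, params.index[is_x], params.index[~is_x]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset(name: str) -> SimulationConfig:
    """Named study conditions.

    * ``mef_female`` — somatic XX cells: Cast Xa upregulated 1.33-fold,
      Mus Xi silenced (accessibility fold of Fig-1D-type analyses).
    * ``mesc_male`` — male pluripotent cells: the sole (Mus) X upregulated
      1.4-fold, no second X.
    * ``ipsc_xx`` — XX pluripotent cells: both X alleles active, no
      upregulation (the null condition).
    * ``mef_expression`` — scRNA-seq somatic condition: Cast Xa expression
      1.35-fold over autosomes.
    """
    # snapshot (single-timepoint) conditions describe the active-allele
    # peak repertoire: every X region is accessible on the measured Xa, so
    # the Xa-closed-at-d0 category of the reprogramming timecourse is not
    # part of the mix
    snapshot = {"early": 0.20, "intermediate": 0.15, "late": 0.20,
                "very_late": 0.20, "escapee": 0.15, "cast_monoallelic": 0.10}
    presets = {
        "mef_female": SimulationConfig(
            xa_fold=1.33, atac_category_fractions=dict(snapshot)),
        "mesc_male": SimulationConfig(
            xa_fold=1.4, xa_allele="mus", other_x="absent",
            atac_category_fractions=dict(snapshot)),
        "ipsc_xx": SimulationConfig(
            xa_fold=1.0, other_x="active",
            atac_category_fractions=dict(snapshot)),
        "mef_expression": SimulationConfig(xa_fold=1.35, snapshot="C0",
                                           n_x_features=440),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return replace(presets[name])
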