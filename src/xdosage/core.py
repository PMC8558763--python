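"""Allelic count matrices: container, I/O, normalization and filtering.

The central object is :class:`AllelicCountMatrix`, a features x samples
container with three raw integer layers — maternal (``mus``), paternal
(``cast``) and total (allele-assigned plus unassignable) read counts — and
optional normalized layers.  It is the shared currency of every analysis
module: bulk ATAC-seq regions x timepoint samples and single-cell RNA-seq
genes x cells are both represented this way.

Conventions baked in here and relied on downstream:

* normalization divides every layer (allelic layers included) by the *total*
  library size of the sample, multiplies by a scale factor (default 10,000)
  and applies log1p;
* "expressed but allelically uninformative" entries (total reads present,
  zero allelic reads) are flagged in ``missing_mask`` and excluded from
  allelic statistics, while entries with no reads at all stay numeric zeros;
* per-group read-sum filters mask a feature only in the groups where it
  fails, so a region can be informative at one timepoint and masked at
  another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_CATEGORIES = ("autosomal", "x_linked", "escapee")
REG_CLASSES = ("enhancer", "promoter", "other", "unknown")
#: chromosomes never used in X-vs-autosome statistics
EXCLUDED_CHROMOSOMES = ("chrY", "chrM")
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 20))

ANNOTATION_COLUMNS = ("chrom", "start", "end", "feature_id", "category", "reg_class")


class AllelicDataError(ValueError):
    """Structural problem in allelic count data (shape, sign, annotation)."""


def _as_count_frame(df: pd.DataFrame, name: str) -> pd.DataFrame:
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise AllelicDataError(f"{name}: non-numeric counts")
    if np.any(~np.isfinite(values)):
        raise AllelicDataError(f"{name}: non-finite counts")
    if np.any(values < 0):
        bad = df.index[np.any(values < 0, axis=1)].tolist()
        raise AllelicDataError(f"{name}: negative counts in features {bad[:10]}")
    if np.any(values != np.round(values)):
        bad = df.index[np.any(values != np.round(values), axis=1)].tolist()
        raise AllelicDataError(f"{name}: non-integer counts in features {bad[:10]}")
    return df.astype(np.int64)


@dataclass
class AllelicCountMatrix:
    """Features x samples allelic count container.

    Raw layers are non-negative integers; ``counts_total`` includes reads
    that could not be assigned to either allele, so element-wise
    ``counts_mus + counts_cast <= counts_total``.  ``annotation`` is indexed
    by feature id with columns ``chrom, start, end, category, reg_class``
    and optionally ``snp_count``.  ``missing_mask`` flags expressed-but-
    allelically-uninformative entries; ``informative_mask`` (True = keep)
    records per-group read-sum filters.
    """

    counts_mus: pd.DataFrame
    counts_cast: pd.DataFrame
    counts_total: pd.DataFrame | None
    annotation: pd.DataFrame
    norm_mus: pd.DataFrame | None = None
    norm_cast: pd.DataFrame | None = None
    norm_total: pd.DataFrame | None = None
    missing_mask: pd.DataFrame | None = None
    informative_mask: pd.DataFrame | None = None

    # -- basic introspection -------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.counts_mus.index

    @property
    def samples(self) -> pd.Index:
        return self.counts_mus.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts_mus.shape

    def layer(self, allele: str, normalized: bool = False, linear: bool = False) -> pd.DataFrame:
        """Return a layer by allele name ('mus', 'cast' or 'total').

        With ``normalized=True`` the log1p-normalized layer is returned;
        ``linear=True`` additionally de-logs it (expm1), recovering
        normalized values on the original count scale, which is the scale on
        which fold changes are interpretable.
        """
        if allele not in ("mus", "cast", "total"):
            raise ValueError(f"unknown allele {allele!r}")
        if normalized:
            out = getattr(self, f"norm_{allele}")
            if out is None:
                raise AllelicDataError(
                    f"normalized layer for {allele!r} absent; run normalize_library first"
                )
            return np.expm1(out) if linear else out
        out = getattr(self, f"counts_{allele}")
        if out is None:
            raise AllelicDataError("total layer absent")
        return out

    # -- validation ----------------------------------------------------------

    def validate(self) -> "AllelicCountMatrix":
        layers = {"mus": self.counts_mus, "cast": self.counts_cast}
        if self.counts_total is not None:
            layers["total"] = self.counts_total
        for name, df in layers.items():
            _as_count_frame(df, name)
            if not df.index.equals(self.features) or not df.columns.equals(self.samples):
                raise AllelicDataError(f"layer {name}: index/columns mismatch")
        if self.counts_total is not None:
            excess = (self.counts_mus.to_numpy() + self.counts_cast.to_numpy()
                      > self.counts_total.to_numpy())
            if excess.any():
                bad = self.features[excess.any(axis=1)].tolist()
                raise AllelicDataError(
                    f"mus + cast exceeds total for features {bad[:10]}")
        missing_ann = self.features.difference(self.annotation.index)
        if len(missing_ann):
            raise AllelicDataError(
                f"features absent from annotation: {missing_ann.tolist()[:10]}")
        ann = self.annotation.loc[self.features]
        if (ann["start"] >= ann["end"]).any():
            bad = ann.index[ann["start"] >= ann["end"]].tolist()
            raise AllelicDataError(f"start >= end for features {bad[:10]}")
        bad_cat = ~ann["category"].isin(FEATURE_CATEGORIES)
        if bad_cat.any():
            raise AllelicDataError(
                f"unknown category for features {ann.index[bad_cat].tolist()[:10]}")
        esc = ann["category"] == "escapee"
        if (esc & (ann["chrom"] != "chrX")).any():
            bad = ann.index[esc & (ann["chrom"] != "chrX")].tolist()
            raise AllelicDataError(f"escapee off chrX: {bad[:10]}")
        return self

    # -- derived masks -------------------------------------------------------

    def usable_mask(self) -> pd.DataFrame:
        """Boolean frame: entries allowed into allelic statistics."""
        mask = pd.DataFrame(True, index=self.features, columns=self.samples)
        if self.missing_mask is not None:
            mask &= ~self.missing_mask
        if self.informative_mask is not None:
            mask &= self.informative_mask
        return mask

    def subset(self, features=None, samples=None) -> "AllelicCountMatrix":
        def take(df):
            if df is None:
                return None
            out = df
            if features is not None:
                out = out.loc[features]
            if samples is not None:
                out = out[samples]
            return out

        return replace(
            self,
            counts_mus=take(self.counts_mus),
            counts_cast=take(self.counts_cast),
            counts_total=take(self.counts_total),
            norm_mus=take(self.norm_mus),
            norm_cast=take(self.norm_cast),
            norm_total=take(self.norm_total),
            missing_mask=take(self.missing_mask),
            informative_mask=take(self.informative_mask),
            annotation=self.annotation.loc[features]
            if features is not None else self.annotation,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Read a BED-like annotation TSV.

    Columns (no header): chrom, start, end, feature_id, category, reg_class
    and optionally snp_count.  Coordinates are 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] not in (6, 7):
        raise AllelicDataError(
            f"annotation must have 6 or 7 columns, got {df.shape[1]}")
    cols = list(ANNOTATION_COLUMNS) + (["snp_count"] if df.shape[1] == 7 else [])
    df.columns = cols
    df = df.set_index("feature_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise AllelicDataError(f"duplicate annotation rows for {dup[:10]}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    out = annotation[cols].copy()
    out["feature_id"] = annotation.index
    out["category"] = annotation["category"]
    out["reg_class"] = annotation["reg_class"]
    if "snp_count" in annotation.columns:
        out["snp_count"] = annotation["snp_count"]
    out.to_csv(path, sep="\t", header=False, index=False)


def _read_layer(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature_id"
    return df


def read_allelic_matrix(mus_path, cast_path, annotation_path,
                        total_path=None) -> AllelicCountMatrix:
    """Read mus/cast(/total) count TSVs plus a BED-like annotation.

    All count files are features-as-rows, samples-as-columns with the
    feature id in the first column.  Files must agree on features and
    samples; mismatches raise :class:`AllelicDataError` naming the
    offending rows/columns.
    """
    mus = _read_layer(mus_path)
    cast = _read_layer(cast_path)
    total = _read_layer(total_path) if total_path is not None else None
    for name, df in (("cast", cast),) + ((("total", total),) if total is not None else ()):
        if not df.index.equals(mus.index):
            diff = mus.index.symmetric_difference(df.index).tolist()
            raise AllelicDataError(f"{name} layer: feature mismatch {diff[:10]}")
        if not df.columns.equals(mus.columns):
            diff = mus.columns.symmetric_difference(df.columns).tolist()
            raise AllelicDataError(f"{name} layer: sample mismatch {diff[:10]}")
    annotation = read_annotation(annotation_path)
    m = AllelicCountMatrix(counts_mus=mus, counts_cast=cast,
                           counts_total=total, annotation=annotation)
    return m.validate()


def write_allelic_matrix(m: AllelicCountMatrix, directory, prefix="matrix") -> dict:
    """Write raw layers + annotation as TSV/BED into ``directory``.

    Returns the paths written.  Round-trips bit-exactly through
    :func:`read_allelic_matrix`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("mus", "cast", "total"):
        df = getattr(m, f"counts_{name}")
        if df is None:
            continue
        p = directory / f"{prefix}.{name}.tsv"
        df.to_csv(p, sep="\t")
        paths[name] = p
    paths["annotation"] = directory / f"{prefix}.annotation.bed"
    write_annotation(m.annotation.loc[m.features], paths["annotation"])
    return paths


def read_pseudotime(path) -> pd.DataFrame:
    """Read a 3-column TSV (sample_id, pseudotime, group_label)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["sample_id", "pseudotime", "group_label"]
    if list(df.columns[:3]) != expected:
        raise AllelicDataError(f"pseudotime file must have columns {expected}")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise AllelicDataError("duplicate sample ids in pseudotime file")
    if not np.all(np.isfinite(df["pseudotime"])) or (df["pseudotime"] < 0).any():
        raise AllelicDataError("pseudotime values must be finite and >= 0")
    return df


def write_pseudotime(pseudotime: pd.DataFrame, path) -> None:
    out = pseudotime.reset_index()
    out.columns = ["sample_id", "pseudotime", "group_label"]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization and filters
# ---------------------------------------------------------------------------

def normalize_library(m: AllelicCountMatrix, scale: float = 10_000.0,
                      log=np.log1p) -> AllelicCountMatrix:
    """Library-size normalize all layers against the *total* library.

    Each layer value x becomes ``log(1 + scale * x / colsum(total))``, with
    the column sum taken over the total layer of that sample so that mus,
    cast and total values of one sample share a divisor.  Raw layers are
    left untouched and re-running simply overwrites the normalized layers.
    """
    if m.counts_total is None:
        raise AllelicDataError("normalize_library requires the total layer")
    lib = m.counts_total.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise AllelicDataError(
            f"zero total library size for samples {zero}; drop them first")

    def norm(df):
        return log(scale * df / lib)

    return replace(m, norm_mus=norm(m.counts_mus), norm_cast=norm(m.counts_cast),
                   norm_total=norm(m.counts_total))


def filter_min_allelic_total(m: AllelicCountMatrix, min_total: int = 10,
                             groups: pd.Series | None = None
                             ) -> tuple[AllelicCountMatrix, pd.DataFrame]:
    """Mask features whose allelic read sum within a sample group is < min_total.

    ``groups`` maps sample -> group label (samples of one timepoint); without
    it every sample is its own group.  A feature failing in one group stays
    usable in groups where it passes.  Returns the masked matrix and a
    per-group report of retained feature counts.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    if groups is None:
        groups = pd.Series(m.samples, index=m.samples)
    groups = groups.reindex(m.samples)
    allelic = m.counts_mus + m.counts_cast
    keep = pd.DataFrame(False, index=m.features, columns=m.samples)
    rows = []
    for label, cols in groups.groupby(groups).groups.items():
        ok = allelic[list(cols)].sum(axis=1) >= min_total
        keep.loc[:, list(cols)] = np.broadcast_to(
            ok.to_numpy()[:, None], (len(ok), len(cols)))
        rows.append({"group": label, "n_retained": int(ok.sum()),
                     "n_total": len(ok)})
    if m.informative_mask is not None:
        keep &= m.informative_mask
    report = pd.DataFrame(rows).set_index("group")
    return replace(m, informative_mask=keep), report


def filter_min_snps(m: AllelicCountMatrix, min_snps: int = 4) -> AllelicCountMatrix:
    """Drop genes covered by fewer than ``min_snps`` strain SNPs."""
    ann = m.annotation.loc[m.features]
    if "snp_count" not in ann.columns:
        raise AllelicDataError("annotation lacks snp_count column")
    snp = ann["snp_count"]
    if snp.isna().any():
        bad = snp.index[snp.isna()].tolist()
        raise AllelicDataError(f"snp_count missing for genes {bad[:10]}")
    keep = m.features[snp >= min_snps]
    return m.subset(features=keep)


def apply_missing_convention(m: AllelicCountMatrix) -> AllelicCountMatrix:
    """Flag expressed-but-allelically-uninformative entries.

    An entry with total reads but no allele-assigned reads carries no
    allelic information and must not enter allelic statistics as a zero;
    entries with no reads at all are true (numeric) zeros.
    """
    if m.counts_total is None:
        raise AllelicDataError("missing-data convention requires the total layer")
    mask = (m.counts_total > 0) & ((m.counts_mus + m.counts_cast) == 0)
    return replace(m, missing_mask=mask)


# ---------------------------------------------------------------------------
# feature selection helpers shared by the statistics modules
# ---------------------------------------------------------------------------

def x_features(annotation: pd.DataFrame, include_escapees: bool = True) -> pd.Index:
    ann = annotation
    on_x = ann["chrom"] == "chrX"
    if not include_escapees:
        on_x &= ann["category"] != "escapee"
    return ann.index[on_x]


def autosomal_features(annotation: pd.DataFrame,
                       exclude_chrom: str | None = None) -> pd.Index:
    ann = annotation
    keep = ann["chrom"].isin(AUTOSOMES)
    if exclude_chrom is not None:
        keep &= ann["chrom"] != exclude_chrom
    return ann.index[keep]
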