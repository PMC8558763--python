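import numpy as np
import pandas as pd
import pytest

from xdosage.core import AllelicCountMatrix


def make_annotation(feature_ids, chroms, categories=None, reg_classes=None,
                    snp_counts=None, starts=None, length=500):
    n = len(feature_ids)
    starts = np.arange(n) * 10_000 + 1000 if starts is None else np.asarray(starts)
    ann = pd.DataFrame({
        "chrom": chroms,
        "start": starts,
        "end": starts + length,
        "category": categories if categories is not None else [
            "x_linked" if c == "chrX" else "autosomal" for c in chroms],
        "reg_class": reg_classes if reg_classes is not None else "unknown",
    }, index=pd.Index(feature_ids, name="feature_id"))
    if snp_counts is not None:
        ann["snp_count"] = snp_counts
    return ann


def make_matrix(mus, cast, chroms, total=None, samples=None, **ann_kwargs):
    """Small AllelicCountMatrix from arrays; total defaults to mus + cast."""
    mus = np.asarray(mus)
    n_feat, n_samp = mus.shape
    features = pd.Index([f"f{i}" for i in range(n_feat)], name="feature_id")
    samples = samples or [f"s{j}" for j in range(n_samp)]
    cast = np.asarray(cast)
    total = mus + cast if total is None else np.asarray(total)
    ann = make_annotation(features, chroms, **ann_kwargs)
    return AllelicCountMatrix(
        counts_mus=pd.DataFrame(mus, index=features, columns=samples),
        counts_cast=pd.DataFrame(cast, index=features, columns=samples),
        counts_total=pd.DataFrame(total, index=features, columns=samples),
        annotation=ann).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_matrix():
    """3 features x 2 samples with hand-checkable counts."""
    return make_matrix(
        mus=[[3, 0], [5, 2], [0, 7]],
        cast=[[1, 4], [5, 0], [2, 0]],
        chroms=["chr1", "chr2", "chrX"],
        total=[[10, 5], [12, 4], [2, 9]],
    )
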