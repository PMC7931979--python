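import numpy as np
import pandas as pd
import pytest

from omicompare import ContrastStats, ExpressionDataset, merge_on_id


def make_dataset(values, ids=None, samples=None, groups=None, name="ds", id_column="feature_id"):
    """Build a small in-memory ExpressionDataset from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    ids = list(ids) if ids is not None else [f"g{i + 1}" for i in range(n_feat)]
    samples = list(samples) if samples is not None else [f"s{j + 1}" for j in range(n_samp)]
    design = pd.DataFrame({"sample": samples})
    if groups is not None:
        design["group"] = list(groups)
    design = design.set_index(pd.Index(samples, name="sample_name"))
    return ExpressionDataset(
        name=name,
        matrix=pd.DataFrame(values, columns=samples),
        feature_annotations=pd.DataFrame({id_column: ids}),
        design=design,
        id_column=id_column,
    )


def make_contrast(p=None, fdr=None, lfc=None, ave=None, n=None, name="c"):
    """ContrastStats from plain lists; unspecified columns default sanely."""
    for v in (p, fdr, lfc, ave):
        if v is not None:
            n = len(v)
            break
    assert n is not None
    as_series = lambda v, fill: pd.Series(v if v is not None else [fill] * n, dtype=float)
    fdr_vals = fdr if fdr is not None else p  # identity adjustment by default
    p_vals = p if p is not None else fdr  # keep fdr >= p coherent
    return ContrastStats(
        contrast_name=name,
        p=as_series(p_vals, 1.0),
        fdr=as_series(fdr_vals, 1.0),
        log2fc=as_series(lfc, 0.0),
        ave=as_series(ave, 10.0),
    )


def make_pair(n, ids=None):
    """A trivial merged pair of two 2-sample datasets sharing n feature IDs."""
    ids = ids or [f"g{i + 1}" for i in range(n)]
    a = make_dataset(np.zeros((n, 2)), ids=ids, name="a")
    b = make_dataset(np.zeros((n, 2)), ids=ids, name="b")
    return merge_on_id(a, b)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
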