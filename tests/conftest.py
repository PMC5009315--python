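import numpy as np
import pytest

from intestsig.expr_io import ExpressionStudy
from intestsig.meta_signature import DirectionalGeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(20160902)


def make_study(
    values,
    feature_ids=None,
    sample_ids=None,
    groups=None,
    study_id="study",
    is_gene_level=True,
    platform_id="",
):
    """Small ExpressionStudy builder with sensible defaults."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if feature_ids is None:
        feature_ids = [f"g{i + 1}" for i in range(n_feat)]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(n_samp)]
    if groups is None:
        half = n_samp // 2
        groups = {s: ("A" if j < half else "B") for j, s in enumerate(sample_ids)}
    return ExpressionStudy(
        study_id=study_id,
        feature_ids=list(feature_ids),
        sample_ids=list(sample_ids),
        values=values,
        groups=groups,
        platform_id=platform_id,
        is_gene_level=is_gene_level,
    )


def gene_set(**entries):
    """DirectionalGeneSet from keyword arguments: gene_set(VIL1='up')."""
    return DirectionalGeneSet(entries=dict(entries))


@pytest.fixture
def small_two_group_study():
    """4 genes x 6 samples, groups A (s1-3) vs B (s4-6)."""
    values = [
        [10, 11, 12, 30, 31, 32],  # up in A? no: B higher -> comparison dependent
        [50, 52, 51, 50, 51, 52],  # flat
        [40, 41, 42, 10, 11, 12],  # down in B
        [5, 6, 7, 5, 6, 7],  # flat
    ]
    return make_study(values)
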