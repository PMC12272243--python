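import numpy as np
import pytest

from oscnets.stats import (
    condition_contrast,
    glm_max_stat_test,
    one_sample_max_stat_test,
)


def test_detects_strong_effect(rng):
    data = rng.standard_normal((20, 30))
    data[:, 5] += 2.0  # large mean shift in one element
    res = one_sample_max_stat_test(data, n_perm=500, seed=0)
    assert res.significant[5]
    assert res.pvalues[5] < 0.01
    # most null elements stay non-significant
    assert res.significant.sum() <= 3


def test_null_p_values_well_behaved(rng):
    data = rng.standard_normal((15, 40))
    res = one_sample_max_stat_test(data, n_perm=300, seed=1)
    assert np.all(res.pvalues > 0) and np.all(res.pvalues <= 1)
    assert res.pvalues.min() >= 1.0 / 301.0
    assert res.null.shape == (300,)


def test_observed_labelling_in_null(rng):
    data = rng.standard_normal((12, 8))
    res = one_sample_max_stat_test(data, n_perm=200, seed=2)
    assert res.null[0] == pytest.approx(np.abs(res.copes).max())


def test_preserves_element_shape(rng):
    data = rng.standard_normal((10, 4, 6))
    res = one_sample_max_stat_test(data, n_perm=100, seed=3)
    assert res.copes.shape == (4, 6)
    assert res.pvalues.shape == (4, 6)
    np.testing.assert_allclose(res.copes, data.mean(axis=0), atol=1e-12)


def test_determinism_and_validation(rng):
    data = rng.standard_normal((10, 5))
    r1 = one_sample_max_stat_test(data, n_perm=100, seed=7)
    r2 = one_sample_max_stat_test(data, n_perm=100, seed=7)
    np.testing.assert_array_equal(r1.pvalues, r2.pvalues)
    with pytest.raises(ValueError):
        one_sample_max_stat_test(data[:1], n_perm=100)
    with pytest.raises(ValueError):
        one_sample_max_stat_test(data, n_perm=0)


def test_glm_detects_group_difference(rng):
    n = 40
    group = np.repeat([0.0, 1.0], n // 2)
    design = np.column_stack([group, np.ones(n)])
    data = rng.standard_normal((n, 10))
    data[group == 1, 3] += 1.5
    res = glm_max_stat_test(data, design, [1.0, 0.0], n_perm=300, seed=4)
    assert res.significant[3]
    with pytest.raises(ValueError):
        glm_max_stat_test(data, design, [1.0], n_perm=10)


def test_glm_rank_deficient_design_rejected(rng):
    data = rng.standard_normal((10, 4))
    design = np.column_stack([np.ones(10), np.ones(10)])
    with pytest.raises(ValueError, match="rank deficient"):
        glm_max_stat_test(data, design, [1.0, -1.0], n_perm=100)
    with pytest.raises(ValueError, match="non-zero"):
        glm_max_stat_test(
            data, np.column_stack([np.ones(10), np.arange(10.0)]),
            [0.0, 0.0], n_perm=100,
        )


def test_condition_contrast(rng):
    times = np.zeros((5, 2))
    subjects = [
        {"a": times + a, "b": times + b, "c": times + c}
        for a, b, c in [(1.0, 3.0, 4.0), (2.0, 0.0, 5.0)]
    ]
    # identical conditions with opposing weights cancel exactly
    same = [{"a": s["a"], "b": s["a"]} for s in subjects]
    out = condition_contrast(same, {"a": 1.0, "b": -1.0})
    np.testing.assert_array_equal(out, np.zeros((2, 5, 2)))
    # single condition with unit weight passes through unchanged
    out = condition_contrast(subjects, {"b": 1.0})
    np.testing.assert_array_equal(out[0], subjects[0]["b"])
    # (a + b)/2 - c on constant responses
    out = condition_contrast(subjects, {"a": 0.5, "b": 0.5, "c": -1.0})
    np.testing.assert_allclose(out[0], times + (1.0 + 3.0) / 2 - 4.0)
    np.testing.assert_allclose(out[1], times + (2.0 + 0.0) / 2 - 5.0)
    with pytest.raises(ValueError, match="subject 1 is missing condition 'd'"):
        condition_contrast(
            [dict(subjects[0], d=times), subjects[1]], {"d": 1.0}
        )


def test_threshold_property(rng):
    data = rng.standard_normal((15, 12))
    res = one_sample_max_stat_test(data, n_perm=200, seed=5)
    sig_by_threshold = np.abs(res.copes) > res.threshold
    # thresholding and p-values agree up to quantile-edge effects
    assert (sig_by_threshold == res.significant).mean() > 0.9
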