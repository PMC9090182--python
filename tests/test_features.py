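import numpy as np
import pytest
from scipy import stats

import muscnet as mn
from muscnet.errors import InputError
from muscnet.features import layout_length


# --- flatten / unflatten ----------------------------------------------------

def test_flatten_upper_triangle_example():
    a, b, c = 0.2, -0.4, 0.7
    cm = mn.ConnectivityMatrix("PCC", [[1, a, b], [a, 1, c], [b, c, 1]])
    fv = mn.flatten(cm, "upper_triangle")
    np.testing.assert_array_equal(fv.values, [a, b, c])


def test_flatten_full_square_example():
    a, b, c = 0.2, -0.4, 0.7
    cm = mn.ConnectivityMatrix("PCC", [[1, a, b], [a, 1, c], [b, c, 1]])
    fv = mn.flatten(cm, "full_square")
    assert fv.values.shape == (9,)
    np.testing.assert_array_equal(fv.values[:5], [1, a, b, a, 1])


@pytest.mark.parametrize("layout", ["upper_triangle", "full_square"])
def test_flatten_round_trip(layout, rng):
    m = rng.standard_normal((5, 5))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    cm = mn.ConnectivityMatrix("PCC", m)
    fv = mn.flatten(cm, layout)
    assert fv.values.shape == (layout_length(5, layout),)
    np.testing.assert_allclose(mn.unflatten(fv.values, 5, layout), m, atol=0)


# --- filter p-values ---------------------------------------------------------

def _ttest_oracle(a, b):
    """Textbook pooled-variance two-sample t statistic + CDF."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), na + nb - 2)


def test_ttest_matches_textbook_formula(rng):
    X = rng.standard_normal((20, 30))
    y = np.array([1] * 10 + [0] * 10)
    p = mn.ttest_pvalues(X, y)
    for j in range(30):
        assert p[j] == pytest.approx(_ttest_oracle(X[:10, j], X[10:, j]), abs=1e-10)


def test_ttest_detects_planted_shift_and_ignores_null(rng):
    n = 20
    X = rng.standard_normal((2 * n, 2))
    X[:n, 0] += 2.0  # planted group shift, d = 2
    y = np.array([1] * n + [0] * n)
    p = mn.ttest_pvalues(X, y)
    assert p[0] < 1e-3
    assert p[1] > 0.05 or p[1] < 1  # null feature: no guarantee, only sanity
    sel = mn.select(X, y, "Ttest", 0.05)
    assert 0 in sel.selected


def test_degenerate_feature_flagged():
    X = np.ones((8, 1))
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    for fn in (mn.ttest_pvalues, mn.ranksum_pvalues, mn.ks_pvalues):
        assert fn(X, y)[0] == 1.0
    res = mn.select(X, y, "Ttest", 1.0)
    assert res.degenerate[0]
    assert res.selected.size == 0


def test_ranksum_separated_groups_exact_p():
    """Complete separation: two-sided p equals 2 / C(na+nb, na) under the
    exact U null (every arrangement equally likely; only the two extreme
    orderings reach |U| at its maximum)."""
    a = np.arange(10.0)  # all smaller
    b = np.arange(100.0, 110.0)
    X = np.concatenate([a, b])[:, None]
    y = np.array([1] * 10 + [0] * 10)
    from math import comb

    expected = 2 / comb(20, 10)
    p = mn.ranksum_pvalues(X, y)[0]
    assert p == pytest.approx(expected, rel=1e-9)


def test_ranksum_monotone_transform_invariance(rng):
    X = rng.standard_normal((16, 5))
    y = np.array([1] * 8 + [0] * 8)
    p1 = mn.ranksum_pvalues(X, y)
    p2 = mn.ranksum_pvalues(np.exp(X), y)
    np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_ks_statistic_matches_ecdf_scan(rng):
    a = rng.standard_normal(20)
    b = rng.standard_normal(20) + 0.5
    X = np.concatenate([a, b])[:, None]
    y = np.array([1] * 20 + [0] * 20)
    # brute-force max ECDF gap over all observed points
    grid = np.concatenate([a, b])
    d_oracle = max(
        abs(np.mean(a <= t) - np.mean(b <= t)) for t in grid
    )
    d_scipy = stats.ks_2samp(a, b, method="asymp").statistic
    assert d_scipy == pytest.approx(d_oracle, abs=1e-12)
    # identical samples: D = 0, p = 1
    Xi = np.concatenate([a, a])[:, None]
    assert mn.ks_pvalues(Xi, y)[0] == 1.0
    # disjoint supports: D = 1 -> tiny p
    Xd = np.concatenate([a, a + 100])[:, None]
    assert mn.ks_pvalues(Xd, y)[0] < 1e-6


def test_select_threshold_monotonicity(rng):
    X = rng.standard_normal((20, 40))
    X[:10, :5] += 1.0
    y = np.array([1] * 10 + [0] * 10)
    for method in ("Ttest", "Wtest", "KStest"):
        small = set(mn.select(X, y, method, 0.05).selected.tolist())
        large = set(mn.select(X, y, method, 0.2).selected.tolist())
        assert small <= large
        all_sel = mn.select(X, y, method, 1.0)
        assert set(all_sel.selected.tolist()) <= set(np.arange(40).tolist())


def test_select_permutation_equivariance(rng):
    X = rng.standard_normal((16, 12))
    X[:8, :3] += 1.5
    y = np.array([1] * 8 + [0] * 8)
    perm = rng.permutation(12)
    for method in ("Ttest", "Wtest", "KStest"):
        base = set(mn.select(X, y, method, 0.1).selected.tolist())
        permuted = mn.select(X[:, perm], y, method, 0.1).selected
        back = set(int(perm[i]) for i in permuted)
        assert back == base


def test_select_recovers_planted_edges(small_pcc_features, small_linear_cohort):
    X, y, cohort = small_pcc_features
    _, spec = small_linear_cohort
    iu = np.triu_indices(spec.num_roi, k=1)
    pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(*iu))}
    planted = {pos[e] for e in cohort.planted_edges}
    sel = set(mn.select(X, y, "Ttest", 0.05).selected.tolist())
    assert len(sel & planted) >= len(planted) - 1


def test_select_validates_inputs(rng):
    X = rng.standard_normal((10, 3))
    y = np.array([1] * 5 + [0] * 5)
    with pytest.raises(InputError):
        mn.select(X, y, "Ftest", 0.05)
    with pytest.raises(InputError):
        mn.select(X, y, "Ttest", 0.0)
    with pytest.raises(InputError):
        mn.select(X, np.ones(10), "Ttest", 0.05)  # single class
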