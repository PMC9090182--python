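import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import muscnet as mn
from muscnet.errors import InputError, MetricUndefinedError

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


def _vector_pairs(min_size=3, max_size=30):
    return st.integers(min_size, max_size).flatmap(
        lambda n: st.tuples(
            st.lists(finite_floats, min_size=n, max_size=n),
            st.lists(finite_floats, min_size=n, max_size=n),
        )
    )


@pytest.mark.parametrize(
    "fn,x,y,expected",
    [
        (mn.pearson, [1, 2, 3], [2, 4, 6], 1.0),
        (mn.pearson, [1, 2, 3], [3, 2, 1], -1.0),
        (mn.pearson, [1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        (mn.spearman, [1, 2, 3], [1, 4, 9], 1.0),
        (mn.spearman, [1, 2, 3], [9, 4, 1], -1.0),
        (mn.spearman, [1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        (mn.kendall, [1, 2, 3], [1, 2, 3], 1.0),
        (mn.kendall, [1, 2, 3], [1, 3, 2], 1 / 3),
        (mn.kendall, [1, 2, 3, 4], [4, 3, 2, 1], -1.0),
        (mn.cosine, [1, 0], [0, 1], 0.0),
        (mn.cosine, [1, 2], [2, 4], 1.0),
        (mn.cosine, [1, 1], [1, -1], 0.0),
    ],
)
def test_metric_worked_examples(fn, x, y, expected):
    assert fn(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_equals_decentralized_cosine(rng):
    """Pearson is cosine similarity applied to mean-centred vectors."""
    for _ in range(50):
        n = int(rng.integers(3, 60))
        x = rng.standard_normal(n) * 3 + rng.normal()
        y = rng.standard_normal(n) * 2 + rng.normal()
        assert mn.pearson(x, y) == pytest.approx(
            mn.cosine(x - x.mean(), y - y.mean()), abs=1e-12
        )


def test_spearman_equals_pearson_of_ranks(rng):
    for _ in range(50):
        n = int(rng.integers(3, 60))
        x = rng.permutation(n).astype(float)  # tie-free
        y = rng.permutation(n).astype(float)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert mn.spearman(x, y) == mn.pearson(rx, ry)


def _kendall_oracle(x, y):
    """Exhaustive O(n^2) concordant/discordant pair count, tau-b tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def test_kendall_matches_pair_counting_oracle(rng):
    for _ in range(40):
        n = int(rng.integers(3, 51))
        x = np.round(rng.standard_normal(n), 1)  # induce ties
        y = np.round(rng.standard_normal(n), 1)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        assert mn.kendall(x, y) == pytest.approx(_kendall_oracle(x, y), abs=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(_vector_pairs())
def test_metrics_symmetric_in_arguments(pair):
    x, y = np.asarray(pair[0]), np.asarray(pair[1])
    for fn in (mn.pearson, mn.spearman, mn.kendall, mn.cosine):
        try:
            v1 = fn(x, y)
        except MetricUndefinedError:
            continue
        assert v1 == pytest.approx(fn(y, x), abs=1e-12)
        assert -1.0 <= v1 <= 1.0


@pytest.mark.parametrize("metric", ["PCC", "SCC", "KCC", "CS"])
def test_static_bfcn_invariants(metric, rng):
    ts = mn.SubjectTimeSeries("s1", rng.standard_normal((6, 40)))
    cm = mn.static_bfcn(ts, metric)
    np.testing.assert_array_equal(cm.values, cm.values.T)
    np.testing.assert_allclose(np.diag(cm.values), 1.0, atol=1e-12)
    assert np.all(cm.values >= -1) and np.all(cm.values <= 1)


def test_static_bfcn_trivial_two_roi():
    ts = mn.SubjectTimeSeries("t", [[1, 2, 3], [2, 4, 6]])
    cm = mn.static_bfcn(ts, "PCC")
    np.testing.assert_allclose(cm.values, [[1, 1], [1, 1]], atol=1e-12)


@pytest.mark.parametrize("metric", ["PCC", "SCC", "KCC", "CS"])
def test_static_bfcn_matches_double_loop_oracle(metric, rng):
    """Brute-force all-pairs recomputation, entry by entry."""
    sig = rng.standard_normal((4, 25))
    ts = mn.SubjectTimeSeries("g", sig)
    cm = mn.static_bfcn(ts, metric)
    fn = {"PCC": mn.pearson, "SCC": mn.spearman, "KCC": mn.kendall, "CS": mn.cosine}[metric]
    for i in range(4):
        for j in range(4):
            assert cm.values[i, j] == pytest.approx(fn(sig[i], sig[j]), abs=1e-12)


def test_zero_variance_row_fails_loudly(rng):
    sig = rng.standard_normal((3, 20))
    sig[1] = 5.0  # constant ROI
    ts = mn.SubjectTimeSeries("z", sig)
    for metric in ("PCC", "SCC", "KCC"):
        with pytest.raises(MetricUndefinedError) as exc:
            mn.static_bfcn(ts, metric)
        assert exc.value.pair is not None
    with pytest.raises(MetricUndefinedError):
        mn.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(MetricUndefinedError):
        mn.cosine([0.0, 0.0], [1.0, 2.0])


def test_length_mismatch_is_input_error():
    with pytest.raises(InputError):
        mn.pearson([1, 2, 3], [1, 2])


def test_subject_time_series_validation(rng):
    with pytest.raises(InputError):
        mn.SubjectTimeSeries("a", rng.standard_normal((1, 10)))  # too few ROIs
    with pytest.raises(InputError):
        mn.SubjectTimeSeries("b", rng.standard_normal((3, 2)))  # too few volumes
    bad = rng.standard_normal((3, 10))
    bad[0, 0] = np.nan
    with pytest.raises(InputError):
        mn.SubjectTimeSeries("c", bad)
    with pytest.raises(InputError):
        mn.SubjectTimeSeries("d", rng.standard_normal((3, 10)), roi_labels=["r", "r", "x"])


def test_connectivity_matrix_tsv_round_trip(tmp_path, rng):
    ts = mn.SubjectTimeSeries("s9", rng.standard_normal((4, 30)),
                              roi_labels=["A", "B", "C", "D"])
    cm = mn.static_bfcn(ts, "SCC")
    path = tmp_path / "net.tsv"
    cm.save(path)
    back = mn.ConnectivityMatrix.load(path)
    assert back.metric == "SCC"
    assert back.roi_labels == ["A", "B", "C", "D"]
    np.testing.assert_allclose(back.values, cm.values, atol=1e-10)
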