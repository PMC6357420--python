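import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import amap
from amap.errors import DegenerateChannelError


def sse_of_partition(xs, boundaries):
    """SSE of a contiguous partition of sorted xs given split indices."""
    total = 0.0
    edges = [0, *boundaries, len(xs)]
    for a, b in zip(edges[:-1], edges[1:]):
        seg = xs[a:b]
        total += ((seg - seg.mean()) ** 2).sum()
    return total


def brute_force_sse(x, k):
    """Exhaustive enumeration over all contiguous k-partitions of sorted x."""
    xs = np.sort(x)
    best = np.inf
    for bounds in itertools.combinations(range(1, len(xs)), k - 1):
        best = min(best, sse_of_partition(xs, bounds))
    return best


def plain_dp_sse(x, k):
    """O(k n^2) dynamic program trying every split point (no monotonicity)."""
    xs = np.sort(x)
    n = len(xs)
    s1 = np.concatenate(([0.0], np.cumsum(xs)))
    s2 = np.concatenate(([0.0], np.cumsum(xs**2)))

    def cost(j, i):
        cnt = i - j + 1
        s = s1[i + 1] - s1[j]
        return (s2[i + 1] - s2[j]) - s * s / cnt

    D = np.array([cost(0, i) for i in range(n)])
    for m in range(2, k + 1):
        D_new = np.full(n, np.inf)
        for i in range(m - 1, n):
            j = np.arange(m - 1, i + 1)
            D_new[i] = np.min(D[j - 1] + cost(j, i))
        D = D_new
    return float(D[n - 1])


def _env(x, names=("M1",)):
    return amap.EnvelopeRecording(
        envelopes=np.atleast_2d(x), rate_hz=1000.0, channel_names=names
    )


def test_perfectly_separated_two_clusters():
    labels, centers, sse = amap.exact_1d_kmeans([0, 0, 0, 10, 10, 10], k=2)
    np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 1])
    np.testing.assert_allclose(centers, [0.0, 10.0])
    assert sse == pytest.approx(0.0, abs=1e-12)


def test_singleton_clusters_have_zero_sse():
    labels, centers, sse = amap.exact_1d_kmeans([1.0, 2.0, 3.0, 4.0], k=4)
    np.testing.assert_array_equal(labels, [0, 1, 2, 3])
    assert sse == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_matches_full_enumeration_small_n(seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=12)
    for k in (2, 3, 4):
        _, _, sse = amap.exact_1d_kmeans(x, k)
        assert sse == pytest.approx(brute_force_sse(x, k), rel=1e-10, abs=1e-12)


@pytest.mark.parametrize("seed", range(3))
def test_matches_plain_dp_medium_n(seed):
    rng = np.random.default_rng(100 + seed)
    x = np.concatenate([rng.normal(0.05, 0.02, 120), rng.normal(0.7, 0.1, 80)])
    _, _, sse = amap.exact_1d_kmeans(x, 5)
    assert sse == pytest.approx(plain_dp_sse(x, 5), rel=1e-10)


def test_bimodal_envelope_mask_accuracy():
    rng = np.random.default_rng(3)
    n = 5000
    truth = np.zeros(n, dtype=bool)
    for start in range(0, n, 1000):
        truth[start + 300 : start + 700] = True
    x = np.where(truth, rng.normal(0.6, 0.05, n), rng.normal(0.05, 0.01, n))
    x = np.clip(x, 0, None)
    mask = amap.kmeans_onoff(_env(x))
    accuracy = (mask.mask[0] == truth).mean()
    assert accuracy >= 0.95


def test_elevated_baseline_still_off():
    # raised baseline (0.2) must land in the lowest-mean cluster, bursts on
    rng = np.random.default_rng(4)
    n = 5000
    truth = np.zeros(n, dtype=bool)
    for start in range(0, n, 1000):
        truth[start + 300 : start + 700] = True
    x = np.where(truth, rng.normal(0.7, 0.05, n), rng.normal(0.2, 0.01, n))
    mask = amap.kmeans_onoff(_env(x))
    assert (mask.mask[0] == truth).mean() >= 0.95
    assert mask.off_cluster_index[0] == int(np.argmin(mask.cluster_means[0]))


def test_constant_channel_is_degenerate():
    with pytest.raises(DegenerateChannelError, match="M1"):
        amap.kmeans_onoff(_env(np.full(100, 0.3)))
    with pytest.raises(DegenerateChannelError):
        amap.exact_1d_kmeans(np.ones(50), k=5)


def test_sse_monotone_in_k():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 1, 300)
    sses = [amap.exact_1d_kmeans(x, k)[2] for k in (2, 3, 4, 5)]
    assert all(a >= b - 1e-12 for a, b in zip(sses[:-1], sses[1:]))


@settings(max_examples=25, deadline=None)
@given(
    st.lists(st.floats(min_value=0, max_value=10), min_size=8, max_size=60),
    st.integers(min_value=2, max_value=5),
)
def test_labels_monotone_in_value(values, k):
    x = np.asarray(values)
    if np.unique(x).size < k:
        return
    labels, centers, _ = amap.exact_1d_kmeans(x, k)
    order = np.argsort(x, kind="stable")
    assert np.all(np.diff(labels[order]) >= 0)  # contiguity in sorted order
    assert np.all(np.diff(centers) > 0)


def test_mask_equals_midpoint_threshold():
    rng = np.random.default_rng(6)
    x = np.clip(
        np.concatenate([rng.normal(0.05, 0.02, 800), rng.normal(0.6, 0.15, 400)]), 0, None
    )
    mask = amap.kmeans_onoff(_env(x))
    labels, _, _ = amap.exact_1d_kmeans(x, 5)
    off_max = x[labels == 0].max()
    on_min = x[labels > 0].min()
    threshold = (off_max + on_min) / 2.0
    np.testing.assert_array_equal(mask.mask[0], x > threshold)


def test_determinism():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 1, size=(2, 1000))
    m1 = amap.kmeans_onoff(_env(x, names=("A", "B")))
    m2 = amap.kmeans_onoff(_env(x.copy(), names=("A", "B")))
    np.testing.assert_array_equal(m1.mask, m2.mask)
    np.testing.assert_array_equal(m1.cluster_means, m2.cluster_means)


def test_exact_never_worse_than_lloyd():
    rng = np.random.default_rng(9)
    for _ in range(5):
        x = rng.uniform(0, 1, 400)
        _, _, sse_exact = amap.exact_1d_kmeans(x, 5)
        _, _, sse_lloyd = amap.lloyd_1d_kmeans(x, 5, seed=0)
        assert sse_exact <= sse_lloyd + 1e-9


def test_min_duration_postprocessing_is_optional():
    rng = np.random.default_rng(10)
    x = np.clip(rng.normal(0.05, 0.01, 500), 0, None)
    x[100:103] = rng.normal(0.6, 0.05, 3)  # 3 ms blip
    x[300:500] = rng.normal(0.6, 0.05, 200)  # sustained burst
    default = amap.kmeans_onoff(_env(x))
    assert default.mask[0][100:103].all()  # short blip kept by default
    cleaned = amap.kmeans_onoff(_env(x), min_on_s=0.01)
    assert not cleaned.mask[0][100:103].any()
    assert cleaned.mask[0][310:490].all()
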