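"""On/off muscle-activity detection by k-means with five clusters.

Each sample of a muscle's linear envelope (the whole trial pooled) is
assigned to one of k=5 clusters by amplitude; the cluster with the lowest
mean is "off", everything else is "on". Five clusters make the split
robust to elevated baseline activity and to bursts of unequal height:
the baseline — even a raised one — collects in the lowest cluster while
bursts occupy the others.

In one dimension, k-means has a globally optimal solution in which the
clusters are contiguous intervals of the sorted values. We compute it
exactly with a divide-and-conquer dynamic program (O(k n log n), using the
monotonicity of optimal split points), which makes the mask deterministic:
no random initialization, no seed. A Lloyd-type iterative solver (fixed
seed) is kept as a cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateChannelError, DomainError
from .preprocess import EnvelopeRecording

__all__ = ["OnOffMask", "exact_1d_kmeans", "kmeans_onoff", "lloyd_1d_kmeans"]

DEFAULT_K = 5


@dataclass
class OnOffMask:
    """Boolean on/off mask per channel, aligned to envelope samples.

    ``cluster_means[c]`` are the k per-channel cluster means in ascending
    order of cluster index; ``off_cluster_index[c]`` is the index of the
    strictly lowest-mean cluster (ties broken toward the lowest index).
    A sample is "on" iff its cluster is not the off cluster.
    """

    mask: np.ndarray
    channel_names: tuple[str, ...]
    cluster_means: np.ndarray
    off_cluster_index: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=bool))
        self.cluster_means = np.atleast_2d(np.asarray(self.cluster_means, dtype=float))
        self.off_cluster_index = np.atleast_1d(
            np.asarray(self.off_cluster_index, dtype=int)
        )

    def channel(self, name: str) -> np.ndarray:
        return self.mask[self.channel_names.index(name)]


def _prefix_sums(xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.concatenate(([0.0], np.cumsum(xs)))
    s2 = np.concatenate(([0.0], np.cumsum(xs * xs)))
    return s1, s2


def _seg_cost(s1: np.ndarray, s2: np.ndarray, j: np.ndarray, i: int) -> np.ndarray:
    """Within-cluster SSE of sorted slice xs[j..i] inclusive (vectorized in j)."""
    cnt = i - j + 1
    s = s1[i + 1] - s1[j]
    return (s2[i + 1] - s2[j]) - s * s / cnt


def exact_1d_kmeans(values, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally optimal 1-D k-means.

    Returns ``(labels, centers, sse)`` where labels are cluster indices in
    ascending order of cluster mean (label 0 = lowest-mean cluster),
    centers are the k cluster means, and sse is the total within-cluster
    sum of squares. Equal values always receive consistent labels through
    a stable sort, and the result is deterministic.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if np.unique(x).size < k:
        raise DegenerateChannelError(
            f"need at least {k} distinct values, got {np.unique(x).size}"
        )
    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1, s2 = _prefix_sums(xs)

    # D[i] = optimal cost of clustering xs[0..i] with the current number of
    # clusters; opts[m][i] = first index of the last cluster in that optimum.
    i_all = np.arange(n)
    D = (s2[1 : n + 1] - s2[0]) - (s1[1 : n + 1] - s1[0]) ** 2 / (i_all + 1)
    opts = np.zeros((k, n), dtype=int)

    for m in range(2, k + 1):
        D_new = np.empty(n)
        D_new[: m - 1] = np.nan
        opt_row = opts[m - 1]

        # monotone divide-and-conquer over i in [m-1, n-1]
        stack = [(m - 1, n - 1, m - 1, n - 1)]
        while stack:
            lo, hi, jlo, jhi = stack.pop()
            if lo > hi:
                continue
            mid = (lo + hi) // 2
            j = np.arange(jlo, min(jhi, mid) + 1)
            cand = D[j - 1] + _seg_cost(s1, s2, j, mid)
            a = int(np.argmin(cand))
            opt_row[mid] = jlo + a
            D_new[mid] = cand[a]
            stack.append((lo, mid - 1, jlo, jlo + a))
            stack.append((mid + 1, hi, jlo + a, jhi))
        D = D_new

    # backtrack cluster boundaries in sorted order
    labels_sorted = np.empty(n, dtype=int)
    end = n - 1
    for m in range(k, 1, -1):
        j = opts[m - 1][end]
        labels_sorted[j : end + 1] = m - 1
        end = j - 1
    labels_sorted[: end + 1] = 0

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    centers = np.array([x[labels == c].mean() for c in range(k)])
    sse = float(D[n - 1])
    return labels, centers, sse


def lloyd_1d_kmeans(values, k: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Iterative (Lloyd) k-means with a fixed seed, for cross-checking.

    Labels are relabeled in ascending order of cluster mean to match
    :func:`exact_1d_kmeans` conventions. Not guaranteed globally optimal.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if np.unique(x).size < k:
        raise DegenerateChannelError(f"need at least {k} distinct values")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    centers = np.sort(km.cluster_centers_.ravel())
    sse = float(km.inertia_)
    return labels, centers, sse


def kmeans_onoff(
    env: EnvelopeRecording,
    k: int = DEFAULT_K,
    min_on_s: float = 0.0,
    min_off_s: float = 0.0,
) -> OnOffMask:
    """Dichotomize every envelope sample as on/off, per channel.

    Clustering pools all trial samples of a channel. The lowest-mean
    cluster is "off"; all others are "on". Optional ``min_on_s`` /
    ``min_off_s`` remove on-runs / off-gaps shorter than the given
    duration (both default to 0: no post-processing).
    """
    n_ch, n = env.n_channels, env.n_samples
    mask = np.zeros((n_ch, n), dtype=bool)
    means = np.zeros((n_ch, k))
    off_idx = np.zeros(n_ch, dtype=int)
    for c in range(n_ch):
        try:
            labels, centers, _ = exact_1d_kmeans(env.envelopes[c], k)
        except DegenerateChannelError as exc:
            raise DegenerateChannelError(
                f"channel {env.channel_names[c]!r}: {exc}"
            ) from None
        off = int(np.argmin(centers))  # argmin takes the lowest index on ties
        m = labels != off
        if min_off_s > 0:
            m = _fill_short_runs(m, False, int(round(min_off_s * env.rate_hz)))
        if min_on_s > 0:
            m = _fill_short_runs(m, True, int(round(min_on_s * env.rate_hz)))
        mask[c] = m
        means[c] = centers
        off_idx[c] = off
    return OnOffMask(
        mask=mask,
        channel_names=env.channel_names,
        cluster_means=means,
        off_cluster_index=off_idx,
    )


def _fill_short_runs(mask: np.ndarray, value: bool, min_len: int) -> np.ndarray:
    """Flip runs of ``value`` shorter than ``min_len`` samples."""
    if min_len <= 1:
        return mask
    out = mask.copy()
    n = out.size
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if out[i] == value and (j - i) < min_len:
            out[i:j] = not value
        i = j
    return out
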