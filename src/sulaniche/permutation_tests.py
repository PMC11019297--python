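"""Permutation tests for niche width and niche position.

Niche width is the mean Euclidean distance of a group's individuals to
the group centroid in (δ13C, δ15N) space — a dispersion measure of the
variety of resources consumed.  Niche position is the group centroid
itself — the type of resources consumed.  Two groups are compared by:

* **dispersion-difference test** — observed statistic
  ``|MD(a) − MD(b)|`` with MD the mean distance to centroid.  The null
  is location-free: each group is centered on its own centroid, the
  centered residual points are pooled and randomly re-assigned to two
  groups of the original sizes, and the statistic recomputed.
* **centroid-distance test** — observed statistic the Euclidean
  distance between the two group centroids.  The null permutes group
  labels over the pooled raw observations, preserving group sizes.

Both use the standard permutation p-value ``p = (b + 1)/(n_perm + 1)``
with ``b`` the number of null statistics >= the observed one (ties
count toward b), so p is never 0 and the minimum attainable value is
``1/(n_perm + 1)``.  Distances are taken on the raw ‰ axes, weighting
δ13C and δ15N equally.

Internally the pooled points are sorted lexicographically before
permuting, and the smaller group size always indexes the first block,
so results are invariant to input row order and to swapping the two
groups (given the same seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .niche_geometry import InsufficientSampleError, _as_xy

MIN_PERMUTATIONS = 99


@dataclass(frozen=True)
class PermutationTestResult:
    """Observed statistic, permutation-null summary, and p-value."""

    statistic_name: str
    observed: float           # ‰ (Euclidean units in δ-space)
    n_perm: int
    p_value: float
    seed: int | None
    null_quantiles: tuple     # (5%, 50%, 95%) of the permutation null


def mean_distance_to_centroid(group) -> float:
    """Mean Euclidean distance of observations to their own centroid."""
    xy = _as_xy(group)
    if xy.shape[0] == 0:
        raise ValueError("mean distance to centroid of an empty group")
    centroid = xy.mean(axis=0)
    return float(np.linalg.norm(xy - centroid, axis=1).mean())


def _canonical_pool(xy_a: np.ndarray, xy_b: np.ndarray) -> tuple[np.ndarray, int]:
    """Pool two point sets in an order-free canonical arrangement.

    Returns the lexicographically sorted pooled array and the size of
    the smaller group (used as the first split block), which makes the
    permutation scheme exactly invariant to argument order.
    """
    pooled = np.vstack([xy_a, xy_b])
    order = np.lexsort((pooled[:, 1], pooled[:, 0]))
    return pooled[order], min(xy_a.shape[0], xy_b.shape[0])


def _permuted_groups(pooled: np.ndarray, k: int, n_perm: int, rng: np.random.Generator):
    """All n_perm random splits of the pooled points into sizes (k, n−k)."""
    n = pooled.shape[0]
    idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    pts = pooled[idx]                     # (n_perm, n, 2)
    return pts[:, :k, :], pts[:, k:, :]


def _mean_dists(groups: np.ndarray) -> np.ndarray:
    centroids = groups.mean(axis=1, keepdims=True)
    return np.sqrt(((groups - centroids) ** 2).sum(axis=2)).mean(axis=1)


def _validate(xy_a, xy_b, n_perm):
    if xy_a.shape[0] < 3 or xy_b.shape[0] < 3:
        raise InsufficientSampleError(
            f"permutation tests require n >= 3 per group "
            f"(got {xy_a.shape[0]} and {xy_b.shape[0]})"
        )
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS}")


def _finish(name, observed, null, n_perm, seed) -> PermutationTestResult:
    b = int(np.count_nonzero(null >= observed))
    p = (b + 1) / (n_perm + 1)
    q = np.quantile(null, [0.05, 0.50, 0.95])
    return PermutationTestResult(
        statistic_name=name,
        observed=float(observed),
        n_perm=int(n_perm),
        p_value=float(p),
        seed=seed,
        null_quantiles=(float(q[0]), float(q[1]), float(q[2])),
    )


def dispersion_difference_test(a, b, n_perm: int = 9999, seed: int | None = None) -> PermutationTestResult:
    """Test for a difference in niche width between two groups.

    Observed statistic: |MD(a) − MD(b)| with MD the mean distance to
    centroid.  Null: group-centered residuals are pooled and randomly
    re-assigned to groups of the original sizes.  Deterministic given
    ``seed``.
    """
    xy_a, xy_b = _as_xy(a), _as_xy(b)
    _validate(xy_a, xy_b, n_perm)
    observed = abs(mean_distance_to_centroid(xy_a) - mean_distance_to_centroid(xy_b))
    resid_a = xy_a - xy_a.mean(axis=0)
    resid_b = xy_b - xy_b.mean(axis=0)
    pooled, k = _canonical_pool(resid_a, resid_b)
    rng = np.random.default_rng(seed)
    ga, gb = _permuted_groups(pooled, k, n_perm, rng)
    null = np.abs(_mean_dists(ga) - _mean_dists(gb))
    return _finish("dispersion_difference", observed, null, n_perm, seed)


def centroid_distance_test(a, b, n_perm: int = 9999, seed: int | None = None) -> PermutationTestResult:
    """Test for a difference in niche position between two groups.

    Observed statistic: Euclidean distance between the group centroids
    in (δ13C, δ15N) space.  Null: group labels permuted over the pooled
    raw observations, preserving group sizes.  Deterministic given
    ``seed``.
    """
    xy_a, xy_b = _as_xy(a), _as_xy(b)
    _validate(xy_a, xy_b, n_perm)
    observed = float(np.linalg.norm(xy_a.mean(axis=0) - xy_b.mean(axis=0)))
    pooled, k = _canonical_pool(xy_a, xy_b)
    rng = np.random.default_rng(seed)
    ga, gb = _permuted_groups(pooled, k, n_perm, rng)
    null = np.linalg.norm(ga.mean(axis=1) - gb.mean(axis=1), axis=1)
    return _finish("centroid_distance", observed, null, n_perm, seed)
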