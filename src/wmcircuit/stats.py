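"""Group-level inference on representation maps.

Cluster-based permutation testing for paired time x time map comparisons
(pointwise paired t, 4-connected suprathreshold clusters, sign-flip
max-null) and plain paired t-tests for scalar summaries. The permutation
null flips each participant's condition difference; for n <= 12
participants all 2^n sign assignments are enumerated, otherwise random
draws are used. Positive and negative exceedances are clustered
separately and each observed cluster mass is compared with the
permutation distribution of the maximum absolute cluster mass, which
controls the family-wise error over the whole map. p-values use +1
smoothing, (b + 1) / (m + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .datatypes import ValidationError

__all__ = ["ClusterResult", "cluster_permutation_paired", "paired_t"]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class ClusterResult:
    """Suprathreshold clusters of a paired map comparison."""

    t_map: np.ndarray
    threshold: float
    cluster_labels: np.ndarray      # 0 = background, 1..n clusters
    cluster_stats: np.ndarray       # signed sum of t per cluster
    cluster_p: np.ndarray
    n_permutations: int
    p_pointwise: float
    enumerated: bool

    @property
    def significant_mask(self) -> np.ndarray:
        """Union of clusters with p < 0.05."""
        mask = np.zeros_like(self.cluster_labels, dtype=bool)
        for i, p in enumerate(self.cluster_p, start=1):
            if p < 0.05:
                mask |= self.cluster_labels == i
        return mask


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, int, float]:
    """Paired two-sided t-test; returns (t, df, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need two equal-length 1-D arrays with n >= 2")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValidationError("missing values not allowed")
    d = a - b
    if np.all(d == 0):
        # identical conditions: no evidence either way
        return 0.0, a.size - 1, 1.0
    if np.std(d, ddof=1) == 0:
        raise ValidationError("zero-variance differences: t undefined")
    res = sstats.ttest_rel(a, b)
    return float(res.statistic), a.size - 1, float(res.pvalue)


def _t_maps(diffs_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t statistic maps for many sign assignments at once.

    ``diffs_flat``: (n_subj, n_px); ``signs``: (n_perm, n_subj) of +-1.
    Squares are sign-invariant, so only the mean changes per permutation.
    """
    n = diffs_flat.shape[0]
    mean = signs @ diffs_flat / n
    sum_sq = (diffs_flat ** 2).sum(axis=0)
    var = (sum_sq - n * mean ** 2) / (n - 1)
    var = np.maximum(var, np.finfo(float).tiny)
    return mean / np.sqrt(var / n)


def _max_cluster_mass(t_map: np.ndarray, threshold: float) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        labels, n = ndimage.label(sign * t_map > threshold, structure=FOUR_CONNECTED)
        if n:
            sums = ndimage.sum_labels(np.abs(t_map), labels, index=np.arange(1, n + 1))
            best = max(best, float(np.max(sums)))
    return best


def cluster_permutation_paired(maps_a: np.ndarray, maps_b: np.ndarray,
                               n_perm: int = 1000, p_point: float = 0.05,
                               seed: int | np.random.Generator = 0,
                               enumerate_max: int = 12) -> ClusterResult:
    """Two-sided cluster-based permutation test of paired map conditions.

    ``maps_a``/``maps_b``: (n_participants, H, W), one map per participant
    per condition. All 2^n sign flips are enumerated for
    ``n <= enumerate_max`` participants; otherwise ``n_perm`` random
    draws are used (set ``enumerate_max=0`` to force Monte Carlo).
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValidationError("need matched (n_participants, H, W) map stacks")
    n = a.shape[0]
    if n < 5:
        raise ValidationError("cluster permutation needs >= 5 participants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = a - b
    shape = diffs.shape[1:]
    flat = diffs.reshape(n, -1)
    threshold = float(sstats.t.ppf(1 - p_point / 2, df=n - 1))

    t_obs = _t_maps(flat, np.ones((1, n)))[0].reshape(shape)

    # observed clusters: positive and negative exceedances separately
    labels_all = np.zeros(shape, dtype=int)
    stats: list[float] = []
    for sign in (1.0, -1.0):
        labels, k = ndimage.label(sign * t_obs > threshold, structure=FOUR_CONNECTED)
        for i in range(1, k + 1):
            mask = labels == i
            labels_all[mask] = len(stats) + 1
            stats.append(float(t_obs[mask].sum()))
    cluster_stats = np.array(stats)

    enumerated = n <= enumerate_max
    if enumerated:
        m = 2 ** n
        signs = np.array(
            [[1.0 if (i >> j) & 1 else -1.0 for j in range(n)] for i in range(m)]
        )
    else:
        m = n_perm
        signs = rng.choice([-1.0, 1.0], size=(m, n))

    null_max = np.empty(m)
    chunk = 256
    for start in range(0, m, chunk):
        t_perm = _t_maps(flat, signs[start:start + chunk])
        for r, row in enumerate(t_perm):
            null_max[start + r] = _max_cluster_mass(row.reshape(shape), threshold)

    cluster_p = np.array([
        (np.sum(null_max >= abs(s)) + 1) / (m + 1) for s in cluster_stats
    ])
    return ClusterResult(
        t_map=t_obs,
        threshold=threshold,
        cluster_labels=labels_all,
        cluster_stats=cluster_stats,
        cluster_p=cluster_p,
        n_permutations=m,
        p_pointwise=p_point,
        enumerated=enumerated,
    )
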