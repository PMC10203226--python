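"""Representational dissimilarity (EED) and encoding-maintenance
similarity (EMS) maps from z-scored spectral power.

Features are the z-scored 1-40 Hz power of all channels of a region,
averaged within 100 ms sliding windows (10 ms step) and vectorized
channel-major. For two feature vectors the Spearman rank correlation is
Fisher z-transformed; EED subtracts it from 1 (dissimilarity), EMS keeps
it (similarity). Averaging over trial pairs (EED, encoding x encoding
windows) or trials (EMS, encoding x maintenance windows) yields the
time x time representation maps.

The pairwise map computation is vectorized: Spearman correlation equals
the Pearson correlation of ranks, so per trial the windowed features are
rank-transformed and standardized once and all window pairs reduce to one
matrix product per trial pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from .datatypes import PERIODS, PowerTensor, ValidationError

__all__ = [
    "WindowGrid",
    "RepresentationMap",
    "make_window_grid",
    "slice_period",
    "window_features",
    "feature_matrix",
    "pair_dissimilarity",
    "eed_map",
    "ems_map",
    "eed_maps_per_pair",
    "ems_maps_per_trial",
    "sample_trial_pairs",
]

RHO_CLIP = 1.0 - 1e-10

#: Period onsets within the padded full-trial window, seconds from fixation onset.
PERIOD_ONSET_S = {
    "fixation": 0.0,
    "encoding": PERIODS["fixation"],
    "maintenance": PERIODS["fixation"] + PERIODS["encoding"],
    "retrieval": PERIODS["fixation"] + PERIODS["encoding"] + PERIODS["maintenance"],
}


@dataclass
class WindowGrid:
    """Regular sliding-window grid over one task period."""

    centers_s: np.ndarray
    width_s: float
    step_s: float
    period: str

    @property
    def n_windows(self) -> int:
        return self.centers_s.size


@dataclass
class RepresentationMap:
    """Time x time map of averaged dissimilarity (EED) or similarity (EMS)."""

    values: np.ndarray
    kind: str  # "EED" | "EMS"
    region: str
    grid_row: WindowGrid
    grid_col: WindowGrid
    n_units: int  # trial pairs (EED) or trials (EMS) averaged
    session: str | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("representation map contains non-finite entries")
        if self.values.shape != (self.grid_row.n_windows, self.grid_col.n_windows):
            raise ValidationError("map shape does not match its window grids")


def make_window_grid(period_start_s: float, period_end_s: float,
                     width_s: float = 0.100, step_s: float = 0.010,
                     period: str = "encoding") -> WindowGrid:
    """Window centers at ``start, start+step, ..., end`` inclusive.

    A 2 s encoding period at the default 10 ms step gives 201 windows and
    the 3 s maintenance period gives 301; edge windows are truncated to
    the available samples.
    """
    if step_s <= 0:
        raise ValidationError("step_s must be positive")
    if period_end_s <= period_start_s:
        raise ValidationError("period_end_s must exceed period_start_s")
    n = int(round((period_end_s - period_start_s) / step_s)) + 1
    centers = period_start_s + step_s * np.arange(n)
    return WindowGrid(centers_s=centers, width_s=width_s, step_s=step_s, period=period)


def slice_period(power: PowerTensor, period: str) -> PowerTensor:
    """Re-express a full-trial power tensor relative to a period onset.

    The tensor keeps all trial samples so that edge windows of the period
    grid can draw on immediately adjacent data.
    """
    if period not in PERIOD_ONSET_S:
        raise ValidationError(f"unknown period {period!r}")
    out = power.slice_time(power.time_s[0], power.time_s[-1] + 1.0 / power.rate_hz,
                           new_origin=False)
    out.time_s = out.time_s - PERIOD_ONSET_S[period]
    return out


def _window_slice(time_s: np.ndarray, center_s: float, width_s: float) -> np.ndarray:
    half = width_s / 2.0
    sel = (time_s >= center_s - half - 1e-9) & (time_s <= center_s + half + 1e-9)
    return np.flatnonzero(sel)


def window_features(power: PowerTensor, center_s: float, width_s: float = 0.100,
                    fmax_hz: float = 40.0) -> np.ndarray:
    """Per-trial feature vectors for one sliding window.

    z-scored power is averaged over the window's time points, then the
    (channel x frequency) block is vectorized channel-major; length is
    ``n_channels * n_freqs``.
    """
    if not power.zscored:
        raise ValidationError("window features require z-scored power")
    sub = power.select_freqs(1.0, fmax_hz)
    idx = _window_slice(sub.time_s, center_s, width_s)
    if idx.size == 0:
        raise ValidationError(f"window at {center_s} s lies outside the epoch")
    block = sub.values[..., idx].mean(axis=-1)  # (trial, ch, f)
    return block.reshape(block.shape[0], -1)


def feature_matrix(power: PowerTensor, grid: WindowGrid,
                   fmax_hz: float = 40.0) -> np.ndarray:
    """Stacked window features, shape ``(n_trials, n_windows, n_features)``."""
    if not power.zscored:
        raise ValidationError("feature matrix requires z-scored power")
    sub = power.select_freqs(1.0, fmax_hz)
    n_tr, n_ch, n_f, _ = sub.values.shape
    out = np.empty((n_tr, grid.n_windows, n_ch * n_f))
    for w, c in enumerate(grid.centers_s):
        idx = _window_slice(sub.time_s, float(c), grid.width_s)
        if idx.size == 0:
            raise ValidationError(f"window at {c} s lies outside the epoch")
        out[:, w] = sub.values[..., idx].mean(axis=-1).reshape(n_tr, -1)
    return out


def _fisher_z(rho: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(rho, -RHO_CLIP, RHO_CLIP))


def pair_dissimilarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """1 minus the Fisher-z-transformed Spearman correlation of two vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1 or v1.size < 3:
        raise ValidationError("need two equal-length 1-D vectors of length >= 3")
    r1 = rankdata(v1)
    r2 = rankdata(v2)
    if r1.std() == 0 or r2.std() == 0:
        raise ValidationError("zero-variance vector: Spearman correlation undefined")
    rho = np.corrcoef(r1, r2)[0, 1]
    return float(1.0 - _fisher_z(rho))


def _rank_standardize(feats: np.ndarray) -> np.ndarray:
    """Rank along the feature axis, center, scale to unit norm.

    After this, ``R_i @ R_j.T`` is the matrix of Spearman correlations
    between all window pairs of trials i and j.
    """
    ranks = rankdata(feats, axis=-1)
    ranks = ranks - ranks.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValidationError("zero-variance feature vector in window features")
    return ranks / norms


def _all_pairs(n: int) -> np.ndarray:
    return np.array(list(combinations(range(n), 2)), dtype=int)


def sample_trial_pairs(n_trials: int, k: int = 100,
                       seed: int | np.random.Generator = 0) -> tuple[np.ndarray, bool]:
    """Sample ``k`` unordered trial pairs.

    Pairs are drawn uniformly without replacement from all C(n, 2)
    pairs; if fewer than ``k`` exist, sampling is with replacement and the
    returned flag is True.
    """
    if n_trials < 2:
        raise ValidationError("need >= 2 trials to form pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = _all_pairs(n_trials)
    if pairs.shape[0] >= k:
        idx = rng.choice(pairs.shape[0], size=k, replace=False)
        return pairs[idx], False
    idx = rng.choice(pairs.shape[0], size=k, replace=True)
    return pairs[idx], True


def eed_maps_per_pair(power: PowerTensor, grid: WindowGrid,
                      pairs: np.ndarray | None = None,
                      fmax_hz: float = 40.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial-pair EED maps, shape ``(n_pairs, n_w, n_w)``.

    Each map entry (w1, w2) is ``1 - atanh(spearman)`` between trial i's
    window-w1 features and trial j's window-w2 features, symmetrized over
    the two orderings of the unordered pair.
    """
    feats = feature_matrix(power, grid, fmax_hz)
    n_tr = feats.shape[0]
    if pairs is None:
        pairs = _all_pairs(n_tr)
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        raise ValidationError("no trial pairs to average")
    R = _rank_standardize(feats)
    maps = np.empty((pairs.shape[0], grid.n_windows, grid.n_windows))
    for p, (i, j) in enumerate(pairs):
        z = _fisher_z(R[i] @ R[j].T)
        maps[p] = 1.0 - 0.5 * (z + z.T)
    return maps, pairs


def eed_map(power: PowerTensor, grid: WindowGrid,
            pairs: np.ndarray | None = None, region: str = "",
            fmax_hz: float = 40.0) -> RepresentationMap:
    """Encoding-encoding dissimilarity map averaged over trial pairs."""
    maps, pairs = eed_maps_per_pair(power, grid, pairs, fmax_hz)
    return RepresentationMap(
        values=maps.mean(axis=0), kind="EED", region=region,
        grid_row=grid, grid_col=grid, n_units=maps.shape[0],
    )


def ems_maps_per_trial(power_enc: PowerTensor, power_maint: PowerTensor,
                       grid_enc: WindowGrid, grid_maint: WindowGrid,
                       fmax_hz: float = 40.0) -> np.ndarray:
    """Per-trial EMS maps, shape ``(n_trials, n_w_enc, n_w_maint)``."""
    if power_enc.trial_ids.shape != power_maint.trial_ids.shape or np.any(
            power_enc.trial_ids != power_maint.trial_ids):
        raise ValidationError("encoding and maintenance tensors hold different trials")
    Re = _rank_standardize(feature_matrix(power_enc, grid_enc, fmax_hz))
    Rm = _rank_standardize(feature_matrix(power_maint, grid_maint, fmax_hz))
    n_tr = Re.shape[0]
    maps = np.empty((n_tr, grid_enc.n_windows, grid_maint.n_windows))
    for t in range(n_tr):
        maps[t] = _fisher_z(Re[t] @ Rm[t].T)
    return maps


def ems_map(power_enc: PowerTensor, power_maint: PowerTensor,
            grid_enc: WindowGrid, grid_maint: WindowGrid, region: str = "",
            fmax_hz: float = 40.0, as_dissimilarity: bool = False) -> RepresentationMap:
    """Encoding-maintenance similarity map averaged over trials."""
    maps = ems_maps_per_trial(power_enc, power_maint, grid_enc, grid_maint, fmax_hz)
    values = maps.mean(axis=0)
    if as_dissimilarity:
        values = 1.0 - values
    return RepresentationMap(
        values=values, kind="EMS", region=region,
        grid_row=grid_enc, grid_col=grid_maint, n_units=maps.shape[0],
    )
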