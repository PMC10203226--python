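"""Morlet time-frequency decomposition and bootstrap baseline z-scoring.

Power is obtained by convolving each epoch with complex Morlet wavelets
(6 cycles by default) on an integer frequency grid, at the native sample
resolution. Task power is then normalized per channel and frequency
against a bootstrap null of the pre-trial baseline: the null is the
distribution of means of ``m`` baseline power samples drawn with
replacement (1000 replicates), and every task time point is z-scored
against its mean and standard deviation.

The feature band handed to the representational analyses is the z-scored
power at 1-40 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .datatypes import BASELINE_S, EpochSet, PowerTensor, ValidationError

__all__ = ["BaselineNull", "morlet_power", "bootstrap_baseline_null", "zscore_power"]

DEFAULT_FREQS = np.arange(1.0, 101.0)


class DegenerateBaselineError(ValidationError):
    """Baseline power has zero variance; the z-score is undefined."""


@dataclass
class BaselineNull:
    """Bootstrap null of the baseline mean, per channel x frequency."""

    mean: np.ndarray  # (ch, freq) or (trial, ch, freq) when per-trial
    std: np.ndarray
    n_boot: int
    m: int
    per_trial: bool
    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.std <= 0):
            raise DegenerateBaselineError(
                "baseline power is (near-)constant; z-scoring undefined"
            )


def morlet_power(es: EpochSet, freqs_hz: np.ndarray | None = None,
                 n_cycles: float = 6.0) -> PowerTensor:
    """Squared-magnitude Morlet wavelet transform of an epoch set.

    Time resolution equals the sample grid. Samples within one wavelet
    half-width of the epoch edges are flagged in ``edge_mask`` (the
    transform is still computed there).
    """
    freqs = DEFAULT_FREQS if freqs_hz is None else np.asarray(freqs_hz, dtype=float)
    if np.any(freqs >= es.rate_hz / 2):
        raise ValidationError(
            f"frequencies up to {freqs.max()} Hz exceed Nyquist {es.rate_hz / 2} Hz"
        )
    n_t = es.data.shape[2]
    # the wavelet support is +-5 sigma_t; zero-pad epochs shorter than the
    # longest wavelet (low frequencies), then crop back — padded-edge
    # estimates fall inside the flagged edge region
    sigma_t = n_cycles / (2.0 * np.pi * freqs.min())
    wavelet_len = 2 * int(np.ceil(5.0 * sigma_t * es.rate_hz)) - 1
    pad = max(0, (wavelet_len - n_t) // 2 + 1)
    data = np.pad(es.data, ((0, 0), (0, 0), (pad, pad))) if pad else es.data
    power = tfr_array_morlet(
        data, sfreq=es.rate_hz, freqs=freqs, n_cycles=n_cycles,
        output="power", zero_mean=False, verbose="error",
    )
    if pad:
        power = power[..., pad:pad + n_t]
    half_width_s = n_cycles / (2.0 * freqs)
    times = es.times_s
    edge = (times[None, :] < times[0] + half_width_s[:, None]) | (
        times[None, :] > times[-1] - half_width_s[:, None]
    )
    return PowerTensor(
        values=power,
        freqs_hz=freqs,
        time_s=times,
        rate_hz=es.rate_hz,
        trial_ids=es.trial_ids,
        channel_names=list(es.channel_names),
        channel_region=dict(es.channel_region),
        zscored=False,
        edge_mask=edge,
    )


def bootstrap_baseline_null(power: PowerTensor,
                            baseline: tuple[float, float] = (-BASELINE_S, 0.0),
                            n_boot: int = 1000, m: int | None = None,
                            seed: int | np.random.Generator = 0,
                            per_trial: bool = False,
                            kept_mask: np.ndarray | None = None) -> BaselineNull:
    """Bootstrap the baseline-mean null per channel and frequency.

    Each of ``n_boot`` replicates is the mean of ``m`` power samples drawn
    with replacement from the baseline time points (default: pooled across
    all kept trials; ``per_trial=True`` restricts the pool to each trial's
    own baseline). ``m`` defaults to the number of baseline samples of one
    trial.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b0, b1 = baseline
    sel = (power.time_s >= b0 - 1e-9) & (power.time_s < b1 - 1e-9)
    if not sel.any():
        raise ValidationError(f"no baseline samples in [{b0}, {b1}) s")
    vals = power.values[..., sel]  # (trial, ch, freq, n_bl)
    if kept_mask is not None:
        vals = vals[np.asarray(kept_mask, dtype=bool)]
    n_tr, n_ch, n_f, n_bl = vals.shape
    if m is None:
        m = n_bl
    if per_trial:
        means = np.empty((n_tr, n_boot, n_ch, n_f))
        for t in range(n_tr):
            pool = vals[t].reshape(n_ch * n_f, n_bl).T  # (n_bl, ch*f)
            for b in range(n_boot):
                idx = rng.integers(0, n_bl, size=m)
                counts = np.bincount(idx, minlength=n_bl).astype(float)
                means[t, b] = (counts @ pool).reshape(n_ch, n_f) / m
        mean = means.mean(axis=1)
        std = means.std(axis=1, ddof=1)
    else:
        pool = np.moveaxis(vals, (1, 2), (2, 3)).reshape(n_tr * n_bl, n_ch * n_f)
        n_pool = pool.shape[0]
        means = np.empty((n_boot, n_ch * n_f))
        for b in range(n_boot):
            idx = rng.integers(0, n_pool, size=m)
            counts = np.bincount(idx, minlength=n_pool).astype(float)
            means[b] = counts @ pool / m
        mean = means.mean(axis=0).reshape(n_ch, n_f)
        std = means.std(axis=0, ddof=1).reshape(n_ch, n_f)
    return BaselineNull(mean=mean, std=std, n_boot=n_boot, m=m,
                        per_trial=per_trial, freqs_hz=power.freqs_hz.copy())


def zscore_power(power: PowerTensor, null: BaselineNull) -> PowerTensor:
    """z-score every task time point against the baseline bootstrap null."""
    if null.freqs_hz.shape != power.freqs_hz.shape or np.any(null.freqs_hz != power.freqs_hz):
        raise ValidationError("frequency axes of power and null do not match")
    if null.per_trial:
        if null.mean.shape[:2] != power.values.shape[:2]:
            raise ValidationError("trial/channel axes of power and null do not match")
        mean = null.mean[..., None]
        std = null.std[..., None]
    else:
        if null.mean.shape != power.values.shape[1:3]:
            raise ValidationError("channel/frequency axes of power and null do not match")
        mean = null.mean[None, :, :, None]
        std = null.std[None, :, :, None]
    z = (power.values - mean) / std
    return PowerTensor(
        values=z,
        freqs_hz=power.freqs_hz,
        time_s=power.time_s,
        rate_hz=power.rate_hz,
        trial_ids=power.trial_ids,
        channel_names=list(power.channel_names),
        channel_region=dict(power.channel_region),
        zscored=True,
        baseline_window=(-BASELINE_S, 0.0),
        edge_mask=power.edge_mask,
    )
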