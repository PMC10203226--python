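"""Signal conditioning: filtering, line-noise removal, resampling,
common-average re-referencing, epoching and trial selection.

The chain mirrors standard intracranial-EEG practice: band-pass FIR
(Hamming window, zero phase), DFT-based line-noise subtraction, polyphase
anti-aliased downsampling, re-referencing to the mean of the clean
channels, then segmentation into the fixed task periods. A reproducible
amplitude-based artifact rule (k x MAD) stands in for manual trial review.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import (
    BASELINE_S,
    EpochSet,
    PERIODS,
    Recording,
    TRIAL_DURATION_S,
    ValidationError,
)

__all__ = [
    "bandpass_fir",
    "remove_line_noise",
    "downsample",
    "rereference_common_average",
    "epoch",
    "select_trials",
    "reject_artifact_trials",
]


def _fir_taps(low_hz: float, high_hz: float, rate_hz: float) -> np.ndarray:
    # transition bandwidth 25% of each cutoff; Hamming main-lobe factor 3.3
    trans = 0.25 * min(low_hz, rate_hz / 2 - high_hz if high_hz < rate_hz / 2 else low_hz)
    trans = max(trans, 0.25 * low_hz)
    numtaps = int(np.ceil(3.3 * rate_hz / trans))
    numtaps += 1 - numtaps % 2  # odd length -> symmetric type-I filter
    return sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                      window="hamming", fs=rate_hz)


def bandpass_fir(rec: Recording, low_hz: float, high_hz: float) -> Recording:
    """Zero-phase Hamming-window FIR band-pass.

    The filter is an odd-length linear-phase FIR applied by FFT convolution
    with its group delay compensated, which is exactly zero-phase. The
    order follows from a transition bandwidth of 25% of the low cutoff.
    """
    if not (0 < low_hz < high_hz):
        raise ValidationError("need 0 < low_hz < high_hz")
    if high_hz >= rec.rate_hz / 2:
        raise ValidationError(
            f"high_hz={high_hz} must be below Nyquist {rec.rate_hz / 2}"
        )
    taps = _fir_taps(low_hz, high_hz, rec.rate_hz)
    half = len(taps) // 2
    padded = np.pad(rec.samples, ((0, 0), (half, half)), mode="reflect")
    out = sps.fftconvolve(padded, taps[None, :], mode="same", axes=1)
    return rec.copy_with(out[:, half:-half])


def remove_line_noise(rec: Recording, freqs_hz: list[float] | None = None) -> Recording:
    """Subtract mains components by least-squares sine/cosine fit (DFT filter).

    For each target frequency the complex amplitude is estimated over the
    whole recording (single window) per channel and the fitted sinusoid is
    subtracted, which nulls the target bin while leaving neighboring
    frequencies essentially untouched.
    """
    if freqs_hz is None:
        freqs_hz = [50.0, 100.0, 150.0]
    x = rec.samples.copy()
    n = x.shape[1]
    t = np.arange(n) / rec.rate_hz
    for f in freqs_hz:
        if f >= rec.rate_hz / 2:
            raise ValidationError(f"line frequency {f} above Nyquist")
        basis = np.stack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)], axis=1)
        coef, *_ = np.linalg.lstsq(basis, x.T, rcond=None)
        x -= (basis @ coef).T
    return rec.copy_with(x)


def downsample(rec: Recording, target_hz: float) -> Recording:
    """Polyphase anti-aliased resampling to ``target_hz``."""
    if target_hz > rec.rate_hz:
        raise ValidationError("target_hz must not exceed the current rate")
    if target_hz == rec.rate_hz:
        return rec.copy_with(rec.samples.copy())
    from fractions import Fraction

    frac = Fraction(target_hz / rec.rate_hz).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(out, rate_hz=rec.rate_hz * frac.numerator / frac.denominator)


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the mean over clean channels from every channel."""
    clean = rec.channel_clean
    if clean.sum() < 2:
        raise ValidationError("common average reference needs >= 2 clean channels")
    avg = rec.samples[clean].mean(axis=0, keepdims=True)
    return rec.copy_with(rec.samples - avg)


def epoch(rec: Recording, tt: pd.DataFrame,
          baseline_s: float = BASELINE_S) -> dict[str, EpochSet]:
    """Segment the recording into the four task periods plus a padded
    full-trial window (``"trial"``: baseline through retrieval) used for
    time-frequency analysis.

    Trials whose window falls outside the recording are flagged in
    ``kept_mask`` rather than silently dropped.
    """
    rate = rec.rate_hz
    out: dict[str, EpochSet] = {}
    onset_col = {
        "fixation": "t_fixation",
        "encoding": "t_encoding",
        "maintenance": "t_maintenance",
        "retrieval": "t_probe",
    }
    windows = {p: (0.0, PERIODS[p]) for p in PERIODS}
    windows["trial"] = (-baseline_s, TRIAL_DURATION_S)
    for label, (t0, t_end) in windows.items():
        col = onset_col.get(label, "t_fixation")
        n_win = int(round((t_end - t0) * rate))
        n_tr = len(tt)
        data = np.zeros((n_tr, rec.n_channels, n_win))
        kept = np.ones(n_tr, dtype=bool)
        for i in range(n_tr):
            i0 = int(round((float(tt[col].iloc[i]) + t0) * rate))
            if i0 < 0 or i0 + n_win > rec.n_samples:
                kept[i] = False
                continue
            data[i] = rec.samples[:, i0:i0 + n_win]
        out[label] = EpochSet(
            data=data,
            window_label=label,
            t0_s=t0,
            rate_hz=rate,
            trial_ids=tt["trial_id"].to_numpy(),
            kept_mask=kept,
            channel_names=list(rec.channel_names),
            channel_region=dict(rec.channel_region),
        )
    return out


def select_trials(es: EpochSet, tt: pd.DataFrame, correct_only: bool = True,
                  loads: set[int] | None = None) -> EpochSet:
    """Filter an epoch set to correct trials and/or a load subset."""
    if loads is not None and len(loads) == 0:
        raise ValidationError("loads must be a non-empty set (or None for all)")
    tt_idx = tt.set_index("trial_id")
    keep = es.kept_mask.copy()
    for i, tid in enumerate(es.trial_ids):
        row = tt_idx.loc[int(tid)]
        if correct_only and not bool(row["correct"]):
            keep[i] = False
        if loads is not None and int(row["load"]) not in loads:
            keep[i] = False
    if not keep.any():
        raise ValidationError("trial selection left an empty epoch set")
    idx = np.flatnonzero(keep)
    return EpochSet(
        data=es.data[idx],
        window_label=es.window_label,
        t0_s=es.t0_s,
        rate_hz=es.rate_hz,
        trial_ids=es.trial_ids[idx],
        kept_mask=np.ones(idx.size, dtype=bool),
        channel_names=list(es.channel_names),
        channel_region=dict(es.channel_region),
    )


def reject_artifact_trials(es: EpochSet, k_mad: float = 8.0,
                           external_mask: np.ndarray | None = None) -> EpochSet:
    """Amplitude-based surrogate for manual artifact review.

    A trial is flagged when any channel's peak absolute amplitude exceeds
    ``k_mad`` times that channel's median absolute deviation across the
    epoch set. An externally supplied boolean keep-mask may be AND-ed in.
    """
    mad = np.median(np.abs(es.data - np.median(es.data, axis=(0, 2), keepdims=True)),
                    axis=(0, 2))
    peak = np.abs(es.data).max(axis=2)  # (trial, ch)
    keep = es.kept_mask & ~(peak > k_mad * mad[None, :] * 1.4826).any(axis=1)
    if external_mask is not None:
        keep &= np.asarray(external_mask, dtype=bool)
    out = EpochSet(
        data=es.data,
        window_label=es.window_label,
        t0_s=es.t0_s,
        rate_hz=es.rate_hz,
        trial_ids=es.trial_ids,
        kept_mask=keep,
        channel_names=list(es.channel_names),
        channel_region=dict(es.channel_region),
    )
    return out
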