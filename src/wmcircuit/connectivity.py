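"""Phase slope index (PSI) directional connectivity with trial-shuffle nulls.

Per-trial segments of two channels are Hann-tapered, zero-padded so that
the DFT grid contains the integer frequencies 1-40 Hz exactly, and
averaged into cross- and auto-spectra; the complex coherency is

    C(f) = S_ab(f) / sqrt(S_aa(f) * S_bb(f)).

The PSI at a center frequency aggregates the phase slope over adjacent
1 Hz bins,

    psi(c) = Im( sum_{f in band} conj(C(f)) * C(f + df) ),   df = 1 Hz,

with band ``[c - h, c + h - df]``. A positive value means the first
signal leads the second; by convention the first signal is the
hippocampal channel, so at the population level z > 1.96 is read as
"hippocampus leads" and z < -1.96 as "amygdala leads".

The null distribution permutes the trial pairing between the two
channels (200 shuffles), which destroys trial-locked coupling while
preserving each channel's spectra; raw PSI and null replicates are
averaged over channel pairs (and sessions) before z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import EpochSet, ValidationError

__all__ = [
    "PSIResult",
    "cross_spectra",
    "coherency_from_ffts",
    "psi_spectrum",
    "psi",
    "psi_null",
    "psi_with_null",
    "region_pair_psi",
    "psi_zscore",
]

Z_CRIT = 1.96
DEFAULT_FMAX = 40


@dataclass
class PSIResult:
    """Population-level PSI with its trial-shuffle null."""

    freqs_hz: np.ndarray
    psi_raw: np.ndarray        # (n_pairs, n_freqs) raw PSI per channel pair
    null: np.ndarray           # (n_pairs, n_shuffles, n_freqs)
    z: np.ndarray              # (n_freqs,) population z-score
    direction: list[str]       # per frequency: HIP_leads | AMY_leads | none
    band_halfwidth_hz: float
    truncated: np.ndarray      # per frequency: band clipped at the range edge

    def significant(self, which: str) -> np.ndarray:
        """Boolean mask of frequencies with significant lead for a region."""
        if which == "HIP_leads":
            return self.z > Z_CRIT
        if which == "AMY_leads":
            return self.z < -Z_CRIT
        raise ValidationError(f"unknown direction {which!r}")


def _pad_length(n_samples: int, rate_hz: float) -> int:
    """Smallest multiple of the sampling rate >= 2x the segment length.

    This puts every integer frequency exactly on the DFT grid (bin spacing
    1/k Hz) while at least doubling the segment, as zero-padding for
    spectral interpolation requires.
    """
    rate = int(round(rate_hz))
    if abs(rate - rate_hz) > 1e-9:
        raise ValidationError("PSI requires an integer sampling rate in Hz")
    k = int(np.ceil(2 * n_samples / rate))
    return k * rate


def _segment_ffts(seg: np.ndarray, rate_hz: float,
                  fmax_hz: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered, zero-padded per-trial FFT at integer frequencies 1..fmax."""
    seg = np.asarray(seg, dtype=float)
    if seg.ndim != 2:
        raise ValidationError("segments must be (n_trials, n_samples)")
    n_tr, n_s = seg.shape
    taper = np.hanning(n_s)
    nfft = _pad_length(n_s, rate_hz)
    spec = np.fft.rfft(seg * taper[None, :], n=nfft, axis=1)
    bins_per_hz = nfft // int(round(rate_hz))
    freqs = np.arange(1, fmax_hz + 1)
    return spec[:, freqs * bins_per_hz], freqs.astype(float)


def _cross_mean(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Trial-averaged cross-spectrum ``mean(fa * conj(fb))``.

    Real and imaginary parts are computed with explicit real arithmetic so
    that the algebraic identities hold exactly in floating point:
    ``fa == fb`` gives an exactly real result, and swapping the arguments
    conjugates it exactly (fused-multiply-add in the complex product
    would break both).
    """
    re = (fa.real * fb.real + fa.imag * fb.imag).mean(axis=0)
    im = (fa.imag * fb.real - fa.real * fb.imag).mean(axis=0)
    return re + 1j * im


def coherency_from_ffts(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Complex coherency from per-trial spectra (trials averaged)."""
    s_ab = _cross_mean(fa, fb)
    s_aa = _cross_mean(fa, fa).real
    s_bb = _cross_mean(fb, fb).real
    denom = np.sqrt(s_aa * s_bb)
    if np.any(denom == 0):
        raise ValidationError("zero auto-spectrum; coherency undefined")
    return s_ab / denom


def cross_spectra(seg_a: np.ndarray, seg_b: np.ndarray, rate_hz: float,
                  fmax_hz: int = DEFAULT_FMAX) -> tuple[np.ndarray, np.ndarray]:
    """Complex coherency of two channels' trial segments at 1..fmax Hz."""
    seg_a = np.atleast_2d(np.asarray(seg_a, dtype=float))
    seg_b = np.atleast_2d(np.asarray(seg_b, dtype=float))
    if seg_a.shape != seg_b.shape:
        raise ValidationError("segments must have equal trial counts and lengths")
    if seg_a.shape[0] < 2:
        raise ValidationError("coherency needs >= 2 trials")
    fa, freqs = _segment_ffts(seg_a, rate_hz, fmax_hz)
    fb, _ = _segment_ffts(seg_b, rate_hz, fmax_hz)
    return coherency_from_ffts(fa, fb), freqs


def psi_spectrum(coh: np.ndarray, freqs_hz: np.ndarray,
                 band_halfwidth_hz: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """PSI at every center frequency; bands clipped at the range edges.

    Returns ``(psi, truncated)`` where ``truncated[c]`` flags centers whose
    band could not extend the full halfwidth.
    """
    freqs_hz = np.asarray(freqs_hz)
    n_f = freqs_hz.size
    out = np.zeros(coh.shape[:-1] + (n_f,))
    truncated = np.zeros(n_f, dtype=bool)
    h = int(round(band_halfwidth_hz))
    # Im(conj(C(f)) * C(f+df)) via explicit real arithmetic: keeps the
    # antisymmetry psi(a,b) == -psi(b,a) exact in floating point
    cr, ci_ = coh.real, coh.imag
    prod_im = cr[..., :-1] * ci_[..., 1:] - ci_[..., :-1] * cr[..., 1:]
    for ci in range(n_f):
        lo = ci - h
        hi = ci + h  # exclusive; term indices lo..hi-1 use bins up to hi
        if lo < 0 or hi > n_f - 1:
            truncated[ci] = True
        lo_c = max(lo, 0)
        hi_c = min(hi, n_f - 1)
        out[..., ci] = prod_im[..., lo_c:hi_c].sum(axis=-1)
    return out, truncated


def psi(seg_a: np.ndarray, seg_b: np.ndarray, rate_hz: float,
        center_hz: float, band_halfwidth_hz: float = 2.0,
        fmax_hz: int = DEFAULT_FMAX) -> float:
    """PSI of a single center frequency; positive when signal A leads B."""
    coh, freqs = cross_spectra(seg_a, seg_b, rate_hz, fmax_hz)
    spec, _ = psi_spectrum(coh, freqs, band_halfwidth_hz)
    ci = int(np.argmin(np.abs(freqs - center_hz)))
    if abs(freqs[ci] - center_hz) > 0.5:
        raise ValidationError(f"center {center_hz} Hz outside 1-{fmax_hz} Hz grid")
    return float(spec[ci])


def psi_with_null(seg_a: np.ndarray, seg_b: np.ndarray, rate_hz: float,
                  band_halfwidth_hz: float = 2.0, n_shuffles: int = 200,
                  seed: int | np.random.Generator = 0,
                  fmax_hz: int = DEFAULT_FMAX) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed PSI spectrum plus its trial-shuffle null for one channel pair.

    Each shuffle permutes the trial order of the second channel's spectra,
    breaking the trial pairing; auto-spectra are unchanged, so only the
    cross-spectrum is recomputed.

    Returns ``(psi_obs (n_f,), null (n_shuffles, n_f), freqs)``.
    """
    seg_a = np.atleast_2d(np.asarray(seg_a, dtype=float))
    seg_b = np.atleast_2d(np.asarray(seg_b, dtype=float))
    if seg_a.shape != seg_b.shape:
        raise ValidationError("segments must have equal trial counts and lengths")
    n_tr = seg_a.shape[0]
    if n_tr < 5:
        raise ValidationError("trial-shuffle null needs >= 5 trials")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fa, freqs = _segment_ffts(seg_a, rate_hz, fmax_hz)
    fb, _ = _segment_ffts(seg_b, rate_hz, fmax_hz)
    denom = np.sqrt(_cross_mean(fa, fa).real * _cross_mean(fb, fb).real)
    coh_obs = _cross_mean(fa, fb) / denom
    obs, _trunc = psi_spectrum(coh_obs, freqs, band_halfwidth_hz)
    null = np.empty((n_shuffles, freqs.size))
    for s in range(n_shuffles):
        perm = rng.permutation(n_tr)
        coh_s = _cross_mean(fa, fb[perm]) / denom
        null[s], _ = psi_spectrum(coh_s, freqs, band_halfwidth_hz)
    return obs, null, freqs


def psi_null(seg_a: np.ndarray, seg_b: np.ndarray, rate_hz: float,
             band_halfwidth_hz: float = 2.0, n_shuffles: int = 200,
             seed: int | np.random.Generator = 0,
             fmax_hz: int = DEFAULT_FMAX) -> np.ndarray:
    """Trial-shuffle null PSI replicates, shape ``(n_shuffles, n_freqs)``."""
    _, null, _ = psi_with_null(seg_a, seg_b, rate_hz, band_halfwidth_hz,
                               n_shuffles, seed, fmax_hz)
    return null


def region_pair_psi(es: EpochSet, band_halfwidth_hz: float = 2.0,
                    n_shuffles: int = 200,
                    seed: int | np.random.Generator = 0,
                    fmax_hz: int = DEFAULT_FMAX) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PSI (+ nulls) for every ipsilateral HIP-AMY channel pair of a session.

    The hippocampal channel is always the first signal of each pair.
    Returns ``(psi_raw (n_pairs, n_f), null (n_pairs, n_shuffles, n_f), freqs)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hip = es.region_indices("HIP")
    amy = es.region_indices("AMY")
    if hip.size == 0 or amy.size == 0:
        raise ValidationError("need channels in both HIP and AMY")
    kept = np.flatnonzero(es.kept_mask)
    raws, nulls = [], []
    freqs = None
    for hi in hip:
        for ai in amy:
            obs, null, freqs = psi_with_null(
                es.data[kept, hi], es.data[kept, ai], es.rate_hz,
                band_halfwidth_hz, n_shuffles, rng, fmax_hz,
            )
            raws.append(obs)
            nulls.append(null)
    return np.array(raws), np.array(nulls), freqs


def psi_zscore(psi_raw: np.ndarray, null: np.ndarray, freqs_hz: np.ndarray,
               band_halfwidth_hz: float = 2.0) -> PSIResult:
    """Pool channel pairs (and sessions) and z-score against the pooled null.

    ``psi_raw``: (n_pairs, n_f); ``null``: (n_pairs, n_shuffles, n_f).
    Pooled observed = mean over pairs; pooled null replicate r = mean over
    pairs of replicate r; z(f) = (obs - mean_null) / std_null.
    """
    psi_raw = np.atleast_2d(psi_raw)
    if null.ndim != 3 or null.shape[0] != psi_raw.shape[0] or null.shape[2] != psi_raw.shape[1]:
        raise ValidationError("psi_raw and null shapes do not match")
    obs = psi_raw.mean(axis=0)
    pooled = null.mean(axis=0)  # (n_shuffles, n_f)
    std = pooled.std(axis=0, ddof=1)
    if np.any(std == 0):
        raise ValidationError("degenerate null: zero variance")
    z = (obs - pooled.mean(axis=0)) / std
    direction = [
        "HIP_leads" if zi > Z_CRIT else ("AMY_leads" if zi < -Z_CRIT else "none")
        for zi in z
    ]
    _, truncated = psi_spectrum(np.zeros(freqs_hz.size, dtype=complex), freqs_hz,
                                band_halfwidth_hz)
    return PSIResult(
        freqs_hz=np.asarray(freqs_hz, dtype=float),
        psi_raw=psi_raw,
        null=null,
        z=z,
        direction=direction,
        band_halfwidth_hz=band_halfwidth_hz,
        truncated=truncated,
    )
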