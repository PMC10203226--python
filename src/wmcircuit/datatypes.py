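"""Shared data containers for the two-region working-memory iEEG pipeline.

Every stage of the pipeline consumes and produces the types defined here,
so that each stage is file-separable (see :mod:`wmcircuit.io`).

Conventions
-----------
* Time is in seconds, 0-based, relative to recording start in the trial
  table; relative to period onset inside an :class:`EpochSet`.
* Epoch sample grids are half-open ``[onset, onset + duration)``.
* Regions are the amygdala (``"AMY"``) and hippocampus (``"HIP"``).
* The trial timeline is fixed by the task: 1 s fixation, 2 s encoding,
  3 s maintenance, 2 s retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIONS = ("AMY", "HIP")

#: Task period durations in seconds (fixation, encoding, maintenance, retrieval).
PERIODS: dict[str, float] = {
    "fixation": 1.0,
    "encoding": 2.0,
    "maintenance": 3.0,
    "retrieval": 2.0,
}

#: Total trial span from fixation onset (s).
TRIAL_DURATION_S = sum(PERIODS.values())

#: Pre-trial baseline used for power normalization (s before fixation onset).
BASELINE_S = 0.5

#: Memory loads used by the Sternberg task.
LOADS = (4, 6, 8)

TRIAL_COLUMNS = [
    "trial_id",
    "load",
    "t_fixation",
    "t_encoding",
    "t_maintenance",
    "t_probe",
    "correct",
    "rt_s",
]


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk artifact is malformed or incomplete."""


@dataclass
class Recording:
    """Continuous multichannel LFP recording.

    Parameters
    ----------
    samples
        Channel-major matrix, shape ``(n_channels, n_timepoints)``, microvolts.
    rate_hz
        Sampling rate in Hz.
    channel_names
        Unique channel identifiers.
    channel_region
        Mapping channel name -> region label in :data:`REGIONS`.
    channel_clean
        Per-channel flag; unclean channels are excluded from the common
        average reference and from analysis channel pools.
    """

    samples: np.ndarray
    rate_hz: float
    channel_names: list[str]
    channel_region: dict[str, str]
    channel_clean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D (channels x time)")
        if self.rate_hz <= 0:
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz}")
        n_ch = self.samples.shape[0]
        if len(self.channel_names) != n_ch:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if len(set(self.channel_names)) != n_ch:
            raise ValidationError("channel names must be unique")
        for name in self.channel_names:
            region = self.channel_region.get(name)
            if region is None:
                raise ValidationError(f"channel {name!r} has no region label")
            if region not in REGIONS:
                raise ValidationError(
                    f"channel {name!r} has unknown region {region!r}; "
                    f"expected one of {REGIONS}"
                )
        if self.channel_clean is None:
            self.channel_clean = np.ones(n_ch, dtype=bool)
        else:
            self.channel_clean = np.asarray(self.channel_clean, dtype=bool)
            if self.channel_clean.shape != (n_ch,):
                raise ValidationError("channel_clean must have one flag per channel")
        for region in set(self.channel_region[n] for n in self.channel_names):
            idx = self.region_indices(region, clean_only=True)
            if idx.size == 0:
                raise ValidationError(f"no clean channel in region {region}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def region_indices(self, region: str, clean_only: bool = False) -> np.ndarray:
        idx = np.array(
            [
                i
                for i, name in enumerate(self.channel_names)
                if self.channel_region[name] == region
            ],
            dtype=int,
        )
        if clean_only and idx.size:
            idx = idx[self.channel_clean[idx]]
        return idx

    def copy_with(self, samples: np.ndarray, rate_hz: float | None = None) -> "Recording":
        return Recording(
            samples=samples,
            rate_hz=self.rate_hz if rate_hz is None else rate_hz,
            channel_names=list(self.channel_names),
            channel_region=dict(self.channel_region),
            channel_clean=self.channel_clean.copy(),
        )


def validate_trial_table(df: pd.DataFrame, tol_s: float = 2e-3) -> pd.DataFrame:
    """Validate and type a trial table.

    Onsets must follow the task structure (1 s fixation, 2 s encoding,
    3 s maintenance before the probe) within ``tol_s`` (one sample at the
    lowest supported rate). Rows violating the invariants raise
    :class:`ValidationError` naming the row.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial table missing columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    df["trial_id"] = df["trial_id"].astype(int)
    df["load"] = df["load"].astype(int)
    bad_load = ~df["load"].isin(LOADS)
    if bad_load.any():
        rows = df.index[bad_load].tolist()
        raise ValidationError(f"load not in {LOADS} at rows {rows}")
    for col in ("t_fixation", "t_encoding", "t_maintenance", "t_probe"):
        df[col] = df[col].astype(float)
    df["correct"] = df["correct"].astype(bool)
    df["rt_s"] = df["rt_s"].astype(float)
    # -1 is the on-disk sentinel for a missing response time
    df.loc[df["rt_s"] < 0, "rt_s"] = np.nan

    gaps = {
        "t_encoding - t_fixation": (df["t_encoding"] - df["t_fixation"], PERIODS["fixation"]),
        "t_maintenance - t_encoding": (df["t_maintenance"] - df["t_encoding"], PERIODS["encoding"]),
        "t_probe - t_maintenance": (df["t_probe"] - df["t_maintenance"], PERIODS["maintenance"]),
    }
    for name, (gap, expected) in gaps.items():
        bad = (gap - expected).abs() > tol_s
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(
                f"row {row}: {name} = {gap.iloc[int(np.flatnonzero(bad)[0])]:.4f} s, "
                f"expected {expected} s"
            )
    return df.reset_index(drop=True)


@dataclass
class EpochSet:
    """Trials x channels x time array for one task period.

    ``t0_s`` is the time of the first sample relative to the period onset
    (negative for the padded full-trial window, which starts at the
    pre-trial baseline).
    """

    data: np.ndarray
    window_label: str
    t0_s: float
    rate_hz: float
    trial_ids: np.ndarray
    kept_mask: np.ndarray
    channel_names: list[str]
    channel_region: dict[str, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be 3-D (trial, channel, time)")
        if self.data.shape[0] != self.trial_ids.size:
            raise ValidationError("trial_ids length mismatch")
        if self.kept_mask.shape != self.trial_ids.shape:
            raise ValidationError("kept_mask length mismatch")
        if self.data.shape[1] != len(self.channel_names):
            raise ValidationError("channel_names length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.data.shape[2]) / self.rate_hz

    def region_indices(self, region: str) -> np.ndarray:
        return np.array(
            [
                i
                for i, name in enumerate(self.channel_names)
                if self.channel_region[name] == region
            ],
            dtype=int,
        )


@dataclass
class PowerTensor:
    """Spectral power, trials x channels x frequencies x time.

    ``time_s`` is relative to fixation onset for full-trial tensors, or to
    the period onset for sliced tensors. ``edge_mask[f, t]`` flags samples
    within one wavelet half-width of the epoch edges.
    """

    values: np.ndarray
    freqs_hz: np.ndarray
    time_s: np.ndarray
    rate_hz: float
    trial_ids: np.ndarray
    channel_names: list[str]
    channel_region: dict[str, str]
    zscored: bool = False
    baseline_window: tuple[float, float] | None = None
    edge_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        if self.values.ndim != 4:
            raise ValidationError("power values must be 4-D (trial, ch, freq, time)")
        n_tr, n_ch, n_f, n_t = self.values.shape
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValidationError("freqs_hz must be strictly increasing")
        if self.freqs_hz.size != n_f or self.time_s.size != n_t:
            raise ValidationError("freqs_hz/time_s shape mismatch")
        if len(self.channel_names) != n_ch or self.trial_ids.size != n_tr:
            raise ValidationError("channel/trial metadata shape mismatch")

    def region_indices(self, region: str) -> np.ndarray:
        return np.array(
            [
                i
                for i, name in enumerate(self.channel_names)
                if self.channel_region[name] == region
            ],
            dtype=int,
        )

    def select_region(self, region: str) -> "PowerTensor":
        idx = self.region_indices(region)
        if idx.size == 0:
            raise ValidationError(f"no channels in region {region}")
        return PowerTensor(
            values=self.values[:, idx],
            freqs_hz=self.freqs_hz,
            time_s=self.time_s,
            rate_hz=self.rate_hz,
            trial_ids=self.trial_ids,
            channel_names=[self.channel_names[i] for i in idx],
            channel_region={self.channel_names[i]: self.channel_region[self.channel_names[i]] for i in idx},
            zscored=self.zscored,
            baseline_window=self.baseline_window,
            edge_mask=self.edge_mask,
        )

    def slice_time(self, start_s: float, end_s: float, new_origin: bool = True) -> "PowerTensor":
        """Return the sub-tensor with ``start_s <= t < end_s``.

        With ``new_origin`` the returned ``time_s`` is re-expressed relative
        to ``start_s``.
        """
        sel = (self.time_s >= start_s - 1e-9) & (self.time_s < end_s - 1e-9)
        if not sel.any():
            raise ValidationError(f"no samples in [{start_s}, {end_s}) s")
        time = self.time_s[sel]
        if new_origin:
            time = time - start_s
        return PowerTensor(
            values=self.values[..., sel],
            freqs_hz=self.freqs_hz,
            time_s=time,
            rate_hz=self.rate_hz,
            trial_ids=self.trial_ids,
            channel_names=list(self.channel_names),
            channel_region=dict(self.channel_region),
            zscored=self.zscored,
            baseline_window=self.baseline_window,
            edge_mask=None if self.edge_mask is None else self.edge_mask[:, sel],
        )

    def select_freqs(self, low_hz: float, high_hz: float) -> "PowerTensor":
        sel = (self.freqs_hz >= low_hz) & (self.freqs_hz <= high_hz)
        return PowerTensor(
            values=self.values[:, :, sel],
            freqs_hz=self.freqs_hz[sel],
            time_s=self.time_s,
            rate_hz=self.rate_hz,
            trial_ids=self.trial_ids,
            channel_names=list(self.channel_names),
            channel_region=dict(self.channel_region),
            zscored=self.zscored,
            baseline_window=self.baseline_window,
            edge_mask=None if self.edge_mask is None else self.edge_mask[sel],
        )

    def select_trials(self, mask: np.ndarray) -> "PowerTensor":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return PowerTensor(
            values=self.values[idx],
            freqs_hz=self.freqs_hz,
            time_s=self.time_s,
            rate_hz=self.rate_hz,
            trial_ids=self.trial_ids[idx],
            channel_names=list(self.channel_names),
            channel_region=dict(self.channel_region),
            zscored=self.zscored,
            baseline_window=self.baseline_window,
            edge_mask=self.edge_mask,
        )
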