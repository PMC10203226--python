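"""On-disk formats for pipeline artifacts.

* :class:`~wmcircuit.datatypes.Recording`: ``<name>.dat`` (float32,
  channel-major) plus a ``<name>.json`` sidecar with rate, channel names,
  regions and clean flags. Optional EDF import via :func:`read_edf`.
* Trial tables: TSV with a fixed column set; missing response times are
  written as the sentinel ``-1``.
* Epochs, power tensors and representation maps: single-file HDF5.

All write/read pairs round-trip losslessly up to float32 precision for
samples and exactly for metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    EpochSet,
    FormatError,
    PowerTensor,
    Recording,
    TRIAL_COLUMNS,
    validate_trial_table,
)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as float32 ``.dat`` + JSON sidecar; returns the data path."""
    path = Path(path)
    if path.suffix != ".dat":
        path = path.with_suffix(".dat")
    np.asarray(rec.samples, dtype=np.float32).tofile(path)
    meta = {
        "rate_hz": float(rec.rate_hz),
        "channel_names": list(rec.channel_names),
        "channel_region": dict(rec.channel_region),
        "channel_clean": [bool(c) for c in rec.channel_clean],
        "n_samples": int(rec.n_samples),
        "dtype": "float32",
        "order": "channel-major",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix != ".dat":
        path = path.with_suffix(".dat")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata {sidecar}")
    if not path.exists():
        raise FormatError(f"missing data file {path}")
    meta = json.loads(sidecar.read_text())
    for key in ("rate_hz", "channel_names", "channel_region", "n_samples"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing field {key!r}")
    n_ch = len(meta["channel_names"])
    samples = np.fromfile(path, dtype=np.float32)
    expected = n_ch * int(meta["n_samples"])
    if samples.size != expected:
        raise FormatError(
            f"{path}: expected {expected} samples, found {samples.size}"
        )
    samples = samples.reshape(n_ch, -1).astype(float)
    clean = meta.get("channel_clean")
    return Recording(
        samples=samples,
        rate_hz=float(meta["rate_hz"]),
        channel_names=list(meta["channel_names"]),
        channel_region=dict(meta["channel_region"]),
        channel_clean=None if clean is None else np.asarray(clean, dtype=bool),
    )


def read_edf(path: str | Path, channel_region: dict[str, str]) -> Recording:
    """Optional EDF adapter: import an EDF/EDF+ file as a :class:`Recording`.

    ``channel_region`` must map each EDF channel name to AMY/HIP.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        rate_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        channel_region=channel_region,
    )


def write_trial_table(tt: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df = validate_trial_table(tt).copy()
    df["rt_s"] = df["rt_s"].fillna(-1.0)
    df["correct"] = df["correct"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:  # pragma: no cover - defensive
        raise FormatError(f"cannot parse trial table {path}: {exc}") from exc
    return validate_trial_table(df)


# ---------------------------------------------------------------------------
# HDF5 containers


def _write_channel_meta(grp: h5py.Group, names: list[str], regions: dict[str, str]) -> None:
    grp.attrs["channel_names"] = json.dumps(names)
    grp.attrs["channel_region"] = json.dumps(regions)


def _read_channel_meta(grp: h5py.Group) -> tuple[list[str], dict[str, str]]:
    return (
        json.loads(grp.attrs["channel_names"]),
        json.loads(grp.attrs["channel_region"]),
    )


def write_epochs(epochs: dict[str, EpochSet], path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for label, es in epochs.items():
            grp = f.create_group(label)
            grp.create_dataset("data", data=es.data.astype(np.float32))
            grp.create_dataset("trial_ids", data=es.trial_ids)
            grp.create_dataset("kept_mask", data=es.kept_mask)
            grp.attrs["t0_s"] = es.t0_s
            grp.attrs["rate_hz"] = es.rate_hz
            grp.attrs["window_label"] = es.window_label
            _write_channel_meta(grp, es.channel_names, es.channel_region)
    return path


def read_epochs(path: str | Path) -> dict[str, EpochSet]:
    out: dict[str, EpochSet] = {}
    with h5py.File(path, "r") as f:
        for label in f:
            grp = f[label]
            names, regions = _read_channel_meta(grp)
            out[label] = EpochSet(
                data=grp["data"][()].astype(float),
                window_label=str(grp.attrs["window_label"]),
                t0_s=float(grp.attrs["t0_s"]),
                rate_hz=float(grp.attrs["rate_hz"]),
                trial_ids=grp["trial_ids"][()],
                kept_mask=grp["kept_mask"][()],
                channel_names=names,
                channel_region=regions,
            )
    return out


def write_power(power: PowerTensor, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=power.values.astype(np.float32))
        f.create_dataset("freqs_hz", data=power.freqs_hz)
        f.create_dataset("time_s", data=power.time_s)
        f.create_dataset("trial_ids", data=power.trial_ids)
        if power.edge_mask is not None:
            f.create_dataset("edge_mask", data=power.edge_mask)
        f.attrs["rate_hz"] = power.rate_hz
        f.attrs["zscored"] = power.zscored
        if power.baseline_window is not None:
            f.attrs["baseline_window"] = list(power.baseline_window)
        _write_channel_meta(f, power.channel_names, power.channel_region)
    return path


def read_power(path: str | Path) -> PowerTensor:
    with h5py.File(path, "r") as f:
        names, regions = _read_channel_meta(f)
        baseline = f.attrs.get("baseline_window")
        return PowerTensor(
            values=f["values"][()].astype(float),
            freqs_hz=f["freqs_hz"][()],
            time_s=f["time_s"][()],
            rate_hz=float(f.attrs["rate_hz"]),
            trial_ids=f["trial_ids"][()],
            channel_names=names,
            channel_region=regions,
            zscored=bool(f.attrs["zscored"]),
            baseline_window=None if baseline is None else tuple(baseline),
            edge_mask=f["edge_mask"][()] if "edge_mask" in f else None,
        )


def write_maps(maps: dict[str, np.ndarray], path: str | Path, **attrs) -> Path:
    """Store named 2-D representation maps with grid metadata as HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in maps.items():
            f.create_dataset(name, data=np.asarray(arr, dtype=float))
        for key, val in attrs.items():
            f.attrs[key] = val
    return path


def read_maps(path: str | Path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {name: f[name][()] for name in f}
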