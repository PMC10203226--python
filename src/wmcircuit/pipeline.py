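"""Configured end-to-end runs: simulate -> preprocess -> tfr -> rsa/psi ->
decode -> stats, with a manifest and per-stage logs.

A run is driven by a YAML/JSON config with a mandatory master ``seed``;
every stochastic stage receives a child seed derived deterministically
from it, so rerunning the same config reproduces every numeric output.
Each stage writes its artifact into the run directory and can be rerun
individually through the CLI against those files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as wio
from . import representation as rep
from .connectivity import psi_zscore, region_pair_psi
from .datatypes import LOADS, PERIODS, ValidationError
from .decoding import build_eed_features, decode_load
from .preprocess import (
    bandpass_fir,
    downsample,
    epoch,
    reject_artifact_trials,
    remove_line_noise,
    rereference_common_average,
    select_trials,
)
from .simulate import Coupling, SimConfig, synthesize_session
from .spectral import bootstrap_baseline_null, morlet_power, zscore_power
from .stats import cluster_permutation_paired


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def demo_config() -> dict:
    """Small bundled configuration that exercises every stage in minutes."""
    return {
        "seed": 7,
        "simulate": {
            "n_sessions": 5,
            "n_trials_per_load": 4,
            "n_channels": {"HIP": 2, "AMY": 2},
            "rate_hz": 200,
            "coupling": [
                {"source": "HIP", "target": "AMY", "band_hz": [4, 8],
                 "lag_ms": 25, "gain": 6.0},
            ],
        },
        "preprocess": {"band": None, "line": None, "resample": None,
                       "car": False, "reject_mad": 8.0},
        "tfr": {"fmax_hz": 40, "n_boot": 200},
        "rsa": {"step_s": 0.1, "pairs": 12},
        "psi": {"n_shuffles": 200, "halfwidth": 2.0},
        "decode": {"n_repeats": 25},
        "stats": {"n_perm": 500, "p_point": 0.05},
    }


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    if "seed" not in cfg:
        raise ValidationError("config is missing the master 'seed'")
    if not isinstance(cfg["seed"], int):
        raise ValidationError("'seed' must be an integer")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


def _child_seed(master: int, tag: str) -> int:
    h = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sim_config(cfg: dict, seed: int) -> SimConfig:
    sim = dict(cfg.get("simulate", {}))
    sim.pop("n_sessions", None)
    coupling = [
        Coupling(c["source"], c["target"], tuple(c.get("band_hz", (4, 8))),
                 float(c.get("lag_ms", 20.0)), float(c.get("gain", 0.0)))
        for c in sim.pop("coupling", [])
    ]
    if "load_gain" in sim:
        sim["load_gain"] = {int(k): float(v) for k, v in sim["load_gain"].items()}
    return SimConfig(coupling=coupling, seed=seed, **sim)


def run_pipeline(cfg: dict, outdir: str | Path) -> Path:
    """Execute all stages; returns the run directory."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    n_sessions = int(cfg.get("simulate", {}).get("n_sessions", 1))
    log: list[dict] = []

    def _stage(name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            log.append({"stage": name, "status": "failed", "error": str(exc)})
            (outdir / "log.jsonl").write_text(
                "\n".join(json.dumps(e) for e in log) + "\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.append({"stage": name, "status": "ok",
                    "seconds": round(time.perf_counter() - t0, 3)})
        return result

    eed_maps = {"AMY": [], "HIP": []}
    psi_raw_all, psi_null_all, psi_freqs = [], [], None
    eed_pair_maps: dict[int, list[np.ndarray]] = {load: [] for load in LOADS}
    rsa_cfg = cfg.get("rsa", {})
    step_s = float(rsa_cfg.get("step_s", 0.01))
    grid_enc = rep.make_window_grid(0.0, PERIODS["encoding"], step_s=step_s,
                                    period="encoding")
    grid_maint = rep.make_window_grid(0.0, PERIODS["maintenance"], step_s=step_s,
                                      period="maintenance")

    for s in range(n_sessions):
        sdir = outdir / "sessions" / f"s{s:02d}"
        sdir.mkdir(parents=True, exist_ok=True)
        sim_cfg = _sim_config(cfg, _child_seed(master, f"simulate:{s}"))

        rec, tt, gt = _stage(f"simulate[{s}]", synthesize_session, sim_cfg)
        wio.write_recording(rec, sdir / "recording.dat")
        wio.write_trial_table(tt, sdir / "trials.tsv")
        (sdir / "ground_truth.json").write_text(json.dumps(gt.to_json_dict()))

        pp = cfg.get("preprocess", {})

        def _preprocess(rec=rec, tt=tt, pp=pp, sdir=sdir):
            out = rec
            if pp.get("band"):
                out = bandpass_fir(out, *pp["band"])
            if pp.get("line"):
                out = remove_line_noise(out, list(np.atleast_1d(pp["line"])))
            if pp.get("resample"):
                out = downsample(out, float(pp["resample"]))
            if pp.get("car"):
                out = rereference_common_average(out)
            epochs = epoch(out, tt)
            if pp.get("reject_mad"):
                epochs["trial"] = reject_artifact_trials(
                    epochs["trial"], k_mad=float(pp["reject_mad"]))
            wio.write_epochs(epochs, sdir / "epochs.h5")
            return epochs

        epochs = _stage(f"preprocess[{s}]", _preprocess)

        tfr_cfg = cfg.get("tfr", {})

        def _tfr(epochs=epochs, tt=tt, tfr_cfg=tfr_cfg, s=s, sdir=sdir):
            es = select_trials(epochs["trial"], tt, correct_only=True)
            power = morlet_power(
                es, freqs_hz=np.arange(1.0, float(tfr_cfg.get("fmax_hz", 40)) + 1))
            null = bootstrap_baseline_null(
                power, n_boot=int(tfr_cfg.get("n_boot", 1000)),
                seed=_child_seed(master, f"tfr:{s}"))
            z = zscore_power(power, null)
            wio.write_power(z, sdir / "power.h5")
            return z

        zpow = _stage(f"tfr[{s}]", _tfr)

        def _rsa(zpow=zpow, s=s, sdir=sdir):
            rng = np.random.default_rng(_child_seed(master, f"rsa:{s}"))
            maps_out = {}
            for region in ("AMY", "HIP"):
                zr = zpow.select_region(region)
                enc = rep.slice_period(zr, "encoding")
                maint = rep.slice_period(zr, "maintenance")
                emap = rep.eed_map(enc, grid_enc, region=region)
                smap = rep.ems_map(enc, maint, grid_enc, grid_maint, region=region)
                eed_maps[region].append(emap.values)
                maps_out[f"eed_{region}"] = emap.values
                maps_out[f"ems_{region}"] = smap.values
            # per-pair maps for decoding, within load, from the configured region
            zr = zpow.select_region(rsa_cfg.get("decode_region", "AMY"))
            enc = rep.slice_period(zr, "encoding")
            return maps_out, enc, rng

        maps_out, enc_region, rng = _stage(f"rsa[{s}]", _rsa)
        wio.write_maps(maps_out, sdir / "maps.h5",
                       step_s=step_s, width_s=grid_enc.width_s)

        def _pairs(enc=enc_region, tt=tt, rng=rng):
            tt_kept = tt[tt["correct"]].reset_index(drop=True)
            k = int(rsa_cfg.get("pairs", 12))
            for load in LOADS:
                sel = np.flatnonzero(tt_kept["load"].to_numpy() == load)
                if sel.size < 2:
                    continue
                sub = enc.select_trials(sel)
                pair_idx, _ = rep.sample_trial_pairs(sel.size, k=k, seed=rng)
                maps, _ = rep.eed_maps_per_pair(sub, grid_enc, pairs=pair_idx)
                eed_pair_maps[load].append(maps)

        _stage(f"rsa-pairs[{s}]", _pairs)

        psi_cfg = cfg.get("psi", {})

        def _psi(epochs=epochs, tt=tt, s=s):
            es = select_trials(epochs["encoding"], tt, correct_only=True)
            return region_pair_psi(
                es, band_halfwidth_hz=float(psi_cfg.get("halfwidth", 2.0)),
                n_shuffles=int(psi_cfg.get("n_shuffles", 200)),
                seed=_child_seed(master, f"psi:{s}"))

        raw, null, freqs = _stage(f"psi[{s}]", _psi)
        psi_raw_all.append(raw)
        psi_null_all.append(null)
        psi_freqs = freqs

    # population-level stages
    def _psi_pool():
        raw = np.concatenate(psi_raw_all, axis=0)
        null = np.concatenate(psi_null_all, axis=0)
        res = psi_zscore(raw, null, psi_freqs,
                         float(cfg.get("psi", {}).get("halfwidth", 2.0)))
        out = {
            "freqs_hz": res.freqs_hz.tolist(),
            "z": res.z.tolist(),
            "direction": res.direction,
        }
        (outdir / "psi.json").write_text(json.dumps(out, indent=1))
        return res

    psi_res = _stage("psi-pool", _psi_pool)

    def _decode():
        fs = build_eed_features(
            {load: np.concatenate(m, axis=0) for load, m in eed_pair_maps.items()
             if m})
        result = decode_load(fs, n_repeats=int(cfg.get("decode", {}).get("n_repeats", 100)),
                             seed=_child_seed(master, "decode"))
        out = {
            "mean_accuracy": result.mean,
            "std_accuracy": result.std,
            "accuracies": result.accuracies.tolist(),
            "n_components": result.n_components.tolist(),
        }
        (outdir / "decoding.json").write_text(json.dumps(out, indent=1))
        return result

    dec = _stage("decode", _decode)

    def _stats():
        if n_sessions < 5:
            return None
        a = np.stack(eed_maps["AMY"])
        b = np.stack(eed_maps["HIP"])
        st = cfg.get("stats", {})
        res = cluster_permutation_paired(
            a, b, n_perm=int(st.get("n_perm", 1000)),
            p_point=float(st.get("p_point", 0.05)),
            seed=_child_seed(master, "stats"))
        out = {
            "n_clusters": int(res.cluster_stats.size),
            "cluster_p": res.cluster_p.tolist(),
            "threshold": res.threshold,
            "n_permutations": res.n_permutations,
        }
        (outdir / "clusters.json").write_text(json.dumps(out, indent=1))
        return res

    _stage("stats", _stats)

    manifest = {
        "config_hash": _config_hash(cfg),
        "config": cfg,
        "version": __version__,
        "n_sessions": n_sessions,
        "mean_decoding_accuracy": dec.mean,
        "psi_directions": {
            str(int(f)): d
            for f, d in zip(psi_res.freqs_hz, psi_res.direction) if d != "none"
        },
        "stages": log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "log.jsonl").write_text("\n".join(json.dumps(e) for e in log) + "\n")
    return outdir
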