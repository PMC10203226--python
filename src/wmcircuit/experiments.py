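"""End-to-end validation experiments on synthetic sessions.

These functions exercise the full pipeline (generator -> epoching ->
time-frequency -> EED/EMS / PSI -> decoding / cluster stats) in regimes
with known ground truth and measure whether the analysis recovers it:

* direction and band of injected inter-regional coupling (PSI),
* the regional distinctiveness/stability regime the study reports
  (distinct amygdala encoding patterns, stable hippocampal maintenance),
* decoding chance calibration and load sensitivity,
* family-wise error control of the cluster permutation test.

Problem sizes are scaled to run on a single CPU in minutes: sessions are
simulated at 200 Hz with 2 channels per region, and recovery maps use a
coarser window step than the 10 ms analysis default. The statistics being
validated (directions of effects, error rates) do not depend on these
sizes.
"""

from __future__ import annotations

import numpy as np

from . import representation as rep
from .connectivity import psi_zscore, region_pair_psi
from .datatypes import LOADS, PERIODS
from .decoding import (
    FeatureSet,
    _stratified_split,
    accuracy_vs_chance_test,
    build_eed_features,
)
from .preprocess import epoch, select_trials
from .simulate import Coupling, SimConfig, synthesize_session
from .spectral import bootstrap_baseline_null, morlet_power, zscore_power
from .stats import cluster_permutation_paired, paired_t

RECOVERY_RATE_HZ = 200.0
RECOVERY_CHANNELS = {"HIP": 2, "AMY": 2}


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def bookkeeping() -> dict[str, int]:
    """Window-grid and feature-vector bookkeeping of the analysis design.

    Encoding carries 201 sliding windows (100 ms window, 10 ms step over
    2 s) and maintenance 301; EED maps flatten to 201^2 = 40401 features
    and EMS maps to 201*301 = 60501. The trial-pair pool for EED decoding
    (100 pairs x 14 participants per load) splits 980/420 under the
    stratified 70/30 rule, and the 172-channel-pair PSI pool splits 120/52.
    """
    grid_enc = rep.make_window_grid(0.0, PERIODS["encoding"], period="encoding")
    grid_maint = rep.make_window_grid(0.0, PERIODS["maintenance"], period="maintenance")

    rng = np.random.default_rng(0)
    eed_fs = build_eed_features({
        load: rng.standard_normal((2, grid_enc.n_windows, grid_enc.n_windows))
        for load in LOADS
    })
    ems_maps = {
        load: rng.standard_normal((2, grid_enc.n_windows, grid_maint.n_windows))
        for load in LOADS
    }
    from .decoding import build_ems_features

    ems_fs = build_ems_features(ems_maps)

    n_pairs_pool = 100 * 14  # pairs per participant x participants, per load
    y = np.repeat(LOADS, n_pairs_pool)
    tr, te = _stratified_split(y, 0.7, np.random.default_rng(0))
    per_load_train = int(np.sum(y[tr] == LOADS[0]))
    per_load_test = int(np.sum(y[te] == LOADS[0]))

    y_psi = np.repeat(LOADS, 172)
    tr_p, te_p = _stratified_split(y_psi, 0.7, np.random.default_rng(0))
    psi_train = int(np.sum(y_psi[tr_p] == LOADS[0]))
    psi_test = int(np.sum(y_psi[te_p] == LOADS[0]))

    return {
        "encoding_windows": grid_enc.n_windows,
        "maintenance_windows": grid_maint.n_windows,
        "eed_feature_length": int(eed_fs.X.shape[1]),
        "ems_feature_length": int(ems_fs.X.shape[1]),
        "eed_samples_per_load": n_pairs_pool,
        "eed_train_per_load": per_load_train,
        "eed_test_per_load": per_load_test,
        "psi_train_per_load": psi_train,
        "psi_test_per_load": psi_test,
    }


# ---------------------------------------------------------------------------
# PSI direction recovery

HIP_TO_AMY_BAND = (4.0, 8.0)
AMY_TO_HIP_BAND = (20.0, 28.0)


def _psi_session_config(seed: int, coupled: bool) -> SimConfig:
    coupling = []
    if coupled:
        coupling = [
            Coupling("HIP", "AMY", band_hz=HIP_TO_AMY_BAND, lag_ms=25.0, gain=6.0),
            Coupling("AMY", "HIP", band_hz=AMY_TO_HIP_BAND, lag_ms=18.0, gain=8.0),
        ]
    return SimConfig(
        n_trials_per_load=10,
        n_channels=dict(RECOVERY_CHANNELS),
        rate_hz=RECOVERY_RATE_HZ,
        coupling=coupling,
        seed=seed,
    )


def _session_psi_z(cfg: SimConfig, period: str = "encoding", n_shuffles: int = 200,
                   seed: int = 0):
    rec, tt, _ = synthesize_session(cfg)
    epochs = epoch(rec, tt)
    es = select_trials(epochs[period], tt, correct_only=True)
    raw, null, freqs = region_pair_psi(es, n_shuffles=n_shuffles, seed=seed)
    return psi_zscore(raw, null, freqs)


def psi_direction_recovery(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """Recover the direction and band of injected coupling, and the
    false-positive rate under no coupling.

    Coupled sessions carry hippocampus->amygdala coupling at 4-8 Hz and
    amygdala->hippocampus coupling at 20-28 Hz; recovery means z > +1.96
    at the interior frequencies of the former band and z < -1.96 in the
    latter. Null sessions (no coupling) measure the fraction of
    frequencies with |z| > 1.96.
    """
    seeds = _child_seeds(seed, 2 * n_seeds)
    hip_ok = amy_ok = both_ok = 0
    fp = []
    for i in range(n_seeds):
        res = _session_psi_z(_psi_session_config(seeds[i], coupled=True),
                             seed=seeds[i])
        # score only centers whose full PSI integration band (center +- 2 Hz)
        # lies inside the coupled band; edge centers mix coupled and
        # uncoupled bins and are attenuated by construction
        f = res.freqs_hz
        in_low = (f >= HIP_TO_AMY_BAND[0] + 2) & (f <= HIP_TO_AMY_BAND[1] - 2)
        in_high = (f >= AMY_TO_HIP_BAND[0] + 2) & (f <= AMY_TO_HIP_BAND[1] - 2)
        h = bool(np.all(res.z[in_low] > 1.96))
        a = bool(np.all(res.z[in_high] < -1.96))
        hip_ok += h
        amy_ok += a
        both_ok += h and a
    for i in range(n_seeds):
        res = _session_psi_z(_psi_session_config(seeds[n_seeds + i], coupled=False),
                             seed=seeds[n_seeds + i])
        fp.append(np.mean(np.abs(res.z) > 1.96))
    return {
        "hip_leads_recovery_rate": hip_ok / n_seeds,
        "amy_leads_recovery_rate": amy_ok / n_seeds,
        "both_bands_recovery_rate": both_ok / n_seeds,
        "null_false_positive_rate": float(np.mean(fp)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Representational regime recovery


def _zscored_power(rec, tt, n_boot: int = 200, seed: int = 0,
                   fmax_hz: float = 40.0):
    epochs = epoch(rec, tt)
    es = select_trials(epochs["trial"], tt, correct_only=True)
    power = morlet_power(es, freqs_hz=np.arange(1.0, fmax_hz + 1.0))
    null = bootstrap_baseline_null(power, n_boot=n_boot, seed=seed)
    return zscore_power(power, null)


def region_maps(zpow, region: str, step_s: float = 0.05,
                pairs: np.ndarray | None = None) -> tuple[float, float]:
    """Mean EED and EMS of one region from z-scored full-trial power."""
    zr = zpow.select_region(region)
    enc = rep.slice_period(zr, "encoding")
    maint = rep.slice_period(zr, "maintenance")
    grid_e = rep.make_window_grid(0.0, PERIODS["encoding"], step_s=step_s,
                                  period="encoding")
    grid_m = rep.make_window_grid(0.0, PERIODS["maintenance"], step_s=step_s,
                                  period="maintenance")
    eed = rep.eed_map(enc, grid_e, pairs=pairs, region=region)
    ems = rep.ems_map(enc, maint, grid_e, grid_m, region=region)
    return float(eed.values.mean()), float(ems.values.mean())


def representation_recovery(n_seeds: int = 20, seed: int = 0,
                            n_trials_per_load: int = 12) -> dict[str, float]:
    """Recover the study regime delta_AMY > delta_HIP, rho_HIP > rho_AMY.

    With distinct amygdala encoding patterns (delta 0.9 vs 0.2) the mean
    EED must be higher in AMY than HIP; with stable hippocampal
    maintenance (rho 0.8 vs 0.1) the mean EMS must be higher in HIP.
    """
    seeds = _child_seeds(seed, n_seeds)
    eed_ok = ems_ok = 0
    for s in seeds:
        cfg = SimConfig(
            n_trials_per_load=n_trials_per_load,
            n_channels=dict(RECOVERY_CHANNELS),
            rate_hz=RECOVERY_RATE_HZ,
            seed=s,
        )
        rec, tt, _ = synthesize_session(cfg)
        zpow = _zscored_power(rec, tt, seed=s)
        eed_amy, ems_amy = region_maps(zpow, "AMY")
        eed_hip, ems_hip = region_maps(zpow, "HIP")
        eed_ok += eed_amy > eed_hip
        ems_ok += ems_hip > ems_amy
    return {
        "eed_amy_gt_hip_rate": eed_ok / n_seeds,
        "ems_hip_gt_amy_rate": ems_ok / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Decoding calibration


def ems_feature_set(load_effect: bool, seed: int, n_sessions: int = 4,
                    n_trials_per_load: int = 24, step_s: float = 0.3,
                    width_s: float = 0.3,
                    region: str = "HIP",
                    pattern_amplitude_uv: float = 35.0,
                    n_channels: dict[str, int] | None = None) -> FeatureSet:
    """Per-trial EMS features pooled over synthetic sessions.

    ``load_effect=False`` sets the generator's load gain flat (null-load
    regime); otherwise the default multiplicative modulation applies.
    Per-trial EMS maps are the decoding unit used for calibration because
    trials are independent samples (trial-pair features share trials
    across samples of the same load, which a classifier can exploit even
    without a load effect). Sessions carry 24 trials per load: with small
    session-by-load cells, the shared within-session noise induces a
    finite-pool anticorrelation between the train and test trials of a
    cell that degrades held-out accuracy; larger cells shrink it.
    """
    seeds = _child_seeds(seed, n_sessions)
    grid_e = rep.make_window_grid(0.0, PERIODS["encoding"], width_s=width_s,
                                  step_s=step_s, period="encoding")
    grid_m = rep.make_window_grid(0.0, PERIODS["maintenance"], width_s=width_s,
                                  step_s=step_s, period="maintenance")
    maps_by_load: dict[int, list[np.ndarray]] = {load: [] for load in LOADS}
    for s in seeds:
        kwargs = {} if load_effect else {"load_gain": {4: 1.0, 6: 1.0, 8: 1.0}}
        cfg = SimConfig(
            n_trials_per_load=n_trials_per_load,
            n_channels=dict(n_channels or RECOVERY_CHANNELS),
            rate_hz=RECOVERY_RATE_HZ,
            pattern_amplitude_uv=pattern_amplitude_uv,
            seed=s,
            **kwargs,
        )
        rec, tt, _ = synthesize_session(cfg)
        zr = _zscored_power(rec, tt, seed=s).select_region(region)
        enc = rep.slice_period(zr, "encoding")
        maint = rep.slice_period(zr, "maintenance")
        maps = rep.ems_maps_per_trial(enc, maint, grid_e, grid_m)
        loads = tt["load"].to_numpy()
        for load in LOADS:
            maps_by_load[load].append(maps[loads == load])
    from .decoding import build_ems_features

    return build_ems_features(
        {load: np.concatenate(m, axis=0) for load, m in maps_by_load.items()},
        provenance={"region": region, "load_effect": load_effect},
    )


def decoding_calibration(seed: int = 0, n_repeats: int = 25,
                         n_perm: int = 99) -> dict[str, float]:
    """Chance calibration and load sensitivity of the decoder.

    * mean accuracy over the label-shuffle null -> chance, near 1/3
      (trials within a session are correlated, so a single shuffled
      labeling can align with session structure by chance; the null
      mean is the calibrated chance estimate);
    * null-load generator (flat load gain) -> accuracy not significantly
      above chance;
    * default load gain -> accuracy above chance (permutation p < 0.05;
      reduced repeats keep the permutation loops tractable).
    """
    seeds = _child_seeds(seed, 4)
    fs_on = ems_feature_set(load_effect=True, seed=seeds[0])
    fs_off = ems_feature_set(load_effect=False, seed=seeds[1])

    acc_on, p_on, chance_on = accuracy_vs_chance_test(
        fs_on, n_perm=n_perm, n_repeats=n_repeats, seed=seeds[3])
    acc_off, p_off, chance_off = accuracy_vs_chance_test(
        fs_off, n_perm=n_perm, n_repeats=n_repeats, seed=seeds[3])
    return {
        "shuffled_label_accuracy": 0.5 * (chance_on + chance_off),
        "load_on_accuracy": acc_on,
        "load_on_p": p_on,
        "load_off_accuracy": acc_off,
        "load_off_p": p_off,
        "n_repeats": n_repeats,
    }


# ---------------------------------------------------------------------------
# Cluster permutation calibration and scalar oracles


def cluster_fwer(n_experiments: int = 200, n_participants: int = 10,
                 shape: tuple[int, int] = (40, 40), alpha: float = 0.05,
                 seed: int = 0) -> dict[str, float]:
    """Family-wise error rate of the cluster test under an i.i.d. null."""
    rng = np.random.default_rng(seed)
    false_pos = 0
    for _ in range(n_experiments):
        a = rng.standard_normal((n_participants, *shape))
        b = rng.standard_normal((n_participants, *shape))
        res = cluster_permutation_paired(a, b, seed=rng)
        if np.any(res.cluster_p < alpha):
            false_pos += 1
    return {
        "fwer": false_pos / n_experiments,
        "n_experiments": n_experiments,
    }


def brute_force_dissimilarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Independent oracle: rank by sorting, Pearson by formula, then 1 - atanh."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1, dtype=float)
        # average ties
        for val in np.unique(v):
            m = v == val
            r[m] = r[m].mean()
        return r

    r1, r2 = ranks(np.asarray(v1, float)), ranks(np.asarray(v2, float))
    d1, d2 = r1 - r1.mean(), r2 - r2.mean()
    rho = float(np.sum(d1 * d2) / np.sqrt(np.sum(d1 ** 2) * np.sum(d2 ** 2)))
    rho = min(max(rho, -(1 - 1e-10)), 1 - 1e-10)
    return 1.0 - np.arctanh(rho)


def brute_force_paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Independent oracle: textbook paired t with the t survival function."""
    from scipy.stats import t as tdist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2 * tdist.sf(abs(t_stat), df=n - 1)
    return float(t_stat), n - 1, float(p)


def oracle_agreement(n_draws: int = 200, seed: int = 0) -> dict[str, float]:
    """Max absolute disagreement with the brute-force scalar oracles."""
    rng = np.random.default_rng(seed)
    err_d = 0.0
    for _ in range(n_draws):
        v1 = rng.standard_normal(25)
        v2 = rng.standard_normal(25)
        err_d = max(err_d, abs(rep.pair_dissimilarity(v1, v2)
                               - brute_force_dissimilarity(v1, v2)))
    err_t = 0.0
    for _ in range(n_draws):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        t1, _, p1 = paired_t(a, b)
        t2, _, p2 = brute_force_paired_t(a, b)
        err_t = max(err_t, abs(t1 - t2), abs(p1 - p2))
    return {
        "pair_dissimilarity_max_err": err_d,
        "paired_t_max_err": err_t,
        "n_draws": n_draws,
    }
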