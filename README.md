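# wmcircuit

Analysis pipeline for two-region intracranial EEG studies of working
memory: how the amygdala (AMY) and hippocampus (HIP) represent memoranda
in a Sternberg task (loads of 4, 6 or 8 items; 1 s fixation, 2 s
encoding, 3 s maintenance, 2 s retrieval), how information flows between
them, and whether memory load is decodable from those signatures. It is
written for electrophysiologists who have continuous depth-electrode
recordings with channel→region labels and a trial table, and for anyone
who wants to study the behavior of these estimators on simulated ground
truth.

The package provides, as composable library modules with a thin
`wmcircuit` CLI on top:

* **Preprocessing** — zero-phase Hamming-window FIR band-pass, DFT
  line-noise removal, polyphase downsampling, common-average
  re-referencing over clean channels, period epoching, MAD-based
  artifact flagging.
* **Spectral features** — 6-cycle Morlet power at 1 Hz resolution,
  z-scored per channel × frequency against a 1000-replicate bootstrap of
  the 500 ms pre-trial baseline.
* **Representation maps** — with z-scored 1–40 Hz power averaged in
  100 ms windows (10 ms step) and vectorized over channels × frequencies,
  the encoding–encoding dissimilarity between trials i ≠ j,

      EED(w1, w2) = 1 − atanh(ρ_spearman(x_i(w1), x_j(w2))),

  averaged over trial pairs (201 × 201 windows), and the within-trial
  encoding–maintenance similarity EMS(w_e, w_m) = atanh(ρ_spearman),
  averaged over trials (201 × 301 windows). Low EED = trials share a
  representation; high EMS = the encoding pattern persists into
  maintenance.
* **Directed connectivity** — the phase slope index over adjacent 1 Hz
  bins of the Hann-tapered, zero-padded cross-spectrum,
  Ψ(c) = Im Σ_f conj(C(f))·C(f+1), per ipsilateral HIP–AMY channel pair,
  with a 200-shuffle trial-pairing null pooled over pairs;
  z > +1.96 ⇒ hippocampus leads, z < −1.96 ⇒ amygdala leads.
* **Load decoding** — stratified 70/30 splits × 100 repeats,
  standardize + PCA (99% variance) fitted on the training fold only,
  linear SVM (cost 1, one-vs-one); label-permutation tests for contrasts
  between regions or directions.
* **Group statistics** — two-sided cluster-based permutation tests
  (paired t maps, 4-connected clusters, sign-flip max-null) and paired
  t-tests.
* **Synthetic sessions** (`wmcircuit.simulate`) — 1/f noise, item-
  specific oscillatory patterns with per-region distinctiveness δ and
  stability ρ, lagged narrowband inter-regional coupling, and
  multiplicative load gain, all reproducible from one seed, with the
  ground truth returned alongside the recording.

See `docs/methods.md` for the model details, parameter defaults and
known limitations.

## Worked example

Simulate a session in the regime the analysis is designed to detect —
distinct amygdala encoding patterns (δ_AMY = 0.9 vs δ_HIP = 0.2), stable
hippocampal maintenance (ρ_HIP = 0.8 vs ρ_AMY = 0.1), and theta-band
hippocampus→amygdala coupling — then run the pipeline:

```python
import numpy as np
from wmcircuit import (SimConfig, Coupling, synthesize_session, epoch,
                       select_trials, morlet_power, bootstrap_baseline_null,
                       zscore_power, make_window_grid, eed_map, ems_map,
                       slice_period, region_pair_psi, psi_zscore)

cfg = SimConfig(
    n_trials_per_load=10,
    n_channels={"HIP": 2, "AMY": 2},
    rate_hz=200.0,
    delta={"AMY": 0.9, "HIP": 0.2},   # distinct AMY patterns, shared HIP template
    rho={"HIP": 0.8, "AMY": 0.1},     # stable HIP maintenance
    coupling=[Coupling("HIP", "AMY", band_hz=(4, 8), lag_ms=25.0, gain=6.0)],
    seed=42,
)
rec, trials, truth = synthesize_session(cfg)
epochs = epoch(rec, trials)

es = select_trials(epochs["trial"], trials, correct_only=True)
power = morlet_power(es, freqs_hz=np.arange(1.0, 41.0))
null = bootstrap_baseline_null(power, n_boot=1000, seed=42)
zpow = zscore_power(power, null)

grid_enc = make_window_grid(0.0, 2.0, step_s=0.05)
grid_mnt = make_window_grid(0.0, 3.0, step_s=0.05)
for region in ("AMY", "HIP"):
    zr = zpow.select_region(region)
    enc, mnt = slice_period(zr, "encoding"), slice_period(zr, "maintenance")
    eed = eed_map(enc, grid_enc, region=region)
    ems = ems_map(enc, mnt, grid_enc, grid_mnt, region=region)
    print(f"{region}: mean EED = {eed.values.mean():.3f}   "
          f"mean EMS = {ems.values.mean():.3f}")

raw, nulls, freqs = region_pair_psi(select_trials(epochs["encoding"], trials),
                                    n_shuffles=200, seed=42)
res = psi_zscore(raw, nulls, freqs)
theta = (freqs >= 5) & (freqs <= 7)
print(f"PSI z at 5-7 Hz: {np.round(res.z[theta], 1)}  -> {res.direction[5]}")
```

Output:

```
AMY: mean EED = 0.960   mean EMS = 0.054
HIP: mean EED = 0.881   mean EMS = 0.142
PSI z at 5-7 Hz: [2.4 3.5 1.7]  -> HIP_leads
```

Reading it: EED is higher in the amygdala (0.960 > 0.881) — its trial
patterns are more distinct, as configured; EMS is higher in the
hippocampus (0.142 > 0.054) — its encoding pattern persists into
maintenance; and at the center of the coupled theta band the PSI
z-score exceeds +1.96, the hippocampus-leads verdict matching the
injected HIP→AMY delay.

The same stages run from the shell against on-disk artifacts
(float32 `.dat` + JSON sidecar recordings, TSV trial tables, HDF5
epochs/power/maps):

```sh
wmcircuit run-all --demo --out runs/demo        # full pipeline, bundled config
wmcircuit simulate --config cfg.yaml --out sess/
wmcircuit preprocess --in sess/recording.dat --trials sess/trials.tsv \
    --band 1 80 --out sess/epochs.h5
wmcircuit tfr --epochs sess/epochs.h5 --trials sess/trials.tsv \
    --fmax 40 --seed 7 --out sess/power.h5
wmcircuit psi --epochs sess/epochs.h5 --trials sess/trials.tsv \
    --period encoding --seed 7 --out sess/psi.json
```

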