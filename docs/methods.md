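# Methods

`wmcircuit` implements a two-region intracranial-EEG analysis of working
memory: how the amygdala (AMY) and hippocampus (HIP) represent memoranda
during a Sternberg task (loads of 4, 6 or 8 letters; 1 s fixation, 2 s
encoding, 3 s maintenance, 2 s retrieval per trial), how information
flows between them, and whether memory load can be decoded from those
signatures. Because the package is validated end-to-end on synthetic
sessions with known ground truth, this note describes both the analysis
methods and the generative model, and is explicit about what passing the
validation does and does not establish about real recordings.

## Signal conditioning

Continuous multichannel recordings (microvolts, channel-major) pass
through a conventional chain:

* **Band-pass FIR** — odd-length linear-phase Hamming-window design,
  applied by FFT convolution with the group delay compensated, which is
  exactly zero-phase. The order follows from a transition bandwidth of
  25% of the low cutoff (the canonical window-design rule of thumb
  `N ≈ 3.3 / Δf_norm`).
* **Line-noise removal** — per target frequency, a least-squares
  sine/cosine fit over the whole recording (a single-window DFT filter)
  is subtracted; this nulls the target bin while leaving neighbors
  essentially untouched. Window length is the whole recording by
  default because the synthetic mains component is stationary; real
  drifting mains would call for shorter windows.
* **Downsampling** — polyphase anti-aliased resampling
  (`scipy.signal.resample_poly`).
* **Common average reference** — each channel minus the mean of the
  channels flagged clean (unclean channels are re-referenced but never
  contribute to the mean).
* **Epoching** — half-open sample windows `[onset, onset + duration)`
  for the four task periods plus a padded full-trial window (0.5 s
  pre-trial baseline through the end of retrieval) used for
  time-frequency analysis. Trials whose window leaves the recording are
  flagged, not dropped.
* **Artifact rejection** — manual trial review is replaced by a
  reproducible rule: a trial is flagged when any channel's peak absolute
  amplitude exceeds `k` (default 8) times that channel's scaled MAD
  across the epoch set; an external keep-mask can be AND-ed in.

## Time-frequency decomposition and baseline normalization

Power is computed by complex Morlet wavelets with 6 cycles on an integer
frequency grid (1–100 Hz available; the analyses consume 1–40 Hz) at the
native sample resolution, via `mne.time_frequency.tfr_array_morlet`.
Because a 6-cycle wavelet at 1 Hz outlasts any single task period, the
transform runs on the padded full-trial epoch; epochs shorter than the
wavelet support are zero-padded and cropped back. Samples within one
wavelet half-width of the epoch edges are flagged (`edge_mask`);
downstream windows include them by default, with the flag available for
exclusion.

Raw power is normalized per channel and frequency against a bootstrap
null of the pre-trial baseline (the 500 ms before fixation onset): each
of 1000 replicates is the mean of `m` baseline power samples drawn with
replacement from the baseline points pooled across kept trials
(`m` defaults to the number of baseline samples of one trial; a
per-trial pool is available as an option). Every task sample is then
z-scored against the null's mean and standard deviation. The z-score is
invariant to positive rescaling of raw power. A constant baseline raises
a degenerate-baseline error rather than emitting infinities. Note the
finite baseline pool bounds the accuracy of the null mean: the residual
bias of the mean z-score scales as `sqrt(m / pool size)`.

## Representation maps (EED and EMS)

Features are the z-scored 1–40 Hz power of all channels of one region,
averaged within 100 ms sliding windows stepped every 10 ms, vectorized
channel-major. Window centers run from period start to period end
inclusive — 201 windows over the 2 s encoding period and 301 over the
3 s maintenance period — with edge windows drawing on the immediately
adjacent samples of the full-trial tensor.

For two feature vectors, similarity is the Fisher-z-transformed Spearman
correlation, with the correlation clipped to ±(1 − 1e-10) before
`atanh` to avoid infinities on degenerate near-identical vectors; ties
receive average ranks.

* **EED** (encoding–encoding dissimilarity): `1 − atanh(ρ)` between the
  window-w1 features of trial i and the window-w2 features of trial j,
  symmetrized over the two orderings of the unordered pair and averaged
  over trial pairs — a 201×201 map per region. Lower values mean more
  similar (less distinct) trial representations.
* **EMS** (encoding–maintenance similarity): `atanh(ρ)` between a
  trial's encoding-window and maintenance-window features, averaged over
  trials — a 201×301 map per region (a dissimilarity variant `1 − z`
  is available as a switch).

Computation is vectorized: Spearman correlation equals the Pearson
correlation of ranks, so each trial's windowed features are
rank-transformed and standardized once and every window pair reduces to
one matrix product per trial pair; the scalar operation is retained and
the map path is tested against it.

When EED feeds the load decoder, pairs are sampled within load (k = 100
pairs per load by default, without replacement when C(n,2) ≥ k, flagged
otherwise); the region-contrast map uses all correct-trial pairs.

## Phase slope index

Per-trial segments of a hippocampal and an amygdalar channel are Hann
tapered and zero-padded to the smallest multiple of the sampling rate at
least twice the segment length, which places every integer frequency
exactly on the DFT grid (chosen over power-of-two padding precisely for
the exact 1 Hz grid). Cross- and auto-spectra are averaged over trials
into the complex coherency C(f), and

    psi(c) = Im( Σ_{f ∈ [c−h, c+h−1]} conj(C(f)) · C(f+1 Hz) ),

with half-width h = 2 Hz by default (five adjacent 1 Hz bins; the span
is a parameter). Positive values mean the first signal leads; the first
signal is by convention the hippocampal channel. Cross-spectral real and
imaginary parts are computed with explicit real arithmetic so the
identities psi(a, a) = 0 and psi(a, b) = −psi(b, a) hold exactly in
floating point (fused multiply-add in the complex product would break
them). Bands clipped at the 1 or 40 Hz edges are computed on the
available bins and flagged.

Significance uses a trial-shuffle null: the trial pairing between the
two channels is permuted 200 times and the PSI recomputed (auto-spectra
are permutation-invariant, so only the cross-spectrum is redone). Raw
PSI and null replicates are averaged over all ipsilateral channel pairs
(and sessions), and z(f) = (obs − mean_null) / sd_null; |z| > 1.96 is
called directional, z > +1.96 "hippocampus leads", z < −1.96 "amygdala
leads".

**Known limitation.** Under strong zero-lag mixing (a volume-conduction
analogue: one channel containing a large undelayed fraction of the
other), the trial-shuffle null destroys the coherence it should condition
on and underestimates the PSI sampling variance, so |z| exceeds 1.96
more often than 5% even though the statistic stays sign-unbiased. The
directional verdict is protected (no consistent sign arises); the
nominal coverage of the ±1.96 band is only approached when the shared
zero-lag fraction is modest. The test suite asserts the sign-unbiasedness
and near-nominal coverage at a realistic admixture.

## Load decoding

Three-class classification (load 4/6/8) from flattened EED maps (one
sample per trial pair, 40401 features at full resolution), EMS maps (one
sample per trial, 60501 features) or directional PSI vectors (one sample
per channel pair, one feature per frequency bin, the off-direction bins
zero-filled). Each of 100 repeats draws a stratified 70/30 split within
load (training share rounded down), standardizes features and fits a PCA
on the training fold only, keeps components reaching 99% cumulative
explained variance, projects the test fold with the training-fit
transform, and scores a linear SVM (cost 1, one-vs-one). Feature
standardization before PCA is on by default (necessary when feature
scales are mixed, as for PSI) and switchable off. Repeat seeds derive
from one master seed.

Contrasts between two feature sets (regions or directions) use a
label-permutation test: the observed difference of mean accuracies
against 200 recomputations under shuffled load labels, two-sided with
(b+1)/(m+1) smoothing. A one-sided variant against the label-shuffle
null tests a single feature set against chance (1/3).

**Sampling-unit caveat.** Trial-pair samples of the same load share
trials; when per-trial patterns are idiosyncratic, a classifier can
exploit trial identity through that overlap and score above chance even
with no load effect, and the label-permutation null (which breaks the
alignment of overlap with labels) then reads it as significant. Per-trial
units (EMS) are free of this dependency, so the decoder's chance
calibration is validated on EMS features; pair-level EED decoding is
supported as an analysis of its representational structure, not as an
independence-assuming test.

## Group statistics

Paired map comparisons use a two-sided cluster-based permutation test:
pointwise paired t over participants, thresholded at two-sided p < 0.05
(the cluster-forming threshold and permutation count are this package's
declared defaults, exposed as parameters); suprathreshold points are
clustered by 4-connectivity, positive and negative exceedances
separately; each cluster's statistic is its summed t; the null flips
each participant's condition difference (all 2^n assignments enumerated
for n ≤ 12, otherwise random draws) and records the maximum absolute
cluster mass; cluster p-values are (b+1)/(m+1)-smoothed and control the
family-wise error over the map. Scalar summaries use the paired t-test
(identical inputs return t = 0, p = 1 as the limiting case; constant
nonzero differences raise a degenerate-variance error).

## Synthetic sessions

The generator emulates what the analysis assumes, with every source of
randomness derived from one seed:

* **Background** — per-channel 1/f^β Gaussian noise (β = 1, RMS 10 µV)
  plus optional mains sine.
* **Item patterns** — per region, a nonnegative unit-norm amplitude
  vector over channels × integer frequencies 2–40 Hz. Distinctiveness
  δ ∈ [0, 1] mixes a session template with a per-trial independent
  vector (`pattern = normalize((1−δ)·template + δ·independent)`);
  stability ρ ∈ [0, 1] carries the encoding pattern into maintenance the
  same way. Patterns play as sinusoid sums during encoding and
  maintenance with random phases, ±0.5 Hz frequency jitter per
  trial/channel (oscillators do not sit exactly on integer bins; exact
  bins would create artificially coherent single-bin phasors), 50 ms
  on/off ramps, and amplitudes scaled by f^(−β/2) so the induced power
  boost tracks the local background level across the band (flat
  amplitudes would make high-frequency z-scores explode and impose a
  frequency ramp shared by all trials). The base amplitude (35 µV before
  the unit-norm division across ~80 channel×frequency bins) was fixed
  once so that single-window Spearman correlations between trials sit
  mid-range, where both the δ and load knobs are visible.
* **Directed coupling** — narrowband (4th-order Butterworth) Gaussian
  noise injected into the source region and, delayed by `lag_ms`, into
  the target region, with per-channel gain jitter (a uniform ±40%
  factor) so a common average reference cannot cancel the pair into an
  artifactual anti-phase pair. The phase-slope ground truth is the
  analytic ramp 2π·f·lag.
* **Load modulation** — multiplicative pattern-amplitude gain
  {4: 1.0, 6: 1.15, 8: 1.3}; setting all gains equal creates the
  null-load regime used for chance calibration.
* **Timeline** — interleaved loads, the fixed 1/2/3/2 s periods, and a
  2 s inter-trial gap (the real task's ~12 s trial cycle includes a
  self-paced response; compact gaps shorten sessions without touching
  any analyzed window). Correctness is Bernoulli with configurable error
  rate; response times are lognormal; missing response times are stored
  as the sentinel −1.

What the generator does **not** emulate: epileptiform artifacts beyond
amplitude outliers, non-stationary noise spectra, cross-frequency
coupling, volume-conducted common sources (couplings are injected
per-region), and electrode geometry. Passing the validation therefore
shows that the pipeline recovers the statistical structure it targets
when that structure is present as modeled — not that real amygdala or
hippocampal recordings contain it.

## Validation experiments and problem sizes

The validation suite (`wmcircuit.experiments`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) runs on reduced
problem sizes chosen for single-CPU minutes, as rates and error
probabilities do not depend on them:

* sessions at 200 Hz with two channels per region (matched counts
  isolate the regional parameter contrast), recovery maps on a 50 ms
  window step (41×61 windows) instead of the 10 ms analysis default;
* **PSI recovery** — 20 sessions (30 trials each) with HIP→AMY coupling
  at 4–8 Hz (25 ms lag) and AMY→HIP at 20–28 Hz (18 ms lag); recovery is
  scored at centers whose whole ±2 Hz integration band lies inside the
  coupled band (edge centers mix coupled and uncoupled bins and are
  attenuated by construction); 20 no-coupling sessions measure the
  false-positive rate, expected near 5%;
* **representation recovery** — 20 sessions in the regime
  δ_AMY = 0.9, δ_HIP = 0.2, ρ_HIP = 0.8, ρ_AMY = 0.1 (36 trials each);
  mean EED must rank AMY above HIP and mean EMS must rank HIP above AMY;
* **decoder calibration** — per-trial EMS features (hippocampus) from 4
  sessions × 72 trials, on 300 ms windows (8 × 11 window pairs); chance
  is reported as the mean of the label-permutation null (a single
  shuffled labeling can align with session structure by chance and is
  not a calibrated chance estimate); the flat-gain regime must not beat
  chance and the default gains must (99-permutation test, 25 repeats
  inside the permutation loops). Three small-sample effects shaped this
  design: the multiplicative load gain acts on rank-correlation features
  only through SNR-dependent attenuation (its effect on mean EMS peaks
  at the default pattern amplitude and vanishes toward saturation);
  small session-by-load cells induce a finite-pool anticorrelation
  between the train and test trials of a cell through shared session
  noise (hence 24 trials per load per session); and per-window-pair
  estimation noise dilutes the common-mode load signal in
  high-dimensional maps (hence the wider validation windows — the full
  100 ms/10 ms grids remain the analysis defaults);
* **cluster-test error control** — 200 null experiments on 40×40 maps,
  10 participants (sign flips fully enumerated), family-wise error near
  5%; scalar operations (pair dissimilarity, paired t) are checked
  against brute-force oracles to 1e-10.
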