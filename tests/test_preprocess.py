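import numpy as np
import pytest
from scipy import signal as sps

from wmcircuit.datatypes import Recording, ValidationError
from wmcircuit.preprocess import (
    bandpass_fir,
    downsample,
    epoch,
    reject_artifact_trials,
    remove_line_noise,
    rereference_common_average,
    select_trials,
)
from wmcircuit.simulate import SimConfig, generate_trial_table, synthesize_session


def _mono(samples, rate_hz):
    samples = np.atleast_2d(samples)
    names = [f"HIP{i}" for i in range(samples.shape[0] - 1)] + ["AMY1"]
    regions = {n: ("AMY" if n.startswith("AMY") else "HIP") for n in names}
    return Recording(samples=samples, rate_hz=rate_hz, channel_names=names,
                     channel_region=regions)


def _band_power(x, rate, f, width=0.5):
    freqs, pxx = sps.periodogram(x, fs=rate)
    sel = (freqs >= f - width) & (freqs <= f + width)
    return pxx[sel].sum()


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        rate = 1000.0
        t = np.arange(int(10 * rate)) / rate
        rec = _mono(np.sin(2 * np.pi * 50 * t), rate)
        out = bandpass_fir(rec, 1.0, 200.0)
        mid = slice(2000, -2000)
        ratio = out.samples[0, mid].std() / rec.samples[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_drift_attenuated(self):
        rate = 1000.0
        t = np.arange(int(40 * rate)) / rate
        rec = _mono(np.sin(2 * np.pi * 0.1 * t), rate)
        out = bandpass_fir(rec, 1.0, 200.0)
        atten_db = 20 * np.log10(rec.samples.std() / out.samples.std())
        assert atten_db > 20

    def test_zero_phase_symmetric_impulse(self):
        rate = 1000.0
        x = np.zeros(20001)
        x[10000] = 1.0
        out = bandpass_fir(_mono(x, rate), 1.0, 200.0)
        resp = out.samples[0]
        w = 3000
        seg = resp[10000 - w:10000 + w + 1]
        assert np.allclose(seg, seg[::-1], atol=1e-10)

    def test_high_cutoff_above_nyquist_rejected(self):
        rec = _mono(np.zeros(1000), 200.0)
        with pytest.raises(ValidationError):
            bandpass_fir(rec, 1.0, 120.0)


class TestLineNoise:
    def test_line_component_removed(self):
        rate = 1000.0
        rng = np.random.default_rng(0)
        t = np.arange(int(10 * rate)) / rate
        x = 5 * np.sin(2 * np.pi * 50 * t + 0.7) + rng.standard_normal(t.size)
        out = remove_line_noise(_mono(x, rate), [50.0])
        before = _band_power(x, rate, 50.0)
        after = _band_power(out.samples[0], rate, 50.0)
        assert 10 * np.log10(before / after) >= 20
        # neighboring frequencies essentially untouched
        for f in (48.0, 52.0):
            b = _band_power(x, rate, f)
            a = _band_power(out.samples[0], rate, f)
            assert abs(a - b) / b < 0.05

    def test_near_identity_without_line_component(self):
        rate = 1000.0
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(80 * rate))
        out = remove_line_noise(_mono(x, rate), [50.0, 100.0])
        assert np.sqrt(np.mean((out.samples[0] - x) ** 2)) / x.std() < 0.01

    def test_harmonics_all_attenuated(self):
        rate = 1000.0
        rng = np.random.default_rng(2)
        t = np.arange(int(10 * rate)) / rate
        x = rng.standard_normal(t.size)
        for f in (50, 100, 150):
            x = x + 3 * np.sin(2 * np.pi * f * t + f)
        out = remove_line_noise(_mono(x, rate), [50.0, 100.0, 150.0])
        for f in (50, 100, 150):
            drop = _band_power(x, rate, f) / _band_power(out.samples[0], rate, f)
            assert 10 * np.log10(drop) >= 20


class TestDownsample:
    def test_sine_amplitude_preserved(self):
        rate = 4000.0
        t = np.arange(int(4 * rate)) / rate
        rec = _mono(np.sin(2 * np.pi * 10 * t), rate)
        out = downsample(rec, 1000.0)
        assert out.rate_hz == 1000.0
        assert out.samples[0].std() == pytest.approx(rec.samples[0].std(), rel=0.02)

    def test_output_length(self):
        rec = _mono(np.zeros(10001), 4000.0)
        out = downsample(rec, 1000.0)
        assert abs(out.n_samples - 10001 * 1000 // 4000) <= 1

    def test_upsampling_rejected(self):
        with pytest.raises(ValidationError):
            downsample(_mono(np.zeros(100), 1000.0), 2000.0)


class TestRereference:
    def test_identical_clean_channels_become_zero(self):
        x = np.vstack([np.sin(np.arange(100.0))] * 2)
        out = rereference_common_average(_mono(x, 100.0))
        assert np.allclose(out.samples, 0.0)

    def test_clean_mean_is_zero_after(self):
        rng = np.random.default_rng(3)
        out = rereference_common_average(_mono(rng.standard_normal((4, 500)), 100.0))
        assert np.allclose(out.samples[out.channel_clean].mean(axis=0), 0.0)

    def test_unclean_channel_excluded_from_mean(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((3, 200))
        rec = _mono(x, 100.0)
        rec.channel_clean[0] = False
        out = rereference_common_average(rec)
        expected = x - x[1:].mean(axis=0, keepdims=True)
        assert np.allclose(out.samples, expected)

    def test_needs_two_clean_channels(self):
        rec = _mono(np.zeros((2, 100)), 100.0)
        rec.channel_clean[0] = False
        with pytest.raises(ValidationError):
            rereference_common_average(rec)


class TestEpoching:
    def test_period_sample_counts(self, small_session):
        rec, tt, _ = small_session  # 200 Hz
        epochs = epoch(rec, tt)
        assert epochs["fixation"].data.shape[2] == 200
        assert epochs["encoding"].data.shape[2] == 400
        assert epochs["maintenance"].data.shape[2] == 600
        assert epochs["retrieval"].data.shape[2] == 400
        assert epochs["trial"].data.shape[2] == 1700  # 0.5 s baseline + 8 s trial

    def test_edge_trial_flagged_not_dropped(self, small_session):
        rec, tt, _ = small_session
        short = rec.copy_with(rec.samples[:, :int(tt["t_probe"].iloc[-1] * rec.rate_hz)])
        epochs = epoch(short, tt)
        assert not epochs["retrieval"].kept_mask[-1]
        assert epochs["retrieval"].kept_mask[:-1].all()
        assert epochs["retrieval"].data.shape[0] == len(tt)

    def test_epoch_values_match_recording(self, small_session):
        rec, tt, _ = small_session
        es = epoch(rec, tt)["encoding"]
        i0 = int(round(tt["t_encoding"].iloc[0] * rec.rate_hz))
        assert np.array_equal(es.data[0], rec.samples[:, i0:i0 + 400])


class TestTrialSelection:
    def test_correct_only(self):
        cfg = SimConfig(n_trials_per_load=10, n_channels={"HIP": 2, "AMY": 2},
                        rate_hz=200.0, p_incorrect=0.15, seed=6)
        rec, tt, _ = synthesize_session(cfg)
        es = epoch(rec, tt)["encoding"]
        kept = select_trials(es, tt, correct_only=True)
        assert kept.n_trials == int(tt["correct"].sum())

    def test_load_subset(self, small_session):
        rec, tt, _ = small_session
        es = epoch(rec, tt)["encoding"]
        kept = select_trials(es, tt, correct_only=False, loads={6, 8})
        assert kept.n_trials == 8

    def test_empty_load_set_rejected(self, small_session):
        rec, tt, _ = small_session
        es = epoch(rec, tt)["encoding"]
        with pytest.raises(ValidationError):
            select_trials(es, tt, loads=set())


def test_artifact_rejection_flags_outlier_trial(small_session):
    rec, tt, _ = small_session
    es = epoch(rec, tt)["trial"]
    es.data[2, 0, 100:130] += 100 * np.abs(es.data).max()
    out = reject_artifact_trials(es, k_mad=8.0)
    assert not out.kept_mask[2]
    assert out.kept_mask.sum() >= es.n_trials - 2
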