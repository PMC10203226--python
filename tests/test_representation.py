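import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmcircuit.datatypes import PowerTensor, ValidationError
from wmcircuit.experiments import brute_force_dissimilarity, region_maps, _zscored_power
from wmcircuit.representation import (
    eed_map,
    ems_map,
    feature_matrix,
    make_window_grid,
    pair_dissimilarity,
    sample_trial_pairs,
    window_features,
)
from wmcircuit.simulate import SimConfig, synthesize_session


def _zpow(values, rate=100.0, t0=0.0):
    n_tr, n_ch, n_f, n_t = values.shape
    names = [f"HIP{i}" for i in range(n_ch)]
    return PowerTensor(
        values=values, freqs_hz=np.arange(1.0, n_f + 1.0),
        time_s=t0 + np.arange(n_t) / rate, rate_hz=rate,
        trial_ids=np.arange(n_tr), channel_names=names,
        channel_region={n: "HIP" for n in names}, zscored=True,
    )


class TestWindowGrid:
    def test_canonical_counts(self):
        assert make_window_grid(0.0, 2.0).n_windows == 201
        assert make_window_grid(0.0, 3.0).n_windows == 301

    def test_small_grid(self):
        grid = make_window_grid(0.0, 0.1, step_s=0.05)
        assert np.allclose(grid.centers_s, [0.0, 0.05, 0.1])

    def test_bad_step_rejected(self):
        with pytest.raises(ValidationError):
            make_window_grid(0.0, 1.0, step_s=0.0)


class TestWindowFeatures:
    def test_vector_length_is_channels_times_freqs(self):
        z = _zpow(np.random.default_rng(0).standard_normal((3, 2, 40, 100)))
        feats = window_features(z, 0.5)
        assert feats.shape == (3, 80)

    def test_constant_power(self):
        z = _zpow(np.full((2, 1, 5, 100), 3.14))
        assert np.allclose(window_features(z, 0.5), 3.14)

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(1)
        z = _zpow(rng.standard_normal((2, 2, 6, 100)))
        center, width = 0.5, 0.1
        feats = window_features(z, center, width_s=width)
        sel = (z.time_s >= center - width / 2 - 1e-9) & (
            z.time_s <= center + width / 2 + 1e-9)
        expected = z.values[..., sel].mean(axis=-1).reshape(2, -1)
        assert np.allclose(feats, expected, atol=1e-12)

    def test_window_outside_epoch_rejected(self):
        z = _zpow(np.ones((2, 1, 5, 100)))
        with pytest.raises(ValidationError):
            window_features(z, 5.0)


class TestPairDissimilarity:
    def test_zero_rank_correlation_gives_one(self):
        assert pair_dissimilarity([1, 2, 3, 4], [2, 4, 1, 3]) == pytest.approx(1.0)

    def test_known_rho(self):
        # perfectly anticorrelated ranks: rho = -1 (clipped)
        v = np.arange(10.0)
        d = pair_dissimilarity(v, -v)
        assert d == pytest.approx(1.0 + np.arctanh(1 - 1e-10))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pair_dissimilarity([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_rank_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        v1 = rng.standard_normal(n)
        v2 = rng.standard_normal(n)
        if rng.random() < 0.3:  # exercise tie handling
            v1 = np.round(v1, 1)
            v2 = np.round(v2, 1)
        assert pair_dissimilarity(v1, v2) == pytest.approx(
            brute_force_dissimilarity(v1, v2), abs=1e-12)


class TestEEDMap:
    def test_identical_trials_minimal_dissimilarity(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((1, 2, 10, 100))
        vals = np.repeat(base, 6, axis=0) + 1e-6 * rng.standard_normal((6, 2, 10, 100))
        grid = make_window_grid(0.0, 0.9, width_s=0.1, step_s=0.1)
        m = eed_map(_zpow(vals), grid)
        # rho ~ 1 -> 1 - atanh(rho) strongly negative
        assert np.diag(m.values).max() < -5.0

    def test_independent_trials_near_one(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((18, 2, 20, 100))  # 153 pairs
        grid = make_window_grid(0.0, 0.9, width_s=0.1, step_s=0.1)
        m = eed_map(_zpow(vals), grid)
        assert abs(m.values.mean() - 1.0) < 0.05

    def test_map_is_symmetric(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((5, 2, 10, 100))
        grid = make_window_grid(0.0, 0.9, width_s=0.1, step_s=0.1)
        m = eed_map(_zpow(vals), grid)
        assert np.allclose(m.values, m.values.T, atol=1e-12)

    def test_matches_scalar_op_on_tiny_grid(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((3, 1, 8, 50))
        z = _zpow(vals, rate=100.0)
        grid = make_window_grid(0.0, 0.4, width_s=0.1, step_s=0.2)
        m = eed_map(z, grid)
        feats = feature_matrix(z, grid)
        pairs = [(0, 1), (0, 2), (1, 2)]
        for wi, wj in [(0, 1), (2, 0)]:
            expected = np.mean([
                0.5 * (pair_dissimilarity(feats[i, wi], feats[j, wj])
                       + pair_dissimilarity(feats[j, wi], feats[i, wj]))
                for i, j in pairs
            ])
            assert m.values[wi, wj] == pytest.approx(expected, abs=1e-10)


class TestEMSMap:
    def test_identical_encoding_and_maintenance(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((4, 2, 10, 100))
        z = _zpow(vals)
        grid = make_window_grid(0.0, 0.9, width_s=0.1, step_s=0.1)
        m = ems_map(z, z, grid, grid)
        assert np.diag(m.values).min() > 5.0  # atanh(clipped rho=1)

    def test_independent_periods_near_zero(self):
        rng = np.random.default_rng(7)
        enc = _zpow(rng.standard_normal((120, 2, 20, 40)), rate=100.0)
        mnt = _zpow(rng.standard_normal((120, 2, 20, 40)), rate=100.0)
        grid = make_window_grid(0.0, 0.3, width_s=0.1, step_s=0.1)
        m = ems_map(enc, mnt, grid, grid)
        assert abs(m.values.mean()) < 0.05

    def test_trial_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        enc = _zpow(rng.standard_normal((4, 1, 5, 50)))
        mnt = _zpow(rng.standard_normal((5, 1, 5, 50)))
        grid = make_window_grid(0.0, 0.4, width_s=0.1, step_s=0.2)
        with pytest.raises(ValidationError):
            ems_map(enc, mnt, grid, grid)


class TestSampleTrialPairs:
    def test_without_replacement(self):
        pairs, flagged = sample_trial_pairs(20, k=100, seed=0)
        assert pairs.shape == (100, 2)
        assert not flagged
        assert len({tuple(p) for p in pairs.tolist()}) == 100

    def test_with_replacement_flagged(self):
        pairs, flagged = sample_trial_pairs(5, k=100, seed=0)
        assert flagged and pairs.shape == (100, 2)

    def test_deterministic(self):
        p1, _ = sample_trial_pairs(12, k=30, seed=7)
        p2, _ = sample_trial_pairs(12, k=30, seed=7)
        assert np.array_equal(p1, p2)

    def test_too_few_trials(self):
        with pytest.raises(ValidationError):
            sample_trial_pairs(1, k=10)


class TestMonotonicity:
    """Mean EED rises with distinctiveness delta; mean EMS with stability rho."""

    @staticmethod
    def _session_summary(delta, rho, seed=21):
        cfg = SimConfig(
            n_trials_per_load=4,
            n_channels={"HIP": 2, "AMY": 2},
            rate_hz=200.0,
            delta={"AMY": delta, "HIP": delta},
            rho={"AMY": rho, "HIP": rho},
            seed=seed,
        )
        rec, tt, _ = synthesize_session(cfg)
        z = _zscored_power(rec, tt, n_boot=150, seed=seed)
        eed_a, ems_a = region_maps(z, "AMY")
        eed_h, ems_h = region_maps(z, "HIP")
        return (eed_a + eed_h) / 2, (ems_a + ems_h) / 2

    def test_eed_monotone_in_delta(self):
        eeds = [self._session_summary(d, 0.5)[0] for d in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert np.all(np.diff(eeds) > 0)

    def test_ems_monotone_in_rho(self):
        emss = [self._session_summary(0.5, r)[1] for r in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert np.all(np.diff(emss) > 0)


def test_exchangeable_regions_unbiased():
    """With equal delta/rho the paired EED region difference is centered on 0."""
    diffs = []
    for seed in range(20):
        cfg = SimConfig(
            n_trials_per_load=4,
            n_channels={"HIP": 2, "AMY": 2},
            rate_hz=200.0,
            delta={"AMY": 0.5, "HIP": 0.5},
            rho={"AMY": 0.5, "HIP": 0.5},
            seed=1000 + seed,
        )
        rec, tt, _ = synthesize_session(cfg)
        z = _zscored_power(rec, tt, n_boot=100, seed=seed)
        eed_a, _ = region_maps(z, "AMY")
        eed_h, _ = region_maps(z, "HIP")
        diffs.append(eed_a - eed_h)
    n_pos = int(np.sum(np.array(diffs) > 0))
    # two-sided sign test at alpha 0.01 for n=20: reject only if <=3 or >=17
    assert 3 < n_pos < 17
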