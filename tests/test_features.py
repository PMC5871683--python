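"""Fingerprint features against brute-force oracles and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from icfp.features import (
    FEATURE_NAMES,
    ArtifactTemplate,
    EpochPlan,
    band_power_fractions,
    build_template,
    cardiac_identification,
    entropy_feature,
    eye_movement_template,
    eyeblink_template,
    fingerprint_dataset,
    max_epoch_variance,
    myogenic_identification,
    normalize_within_dataset,
    spatial_average_difference,
    spatial_eye_difference,
    template_correlation,
    temporal_kurtosis,
)
from icfp.montage import ElectrodeMontage, make_quasi_equidistant_montage
from icfp.preprocess import ICDecomposition


def sine(freq, fs, seconds):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestTemporalKurtosis:
    def test_gaussian_noise_near_zero(self, rng):
        tc = rng.standard_normal(int(120 * 64))
        assert temporal_kurtosis(tc, 64.0) < 0.3

    def test_spiky_signal_positive(self):
        tc = np.zeros(64 * 20)
        tc[::320] = 50.0
        assert temporal_kurtosis(tc, 64.0) > 1.0

    def test_matches_moment_oracle(self, rng):
        tc = rng.standard_normal(int(16 * 13.7)) * 7 + 2
        got = temporal_kurtosis(tc, 16.0)
        assert got == pytest.approx(oracles.kurtosis_oracle(tc, 16.0), rel=1e-9)

    def test_negative_kurtosis_clamped(self):
        # a pure sine has negative excess kurtosis (-1.5)
        assert temporal_kurtosis(sine(2.0, 64.0, 10.0), 64.0) == 0.0

    def test_scale_invariant(self, rng):
        tc = rng.standard_normal(16 * 20)
        a = temporal_kurtosis(tc, 16.0)
        b = temporal_kurtosis(1000 * tc, 16.0)
        assert a == pytest.approx(b, rel=1e-9)


class TestMaxEpochVariance:
    def test_uniform_epochs_give_one(self):
        tc = np.tile(sine(2.0, 64.0, 5.0), 5)  # identical 5 s epochs, hop 4 s
        assert max_epoch_variance(tc, 64.0) == pytest.approx(1.0, rel=1e-6)

    def test_one_loud_epoch_exceeds_one(self, rng):
        tc = rng.standard_normal(64 * 41)
        tc[64 * 20 : 64 * 25] *= 3
        assert max_epoch_variance(tc, 64.0) > 1.5

    def test_matches_variance_oracle(self, rng):
        tc = rng.standard_normal(int(8 * 13))  # 3 epochs at fs=8
        got = max_epoch_variance(tc, 8.0)
        assert got == pytest.approx(oracles.mev_oracle(tc, 8.0), rel=1e-9)

    def test_all_zero_gives_zero(self):
        assert max_epoch_variance(np.zeros(64 * 20), 64.0) == 0.0


def toy_montage():
    """Six electrodes: 2 frontal (FA), 2 outer-ring (PA), 1 LE, 1 RE."""
    return ElectrodeMontage(
        labels=("F1", "F2", "P1", "P2", "L1", "R1"),
        theta=np.array([-20.0, 20.0, 110.0, -110.0, -45.0, 45.0]),
        # LE/RE radius below 0.4 keeps them out of the FA region
        radius=np.array([0.6, 0.6, 1.0, 1.0, 0.35, 0.35]),
    )


class TestSpatialFeatures:
    def test_all_zero_weights_give_zero(self):
        m = toy_montage()
        assert spatial_average_difference(np.zeros(6), m) == 0.0
        assert spatial_eye_difference(np.zeros(6), m) == 0.0

    def test_frontal_map_positive_sad(self):
        m = toy_montage()
        w = np.array([5.0, 4.0, 0.1, -0.1, 2.0, 2.0])
        sad = spatial_average_difference(w, m)
        assert sad == pytest.approx(abs((5 + 4) / 2) - abs((0.1 - 0.1) / 2), rel=1e-9)

    def test_posterior_map_zeroed_by_variance_guard(self):
        m = toy_montage()
        w = np.array([0.1, 0.1, 6.0, -5.0, 0.5, 0.5])
        assert spatial_average_difference(w, m) == 0.0

    def test_opposite_le_re_sign_zeroes_sad(self):
        m = toy_montage()
        w = np.array([5.0, 4.0, 0.1, -0.1, 2.0, -2.0])
        assert spatial_average_difference(w, m) == 0.0

    def test_dipolar_map_positive_sed(self):
        m = toy_montage()
        w = np.array([0.0, 0.0, 0.0, 0.0, 3.0, -2.0])
        assert spatial_eye_difference(w, m) == pytest.approx(5.0, rel=1e-9)

    def test_same_sign_le_re_zeroes_sed(self):
        m = toy_montage()
        w = np.array([0.0, 0.0, 0.0, 0.0, 3.0, 2.0])
        assert spatial_eye_difference(w, m) == 0.0


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([2.0, 1.0, 0.0], [1.0, 0.5, 0.0]),
            ([0.0, 0.0], [0.0, 0.0]),
            ([0.37], [1.0]),
        ],
    )
    def test_examples(self, raw, expected):
        np.testing.assert_allclose(normalize_within_dataset(np.array(raw)), expected)

    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_result_in_unit_interval_with_max_one(self, raw):
        out = normalize_within_dataset(np.array(raw))
        assert np.all((out >= 0) & (out <= 1))
        if max(raw) > 0:
            assert out.max() == pytest.approx(1.0)


class TestBandPower:
    def test_alpha_tone_concentrates(self):
        fr = band_power_fractions(sine(10.0, 256.0, 8.0), 256.0)
        assert fr["PSD_ALPHA"] >= 0.95
        assert all(v <= 0.05 for k, v in fr.items() if k != "PSD_ALPHA")

    def test_fractions_sum_to_one(self, rng):
        fr = band_power_fractions(rng.standard_normal(256 * 8), 256.0)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-6)

    def test_matches_manual_welch_oracle(self, rng):
        tc = sine(2.0, 256.0, 8.0) + sine(30.0, 256.0, 8.0) + 0.1 * rng.standard_normal(2048)
        got = band_power_fractions(tc, 256.0)
        ref = oracles.band_fraction_oracle(tc, 256.0)
        np.testing.assert_allclose([got[k] for k in got], ref, rtol=1e-9)

    def test_zero_signal_all_zero(self):
        fr = band_power_fractions(np.zeros(2048), 256.0)
        assert all(v == 0.0 for v in fr.values())


class TestMIF:
    def test_low_band_tone_zero(self):
        assert myogenic_identification(sine(5.0, 256.0, 8.0), 256.0) == 0.0

    def test_high_band_tone_near_one(self):
        assert myogenic_identification(sine(60.0, 256.0, 8.0), 256.0) > 0.97

    def test_matches_band_integration_oracle(self):
        tc = sine(2.0, 256.0, 8.0) + np.sqrt(3.0) * sine(40.0, 256.0, 8.0)
        got = myogenic_identification(tc, 256.0)
        assert got == pytest.approx(oracles.mif_oracle(tc, 256.0), rel=1e-9)
        assert got == pytest.approx(0.75, abs=0.01)


def spike_train(rate_hz, fs, seconds, keep_every=1):
    t = np.arange(int(seconds * fs)) / fs
    events = np.arange(0.5, seconds - 0.5, 1.0 / rate_hz)[::keep_every]
    tc = np.zeros(t.size)
    width = int(0.05 * fs)
    kernel = np.exp(-0.5 * ((np.arange(-3 * width, 3 * width + 1)) / width) ** 2)
    for ev in events:
        c = int(ev * fs)
        lo, hi = c - 3 * width, c + 3 * width + 1
        if lo >= 0 and hi <= tc.size:
            tc[lo:hi] += kernel
    return tc, events


class TestCIF:
    def test_periodic_train_near_one(self):
        tc, events = spike_train(1.5, 128.0, 30.0)
        cif = cardiac_identification(tc, 128.0)
        # counting oracle: every planted beat found, expected = floor(30 * 1.5)
        assert cif == pytest.approx(len(events) / np.floor(30 * 1.5), abs=0.1)
        assert cif == pytest.approx(1.0, abs=0.1)

    def test_broadband_noise_zero(self, rng):
        assert cardiac_identification(rng.standard_normal(128 * 30), 128.0) == 0.0

    def test_half_deleted_train_half_score(self):
        tc, events = spike_train(1.5, 128.0, 30.0, keep_every=2)
        cif = cardiac_identification(tc, 128.0)
        assert cif == pytest.approx(len(events) / np.floor(30 * 1.5), abs=0.1)
        assert cif == pytest.approx(0.5, abs=0.1)


class TestTemplateCorrelation:
    def test_tiled_template_perfect_alignments(self):
        tmpl = eyeblink_template(64.0)
        tc = np.tile(tmpl.waveform, 4)
        from icfp.features import sliding_correlation

        r = sliding_correlation(tc, tmpl, 64.0)
        # perfect alignments at each tile offset correlate exactly 1
        for k in range(3):
            assert r[k * tmpl.waveform.size] == pytest.approx(1.0, abs=1e-9)
        # the feature averages every retained window, all >= the threshold
        score = template_correlation(tc, 64.0, tmpl)
        assert 0.65 <= score <= 1.0
        assert score == pytest.approx(
            oracles.template_corr_oracle(tc, tmpl.waveform), rel=1e-9
        )

    def test_white_noise_below_threshold_zero(self, rng):
        tmpl = eyeblink_template(64.0)
        tc = rng.standard_normal(64 * 8)
        assert template_correlation(tc, 64.0, tmpl) == 0.0

    def test_matches_dense_scan_oracle(self, rng):
        fs = 32.0
        tmpl = eyeblink_template(fs)
        tc = 0.5 * rng.standard_normal(int(7 * fs))
        start = int(1.5 * fs)
        tc[start : start + tmpl.waveform.size] += tmpl.waveform
        got = template_correlation(tc, fs, tmpl)
        ref = oracles.template_corr_oracle(tc, tmpl.waveform, threshold=0.65)
        assert got == pytest.approx(ref, rel=1e-9)
        # the full |r| profile matches sample for sample
        from icfp.features import sliding_correlation

        np.testing.assert_allclose(
            sliding_correlation(tc, tmpl, fs),
            oracles.sliding_corr_oracle(tc, tmpl.waveform),
            atol=1e-9,
        )

    def test_sign_symmetric(self, rng):
        fs = 32.0
        tmpl = eye_movement_template(fs)
        tc = rng.standard_normal(int(6 * fs))
        a = template_correlation(tc, fs, tmpl)
        b = template_correlation(-tc, fs, tmpl)
        assert a == pytest.approx(b, abs=1e-12)


class TestBuildTemplate:
    def test_single_exemplar_identity(self):
        fs = 64.0
        ex = eyeblink_template(fs).waveform + 0.5
        tmpl = build_template([ex], fs)
        np.testing.assert_allclose(tmpl.waveform, ex - ex.mean(), atol=1e-12)

    def test_duplicate_exemplars_idempotent(self):
        fs = 64.0
        ex = eyeblink_template(fs).waveform
        one = build_template([ex], fs)
        two = build_template([ex, ex.copy()], fs)
        np.testing.assert_allclose(one.waveform, two.waveform, atol=1e-12)

    def test_noisy_exemplars_average_to_pulse(self, rng):
        fs = 64.0
        clean = eyeblink_template(fs).waveform
        exemplars = [clean + 0.02 * rng.standard_normal(clean.size) for _ in range(20)]
        tmpl = build_template(exemplars, fs)
        r = np.corrcoef(tmpl.waveform, clean)[0, 1]
        assert abs(r) > 0.99


class TestEntropyFeature:
    def test_iid_ics_mostly_zero(self, rng):
        tcs = rng.standard_normal((8, int(64 * 50)))
        ef = entropy_feature(tcs, 64.0)
        assert np.mean(ef == 0) > 0.6  # the 0.2 floor suppresses null ICs

    def test_outlier_ic_scores_one(self, rng):
        n = int(64 * 50)
        tcs = rng.standard_normal((6, n))
        # rare huge spikes widen the range so the histogram mass collapses
        # into a few central bins: far lower entropy in every segment
        tcs[0, ::50] *= 100.0
        ef = entropy_feature(tcs, 64.0)
        assert ef[0] == 1.0

    def test_matches_hand_computed_oracle(self, rng):
        tcs = rng.standard_normal((3, int(16 * 25)))  # 3 ICs x 5 segments at fs=16
        got = entropy_feature(tcs, 16.0)
        ref = oracles.entropy_feature_oracle(tcs, 16.0)
        np.testing.assert_allclose(got, ref, rtol=1e-9, atol=1e-12)

    def test_single_ic_warns_and_zeroes(self, rng):
        with pytest.warns(UserWarning, match=">= 2 ICs"):
            ef = entropy_feature(rng.standard_normal((1, 16 * 25)), 16.0)
        assert ef.tolist() == [0.0]


def random_decomposition(rng, n_ics=8, n_elec=16, fs=128.0, seconds=25.0):
    return ICDecomposition(
        weights=rng.standard_normal((n_elec, n_ics)),
        timecourses=rng.standard_normal((n_ics, int(fs * seconds))),
        fs=fs,
        montage=make_quasi_equidistant_montage(n_elec),
        dataset_id="rand",
    )


class TestFingerprintDataset:
    def test_feature_order_and_shape(self, rng):
        d = random_decomposition(rng)
        fp = fingerprint_dataset(d)
        assert list(fp.columns) == ["dataset_id", "ic_id", *FEATURE_NAMES]
        assert len(fp) == d.n_ics

    def test_row_permutation_equivariance(self, rng):
        d = random_decomposition(rng)
        fp = fingerprint_dataset(d)
        perm = rng.permutation(d.n_ics)
        d2 = ICDecomposition(
            weights=d.weights[:, perm],
            timecourses=d.timecourses[perm],
            fs=d.fs,
            montage=d.montage,
            dataset_id="rand",
        )
        fp2 = fingerprint_dataset(d2)
        np.testing.assert_allclose(
            fp2[list(FEATURE_NAMES)].to_numpy(),
            fp.iloc[perm][list(FEATURE_NAMES)].to_numpy(),
            rtol=1e-9,
            atol=1e-12,
        )

    def test_tc_scaling_leaves_scale_free_features(self, rng):
        d = random_decomposition(rng)
        fp = fingerprint_dataset(d)
        d2 = ICDecomposition(
            weights=d.weights * 3.5,
            timecourses=d.timecourses * 40.0,
            fs=d.fs,
            montage=d.montage,
            dataset_id="rand",
        )
        fp2 = fingerprint_dataset(d2)
        for col in ("K", "MEV", "SAD", "SED", "PSD_DELTA", "PSD_THETA",
                    "PSD_ALPHA", "PSD_BETA", "PSD_GAMMA", "MIF"):
            np.testing.assert_allclose(
                fp2[col].to_numpy(), fp[col].to_numpy(), rtol=1e-7, atol=1e-9
            )
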