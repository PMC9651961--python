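"""Semipartial connectivity: masks, filtering, residualization, Fisher z."""

import numpy as np
import pytest

import transfc as tf


def _run_from_series(series_matrix, tr=1.0):
    """Stack 1D series into a (k,1,1,T) BoldRun."""
    arr = np.asarray(series_matrix, dtype=float)
    return tf.BoldRun(data=arr.reshape(arr.shape[0], 1, 1, arr.shape[1]),
                      tr_seconds=tr)


class TestIntensityExclude:
    def test_low_intensity_voxel_removed(self):
        # nine voxels with mean 10, one with mean 0: sample SD over voxel
        # means = sqrt(10) -> threshold 9 - 2*3.162 = 2.68 -> drop the zero
        data = np.full((10, 1, 1, 20), 10.0)
        data[3] = 0.0
        run = tf.BoldRun(data=data, tr_seconds=1.0)
        mask = np.ones((10, 1, 1), dtype=bool)
        kept = tf.intensity_exclude(mask, run, k_sd=2.0)
        assert kept.sum() == 9
        assert not kept[3, 0, 0]

    def test_uniform_means_nothing_excluded(self):
        run = tf.BoldRun(data=np.full((6, 1, 1, 20), 5.0), tr_seconds=1.0)
        mask = np.ones((6, 1, 1), dtype=bool)
        assert tf.intensity_exclude(mask, run, 2.0).sum() == 6

    def test_infinite_k_disables_exclusion(self):
        data = np.full((10, 1, 1, 20), 10.0)
        data[3] = -1000.0
        run = tf.BoldRun(data=data, tr_seconds=1.0)
        mask = np.ones((10, 1, 1), dtype=bool)
        np.testing.assert_array_equal(tf.intensity_exclude(mask, run, np.inf),
                                      mask)

    def test_empty_mask_rejected(self):
        run = tf.BoldRun(data=np.zeros((2, 1, 1, 5)), tr_seconds=1.0)
        with pytest.raises(tf.InvalidInputError):
            tf.intensity_exclude(np.zeros((2, 1, 1), dtype=bool), run)


class TestMeanTimeseries:
    def test_single_voxel_identity(self, rng):
        data = rng.normal(size=(3, 1, 1, 15))
        run = tf.BoldRun(data=data, tr_seconds=1.0)
        mask = np.zeros((3, 1, 1), dtype=bool)
        mask[1] = True
        np.testing.assert_array_equal(tf.mean_timeseries(run, mask),
                                      data[1, 0, 0])

    def test_opposite_series_cancel(self, rng):
        s = rng.normal(size=15)
        run = _run_from_series([s, -s])
        np.testing.assert_allclose(
            tf.mean_timeseries(run, np.ones((2, 1, 1), dtype=bool)), 0,
            atol=1e-12)

    def test_three_voxel_hand_mean(self):
        run = _run_from_series([[1.0, 2.0], [3.0, 4.0], [5.0, 9.0]])
        np.testing.assert_allclose(
            tf.mean_timeseries(run, np.ones((3, 1, 1), dtype=bool)),
            [3.0, 5.0])


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        # 0.05 Hz sits on an exact FFT bin for 600 s: amplitude ratio ~ 1
        t = np.arange(250) * 2.4
        x = np.sin(2 * np.pi * 0.05 * t)
        y = tf.bandpass(x, (0.01, 0.1), 2.4)
        ratio = np.sqrt((y**2).mean() / (x**2).mean())
        assert 0.9 <= ratio <= 1.1

    def test_stopband_sinusoid_suppressed(self):
        t = np.arange(250) * 2.4
        x = np.sin(2 * np.pi * 0.004 * t)
        y = tf.bandpass(x, (0.01, 0.1), 2.4)
        ratio = np.sqrt((y**2).mean() / (x**2).mean())
        assert ratio <= 0.3

    def test_constant_series_removed(self):
        y = tf.bandpass(np.full(100, 7.3), (0.01, 0.1), 2.4)
        assert np.abs(y).max() <= 1e-8

    def test_matrix_input_filters_columns(self, rng):
        X = rng.normal(size=(120, 3))
        Y = tf.bandpass(X, (0.01, 0.1), 2.4)
        for j in range(3):
            np.testing.assert_allclose(Y[:, j],
                                       tf.bandpass(X[:, j], (0.01, 0.1), 2.4))


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert tf.fisher_z(0.0) == 0.0

    def test_half_closed_form(self):
        assert abs(tf.fisher_z(0.5) - 0.5493) < 1e-4

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, size=20)
        np.testing.assert_allclose(tf.fisher_z(-r), -tf.fisher_z(r),
                                   atol=1e-12)

    def test_clipping_at_unity(self):
        assert tf.fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))

    def test_out_of_range_rejected(self):
        with pytest.raises(tf.InvalidInputError):
            tf.fisher_z(1.5)


def _oracle_semipartial(voxels, seed, controls, nuisance, band, tr):
    """Brute-force oracle: FFT band mask + explicit OLS + np.corrcoef."""
    def bp(x):
        x = np.asarray(x, dtype=float)
        spec = np.fft.rfft(x, axis=0)
        f = np.fft.rfftfreq(x.shape[0], d=tr)
        keep = (f >= band[0]) & (f <= band[1])
        keep[0] = False
        spec[~keep] = 0
        return np.fft.irfft(spec, n=x.shape[0], axis=0)

    def ols_resid(y, X):
        X = np.column_stack([np.ones(len(y))] + list(X))
        beta = np.linalg.pinv(X) @ y
        return y - X @ beta

    seed_f = bp(seed)
    ctrl_f = [bp(c) for c in controls]
    nuis_cols = [bp(nuisance[:, j]) for j in range(nuisance.shape[1])] \
        if nuisance is not None else []
    seed_res = ols_resid(seed_f, ctrl_f + nuis_cols)
    out = []
    for v in voxels:
        v_clean = ols_resid(bp(v), nuis_cols)
        out.append(np.corrcoef(seed_res, v_clean)[0, 1])
    return np.arctanh(np.clip(out, -(1 - 1e-7), 1 - 1e-7))


class TestSemipartialConnectivity:
    def test_no_controls_reduces_to_pearson(self, rng):
        T = 80
        series = rng.normal(size=(4, T))
        run = _run_from_series(series)
        seed = rng.normal(size=T)
        band = (0.05, 0.45)
        cmap = tf.semipartial_connectivity(run, seed, [], None, band)
        seed_f = tf.bandpass(seed, band, 1.0)
        for i in range(4):
            v_f = tf.bandpass(series[i], band, 1.0)
            expected = np.arctanh(np.corrcoef(seed_f, v_f)[0, 1])
            assert abs(cmap.z_values[i, 0, 0] - expected) < 1e-10

    def test_voxel_identical_to_seed_is_clipped(self, rng):
        T = 60
        seed = rng.normal(size=T)
        band = (0.05, 0.45)
        seed_f = tf.bandpass(seed, band, 1.0)
        run = _run_from_series([seed_f])
        cmap = tf.semipartial_connectivity(run, seed, [], None, band)
        assert cmap.z_values[0, 0, 0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_matches_brute_force_oracle(self, rng):
        # small fixture, one control plus nuisance, tolerance 1e-10
        T = 6
        voxels = rng.normal(size=(3, T))
        seed = rng.normal(size=T)
        control = rng.normal(size=T)
        nuisance = rng.normal(size=(T, 1))
        band = (0.1, 0.45)
        run = _run_from_series(voxels)
        cmap = tf.semipartial_connectivity(run, seed, [control], nuisance,
                                           band)
        expected = _oracle_semipartial(voxels, seed, [control], nuisance,
                                       band, 1.0)
        np.testing.assert_allclose(cmap.z_values[:, 0, 0], expected,
                                   atol=1e-10)

    def test_control_order_invariance(self, rng):
        T = 50
        voxels = rng.normal(size=(3, T))
        seed = rng.normal(size=T)
        c1, c2, c3 = rng.normal(size=(3, T))
        run = _run_from_series(voxels)
        band = (0.05, 0.45)
        a = tf.semipartial_connectivity(run, seed, [c1, c2, c3], None, band)
        b = tf.semipartial_connectivity(run, seed, [c3, c1, c2], None, band)
        np.testing.assert_allclose(a.z_values, b.z_values, atol=1e-10)

    def test_orthogonal_controls_equal_plain_pearson(self):
        # controls orthogonal to the seed leave the seed untouched
        T = 64
        t = np.arange(T)
        band = (0.01, 0.45)
        seed = np.sin(2 * np.pi * 8 * t / T)
        control = np.sin(2 * np.pi * 16 * t / T)   # orthogonal Fourier mode
        rng = np.random.default_rng(3)
        voxels = rng.normal(size=(3, T))
        run = _run_from_series(voxels)
        with_ctrl = tf.semipartial_connectivity(run, seed, [control], None,
                                                band)
        without = tf.semipartial_connectivity(run, seed, [], None, band)
        np.testing.assert_allclose(with_ctrl.z_values, without.z_values,
                                   atol=1e-8)

    def test_seed_explained_by_controls_rejected(self, rng):
        T = 40
        seed = rng.normal(size=T)
        run = _run_from_series(rng.normal(size=(2, T)))
        with pytest.raises(tf.InvalidInputError, match="zero variance"):
            tf.semipartial_connectivity(run, seed, [seed.copy()], None,
                                        (0.05, 0.45))

    def test_zero_noise_phantom_unique_attribution(self):
        # EC voxels correlate perfectly (clip-free high z) with their own
        # source and exactly zero with other sources once the own latent
        # is among the controls
        cfg = tf.PhantomConfig(noise_sd=0.0, spike_rate=0.0,
                               n_volumes_per_run=120)
        anatomy, truth = tf.build_phantom_anatomy(cfg)
        subj = tf.synthesize_subject(anatomy, truth, None, cfg, subject_seed=21)
        run = subj.runs[0]
        lat = subj.latents[0]
        sources = {s: tf.mean_timeseries(run, anatomy.mask(s))
                   for s in tf.SOURCE_ORDER}
        ec_mask = anatomy.mask("EC")
        for k, name in enumerate(tf.SOURCE_ORDER):
            controls = [sources[o] for o in tf.SOURCE_ORDER if o != name]
            cmap = tf.semipartial_connectivity(run, sources[name], controls,
                                               None, cfg.band_hz, mask=ec_mask)
            own = cmap.z_values[anatomy.ec_sublabel == k + 1]
            other = cmap.z_values[(anatomy.ec_sublabel > 0)
                                  & (anatomy.ec_sublabel != k + 1)]
            assert own.min() > 1.5            # r > 0.90
            assert np.abs(other).max() < 1e-8
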