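"""LCMV spatial filters, localization, and virtual electrodes."""

import numpy as np
import pytest

import oscmem as om
from oscmem.beamformer import (bandpass_data, lcmv_filters, localize_peak,
                               sensor_covariance, source_power_map,
                               virtual_electrode)
from oscmem.cohort import EpochedEEG


def epochs_from_array(data, srate=250.0):
    n = data.shape[-1]
    times = np.arange(n) / srate
    labels = np.array([om.CELLS[i % 4] for i in range(data.shape[0])])
    return EpochedEEG("sub-x", data.astype(np.float32), srate, times, labels)


@pytest.fixture(scope="module")
def filters16(sensors16, model24):
    """Filters from a well-conditioned noise covariance."""
    rng = np.random.default_rng(0)
    data = rng.standard_normal((20, 16, 500)).astype(np.float32)
    cov = sensor_covariance(epochs_from_array(data))
    return lcmv_filters(model24, cov)


class TestSensorCovariance:
    def test_rank_one_pattern_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=8)
        a -= a.mean()  # average-reference invariant pattern
        s = rng.normal(size=(10, 2000))
        data = a[None, :, None] * s[:, None, :]
        cov = sensor_covariance(epochs_from_array(data))
        expect = np.var(s.ravel(), ddof=1) * np.outer(a, a)
        np.testing.assert_allclose(cov, expect, atol=1e-8 * np.abs(expect).max())
        assert np.linalg.matrix_rank(cov, tol=1e-8) == 1

    def test_white_noise_approaches_scaled_centering_matrix(self):
        rng = np.random.default_rng(2)
        n_ch = 8
        data = rng.standard_normal((50, n_ch, 2000))
        cov = sensor_covariance(epochs_from_array(data))
        centering = np.eye(n_ch) - np.ones((n_ch, n_ch)) / n_ch
        # 100k samples: entries match sigma^2 * centering within 3 SE
        se = 3.0 / np.sqrt(50 * 2000)
        assert np.abs(cov - centering).max() < 3 * se + 0.01

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((12, 6, 300))
        c1 = sensor_covariance(epochs_from_array(data))
        c2 = sensor_covariance(epochs_from_array(data[::-1]))
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            sensor_covariance(epochs_from_array(np.zeros((1, 32, 10))))


class TestLcmvFilters:
    def test_unit_gain_everywhere(self, filters16, model24):
        """W(r) L(r) = I on the full 3D filters, and w·l = 1 for the
        orientation-selected scalar filter, at every grid point."""
        gains = np.einsum("gkc,gcd->gkd", filters16.vector_weights,
                          model24.leadfield)
        assert np.abs(gains - np.eye(3)[None]).max() < 1e-8
        l_s = np.einsum("gcd,gd->gc", model24.leadfield, filters16.orientations)
        scalar_gain = np.einsum("gc,gc->g", filters16.weights, l_s)
        np.testing.assert_allclose(scalar_gain, 1.0, atol=1e-8)

    def test_single_dipole_localized_within_one_spacing(self, sensors16, model24):
        """A simulated dipole at SNR >= 10 is found within one grid
        spacing by the noise-normalized power scan in >= 95% of trials."""
        rng = np.random.default_rng(4)
        hits = 0
        n_trials = 40
        interior = np.flatnonzero(
            np.linalg.norm(model24.grid, axis=1) < 0.85 * model24.head_radius)
        for _ in range(n_trials):
            gi = int(rng.choice(interior))
            ori = rng.standard_normal(3)
            ori /= np.linalg.norm(ori)
            gain = model24.leadfield[gi] @ ori
            s = rng.standard_normal((30, 600))
            noise = rng.standard_normal((30, 16, 600))
            noise -= noise.mean(axis=1, keepdims=True)
            amp = 10.0 * np.sqrt((noise**2).mean()) / np.sqrt((gain**2).mean())
            data = amp * gain[None, :, None] * s[:, None, :] + noise
            cov = sensor_covariance(epochs_from_array(data))
            filt = lcmv_filters(model24, cov)
            peak, _ = localize_peak(filt, cov)
            err = np.linalg.norm(model24.grid[peak] - model24.grid[gi])
            hits += err <= model24.spacing + 1e-9
        assert hits / n_trials >= 0.95

    def test_two_uncorrelated_dipoles_both_recovered(self, sensors16, model24):
        rng = np.random.default_rng(5)
        g1 = int(np.argmin(np.linalg.norm(model24.grid - [-0.04, 0.0, 0.02], axis=1)))
        g2 = int(np.argmin(np.linalg.norm(model24.grid - [0.04, 0.0, 0.02], axis=1)))
        data = np.zeros((30, 16, 600))
        for gi, seed in ((g1, 10), (g2, 11)):
            r = np.random.default_rng(seed)
            ori = model24.grid[gi] / np.linalg.norm(model24.grid[gi])
            gain = model24.leadfield[gi] @ ori
            amp = 8.0 / np.sqrt((gain**2).mean())
            data += amp * gain[None, :, None] * r.standard_normal((30, 1, 600))
        noise = rng.standard_normal((30, 16, 600))
        data += noise - noise.mean(axis=1, keepdims=True)
        cov = sensor_covariance(epochs_from_array(data))
        filt = lcmv_filters(model24, cov)
        _, nai = localize_peak(filt, cov)
        for gi in (g1, g2):
            near = np.linalg.norm(model24.grid - model24.grid[gi], axis=1) \
                <= model24.spacing + 1e-9
            far = ~near
            assert nai[near].max() > np.percentile(nai[far], 95)

    def test_source_contrast_monotone_in_sensor_noise(self, sensors16, model24):
        """The localization contrast (noise-normalized power at the true
        source relative to the background) never grows as sensor noise is
        added; raw output power cannot be monotone because the unit-gain
        constraint passes the noise floor itself."""
        rng = np.random.default_rng(6)
        gi = int(np.argmin(np.linalg.norm(model24.grid - [0.0, -0.03, 0.03], axis=1)))
        ori = np.array([0.0, 0.0, 1.0])
        gain = model24.leadfield[gi] @ ori
        gain_scale = np.sqrt((gain**2).mean())
        s = rng.standard_normal((20, 500))
        base = (gain[None, :, None] / gain_scale) * s[:, None, :]
        noise = rng.standard_normal((20, 16, 500))
        noise -= noise.mean(axis=1, keepdims=True)
        contrasts = []
        for level in (0.1, 0.5, 1.0, 2.0, 4.0):
            cov = sensor_covariance(epochs_from_array(base + level * noise))
            filt = lcmv_filters(model24, cov)
            _, nai = localize_peak(filt, cov)
            contrasts.append(nai[gi] / np.median(nai))
        assert np.all(np.diff(contrasts) < 0)


class TestVirtualElectrode:
    def test_single_point_roi_equals_point_time_course(self, filters16, model24,
                                                       sensors16):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((5, 16, 200))
        epochs = epochs_from_array(data)
        mask = np.zeros(model24.n_points, dtype=bool)
        mask[10] = True
        ve = virtual_electrode(filters16, epochs, model24, mask)
        stored = epochs.data.astype(float)  # float32 storage is the reference
        ref = np.einsum("c,tcs->ts",
                        filters16.weights[10],
                        stored - stored.mean(axis=1, keepdims=True))
        np.testing.assert_allclose(ve.data[:, 0, :], ref, atol=1e-10)
        assert ve.grid_points.tolist() == [10]

    def test_linearity_of_roi_averaging(self, filters16, model24):
        rng = np.random.default_rng(8)
        d1 = rng.standard_normal((4, 16, 100))
        d2 = rng.standard_normal((4, 16, 100))
        v1 = virtual_electrode(filters16, epochs_from_array(d1), model24, "mtl_left")
        v2 = virtual_electrode(filters16, epochs_from_array(d2), model24, "mtl_left")
        v12 = virtual_electrode(filters16, epochs_from_array(d1 + d2), model24,
                                "mtl_left")
        np.testing.assert_allclose(v12.data, v1.data + v2.data, atol=1e-6)

    def test_empty_roi_rejected(self, filters16, model24):
        rng = np.random.default_rng(9)
        epochs = epochs_from_array(rng.standard_normal((4, 16, 100)))
        with pytest.raises(KeyError):
            virtual_electrode(filters16, epochs, model24,
                              np.zeros(model24.n_points, dtype=bool))

    def test_channel_permutation_invariance(self, sensors16, model24):
        """Consistently permuting channels in data and leadfield leaves
        source quantities unchanged."""
        from dataclasses import replace
        rng = np.random.default_rng(10)
        data = rng.standard_normal((10, 16, 400))
        perm = rng.permutation(16)
        model_p = replace(model24, leadfield=model24.leadfield[:, perm, :])
        cov = sensor_covariance(epochs_from_array(data))
        cov_p = sensor_covariance(epochs_from_array(data[:, perm, :]))
        f = lcmv_filters(model24, cov)
        f_p = lcmv_filters(model_p, cov_p)
        _, nai = localize_peak(f, cov)
        _, nai_p = localize_peak(f_p, cov_p)
        np.testing.assert_allclose(nai, nai_p, rtol=1e-8)


class TestSourcePower:
    def test_injected_roi_effect_recovered_in_virtual_electrode(self, sensors16,
                                                                model24):
        """A theta amplitude decrease injected in the left MTL shows up as
        lower 3-7 Hz virtual-electrode power in the affected cells."""
        eff = om.EffectSpec("theta", (3.0, 7.0), (-1.0, 3.0),
                            ("spatial/remembered", "spatial/forgotten"),
                            -0.4, "mtl_left", amplitude=3.0)
        subj = om.simulate_subject(sensors16, model24, (eff,),
                                   {c: 30 for c in om.CELLS}, seed=12,
                                   srate=250.0, n_noise_dipoles=16)
        cov = sensor_covariance(subj)
        filt = lcmv_filters(model24, cov)
        ve = virtual_electrode(filt, subj, model24, "mtl_left")
        band = bandpass_data(ve.data[:, 0, :], subj.srate, (3.0, 7.0))
        power = (band**2).mean(axis=1)
        spatial = np.isin(subj.cell_labels,
                          ("spatial/remembered", "spatial/forgotten"))
        assert power[spatial].mean() < power[~spatial].mean()

    def test_source_power_map_cell_structure(self, sensors16, model24):
        eff = om.EffectSpec("theta", (3.0, 7.0), (-0.5, 2.0),
                            ("spatial/remembered", "spatial/forgotten"),
                            -0.4, "mtl_left", amplitude=3.0)
        subj = om.simulate_subject(sensors16, model24, (eff,),
                                   {c: 20 for c in om.CELLS}, seed=13,
                                   srate=250.0, n_noise_dipoles=12)
        cov = sensor_covariance(subj)
        filt = lcmv_filters(model24, cov)
        maps = source_power_map(filt, subj, (3.0, 7.0), (-0.5, 2.0))
        assert set(maps) == set(om.CELLS)
        roi = model24.roi_masks["mtl_left"]
        diff = ((maps["spatial/remembered"] + maps["spatial/forgotten"])
                - (maps["nonspatial/remembered"] + maps["nonspatial/forgotten"])) / 2
        # injected decrease: spatial cells weaker at the ROI
        assert diff[roi].mean() < 0
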