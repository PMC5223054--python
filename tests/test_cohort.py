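"""Synthetic cohort generator: montage, leadfield, noise and effect injection."""

import numpy as np
import pytest
from scipy.signal import hilbert

import oscmem as om
from oscmem.cohort import (DEFAULT_TRIAL_MEANS, bandpass_noise, pink_noise,
                           sample_trial_counts, sphere_potential)


class TestSensorSpace:
    def test_63_channel_montage_has_distinct_positions(self):
        s = om.make_sensor_space(63)
        assert s.positions.shape == (63, 3)
        d = np.linalg.norm(s.positions[:, None] - s.positions[None], axis=-1)
        assert d[~np.eye(63, dtype=bool)].min() > 1e-4
        # upper hemisphere, on the sphere
        assert np.all(s.positions[:, 2] > 0)
        np.testing.assert_allclose(np.linalg.norm(s.positions, axis=1), 0.09)

    def test_infinite_neighbor_distance_gives_complete_graph(self):
        s = om.make_sensor_space(4, neighbor_distance=np.inf)
        assert s.adjacency.sum() == 4 * 3  # 6 undirected edges

    def test_adjacency_matches_bruteforce_distance_threshold(self):
        s = om.make_sensor_space(63)
        d = np.linalg.norm(s.positions[:, None] - s.positions[None], axis=-1)
        # oracle: recover the implied threshold from the realized graph
        thr = d[s.adjacency].max()
        oracle = (d <= thr) & ~np.eye(63, dtype=bool)
        np.testing.assert_array_equal(s.adjacency, oracle)
        assert np.array_equal(s.adjacency, s.adjacency.T)
        assert s.adjacency.sum(1).min() >= 1

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            om.make_sensor_space(3)


class TestLeadfield:
    def test_grid_strictly_inside_sphere(self, model24):
        r = np.linalg.norm(model24.grid, axis=1)
        assert np.all(r < model24.head_radius)

    def test_12mm_grid_inside_80mm_sphere(self):
        s = om.make_sensor_space(8)
        m = om.build_leadfield(s, grid_spacing=0.012, head_radius=0.08)
        assert np.all(np.linalg.norm(m.grid, axis=1) < 0.08)
        assert m.n_points > 500

    def test_average_reference_zero_column_sums(self, model24):
        sums = model24.leadfield.sum(axis=1)
        assert np.abs(sums).max() < 1e-10

    def test_central_dipole_weak_relative_to_superficial(self, sensors16):
        """Deep sources project weakly: pattern norm shrinks monotonically
        with depth and the central dipole is small next to a superficial one."""
        r = sensors16.radius
        norms = [np.linalg.norm(sphere_potential(sensors16.positions,
                                                 (0.0, 0.0, frac * r), r))
                 for frac in (0.0, 0.3, 0.6, 0.9)]
        assert np.all(np.diff(norms) > 0)
        assert norms[0] / norms[-1] < 0.5

    def test_central_dipole_closed_form(self, sensors16):
        # V = 3 q·e_hat / (4 pi sigma R^2) for a dipole at the center
        r = sensors16.radius
        got = sphere_potential(sensors16.positions, (0.0, 0.0, 0.0), r)
        e_hat = sensors16.positions / r
        expect = 3.0 * e_hat / (4 * np.pi * 0.33 * r**2)
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_series_converged(self, sensors16):
        pos = (0.0, 0.02, 0.05)
        a = sphere_potential(sensors16.positions, pos, sensors16.radius, n_terms=60)
        b = sphere_potential(sensors16.positions, pos, sensors16.radius, n_terms=200)
        np.testing.assert_allclose(a, b, rtol=1e-8)

    def test_empty_grid_rejected(self, sensors16):
        with pytest.raises(ValueError):
            om.build_leadfield(sensors16, grid_spacing=0.5)

    def test_rois_nonempty_at_default_resolution(self):
        s = om.make_sensor_space(16)
        m = om.build_leadfield(s, grid_spacing=0.012)
        for name, mask in m.roi_masks.items():
            assert mask.sum() >= 1, name


class TestNoise:
    def test_pink_noise_loglog_slope_near_minus_one(self):
        rng = np.random.default_rng(0)
        x = pink_noise(rng, (200,), 4096, 500.0)
        spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
        f = np.fft.rfftfreq(4096, 1 / 500.0)
        sel = (f >= 2) & (f <= 30)
        slope = np.polyfit(np.log(f[sel]), np.log(spec.mean(0)[sel]), 1)[0]
        assert abs(slope + 1.0) < 0.3

    def test_bandpass_noise_confined_to_band(self):
        rng = np.random.default_rng(1)
        x = bandpass_noise(rng, (100,), 2048, 250.0, (8.0, 12.0))
        spec = np.abs(np.fft.rfft(x, axis=-1)).mean(0)
        f = np.fft.rfftfreq(2048, 1 / 250.0)
        inband = spec[(f >= 8) & (f <= 12)].mean()
        outband = spec[(f >= 20) | (f <= 4)].mean()
        assert inband > 50 * outband

    def test_unit_rms(self):
        rng = np.random.default_rng(2)
        x = pink_noise(rng, (400,), 2000, 500.0)
        assert abs(np.sqrt(np.mean(x**2)) - 1.0) < 0.05


class TestSimulateSubject:
    def test_determinism_bitwise(self, sensors16, model24):
        counts = {c: 15 for c in om.CELLS}
        a = om.simulate_subject(sensors16, model24, om.default_effects(), counts,
                                seed=5, srate=250.0, n_noise_dipoles=12)
        b = om.simulate_subject(sensors16, model24, om.default_effects(), counts,
                                seed=5, srate=250.0, n_noise_dipoles=12)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.cell_labels, b.cell_labels)

    def test_epoch_axis_and_cells(self, small_subject):
        assert small_subject.times[0] == pytest.approx(-2.5)
        assert small_subject.times[-1] == pytest.approx(3.5)
        assert np.isfinite(small_subject.data).all()
        assert all(n >= 1 for n in small_subject.cell_counts().values())

    def test_missing_cell_rejected(self, sensors16, model24):
        counts = {c: 10 for c in om.CELLS[:3]}
        with pytest.raises(ValueError):
            om.simulate_subject(sensors16, model24, (), counts, seed=0)

    def test_unknown_roi_rejected(self, sensors16, model24):
        eff = om.EffectSpec("bad", (3, 7), (0, 1), (om.CELLS[0],), -0.3,
                            "no_such_roi")
        with pytest.raises(KeyError):
            om.simulate_subject(sensors16, model24, (eff,),
                                {c: 15 for c in om.CELLS}, seed=0)

    def test_effect_injectivity_against_narrowband_oracle(self, sensors16, model24):
        """Amplitude delta recovered within 20% at the max-gain sensor, noise-free."""
        delta = -0.3
        eff = om.EffectSpec("theta", (3.0, 7.0), (-1.0, 3.0),
                            ("spatial/remembered", "spatial/forgotten"),
                            delta, "mtl_left")
        subj = om.simulate_subject(
            sensors16, model24, (eff,), {c: 40 for c in om.CELLS},
            noise_level=0.0, sensor_noise=0.0, seed=3, srate=250.0)
        # independent oracle: FFT band-pass + analytic-signal amplitude
        from oscmem.beamformer import bandpass_data
        narrow = bandpass_data(subj.data.astype(float), subj.srate, (3.0, 7.0))
        amp = np.abs(hilbert(narrow, axis=-1))
        ch = np.argmax(amp.mean(axis=(0, 2)))
        core = (subj.times > -0.5) & (subj.times < 2.5)  # inside effect window
        spatial = np.isin(subj.cell_labels,
                          ("spatial/remembered", "spatial/forgotten"))
        a_aff = amp[spatial][:, ch, :][:, core].mean()
        a_un = amp[~spatial][:, ch, :][:, core].mean()
        measured = a_aff / a_un - 1.0
        assert abs(measured - delta) < 0.2 * abs(delta)

    def test_null_effects_no_cell_difference(self, sensors16, model24):
        """With no effects, band power differs between cells only by noise."""
        from scipy import stats
        diffs = []
        for seed in range(24):
            subj = om.simulate_subject(sensors16, model24, (), {c: 12 for c in om.CELLS},
                                       seed=seed, srate=250.0, n_noise_dipoles=8)
            p = (subj.data.astype(float) ** 2).mean(axis=(1, 2))
            a = p[subj.cell_labels == om.CELLS[0]].mean()
            b = p[subj.cell_labels == om.CELLS[2]].mean()
            diffs.append(a - b)
        t, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01


class TestCohort:
    def test_trial_count_sampler_matches_configured_means(self):
        """Mean over 200 sampled subjects within 2 SE of each cell mean."""
        rng = np.random.default_rng(42)
        draws = [sample_trial_counts(rng) for _ in range(200)]
        for cell, mu in DEFAULT_TRIAL_MEANS.items():
            vals = np.array([d[cell] for d in draws])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - mu) < 2 * se + 1.0  # +1 absorbs truncation bias
            assert vals.min() >= 15

    def test_cohort_determinism_and_manifest(self, sensors16, model24):
        cfg = om.CohortConfig(n_subjects=3, n_channels=16, srate=250.0,
                              n_noise_dipoles=8, grid_spacing=0.024,
                              trial_means={c: 16.0 for c in om.CELLS}, trial_sd=2.0)
        a = om.generate_cohort(config=cfg, master_seed=9, sensors=sensors16,
                               model=model24)
        b = om.generate_cohort(config=cfg, master_seed=9, sensors=sensors16,
                               model=model24)
        assert a.n_subjects == 3
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.data, sb.data)
        assert a.manifest == b.manifest
        assert len(a.manifest["effects"]) == 4
        assert set(a.manifest["trial_counts"]) == {s.subject_id for s in a.subjects}

    def test_recall_logs_score_to_manifest_counts(self, sensors16, model24):
        from oscmem.recall import RecallLog, score_recall
        cfg = om.CohortConfig(n_subjects=2, n_channels=16, srate=250.0,
                              n_noise_dipoles=8, grid_spacing=0.024)
        cohort = om.generate_cohort(config=cfg, master_seed=4, sensors=sensors16,
                                    model=model24)
        for subj in cohort.subjects:
            counts = cohort.manifest["trial_counts"][subj.subject_id]
            for cond in ("spatial", "nonspatial"):
                n_rem = 0
                for seq in cohort.recall_logs[subj.subject_id][cond]:
                    score = score_recall(RecallLog(cfg.n_items, tuple(seq)))
                    n_rem += score.counts["remembered"]
                assert n_rem == counts[f"{cond}/remembered"]
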