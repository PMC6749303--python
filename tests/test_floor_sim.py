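import numpy as np
import pytest

import vibrafall as vf
from vibrafall.fall_load import GRAVITY, ForceProfile


def impulse_profile(fs=1000.0, duration=1.0, amplitude=100.0):
    n = int(round(duration * fs)) + 1
    F = np.zeros(n)
    F[0] = amplitude
    return ForceProfile(t=np.arange(n) / fs, F=F)


class TestFloorModel:
    def test_mode_frequencies_positive_and_anchored(self, floor):
        freqs = [floor.mode_frequency(p, q) for p, q in floor.modes]
        assert freqs[0] == pytest.approx(floor.f_fundamental)
        assert all(f > 0 for f in freqs)
        assert freqs == sorted(freqs)

    def test_point_outside_plate_rejected(self, floor):
        with pytest.raises(ValueError, match="outside"):
            floor.mode_shapes((floor.a + 1.0, 1.0))

    @pytest.mark.parametrize("bad", [dict(zeta=0.0), dict(zeta=0.5),
                                     dict(n_modes_axis=0), dict(a=-1.0)])
    def test_invalid_model_rejected(self, bad):
        with pytest.raises(ValueError):
            vf.FloorModel(**bad)


class TestFloorResponse:
    def test_zero_force_zero_response(self, floor):
        fp = ForceProfile(t=np.arange(100) / 500.0, F=np.zeros(100))
        rec = vf.floor_response(floor, fp, (1.0, 1.0), [(2.0, 2.0), (3.0, 3.0)])
        np.testing.assert_array_equal(rec.channels, np.zeros((100, 2)))

    def test_linearity_in_force_amplitude(self, floor):
        fp1 = impulse_profile()
        fp2 = ForceProfile(t=fp1.t, F=2.0 * fp1.F)
        sensors = [(2.0, 2.5), (1.0, 4.0)]
        r1 = vf.floor_response(floor, fp1, (1.5, 2.0), sensors)
        r2 = vf.floor_response(floor, fp2, (1.5, 2.0), sensors)
        np.testing.assert_allclose(r2.channels, 2.0 * r1.channels, rtol=1e-12)

    def test_single_mode_impulse_matches_damped_sinusoid(self):
        """One retained mode excited by a one-sample impulse must follow the
        closed-form damped sinusoid of that mode's free decay."""
        fm = vf.FloorModel(n_modes_axis=1)
        fs, A = 2000.0, 50.0
        fp = impulse_profile(fs=fs, amplitude=A)
        src, sen = (1.2, 1.7), (2.4, 3.1)
        rec = vf.floor_response(fm, fp, src, [sen, (1.0, 1.0)], fs=fs)
        w = 2 * np.pi * fm.f_fundamental
        z = fm.zeta
        wd = w * np.sqrt(1 - z ** 2)
        t = fp.t[1:]
        h = np.exp(-z * w * t) * np.sin(wd * t) / wd
        hdot = np.exp(-z * w * t) * (np.cos(wd * t) - z * w * np.sin(wd * t) / wd)
        hddot = -2 * z * w * hdot - w ** 2 * h
        phi = fm.mode_shapes(src)[0] * fm.mode_shapes(sen)[0]
        expected = phi * A / fs * hddot / GRAVITY
        scale = np.max(np.abs(expected))
        np.testing.assert_allclose(rec.channels[1:, 0], expected, atol=1e-6 * scale)

    def test_noise_deterministic_given_rng_seed(self, floor):
        fp = impulse_profile()
        kw = dict(noise_sd=0.001)
        sensors = [(2.0, 2.0), (3.0, 4.0)]
        r1 = vf.floor_response(floor, fp, (1.0, 1.0), sensors,
                               rng=np.random.default_rng(5), **kw)
        r2 = vf.floor_response(floor, fp, (1.0, 1.0), sensors,
                               rng=np.random.default_rng(5), **kw)
        np.testing.assert_array_equal(r1.channels, r2.channels)


class TestActivityForce:
    def test_unknown_activity_rejected(self):
        with pytest.raises(ValueError, match="unknown activity"):
            vf.activity_force("cartwheel", {}, 1000.0, 1.0)

    def test_rhythmic_jump_spacing_at_default_rate(self):
        fp = vf.activity_force("rhythmic_jump", {"mass_kg": 70.0}, 1652.0, 10.0)
        peaks = []
        F = fp.F
        for i in range(1, F.size - 1):
            if F[i] > 0 and F[i] >= F[i - 1] and F[i] > F[i + 1]:
                peaks.append(fp.t[i])
        gaps = np.diff(peaks)
        np.testing.assert_allclose(gaps, 2.0 / 3.0, atol=2.0 / 1652.0)

    def test_ball_drop_peak_scales_with_mass(self):
        common = {"drop_height_m": 1.45}
        f1 = vf.activity_force("ball_drop", {"mass_kg": 0.6, **common}, 1000.0, 1.0)
        f2 = vf.activity_force("ball_drop", {"mass_kg": 5.0, **common}, 1000.0, 1.0)
        assert f2.F.max() / f1.F.max() == pytest.approx(5.0 / 0.6, rel=1e-6)

    def test_drop_peak_scales_with_impact_velocity(self):
        f1 = vf.activity_force("bag_drop", {"mass_kg": 5.0, "drop_height_m": 0.6},
                               1000.0, 1.0)
        f2 = vf.activity_force("bag_drop", {"mass_kg": 5.0, "drop_height_m": 2.4},
                               1000.0, 1.0)
        assert f2.F.max() / f1.F.max() == pytest.approx(2.0, rel=1e-6)

    def test_walk_with_zero_steps_is_silent(self):
        fp = vf.activity_force("walk", {"mass_kg": 70.0, "n_steps": 0}, 1000.0, 2.0)
        np.testing.assert_array_equal(fp.F, 0.0)

    def test_fall_profile_starts_at_body_weight(self):
        fp = vf.activity_force("fall", {"mass_kg": 75.0}, 1000.0, 2.0)
        assert fp.F[0] == pytest.approx(75.0 * GRAVITY)


class TestGenerateScenario:
    def test_deterministic_given_seed(self, tiny_design, floor):
        d1 = vf.generate_scenario(tiny_design, floor, seed=123)
        d2 = vf.generate_scenario(tiny_design, floor, seed=123)
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.channels, b.channels)
            assert a.label == b.label

    def test_different_seeds_differ(self, tiny_design, floor):
        d1 = vf.generate_scenario(tiny_design, floor, seed=1)
        d2 = vf.generate_scenario(tiny_design, floor, seed=2)
        assert not np.array_equal(d1[0].channels, d2[0].channels)

    def test_inventory_counts_preserved(self, tiny_dataset, tiny_design):
        labels = tiny_dataset.labels()
        for entry in tiny_design.inventory:
            assert labels.count(entry.activity) == entry.count

    def test_fall_peaks_exceed_walk_peaks(self, tiny_dataset):
        peak, _, _ = vf.extract_views(tiny_dataset)
        labels = np.array(tiny_dataset.labels())
        assert peak.matrix[labels == "fall"].mean() > peak.matrix[labels == "walk"].mean()

    def test_records_share_shape_and_rate(self, tiny_dataset, tiny_design):
        assert tiny_dataset.n_sensors == len(tiny_design.sensors)
        assert tiny_dataset.fs == tiny_design.fs


class TestPresets:
    def test_lab_inventory_matches_experiment_design(self):
        d = vf.preset_designs("lab_table1")
        counts = {e.activity: e.count for e in d.inventory}
        assert counts["fall"] == 520
        assert sum(c for a, c in counts.items() if a != "fall") == 1170
        assert d.total_events() == 1690
        assert d.fs == 1652.0
        assert len(d.sensors) == 4

    def test_benchmark_inventory_totals(self):
        d = vf.preset_designs("benchmark_table8")
        counts = {e.activity: e.count for e in d.inventory}
        assert counts["fall"] == 1725
        assert sum(c for a, c in counts.items() if a != "fall") == 7475
        assert d.total_events() == 9200

    def test_rhythmic_jump_preset_rate_is_90_bpm(self):
        d = vf.preset_designs("lab_table1")
        entry = next(e for e in d.inventory if e.activity == "rhythmic_jump")
        assert entry.params["rate_hz"] == 1.5

    def test_bag_drop_preset_height(self):
        d = vf.preset_designs("lab_table1")
        entry = next(e for e in d.inventory if e.activity == "bag_drop")
        assert entry.params["drop_height_m"] == 0.6

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            vf.preset_designs("table99")
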