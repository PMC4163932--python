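"""Synthetic session generator: presets, state process, ground truth."""

import numpy as np
import pytest

from lfpmodes import (
    GroundTruth,
    MixingParams,
    SimulationSpec,
    apply_raclopride,
    make_session,
    spec_for,
    zt_preset,
)
from lfpmodes.experiments import SINGLE_STR_LAYOUT
from lfpmodes.simulate import SLOW, THETA, draw_state_intervals, simulate_to_dir

FS = 250.0


class TestPresets:
    def test_zt1_striatal_slow_occupancy(self):
        assert zt_preset(1, "Str")["slow_occupancy"] == pytest.approx(0.942)
        assert not zt_preset(1, "Str")["interpolated"]

    def test_zt13_cerebellar_theta_occupancy(self):
        preset = zt_preset(13, "CB")
        assert preset["theta_occupancy"] == pytest.approx(0.577)

    def test_intermediate_times_flagged_interpolated(self):
        for zt in (7, 19):
            p = zt_preset(zt, "Str")
            assert p["interpolated"]
            assert 0.600 < p["slow_occupancy"] < 0.942

    def test_unsampled_time_rejected(self):
        with pytest.raises(ValueError, match="not sampled"):
            zt_preset(4, "Str")

    def test_region_aliases(self):
        assert zt_preset(1, "MStr") == zt_preset(1, "Str") == zt_preset(1, "LStr")


class TestRaclopride:
    def test_zt13_shift(self):
        spec = SimulationSpec(zt=13, slow_occupancy=0.45)
        post = apply_raclopride(spec)
        assert post.condition == "post"
        assert post.slow_occupancy == pytest.approx(0.60)

    def test_no_shift_at_other_times(self):
        spec = SimulationSpec(zt=1, slow_occupancy=0.94)
        assert apply_raclopride(spec).slow_occupancy == pytest.approx(0.94)

    def test_clipped_at_one(self):
        spec = SimulationSpec(zt=13, slow_occupancy=0.95)
        assert apply_raclopride(spec).slow_occupancy == 1.0

    def test_double_application_rejected(self):
        post = apply_raclopride(SimulationSpec(zt=13, slow_occupancy=0.5))
        with pytest.raises(ValueError, match="already"):
            apply_raclopride(post)


class TestStateProcess:
    def test_intervals_tile_duration(self, rng):
        intervals = draw_state_intervals(rng, 120.0, 0.6)
        assert intervals[0][0] == 0.0
        assert intervals[-1][1] == pytest.approx(120.0)
        for (s0, e0, st0), (s1, e1, st1) in zip(intervals, intervals[1:]):
            assert e0 == pytest.approx(s1)
            assert st0 != st1

    def test_degenerate_occupancies(self, rng):
        assert draw_state_intervals(rng, 50.0, 1.0) == [(0.0, 50.0, SLOW)]
        assert draw_state_intervals(rng, 50.0, 0.0) == [(0.0, 50.0, THETA)]

    def test_occupancy_converges(self):
        """Interval-bookkeeping oracle: mean SLOW fraction over 50 long
        sessions approaches the requested occupancy."""
        fractions = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            intervals = draw_state_intervals(rng, 600.0, 0.9)
            slow_time = sum(e - s for s, e, st in intervals if st == SLOW)
            fractions.append(slow_time / 600.0)
        assert abs(np.mean(fractions) - 0.9) < 0.05


class TestMakeSession:
    def test_determinism(self):
        spec = spec_for(13, "Str", fs=FS, duration=20.0, seed=7)
        s1, g1 = make_session(spec)
        s2, g2 = make_session(spec)
        for a, b in zip(s1.channels, s2.channels):
            np.testing.assert_array_equal(a.data, b.data)
        assert g1.state_intervals == g2.state_intervals
        assert g1.spindle_times == g2.spindle_times

    def test_ground_truth_spindles_inside_slow_intervals(self):
        spec = spec_for(13, "Str", fs=FS, duration=60.0, seed=3,
                        channel_layout=SINGLE_STR_LAYOUT)
        _, truth = make_session(spec)
        slow = [(s, e) for s, e, st in truth.state_intervals if st == SLOW]
        times = truth.spindle_times["Str_0"]
        assert times, "expected at least one burst"
        for t in times:
            assert any(s <= t < e for s, e in slow)

    def test_no_spindles_when_probability_zero(self):
        spec = spec_for(1, "Str", fs=FS, duration=30.0, seed=1, spindle_prob=0.0)
        _, truth = make_session(spec)
        assert all(len(v) == 0 for v in truth.spindle_times.values())

    def test_tier_map_covers_all_pairs(self):
        spec = spec_for(1, "Str", fs=FS, duration=10.0, seed=1)
        session, truth = make_session(spec)
        n = len(session.channels)
        assert len(truth.tier_map) == n * (n - 1) // 2
        assert set(truth.tier_map.values()) == {"within_pair", "between_pair", "str_cb"}

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            SimulationSpec(duration=0.0)
        with pytest.raises(ValueError, match="slow_occupancy"):
            SimulationSpec(slow_occupancy=1.2)
        with pytest.raises(ValueError, match="amplitude"):
            SimulationSpec(slow_amp=0.0, theta_amp=0.0)
        with pytest.raises(ValueError, match="fs"):
            SimulationSpec(fs=20.0)
        with pytest.raises(ValueError, match="non-negative"):
            MixingParams(structure_gain=-0.1)

    def test_slow_only_session_is_spectrally_pure(self, config):
        """A slow-only no-spindle session keeps >=95% of its 0.1-55 Hz power
        below 3 Hz when analyzed by the spectral layer."""
        from lfpmodes.preprocess import segment_windows
        from lfpmodes.spectral import BandPowerTransform

        spec = SimulationSpec(
            zt=1, duration=60.0, fs=FS, slow_occupancy=1.0, spindle_prob=0.0,
            slow_theta_leak=0.0, seed=5,
        )
        session, _ = make_session(spec)
        for ch in session.channels:
            w = segment_windows(ch.data, FS, 2.0)
            p = BandPowerTransform(fs=FS, config=config).transform(w)
            assert p[:, 0].mean() >= 95.0


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["f32", "csv"])
    def test_simulate_write_read(self, tmp_path, fmt):
        from lfpmodes import read_session

        spec = spec_for(1, "Str", fs=FS, duration=10.0, seed=9)
        manifest = simulate_to_dir(spec, tmp_path / fmt, fmt=fmt)
        session, _ = make_session(spec)
        loaded = read_session(manifest)
        assert loaded.channel_names == session.channel_names
        atol = 1e-6 if fmt == "f32" else 1e-8
        for a, b in zip(session.channels, loaded.channels):
            np.testing.assert_allclose(b.data, a.data, atol=atol)
        assert (tmp_path / fmt / "ground_truth.json").exists()
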