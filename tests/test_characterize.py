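import numpy as np
import pytest

import rpmap as rp
from rpmap.annotate import CycleLengthEstimate, PhaseSnapshotSeries
from rpmap.characterize import (
    average_pattern,
    conduction_direction,
    electrode_distance_map,
    pattern_size,
    to_activation_map,
)
from rpmap.recurrence import snapshot_distance


def afcl_of(ms=150.0, rate=100.0):
    return CycleLengthEstimate(ms, int(round(ms * rate / 1000)), 0.0, rate)


def series_from(phase, rate=100.0):
    phase = np.asarray(phase, float)
    return PhaseSnapshotSeries(
        np.arange(phase.shape[0]) * 1000.0 / rate, phase,
        np.ones(phase.shape, bool), rate,
    )


class TestAveragePattern:
    def test_identical_recurrences_average_to_member(self, periodic_result):
        res = periodic_result
        avg, rows = average_pattern(
            res.phases, res.rp, res.intervals[0], res.dm.snapshot_index
        )
        member = res.phases.phase[res.dm.snapshot_index[rows[0]]]
        # noise-free periodic recording: recurrent snapshots are identical
        assert np.allclose(
            np.angle(np.exp(1j * (avg - member))), 0.0, atol=1e-6
        )

    def test_opposed_phases_average_to_zero(self):
        z = np.exp(1j * np.array([-np.pi / 2, np.pi / 2])).mean()
        assert np.angle(z) == pytest.approx(0.0)

    def test_global_rotation_equivariance(self, periodic_result):
        res = periodic_result
        rot = 0.8
        shifted = np.angle(np.exp(1j * (res.phases.phase + rot)))
        ph2 = PhaseSnapshotSeries(
            res.phases.t_ms, shifted, res.phases.valid, res.phases.rate_hz
        )
        a1, _ = average_pattern(res.phases, res.rp, res.intervals[0],
                                res.dm.snapshot_index)
        a2, _ = average_pattern(ph2, res.rp, res.intervals[0],
                                res.dm.snapshot_index)
        assert np.allclose(np.angle(np.exp(1j * (a2 - a1 - rot))), 0.0, atol=1e-6)


class TestActivationMap:
    def test_uniform_phase_all_zero(self):
        out = to_activation_map(np.full(6, 0.3), afcl_of())
        assert np.allclose(out, 0.0)

    def test_just_activated_vs_half_cycle(self):
        out = to_activation_map(np.array([-np.pi, 0.0]), afcl_of(150.0))
        assert out[0] == pytest.approx(75.0)  # half a cycle after B
        assert out[1] == pytest.approx(0.0)

    def test_earliest_is_zero_minimum(self):
        rng = np.random.default_rng(0)
        out = to_activation_map(rng.uniform(-np.pi, np.pi, 20), afcl_of())
        assert out.min() == pytest.approx(0.0)
        assert out.max() <= 150.0

    def test_paced_fixture_phase_ramps_along_pacing_direction(
        self, paced4_truth, paced4_result, layout249
    ):
        """Closed form: a planar wave with delay d_k = (r_k·u)/CV has mean
        phase φ_k ≡ c − 2π d_k / CL, so φ_k + 2π d_k / CL is constant."""
        res = paced4_result
        step = 1000.0 / res.phases.rate_hz
        idx = res.dm.snapshot_index
        for s in res.summaries:
            label = paced4_truth.label_at(
                np.array([idx[int(np.median(s.recurrence_times))] * step])
            )[0]
            a = np.deg2rad(float(label.removeprefix("planar")))
            delay = layout249.positions @ np.array([np.cos(a), np.sin(a)]) / 0.5
            resultant = np.abs(
                np.mean(np.exp(1j * (s.avg_phase + 2 * np.pi * delay / 150.0)))
            )
            assert resultant > 0.99, label


class TestElectrodeDistanceMap:
    def test_locked_electrode_zero(self):
        ph = series_from(np.tile([[0.1, -2.0]], (4, 1)))
        d = electrode_distance_map(ph, np.arange(4))
        assert np.allclose(d, 0.0)

    def test_alternating_opposed_phase_half_cycle(self):
        phase = np.array([[0.0], [np.pi - 1e-12], [0.0], [np.pi - 1e-12]])
        d = electrode_distance_map(series_from(phase), np.arange(4))
        # 4 of 6 unordered pairs are opposed: mean = (4*0.5 + 2*0)/6
        assert d[0] == pytest.approx(4 * 0.5 / 6, abs=1e-6)

    def test_single_electrode_matches_snapshot_distance(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-np.pi, np.pi, (5, 3))
        ph = series_from(phase)
        d = electrode_distance_map(ph, np.arange(5))
        k = 2
        pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        oracle = np.mean(
            [snapshot_distance(phase[i, [k]], phase[j, [k]]) for i, j in pairs]
        )
        assert d[k] == pytest.approx(oracle, abs=1e-9)

    def test_paced_pattern_mostly_below_threshold(self, paced4_result):
        res = paced4_result
        for s in res.summaries:
            frac = np.mean(s.delta_kp <= res.delta_max)
            assert frac >= 0.95


class TestPatternSize:
    def test_full_array_area(self, layout249):
        d = np.zeros(249)
        size = pattern_size(d, layout249, afcl_of(), "adaptive", delta_max=0.1)
        assert size == pytest.approx(249 * 0.0576)  # 14.3424 cm²

    def test_none_below_threshold(self, layout249):
        d = np.full(249, 0.4)
        assert pattern_size(d, layout249, afcl_of(), "adaptive", delta_max=0.1) == 0.0

    def test_fixed_dt_closed_form(self, layout249):
        d = np.full(249, 0.05)
        # 0.05 × 150 ms = 7.5 ms < 10 ms → full area
        size = pattern_size(d, layout249, afcl_of(150.0), "fixed_dt", dt_ms=10.0)
        assert size == pytest.approx(layout249.area_mm2() / 100.0)

    def test_monotone_in_thresholds(self, layout100):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 0.5, 100)
        sizes_d = [
            pattern_size(d, layout100, afcl_of(), "adaptive", delta_max=x)
            for x in np.linspace(0, 0.5, 11)
        ]
        sizes_t = [
            pattern_size(d, layout100, afcl_of(), "fixed_dt", dt_ms=x)
            for x in np.linspace(1, 80, 11)
        ]
        assert all(a <= b for a, b in zip(sizes_d, sizes_d[1:]))
        assert all(a <= b for a, b in zip(sizes_t, sizes_t[1:]))

    def test_unknown_mode_rejected(self, layout100):
        with pytest.raises(ValueError):
            pattern_size(np.zeros(100), layout100, afcl_of(), "nope")


class TestConductionDirection:
    def test_planar_gradient_recovers_direction(self, layout100):
        a = np.deg2rad(30.0)
        u = np.array([np.cos(a), np.sin(a)])
        act = layout100.positions @ u / 0.5  # plane wave at 0.5 mm/ms
        d = conduction_direction(act, layout100)
        ok = ~np.isnan(d[:, 0])
        assert ok.all()
        ang = np.degrees(np.arctan2(d[ok, 1], d[ok, 0]))
        assert np.all(np.abs(ang - 30.0) < 5.0)

    def test_focal_field_points_radially_outward(self, layout100):
        act = np.hypot(layout100.x, layout100.y) / 0.5
        d = conduction_direction(act, layout100)
        pos = layout100.positions
        for k in range(100):
            if np.isnan(d[k, 0]) or np.hypot(*pos[k]) < 3.0:
                continue
            radial = pos[k] / np.hypot(*pos[k])
            assert d[k] @ radial > 0.9

    def test_uniform_map_undefined_everywhere(self, layout100):
        d = conduction_direction(np.zeros(100), layout100)
        assert np.isnan(d).all()
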