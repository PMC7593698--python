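import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import rpmap as rp
from rpmap.annotate import PhaseSnapshotSeries
from rpmap.recurrence import (
    adaptive_threshold,
    distance_matrix,
    erode,
    recurrence_rate_per_cycle,
    snapshot_distance,
    threshold_plot,
)

phases_vec = arrays(np.float64, 8, elements=st.floats(-np.pi, np.pi - 1e-9))


def series_from(phase, rate=100.0):
    phase = np.asarray(phase, float)
    return PhaseSnapshotSeries(
        np.arange(phase.shape[0]) * 1000.0 / rate, phase,
        np.ones(phase.shape, bool), rate,
    )


def random_series(n, k, seed):
    rng = np.random.default_rng(seed)
    return series_from(rng.uniform(-np.pi, np.pi, (n, k)))


class TestSnapshotDistance:
    def test_extremes(self):
        x = np.linspace(-3, 3, 10)
        assert snapshot_distance(x, x) == 0.0
        assert snapshot_distance(x, x + np.pi) == pytest.approx(0.5)

    def test_quarter_cycle(self):
        x = np.zeros(6)
        assert snapshot_distance(x, x + np.pi / 2) == pytest.approx(0.25)

    def test_half_in_phase_half_opposed(self):
        a = np.zeros(10)
        b = np.concatenate([np.zeros(5), np.full(5, np.pi)])
        # oracle: mean cos = (5*1 + 5*(-1))/10 = 0 → arccos(0)/2π
        assert snapshot_distance(a, b) == pytest.approx(np.arccos(0.0) / (2 * np.pi))

    @given(phases_vec, phases_vec)
    def test_bounds_symmetry_identity(self, a, b):
        d = snapshot_distance(a, b)
        assert 0.0 <= d <= 0.5
        assert d == pytest.approx(snapshot_distance(b, a))
        assert snapshot_distance(a, a) == 0.0

    def test_mask_and_errors(self):
        a, b = np.zeros(4), np.full(4, np.pi)
        m = np.array([True, True, False, False])
        b2 = b.copy()
        b2[2:] = 0.0
        assert snapshot_distance(a, b2, m) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            snapshot_distance(a, b, np.zeros(4, bool))
        with pytest.raises(ValueError):
            snapshot_distance(a, b[:-1])


class TestDistanceMatrix:
    def test_identical_snapshots_zero_matrix(self):
        dm = distance_matrix(series_from(np.tile(np.linspace(-1, 1, 5), (3, 1))))
        assert np.allclose(dm.values, 0.0)

    def test_matches_brute_force(self):
        ph = random_series(50, 6, seed=0)
        dm = distance_matrix(ph)
        for i in range(0, 50, 7):
            for j in range(0, 50, 11):
                assert dm.values[i, j] == pytest.approx(
                    snapshot_distance(ph.phase[i], ph.phase[j]), abs=1e-6
                )

    def test_periodic_zero_at_period_multiples(self):
        base = np.random.default_rng(1).uniform(-np.pi, np.pi, (5, 6))
        ph = series_from(np.tile(base, (8, 1)))
        dm = distance_matrix(ph)
        n = dm.n
        for lag in (5, 10, 15):
            assert np.allclose(np.diagonal(dm.values, lag), 0.0, atol=1e-3)

    def test_invalid_snapshots_excluded(self):
        phase = np.random.default_rng(2).uniform(-np.pi, np.pi, (6, 4))
        valid = np.ones((6, 4), bool)
        valid[2, 1] = False  # snapshot 2 has an invalid electrode
        ph = PhaseSnapshotSeries(np.arange(6.0) * 10, phase, valid, 100.0)
        dm = distance_matrix(ph)
        assert dm.n == 5
        assert 2 not in dm.snapshot_index

    def test_too_few_snapshots_raise(self):
        phase = np.zeros((2, 3))
        valid = np.zeros((2, 3), bool)
        with pytest.raises(ValueError):
            distance_matrix(PhaseSnapshotSeries(np.arange(2.0), phase, valid, 100.0))


class TestAdaptiveThreshold:
    def test_matches_sort_based_quantile_oracle(self):
        dm = distance_matrix(random_series(120, 8, seed=3))
        afcl = 10
        got = adaptive_threshold(dm, afcl, rr_max=1.0)
        # oracle: sort all eligible distances, take the f-quantile
        i, j = np.triu_indices(dm.n, k=5)  # lag >= afcl/2
        assert got == pytest.approx(float(np.quantile(dm.values[i, j], 1.0 / afcl)))

    def test_monotone_in_rr_max(self):
        dm = distance_matrix(random_series(100, 8, seed=4))
        ds = [adaptive_threshold(dm, 10, rr_max=r) for r in (0.25, 0.5, 1.0, 2.0, 4.0)]
        assert all(a <= b for a, b in zip(ds, ds[1:]))

    def test_calibrated_rate_close_to_target(self):
        dm = distance_matrix(random_series(400, 10, seed=5))
        for rr_max in (0.5, 1.0, 2.0):
            d = adaptive_threshold(dm, 12, rr_max=rr_max)
            plot = threshold_plot(dm, d, rr_max, 12)
            got = recurrence_rate_per_cycle(plot, exclude_band=True)
            assert got == pytest.approx(rr_max, rel=0.05)

    def test_bad_inputs_raise(self):
        dm = distance_matrix(random_series(10, 4, seed=6))
        with pytest.raises(ValueError):
            adaptive_threshold(dm, 1, 1.0)
        with pytest.raises(ValueError):
            adaptive_threshold(dm, 10, 0.0)
        with pytest.raises(ValueError):
            adaptive_threshold(dm, 40, 1.0)  # band swallows every pair


class TestThresholdPlot:
    def test_max_threshold_all_true(self):
        dm = distance_matrix(random_series(30, 5, seed=7))
        assert threshold_plot(dm, 0.5).recurrent.all()

    def test_zero_threshold_identity_on_distinct(self):
        dm = distance_matrix(random_series(30, 5, seed=8))
        plot = threshold_plot(dm, 0.0)
        assert np.array_equal(plot.recurrent, np.eye(30, dtype=bool))

    def test_periodic_small_threshold_marks_period_multiples(self):
        base = np.random.default_rng(9).uniform(-np.pi, np.pi, (7, 8))
        dm = distance_matrix(series_from(np.tile(base, (6, 1))))
        plot = threshold_plot(dm, 0.01)
        i, j = np.nonzero(plot.recurrent)
        assert np.all((i - j) % 7 == 0)

    def test_out_of_range_threshold_raises(self):
        dm = distance_matrix(random_series(10, 4, seed=10))
        with pytest.raises(ValueError):
            threshold_plot(dm, 0.7)


class TestErosion:
    def plot_from(self, rec, dist, afcl=5):
        return rp.RecurrencePlot(rec, 0.1, 1.0, afcl), rp.DistanceMatrix(
            dist.astype(np.float32), np.arange(rec.shape[0])
        )

    def test_row_run_keeps_minimum_distance_cell(self):
        n = 20
        rec = np.eye(n, dtype=bool)
        dist = np.ones((n, n), np.float32) * 0.4
        for j, d in zip((10, 11, 12), (0.10, 0.05, 0.08)):
            rec[5, j] = rec[j, 5] = True
            dist[5, j] = dist[j, 5] = d
        plot, dm = self.plot_from(rec, dist)
        out = erode(plot, dm)
        assert out.recurrent[5, 11]
        assert not out.recurrent[5, 10] and not out.recurrent[5, 12]

    def test_isolated_points_unchanged_and_idempotent(self):
        n = 30
        rng = np.random.default_rng(11)
        rec = np.eye(n, dtype=bool)
        # isolated off-diagonal recurrences: no two share an edge, none
        # touches the diagonal band
        for i, j in [(0, 10), (3, 20), (7, 27), (12, 25), (15, 5)]:
            rec[i, j] = rec[j, i] = True
        dist = rng.uniform(0.05, 0.4, (n, n)).astype(np.float32)
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        plot, dm = self.plot_from(rec, dist)
        once = erode(plot, dm)
        assert np.array_equal(once.recurrent, rec)
        twice = erode(
            rp.RecurrencePlot(once.recurrent, 0.1, 1.0, 5), dm
        )
        assert np.array_equal(twice.recurrent, once.recurrent)

    def test_near_diagonal_band_collapses_onto_diagonal(self):
        n = 25
        rec = np.zeros((n, n), bool)
        for k in (-2, -1, 0, 1, 2):
            rec |= np.eye(n, k=k, dtype=bool)
        dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(np.float32) / 50
        plot, dm = self.plot_from(rec, dist)
        out = erode(plot, dm)
        assert np.array_equal(out.recurrent, np.eye(n, dtype=bool))

    def test_erosion_never_increases_recurrences(self, periodic_result):
        raw, er = periodic_result.rp_raw, periodic_result.rp
        assert er.recurrent.sum() <= raw.recurrent.sum()
        off = er.recurrent & ~np.eye(er.n, dtype=bool)
        assert not (off & ~raw.recurrent).any()  # eroded ⊆ raw off-diagonal
        assert recurrence_rate_per_cycle(er) <= recurrence_rate_per_cycle(raw)

    def test_double_erosion_rejected(self, periodic_result):
        with pytest.raises(ValueError):
            erode(periodic_result.rp, periodic_result.dm)


class TestPeriodicRecording:
    def test_eroded_one_recurrence_per_cycle_per_row(self, periodic_result):
        er = periodic_result.rp
        afcl = er.afcl_samples
        n = er.n
        per_row = er.recurrent.sum(axis=1) - 1  # off-diagonal
        expected = np.array([(n - 1) // afcl for _ in range(n)])
        interior = slice(afcl, n - afcl)
        # each interior row recurs once per cycle of the recording (±1)
        assert np.all(np.abs(per_row[interior] - expected[interior]) <= 1)

    def test_calibration_invariant_on_periodic_input(self, periodic_result):
        raw = periodic_result.rp_raw
        got = recurrence_rate_per_cycle(raw, exclude_band=True)
        assert got == pytest.approx(1.0, rel=0.05)
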