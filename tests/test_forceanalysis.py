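"""Rupture forces, replica aggregation, force-distance pairing, H-bonds."""

import numpy as np
import pytest

from smdfan.errors import AlignmentError, InputError
from smdfan.forceanalysis import (HBondCriterion, aggregate_replicas,
                                  anisotropy_table, count_hbonds,
                                  force_vs_distance, hbond_series,
                                  max_rupture_force, summarize_ruptures)
from smdfan.smdparse import ForceTrace


def trace(time, force, **kw):
    kw.setdefault("direction", np.array([0.0, 0.0, 1.0]))
    kw.setdefault("source", "toysim")
    return ForceTrace(time=np.asarray(time, float),
                      force=np.asarray(force, float), **kw)


class TestMaxRuptureForce:
    def test_triangle_profile(self):
        t = np.linspace(0, 10, 101)
        f = 50 - 10 * np.abs(t - 5)
        fmax, tat = max_rupture_force(trace(t, f))
        assert (fmax, tat) == (50.0, 5.0)

    def test_tie_break_earliest(self):
        tr = trace([0.0, 1.0, 2.0], [10.0, 10.0, 10.0])
        assert max_rupture_force(tr) == (10.0, 0.0)

    def test_equals_bruteforce_on_noisy_fixture(self):
        rng = np.random.default_rng(12)
        t = np.arange(10_000) * 0.1
        f = rng.normal(scale=30, size=10_000) + np.sin(t / 50) * 100
        tr = trace(t, f)
        fmax, tat = max_rupture_force(tr)
        # independent brute-force scan
        best_f, best_t = -np.inf, None
        for ti, fi in zip(t, f):
            if fi > best_f:
                best_f, best_t = fi, ti
        assert fmax == best_f and tat == best_t

    def test_bound_property(self):
        rng = np.random.default_rng(13)
        tr = trace(np.arange(100.0), rng.normal(size=100))
        fmax, _ = max_rupture_force(tr)
        assert np.all(fmax >= tr.force)

    def test_empty_trace_rejected(self):
        tr = trace([0.0], [1.0])
        tr.time = np.array([]); tr.force = np.array([])
        with pytest.raises(InputError):
            max_rupture_force(tr)


class TestForceVsDistance:
    def test_triangle_peak_preserved(self):
        t = np.linspace(0, 10, 11)
        f = 50 - 10 * np.abs(t - 5)
        d = 10 + t  # linear COM separation
        pairs = force_vs_distance(trace(t, f), d)
        k = int(np.argmax(pairs[:, 1]))
        assert pairs[k, 0] == 15.0 and pairs[k, 1] == 50.0

    def test_constant_distance_degenerate(self):
        pairs = force_vs_distance(trace([0, 1, 2.0], [1, 2, 3.0]),
                                  [7.0, 7.0, 7.0])
        assert np.allclose(pairs[:, 0], 7.0)

    def test_random_fixture_zip_equality(self):
        rng = np.random.default_rng(3)
        t = np.arange(50.0)
        f = rng.normal(size=50)
        d = rng.uniform(5, 30, size=50)
        pairs = force_vs_distance(trace(t, f), d)
        assert np.array_equal(pairs, np.column_stack([d, f]))

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            force_vs_distance(trace([0, 1.0], [1, 1.0]), [1.0])


class TestAggregateReplicas:
    def test_identical_traces_zero_sd(self):
        tr = trace(np.arange(10.0), np.sin(np.arange(10.0)))
        ens = aggregate_replicas([tr, trace(tr.time, tr.force)])
        assert np.allclose(ens.sd_force, 0.0)
        assert np.allclose(ens.mean_force, np.interp(
            ens.common_time, tr.time, tr.force))

    def test_two_constant_traces(self):
        t = np.arange(5.0)
        ens = aggregate_replicas([trace(t, np.full(5, 1.0)),
                                  trace(t, np.full(5, 3.0))])
        assert np.allclose(ens.mean_force, 2.0)
        assert np.allclose(ens.sd_force, np.sqrt(2.0))

    def test_single_trace_sd_zero(self):
        ens = aggregate_replicas([trace(np.arange(4.0), np.arange(4.0))])
        assert np.allclose(ens.sd_force, 0.0)

    def test_five_synthetic_traces_match_direct_computation(self):
        rng = np.random.default_rng(9)
        traces = [trace(np.arange(0, 10, 0.5), rng.normal(size=20))
                  for _ in range(5)]
        ens = aggregate_replicas(traces, grid_dt=0.5)
        ys = np.array([np.interp(ens.common_time, tr.time, tr.force)
                       for tr in traces])
        assert np.allclose(ens.mean_force, ys.mean(axis=0))
        assert np.allclose(ens.sd_force, ys.std(axis=0, ddof=1))

    def test_overlap_is_intersection(self):
        a = trace(np.arange(0, 10.0), np.zeros(10))
        b = trace(np.arange(5, 15.0), np.zeros(10))
        ens = aggregate_replicas([a, b])
        assert ens.common_time[0] >= 5.0 and ens.common_time[-1] <= 9.0

    def test_disjoint_spans_rejected(self):
        a = trace([0.0, 1.0], [0.0, 0.0])
        b = trace([5.0, 6.0], [0.0, 0.0])
        with pytest.raises(AlignmentError):
            aggregate_replicas([a, b])


def brute_force_hbond_count(frame, donors, acceptors, crit):
    """Independent O(donors x acceptors) double loop."""
    count = 0
    for d, h in donors:
        for a in acceptors:
            if a == d:
                continue
            if np.linalg.norm(frame[a] - frame[d]) > crit.d_max:
                continue
            v1 = frame[d] - frame[h]
            v2 = frame[a] - frame[h]
            cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang >= crit.angle_min:
                count += 1
    return count


class TestHBonds:
    def linear_nho(self, r_na=2.8):
        # N at origin, H 1 A along +z, O acceptor at r_na along +z
        return np.array([[0, 0, 0.0], [0, 0, 1.0], [0, 0, r_na]])

    def test_ideal_linear_bond(self):
        n = count_hbonds(self.linear_nho(2.8), [(0, 1)], [2])
        assert n == 1

    def test_distance_cutoff(self):
        assert count_hbonds(self.linear_nho(5.0), [(0, 1)], [2]) == 0

    def test_angle_cutoff(self):
        frame = self.linear_nho(2.8)
        frame[1] = [1.0, 0, 0]  # H perpendicular: angle ~45 deg
        assert count_hbonds(frame, [(0, 1)], [2]) == 0

    def test_matches_double_loop_on_random_frames(self):
        rng = np.random.default_rng(21)
        crit = HBondCriterion(d_max=3.5, angle_min=120.0)
        for _ in range(100):
            frame = rng.uniform(0, 8, size=(20, 3))
            donors = [(i, i + 1) for i in range(0, 10, 2)]
            acceptors = list(range(10, 20))
            assert count_hbonds(frame, donors, acceptors, crit) == \
                brute_force_hbond_count(frame, donors, acceptors, crit)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(22)
        frame = rng.uniform(0, 6, size=(12, 3))
        donors = [(0, 1), (2, 3), (4, 5)]
        acceptors = [6, 7, 8, 9, 10, 11]
        n0 = count_hbonds(frame, donors, acceptors)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = frame @ q.T + np.array([5.0, -2.0, 9.0])
        assert count_hbonds(moved, donors, acceptors) == n0

    def test_inter_fragment_filter(self):
        frame = self.linear_nho(2.8)
        frag_same = {0: 0, 1: 0, 2: 0}
        frag_diff = {0: 0, 1: 0, 2: 1}
        assert count_hbonds(frame, [(0, 1)], [2], fragment_of=frag_same) == 0
        assert count_hbonds(frame, [(0, 1)], [2], fragment_of=frag_diff) == 1

    def test_series_drop_at_break_frame(self):
        # scripted trajectory: acceptor walks away after frame 3
        frames = []
        for k in range(8):
            f = self.linear_nho(2.8)
            if k >= 3:
                f[2, 2] += 10.0
            frames.append(f)
        series = hbond_series(frames, [(0, 1)], [2])
        assert list(series) == [1, 1, 1, 0, 0, 0, 0, 0]

    def test_static_trajectory_constant(self):
        frames = [self.linear_nho(2.8)] * 5
        assert np.all(hbond_series(frames, [(0, 1)], [2]) == 1)

    def test_criterion_validation(self):
        with pytest.raises(InputError):
            HBondCriterion(d_max=-1.0)
        with pytest.raises(InputError):
            HBondCriterion(angle_min=200.0)

    def test_index_out_of_range(self):
        with pytest.raises(InputError):
            count_hbonds(np.zeros((3, 3)), [(0, 5)], [2])


class TestAnisotropyTable:
    def _summary(self, label, theta, phi, forces):
        traces = [trace(np.arange(4.0), np.full(4, f)) for f in forces]
        return summarize_ruptures(label, theta, phi, traces)

    def test_shape_and_order(self):
        rng = np.random.default_rng(31)
        summaries = [self._summary(f"theta_45_phi_{p}", 45, p,
                                   rng.uniform(10, 50, 5))
                     for p in (0, 90, 180, 270)]
        table = anisotropy_table(summaries)
        assert len(table) == 4
        assert list(table["label"]) == [s.label for s in summaries]

    def test_single_replica_sd_zero(self):
        table = anisotropy_table([self._summary("d", 0, 0, [13.0])])
        assert table["sd_f_max_pN"].iloc[0] == 0.0

    def test_values_equal_direct_recomputation(self):
        forces = [11.0, 14.0, 9.5, 20.0, 17.0]
        table = anisotropy_table([self._summary("d", 0, 0, forces)])
        assert table["mean_f_max_pN"].iloc[0] == pytest.approx(np.mean(forces))
        assert table["sd_f_max_pN"].iloc[0] == pytest.approx(
            np.std(forces, ddof=1))

    def test_duplicate_labels_rejected(self):
        s = self._summary("d", 0, 0, [1.0])
        with pytest.raises(InputError):
            anisotropy_table([s, s])
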