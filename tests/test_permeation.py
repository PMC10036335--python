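"""Crossing classification, %M2 summaries, pore-radius windows, occupancy."""

import numpy as np
import pytest

import gatekin as gk
from gatekin.permeation import (
    BoundsError,
    CompartmentBounds,
    PoreProfile,
    events_to_table,
)

SYM = CompartmentBounds(14.0, 9.0, -9.0, -14.0, commit_margin=5.0)


class TestBounds:
    def test_defaults_follow_pore_windows(self):
        b = CompartmentBounds()
        assert (b.z_m3_commit, b.z_vest_top) == (14.1, 8.8)
        assert (b.z_m2_top, b.z_m2_bottom) == (-3.9, -7.0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(BoundsError):
            CompartmentBounds(8.8, 14.1, -3.9, -7.0)

    def test_margin_swallowing_vestibule_rejected(self):
        with pytest.raises(BoundsError):
            CompartmentBounds(14.1, 8.8, -3.9, -7.0, commit_margin=7.0)


class TestDetectCrossings:
    def test_monotone_outward_trace(self):
        ev = gk.detect_crossings([("i0", np.linspace(0, 25, 200))],
                                 CompartmentBounds())
        assert len(ev) == 1
        e = ev[0]
        assert (e.barrier, e.direction) == ("M3", "outward")
        assert e.start_compartment == "vestibule"
        assert e.frame_commit > e.frame_start

    def test_window_excursion_without_commit_is_ignored(self):
        z = np.concatenate([np.linspace(2, 13, 50), np.linspace(13, 2, 50)])
        assert gk.detect_crossings([("i1", z)], CompartmentBounds()) == []

    def test_zero_margin_reproduces_plane_crossing(self):
        b = CompartmentBounds(commit_margin=0.0)
        z = np.array([0.0, 15.0, 0.0, -8.0])
        ev = gk.detect_crossings([("i2", z)], b)
        assert [(e.barrier, e.direction) for e in ev] == [
            ("M3", "outward"), ("M3", "inward"), ("M2", "inward")]

    def test_direct_jump_counts_both_barriers(self):
        z = np.array([-20.0, 25.0])
        ev = gk.detect_crossings([("i3", z)], CompartmentBounds())
        assert [(e.barrier, e.direction) for e in ev] == [
            ("M2", "outward"), ("M3", "outward")]
        assert all(e.start_compartment == "intracellular" for e in ev)

    def test_nan_trace_rejected_with_ion_id(self):
        z = np.array([0.0, np.nan, 25.0])
        with pytest.raises(ValueError, match="ion7"):
            gk.detect_crossings([("ion7", z)], CompartmentBounds())

    def test_empty_traces_give_empty_result(self):
        assert gk.detect_crossings([], CompartmentBounds()) == []

    def test_matches_generator_ground_truth(self):
        traces = gk.simulate_ion_traces(300, 600, bounds=SYM, seed=71)
        det = gk.detect_crossings(traces, SYM)
        assert events_to_table(det).equals(events_to_table(traces.ground_truth))
        assert len(det) > 100

    def test_time_reversal_flips_directions(self):
        traces = gk.simulate_ion_traces(150, 500, bounds=SYM, seed=72)
        fwd = gk.detect_crossings(traces, SYM)
        rev = gk.detect_crossings(
            zip(traces.ion_ids, traces.z[:, ::-1]), SYM
        )
        flip = {"outward": "inward", "inward": "outward"}
        fwd_counts = {}
        rev_counts = {}
        for e in fwd:
            key = (e.barrier, flip[e.direction])
            fwd_counts[key] = fwd_counts.get(key, 0) + 1
        for e in rev:
            key = (e.barrier, e.direction)
            rev_counts[key] = rev_counts.get(key, 0) + 1
        assert fwd_counts == rev_counts


class TestCrossingSummary:
    def _events(self, n_m2, n_m3, start="vestibule"):
        return [
            gk.CrossingEvent("x", "M2", "inward", start, 0, 1)
            for _ in range(n_m2)
        ] + [
            gk.CrossingEvent("x", "M3", "outward", start, 0, 1)
            for _ in range(n_m3)
        ]

    def test_percentage_definition(self):
        s = gk.crossing_summary(self._events(22, 34))
        assert s.pct_m2_total == pytest.approx(100 * 22 / 56)
        assert s.n_m2 == 22 and s.n_m3 == 34

    def test_restrict_start_filters_headline_counts(self):
        evs = self._events(3, 5, "vestibule") + self._events(4, 6, "extracellular")
        s_all = gk.crossing_summary(evs)
        s_vest = gk.crossing_summary(evs, restrict_start="vestibule")
        assert (s_all.n_m2, s_all.n_m3) == (7, 11)
        assert (s_vest.n_m2, s_vest.n_m3) == (3, 5)
        assert s_all.n_m2_vestibule_start == 3
        assert s_vest.pct_m2_total == s_all.pct_m2_vestibule

    def test_zero_events_leave_percentages_absent(self):
        s = gk.crossing_summary([])
        assert s.pct_m2_total is None
        assert s.pct_m2_vestibule is None

    def test_symmetric_null_is_fifty_percent(self):
        # unbiased walks from the vestibule exit evenly across both barriers;
        # each ion's first crossing is an independent Bernoulli(1/2) trial
        traces = gk.simulate_ion_traces(800, 1500, bounds=SYM, seed=73)
        events = gk.detect_crossings(traces, SYM)
        first = {}
        for e in events:
            if e.start_compartment == "vestibule" and e.ion_id not in first:
                first[e.ion_id] = e.barrier
        n = len(first)
        pct = 100 * sum(1 for b in first.values() if b == "M2") / n
        se = 100 * np.sqrt(0.25 / n)
        assert n > 500
        assert abs(pct - 50.0) < 3 * se


class TestWindowRadius:
    def test_constant_profile(self):
        p = PoreProfile(np.linspace(-10, 20, 61), np.full((5, 61), 2.0))
        w = gk.window_radius(p, 8.8, 14.1)
        assert (w.mean, w.sd, w.min, w.max) == (2.0, 0.0, 2.0, 2.0)

    def test_two_frame_arithmetic(self):
        z = np.linspace(0, 10, 11)
        radii = np.vstack([np.full(11, 1.0), np.full(11, 3.0)])
        w = gk.window_radius(PoreProfile(z, radii), 0, 10)
        assert w.mean == pytest.approx(2.0)
        assert (w.min, w.max) == (1.0, 3.0)

    def test_linear_profile_integral(self):
        # r(z) = z/10 averaged on [8.8, 14.1] -> midpoint value 1.145
        z = np.arange(8.8, 14.1 + 1e-9, 0.1)
        p = PoreProfile(z, (z / 10.0)[None, :])
        w = gk.window_radius(p, 8.8, 14.1)
        assert w.mean == pytest.approx(1.145, abs=0.005)

    def test_empty_window_rejected(self):
        p = PoreProfile(np.linspace(0, 10, 11), np.ones((1, 11)))
        with pytest.raises(ValueError, match="window"):
            gk.window_radius(p, 20.0, 25.0)

    def test_profile_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        z = np.linspace(-5, 5, 11)
        radii = np.random.default_rng(1).uniform(1, 3, (3, 11))
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(3), 11),
                "z_A": np.tile(z, 3),
                "radius_A": radii.ravel(),
            }
        )
        path = tmp_path / "profile.tsv"
        df.to_csv(path, sep="\t", index=False)
        p = PoreProfile.from_tsv(path)
        assert np.allclose(p.z, z)
        assert np.allclose(p.radii, radii)


class TestCompartmentOccupancy:
    def test_all_inside(self):
        b = CompartmentBounds()
        counts = gk.compartment_occupancy(np.zeros((4, 7)), b)
        assert np.array_equal(counts, [7, 7, 7, 7])

    def test_constructed_pattern(self):
        b = CompartmentBounds()
        frame = np.array([[0.0, 20.0, -5.0, -10.0, 14.1]])
        # inside slab: 0.0, -5.0 (>= -3.9? no: -5.0 < -3.9 -> outside), 14.1
        counts = gk.compartment_occupancy(frame, b)
        assert counts[0] == 2

    def test_uniform_density_fraction(self):
        b = CompartmentBounds()
        rng = np.random.default_rng(3)
        n = 2000
        z = rng.uniform(-30, 30, (200, n))
        counts = gk.compartment_occupancy(z, b)
        expect = n * (b.z_m3_commit - b.z_m2_top) / 60.0
        se = np.sqrt(n * 0.3 * 0.7) / np.sqrt(200)
        assert abs(counts.mean() - expect) < 3 * se
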