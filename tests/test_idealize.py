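"""Idealization: threshold and SKM detectors, dead-time imposition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import gatekin as gk
from gatekin.dwells import DwellSequence
from gatekin.idealize import IdealizationError, impose_dead_time


def _grid_sequence(dt):
    """Dwell sequence whose durations are exact multiples of dt."""
    return DwellSequence.from_events(
        [("closed", 10 * dt), ("open", 5 * dt), ("closed", 3 * dt),
         ("open", 7 * dt), ("closed", 12 * dt)]
    )


class TestHalfAmplitude:
    def test_noiseless_roundtrip(self):
        dt = 4e-5
        d = _grid_sequence(dt)
        tr = gk.render_trace(d, dt, {"closed": 0.0, "open": -6.0})
        rec = gk.half_amplitude_idealize(tr, (0.0, -6.0))
        assert np.array_equal(rec.classes, d.classes)
        assert np.allclose(rec.durations, d.durations, rtol=1e-12)

    def test_all_closed_trace(self):
        tr = gk.CurrentTrace(np.zeros(500), dt=1e-4)
        rec = gk.half_amplitude_idealize(tr, (0.0, -6.0))
        assert rec.n_events == 1
        assert rec.classes[0] == 0
        assert rec.durations[0] == pytest.approx(0.05)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            gk.half_amplitude_idealize(gk.CurrentTrace(np.zeros(1), 1e-4),
                                       (0.0, -6.0))

    def test_identical_levels_rejected(self):
        with pytest.raises(ValueError):
            gk.half_amplitude_idealize(gk.CurrentTrace(np.zeros(10), 1e-4),
                                       (1.0, 1.0))

    def test_snr10_recovers_events_above_1ms(self):
        # millisecond-scale events at SNR 10 are essentially always recovered
        scheme = gk.build_scheme(
            [("C", "O", 40.0), ("O", "C", 100.0)], {"C": "closed", "O": "open"}
        )
        dt = 4e-5
        d = gk.simulate_dwell_sequence(scheme, 30.0, seed=9)
        tr = gk.render_trace(d, dt, {"closed": 0.0, "open": -6.0},
                             noise_sd=0.6, seed=10)
        rec = gk.half_amplitude_idealize(tr, (0.0, -6.0))
        labels = np.repeat(rec.classes, np.rint(rec.durations / dt).astype(int))
        cum = np.concatenate([[0.0], np.cumsum(d.durations)])
        mids = (cum[:-1] + cum[1:]) / 2
        checked = correct = 0
        for c, mid, dur in zip(d.classes, mids, d.durations):
            if dur < 1e-3:
                continue
            i = int(mid / dt)
            if i < labels.size:
                checked += 1
                correct += int(labels[i] == c)
        assert checked > 500
        assert correct / checked >= 0.99


class TestSKM:
    def test_noiseless_is_fixed_point(self):
        dt = 4e-5
        d = _grid_sequence(dt)
        tr = gk.render_trace(d, dt, {"closed": 0.0, "open": -6.0})
        res = gk.skm_idealize(tr, init_amplitudes=[0.0, -6.0])
        assert res.converged
        assert res.iterations == 1
        assert np.array_equal(res.dwells.classes, d.classes)
        assert np.allclose(res.dwells.durations, d.durations)

    def test_matches_half_amplitude_on_noiseless_trace(self, two_state):
        dt = 4e-5
        d = gk.simulate_dwell_sequence(two_state, 2.0, seed=13)
        tr = gk.render_trace(d, dt, {"closed": 0.0, "open": -6.0})
        ha = gk.half_amplitude_idealize(tr, (0.0, -6.0))
        skm = gk.skm_idealize(tr, init_amplitudes=[0.0, -6.0]).dwells
        assert np.array_equal(skm.classes, ha.classes)
        assert np.allclose(skm.durations, ha.durations)

    def test_swapped_init_same_segmentation(self, two_state):
        d = gk.simulate_dwell_sequence(two_state, 5.0, seed=14)
        tr = gk.render_trace(d, 4e-5, {"closed": 0.0, "open": -6.0},
                             noise_sd=1.0, seed=15)
        a = gk.skm_idealize(tr, init_amplitudes=[0.0, -6.0])
        b = gk.skm_idealize(tr, init_amplitudes=[-6.0, 0.0])
        assert np.array_equal(a.dwells.classes, b.dwells.classes)
        assert np.allclose(a.fitted_amplitudes, b.fitted_amplitudes)

    def test_auto_init_finds_levels(self, two_state):
        d = gk.simulate_dwell_sequence(two_state, 5.0, seed=16)
        tr = gk.render_trace(d, 4e-5, {"closed": 0.0, "open": -6.0},
                             noise_sd=0.8, seed=17)
        res = gk.skm_idealize(tr)
        assert res.fitted_amplitudes[0] == pytest.approx(0.0, abs=0.1)
        assert res.fitted_amplitudes[1] == pytest.approx(-6.0, abs=0.1)

    def test_degenerate_class_raises(self):
        tr = gk.CurrentTrace(np.zeros(1000), dt=1e-4)
        with pytest.raises(IdealizationError):
            gk.skm_idealize(tr, init_amplitudes=[0.0, -6.0])


class TestImposeDeadTime:
    def test_noop_when_all_events_long(self):
        d = DwellSequence.from_events([("open", 0.005), ("closed", 0.003)])
        out = impose_dead_time(d, 1e-4)
        assert np.array_equal(out.classes, d.classes)
        assert np.allclose(out.durations, d.durations)
        assert out.dead_time == 1e-4

    def test_short_gap_merges_into_preceding(self):
        d = DwellSequence.from_events(
            [("open", 5e-3), ("closed", 1e-5), ("open", 3e-3)]
        )
        out = impose_dead_time(d, 2e-5)
        assert out.n_events == 1
        assert out.events[0][0] == "open"
        assert out.durations[0] == pytest.approx(8.01e-3)

    def test_leading_short_event_merges_forward(self):
        d = DwellSequence.from_events(
            [("closed", 1e-5), ("open", 5e-3), ("closed", 2e-3)]
        )
        out = impose_dead_time(d, 2e-5)
        assert out.events[0] == ("open", pytest.approx(5.01e-3))

    def test_all_short_collapses_with_warning(self):
        d = DwellSequence.from_events([("open", 1e-5), ("closed", 1e-5)])
        with pytest.warns(UserWarning):
            out = impose_dead_time(d, 1e-3)
        assert out.n_events == 1
        assert out.durations[0] == pytest.approx(2e-5)

    @staticmethod
    def _reference(d: DwellSequence, td: float) -> DwellSequence:
        """Brute-force rule: each sub-dead-time event is absorbed by the
        nearest preceding resolvable event (the following one if none
        precedes); adjacent same-class survivors then merge."""
        anchors = [i for i, dur in enumerate(d.durations) if dur >= td]
        if not anchors:
            return DwellSequence(
                d.classes[:1].copy(), np.array([d.durations.sum()]), dead_time=td
            )
        dur = {i: float(d.durations[i]) for i in anchors}
        for i, dv in enumerate(d.durations):
            if dv >= td:
                continue
            prev = [a for a in anchors if a < i]
            target = prev[-1] if prev else anchors[0]
            dur[target] += float(dv)
        cls_out: list[int] = []
        dur_out: list[float] = []
        for a in anchors:
            c = int(d.classes[a])
            if cls_out and cls_out[-1] == c:
                dur_out[-1] += dur[a]
            else:
                cls_out.append(c)
                dur_out.append(dur[a])
        return DwellSequence(np.array(cls_out, np.uint8), np.array(dur_out),
                             dead_time=td)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=0.1), min_size=1,
                 max_size=60),
        st.integers(0, 1),
        st.floats(min_value=1e-5, max_value=5e-3),
    )
    def test_matches_bruteforce_reference(self, durs, first, td):
        classes = ((np.arange(len(durs)) + first) % 2).astype(np.uint8)
        d = DwellSequence(classes, np.array(durs))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = impose_dead_time(d, td)
            ref = self._reference(d, td)
        assert np.array_equal(out.classes, ref.classes)
        assert np.allclose(out.durations, ref.durations, rtol=1e-12)
        # conservation and resolution invariants
        assert out.total_duration == pytest.approx(d.total_duration, rel=1e-9)
        if out.n_events > 1:
            assert np.all(out.durations >= td)
        # idempotence
        again = impose_dead_time(out, td)
        assert np.array_equal(again.classes, out.classes)
        assert np.allclose(again.durations, out.durations)


def test_idealized_histogram_matches_truncated_mixture(chain_scheme):
    """Closed dwell histogram after dead-time imposition follows the
    predicted mixture truncated at the dead time (chi-square GOF)."""
    mix = gk.predicted_dwell_mixture(chain_scheme, gk.CLOSED)
    td = 20e-6
    d = impose_dead_time(
        gk.simulate_dwell_sequence(chain_scheme, 4000.0, seed=42,
                                   max_events=60_000),
        td,
    )
    tc = d.closed_durations
    a, tau = mix.areas, mix.taus

    def surv(t):
        return np.sum(a * np.exp(-np.atleast_1d(t)[:, None] / tau), axis=1)

    edges = np.concatenate(
        [np.geomspace(td, np.quantile(tc, 0.999), 15), [np.inf]]
    )
    se = np.concatenate([surv(edges[:-1]), [0.0]])
    prob = (se[:-1] - se[1:]) / surv(np.array([td]))[0]
    obs, _ = np.histogram(tc, bins=edges)
    expected = prob * obs.sum() / prob.sum()
    assert expected.min() > 5
    assert stats.chisquare(obs, expected).pvalue > 0.01
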