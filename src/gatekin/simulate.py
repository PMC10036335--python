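"""Ground-truth generators: CTMC gating records, noisy current traces,
two-gate scheme presets, and 1-D ion random walks.

Every generator takes an integer ``seed`` and is bit-reproducible for a
fixed seed.  Dwell sequences come from an exact Gillespie path through the
scheme, aggregated by class; traces are piecewise-constant renderings with
optional Gaussian low-pass filtering and additive white Gaussian noise; ion
traces are reflected Gaussian random walks with configurable per-barrier
passage probability, emitted together with a ground-truth crossing log.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .dwells import CLOSED_CODE, OPEN_CODE, DwellSequence
from .permeation import (
    INWARD,
    M2,
    M3,
    OUTWARD,
    CompartmentBounds,
    CrossingEvent,
    _COMP_NAME,
)
from .schemes import CLOSED, OPEN, KineticScheme, SchemeError, build_scheme, \
    stationary_distribution

#: -3 dB cutoff of a Gaussian filter with impulse-response SD sigma_t is
#: fc = 0.1325 / sigma_t; the corresponding 10-90% step rise time is
#: approximately 0.34 / fc (standard single-channel filtering relation).
GAUSSIAN_SIGMA_FC = 0.1325


class _Uniforms:
    """Chunked stream of uniforms to keep the Gillespie loop cheap."""

    def __init__(self, rng: np.random.Generator, chunk: int = 1 << 14):
        self._rng = rng
        self._chunk = chunk
        self._buf = rng.random(chunk)
        self._i = 0

    def next(self) -> float:
        if self._i == self._buf.size:
            self._buf = self._rng.random(self._chunk)
            self._i = 0
        u = self._buf[self._i]
        self._i += 1
        return u


def simulate_dwell_sequence(
    scheme: KineticScheme,
    duration: float,
    seed: int | None = None,
    max_events: int | None = None,
) -> DwellSequence:
    """Exact Gillespie path through the scheme, aggregated by class.

    The chain starts from the stationary distribution (an equilibrium
    recording).  Consecutive state dwells within a class are merged into one
    event; the final event is truncated at ``duration``.  If ``max_events``
    is given, simulation also stops once that many aggregated events have
    been emitted.  The returned sequence has ``dead_time = 0``.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    n = scheme.n_states
    q = scheme.rates
    exit_rates = -np.diag(q)
    if np.any(~np.isfinite(exit_rates)) or np.any(exit_rates <= 0):
        raise SchemeError("every state must have a finite positive exit rate")
    jump_cum = np.cumsum(
        (q - np.diag(np.diag(q))) / exit_rates[:, None], axis=1
    )
    is_open = np.zeros(n, dtype=bool)
    is_open[scheme.states_of(OPEN)] = True

    pi = stationary_distribution(scheme).pi
    state = int(rng.choice(n, p=pi))

    classes: list[int] = []
    durs: list[float] = []
    u = _Uniforms(rng)
    t = 0.0
    cur_open = bool(is_open[state])
    cur_dur = 0.0
    while t < duration:
        dwell = -math.log(1.0 - u.next()) / exit_rates[state]
        if t + dwell > duration:
            dwell = duration - t
        t += dwell
        cur_dur += dwell
        if t >= duration:
            break
        nxt = int(np.searchsorted(jump_cum[state], u.next()))
        nxt = min(nxt, n - 1)
        if is_open[nxt] != cur_open:
            classes.append(OPEN_CODE if cur_open else CLOSED_CODE)
            durs.append(cur_dur)
            if max_events is not None and len(classes) >= max_events:
                cur_dur = 0.0
                break
            cur_open = bool(is_open[nxt])
            cur_dur = 0.0
        state = nxt
    if cur_dur > 0:
        classes.append(OPEN_CODE if cur_open else CLOSED_CODE)
        durs.append(cur_dur)
    return DwellSequence(
        np.array(classes, dtype=np.uint8),
        np.array(durs, dtype=float),
        dead_time=0.0,
        source=f"gillespie(seed={seed})",
    )


# ---------------------------------------------------------------------------
# current traces
# ---------------------------------------------------------------------------


@dataclass
class CurrentTrace:
    """Sampled current record (pA) with its generation metadata."""

    samples: np.ndarray
    dt: float
    noise_sd: float = 0.0
    amplitudes: dict = field(default_factory=dict)
    filter_cutoff: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "current_pA": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "CurrentTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        return cls(df["current_pA"].to_numpy(float), dt)


def render_trace(
    dwells: DwellSequence,
    dt: float,
    amplitudes: dict | None = None,
    noise_sd: float = 0.0,
    filter_cutoff: float = 0.0,
    seed: int | None = None,
) -> CurrentTrace:
    """Sample a dwell sequence into a noisy current trace.

    The ideal piecewise-constant trace is sampled at ``dt`` (event
    boundaries land on the nearest sample edge; the boundary sample belongs
    to the new class), optionally low-pass filtered with a Gaussian filter
    whose -3 dB cutoff is ``filter_cutoff`` Hz, then white Gaussian noise of
    SD ``noise_sd`` pA is added.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    amplitudes = amplitudes or {CLOSED: 0.0, OPEN: -6.0}
    if dwells.n_events == 0:
        warnings.warn("empty dwell sequence renders an empty trace")
        return CurrentTrace(np.empty(0), dt, noise_sd, dict(amplitudes), filter_cutoff)
    cum = np.cumsum(dwells.durations)
    edges = np.rint(cum / dt).astype(np.int64)
    edges[-1] = int(np.ceil(cum[-1] / dt))
    counts = np.diff(edges, prepend=0)
    amp_per_event = np.where(
        dwells.classes == OPEN_CODE, amplitudes[OPEN], amplitudes[CLOSED]
    )
    ideal = np.repeat(amp_per_event, counts)
    if filter_cutoff > 0:
        sigma_samples = GAUSSIAN_SIGMA_FC / (filter_cutoff * dt)
        ideal = gaussian_filter1d(ideal, sigma_samples, mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ideal = ideal + rng.normal(0.0, noise_sd, ideal.size)
    return CurrentTrace(ideal, dt, noise_sd, dict(amplitudes), filter_cutoff)


# ---------------------------------------------------------------------------
# scheme factories
# ---------------------------------------------------------------------------

#: Synthetic two-gate preset rates (s^-1).  These are package defaults chosen
#: so the wild-type-like preset sits at a realistic single-channel scale
#: (clusters of seconds separated by seconds-long interclusters, millisecond
#: open times) and the mutant-like presets perturb one gate each: the
#: "GluN1-glycine-like" preset loads the fast intra-cluster (M2) gate, which
#: depresses cluster open probability at unchanged cluster/intercluster
#: balance; the "GluN2-glycine-like" preset slows the cluster (M3) gate,
#: shortening clusters and stretching interclusters.  They target those
#: orderings, not any experimental rate values.
TWO_GATE_PRESETS: dict[str, dict[tuple[str, str], float]] = {
    "wildtype_like": {
        ("open", "intercluster"): 0.14,
        ("intercluster", "open"): 1.0 / 2.3,
        ("open", "flicker_closed"): 100.0,
        ("flicker_closed", "open"): 5000.0,
        ("open", "m2_closed"): 50.0,
        ("m2_closed", "open"): 500.0,
        ("open", "long_closed"): 6.0,
        ("long_closed", "open"): 10.0,
    },
    "n1_ga_like": {
        ("open", "intercluster"): 0.376,
        ("intercluster", "open"): 1.0 / 2.3,
        ("open", "flicker_closed"): 100.0,
        ("flicker_closed", "open"): 5000.0,
        ("open", "m2_closed"): 1500.0,
        ("m2_closed", "open"): 500.0,
        ("open", "long_closed"): 6.0,
        ("long_closed", "open"): 10.0,
    },
    "n2_ga_like": {
        ("open", "intercluster"): 0.45,
        ("intercluster", "open"): 0.15,
        ("open", "flicker_closed"): 100.0,
        ("flicker_closed", "open"): 5000.0,
        ("open", "m2_closed"): 50.0,
        ("m2_closed", "open"): 500.0,
        ("open", "long_closed"): 6.0,
        ("long_closed", "open"): 4.0,
    },
}

_TWO_GATE_CLASSES = {
    "intercluster": CLOSED,
    "flicker_closed": CLOSED,
    "m2_closed": CLOSED,
    "long_closed": CLOSED,
    "open": OPEN,
}


def make_two_gate_scheme(
    preset: str = "wildtype_like",
    overrides: dict[tuple[str, str], float] | None = None,
) -> KineticScheme:
    """Five-state star scheme with a slow cluster gate and two fast gates.

    All closed states connect only through the open state: ``intercluster``
    (seconds-long silent periods, the slow gate), ``flicker_closed`` and
    ``m2_closed`` (sub-millisecond and millisecond intra-cluster closures,
    the fast gates), and ``long_closed`` (the ~hundred-millisecond closed
    component).  ``overrides`` replaces individual ``(from, to)`` rates.
    """
    if preset not in TWO_GATE_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(TWO_GATE_PRESETS)}"
        )
    rates = dict(TWO_GATE_PRESETS[preset])
    if overrides:
        rates.update(overrides)
    return build_scheme(
        [(a, b, r) for (a, b), r in rates.items()], _TWO_GATE_CLASSES
    )


#: Default multi-state reference scheme: five closed and three open
#: exponential components with well-separated time constants, the component
#: structure characteristic of equilibrium NMDA-receptor gating records.
DEFAULT_CLOSED_TAUS = (1e-4, 1e-3, 1e-2, 0.15, 1.5)
DEFAULT_CLOSED_AREAS = (0.30, 0.25, 0.20, 0.15, 0.10)
DEFAULT_OPEN_TAUS = (3e-4, 3e-3, 1.5e-2)
DEFAULT_OPEN_AREAS = (0.35, 0.40, 0.25)


def make_bipartite_scheme(
    closed_taus=DEFAULT_CLOSED_TAUS,
    closed_areas=DEFAULT_CLOSED_AREAS,
    open_taus=DEFAULT_OPEN_TAUS,
    open_areas=DEFAULT_OPEN_AREAS,
) -> KineticScheme:
    """Scheme whose class sojourn mixtures are exactly the given components.

    States of one class connect only to states of the other, with exit
    probabilities independent of the source state.  Each class sojourn is
    then a single-state stay, so the closed/open dwell mixtures have exactly
    the requested (area, tau) components — a transparent ground truth for
    parameter-recovery studies.
    """
    ct, ca = np.asarray(closed_taus, float), np.asarray(closed_areas, float)
    ot, oa = np.asarray(open_taus, float), np.asarray(open_areas, float)
    for areas in (ca, oa):
        if not np.isclose(areas.sum(), 1.0):
            raise ValueError("component areas must sum to 1")
    if np.any(ct <= 0) or np.any(ot <= 0):
        raise ValueError("time constants must be positive")
    classes = {f"C{i+1}": CLOSED for i in range(ct.size)}
    classes.update({f"O{j+1}": OPEN for j in range(ot.size)})
    transitions = []
    for j, tau_o in enumerate(ot):
        for i, p in enumerate(ca):
            transitions.append((f"O{j+1}", f"C{i+1}", p / tau_o))
    for i, tau_c in enumerate(ct):
        for j, w in enumerate(oa):
            transitions.append((f"C{i+1}", f"O{j+1}", w / tau_c))
    return build_scheme(transitions, classes)


# ---------------------------------------------------------------------------
# ion random walks
# ---------------------------------------------------------------------------


@dataclass
class IonTraceSet:
    """Per-ion z(t) traces plus, for synthetic data, a ground-truth log."""

    ion_ids: tuple[str, ...]
    z: np.ndarray  # (n_ions, n_frames), angstrom
    frame_interval: float = 1.0
    bounds: CompartmentBounds | None = None
    ground_truth: list[CrossingEvent] | None = None

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if len(self.ion_ids) != self.z.shape[0]:
            raise ValueError("ion_ids length must match z rows")

    def to_tsv(self, path) -> None:
        n_ions, n_frames = self.z.shape
        pd.DataFrame(
            {
                "ion_id": np.repeat(self.ion_ids, n_frames),
                "frame": np.tile(np.arange(n_frames), n_ions),
                "z_A": self.z.ravel(),
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, frame_interval: float = 1.0) -> "IonTraceSet":
        df = pd.read_csv(path, sep="\t")
        wide = df.pivot(index="ion_id", columns="frame", values="z_A").sort_index()
        return cls(
            tuple(str(i) for i in wide.index),
            wide.to_numpy(float),
            frame_interval=frame_interval,
        )


def _ground_truth_walk(
    ion_id: str, z: np.ndarray, b: CompartmentBounds
) -> list[CrossingEvent]:
    """Naive per-frame compartment walk; the generator's ground-truth log."""
    m = b.commit_margin
    events: list[CrossingEvent] = []
    cur = None
    start_name = None
    last_frame = -1
    for t in range(z.size):
        zt = z[t]
        if zt >= b.z_m3_commit + m:
            comp = 2
        elif zt <= b.z_m2_bottom - m:
            comp = 0
        elif b.z_m2_top + m <= zt <= b.z_vest_top - m:
            comp = 1
        else:
            comp = None
        if comp is None:
            continue
        if cur is None:
            cur = comp
            start_name = _COMP_NAME[comp]
            last_frame = t
            continue
        if comp != cur:
            def emit(barrier, direction):
                events.append(
                    CrossingEvent(ion_id, barrier, direction, start_name,
                                  last_frame, t)
                )
            if cur == 1 and comp == 2:
                emit(M3, OUTWARD)
            elif cur == 2 and comp == 1:
                emit(M3, INWARD)
            elif cur == 1 and comp == 0:
                emit(M2, INWARD)
            elif cur == 0 and comp == 1:
                emit(M2, OUTWARD)
            elif cur == 0 and comp == 2:
                emit(M2, OUTWARD)
                emit(M3, OUTWARD)
            elif cur == 2 and comp == 0:
                emit(M3, INWARD)
                emit(M2, INWARD)
            cur = comp
        last_frame = t
    return events


def simulate_ion_traces(
    n_ions: int,
    frames: int,
    frame_interval: float = 1.0,
    bounds: CompartmentBounds | None = None,
    diffusion_sd: float = 1.5,
    barrier_pass_prob: float | dict = 1.0,
    seed: int | None = None,
    start: str | np.ndarray = "vestibule",
    z_limits: tuple[float, float] = (-30.0, 30.0),
) -> IonTraceSet:
    """Reflected 1-D Gaussian random walks through the pore compartments.

    Each proposed step that would cross a barrier plane (the midpoint of the
    M3 or M2 window) is accepted with the per-barrier passage probability
    and otherwise reflected about that plane; steps beyond ``z_limits`` are
    reflected back.  A ground-truth crossing log, computed by a naive
    per-frame compartment walk, is attached to the returned set.

    ``diffusion_sd`` is the per-frame step SD in angstrom (a free-diffusion
    scale); barrier passage probabilities model the free-energy barriers.
    """
    if frames <= 0:
        raise ValueError("frames must be positive")
    bounds = bounds or CompartmentBounds()
    zlo, zhi = z_limits
    if zlo >= zhi:
        raise ValueError("z_limits must be ordered (low, high)")
    if isinstance(barrier_pass_prob, dict):
        p_m3 = float(barrier_pass_prob.get("m3", 1.0))
        p_m2 = float(barrier_pass_prob.get("m2", 1.0))
    else:
        p_m3 = p_m2 = float(barrier_pass_prob)
    for p in (p_m3, p_m2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("barrier passage probabilities must lie in [0, 1]")
    m3_plane = 0.5 * (bounds.z_vest_top + bounds.z_m3_commit)
    m2_plane = 0.5 * (bounds.z_m2_top + bounds.z_m2_bottom)

    rng = np.random.default_rng(seed)
    if isinstance(start, str):
        if start != "vestibule":
            raise ValueError("start must be 'vestibule' or an array of z0")
        z0 = np.full(n_ions, 0.5 * (bounds.z_vest_top + bounds.z_m2_top))
    else:
        z0 = np.asarray(start, dtype=float)
        if z0.size != n_ions:
            raise ValueError("start array length must equal n_ions")
    traj = np.empty((n_ions, frames))
    traj[:, 0] = z0
    z = z0.copy()
    for t in range(1, frames):
        prop = z + rng.normal(0.0, diffusion_sd, n_ions)
        for plane, p in ((m3_plane, p_m3), (m2_plane, p_m2)):
            crossed = (z - plane) * (prop - plane) < 0
            if p < 1.0 and crossed.any():
                blocked = crossed & (rng.random(n_ions) >= p)
                prop[blocked] = 2 * plane - prop[blocked]
        prop = np.where(prop > zhi, 2 * zhi - prop, prop)
        prop = np.where(prop < zlo, 2 * zlo - prop, prop)
        z = prop
        traj[:, t] = z

    ids = tuple(f"ion{i}" for i in range(n_ions))
    log: list[CrossingEvent] = []
    for i, ion in enumerate(ids):
        log.extend(_ground_truth_walk(ion, traj[i], bounds))
    return IonTraceSet(
        ion_ids=ids,
        z=traj,
        frame_interval=frame_interval,
        bounds=bounds,
        ground_truth=log,
    )
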