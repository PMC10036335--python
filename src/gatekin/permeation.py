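"""Ion-permeation event counting and pore-geometry summaries from MD output.

The permeation pathway is divided along the pore (z) axis into three
residence compartments — extracellular, vestibule, and intracellular —
separated by two barrier windows: the M3 helix-bundle gate above the
vestibule and the M2 pore loop below it.  Per-ion z(t) traces are classified
into committed barrier crossings with a finite-state machine; a crossing is
counted only once the ion has penetrated ``commit_margin`` angstroms beyond
the far plane of the barrier it traversed, which suppresses boundary
re-crossing chatter.  Fractions of M2 crossings (%M2) report the relative
use of the two pathways.

Pore-radius profiles (e.g. HOLE output) are consumed, not computed:
:func:`window_radius` averages the radius over a z window per frame and
reduces across frames to mean +/- SD with min/max.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INTRACELLULAR = "intracellular"
VESTIBULE = "vestibule"
EXTRACELLULAR = "extracellular"

_COMP_NAME = {0: INTRACELLULAR, 1: VESTIBULE, 2: EXTRACELLULAR}

M3 = "M3"
M2 = "M2"
OUTWARD = "outward"
INWARD = "inward"


class BoundsError(ValueError):
    """Inconsistent compartment bounds."""


@dataclass(frozen=True)
class CompartmentBounds:
    """z-axis planes (angstrom) delimiting the permeation compartments.

    Defaults follow the pore-axis windows used for the radius analysis:
    M3 gate window 8.8-14.1 A, M2 loop window -3.9 to -7.0 A.  Extracellular
    lies beyond ``z_m3_commit``; intracellular below ``z_m2_bottom``; the
    vestibule sits between ``z_vest_top`` and ``z_m2_top``.  An ion commits
    to a compartment only ``commit_margin`` A beyond its boundary plane;
    a margin of 0 reproduces naive plane-crossing counts.
    """

    z_m3_commit: float = 14.1
    z_vest_top: float = 8.8
    z_m2_top: float = -3.9
    z_m2_bottom: float = -7.0
    commit_margin: float = 5.0

    def __post_init__(self) -> None:
        if not (
            self.z_m3_commit > self.z_vest_top > self.z_m2_top > self.z_m2_bottom
        ):
            raise BoundsError(
                "bounds must satisfy z_m3_commit > z_vest_top > z_m2_top > "
                f"z_m2_bottom, got {self}"
            )
        if self.commit_margin < 0:
            raise BoundsError("commit_margin must be non-negative")
        if self.z_m2_top + self.commit_margin >= self.z_vest_top - self.commit_margin:
            raise BoundsError(
                "commit_margin leaves no committed vestibule region"
            )

    def commit_codes(self, z: np.ndarray) -> np.ndarray:
        """Committed-compartment code per sample: 0 intra, 1 vest, 2 extra, -1 none."""
        z = np.asarray(z, dtype=float)
        m = self.commit_margin
        code = np.full(z.shape, -1, dtype=np.int8)
        code[(z >= self.z_m2_top + m) & (z <= self.z_vest_top - m)] = 1
        code[z >= self.z_m3_commit + m] = 2
        code[z <= self.z_m2_bottom - m] = 0
        return code


@dataclass(frozen=True)
class CrossingEvent:
    """One committed barrier passage by a tracked ion."""

    ion_id: str
    barrier: str  # "M3" | "M2"
    direction: str  # "outward" | "inward"
    start_compartment: str  # ion's first committed compartment in its trace
    frame_start: int  # last frame committed in the previous compartment
    frame_commit: int  # frame at which the new compartment was committed

    def __post_init__(self) -> None:
        if self.frame_commit <= self.frame_start:
            raise ValueError("frame_commit must exceed frame_start")


@dataclass(frozen=True)
class CrossingSummary:
    """Crossing counts and %M2 statistics.

    ``pct_m2_total`` is ``100 * n_m2 / (n_m2 + n_m3)`` over the events
    supplied (possibly restricted to vestibule-start ions); the
    ``*_vestibule_start`` fields always refer to ions whose first committed
    compartment was the vestibule.  Percentages are ``None`` when the
    denominator is zero.
    """

    n_m3: int
    n_m2: int
    pct_m2_total: float | None
    n_m3_vestibule_start: int
    n_m2_vestibule_start: int
    pct_m2_vestibule: float | None

    def to_dict(self) -> dict:
        return {
            "n_m3": self.n_m3,
            "n_m2": self.n_m2,
            "pct_m2_total": self.pct_m2_total,
            "n_m3_vestibule_start": self.n_m3_vestibule_start,
            "n_m2_vestibule_start": self.n_m2_vestibule_start,
            "pct_m2_vestibule": self.pct_m2_vestibule,
        }


# ---------------------------------------------------------------------------
# crossing detection
# ---------------------------------------------------------------------------

# events generated by a committed-compartment transition a -> b; direct
# intracellular<->extracellular jumps (possible with coarse frames) yield
# both barrier passages in traversal order
_TRANSITION_EVENTS: dict[tuple[int, int], tuple[tuple[str, str], ...]] = {
    (1, 2): ((M3, OUTWARD),),
    (2, 1): ((M3, INWARD),),
    (1, 0): ((M2, INWARD),),
    (0, 1): ((M2, OUTWARD),),
    (0, 2): ((M2, OUTWARD), (M3, OUTWARD)),
    (2, 0): ((M3, INWARD), (M2, INWARD)),
}


def _events_for_ion(
    ion_id: str, z: np.ndarray, bounds: CompartmentBounds
) -> list[CrossingEvent]:
    z = np.asarray(z, dtype=float)
    if z.size and not np.all(np.isfinite(z)):
        raise ValueError(f"ion {ion_id!r}: trace contains non-finite z values")
    codes = bounds.commit_codes(z)
    frames = np.nonzero(codes >= 0)[0]
    if frames.size == 0:
        return []
    seq = codes[frames]
    start = _COMP_NAME[int(seq[0])]
    events: list[CrossingEvent] = []
    change = np.nonzero(np.diff(seq) != 0)[0]
    for k in change:
        for barrier, direction in _TRANSITION_EVENTS[(int(seq[k]), int(seq[k + 1]))]:
            events.append(
                CrossingEvent(
                    ion_id=ion_id,
                    barrier=barrier,
                    direction=direction,
                    start_compartment=start,
                    frame_start=int(frames[k]),
                    frame_commit=int(frames[k + 1]),
                )
            )
    return events


def detect_crossings(traces, bounds: CompartmentBounds) -> list[CrossingEvent]:
    """Classify committed M3/M2 barrier passages for every ion trace.

    ``traces`` is anything with ``ion_ids`` and a ``z`` array of shape
    (n_ions, n_frames) — e.g. an ``IonTraceSet`` — or an iterable of
    ``(ion_id, z_array)`` pairs.  Traces containing NaN are rejected with an
    error naming the ion.
    """
    if hasattr(traces, "ion_ids") and hasattr(traces, "z"):
        pairs: Iterable = zip(traces.ion_ids, traces.z)
    else:
        pairs = traces
    events: list[CrossingEvent] = []
    for ion_id, z in pairs:
        events.extend(_events_for_ion(str(ion_id), np.asarray(z), bounds))
    return events


def crossing_summary(
    events: Sequence[CrossingEvent], restrict_start: str = "all"
) -> CrossingSummary:
    """Count M3/M2 crossings and the %M2 fractions.

    ``restrict_start="vestibule"`` restricts the headline counts to events
    from ions whose trace began (first committed) in the vestibule — the
    population for which an unbiased ion has even odds of leaving outward
    across M3 or inward across M2.
    """
    if restrict_start not in ("all", VESTIBULE):
        raise ValueError(f"restrict_start must be 'all' or 'vestibule'")
    vest = [e for e in events if e.start_compartment == VESTIBULE]
    head = vest if restrict_start == VESTIBULE else list(events)

    def _counts(evs):
        n_m3 = sum(1 for e in evs if e.barrier == M3)
        n_m2 = sum(1 for e in evs if e.barrier == M2)
        pct = 100.0 * n_m2 / (n_m2 + n_m3) if (n_m2 + n_m3) else None
        return n_m3, n_m2, pct

    n_m3, n_m2, pct_total = _counts(head)
    n_m3_v, n_m2_v, pct_v = _counts(vest)
    return CrossingSummary(n_m3, n_m2, pct_total, n_m3_v, n_m2_v, pct_v)


def events_to_table(events: Sequence[CrossingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ion_id": [e.ion_id for e in events],
            "barrier": [e.barrier for e in events],
            "direction": [e.direction for e in events],
            "start_compartment": [e.start_compartment for e in events],
            "frame_start": [e.frame_start for e in events],
            "frame_commit": [e.frame_commit for e in events],
        }
    )


# ---------------------------------------------------------------------------
# pore-radius profiles and pore occupancy
# ---------------------------------------------------------------------------


@dataclass
class PoreProfile:
    """Per-frame pore radius along the z axis for one replicate."""

    z: np.ndarray  # (n_z,), monotone increasing, angstrom
    radii: np.ndarray  # (n_frames, n_z), angstrom
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.radii = np.atleast_2d(np.asarray(self.radii, dtype=float))
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if self.radii.shape[1] != self.z.size:
            raise ValueError("radii row length must match z grid")
        if np.any(self.radii < 0):
            raise ValueError("pore radii must be non-negative")

    @classmethod
    def from_tsv(cls, path, replicate_id: str = "") -> "PoreProfile":
        """Long-format TSV with columns frame, z_A, radius_A."""
        df = pd.read_csv(path, sep="\t")
        wide = df.pivot(index="frame", columns="z_A", values="radius_A").sort_index()
        return cls(wide.columns.to_numpy(float), wide.to_numpy(float),
                   replicate_id=replicate_id or str(path))


@dataclass(frozen=True)
class WindowRadius:
    mean: float
    sd: float
    min: float
    max: float
    n_frames: int

    def to_dict(self) -> dict:
        return {"mean_A": self.mean, "sd_A": self.sd,
                "min_A": self.min, "max_A": self.max, "n_frames": self.n_frames}


def window_radius(
    profiles: Sequence[PoreProfile] | PoreProfile,
    z_min: float,
    z_max: float,
) -> WindowRadius:
    """Average pore radius over a z window, reduced across frames/replicates.

    The radius is averaged over grid points inside ``[z_min, z_max]`` for
    each frame; the per-frame means are pooled over replicates and reduced
    to mean, SD (ddof=1), and min/max.
    """
    if isinstance(profiles, PoreProfile):
        profiles = [profiles]
    per_frame: list[np.ndarray] = []
    for p in profiles:
        mask = (p.z >= z_min) & (p.z <= z_max)
        if not mask.any():
            raise ValueError(
                f"window [{z_min}, {z_max}] A contains no grid points "
                f"(replicate {p.replicate_id!r})"
            )
        per_frame.append(p.radii[:, mask].mean(axis=1))
    means = np.concatenate(per_frame)
    sd = float(means.std(ddof=1)) if means.size > 1 else 0.0
    return WindowRadius(
        mean=float(means.mean()),
        sd=sd,
        min=float(means.min()),
        max=float(means.max()),
        n_frames=int(means.size),
    )


def compartment_occupancy(
    frame_positions: np.ndarray, bounds: CompartmentBounds
) -> np.ndarray:
    """Per-frame count of particles inside the pore slab.

    The slab runs from the M2 top plane to the M3 commit plane (the region
    used to count pore waters).  ``frame_positions`` has shape
    (n_frames, n_particles) of z coordinates.
    """
    z = np.atleast_2d(np.asarray(frame_positions, dtype=float))
    inside = (z >= bounds.z_m2_top) & (z <= bounds.z_m3_commit)
    return inside.sum(axis=1)
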