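"""Idealized dwell sequences: the shared container between analysis stages.

A :class:`DwellSequence` is an ordered run of ``(class, duration)`` events —
the output of idealization and the input to dwell-time fitting and cluster
analysis.  Durations are seconds.  Classes alternate closed/open; after
dead-time imposition no event is shorter than the dead time.

Two text formats are supported: a plain TSV (``class`` / ``duration_s``
columns) and a QuB-style DWT segment file (integer class codes, durations in
milliseconds), so dwell tables can be exchanged with standard single-channel
software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemes import CLOSED, OPEN

CLOSED_CODE = 0
OPEN_CODE = 1
_CODE_OF = {CLOSED: CLOSED_CODE, OPEN: OPEN_CODE}
_NAME_OF = {CLOSED_CODE: CLOSED, OPEN_CODE: OPEN}


@dataclass
class DwellSequence:
    """Alternating (class, duration) events with dead-time metadata.

    ``classes`` holds integer codes (0 closed, 1 open) and ``durations``
    seconds; both are 1-D arrays of equal length.
    """

    classes: np.ndarray
    durations: np.ndarray
    dead_time: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.classes.shape != self.durations.shape or self.classes.ndim != 1:
            raise ValueError("classes and durations must be equal-length 1-D arrays")
        if self.classes.size and not np.all(np.isin(self.classes, (0, 1))):
            raise ValueError("class codes must be 0 (closed) or 1 (open)")
        if np.any(self.durations <= 0):
            raise ValueError("all dwell durations must be positive")
        if self.dead_time < 0:
            raise ValueError("dead_time must be non-negative")
        if self.dead_time > 0 and self.classes.size > 1:
            # a single-event record may legally be shorter than the dead time
            # (a record that collapsed entirely under dead-time imposition)
            if np.any(self.durations < self.dead_time * (1 - 1e-12)):
                raise ValueError("events shorter than the dead time are present")
            if np.any(np.diff(self.classes.astype(int)) == 0):
                raise ValueError("classes must alternate after dead-time imposition")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_events(
        cls, events, dead_time: float = 0.0, source: str = ""
    ) -> "DwellSequence":
        """Build from an iterable of ``("closed"|"open", seconds)`` pairs."""
        events = list(events)
        codes = np.array([_CODE_OF[c] for c, _ in events], dtype=np.uint8)
        durs = np.array([d for _, d in events], dtype=float)
        return cls(codes, durs, dead_time=dead_time, source=source)

    # -- views ------------------------------------------------------------
    @property
    def n_events(self) -> int:
        return int(self.classes.size)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    @property
    def open_durations(self) -> np.ndarray:
        return self.durations[self.classes == OPEN_CODE]

    @property
    def closed_durations(self) -> np.ndarray:
        return self.durations[self.classes == CLOSED_CODE]

    def durations_of(self, cls: str) -> np.ndarray:
        return self.durations[self.classes == _CODE_OF[cls]]

    @property
    def events(self) -> list[tuple[str, float]]:
        return [(_NAME_OF[c], float(d)) for c, d in zip(self.classes, self.durations)]

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"class": [_NAME_OF[c] for c in self.classes], "duration_s": self.durations}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, dead_time: float = 0.0) -> "DwellSequence":
        df = pd.read_csv(path, sep="\t")
        codes = df["class"].map(_CODE_OF).to_numpy(dtype=np.uint8)
        return cls(codes, df["duration_s"].to_numpy(float),
                   dead_time=dead_time, source=str(path))

    def to_dwt(self, path, segment: int = 1) -> None:
        """QuB-style DWT text: class code and duration in milliseconds."""
        with open(path, "w") as fh:
            fh.write(f"Segment: {segment} Dwells: {self.n_events}\n")
            for c, d in zip(self.classes, self.durations):
                fh.write(f"\t{int(c)}\t{d * 1e3:.6f}\n")

    @classmethod
    def from_dwt(cls, path, dead_time: float = 0.0) -> "DwellSequence":
        codes: list[int] = []
        durs: list[float] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.lower().startswith("segment"):
                    continue
                c, d = line.split()
                codes.append(int(c))
                durs.append(float(d) * 1e-3)
        return cls(np.array(codes, dtype=np.uint8), np.array(durs),
                   dead_time=dead_time, source=str(path))
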