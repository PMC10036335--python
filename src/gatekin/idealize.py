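"""Trace idealization: from noisy current samples to dwell sequences.

Two detectors are provided.  Half-amplitude threshold crossing classifies
each sample by the nearest of two known current levels — the classical
baseline method.  Segmental k-means (SKM) alternates Viterbi segmentation
under per-class Gaussian emissions (shared noise SD) with re-estimation of
the class amplitudes and of the transition probabilities from the current
segmentation, converging when the segmentation stops changing.

:func:`impose_dead_time` applies the recording dead time: events shorter
than the dead time are unresolvable and are merged into the preceding event
(a leading short event merges forward), conserving total duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .dwells import CLOSED_CODE, OPEN_CODE, DwellSequence
from .simulate import CurrentTrace


class IdealizationError(RuntimeError):
    """Idealization could not produce a usable segmentation."""


@dataclass
class IdealizationResult:
    """SKM output: dwells plus the fitted emission model."""

    dwells: DwellSequence
    fitted_amplitudes: np.ndarray  # pA, ordered [closed, open]
    fitted_noise_sd: float
    iterations: int
    converged: bool


def _runs_to_dwells(labels: np.ndarray, dt: float, source: str) -> DwellSequence:
    """Collapse a per-sample class-label array into run-length events."""
    if labels.size == 0:
        return DwellSequence(np.empty(0, np.uint8), np.empty(0), source=source)
    change = np.nonzero(np.diff(labels) != 0)[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    durations = (ends - starts) * dt
    return DwellSequence(labels[starts].astype(np.uint8), durations, source=source)


def half_amplitude_idealize(
    trace: CurrentTrace, levels: tuple[float, float]
) -> DwellSequence:
    """Classify each sample by the nearest of the two current levels.

    ``levels`` is ``(closed_amplitude, open_amplitude)`` in pA; the decision
    boundary is their midpoint (the half-amplitude criterion).  Runs of
    equal class become events of duration run_length * dt.
    """
    closed_amp, open_amp = levels
    if closed_amp == open_amp:
        raise ValueError("closed and open amplitudes must differ")
    if trace.n_samples < 2:
        raise ValueError("trace must contain at least 2 samples")
    x = trace.samples
    labels = np.where(
        np.abs(x - open_amp) < np.abs(x - closed_amp), OPEN_CODE, CLOSED_CODE
    ).astype(np.uint8)
    return _runs_to_dwells(labels, trace.dt, source="half_amplitude")


# ---------------------------------------------------------------------------
# segmental k-means
# ---------------------------------------------------------------------------


@njit(cache=False)
def _viterbi(x, means, inv_two_var, log_trans, log_init):  # pragma: no cover
    n = x.size
    k = means.size
    delta = np.empty(k)
    work = np.empty(k)
    back = np.empty((n, k), dtype=np.uint8)
    for j in range(k):
        d = x[0] - means[j]
        delta[j] = log_init[j] - d * d * inv_two_var
    for t in range(1, n):
        for j in range(k):
            best = delta[0] + log_trans[0, j]
            arg = 0
            for i in range(1, k):
                v = delta[i] + log_trans[i, j]
                if v > best:
                    best = v
                    arg = i
            d = x[t] - means[j]
            work[j] = best - d * d * inv_two_var
            back[t, j] = arg
        for j in range(k):
            delta[j] = work[j]
    path = np.empty(n, dtype=np.uint8)
    best = delta[0]
    arg = 0
    for j in range(1, k):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path[n - 1] = arg
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _auto_init_amplitudes(x: np.ndarray, n_classes: int) -> np.ndarray:
    """Class means from the largest well-separated modes of a 200-bin histogram."""
    counts, edges = np.histogram(x, bins=200)
    centers = 0.5 * (edges[:-1] + edges[1:])
    min_sep = (x.max() - x.min()) / 10 or 1.0
    order = np.argsort(counts)[::-1]
    picks: list[float] = []
    for i in order:
        c = centers[i]
        if all(abs(c - p) >= min_sep for p in picks):
            picks.append(float(c))
        if len(picks) == n_classes:
            break
    if len(picks) < n_classes:
        picks = list(np.quantile(x, np.linspace(0.05, 0.95, n_classes)))
    return np.sort(np.array(picks))


def skm_idealize(
    trace: CurrentTrace,
    n_classes: int = 2,
    init_amplitudes=None,
    max_iterations: int = 50,
) -> IdealizationResult:
    """Segmental k-means idealization of a current trace.

    Iterates (i) Viterbi segmentation under Gaussian emissions with a shared
    noise SD and transition probabilities estimated from the current
    segmentation, and (ii) re-estimation of the class means and SD from the
    assigned samples.  Stops when the segmentation is unchanged or after
    ``max_iterations`` (``converged=False``, not an error).  Classes in the
    result are ordered by increasing |amplitude|, so with a ~0 pA baseline
    the first class is closed regardless of initialization order.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    x = trace.samples
    if x.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    if init_amplitudes is None:
        means = _auto_init_amplitudes(x, n_classes)
    else:
        means = np.sort(np.asarray(init_amplitudes, dtype=float))
        if np.unique(means).size != n_classes:
            raise ValueError("init amplitudes must be distinct")

    labels = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1).astype(np.uint8)
    sd = max(float(np.std(x - means[labels])), 1e-12)
    reseeded = False
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        # transition probabilities from the current segmentation (+1 smoothing)
        counts = np.ones((n_classes, n_classes))
        np.add.at(counts, (labels[:-1], labels[1:]), 1)
        log_trans = np.log(counts / counts.sum(axis=1, keepdims=True))
        occ = np.bincount(labels, minlength=n_classes).astype(float)
        log_init = np.log((occ + 1) / (occ + 1).sum())
        new_labels = _viterbi(x, means, 1.0 / (2.0 * sd * sd), log_trans, log_init)
        # re-estimate emission model from the new segmentation
        new_occ = np.bincount(new_labels, minlength=n_classes)
        if np.any(new_occ == 0):
            if reseeded:
                raise IdealizationError(
                    "degenerate class (no samples assigned) after re-seeding"
                )
            reseeded = True
            means = np.quantile(x, np.linspace(0.05, 0.95, n_classes))
            labels = np.argmin(
                np.abs(x[:, None] - means[None, :]), axis=1
            ).astype(np.uint8)
            sd = max(float(np.std(x - means[labels])), 1e-12)
            continue
        means = np.array([x[new_labels == j].mean() for j in range(n_classes)])
        sd = max(float(np.std(x - means[new_labels])), 1e-12)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            converged = True
            break
        labels = new_labels
    if not converged:
        warnings.warn(f"SKM did not converge in {max_iterations} iterations")

    # label-fix: order classes by |amplitude| (baseline/closed first)
    order = np.argsort(np.abs(means))
    relabel = np.empty(n_classes, dtype=np.uint8)
    relabel[order] = np.arange(n_classes, dtype=np.uint8)
    labels = relabel[labels]
    means = means[order]
    dwells = _runs_to_dwells(labels, trace.dt, source="skm")
    return IdealizationResult(
        dwells=dwells,
        fitted_amplitudes=means,
        fitted_noise_sd=sd,
        iterations=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# dead time
# ---------------------------------------------------------------------------


def impose_dead_time(dwells: DwellSequence, td: float) -> DwellSequence:
    """Merge events shorter than the dead time into their neighbours.

    Every event shorter than ``td`` is deleted and its duration added to the
    preceding event; a leading short event merges into the following one.
    Adjacent same-class events are then merged.  Total duration is
    conserved and the operation is idempotent.  If no event reaches ``td``
    the whole record collapses to a single event (with a warning).
    """
    if td < 0:
        raise ValueError("dead time must be non-negative")
    if td == 0 or dwells.n_events == 0:
        return DwellSequence(
            dwells.classes.copy(), dwells.durations.copy(),
            dead_time=td, source=dwells.source,
        )
    out_cls: list[int] = []
    out_dur: list[float] = []
    pending = 0.0  # leading sub-dead-time duration carried forward
    for c, d in zip(dwells.classes, dwells.durations):
        if d < td:
            if out_cls:
                out_dur[-1] += d
            else:
                pending += d
            continue
        d = d + pending
        pending = 0.0
        if out_cls and out_cls[-1] == c:
            out_dur[-1] += d
        else:
            out_cls.append(int(c))
            out_dur.append(float(d))
    if pending > 0:
        # every event was shorter than td
        warnings.warn(
            "no event reached the dead time; record collapsed to one event"
        )
        out_cls = [int(dwells.classes[0])]
        out_dur = [pending]
    return DwellSequence(
        np.array(out_cls, dtype=np.uint8),
        np.array(out_dur, dtype=float),
        dead_time=td,
        source=dwells.source,
    )
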