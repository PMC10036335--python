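"""Critical-time cluster analysis of single-channel records.

Records of equilibrium channel activity show clusters — runs of rapid
open/close transitions — separated by long silent closed periods
(interclusters).  The boundary is a critical closed duration T_crit placed
between two adjacent closed mixture components (by default the third and
fourth): closed events longer than T_crit are intercluster separators.

Two T_crit conventions are implemented.  ``minimize_total`` minimizes the
total number of misclassified events, ``a_i exp(-t/tau_i) + a_j (1 -
exp(-t/tau_j))``, which has the closed form ``t* = ln(a_i tau_j / (a_j
tau_i)) / (1/tau_i - 1/tau_j)``; ``equal_misclassified`` instead equates
the two misclassified fractions and is solved by bisection.

Cluster statistics follow the standard definitions: cluster P_open is the
open-time fraction inside clusters only, and P_cluster = mean cluster
duration / (mean cluster duration + mean intercluster duration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .dwells import CLOSED_CODE, OPEN_CODE, DwellSequence
from .dwellfit import ExpMixtureFit


class TcritError(ValueError):
    """No valid critical time exists for the supplied components."""


def _components(fit) -> list[tuple[float, float]]:
    if hasattr(fit, "components"):
        return list(fit.components)
    return [(float(a), float(t)) for a, t in fit]


def compute_tcrit(
    fit,
    i: int = 3,
    j: int = 4,
    method: str = "minimize_total",
) -> float:
    """Critical time between closed components ``i`` and ``j`` (1-based).

    ``fit`` is an :class:`ExpMixtureFit`, a :class:`PredictedMixture`, or a
    plain sequence of ``(area, tau)`` pairs sorted by ascending tau.  The
    result must lie strictly between tau_i and tau_j, else the separation is
    degenerate and an error is raised.
    """
    comps = _components(fit)
    if j <= i:
        raise ValueError("require i < j")
    if len(comps) < j:
        raise TcritError(
            f"fit has {len(comps)} components, need at least {j}: {comps}"
        )
    ai, ti = comps[i - 1]
    aj, tj = comps[j - 1]
    if ti >= tj:
        raise TcritError(f"tau_{i}={ti} must be smaller than tau_{j}={tj}")
    if ai <= 0 or aj <= 0:
        raise TcritError("component areas must be positive")
    if method == "minimize_total":
        arg = ai * tj / (aj * ti)
        if arg <= 1.0:
            raise TcritError(
                "degenerate separation: a_i tau_j <= a_j tau_i gives t* <= 0"
            )
        tcrit = np.log(arg) / (1.0 / ti - 1.0 / tj)
    elif method == "equal_misclassified":
        f = lambda t: ai * np.exp(-t / ti) - aj * (1.0 - np.exp(-t / tj))
        hi = 10.0 * tj
        if f(0.0) <= 0 or f(hi) >= 0:
            raise TcritError(
                f"no balanced misclassification root in (0, {hi}) for {comps}"
            )
        tcrit = float(brentq(f, 1e-300, hi, xtol=1e-15, rtol=1e-14))
    else:
        raise ValueError(f"unknown method {method!r}")
    if not ti < tcrit < tj:
        raise TcritError(
            f"critical time {tcrit} falls outside (tau_{i}, tau_{j}) = "
            f"({ti}, {tj}); components are not separable"
        )
    return float(tcrit)


def tcrit_numeric(fit, i: int = 3, j: int = 4) -> float:
    """Bounded numeric minimization of the total misclassified events.

    Independent cross-check of the ``minimize_total`` closed form.
    """
    comps = _components(fit)
    ai, ti = comps[i - 1]
    aj, tj = comps[j - 1]
    loss = lambda t: ai * np.exp(-t / ti) + aj * (1.0 - np.exp(-t / tj))
    res = minimize_scalar(loss, bounds=(ti, tj), method="bounded",
                          options={"xatol": 1e-12 * tj})
    return float(res.x)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    start_index: int  # first event of the run (inclusive)
    end_index: int  # last event of the run (inclusive)
    duration: float
    n_events: int
    popen: float
    censored: bool = False  # run touches a record edge; excluded from means


@dataclass
class ClusterSegmentation:
    """Clusters, intercluster durations, and the criterion used."""

    tcrit: float
    clusters: list[Cluster]
    interclusters: list[float]
    method: str = "minimize_total"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_index": [c.start_index for c in self.clusters],
                "end_index": [c.end_index for c in self.clusters],
                "duration_s": [c.duration for c in self.clusters],
                "n_events": [c.n_events for c in self.clusters],
                "popen": [c.popen for c in self.clusters],
                "censored": [c.censored for c in self.clusters],
            }
        )


def segment_clusters(
    dwells: DwellSequence,
    tcrit: float,
    min_openings: int = 1,
    method: str = "minimize_total",
) -> ClusterSegmentation:
    """Split a record into clusters at closed events longer than T_crit.

    Closed events with duration > ``tcrit`` are intercluster separators.
    Maximal event runs between separators containing at least
    ``min_openings`` open events are clusters; cluster duration is the sum
    of its event durations (first to last event of the run inclusive).
    Runs touching a record edge are flagged ``censored`` and are excluded
    from the duration means downstream, as are separators that are
    themselves the first or last event of the record.
    """
    if tcrit <= dwells.dead_time:
        raise ValueError(
            f"tcrit {tcrit} must exceed the dead time {dwells.dead_time}"
        )
    cls = dwells.classes
    dur = dwells.durations
    n = dwells.n_events
    sep = np.nonzero((cls == CLOSED_CODE) & (dur > tcrit))[0]
    interclusters = [float(dur[s]) for s in sep if 0 < s < n - 1]
    clusters: list[Cluster] = []
    edges = [-1, *sep.tolist(), n]
    for a, b in zip(edges[:-1], edges[1:]):
        lo, hi = a + 1, b - 1  # run strictly between consecutive separators
        if hi < lo:
            continue
        run_cls = cls[lo : hi + 1]
        run_dur = dur[lo : hi + 1]
        n_open = int((run_cls == OPEN_CODE).sum())
        if n_open < min_openings:
            continue
        total = float(run_dur.sum())
        popen = float(run_dur[run_cls == OPEN_CODE].sum() / total)
        clusters.append(
            Cluster(
                start_index=int(lo),
                end_index=int(hi),
                duration=total,
                n_events=int(run_cls.size),
                popen=popen,
                censored=(a == -1 or b == n),
            )
        )
    return ClusterSegmentation(
        tcrit=float(tcrit), clusters=clusters,
        interclusters=interclusters, method=method,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def p_cluster_from_means(mean_cluster: float, mean_intercluster: float) -> float:
    """P_cluster = mean cluster / (mean cluster + mean intercluster)."""
    if mean_cluster <= 0 or mean_intercluster <= 0:
        raise ValueError("mean durations must be positive")
    return mean_cluster / (mean_cluster + mean_intercluster)


@dataclass(frozen=True)
class ClusterStats:
    """Record-level cluster statistics; fields are None when undefined
    (e.g. P_cluster without at least one cluster and one intercluster)."""

    cluster_popen: float | None
    p_cluster: float | None
    mean_cluster_s: float | None
    mean_intercluster_s: float | None
    eq_popen: float
    n_clusters: int

    def to_dict(self) -> dict:
        return {
            "cluster_popen": self.cluster_popen,
            "p_cluster": self.p_cluster,
            "mean_cluster_s": self.mean_cluster_s,
            "mean_intercluster_s": self.mean_intercluster_s,
            "eq_popen": self.eq_popen,
            "n_clusters": self.n_clusters,
        }


def cluster_stats(seg: ClusterSegmentation, dwells: DwellSequence) -> ClusterStats:
    """Cluster P_open, P_cluster, and duration means for one record.

    Cluster P_open pools open and total time over all clusters (censored
    runs included — the open fraction is unbiased by edge truncation);
    duration means use only uncensored clusters and interior separators;
    eq. P_open is over the entire record.
    """
    total = dwells.total_duration
    eq_popen = float(dwells.open_durations.sum() / total) if total > 0 else 0.0
    if seg.clusters:
        open_in = sum(c.duration * c.popen for c in seg.clusters)
        time_in = sum(c.duration for c in seg.clusters)
        cluster_popen = float(open_in / time_in)
    else:
        cluster_popen = None
    interior = [c.duration for c in seg.clusters if not c.censored]
    mean_cluster = float(np.mean(interior)) if interior else None
    mean_ic = float(np.mean(seg.interclusters)) if seg.interclusters else None
    p_cluster = (
        p_cluster_from_means(mean_cluster, mean_ic)
        if (mean_cluster is not None and mean_ic is not None)
        else None
    )
    return ClusterStats(
        cluster_popen=cluster_popen,
        p_cluster=p_cluster,
        mean_cluster_s=mean_cluster,
        mean_intercluster_s=mean_ic,
        eq_popen=eq_popen,
        n_clusters=seg.n_clusters,
    )
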