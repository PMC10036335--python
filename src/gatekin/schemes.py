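"""Aggregated continuous-time Markov models of ion-channel gating.

An ion channel is modelled as a CTMC whose states are partitioned into two
aggregated classes, ``closed`` and ``open``; only the class (via its current
level) is observable.  This module builds and validates such schemes, solves
for the stationary distribution and equilibrium open probability, and
decomposes the sojourn time of each aggregated class into its exponential
mixture components (the phase-type decomposition).  Those predicted
components are the ground truth against which dwell-time fits are judged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

CLOSED = "closed"
OPEN = "open"
CLASSES = (CLOSED, OPEN)

#: relative tolerance for linear-algebra checks (row sums, probability sums)
ATOL = 1e-9


class SchemeError(ValueError):
    """Invalid kinetic scheme (bad rates, labels, or connectivity)."""


class NumericalError(RuntimeError):
    """A linear-algebra solve was too ill-conditioned to trust."""


class UnsupportedSchemeError(SchemeError):
    """Scheme whose class sub-generator has complex (oscillatory) eigenvalues."""


@dataclass(frozen=True, eq=False)
class KineticScheme:
    """Aggregated Markov gating scheme.

    Parameters
    ----------
    state_ids:
        State labels, in matrix order.
    class_of_state:
        Map from state label to ``"closed"`` or ``"open"``.
    rates:
        Square generator matrix in s^-1.  Off-diagonal entries are transition
        rates; each diagonal entry is minus the row sum of the off-diagonals.
    conductance_of_class:
        Current amplitude (pA) carried by each class; closed is 0 by
        convention.
    """

    state_ids: tuple[str, ...]
    class_of_state: Mapping[str, str]
    rates: np.ndarray
    conductance_of_class: Mapping[str, float] = field(
        default_factory=lambda: {CLOSED: 0.0, OPEN: -6.0}
    )

    def __post_init__(self) -> None:
        q = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", q)
        n = len(self.state_ids)
        if q.shape != (n, n):
            raise SchemeError(
                f"rate matrix shape {q.shape} does not match {n} states"
            )
        if not np.all(np.isfinite(q)):
            raise SchemeError("rate matrix contains non-finite entries")
        off = q - np.diag(np.diag(q))
        if np.any(off < 0):
            i, j = np.argwhere(off < 0)[0]
            raise SchemeError(
                f"negative rate {q[i, j]} for transition "
                f"{self.state_ids[i]} -> {self.state_ids[j]}"
            )
        scale = max(np.abs(q).max(), 1.0)
        if np.any(np.abs(q.sum(axis=1)) > ATOL * scale):
            raise SchemeError("rate-matrix rows do not sum to zero")
        for s in self.state_ids:
            if self.class_of_state.get(s) not in CLASSES:
                raise SchemeError(f"state {s!r} has no closed/open class label")
        for cls in CLASSES:
            if not self.states_of(cls):
                raise SchemeError(f"scheme has no {cls} state")
        # irreducibility on the support graph of the off-diagonal rates
        support = csr_matrix(off > 0)
        n_comp, _ = connected_components(support, directed=True, connection="strong")
        if n_comp != 1:
            raise SchemeError(
                "transition graph is reducible "
                f"({n_comp} strongly connected components)"
            )

    # -- indexing helpers -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    def index(self, state: str) -> int:
        return self.state_ids.index(state)

    def states_of(self, cls: str) -> list[int]:
        """Indices of states belonging to an aggregated class."""
        return [
            i for i, s in enumerate(self.state_ids) if self.class_of_state[s] == cls
        ]

    def rescaled(self, factor: float) -> "KineticScheme":
        """Uniformly rescale every rate (time-axis stretch)."""
        return KineticScheme(
            self.state_ids,
            dict(self.class_of_state),
            self.rates * factor,
            dict(self.conductance_of_class),
        )

    # -- serialisation ----------------------------------------------------
    def to_config(self) -> dict:
        off = self.rates - np.diag(np.diag(self.rates))
        transitions = [
            [self.state_ids[i], self.state_ids[j], float(off[i, j])]
            for i, j in np.argwhere(off > 0)
        ]
        return {
            "states": {s: self.class_of_state[s] for s in self.state_ids},
            "rates": transitions,
            "conductances": dict(self.conductance_of_class),
        }

    def rate_table(self):
        """Rate matrix as a pandas DataFrame (states as index/columns)."""
        import pandas as pd

        ids = list(self.state_ids)
        return pd.DataFrame(self.rates, index=ids, columns=ids)


@dataclass(frozen=True)
class StationaryResult:
    """Stationary occupancy per state and the derived open probability."""

    pi: np.ndarray
    popen: float

    def to_dict(self, state_ids: Sequence[str] | None = None) -> dict:
        pi = [float(p) for p in self.pi]
        out: dict = {"popen": float(self.popen)}
        out["pi"] = dict(zip(state_ids, pi)) if state_ids is not None else pi
        return out


@dataclass(frozen=True)
class PredictedMixture:
    """Exponential mixture predicted for one aggregated class's sojourns.

    ``components`` is a tuple of ``(area, tau)`` pairs sorted by ascending
    tau; the sojourn density is ``sum_i (a_i / tau_i) exp(-t / tau_i)`` with
    ``sum_i a_i = 1``.
    """

    cls: str
    components: tuple[tuple[float, float], ...]

    @property
    def areas(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for _, t in self.components])

    @property
    def mean_time(self) -> float:
        """Mean class sojourn, sum a_i tau_i (seconds)."""
        return float(np.dot(self.areas, self.taus))

    def to_dict(self) -> dict:
        return {
            "class": self.cls,
            "components": [
                {"area": float(a), "tau_s": float(t)} for a, t in self.components
            ],
        }


def build_scheme(
    transitions: Iterable[tuple[str, str, float]],
    classes: Mapping[str, str],
    conductances: Mapping[str, float] | None = None,
) -> KineticScheme:
    """Assemble a validated :class:`KineticScheme` from a transition table.

    Parameters
    ----------
    transitions:
        Iterable of ``(from_state, to_state, rate)`` with rates in s^-1.
    classes:
        Map from every state label to ``"closed"`` or ``"open"``; this also
        fixes the state order.
    conductances:
        Optional class->pA map; defaults to closed 0 pA, open -6 pA.
    """
    state_ids = tuple(classes)
    idx = {s: i for i, s in enumerate(state_ids)}
    n = len(state_ids)
    q = np.zeros((n, n))
    for a, b, rate in transitions:
        for s in (a, b):
            if s not in idx:
                raise SchemeError(f"unknown state label {s!r} in transition table")
        if not np.isfinite(rate) or rate < 0:
            raise SchemeError(f"invalid rate {rate!r} for {a} -> {b}")
        if a == b:
            raise SchemeError(f"self-transition {a} -> {a} is not allowed")
        q[idx[a], idx[b]] += rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    cond = dict(conductances) if conductances is not None else {CLOSED: 0.0, OPEN: -6.0}
    return KineticScheme(state_ids, dict(classes), q, cond)


def stationary_distribution(scheme: KineticScheme) -> StationaryResult:
    """Solve pi^T Q = 0, sum(pi) = 1 and report the open-class occupancy."""
    q = scheme.rates
    n = scheme.n_states
    m = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, _, _, sv = np.linalg.lstsq(m, b, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    if cond > 1e12:
        raise NumericalError(
            f"stationary solve is ill-conditioned (condition number {cond:.3g})"
        )
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    popen = float(pi[scheme.states_of(OPEN)].sum())
    return StationaryResult(pi=pi, popen=popen)


def predicted_dwell_mixture(scheme: KineticScheme, cls: str) -> PredictedMixture:
    """Phase-type decomposition of a class's sojourn-time distribution.

    The sub-generator restricted to the states of ``cls`` is
    eigendecomposed; each real eigenvalue ``lambda_i < 0`` contributes a
    component with ``tau_i = -1/lambda_i``.  The entrance distribution is the
    stationary flux into the class (rate-weighted stationary occupancy of the
    source states), which is the distribution seen at equilibrium by an
    observer marking class entries.
    """
    if cls not in CLASSES:
        raise ValueError(f"cls must be one of {CLASSES}, got {cls!r}")
    inside = scheme.states_of(cls)
    outside = [i for i in range(scheme.n_states) if i not in inside]
    q = scheme.rates
    qaa = q[np.ix_(inside, inside)]
    pi = stationary_distribution(scheme).pi
    flux = pi[outside] @ q[np.ix_(outside, inside)]
    if flux.sum() <= 0:
        raise SchemeError(f"no stationary flux into the {cls} class")
    phi = flux / flux.sum()

    w, v = np.linalg.eig(qaa)
    scale = np.abs(w).max()
    if np.abs(w.imag).max() > 1e-9 * scale:
        raise UnsupportedSchemeError(
            "class sub-generator has complex eigenvalues "
            f"(oscillatory sojourn density): {np.sort_complex(w)}"
        )
    w = w.real
    if np.any(w >= 0):
        raise SchemeError(f"{cls} sub-generator has a non-negative eigenvalue")
    r = -qaa @ np.ones(len(inside))
    c = (phi @ v).real * (np.linalg.solve(v, r)).real
    taus = -1.0 / w
    areas = c * taus
    keep = np.abs(areas) > 1e-12
    taus, areas = taus[keep], areas[keep]
    order = np.argsort(taus)
    taus, areas = taus[order], areas[order]
    total = areas.sum()
    if not np.isclose(total, 1.0, rtol=1e-6):
        raise NumericalError(f"mixture areas sum to {total}, expected 1")
    areas = areas / total
    return PredictedMixture(
        cls=cls, components=tuple((float(a), float(t)) for a, t in zip(areas, taus))
    )


# ---------------------------------------------------------------------------
# config file IO
# ---------------------------------------------------------------------------

def load_scheme(path) -> KineticScheme:
    """Read a scheme from a YAML config (states/rates/conductances keys)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return build_scheme(
        [(a, b, float(r)) for a, b, r in cfg["rates"]],
        cfg["states"],
        cfg.get("conductances"),
    )


def save_scheme(scheme: KineticScheme, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scheme.to_config(), fh, sort_keys=False)


def save_json(obj, path) -> None:
    """JSON export for StationaryResult / PredictedMixture / plain dicts."""
    data = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
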