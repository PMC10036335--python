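"""MTS modification kinetics from macroscopic current decays.

Continuous application of a methanethiosulfonate (MTS) reagent to a
substituted cysteine irreversibly modifies accessible channels, so the
agonist-evoked current decays mono-exponentially,
``I(t) = baseline + amplitude * exp(-t / tau)``.  The apparent second-order
modification rate constant is ``k = 1 / (tau * [MTS])`` in M^-1 s^-1, and
reports how accessible the engineered cysteine is — a probe for gates
upstream of its position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class DecayFitError(RuntimeError):
    """The record does not contain a resolvable exponential decay."""


@dataclass(frozen=True)
class MtsFit:
    """Single-exponential decay fit plus the derived modification rate."""

    tau: float  # seconds
    amplitude: float  # pA
    baseline: float  # pA
    k: float  # M^-1 s^-1
    mts_conc: float  # molar
    rss: float  # residual sum of squares

    def to_dict(self) -> dict:
        return {
            "tau_s": self.tau,
            "amplitude_pA": self.amplitude,
            "baseline_pA": self.baseline,
            "k_per_M_per_s": self.k,
            "mts_conc_M": self.mts_conc,
            "rss": self.rss,
        }


def _model(t, baseline, amplitude, tau):
    return baseline + amplitude * np.exp(-t / tau)


def fit_decay(
    time: np.ndarray,
    current: np.ndarray,
    constrain_baseline: bool = False,
) -> tuple[float, float, float]:
    """Least-squares single-exponential fit; returns (tau, amplitude, baseline).

    The nonlinear fit is seeded analytically: the baseline from the tail of
    the record, tau from a log-linear regression of the baseline-subtracted
    current.  Deterministic.  ``constrain_baseline`` pins the baseline to
    zero.  Records with no resolvable decay (constant current, or a best-fit
    tau pinned far beyond the record) raise :class:`DecayFitError`.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(current, dtype=float)
    if t.size != y.size or t.size < 10:
        raise ValueError("need at least 10 (time, current) samples")
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ValueError("time must be increasing")
    tail = y[int(0.9 * y.size):]
    b0 = 0.0 if constrain_baseline else float(tail.mean())
    a0 = float(y[0] - b0)
    resid_scale = max(float(np.std(tail)), 1e-12)
    if abs(a0) < 3 * resid_scale and abs(a0) < 1e-3 * max(abs(y).max(), 1e-12):
        raise DecayFitError("no decay: initial amplitude indistinguishable from tail")
    # log-linear seed for tau on the monotone part of the decay
    dy = (y - b0) / a0
    mask = dy > 1e-3
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(dy[mask]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else span / 3
    else:
        tau0 = span / 3
    tau0 = float(np.clip(tau0, span * 1e-4, span * 10))

    tau_max = 50.0 * span
    try:
        if constrain_baseline:
            popt, _ = curve_fit(
                lambda tt, amplitude, tau: _model(tt, 0.0, amplitude, tau),
                t, y, p0=[a0, tau0],
                bounds=([-np.inf, span * 1e-6], [np.inf, tau_max]),
                maxfev=10000,
            )
            baseline, (amplitude, tau) = 0.0, popt
        else:
            popt, _ = curve_fit(
                _model, t, y, p0=[b0, a0, tau0],
                bounds=([-np.inf, -np.inf, span * 1e-6],
                        [np.inf, np.inf, tau_max]),
                maxfev=10000,
            )
            baseline, amplitude, tau = popt
    except RuntimeError as exc:
        raise DecayFitError(f"exponential fit failed to converge: {exc}") from exc
    if tau > 0.99 * tau_max:
        raise DecayFitError(
            f"fitted tau {tau:.3g} s pinned at the bound; record is not decaying"
        )
    return float(tau), float(amplitude), float(baseline)


def modification_rate(tau: float, conc: float) -> float:
    """Apparent second-order modification rate, k = 1 / (tau [MTS])."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if conc <= 0:
        raise ValueError("MTS concentration must be positive")
    return 1.0 / (tau * conc)


def fit_modification(
    time: np.ndarray,
    current: np.ndarray,
    mts_conc: float,
    constrain_baseline: bool = False,
) -> MtsFit:
    """Fit the decay during MTS application and report the rate constant."""
    tau, amplitude, baseline = fit_decay(time, current, constrain_baseline)
    y = np.asarray(current, dtype=float)
    resid = y - _model(np.asarray(time, float), baseline, amplitude, tau)
    return MtsFit(
        tau=tau,
        amplitude=amplitude,
        baseline=baseline,
        k=modification_rate(tau, mts_conc),
        mts_conc=float(mts_conc),
        rss=float(np.sum(resid**2)),
    )
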