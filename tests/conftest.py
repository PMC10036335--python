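import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gatekin as gk

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def two_state():
    """C <-> O with opening rate 100/s and closing rate 300/s (popen 1/4)."""
    return gk.build_scheme(
        [("C", "O", 100.0), ("O", "C", 300.0)], {"C": "closed", "O": "open"}
    )


@pytest.fixture(scope="session")
def chain_scheme():
    """Linear C1 - C2 - O chain with a two-component closed mixture."""
    return gk.build_scheme(
        [
            ("C1", "C2", 10.0),
            ("C2", "C1", 50.0),
            ("C2", "O", 200.0),
            ("O", "C2", 300.0),
        ],
        {"C1": "closed", "C2": "closed", "O": "open"},
    )


@pytest.fixture(scope="session")
def bipartite():
    """Reference scheme with exactly 5 closed / 3 open mixture components."""
    return gk.make_bipartite_scheme()


def popen_batch_se(dwells: gk.DwellSequence, n_blocks: int = 10):
    """Empirical open fraction and its batch-means standard error."""
    edges = np.linspace(0, dwells.total_duration, n_blocks + 1)
    cum = np.concatenate([[0.0], np.cumsum(dwells.durations)])
    fracs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        o = 0.0
        t = 0.0
        for c, a, b in zip(dwells.classes, cum[:-1], cum[1:]):
            ov = max(0.0, min(b, hi) - max(a, lo))
            if ov > 0:
                t += ov
                if c == 1:
                    o += ov
        fracs.append(o / t)
    fracs = np.asarray(fracs)
    return float(fracs.mean()), float(fracs.std(ddof=1) / np.sqrt(n_blocks))
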