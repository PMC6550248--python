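import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenoqc.schedules import SamplingSchedule
from phenoqc.simulate import MissingnessConfig, SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def light_config(**overrides) -> SimulationConfig:
    """A small, fast study: 1 Hz sensors, mild missingness, 3 subjects.

    Used by plumbing tests (I/O, CLI wiring) where data volume, not the
    full 10 Hz accelerometer regime, is what matters.
    """
    defaults = dict(
        n_subjects=3,
        n_weeks=5,
        schedules={
            "accelerometer": SamplingSchedule("accelerometer", f=1.0, d=60.0, r=60.0),
            "gps": SamplingSchedule("gps", f=1.0, d=60.0, r=600.0),
        },
        missingness={
            "accelerometer": MissingnessConfig(0.2, 0.8, 0.9),
            "gps": MissingnessConfig(0.3, 0.8, 0.9),
        },
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def light_study(tmp_path_factory):
    """A simulated light study directory shared across plumbing tests."""
    from phenoqc.simulate import simulate_study

    out = tmp_path_factory.mktemp("study")
    simulate_study(light_config(), out, force=True)
    return out


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_segments(timestamps, threshold):
    """O(n^2)-style reference segmentation: every consecutive-gap
    comparison is evaluated independently against the full input, then
    segments and their statistics are rebuilt from scratch with plain
    Python."""
    ts = list(timestamps)
    n = len(ts)
    if n == 0:
        return []
    splits = [i for i in range(1, n) if (ts[i] - ts[i - 1]) > threshold]
    edges = [0] + splits + [n]
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        seg = ts[a:b]
        out.append(
            {"start": min(seg), "end": max(seg), "count": len(seg),
             "duration": max(seg) - min(seg)}
        )
    return out


def brute_force_bhy(pvals, q):
    """Step-up BY by exhaustively testing every rejection-set size."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    psort = p[order]
    istar = 0
    for i in range(1, m + 1):
        if psort[i - 1] <= i * q / (m * c_m):
            istar = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:istar]] = True
    return reject
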