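import numpy as np
import pytest

from traffex.cohort import detect_all_events, person_outcomes
from traffex.synth import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic study shared by read-only tests."""
    return simulate(SimulationConfig(seed=3, n_persons=150))


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    """Analysis dataset built from the shared small study."""
    from traffex.analysis import build_dataset

    events = detect_all_events(small_sim.visits)
    outcomes = person_outcomes(events, small_sim.persons)
    ds, _ = build_dataset(outcomes, small_sim.persons, small_sim.exposures)
    return ds


def discretized_length_in_disc(vertices, center, radius, step=0.1):
    """Brute-force oracle: walk the polyline in `step`-metre increments and
    accumulate the sub-lengths whose midpoints fall inside the disc."""
    vertices = np.asarray(vertices, float)
    center = np.asarray(center, float)
    total = 0.0
    for a, b in zip(vertices[:-1], vertices[1:]):
        L = float(np.hypot(*(b - a)))
        if L == 0:
            continue
        n = max(int(np.ceil(L / step)), 1)
        t = (np.arange(n) + 0.5) / n
        pts = a + t[:, None] * (b - a)
        inside = np.hypot(*(pts - center).T) <= radius
        total += inside.sum() * (L / n)
    return total
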