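import numpy as np
import pytest

from cycloplex import build_toy_complex
from cycloplex.core import AnnotatedSystem, Trajectory
from cycloplex.synthetic import ScenarioSpec, ToyHostSpec, simulate_inclusion_trajectory


@pytest.fixture(scope="session")
def toy():
    """Default 7-unit toy complex: (system, reference coordinates)."""
    return build_toy_complex()


@pytest.fixture(scope="session")
def short_traj(toy):
    """A short stable-wide trajectory for plumbing tests."""
    system, xyz = toy
    spec = ScenarioSpec(scenario="stable_wide", n_frames=40,
                        timestep_label=0.05, ou_mean=2.0, seed=42)
    return simulate_inclusion_trajectory(system, xyz, spec)


def make_system(coords, radii=None, charges=None, eps=None, rmin_half=None,
                elements=None, groups=None):
    """Minimal ad-hoc system for single-purpose energy/geometry checks."""
    n = len(coords)
    elements = np.array(elements if elements is not None else ["C"] * n)
    return AnnotatedSystem(
        names=np.array([f"X{i}" for i in range(n)]),
        elements=elements,
        radii=np.asarray(radii if radii is not None else np.full(n, 1.7)),
        charges=np.asarray(charges if charges is not None else np.zeros(n)),
        lj_eps=np.asarray(eps if eps is not None else np.full(n, 0.1)),
        lj_rmin_half=np.asarray(
            rmin_half if rmin_half is not None else np.full(n, 1.9)),
        groups={k: np.asarray(v, dtype=int) for k, v in (groups or {}).items()},
    )


@pytest.fixture
def ad_hoc_system():
    return make_system
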