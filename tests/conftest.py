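import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stickermd as sm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return sm.ForceFieldParams.from_kT(es_kT=6.0, ens_kT=0.3)


@pytest.fixture(scope="session")
def small_packed():
    """Six 10-bead two-component chains in an 80 Å box (session template)."""
    ta, tb = sm.two_component_templates(block_length=5, repeats=2)
    state, topo = sm.pack_system(
        [(sm.build_chain(ta), 3), (sm.build_chain(tb), 3)], box=(80.0, 80.0, 80.0), seed=3
    )
    return state, topo


@pytest.fixture
def small_system(small_packed):
    """Fresh copy of the small packed system with thermal velocities."""
    state, topo = small_packed
    st = state.copy()
    st.velocities = sm.init_velocities(310.0, 100.0, 5, st.n_beads)
    return st, topo


def random_bead_cloud(n, box, seed, min_sep=6.0):
    """Random positions with a soft minimum separation (rejection sampling)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    pts = [rng.random(3) * box]
    while len(pts) < n:
        cand = rng.random(3) * box
        d = np.asarray(pts) - cand
        d -= box * np.round(d / box)
        if (d * d).sum(axis=1).min() > min_sep**2:
            pts.append(cand)
    return np.asarray(pts)
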