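"""Shared fixtures: the expensive continuum-model assays are session-scoped
so the interface-width, signature and statistics tests reuse one run."""

import numpy as np
import pytest

from swarmpat import pde, stats


@pytest.fixture(scope="session")
def adhesive_assay():
    """Two complementary colonies 9 mm apart, fitted parameters (K=130/h)."""
    x, inten, state = pde.interface_assay(pde.PAPER_K_PER_H)
    fit = stats.fit_profile(x, inten)
    return {"x": x, "intensity": inten, "fit": fit, "state": state}


@pytest.fixture(scope="session")
def nonadhesive_assay():
    """Same assay with adhesion disabled (non-adhesive control, K=0)."""
    x, inten, state = pde.interface_assay(0.0)
    fit = stats.fit_profile(x, inten)
    return {"x": x, "intensity": inten, "fit": fit, "state": state}


@pytest.fixture(scope="session")
def width_vs_K():
    """Curvature widths (mm) for K in {0, 13, 130, 1300} /h."""
    out = {}
    for K in (0.0, 13.0, 130.0, 1300.0):
        x, inten, _ = pde.interface_assay(K)
        out[K] = stats.fit_profile(x, inten).w
    return out


@pytest.fixture(scope="session")
def fisher_front():
    """Single-strain colony expansion for the pulled-front speed check."""
    params = pde.ModelParams(K=0.0, extent=60.0, dx=0.025)
    traj = pde.simulate([pde.SeedInit(2.0, 0)], params, ["Nb2"],
                        t_end=10.0, snapshot_every=2.0)

    def at(t):
        return min(traj, key=lambda s: abs(s.t - t))

    x6, x10 = at(6.0), at(10.0)
    speed = ((pde.front_position(x10, 0, 0.5) - pde.front_position(x6, 0, 0.5))
             / (x10.t - x6.t))
    return {"speed": speed, "trajectory": traj}


def rel_err(got, want):
    return abs(got - want) / abs(want)
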