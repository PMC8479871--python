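"""Shared fixtures: small synthetic cells reused across test modules."""

import numpy as np
import pytest

from memwave.synthetic_cell import SceneSpec, make_geometry, make_signal


@pytest.fixture(scope="session")
def sphere_mesh():
    """Free-floating sphere, R = 3 um, ~380 nodes."""
    return make_geometry(SceneSpec(radius=3.0, contact_angle=0.0, pattern="quiet"))


@pytest.fixture(scope="session")
def trunc_mesh():
    """Adhered cell, R = 2.5 um, Omega = pi/3."""
    return make_geometry(SceneSpec(radius=2.5, contact_angle=np.pi / 3, pattern="quiet"))


@pytest.fixture(scope="session")
def spiral_scene():
    """Pinned spiral on an adhered cell, low noise, 600 s."""
    spec = SceneSpec(radius=3.0, contact_angle=np.pi / 3, pattern="pinned_spiral",
                     period=200.0, noise_sd=0.05, duration=600.0, seed=2)
    mesh = make_geometry(spec)
    signal, truth = make_signal(mesh, spec)
    return spec, mesh, signal, truth
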