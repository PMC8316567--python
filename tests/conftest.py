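"""Shared fixtures: the reference phantom, projection geometries, and small
synthetic volumes used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from radulna.drr import ProjectionGeometry
from radulna.phantoms import PhantomSpec, rasterize_phantom


@pytest.fixture(scope="session")
def ref_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def ref_phantom(ref_spec):
    """Reference wrist phantom at 1.25 mm on a 72x72x96 grid."""
    ct, label, lm = rasterize_phantom(ref_spec, (72, 72, 96), 1.25)
    return ct, label, lm


@pytest.fixture(scope="session")
def ref_geom() -> ProjectionGeometry:
    """48x48 detector at 2 mm pitch, orthographic along -Y."""
    return ProjectionGeometry(
        detector_shape=(48, 48), pixel_spacing=2.0, step_length=1.25
    )


@pytest.fixture(scope="session")
def sphere_mu():
    """Homogeneous sphere (mu = 0.01/mm, r = 20 mm) with partial-volume
    antialiased boundary, on a 64^3 grid at 1 mm."""
    n = 64
    orig = -(n - 1) / 2.0
    xs = np.arange(n) + orig
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    dist = np.sqrt(X**2 + Y**2 + Z**2)
    r = 20.0
    mu = 0.01 * np.clip(r - dist + 0.5, 0.0, 1.0)
    return mu, np.ones(3), np.full(3, orig), r, 0.01
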