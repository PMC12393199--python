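"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's solver code paths:
constant fields are propagated with scipy's axis-angle rotations and free
precession with its elementary closed form, so that agreement with the
analytic solvers is a genuine cross-check.
"""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import blochsolve as bs

TWOPI = 2.0 * math.pi


def rotation_oracle(omega1m, phic, Omega, M0, dt):
    """Constant-field propagation as an axis-angle rotation.

    The rotating-frame Bloch equation with a constant field is dM/dt =
    a x M with a = -(w1 cos phic, w1 sin phic, Omega); over a time dt the
    state rotates by the rotation vector a*dt.
    """
    axis = -np.array(
        [omega1m * math.cos(phic), omega1m * math.sin(phic), Omega]
    )
    return Rotation.from_rotvec(axis * dt).apply(np.asarray(M0, dtype=float))


def precession_oracle(Omega, M0, dt):
    """Free precession (w1 = 0): rotation about z by -Omega*dt."""
    return rotation_oracle(0.0, 0.0, Omega, M0, dt)


def fig_hs1(truncation, R=10.0, omega1m_hz=2000.0, Tp=5e-3):
    """HS1 inversion pulse family used throughout the validation plots."""
    return bs.hs1_from_spec(
        omega1m=TWOPI * omega1m_hz, Tp=Tp, R=R, truncation_fraction=truncation
    )


@pytest.fixture
def equilibrium():
    return bs.Isochromat(0.0, bs.Magnetization.equilibrium())


@pytest.fixture
def tilted_iso():
    """Off-resonance isochromat with a non-trivial initial orientation."""
    return bs.Isochromat(
        TWOPI * 100.0,
        bs.Magnetization.from_array([0.3, -0.4, math.sqrt(0.75)]),
    )
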