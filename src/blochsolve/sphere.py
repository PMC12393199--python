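"""Magnetization vectors, stereographic projection, and the angular error
metric.

The relaxation-free Bloch equation conserves the magnetization norm, so a
state is a point on a sphere of radius ``|M| in (0, 1]`` (in units of the
equilibrium magnetization M0).  Stereographic projection from the south
pole maps that sphere bijectively onto the extended complex plane:

    f = (Mx + i My) / (|M| + Mz)

with the south pole (0, 0, -|M|) mapping to the point at infinity.  The
inverse map is

    Mx + i My = |M| 2 f / (1 + |f|^2),   Mz = |M| (1 - |f|^2) / (1 + |f|^2),

which conserves the norm identically.  Discrepancies between two states
are reported as the frame-independent angle between the vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Magnetization",
    "Isochromat",
    "RiemannPoint",
    "project",
    "unproject",
    "angular_error",
    "random_isochromats",
]

#: |M| + Mz below this fraction of |M| projects to the point at infinity
POLE_THRESHOLD = 1e-12


@dataclass(frozen=True)
class Magnetization:
    """Magnetization 3-vector in units of M0.

    Physical states have norm in (0, 1]; the container itself only
    requires a positive norm, so that numerical trajectories whose norm
    drifts slightly past M0 (e.g. coarse RK4 runs) remain representable.
    """

    mx: float
    my: float
    mz: float

    def __post_init__(self):
        if not self.norm > 0.0:
            raise ValueError("magnetization must have positive norm")

    @classmethod
    def from_array(cls, arr) -> "Magnetization":
        mx, my, mz = np.asarray(arr, dtype=float)
        return cls(float(mx), float(my), float(mz))

    @classmethod
    def equilibrium(cls, norm: float = 1.0) -> "Magnetization":
        return cls(0.0, 0.0, float(norm))

    @property
    def norm(self) -> float:
        return math.sqrt(self.mx**2 + self.my**2 + self.mz**2)

    def as_array(self) -> np.ndarray:
        return np.array([self.mx, self.my, self.mz], dtype=float)


@dataclass(frozen=True)
class Isochromat:
    """A spin ensemble with a single resonance offset.

    ``omega`` is the offset Omega = omega0 - omegac in rad/s (positive for
    spins precessing faster than the carrier).
    """

    omega: float
    M: Magnetization


@dataclass(frozen=True)
class RiemannPoint:
    """Point on the extended complex plane with its carried norm.

    Exactly one of {finite ``value``, at-infinity} holds; the norm ``|M|``
    is carried alongside so that the inverse projection is well defined.
    """

    value: Optional[complex]
    norm: float = 1.0

    def __post_init__(self):
        if not self.norm > 0.0:
            raise ValueError("carried norm must be positive")

    @classmethod
    def finite(cls, value: complex, norm: float = 1.0) -> "RiemannPoint":
        return cls(complex(value), norm)

    @classmethod
    def infinity(cls, norm: float = 1.0) -> "RiemannPoint":
        return cls(None, norm)

    @property
    def at_infinity(self) -> bool:
        return self.value is None


def project(M: Magnetization) -> RiemannPoint:
    """Stereographic projection of a magnetization onto the extended
    complex plane; the south pole maps to the point at infinity.

    For Mz < 0 the denominator |M| + Mz is evaluated through the
    cancellation-free identity (Mx^2 + My^2) / (|M| - Mz), so states
    arbitrarily close to the south pole project accurately.
    """
    n = M.norm
    if M.mz >= 0.0:
        return RiemannPoint.finite(complex(M.mx, M.my) / (n + M.mz), n)
    mxy2 = M.mx**2 + M.my**2
    den = mxy2 / (n - M.mz)  # == |M| + Mz, stable
    if den < POLE_THRESHOLD * n:
        return RiemannPoint.infinity(n)
    return RiemannPoint.finite((n - M.mz) / complex(M.mx, -M.my), n)


def unproject(p: RiemannPoint) -> Magnetization:
    """Inverse stereographic projection; exact inverse of :func:`project`."""
    if p.at_infinity:
        return Magnetization(0.0, 0.0, -p.norm)
    f = p.value
    d = 1.0 + abs(f) ** 2
    mxy = p.norm * 2.0 * f / d
    mz = p.norm * (1.0 - abs(f) ** 2) / d
    return Magnetization(mxy.real, mxy.imag, mz)


def magnetization_from_ratio(num: complex, den: complex, norm: float = 1.0) -> Magnetization:
    """Magnetization for the projective point f = num/den.

    Numerically stable on the whole sphere (including f at or near
    infinity, where ``den`` underflows).
    """
    n2 = abs(num) ** 2
    d2 = abs(den) ** 2
    s = n2 + d2
    if s == 0.0:
        raise ValueError("degenerate projective point (0 : 0)")
    mxy = norm * 2.0 * num * den.conjugate() / s
    mz = norm * (d2 - n2) / s
    return Magnetization(mxy.real, mxy.imag, mz)


def angular_error(M1: Magnetization, M2: Magnetization) -> float:
    """Angle (rad) between two magnetization vectors, in [0, pi].

    Computed as atan2(|M1 x M2|, M1 . M2), which stays accurate down to
    the round-off floor for nearly parallel (and nearly antiparallel)
    vectors, unlike the arccos of the normalized dot product.
    """
    a = M1.as_array()
    b = M2.as_array()
    if not (np.linalg.norm(a) > 0.0 and np.linalg.norm(b) > 0.0):
        raise ValueError("angular error undefined for zero-norm input")
    cross = np.linalg.norm(np.cross(a, b))
    dot = float(np.dot(a, b))
    return float(math.atan2(cross, dot))


def random_isochromats(
    seed: int,
    count: int,
    norm: float = 1.0,
    offset_range: Sequence[float] = (-2 * np.pi * 5000.0, 2 * np.pi * 5000.0),
) -> list:
    """Seeded fixture generator: isochromats with orientations uniform on
    the sphere (normalized standard-normal triples) and offsets uniform in
    ``offset_range`` (rad/s)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if not 0.0 < norm <= 1.0:
        raise ValueError("norm must lie in (0, 1] (units of M0)")
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((count, 3))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    offsets = rng.uniform(offset_range[0], offset_range[1], size=count)
    return [
        Isochromat(float(om), Magnetization.from_array(norm * v))
        for om, v in zip(offsets, vecs)
    ]
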