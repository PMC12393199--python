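"""Exact analytical propagator for the HS1 driving function.

Stereographic projection turns the relaxation-free Bloch equation into the
complex Riccati equation

    df/dt = (i/2) w1(t) - i Omega f - (i/2) conj(w1(t)) f^2 .

For the HS1 pulse, the substitutions

    p(t) = (1 + tanh((2 beta / Tp)(t - tc))) / 2,
    ln q = (i/2) Integral conj(w1) f dt

linearize this into the Gauss hypergeometric equation in p on (0, 1),

    p (1-p) q'' + [c - (a+b+1) p] q' - a b q = 0,

with complex parameters (phase convention d(phase)/dt = +fm)

    a = (Tp / 4 beta)(-iA + sqrt(w1m^2 - A^2)),
    b = (Tp / 4 beta)(-iA - sqrt(w1m^2 - A^2)),
    c = 1/2 + i (Tp / 4 beta)(Omega - A).

The general solution q = FA + C FB uses the standard fundamental pair
about p = 0 (FA the Gauss series, FB the p^(1-c) branch), and

    f(t) = -i (2 beta / Tp) (w1(t) / w1m^2) * (FA' + C FB') / (FA + C FB).

The single constant C is fixed, without approximation, by the
magnetization at any one time during the pulse; it is stored as a
projective pair (CA : CB) so anchors at or near the south pole (f at
infinity) and vanishing denominators are handled exactly.

Hypergeometric values are computed with mpmath at a configurable working
precision (default 30 significant digits) and the resulting magnetization
is emitted in double precision.  Since Re(c) = 1/2 exactly, none of the
parameter-degeneracy cases of the hypergeometric equation can occur, and
mpmath's built-in analytic continuation covers the p -> 1 tail without
loss of accuracy.

For A = 0, Omega = 0 and C = 0 the solution collapses to the
self-induced-transparency closed form f = i tan(2 a arcsin(sqrt(p)))
(:func:`sit_closed_form`), a pure rotation in the y-z plane whose final
angle for a 2*pi-amplitude pulse is exactly 2*pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import mpmath as mp
import numpy as np

from .pulses import HS1Pulse, _check_support
from .sphere import (
    Isochromat,
    Magnetization,
    RiemannPoint,
    magnetization_from_ratio,
    project,
)
from .trajectory import Trajectory

__all__ = [
    "DEFAULT_DPS",
    "HS1SolverContext",
    "ParticularConstant",
    "hs1_p",
    "hs1_abc",
    "hs1_basis",
    "hs1_particular",
    "hs1_evaluate",
    "hs1_propagate",
    "sit_final_angle",
    "sit_closed_form",
]

#: default working precision, significant decimal digits
DEFAULT_DPS = 30


@dataclass(frozen=True)
class ParticularConstant:
    """Projective pair (CA : CB) encoding the integration constant
    C = CB / CA on the extended complex plane."""

    CA: object  # mpmath mpc
    CB: object

    def __post_init__(self):
        if self.CA == 0 and self.CB == 0:
            raise ValueError(
                "degenerate particular constant (0 : 0); "
                "increase the working precision"
            )

    @property
    def C(self) -> complex:
        """The constant as a plain complex number (inf if CA == 0)."""
        if self.CA == 0:
            return complex(math.inf, 0.0)
        return complex(self.CB / self.CA)


def hs1_p(t, pulse: HS1Pulse):
    """Reparameterized time p = (1 + tanh((2 beta/Tp)(t - tc))) / 2."""
    u = (2.0 * pulse.beta / pulse.Tp) * (np.asarray(t, dtype=float) - pulse.tc)
    out = 0.5 * (1.0 + np.tanh(u))
    return out if np.ndim(t) else float(out)


def hs1_abc(pulse: HS1Pulse, Omega: float):
    """Complex hypergeometric parameters (a, b, c) for the HS1 solution."""
    Tp, beta, A, w1m = pulse.Tp, pulse.beta, pulse.A, pulse.omega1m
    s = mp.sqrt(mp.mpc(w1m * w1m - A * A))  # principal branch
    pref = mp.mpf(Tp) / (4 * mp.mpf(beta))
    a = pref * (-1j * A + s)
    b = pref * (-1j * A - s)
    c = mp.mpf("0.5") + 1j * pref * (Omega - A)
    return a, b, c


@dataclass(frozen=True)
class HS1SolverContext:
    """Pulse + offset + precomputed hypergeometric parameters."""

    pulse: HS1Pulse
    omega: float
    a: object
    b: object
    c: object
    dps: int = DEFAULT_DPS

    @classmethod
    def create(cls, pulse: HS1Pulse, Omega: float, dps: int = DEFAULT_DPS):
        with mp.workdps(dps):
            a, b, c = hs1_abc(pulse, Omega)
        return cls(pulse=pulse, omega=Omega, a=a, b=b, c=c, dps=dps)


def hs1_basis(p, a, b, c):
    """Fundamental pair (FA, FB) of the hypergeometric equation about
    p = 0, and their p-derivatives.

    FA is the Gauss series 2F1(a, b; c; p); FB is the second solution
    p^(1-c) 2F1(a-c+1, b-c+1; 2-c; p).  Valid for p in (0, 1); Re(c)=1/2
    guarantees the pair is never degenerate.
    """
    p = mp.mpf(p)
    if not 0 < p < 1:
        raise ValueError(f"p={p} outside (0, 1)")
    FA = mp.hyp2f1(a, b, c, p)
    FAp = a * b / c * mp.hyp2f1(a + 1, b + 1, c + 1, p)
    # p^(1-c) = exp((1-c) ln p) with real ln p: single-valued on (0,1)
    g = mp.hyp2f1(a - c + 1, b - c + 1, 2 - c, p)
    gp = (a - c + 1) * (b - c + 1) / (2 - c) * mp.hyp2f1(
        a - c + 2, b - c + 2, 3 - c, p
    )
    FB = p ** (1 - c) * g
    FBp = (1 - c) * p ** (-c) * g + p ** (1 - c) * gp
    return FA, FB, FAp, FBp


def _kappa(ctx: HS1SolverContext, t: float):
    """Prefactor -i (2 beta / Tp) w1(t) / w1m^2 of the logarithmic
    derivative in the HS1 solution, at working precision."""
    pulse = ctx.pulse
    u = (2 * mp.mpf(pulse.beta) / pulse.Tp) * (mp.mpf(t) - pulse.tc)
    am = pulse.omega1m * mp.sech(u)
    phase = pulse.phic + (pulse.A * pulse.Tp / (2 * pulse.beta)) * mp.log(
        mp.cosh(u)
    )
    w1 = am * mp.exp(1j * phase)
    return -1j * (2 * mp.mpf(pulse.beta) / pulse.Tp) * w1 / pulse.omega1m**2


def _p_mp(ctx: HS1SolverContext, t: float):
    pulse = ctx.pulse
    u = (2 * mp.mpf(pulse.beta) / pulse.Tp) * (mp.mpf(t) - pulse.tc)
    return (1 + mp.tanh(u)) / 2


def _as_projective(f_known) -> tuple:
    """Normalize an anchor orientation to a projective pair (fN, fD)."""
    if isinstance(f_known, RiemannPoint):
        if f_known.at_infinity:
            return mp.mpc(1), mp.mpc(0)
        return mp.mpc(f_known.value), mp.mpc(1)
    if isinstance(f_known, tuple):
        return mp.mpc(f_known[0]), mp.mpc(f_known[1])
    return mp.mpc(f_known), mp.mpc(1)


def hs1_particular(
    f_known, t_known: float, ctx: HS1SolverContext
) -> ParticularConstant:
    """Particular constant (CA : CB) from one known orientation.

    ``f_known`` may be a :class:`RiemannPoint` (finite or at infinity), a
    complex number, or a projective ``(num, den)`` pair.  The returned
    pair reproduces ``f_known`` at ``p(t_known)`` exactly; the projective
    representation absorbs anchors at the south pole and vanishing
    denominators.
    """
    with mp.workdps(ctx.dps):
        fN, fD = _as_projective(f_known)
        FA, FB, FAp, FBp = hs1_basis(_p_mp(ctx, t_known), ctx.a, ctx.b, ctx.c)
        k = _kappa(ctx, t_known)
        # f (CA FA + CB FB) = kappa (CA FA' + CB FB')
        CA = fN * FB - fD * k * FBp
        CB = -(fN * FA - fD * k * FAp)
        return ParticularConstant(CA, CB)


def _evaluate_projective(ctx: HS1SolverContext, const: ParticularConstant, t: float):
    """(num, den) of f(t) at working precision (caller sets mp context)."""
    FA, FB, FAp, FBp = hs1_basis(_p_mp(ctx, t), ctx.a, ctx.b, ctx.c)
    k = _kappa(ctx, t)
    num = k * (const.CA * FAp + const.CB * FBp)
    den = const.CA * FA + const.CB * FB
    return num, den


def hs1_evaluate(
    ctx: HS1SolverContext, const: ParticularConstant, t: float
) -> RiemannPoint:
    """Evaluate the particular solution f(t) on the extended plane."""
    with mp.workdps(ctx.dps):
        num, den = _evaluate_projective(ctx, const, t)
        if abs(den) <= mp.mpf(10) ** (-ctx.dps) * abs(num):
            return RiemannPoint.infinity()
        return RiemannPoint.finite(complex(num / den))


def hs1_propagate(
    pulse: HS1Pulse,
    iso: Isochromat,
    eval_times: Sequence[float],
    t_init: Optional[float] = None,
    dps: int = DEFAULT_DPS,
) -> Trajectory:
    """Exact trajectory of ``iso`` under ``pulse`` at ``eval_times``.

    The particular constant is anchored at ``t_init`` (default: pulse
    start, where the magnetization is known).  Norm is conserved
    identically by the inverse projection.
    """
    if t_init is None:
        t_init = pulse.t_start
    eval_times = np.asarray(eval_times, dtype=float)
    _check_support(eval_times, pulse.t_start, pulse.t_end)
    _check_support(t_init, pulse.t_start, pulse.t_end)
    ctx = HS1SolverContext.create(pulse, iso.omega, dps)
    const = hs1_particular(project(iso.M), t_init, ctx)
    norm = iso.M.norm
    out = np.empty((eval_times.size, 3))
    with mp.workdps(dps):
        for i, t in enumerate(eval_times):
            num, den = _evaluate_projective(ctx, const, float(t))
            out[i] = magnetization_from_ratio(
                complex(num), complex(den), norm
            ).as_array()
    return Trajectory(
        times=eval_times,
        M=out,
        provenance="analytic-hs1",
        meta={"omega": iso.omega, "t_init": float(t_init), "dps": dps,
              "C": const.C},
    )


def sit_final_angle(pulse: HS1Pulse) -> float:
    """Final polar angle (rad) swept by a non-swept (A = 0) HS1 pulse on
    resonance: theta_f = (w1m Tp / beta) arctan(exp(u_end)), where u_end
    is the boundary value of the sech argument (beta for a symmetric
    pulse)."""
    if pulse.A != 0.0:
        raise ValueError("SIT closed form requires A = 0")
    u_end = (2.0 * pulse.beta / pulse.Tp) * (pulse.t_end - pulse.tc)
    return (pulse.omega1m * pulse.Tp / pulse.beta) * math.atan(math.exp(u_end))


def sit_closed_form(t, pulse: HS1Pulse):
    """Self-induced-transparency closed form for A = 0 on resonance.

    Returns ``(theta, M)``: the polar angle(s)

        theta(t) = (w1m Tp / beta) arctan(exp((2 beta/Tp)(t - tc)))

    and the magnetization rotating in the y-z plane,
    M = (0, sin theta, cos theta).

    This is the ideal *untruncated* sech-pulse trajectory (equilibrium at
    t -> -infinity): at the truncated pulse start it is tilted from +z by
    theta(t_start) ~ 2 x truncation, which is exactly its deviation from
    the truncated equilibrium-start solution; the two converge as the
    truncation shrinks.  For a 2*pi amplitude the closed form ends at
    exactly +z.

    For scalar ``t`` the magnetization is a :class:`Magnetization`; for
    array ``t`` an (n, 3) array.
    """
    if pulse.A != 0.0:
        raise ValueError("SIT closed form requires A = 0")
    scale = pulse.omega1m * pulse.Tp / pulse.beta
    u = (2.0 * pulse.beta / pulse.Tp) * (np.asarray(t, dtype=float) - pulse.tc)
    theta = scale * np.arctan(np.exp(u))
    if np.ndim(t):
        M = np.stack(
            [np.zeros_like(theta), np.sin(theta), np.cos(theta)], axis=-1
        )
        return theta, M
    theta = float(theta)
    return theta, Magnetization(0.0, math.sin(theta), math.cos(theta))
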