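"""Exact analytical propagators for the chirp and square pulses.

Chirp (A != 0)
--------------
With the complex reparameterized time

    p(t) = sqrt(i A / Tp) * (t - tc + Tp Omega / (2 A))

the Bloch-Riccati equation under a chirp driving function linearizes into
the confluent-hypergeometric-type equation

    q'' + 2 p q' - i (Tp w1m^2 / 4 A) q = 0 ,

whose fundamental pair is built from solutions of the Hermite equation of
complex order a = -1 - i Tp w1m^2 / (8 A):

    FA(p)          = 1F1((a+1)/2; 1/2; -p^2)        (even branch)
    FB(p) e^{-p^2} = H_a(p) e^{-p^2}                (Hermite function)

and the solution on the extended plane is

    f(t) = -2i sqrt(i A / Tp) (w1(t) / w1m^2) * q'(p)/q(p),

the prefactor equal to (1-i) sqrt(2 A / Tp) w1/w1m^2 for A > 0 and
branch-correct for A < 0.  As for the HS1 solver, the single integration
constant is held as a projective pair (CA : CB) fixed by one known
orientation; values are computed with mpmath at a configurable working
precision.

Square (A = 0)
--------------
The square pulse admits an elementary solution on the extended plane,

    f(t) = e^{i phic} / w1m * (-Omega + weff tanh(C + (i/2) weff t)),
    weff = sqrt(Omega^2 + w1m^2),

with the constant fixed by one orientation fc at time t0:

    C = artanh((w1m e^{-i phic} fc + Omega) / weff) - (i/2) weff t0

(principal artanh branch; the iπ branch ambiguity is a period of tanh and
therefore harmless).  A chirp pulse with A = 0 is dispatched to this
solver automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import mpmath as mp
import numpy as np

from .hs1 import DEFAULT_DPS, ParticularConstant, _as_projective
from .pulses import ChirpPulse, SquarePulse, _check_support
from .sphere import (
    Isochromat,
    RiemannPoint,
    magnetization_from_ratio,
    project,
)
from .trajectory import Trajectory

__all__ = [
    "ChirpSolverContext",
    "SquareSolverContext",
    "chirp_p",
    "chirp_basis",
    "chirp_particular",
    "chirp_evaluate",
    "chirp_propagate",
    "square_particular",
    "square_evaluate",
    "square_propagate",
    "BranchPointError",
]

#: anchors closer than this to an artanh branch point are rejected
BRANCH_POINT_TOL = 1e-10


class BranchPointError(ValueError):
    """Anchor falls on a branch point of the square-pulse constant."""


@dataclass(frozen=True)
class ChirpSolverContext:
    """Chirp pulse + offset + basis order a = -1 - i Tp w1m^2 / (8 A)."""

    pulse: ChirpPulse
    omega: float
    a: object  # mpmath mpc
    alpha: object  # sqrt(i A / Tp), the time scaling of p
    dps: int = DEFAULT_DPS

    @classmethod
    def create(cls, pulse: ChirpPulse, Omega: float, dps: int = DEFAULT_DPS):
        if pulse.A == 0.0:
            raise ValueError("chirp solver requires A != 0 (use the square solver)")
        with mp.workdps(dps):
            a = -1 - 1j * mp.mpf(pulse.Tp) * pulse.omega1m**2 / (8 * pulse.A)
            alpha = mp.sqrt(1j * mp.mpf(pulse.A) / pulse.Tp)
        return cls(pulse=pulse, omega=Omega, a=a, alpha=alpha, dps=dps)


@dataclass(frozen=True)
class SquareSolverContext:
    """Square pulse + offset + effective frequency weff."""

    pulse: SquarePulse
    omega: float
    weff: float
    dps: int = DEFAULT_DPS

    @classmethod
    def create(cls, pulse: SquarePulse, Omega: float, dps: int = DEFAULT_DPS):
        if pulse.omega1m == 0.0:
            raise ValueError("square solver requires omega1m > 0")
        weff = math.hypot(Omega, pulse.omega1m)
        return cls(pulse=pulse, omega=Omega, weff=weff, dps=dps)


def chirp_p(t, pulse: ChirpPulse, Omega: float):
    """Complex reparameterized time of the chirp solution (affine in t)."""
    if pulse.A == 0.0:
        raise ValueError("chirp reparameterization requires A != 0")
    alpha = complex(mp.sqrt(1j * mp.mpf(pulse.A) / pulse.Tp))
    shift = pulse.Tp * Omega / (2.0 * pulse.A)
    out = alpha * (np.asarray(t, dtype=float) - pulse.tc + shift)
    return out if np.ndim(t) else complex(out)


def chirp_basis(p, a):
    """Fundamental pair for the chirp equation and p-derivatives.

    Returns ``(FA, FB, FA', FB')`` where FA = 1F1((a+1)/2; 1/2; -p^2) and
    FB = H_a(p), the Hermite function of complex order a (the e^{-p^2}
    factor on the B branch is applied by the evaluator, matching the form
    q = FA + C FB e^{-p^2}).
    """
    p = mp.mpc(p)
    FA = mp.hyp1f1((a + 1) / 2, mp.mpf("0.5"), -p * p)
    FAp = -2 * p * (a + 1) * mp.hyp1f1((a + 3) / 2, mp.mpf("1.5"), -p * p)
    FB = mp.hermite(a, p)
    FBp = 2 * a * mp.hermite(a - 1, p)  # d/dp H_a = 2 a H_{a-1}
    return FA, FB, FAp, FBp


def _chirp_basis_q(ctx: ChirpSolverContext, t: float):
    """Basis of q-space solutions (qA, qB) = (FA, FB e^{-p^2}) and their
    p-derivatives at p(t)."""
    pulse = ctx.pulse
    shift = mp.mpf(pulse.Tp) * ctx.omega / (2 * pulse.A)
    p = ctx.alpha * (mp.mpf(t) - pulse.tc + shift)
    FA, FB, FAp, FBp = chirp_basis(p, ctx.a)
    e = mp.exp(-p * p)
    qB = FB * e
    qBp = (FBp - 2 * p * FB) * e
    return FA, qB, FAp, qBp


def _chirp_kappa(ctx: ChirpSolverContext, t: float):
    """Prefactor -2i alpha w1(t) / w1m^2 of the chirp solution."""
    pulse = ctx.pulse
    dt = mp.mpf(t) - pulse.tc
    phase = pulse.phic + (mp.mpf(pulse.A) / pulse.Tp) * dt * dt
    w1 = pulse.omega1m * mp.exp(1j * phase)
    return -2j * ctx.alpha * w1 / pulse.omega1m**2


def chirp_particular(
    f_known, t_known: float, ctx: ChirpSolverContext
) -> ParticularConstant:
    """Particular constant (CA : CB) from one known orientation (a
    :class:`RiemannPoint`, complex value, or projective pair)."""
    with mp.workdps(ctx.dps):
        fN, fD = _as_projective(f_known)
        qA, qB, qAp, qBp = _chirp_basis_q(ctx, t_known)
        k = _chirp_kappa(ctx, t_known)
        CA = fN * qB - fD * k * qBp
        CB = -(fN * qA - fD * k * qAp)
        return ParticularConstant(CA, CB)


def _chirp_evaluate_projective(
    ctx: ChirpSolverContext, const: ParticularConstant, t: float
):
    qA, qB, qAp, qBp = _chirp_basis_q(ctx, t)
    k = _chirp_kappa(ctx, t)
    num = k * (const.CA * qAp + const.CB * qBp)
    den = const.CA * qA + const.CB * qB
    return num, den


def chirp_evaluate(
    ctx: ChirpSolverContext, const: ParticularConstant, t: float
) -> RiemannPoint:
    """Evaluate the chirp particular solution f(t) on the extended plane."""
    with mp.workdps(ctx.dps):
        num, den = _chirp_evaluate_projective(ctx, const, t)
        if abs(den) <= mp.mpf(10) ** (-ctx.dps) * abs(num):
            return RiemannPoint.infinity()
        return RiemannPoint.finite(complex(num / den))


def chirp_propagate(
    pulse: ChirpPulse,
    iso: Isochromat,
    eval_times: Sequence[float],
    t_init: Optional[float] = None,
    dps: int = DEFAULT_DPS,
) -> Trajectory:
    """Exact trajectory under a chirp pulse.

    A chirp with A = 0 is a square pulse and is dispatched to
    :func:`square_propagate` automatically.
    """
    if pulse.A == 0.0:
        sq = SquarePulse(
            omega1m=pulse.omega1m, phic=pulse.phic,
            t_start=pulse.t_start, t_end=pulse.t_end,
        )
        traj = square_propagate(sq, iso, eval_times, t_init=t_init, dps=dps)
        traj.provenance = "analytic-square"
        return traj
    if t_init is None:
        t_init = pulse.t_start
    eval_times = np.asarray(eval_times, dtype=float)
    _check_support(eval_times, pulse.t_start, pulse.t_end)
    _check_support(t_init, pulse.t_start, pulse.t_end)
    ctx = ChirpSolverContext.create(pulse, iso.omega, dps)
    const = chirp_particular(project(iso.M), t_init, ctx)
    norm = iso.M.norm
    out = np.empty((eval_times.size, 3))
    with mp.workdps(dps):
        for i, t in enumerate(eval_times):
            num, den = _chirp_evaluate_projective(ctx, const, float(t))
            out[i] = magnetization_from_ratio(
                complex(num), complex(den), norm
            ).as_array()
    return Trajectory(
        times=eval_times,
        M=out,
        provenance="analytic-chirp",
        meta={"omega": iso.omega, "t_init": float(t_init), "dps": dps,
              "C": const.C},
    )


def square_particular(fc, tc_anchor: float, ctx: SquareSolverContext):
    """Integration constant of the square-pulse solution (mpmath mpc).

    ``fc`` may be a :class:`RiemannPoint`, complex value, or projective
    pair; an anchor at the south pole maps through the tanh -> infinity
    limit (artanh branch shifts are periods of tanh and drop out).
    Anchors landing exactly on an artanh branch point (+-1) are rejected.
    """
    pulse = ctx.pulse
    with mp.workdps(ctx.dps):
        fN, fD = _as_projective(fc)
        weff = mp.hypot(ctx.omega, pulse.omega1m)
        if fD == 0 or abs(fN) > mp.mpf(10) ** ctx.dps * abs(fD):
            arg = None  # south pole: tanh(g) -> infinity, g = i pi/2
        else:
            f = fN / fD
            arg = (pulse.omega1m * mp.exp(-1j * mp.mpf(pulse.phic)) * f
                   + ctx.omega) / weff
        if arg is None:
            C0 = 1j * mp.pi / 2
        else:
            if min(abs(arg - 1), abs(arg + 1)) < BRANCH_POINT_TOL:
                raise BranchPointError(
                    f"anchor argument {complex(arg)} lies on an artanh "
                    "branch point"
                )
            C0 = mp.atanh(arg)
        return C0 - 0.5j * mp.mpf(tc_anchor) * weff


def align_square_constants(constants):
    """Reduce square-pulse constants to a common artanh branch.

    ``tanh`` has period i*pi, so constants determined from different
    anchor points on one trajectory may differ by integer multiples of
    i*pi while describing the same solution.  Returns the constants with
    those multiples removed (relative to the first entry), suitable for
    constant-of-motion comparisons.
    """
    cs = [complex(c) for c in constants]
    ref = cs[0]
    out = []
    for c in cs:
        k = round((c.imag - ref.imag) / math.pi)
        out.append(c - 1j * math.pi * k)
    return out


def _square_projective(ctx: SquareSolverContext, C, t: float):
    """(num, den) of f(t) for the square solution, stable at the poles."""
    pulse = ctx.pulse
    weff = mp.hypot(ctx.omega, pulse.omega1m)
    g = C + 0.5j * mp.mpf(t) * weff
    # tanh(g) as sinh/cosh keeps the south-pole limit (cosh -> 0) exact
    sh, ch = mp.sinh(g), mp.cosh(g)
    num = mp.exp(1j * mp.mpf(pulse.phic)) * (-ctx.omega * ch + weff * sh)
    den = pulse.omega1m * ch
    return num, den


def square_evaluate(ctx: SquareSolverContext, C, t: float) -> RiemannPoint:
    """Evaluate the square-pulse solution f(t) on the extended plane."""
    with mp.workdps(ctx.dps):
        num, den = _square_projective(ctx, C, t)
        if abs(den) <= mp.mpf(10) ** (-ctx.dps) * abs(num):
            return RiemannPoint.infinity()
        return RiemannPoint.finite(complex(num / den))


def square_propagate(
    pulse: SquarePulse,
    iso: Isochromat,
    eval_times: Sequence[float],
    t_init: Optional[float] = None,
    dps: int = DEFAULT_DPS,
) -> Trajectory:
    """Exact trajectory under a square pulse (norm conserved identically)."""
    if t_init is None:
        t_init = pulse.t_start
    eval_times = np.asarray(eval_times, dtype=float)
    _check_support(eval_times, pulse.t_start, pulse.t_end)
    _check_support(t_init, pulse.t_start, pulse.t_end)
    ctx = SquareSolverContext.create(pulse, iso.omega, dps)
    C = square_particular(project(iso.M), t_init, ctx)
    norm = iso.M.norm
    out = np.empty((eval_times.size, 3))
    with mp.workdps(dps):
        for i, t in enumerate(eval_times):
            num, den = _square_projective(ctx, C, float(t))
            out[i] = magnetization_from_ratio(
                complex(num), complex(den), norm
            ).as_array()
    return Trajectory(
        times=eval_times,
        M=out,
        provenance="analytic-square",
        meta={"omega": iso.omega, "t_init": float(t_init), "dps": dps,
              "C": complex(C)},
    )
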