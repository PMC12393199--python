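"""Frequency-modulated RF pulse waveforms.

Shaped RF pulses are described in the rotating frame at the carrier
frequency by an amplitude-modulation function ``am(t)`` (the instantaneous
Rabi rate, rad/s), a frequency-modulation function ``fm(t)`` (rad/s), and
the accumulated RF phase ``phase(t)`` with d(phase)/dt = fm.  Three
families are implemented:

* :class:`HS1Pulse` -- hyperbolic-secant amplitude with tanh frequency
  sweep, the workhorse adiabatic inversion pulse.
* :class:`ChirpPulse` -- constant amplitude with a linear frequency sweep
  of total width ``2 A`` over the characteristic duration ``Tp``.
* :class:`SquarePulse` -- constant amplitude, constant phase.

Composites (:class:`CompositePulse`) chain pulse segments contiguously in
time with per-segment additive phase offsets; :func:`make_bir4` builds the
B1-insensitive rotation composite from four asymmetrically truncated
half-HS1 segments.

All angular frequencies are stored in rad/s.  Pulse supports are closed
intervals ``[t_start, t_end]``; evaluation outside raises
:class:`OutOfSupportError`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "OutOfSupportError",
    "HS1Pulse",
    "ChirpPulse",
    "SquarePulse",
    "Segment",
    "CompositePulse",
    "Pulse",
    "eval_waveform",
    "eval_rf",
    "hs1_time_bandwidth",
    "hs1_from_spec",
    "beta_from_truncation",
    "sit_amplitude",
    "make_bir4",
]

#: relative slack allowed when testing membership of the closed support
_SUPPORT_RTOL = 1e-9


class OutOfSupportError(ValueError):
    """Raised when a pulse is evaluated outside its support interval."""


def _check_support(t, t_start: float, t_end: float) -> None:
    tol = _SUPPORT_RTOL * (t_end - t_start)
    t = np.asarray(t, dtype=float)
    if np.any(t < t_start - tol) or np.any(t > t_end + tol):
        raise OutOfSupportError(
            f"time {t} outside pulse support [{t_start}, {t_end}]"
        )


@dataclass(frozen=True)
class HS1Pulse:
    """Hyperbolic-secant (HS1) pulse.

    Parameters
    ----------
    omega1m : float
        Peak Rabi angular frequency, rad/s (>= 0).
    A : float
        Frequency-sweep magnitude parameter, rad/s.  The effective swept
        width of a truncated pulse is reduced by tanh(beta).
    beta : float
        Signed dimensionless truncation factor; ``sech(beta)`` is the
        fractional amplitude at the symmetric boundaries ``tc +/- Tp/2``
        and the sign sets the sweep direction.  Must be nonzero.
    Tp : float
        Characteristic duration, s: twice the interval from ``tc`` at
        which the amplitude falls to ``sech(beta)`` of its peak.
    tc : float
        Time of peak amplitude, s.
    phic : float
        RF phase at ``tc``, rad.
    t_start, t_end : float
        Support interval, s.  Defaults to the symmetric truncation
        ``[tc - Tp/2, tc + Tp/2]``; setting them independently of ``tc``
        produces asymmetrically truncated pulses (e.g. half-pulses).
    """

    omega1m: float
    A: float
    beta: float
    Tp: float
    tc: float = 0.0
    phic: float = 0.0
    t_start: float = None  # type: ignore[assignment]
    t_end: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.omega1m < 0:
            raise ValueError("omega1m must be >= 0")
        if self.Tp <= 0:
            raise ValueError("Tp must be > 0")
        if self.beta == 0:
            raise ValueError("beta must be nonzero")
        if self.t_start is None:
            object.__setattr__(self, "t_start", self.tc - self.Tp / 2)
        if self.t_end is None:
            object.__setattr__(self, "t_end", self.tc + self.Tp / 2)
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def _u(self, t):
        return (2.0 * self.beta / self.Tp) * (np.asarray(t, dtype=float) - self.tc)

    def am(self, t):
        _check_support(t, self.t_start, self.t_end)
        return self.omega1m / np.cosh(self._u(t))

    def fm(self, t):
        _check_support(t, self.t_start, self.t_end)
        return self.A * np.tanh(self._u(t))

    def phase(self, t):
        _check_support(t, self.t_start, self.t_end)
        # integral of fm: phic + (A Tp / 2 beta) ln(omega1m / am(t));
        # ln cosh written overflow-safely
        u = self._u(t)
        logcosh = np.abs(u) + np.log1p(np.exp(-2.0 * np.abs(u))) - math.log(2.0)
        return self.phic + (self.A * self.Tp / (2.0 * self.beta)) * logcosh


@dataclass(frozen=True)
class ChirpPulse:
    """Chirp pulse: constant amplitude, linear frequency sweep.

    ``Tp`` is the duration over which the sweep covers the full width
    ``2 A`` (rad/s); the sweep is centered (fm = 0) at ``tc`` and the
    phase is quadratic about ``tc``.
    """

    omega1m: float
    A: float
    Tp: float
    tc: float = 0.0
    phic: float = 0.0
    t_start: float = None  # type: ignore[assignment]
    t_end: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.omega1m < 0:
            raise ValueError("omega1m must be >= 0")
        if self.Tp <= 0:
            raise ValueError("Tp must be > 0")
        if self.t_start is None:
            object.__setattr__(self, "t_start", self.tc - self.Tp / 2)
        if self.t_end is None:
            object.__setattr__(self, "t_end", self.tc + self.Tp / 2)
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def am(self, t):
        _check_support(t, self.t_start, self.t_end)
        return np.full_like(np.asarray(t, dtype=float), self.omega1m)

    def fm(self, t):
        _check_support(t, self.t_start, self.t_end)
        return (2.0 * self.A / self.Tp) * (np.asarray(t, dtype=float) - self.tc)

    def phase(self, t):
        _check_support(t, self.t_start, self.t_end)
        return self.phic + (self.A / self.Tp) * (
            np.asarray(t, dtype=float) - self.tc
        ) ** 2


@dataclass(frozen=True)
class SquarePulse:
    """Square pulse: constant amplitude ``omega1m`` and phase ``phic``."""

    omega1m: float
    phic: float
    t_start: float
    t_end: float

    def __post_init__(self):
        if self.omega1m < 0:
            raise ValueError("omega1m must be >= 0")
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def am(self, t):
        _check_support(t, self.t_start, self.t_end)
        return np.full_like(np.asarray(t, dtype=float), self.omega1m)

    def fm(self, t):
        _check_support(t, self.t_start, self.t_end)
        return np.zeros_like(np.asarray(t, dtype=float))

    def phase(self, t):
        _check_support(t, self.t_start, self.t_end)
        return np.full_like(np.asarray(t, dtype=float), self.phic)


@dataclass(frozen=True)
class Segment:
    """One segment of a composite pulse: a pulse plus an additive phase
    offset (rad) applied on top of the pulse's own phase."""

    pulse: Union[HS1Pulse, ChirpPulse, SquarePulse]
    phase_offset: float = 0.0

    @property
    def t_start(self) -> float:
        return self.pulse.t_start

    @property
    def t_end(self) -> float:
        return self.pulse.t_end


@dataclass(frozen=True)
class CompositePulse:
    """Ordered chain of contiguous, non-overlapping pulse segments."""

    segments: tuple

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("composite pulse needs at least one segment")
        for prev, nxt in zip(segs, segs[1:]):
            gap = abs(nxt.t_start - prev.t_end)
            if gap > _SUPPORT_RTOL * self.duration_hint(segs):
                raise ValueError(
                    f"segments not contiguous at t={prev.t_end} (gap {gap})"
                )

    @staticmethod
    def duration_hint(segs) -> float:
        return segs[-1].t_end - segs[0].t_start

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def segment_index(self, t: float) -> int:
        """Index of the segment containing time ``t``.

        Junction times belong to the later segment, so that the value at a
        phase-jump instant is the post-jump one.
        """
        _check_support(t, self.t_start, self.t_end)
        for k in range(len(self.segments) - 1, -1, -1):
            seg = self.segments[k]
            if t >= seg.t_start - _SUPPORT_RTOL * self.duration:
                return k
        return 0

    def _eval(self, t, what: str):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        _check_support(t_arr, self.t_start, self.t_end)
        out = np.empty_like(t_arr)
        starts = np.array([s.t_start for s in self.segments])
        idx = np.searchsorted(starts, t_arr + _SUPPORT_RTOL * self.duration) - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)
        for k, seg in enumerate(self.segments):
            m = idx == k
            if not np.any(m):
                continue
            tk = np.clip(t_arr[m], seg.t_start, seg.t_end)
            val = getattr(seg.pulse, what)(tk)
            if what == "phase":
                val = val + seg.phase_offset
            out[m] = val
        return out if np.ndim(t) else out[0]

    def am(self, t):
        return self._eval(t, "am")

    def fm(self, t):
        return self._eval(t, "fm")

    def phase(self, t):
        return self._eval(t, "phase")


Pulse = Union[HS1Pulse, ChirpPulse, SquarePulse, CompositePulse]


def eval_waveform(pulse: Pulse, t):
    """Return ``(am, fm, phase)`` of ``pulse`` at time(s) ``t``."""
    return pulse.am(t), pulse.fm(t), pulse.phase(t)


def eval_rf(pulse: Pulse, t):
    """Complex RF amplitude ``am(t) * exp(i phase(t))`` in rad/s."""
    return pulse.am(t) * np.exp(1j * pulse.phase(t))


def hs1_time_bandwidth(pulse: HS1Pulse) -> float:
    """Truncation-corrected time-bandwidth factor R = A Tp tanh(beta) / pi."""
    return pulse.A * pulse.Tp * math.tanh(pulse.beta) / math.pi


def beta_from_truncation(truncation_fraction: float) -> float:
    """Truncation factor beta = arcsech(truncation_fraction)."""
    if not 0.0 < truncation_fraction < 1.0:
        raise ValueError("truncation_fraction must lie in (0, 1)")
    x = 1.0 / truncation_fraction
    return math.log(x + math.sqrt(x * x - 1.0))


def hs1_from_spec(
    omega1m: float,
    Tp: float,
    R: float,
    truncation_fraction: float,
    tc: float = 0.0,
    phic: float = 0.0,
    t_start: float = None,
    t_end: float = None,
) -> HS1Pulse:
    """Construct an HS1 pulse from the practitioner-facing parameters.

    ``R`` is the truncation-corrected time-bandwidth factor and
    ``truncation_fraction`` the fractional amplitude at the symmetric
    boundaries; the sweep magnitude is recovered as
    ``A = pi R / (Tp tanh(beta))``.
    """
    if R < 0:
        raise ValueError("R must be >= 0")
    beta = beta_from_truncation(truncation_fraction)
    A = math.pi * R / (Tp * math.tanh(beta))
    return HS1Pulse(
        omega1m=omega1m, A=A, beta=beta, Tp=Tp, tc=tc, phic=phic,
        t_start=t_start, t_end=t_end,
    )


def sit_amplitude(beta: float, Tp: float) -> float:
    """Peak amplitude (rad/s) of the non-swept HS1 pulse whose final
    rotation angle is exactly 2*pi (self-induced transparency)."""
    if beta <= 0 or Tp <= 0:
        raise ValueError("beta and Tp must be > 0")
    return 2.0 * math.pi * beta / (Tp * math.atan(math.exp(beta)))


def make_bir4(theta: float, component: HS1Pulse) -> CompositePulse:
    """Build a BIR-4 composite pulse for target flip angle ``theta``.

    The composite consists of four asymmetrically truncated half-HS1
    segments, each of duration ``Tp/2`` where ``Tp`` is the component
    characteristic duration (total duration ``2 Tp``).  The amplitude
    peaks at the composite start, middle and end; the frequency sweep
    within each half runs along the component's tanh branch.  The
    flip-angle-setting phase shifts ``pi + theta/2`` are applied to the
    middle two segments (jumps at the quarter and three-quarter points).

    The component's own support is ignored; only its ``omega1m``, ``A``,
    ``beta``, ``Tp`` and ``phic`` are used.  The composite starts at t=0.
    """
    w, A, b, Tp, phic = (
        component.omega1m, component.A, component.beta,
        component.Tp, component.phic,
    )
    dphi = math.pi + theta / 2.0
    half = Tp / 2.0

    def seg(tc, t0, t1, off):
        return Segment(
            HS1Pulse(omega1m=w, A=A, beta=b, Tp=Tp, tc=tc, phic=phic,
                     t_start=t0, t_end=t1),
            phase_offset=off,
        )

    return CompositePulse(segments=(
        seg(0.0, 0.0, half, 0.0),          # descending half, peak at start
        seg(Tp, half, Tp, dphi),           # ascending half, peak at middle
        seg(Tp, Tp, Tp + half, dphi),      # descending half
        seg(2 * Tp, Tp + half, 2 * Tp, 0.0),  # ascending half, peak at end
    ))
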