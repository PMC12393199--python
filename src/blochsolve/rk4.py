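"""Classic fixed-step RK4 integration of the rotating-frame Bloch equation.

The integrator serves as the independent verification oracle for the
analytic propagators: with the RF field sampled at the RK4 sub-stage
times, the global error decreases as the fourth power of the step size
until double-precision round-off is reached.

Composite pulses are integrated segment by segment (steps allotted
proportionally to segment duration), so that the phase discontinuities at
segment junctions fall exactly on step boundaries and each step sees a
smooth field -- a requirement for clean fourth-order convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .pulses import CompositePulse, Pulse, _check_support
from .sphere import Isochromat, Magnetization
from .trajectory import Trajectory

__all__ = ["RK4Settings", "bloch_derivative", "rk4_propagate"]


@dataclass(frozen=True)
class RK4Settings:
    """Fixed-step integration window: ``n_steps`` uniform steps over
    ``[t_init, t_final]``."""

    n_steps: int
    t_init: float
    t_final: float

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not self.t_final > self.t_init:
            raise ValueError("t_final must be > t_init")


def bloch_derivative(M: Magnetization, t: float, pulse: Pulse, Omega: float):
    """dM/dt of the relaxation-free Bloch equation at time ``t``.

    The instantaneous rotation vector is -(w1x, w1y, Omega) with
    w1x = am cos(phase), w1y = am sin(phase); the returned derivative is
    its cross product with M (skew-symmetric, so M . dM/dt = 0).
    """
    am = float(pulse.am(t))
    ph = float(pulse.phase(t))
    ax, ay, az = -am * math.cos(ph), -am * math.sin(ph), -Omega
    mx, my, mz = M.mx, M.my, M.mz
    return np.array(
        [ay * mz - az * my, az * mx - ax * mz, ax * my - ay * mx]
    )


def _stage_fields(pulse: Pulse, t0: float, h: float, n: int):
    """RF field (w1x, w1y) at the 2n+1 half-step stage times."""
    ts = t0 + 0.5 * h * np.arange(2 * n + 1)
    # clip the boundary stages against support round-off
    ts = np.clip(ts, pulse.t_start, pulse.t_end)
    am = pulse.am(ts)
    ph = pulse.phase(ts)
    return (am * np.cos(ph)).tolist(), (am * np.sin(ph)).tolist()


def _rk4_segment(pulse, Omega, M, t0, h, n, local_rec):
    """Integrate n uniform steps from t0; return the final state and the
    states after the step counts listed in ``local_rec`` (sorted, in
    [1, n]).

    The inner loop runs on plain floats: at a million steps the numpy
    per-call overhead would dominate the runtime.
    """
    w1x, w1y = _stage_fields(pulse, t0, h, n)
    az = -Omega
    mx, my, mz = M
    h6 = h / 6.0
    recorded = []
    pos = 0
    nxt = local_rec[0] if local_rec else -1
    for i in range(n):
        ax = -w1x[2 * i]
        ay = -w1y[2 * i]
        k1x = ay * mz - az * my
        k1y = az * mx - ax * mz
        k1z = ax * my - ay * mx
        ax = -w1x[2 * i + 1]
        ay = -w1y[2 * i + 1]
        px = mx + 0.5 * h * k1x
        py = my + 0.5 * h * k1y
        pz = mz + 0.5 * h * k1z
        k2x = ay * pz - az * py
        k2y = az * px - ax * pz
        k2z = ax * py - ay * px
        px = mx + 0.5 * h * k2x
        py = my + 0.5 * h * k2y
        pz = mz + 0.5 * h * k2z
        k3x = ay * pz - az * py
        k3y = az * px - ax * pz
        k3z = ax * py - ay * px
        ax = -w1x[2 * i + 2]
        ay = -w1y[2 * i + 2]
        px = mx + h * k3x
        py = my + h * k3y
        pz = mz + h * k3z
        k4x = ay * pz - az * py
        k4y = az * px - ax * pz
        k4z = ax * py - ay * px
        mx += h6 * (k1x + 2.0 * (k2x + k3x) + k4x)
        my += h6 * (k1y + 2.0 * (k2y + k3y) + k4y)
        mz += h6 * (k1z + 2.0 * (k2z + k3z) + k4z)
        if i + 1 == nxt:
            recorded.append((mx, my, mz))
            pos += 1
            nxt = local_rec[pos] if pos < len(local_rec) else -1
    return (mx, my, mz), recorded


def _segment_plan(pulse: Pulse, t0: float, t1: float, n_steps: int):
    """(pulse-or-segment, start, end, steps) covering [t0, t1].

    For composites, steps are allotted per overlapped segment in
    proportion to duration (at least one step each).
    """
    if not isinstance(pulse, CompositePulse):
        return [(pulse, t0, t1, n_steps)]
    spans = []
    for seg in pulse.segments:
        a = max(t0, seg.t_start)
        b = min(t1, seg.t_end)
        if b - a > 1e-12 * pulse.duration:
            from dataclasses import replace

            p = seg.pulse
            if seg.phase_offset:
                p = replace(p, phic=p.phic + seg.phase_offset)
            spans.append((p, a, b))
    total = sum(b - a for _, a, b in spans)
    counts = [max(1, round(n_steps * (b - a) / total)) for _, a, b in spans]
    # adjust rounding so the step counts sum to n_steps
    k = 0
    while sum(counts) != n_steps:
        j = k % len(counts)
        if sum(counts) > n_steps and counts[j] > 1:
            counts[j] -= 1
        elif sum(counts) < n_steps:
            counts[j] += 1
        k += 1
    return [(p, a, b, c) for (p, a, b), c in zip(spans, counts)]


def rk4_propagate(
    pulse: Pulse,
    iso: Isochromat,
    n_steps: int,
    t_init: Optional[float] = None,
    t_final: Optional[float] = None,
    eval_times: Optional[Sequence[float]] = None,
) -> Trajectory:
    """RK4 trajectory over ``[t_init, t_final]`` (default: full support).

    ``eval_times`` are snapped to the nearest grid point (exact when they
    are multiples of the step); by default every grid point is returned.
    """
    if t_init is None:
        t_init = pulse.t_start
    if t_final is None:
        t_final = pulse.t_end
    settings = RK4Settings(n_steps=n_steps, t_init=t_init, t_final=t_final)
    plan = _segment_plan(pulse, t_init, t_final, n_steps)

    # global grid: concatenation of per-segment uniform grids
    grid = [t_init]
    for _, a, b, c in plan:
        h = (b - a) / c
        grid.extend(a + h * (i + 1) for i in range(c))
    grid = np.array(grid)
    grid[-1] = t_final

    if eval_times is None:
        rec = np.arange(grid.size)
    else:
        eval_times = np.asarray(eval_times, dtype=float)
        _check_support(eval_times, t_init, t_final)
        rec = np.searchsorted(grid, eval_times)
        rec = np.clip(rec, 0, grid.size - 1)
        left_ok = rec > 0
        use_left = np.zeros_like(rec, dtype=bool)
        use_left[left_ok] = np.abs(
            grid[rec[left_ok] - 1] - eval_times[left_ok]
        ) < np.abs(grid[rec[left_ok]] - eval_times[left_ok])
        rec[use_left] -= 1
        rec = np.unique(rec)

    rec_list = rec.tolist()
    M = (iso.M.mx, iso.M.my, iso.M.mz)
    states = {0: M} if 0 in rec else {}
    offset = 0
    for p, a, b, c in plan:
        h = (b - a) / c
        local = [r - offset for r in rec_list if 0 < r - offset <= c]
        M, recorded = _rk4_segment(p, iso.omega, M, a, h, c, local)
        for r, st in zip(local, recorded):
            states[r + offset] = st
        offset += c
    out = [states[r] for r in rec_list]
    times = grid[rec]
    return Trajectory(
        times=times,
        M=np.array(out, dtype=float),
        provenance="rk4",
        meta={"omega": iso.omega, "n_steps": n_steps,
              "t_init": t_init, "t_final": t_final},
    )
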