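"""Time-ordered magnetization trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sphere import Magnetization

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Ordered (time, magnetization) samples from one propagator.

    ``times`` is strictly increasing; ``M`` is the matching (n, 3) array.
    ``provenance`` tags the producing solver (``analytic-hs1``,
    ``analytic-chirp``, ``analytic-square``, ``analytic-composite``,
    ``rk4``, ``sit-closed-form``).  ``meta`` carries solver settings and
    diagnostics (e.g. junction jumps for composites).
    """

    times: np.ndarray
    M: np.ndarray
    provenance: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (self.times.size, 3):
            raise ValueError("M must have shape (len(times), 3)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.M[0]))

    def magnetization(self, i: int) -> Magnetization:
        return Magnetization.from_array(self.M[i])

    @property
    def final(self) -> Magnetization:
        return self.magnetization(-1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.times,
                "Mx": self.M[:, 0],
                "My": self.M[:, 1],
                "Mz": self.M[:, 2],
                "Mxy_abs": np.hypot(self.M[:, 0], self.M[:, 1]),
            }
        )
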