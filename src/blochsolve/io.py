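"""Serialization: trajectory CSVs, pulse shape files, JSON parameter
round-trips, and config-driven runs.

Config schema (YAML or JSON)::

    pulse:
      type: hs1 | chirp | square | bir4
      omega1m_hz: 2000.0        # peak amplitude, Hz
      tp_s: 0.005
      truncation: 0.1           # HS1/bir4: fraction, or beta: 2.993
      R: 10.0                   # HS1/bir4/chirp: time-bandwidth, or A_hz
      tc_s: 0.0
      phic_rad: 0.0
      t_start_s: ...            # optional, asymmetric truncation
      t_end_s: ...
    bir4:
      theta_rad: 3.14159        # target flip angle
    isochromat:
      offset_hz: 100.0
      M: [0.0, 0.0, 1.0]        # optional, default equilibrium
    solver:
      method: analytic | rk4 | both
      rk4_steps: 10000
      n_samples: 1000
      precision_dps: 30
    output:
      directory: out
      prefix: run

Frequencies are accepted in Hz (``_hz`` keys) and converted to rad/s
internally; file outputs report both.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .composite import analytic_propagate, compare_trajectories
from .hs1 import DEFAULT_DPS
from .pulses import (
    ChirpPulse,
    CompositePulse,
    HS1Pulse,
    Pulse,
    Segment,
    SquarePulse,
    beta_from_truncation,
    hs1_from_spec,
    make_bir4,
)
from .rk4 import rk4_propagate
from .sphere import Isochromat, Magnetization
from .trajectory import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "export_pulse_shape",
    "pulse_to_dict",
    "pulse_from_dict",
    "load_config",
    "build_pulse",
    "build_isochromat",
    "run_config",
]

logger = logging.getLogger("blochsolve")

TWOPI = 2.0 * math.pi

_COLUMNS = ["t_s", "Mx", "My", "Mz", "Mxy_abs"]


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV (columns t_s, Mx, My, Mz, Mxy_abs)."""
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    df = traj.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path, provenance: str = "file") -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file missing columns {missing}")
    return Trajectory(
        times=df["t_s"].to_numpy(),
        M=df[["Mx", "My", "Mz"]].to_numpy(),
        provenance=provenance,
    )


def export_pulse_shape(pulse: Pulse, n_samples: int, path) -> None:
    """Write a plain-text two-column shape file.

    One row per uniform time sample: normalized amplitude in [0, 1] and
    phase in degrees.  The header line records the peak amplitude (Hz),
    total duration (s) and sample count.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    ts = np.linspace(pulse.t_start, pulse.t_end, n_samples)
    am = np.atleast_1d(pulse.am(ts))
    ph = np.atleast_1d(pulse.phase(ts))
    peak = float(am.max())
    norm = am / peak if peak > 0 else am
    with open(path, "w") as fh:
        fh.write(
            f"# omega1m_hz={peak / TWOPI:.17g} tp_s={pulse.duration:.17g} "
            f"n={n_samples}\n"
        )
        for a, p in zip(norm, np.degrees(ph)):
            fh.write(f"{a:.12f} {p:.12f}\n")


def _dataclass_dict(pulse) -> dict:
    return {k: v for k, v in dataclasses.asdict(pulse).items()}


def pulse_to_dict(pulse: Pulse) -> dict:
    """JSON-serializable dict of all pulse parameters (rad/s units)."""
    if isinstance(pulse, HS1Pulse):
        return {"type": "hs1", **_dataclass_dict(pulse)}
    if isinstance(pulse, ChirpPulse):
        return {"type": "chirp", **_dataclass_dict(pulse)}
    if isinstance(pulse, SquarePulse):
        return {"type": "square", **_dataclass_dict(pulse)}
    if isinstance(pulse, CompositePulse):
        return {
            "type": "composite",
            "segments": [
                {"phase_offset": seg.phase_offset,
                 "pulse": pulse_to_dict(seg.pulse)}
                for seg in pulse.segments
            ],
        }
    raise TypeError(f"cannot serialize pulse type {type(pulse)!r}")


def pulse_from_dict(d: dict) -> Pulse:
    """Inverse of :func:`pulse_to_dict`."""
    d = dict(d)
    kind = d.pop("type")
    if kind == "hs1":
        return HS1Pulse(**d)
    if kind == "chirp":
        return ChirpPulse(**d)
    if kind == "square":
        return SquarePulse(**d)
    if kind == "composite":
        return CompositePulse(
            segments=tuple(
                Segment(pulse_from_dict(s["pulse"]), s["phase_offset"])
                for s in d["segments"]
            )
        )
    raise ValueError(f"unknown pulse type {kind!r}")


def load_config(path) -> dict:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _require(block: dict, keys, where: str):
    missing = [k for k in keys if k not in block]
    if missing:
        raise ValueError(f"config section '{where}' missing keys {missing}")


def build_pulse(cfg: dict) -> Pulse:
    """Construct a pulse from the ``pulse`` (and optional ``bir4``)
    config blocks."""
    p = cfg.get("pulse")
    if not isinstance(p, dict):
        raise ValueError("config missing 'pulse' section")
    kind = p.get("type")
    if kind not in {"hs1", "chirp", "square", "bir4"}:
        raise ValueError(f"pulse.type must be hs1|chirp|square|bir4, got {kind!r}")
    _require(p, ["omega1m_hz"], "pulse")
    w1m = TWOPI * float(p["omega1m_hz"])
    tc = float(p.get("tc_s", 0.0))
    phic = float(p.get("phic_rad", 0.0))
    t_start = p.get("t_start_s")
    t_end = p.get("t_end_s")

    if kind == "square":
        _require(p, ["tp_s"], "pulse")
        Tp = float(p["tp_s"])
        t0 = float(t_start) if t_start is not None else tc - Tp / 2
        t1 = float(t_end) if t_end is not None else tc + Tp / 2
        return SquarePulse(omega1m=w1m, phic=phic, t_start=t0, t_end=t1)

    _require(p, ["tp_s"], "pulse")
    Tp = float(p["tp_s"])

    if kind == "chirp":
        if "A_hz" in p:
            A = TWOPI * float(p["A_hz"])
        elif "R" in p:
            A = math.pi * float(p["R"]) / Tp
        else:
            raise ValueError("chirp pulse needs A_hz or R")
        return ChirpPulse(
            omega1m=w1m, A=A, Tp=Tp, tc=tc, phic=phic,
            t_start=None if t_start is None else float(t_start),
            t_end=None if t_end is None else float(t_end),
        )

    # hs1 or bir4 component
    if "beta" in p:
        beta = float(p["beta"])
    elif "truncation" in p:
        beta = beta_from_truncation(float(p["truncation"]))
    else:
        raise ValueError("HS1 pulse needs truncation or beta")
    if "A_hz" in p:
        A = TWOPI * float(p["A_hz"])
    elif "R" in p:
        A = math.pi * float(p["R"]) / (Tp * math.tanh(beta))
    else:
        raise ValueError("HS1 pulse needs A_hz or R")
    component = HS1Pulse(
        omega1m=w1m, A=A, beta=beta, Tp=Tp, tc=tc, phic=phic,
        t_start=None if t_start is None else float(t_start),
        t_end=None if t_end is None else float(t_end),
    )
    if kind == "hs1":
        return component
    bir4 = cfg.get("bir4", {})
    _require(bir4, ["theta_rad"], "bir4")
    return make_bir4(float(bir4["theta_rad"]), component)


def build_isochromat(cfg: dict) -> Isochromat:
    iso = cfg.get("isochromat", {})
    omega = TWOPI * float(iso.get("offset_hz", 0.0))
    Mvec = iso.get("M", [0.0, 0.0, 1.0])
    return Isochromat(omega, Magnetization.from_array(Mvec))


def run_config(config_path, out_dir: Optional[str] = None) -> dict:
    """Run a simulation described by a config file.

    Writes trajectory CSV(s), a JSON parameter sidecar, and -- when both
    solvers are requested -- a JSON comparison report.  Returns a dict of
    the produced file paths and the comparison summary.  Deterministic
    given the config.
    """
    cfg = load_config(config_path)
    pulse = build_pulse(cfg)
    iso = build_isochromat(cfg)
    solver = cfg.get("solver", {})
    method = solver.get("method", "analytic")
    if method not in {"analytic", "rk4", "both"}:
        raise ValueError(f"solver.method must be analytic|rk4|both, got {method!r}")
    n_samples = int(solver.get("n_samples", 501))
    rk4_steps = int(solver.get("rk4_steps", 10000))
    dps = int(solver.get("precision_dps", DEFAULT_DPS))

    out_block = cfg.get("output", {})
    directory = Path(out_dir or out_block.get("directory", "."))
    directory.mkdir(parents=True, exist_ok=True)
    prefix = out_block.get("prefix", "run")

    eval_times = np.linspace(pulse.t_start, pulse.t_end, n_samples)
    produced = {}
    trajs = {}
    if method in ("analytic", "both"):
        logger.info("analytic solver: dps=%d, %d samples", dps, n_samples)
        trajs["analytic"] = analytic_propagate(pulse, iso, eval_times, dps=dps)
    if method in ("rk4", "both"):
        logger.info("rk4 solver: %d steps", rk4_steps)
        trajs["rk4"] = rk4_propagate(
            pulse, iso, rk4_steps, eval_times=eval_times
        )
    for name, traj in trajs.items():
        path = directory / f"{prefix}_{name}.csv"
        write_trajectory(traj, path)
        produced[name] = str(path)

    sidecar = {
        "pulse": pulse_to_dict(pulse),
        "isochromat": {
            "offset_hz": iso.omega / TWOPI,
            "offset_rad_s": iso.omega,
            "M": list(iso.M.as_array()),
        },
        "solver": {
            "method": method,
            "rk4_steps": rk4_steps,
            "n_samples": n_samples,
            "precision_dps": dps,
        },
    }
    sidecar_path = directory / f"{prefix}_params.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=float))
    produced["params"] = str(sidecar_path)

    result = {"files": produced}
    if method == "both":
        cmp = compare_trajectories(trajs["analytic"], trajs["rk4"])
        report = cmp.summary()
        report_path = directory / f"{prefix}_comparison.json"
        report_path.write_text(json.dumps(report, indent=2))
        produced["comparison"] = str(report_path)
        result["comparison"] = report
        logger.info(
            "analytic vs rk4: mean %.3e, max %.3e, final %.3e rad",
            report["mean"], report["max"], report["final"],
        )
    return result
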