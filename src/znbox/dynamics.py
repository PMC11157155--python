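"""Time-domain simulation of the delta-dynamics.

The delta-linear system ``d(delta)/dt = A delta + b(t)`` spans timescales
from ~0.02 day (plasma) to ~700 days (integument), so explicit stepping is
impractical.  The integrator is an exponential one-step scheme built from
the matrix exponential of ``A dt``: exact for forcing that is constant over
a step (constant and step diets) and second-order for smooth forcing
(sinusoids), evaluated at the step midpoint.  Unconditionally stable at any
``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .model import BoxModel, ModelError, relaxation_times, steady_state

__all__ = [
    "DietForcing",
    "Trajectory",
    "EquilibrationProgress",
    "ForcingResponse",
    "simulate",
    "equilibration_progress",
    "sinusoid_response",
]


@dataclass(frozen=True)
class DietForcing:
    """Prescribed dietary delta66Zn through time.

    Use the constructors :meth:`constant`, :meth:`step`, :meth:`sinusoid`.
    """

    kind: str
    params: dict

    @classmethod
    def constant(cls, delta: float) -> "DietForcing":
        return cls("constant", {"delta": float(delta)})

    @classmethod
    def step(cls, before: float, after: float, switch_day: float = 0.0) -> "DietForcing":
        return cls(
            "step",
            {"before": float(before), "after": float(after), "switch_day": float(switch_day)},
        )

    @classmethod
    def sinusoid(cls, mean: float, amplitude: float, period: float) -> "DietForcing":
        if period <= 0:
            raise ValueError(f"sinusoid period must be > 0, got {period}")
        if amplitude < 0:
            raise ValueError(f"sinusoid amplitude must be >= 0, got {amplitude}")
        return cls(
            "sinusoid",
            {"mean": float(mean), "amplitude": float(amplitude), "period": float(period)},
        )

    def delta_at(self, t: float) -> float:
        p = self.params
        if self.kind == "constant":
            return p["delta"]
        if self.kind == "step":
            return p["after"] if t >= p["switch_day"] else p["before"]
        if self.kind == "sinusoid":
            return p["mean"] + p["amplitude"] * np.sin(2 * np.pi * t / p["period"])
        raise ValueError(f"unknown forcing kind {self.kind!r}")

    @property
    def initial_delta(self) -> float:
        """Diet composition at (just before) t = 0, used for the default start state."""
        if self.kind == "step" and self.params["switch_day"] <= 0:
            return self.params["before"]
        if self.kind == "sinusoid":
            return self.params["mean"]
        return self.delta_at(0.0)


@dataclass
class Trajectory:
    """Simulated delta66Zn time series for every finite box."""

    t: np.ndarray                # days, strictly increasing, starts at 0
    deltas: pd.DataFrame         # one column per finite box
    forcing: DietForcing
    model: BoxModel

    def __getitem__(self, box: str) -> np.ndarray:
        return self.deltas[box].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = self.deltas.copy()
        out.insert(0, "t_days", self.t)
        return out


def simulate(
    model: BoxModel,
    forcing: DietForcing,
    t_end: float,
    dt: float = 0.1,
    initial: dict[str, float] | None = None,
) -> Trajectory:
    """Integrate the delta-dynamics from 0 to ``t_end``.

    The initial state defaults to the steady state of the initial diet
    composition, which makes a step forcing a relaxation experiment from a
    fully equilibrated organism.  Per-box masses are constant throughout.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    A, b_const, b_source, boxes = model.linear_system()
    if initial is None:
        x = np.array([steady_state(model, forcing.initial_delta)[b] for b in boxes])
    else:
        missing = [b for b in boxes if b not in initial]
        if missing:
            raise ModelError(f"initial state missing boxes {missing}")
        x = np.array([initial[b] for b in boxes])

    n_steps = int(np.ceil(t_end / dt - 1e-12))
    t = np.empty(n_steps + 1)
    out = np.empty((n_steps + 1, len(boxes)))
    t[0] = 0.0
    out[0] = x
    E = expm(A * dt)
    # phi = A^-1 (E - I): affine response to forcing held constant over a step
    phi = np.linalg.solve(A, E - np.eye(len(boxes)))
    for k in range(1, n_steps + 1):
        tm = (k - 0.5) * dt  # midpoint forcing: exact for piecewise-constant diets
        b = b_const + b_source * forcing.delta_at(tm)
        x = E @ x + phi @ b
        t[k] = k * dt
        out[k] = x
    return Trajectory(t=t, deltas=pd.DataFrame(out, columns=boxes), forcing=forcing, model=model)


@dataclass
class EquilibrationProgress:
    """Fractional approach (in %) of one box to its post-switch steady state.

    ``progress(t) = 100 (delta(t) - delta(0)) / (delta(inf) - delta(0))``.
    The ratio is signed, so a non-monotone box can transiently exceed 100%.
    """

    box: str
    t: np.ndarray
    progress: np.ndarray

    def time_to(self, percent: float) -> float:
        """First crossing of ``percent``, linearly interpolated between grid points."""
        above = self.progress >= percent
        if not above.any():
            raise ValueError(
                f"{self.box}: progress never reaches {percent}% within the simulated window"
            )
        k = int(np.argmax(above))
        if k == 0:
            return float(self.t[0])
        p0, p1 = self.progress[k - 1], self.progress[k]
        return float(self.t[k - 1] + (percent - p0) / (p1 - p0) * (self.t[k] - self.t[k - 1]))


def equilibration_progress(trajectory: Trajectory, box: str) -> EquilibrationProgress:
    """Equilibration-progress curve of one box after a step diet switch."""
    forcing = trajectory.forcing
    if forcing.kind != "step":
        raise ValueError("equilibration progress is defined for step forcing only")
    model = trajectory.model
    s0 = steady_state(model, forcing.params["before"])[box]
    s1 = steady_state(model, forcing.params["after"])[box]
    if s0 == s1:
        raise ValueError(
            f"progress undefined for {box!r}: initial and final steady states coincide"
        )
    prog = 100.0 * (trajectory[box] - s0) / (s1 - s0)
    return EquilibrationProgress(box=box, t=trajectory.t, progress=prog)


@dataclass(frozen=True)
class ForcingResponse:
    """Response of one box to a periodic dietary forcing.

    ``buffering`` is the proportion of the dietary amplitude lost, in %;
    ``phase_shift`` is the lag (days) of the box's local maximum behind the
    preceding diet maximum, within [0, period).
    """

    compartment: str
    period: float
    buffering: float
    phase_shift: float


def sinusoid_response(
    model: BoxModel,
    box: str,
    period: float,
    amplitude: float = 1.0,
    mean: float = 0.0,
    dt: float = 0.1,
    transient: float | None = None,
) -> ForcingResponse:
    """Buffering and phase shift of one box under a sinusoidal diet.

    The model is simulated from its mean-diet steady state for ``transient``
    days (default 5x the slowest whole-system relaxation time, rounded up to
    a whole number of forcing cycles) plus one full cycle; buffering and
    phase are measured on that last cycle.  By linearity both are
    independent of the forcing amplitude.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0 to measure buffering")
    if transient is None:
        transient = 5.0 * float(relaxation_times(model)[-1])
    n_trans = int(np.ceil(transient / period))
    if n_trans < 1:
        n_trans = 1
    t_end = (n_trans + 1) * period
    forcing = DietForcing.sinusoid(mean=mean, amplitude=amplitude, period=period)
    traj = simulate(model, forcing, t_end=t_end, dt=dt)
    sel = traj.t >= n_trans * period - 1e-9
    t_cycle = traj.t[sel]
    y = traj[box][sel]
    if t_cycle[-1] - t_cycle[0] < period - dt:
        raise ValueError("fewer than one post-transient full cycle available")
    box_amp = 0.5 * (y.max() - y.min())
    buffering = 100.0 * (1.0 - box_amp / amplitude)
    # phase: box local maximum vs the preceding diet local maximum (t = P/4 mod P)
    t_max = t_cycle[int(np.argmax(y))]
    m = np.floor((t_max - period / 4.0) / period)
    t_diet_max = period / 4.0 + m * period
    phase = float(t_max - t_diet_max) % period
    return ForcingResponse(
        compartment=box, period=period, buffering=float(buffering), phase_shift=phase
    )
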