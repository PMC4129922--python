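"""Fixed-step RK4 integration of the model under fixed therapy protocols.

Bolus dosing ("X mg/L every 21 days") is realized as instantaneous jumps in
the drug compartment (chemotherapy) or the CD8 compartment (immunotherapy),
applied at a grid node before the step departing that node.  Stored states
are the pre-bolus (left-limit) values, so ``states[0]`` always equals the
supplied initial state; applied jumps are recorded in ``Trajectory.events``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import NSTATE, STATE_NAMES, _rhs_core, make_initial_state
from .params import ModelParameters

__all__ = [
    "TherapySchedule",
    "Trajectory",
    "IntegrationError",
    "integrate_rk4",
    "run_protocol",
    "REGIMES",
    "CHEMO_BOLUS_DOSE",
    "IMMUNO_BOLUS_DOSE",
    "BOLUS_INTERVAL",
]

#: reference dosing: drug bolus (mg/L), CD8 bolus (cells/L), interval (days)
CHEMO_BOLUS_DOSE = 2.3869
IMMUNO_BOLUS_DOSE = 1.77e10
BOLUS_INTERVAL = 21.0

REGIMES = ("none", "immunotherapy", "chemotherapy", "combined")


class IntegrationError(RuntimeError):
    """Raised when a step produces a non-finite or badly negative state."""


@dataclass(frozen=True)
class TherapySchedule:
    """Discrete bolus times/doses plus optional continuous infusion rates."""

    chemo_boluses: tuple[tuple[float, float], ...] = ()
    immuno_boluses: tuple[tuple[float, float], ...] = ()
    continuous_vE: float = 0.0
    continuous_vM: float = 0.0

    def __post_init__(self) -> None:
        for name in ("chemo_boluses", "immuno_boluses"):
            boluses = tuple((float(t), float(a)) for t, a in getattr(self, name))
            object.__setattr__(self, name, boluses)
            times = [t for t, _ in boluses]
            if any(t < 0 for t in times):
                raise ValueError(f"{name}: bolus times must be >= 0")
            if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(f"{name}: bolus times must be nondecreasing")
            if any(a < 0 for _, a in boluses):
                raise ValueError(f"{name}: doses must be >= 0")
        if self.continuous_vE < 0 or self.continuous_vM < 0:
            raise ValueError("continuous infusion rates must be >= 0")

    @classmethod
    def periodic(
        cls,
        chemo_dose: float = 0.0,
        immuno_dose: float = 0.0,
        interval: float = BOLUS_INTERVAL,
        horizon: float = 100.0,
        start: float = 0.0,
    ) -> "TherapySchedule":
        """Repeat the given doses every `interval` days on [start, horizon)."""
        if interval <= 0:
            raise ValueError("interval must be > 0")
        times = []
        t = start
        while t < horizon:
            times.append(t)
            t += interval
        chemo = tuple((t, chemo_dose) for t in times) if chemo_dose > 0 else ()
        immuno = tuple((t, immuno_dose) for t in times) if immuno_dose > 0 else ()
        return cls(chemo_boluses=chemo, immuno_boluses=immuno)

    def total_chemo(self) -> float:
        return sum(a for _, a in self.chemo_boluses)

    def total_immuno(self) -> float:
        return sum(a for _, a in self.immuno_boluses)


@dataclass
class Trajectory:
    """Uniform time grid and the state at every node (left limits at boluses)."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 11)
    events: list[tuple[float, str, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, NSTATE):
            raise ValueError("states must have shape (len(times), 11)")

    def __len__(self) -> int:
        return self.times.size

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self) > 1 else 0.0

    def component(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write the trajectory with the resolved configuration embedded as
        '#'-prefixed header lines (readable with ``pd.read_csv(comment='#')``)."""
        path = Path(path)
        with path.open("w") as fh:
            if self.meta:
                fh.write("# " + json.dumps(self.meta, sort_keys=True) + "\n")
            self.to_dataframe().to_csv(fh, index=False)


def _bolus_map(
    boluses: Iterable[tuple[float, float]], step: float, n_steps: int, label: str
) -> dict[int, float]:
    out: dict[int, float] = {}
    for t, amount in boluses:
        k = t / step
        idx = int(round(k))
        if abs(k - idx) > 1e-6 * max(1.0, abs(k)):
            raise ValueError(f"{label} bolus at t={t} does not align with the step grid")
        if idx > n_steps:
            raise ValueError(f"{label} bolus at t={t} lies beyond the horizon")
        out[idx] = out.get(idx, 0.0) + amount
    return out


def _rk4_step(y, h, p, uE_a, uE_b, uM_a, uM_b):
    """One classical RK4 step on a tuple state; stage controls are the left
    value, the midpoint average (twice), and the right value."""
    uE_m = 0.5 * (uE_a + uE_b)
    uM_m = 0.5 * (uM_a + uM_b)
    k1 = _rhs_core(y, p, uE_a, uM_a)
    h2 = 0.5 * h
    y2 = tuple(yi + h2 * ki for yi, ki in zip(y, k1))
    k2 = _rhs_core(y2, p, uE_m, uM_m)
    y3 = tuple(yi + h2 * ki for yi, ki in zip(y, k2))
    k3 = _rhs_core(y3, p, uE_m, uM_m)
    y4 = tuple(yi + h * ki for yi, ki in zip(y, k3))
    k4 = _rhs_core(y4, p, uE_b, uM_b)
    h6 = h / 6.0
    return tuple(
        yi + h6 * (a + 2.0 * (b + c) + d_)
        for yi, a, b, c, d_ in zip(y, k1, k2, k3, k4)
    )


def _clamp(y, y_prev, t):
    """Zero out tiny negative components; reject larger negatives."""
    out = []
    for yi, pi in zip(y, y_prev):
        if not math.isfinite(yi):
            raise IntegrationError(f"non-finite state at t={t:.6g}; reduce the step size")
        if yi < 0.0:
            if yi >= -1e-9 * max(1.0, abs(pi)):
                yi = 0.0
            else:
                raise IntegrationError(
                    f"state went negative at t={t:.6g} ({yi:.3g}); reduce the step size"
                )
        out.append(yi)
    return tuple(out)


def integrate_rk4(
    initial: Sequence[float],
    params: ModelParameters,
    schedule: TherapySchedule | None = None,
    controls=None,
    horizon: float = 100.0,
    step: float = 0.01,
    control_interpolation: str = "constant",
) -> Trajectory:
    """Classical fixed-step RK4 integration of the model.

    Parameters
    ----------
    controls : optional object with ``uE``/``uM`` arrays of length
        ``n_steps + 1`` (one value per grid node).  With
        ``control_interpolation='constant'`` each interval uses the left-node
        value at every RK4 stage; with ``'linear'`` the stages use the
        left/midpoint/right values (the convention of the sweep solver).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    n_steps_f = horizon / step
    n_steps = int(round(n_steps_f))
    if n_steps < 1 or abs(n_steps_f - n_steps) > 1e-9 * max(1.0, n_steps_f):
        raise ValueError("horizon must be a positive multiple of step")
    if control_interpolation not in ("constant", "linear"):
        raise ValueError("control_interpolation must be 'constant' or 'linear'")

    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (NSTATE,):
        raise ValueError(f"initial state must have shape ({NSTATE},)")
    if np.any(y0 < 0) or not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be finite and nonnegative")

    schedule = schedule or TherapySchedule()
    p = params.replace(
        vE=params.vE + schedule.continuous_vE,
        vM=params.vM + schedule.continuous_vM,
    )
    chemo = _bolus_map(schedule.chemo_boluses, step, n_steps, "chemo")
    immuno = _bolus_map(schedule.immuno_boluses, step, n_steps, "immuno")

    if controls is not None:
        uE = np.asarray(controls.uE, dtype=float)
        uM = np.asarray(controls.uM, dtype=float)
        if uE.shape != (n_steps + 1,) or uM.shape != (n_steps + 1,):
            raise ValueError("controls must provide one value per grid node")
        if uE.min() < 0 or uE.max() > 1 or uM.min() < 0 or uM.max() > 1:
            raise ValueError("controls must lie in [0, 1]")
    else:
        uE = uM = None

    times = np.arange(n_steps + 1) * step
    states = np.empty((n_steps + 1, NSTATE))
    events: list[tuple[float, str, float]] = []

    y = tuple(float(v) for v in y0)
    for k in range(n_steps + 1):
        states[k] = y
        if k == n_steps:
            break
        t = times[k]
        if k in immuno:
            amt = immuno[k]
            y = y[:2] + (y[2] + amt,) + y[3:]
            events.append((float(t), "ET", amt))
        if k in chemo:
            amt = chemo[k]
            y = y[:10] + (y[10] + amt,)
            events.append((float(t), "M", amt))
        if uE is None:
            ua = ub = 0.0
            va = vb = 0.0
        elif control_interpolation == "constant":
            ua = ub = uE[k]
            va = vb = uM[k]
        else:
            ua, ub = uE[k], uE[k + 1]
            va, vb = uM[k], uM[k + 1]
        y_new = _rk4_step(y, step, p, ua, ub, va, vb)
        y = _clamp(y_new, y, t + step)

    return Trajectory(times=times, states=states, events=events)


def run_protocol(
    regime: str,
    T0: float,
    params: ModelParameters | None = None,
    horizon: float = 100.0,
    step: float = 0.01,
    suppression: bool = True,
    chemo_dose: float = CHEMO_BOLUS_DOSE,
    immuno_dose: float = IMMUNO_BOLUS_DOSE,
    interval: float = BOLUS_INTERVAL,
) -> Trajectory:
    """Integrate one of the reference therapy regimes.

    ``chemotherapy`` administers `chemo_dose` mg/L to the drug compartment and
    ``immunotherapy`` administers `immuno_dose` cells/L to the CD8 compartment,
    each every `interval` days starting at t=0; ``combined`` does both;
    ``none`` applies no therapy.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    params = (params or ModelParameters()).with_suppression(suppression)
    schedule = TherapySchedule.periodic(
        chemo_dose=chemo_dose if regime in ("chemotherapy", "combined") else 0.0,
        immuno_dose=immuno_dose if regime in ("immunotherapy", "combined") else 0.0,
        interval=interval,
        horizon=horizon,
    )
    traj = integrate_rk4(
        make_initial_state(T0, suppression=suppression),
        params,
        schedule=schedule,
        horizon=horizon,
        step=step,
    )
    traj.meta = {
        "regime": regime,
        "T0": T0,
        "horizon": horizon,
        "step": step,
        "suppression": suppression,
        "chemo_dose": chemo_dose if regime in ("chemotherapy", "combined") else 0.0,
        "immuno_dose": immuno_dose if regime in ("immunotherapy", "combined") else 0.0,
        "interval": interval,
        "params": params.to_dict(),
    }
    return traj
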