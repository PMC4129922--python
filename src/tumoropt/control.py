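"""Optimal therapy scheduling via Pontryagin's principle.

The running cost is ``A*T + B*uE^2 + C*uM^2``; the costate system is the
exact negative state-gradient of the Hamiltonian (machine-generated in
``_adjoint.py`` and verified against finite differences in the test suite);
the minimizing controls are the clipped-quadratic characterization

    uE* = clip(-lam3 * omega1 / (2B), 0, 1)
    uM* = clip(-lam11 * omega2 / (2C), 0, 1)

solved by a relaxed forward-backward sweep.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._adjoint import adjoint_rhs_core
from .model import NSTATE, STATE_NAMES, _rhs_core, make_initial_state
from .params import ModelParameters
from .simulate import IntegrationError, Trajectory, _clamp, _rk4_step

__all__ = [
    "CostWeights",
    "ControlGrid",
    "OptimalSolution",
    "cost_functional",
    "hamiltonian",
    "adjoint_rhs",
    "characterize_controls",
    "evaluate_controls",
    "forward_backward_sweep",
    "gradient_check",
]

_LAM3 = STATE_NAMES.index("ET")   # costate paired with the CD8 compartment
_LAM11 = STATE_NAMES.index("M")   # costate paired with the drug compartment


@dataclass(frozen=True)
class CostWeights:
    """Weights of the cost functional and the planning horizon (days)."""

    A: float = 1.0
    B: float = 1.0
    C: float = 1.0
    tf: float = 50.0

    def __post_init__(self) -> None:
        # A == 0 (no tumor penalty) is admitted as a degenerate case: the
        # costate system is then homogeneous and the optimal controls vanish
        if self.A < 0 or self.B <= 0 or self.C <= 0:
            raise ValueError("cost weights require A >= 0 and B, C > 0")
        if self.tf <= 0:
            raise ValueError("horizon tf must be > 0")


@dataclass
class ControlGrid:
    """Pair of bounded control signals sampled on a uniform time grid."""

    times: np.ndarray
    uE: np.ndarray
    uM: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.uE = np.asarray(self.uE, dtype=float)
        self.uM = np.asarray(self.uM, dtype=float)
        if self.uE.shape != self.times.shape or self.uM.shape != self.times.shape:
            raise ValueError("uE and uM must match the time grid")
        for name, u in (("uE", self.uE), ("uM", self.uM)):
            if u.size and (u.min() < 0.0 or u.max() > 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def constant(cls, times: np.ndarray, uE: float = 0.0, uM: float = 0.0) -> "ControlGrid":
        times = np.asarray(times, dtype=float)
        return cls(times, np.full_like(times, float(uE)), np.full_like(times, float(uM)))

    def integrals(self) -> tuple[float, float]:
        """Trapezoidal time-integrals (total 'on-time') of uE and uM."""
        return (
            float(np.trapezoid(self.uE, self.times)),
            float(np.trapezoid(self.uM, self.times)),
        )


@dataclass
class OptimalSolution:
    """Converged (or best-effort) output of the forward-backward sweep."""

    times: np.ndarray
    states: np.ndarray        # (n, 11)
    adjoints: np.ndarray      # (n, 11), adjoints[-1] == 0 (transversality)
    controls: ControlGrid
    weights: CostWeights
    params: ModelParameters
    cost_history: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    control_residual: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def cost(self) -> float:
        return self.cost_history[-1] if self.cost_history else float("nan")

    def trajectory(self) -> Trajectory:
        return Trajectory(times=self.times, states=self.states, meta=dict(self.meta))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        for i in range(NSTATE):
            df[f"lam{i + 1}"] = self.adjoints[:, i]
        df["uE"] = self.controls.uE
        df["uM"] = self.controls.uM
        df.insert(0, "time", self.times)
        return df

    def diagnostics(self) -> dict:
        uE_int, uM_int = self.controls.integrals()
        return {
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "cost": float(self.cost),
            "cost_history": [float(c) for c in self.cost_history],
            "control_residual": float(self.control_residual),
            "uE_integral": uE_int,
            "uM_integral": uM_int,
            "final_tumor": float(self.states[-1, 0]),
            "weights": {"A": self.weights.A, "B": self.weights.B,
                        "C": self.weights.C, "tf": self.weights.tf},
        }

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write per-node states/adjoints/controls; diagnostics and the
        resolved configuration go to a JSON sidecar (default: same stem)."""
        path = Path(path)
        with path.open("w") as fh:
            if self.meta:
                fh.write("# " + json.dumps(self.meta, sort_keys=True) + "\n")
            self.to_dataframe().to_csv(fh, index=False)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
        payload = {"diagnostics": self.diagnostics(), "config": self.meta}
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def cost_functional(traj: Trajectory, controls: ControlGrid, w: CostWeights) -> float:
    """Trapezoidal quadrature of ``A*T + B*uE^2 + C*uM^2`` over the grid."""
    if traj.times.shape != controls.times.shape or not np.allclose(
        traj.times, controls.times, rtol=0.0, atol=1e-9
    ):
        raise ValueError("trajectory and controls must share the time grid")
    integrand = w.A * traj.states[:, 0] + w.B * controls.uE**2 + w.C * controls.uM**2
    return float(np.trapezoid(integrand, traj.times))


def hamiltonian(
    state: Sequence[float],
    adjoint: Sequence[float],
    uE: float,
    uM: float,
    params: ModelParameters,
    w: CostWeights,
) -> float:
    """Running cost plus the costate-weighted model right-hand side."""
    y = tuple(float(v) for v in state)
    lam = tuple(float(v) for v in adjoint)
    f = _rhs_core(y, params, uE, uM)
    return (
        w.A * y[0]
        + w.B * uE * uE
        + w.C * uM * uM
        + math.fsum(l * fi for l, fi in zip(lam, f))
    )


def adjoint_rhs(
    adjoint: Sequence[float],
    state: Sequence[float],
    params: ModelParameters,
    w: CostWeights,
) -> np.ndarray:
    """Costate derivatives ``-dH/dx`` (controls do not enter the gradient)."""
    lam = tuple(float(v) for v in adjoint)
    y = tuple(float(v) for v in state)
    return np.array(adjoint_rhs_core(lam, y, params, w.A))


def characterize_controls(
    adjoint: Sequence[float], params: ModelParameters, w: CostWeights
) -> tuple[float, float]:
    """Pointwise Hamiltonian minimizers projected onto [0, 1]^2."""
    uE = min(1.0, max(0.0, -float(adjoint[_LAM3]) * params.omega1 / (2.0 * w.B)))
    uM = min(1.0, max(0.0, -float(adjoint[_LAM11]) * params.omega2 / (2.0 * w.C)))
    return uE, uM


def _forward(y0, p, uE, uM, h):
    """Forward RK4 with node controls, linear stage interpolation."""
    n = uE.size - 1
    states = np.empty((n + 1, NSTATE))
    y = tuple(float(v) for v in y0)
    states[0] = y
    for k in range(n):
        y_new = _rk4_step(y, h, p, uE[k], uE[k + 1], uM[k], uM[k + 1])
        y = _clamp(y_new, y, (k + 1) * h)
        states[k + 1] = y
    return states


def _backward(states, p, A, h):
    """Backward RK4 of the costate system from the zero terminal condition,
    with linear interpolation of the stored state at RK4 substages."""
    n = states.shape[0] - 1
    lams = np.empty((n + 1, NSTATE))
    lam = (0.0,) * NSTATE
    lams[n] = lam
    h2, h6 = 0.5 * h, h / 6.0
    for k in range(n, 0, -1):
        y1 = tuple(states[k])
        y0 = tuple(states[k - 1])
        ym = tuple(0.5 * (a + b) for a, b in zip(y0, y1))
        g1 = adjoint_rhs_core(lam, y1, p, A)
        g2 = adjoint_rhs_core(tuple(l - h2 * g for l, g in zip(lam, g1)), ym, p, A)
        g3 = adjoint_rhs_core(tuple(l - h2 * g for l, g in zip(lam, g2)), ym, p, A)
        g4 = adjoint_rhs_core(tuple(l - h * g for l, g in zip(lam, g3)), y0, p, A)
        lam = tuple(
            l - h6 * (a + 2.0 * (b + c) + d_)
            for l, a, b, c, d_ in zip(lam, g1, g2, g3, g4)
        )
        lams[k - 1] = lam
    return lams


def _characterized(lams, p, w):
    uE = np.clip(-lams[:, _LAM3] * p.omega1 / (2.0 * w.B), 0.0, 1.0)
    uM = np.clip(-lams[:, _LAM11] * p.omega2 / (2.0 * w.C), 0.0, 1.0)
    return uE, uM


def _rel_change(new: np.ndarray, old: np.ndarray) -> float:
    scale = max(float(np.max(np.abs(new))), 1e-12)
    return float(np.max(np.abs(new - old))) / scale


def evaluate_controls(
    y0: Sequence[float],
    params: ModelParameters,
    w: CostWeights,
    controls: ControlGrid,
    step: float | None = None,
) -> OptimalSolution:
    """Single forward + backward evaluation of a given control pair (no
    iteration): states, consistent costates, cost, and the fixed-point
    residual of the characterization."""
    times = controls.times
    h = step if step is not None else float(times[1] - times[0])
    states = _forward(y0, params, controls.uE, controls.uM, h)
    lams = _backward(states, params, w.A, h)
    uE_star, uM_star = _characterized(lams, params, w)
    residual = max(
        float(np.max(np.abs(controls.uE - uE_star))),
        float(np.max(np.abs(controls.uM - uM_star))),
    )
    traj = Trajectory(times=times, states=states)
    cost = cost_functional(traj, controls, w)
    return OptimalSolution(
        times=times,
        states=states,
        adjoints=lams,
        controls=controls,
        weights=w,
        params=params,
        cost_history=[cost],
        iterations=0,
        converged=False,
        control_residual=residual,
    )


def forward_backward_sweep(
    T0: float,
    params: ModelParameters | None = None,
    weights: CostWeights = CostWeights(),
    suppression: bool = True,
    step: float = 0.01,
    relaxation: float = 0.5,
    tol: float = 1e-3,
    max_iter: int = 50,
    u_init: tuple[float, float] = (0.0, 0.0),
) -> OptimalSolution:
    """Relaxed forward-backward sweep for the two-control problem.

    Each iteration integrates the state system forward with the current
    controls, the costate system backward from the zero terminal condition,
    forms the clipped-quadratic characterized controls, and relaxes:
    ``u <- relaxation * u_star + (1 - relaxation) * u``.  Convergence requires
    the max relative change of controls, states, and costates each to fall
    below `tol`.  Non-convergence is reported via ``converged=False``, not an
    exception.

    Continuous infusions are zeroed here: in the optimal-control problem all
    therapy enters through ``omega1*uE`` and ``omega2*uM``.
    """
    if not 0.0 < relaxation <= 1.0:
        raise ValueError("relaxation must lie in (0, 1]")
    if step <= 0 or tol <= 0 or max_iter < 1:
        raise ValueError("need step > 0, tol > 0, max_iter >= 1")
    p = (params or ModelParameters()).with_suppression(suppression).replace(vE=0.0, vM=0.0)
    n_f = weights.tf / step
    n = int(round(n_f))
    if n < 1 or abs(n_f - n) > 1e-9 * max(1.0, n_f):
        raise ValueError("tf must be a positive multiple of step")
    times = np.arange(n + 1) * step
    y0 = make_initial_state(T0, suppression=suppression)

    uE = np.full(n + 1, float(u_init[0]))
    uM = np.full(n + 1, float(u_init[1]))
    states = lams = None
    cost_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            states_new = _forward(y0, p, uE, uM, step)
            lams_new = _backward(states_new, p, weights.A, step)
        except IntegrationError as err:
            raise IntegrationError(f"sweep iteration {it}: {err}") from err
        if not (np.all(np.isfinite(states_new)) and np.all(np.isfinite(lams_new))):
            raise IntegrationError(f"sweep iteration {it}: non-finite iterate")
        uE_star, uM_star = _characterized(lams_new, p, weights)
        uE_new = relaxation * uE_star + (1.0 - relaxation) * uE
        uM_new = relaxation * uM_star + (1.0 - relaxation) * uM

        cost_history.append(
            cost_functional(
                Trajectory(times=times, states=states_new),
                ControlGrid(times, uE, uM),
                weights,
            )
        )
        if states is not None:
            delta = max(
                _rel_change(uE_new, uE),
                _rel_change(uM_new, uM),
                _rel_change(states_new, states),
                _rel_change(lams_new, lams),
            )
        else:
            delta = math.inf
        # the A -> 0 / lam == 0 fixed point converges in one pass
        if np.array_equal(uE_new, uE) and np.array_equal(uM_new, uM):
            delta = 0.0
        states, lams = states_new, lams_new
        uE, uM = uE_new, uM_new
        if delta < tol:
            converged = True
            break

    # final consistent pass with the converged controls
    states = _forward(y0, p, uE, uM, step)
    lams = _backward(states, p, weights.A, step)
    uE_star, uM_star = _characterized(lams, p, weights)
    residual = max(
        float(np.max(np.abs(uE - uE_star))), float(np.max(np.abs(uM - uM_star)))
    )
    controls = ControlGrid(times, uE, uM)
    cost_history.append(
        cost_functional(Trajectory(times=times, states=states), controls, weights)
    )
    return OptimalSolution(
        times=times,
        states=states,
        adjoints=lams,
        controls=controls,
        weights=weights,
        params=p,
        cost_history=cost_history,
        iterations=it,
        converged=converged,
        control_residual=residual,
        meta={
            "T0": T0,
            "suppression": suppression,
            "step": step,
            "relaxation": relaxation,
            "tol": tol,
            "max_iter": max_iter,
            "weights": {"A": weights.A, "B": weights.B, "C": weights.C, "tf": weights.tf},
            "params": p.to_dict(),
        },
    )


def _bump(n: int, center: int, halfwidth: int) -> np.ndarray:
    """Triangular bump on the node grid, peak 1 at `center`."""
    x = np.arange(n, dtype=float)
    return np.clip(1.0 - np.abs(x - center) / halfwidth, 0.0, None)


def gradient_check(
    solution: OptimalSolution,
    params: ModelParameters | None = None,
    w: CostWeights | None = None,
    perturbation: float = 1e-3,
) -> float:
    """Worst relative discrepancy between the costate-based cost gradient and
    a central finite difference of the cost under a localized control bump.

    The costate-based first variation is ``int (2B*uE + lam3*omega1) duE dt``
    for the immunotherapy channel and the analogous expression with
    ``(2C*uM + lam11*omega2)`` for chemotherapy.  Returns 0 for a zero
    perturbation size.
    """
    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    if perturbation == 0.0:
        return 0.0
    params = params if params is not None else solution.params
    w = w if w is not None else solution.weights
    times = solution.times
    h = float(times[1] - times[0])
    n = times.size
    bump = _bump(n, n // 2, max(2, n // 10))
    y0 = solution.states[0]

    grads = {
        "uE": 2.0 * w.B * solution.controls.uE + solution.adjoints[:, _LAM3] * params.omega1,
        "uM": 2.0 * w.C * solution.controls.uM + solution.adjoints[:, _LAM11] * params.omega2,
    }
    worst = 0.0
    for channel in ("uE", "uM"):
        uE = solution.controls.uE.copy()
        uM = solution.controls.uM.copy()
        base = uE if channel == "uE" else uM
        up = np.clip(base + perturbation * bump, 0.0, 1.0)
        dn = np.clip(base - perturbation * bump, 0.0, 1.0)
        du = 0.5 * (up - dn)
        if not np.any(du):
            continue

        def run(u):
            kw = {channel: u}
            cE = kw.get("uE", uE)
            cM = kw.get("uM", uM)
            states = _forward(y0, params, cE, cM, h)
            return cost_functional(
                Trajectory(times=times, states=states), ControlGrid(times, cE, cM), w
            )

        fd = 0.5 * (run(up) - run(dn))
        lin = float(np.trapezoid(grads[channel] * du, times))
        denom = max(abs(fd), abs(lin))
        if denom > 0:
            worst = max(worst, abs(fd - lin) / denom)
    return worst
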