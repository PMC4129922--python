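"""One-at-a-time local parameter sensitivity.

Each parameter is scaled by a factor (default +-20%) while all others stay
fixed; the readout is the percent change of the tumor burden after a short
therapy-free simulation (default 5 days).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import make_initial_state
from .params import PARAM_NAMES, ModelParameters
from .simulate import integrate_rk4

__all__ = [
    "SensitivityResult",
    "DEFAULT_SWEEP_PARAMS",
    "perturb_and_simulate",
    "sweep",
    "rank_parameters",
    "results_to_csv",
]

#: therapy settings are excluded from the sweep — they are not model biology
_EXCLUDED = ("omega1", "omega2", "vE", "vM")
DEFAULT_SWEEP_PARAMS: tuple[str, ...] = tuple(n for n in PARAM_NAMES if n not in _EXCLUDED)


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    factor: float                 # 1.2 for +20%, 0.8 for -20%
    baseline: float               # tumor burden at the readout day (cells/L)
    perturbed: float
    percent_change: float

    @property
    def direction(self) -> str:
        return f"{100.0 * (self.factor - 1.0):+.0f}%"


def _tumor_at(params: ModelParameters, T0: float, suppression: bool, days: float, step: float) -> float:
    traj = integrate_rk4(
        make_initial_state(T0, suppression=suppression),
        params.with_suppression(suppression),
        horizon=days,
        step=step,
    )
    return float(traj.states[-1, 0])


def perturb_and_simulate(
    name: str,
    factor: float,
    T0: float = 1e7,
    params: ModelParameters | None = None,
    suppression: bool = True,
    days: float = 5.0,
    step: float = 0.01,
    baseline: float | None = None,
) -> SensitivityResult:
    """Percent change of the day-`days` tumor burden when `name` is scaled by
    `factor` (no therapy).  `baseline` may be passed to reuse a precomputed
    unperturbed run."""
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}")
    params = params or ModelParameters()
    if baseline is None:
        baseline = _tumor_at(params, T0, suppression, days, step)
    if baseline <= 0:
        raise ValueError("baseline tumor burden must be positive at the readout day")
    perturbed_params = params.replace(**{name: getattr(params, name) * factor})
    perturbed = _tumor_at(perturbed_params, T0, suppression, days, step)
    return SensitivityResult(
        parameter=name,
        factor=factor,
        baseline=baseline,
        perturbed=perturbed,
        percent_change=100.0 * (perturbed - baseline) / baseline,
    )


def sweep(
    params: ModelParameters | None = None,
    T0: float = 1e7,
    suppression: bool = True,
    days: float = 5.0,
    step: float = 0.01,
    factors: Sequence[float] = (0.8, 1.2),
    parameters: Sequence[str] | None = None,
) -> list[SensitivityResult]:
    """Run the full one-at-a-time sweep (both directions per parameter)."""
    params = params or ModelParameters()
    names = tuple(parameters) if parameters is not None else DEFAULT_SWEEP_PARAMS
    baseline = _tumor_at(params, T0, suppression, days, step)
    return [
        perturb_and_simulate(
            name, factor, T0=T0, params=params, suppression=suppression,
            days=days, step=step, baseline=baseline,
        )
        for name in names
        for factor in factors
    ]


def rank_parameters(results: Iterable[SensitivityResult]) -> list[str]:
    """Parameters ordered by the largest absolute percent change over the
    available directions, ties broken alphabetically."""
    score: dict[str, float] = {}
    for r in results:
        score[r.parameter] = max(score.get(r.parameter, 0.0), abs(r.percent_change))
    if not score:
        raise ValueError("no sensitivity results to rank")
    return sorted(score, key=lambda k: (-score[k], k))


def results_to_csv(
    results: Sequence[SensitivityResult], path: str | Path, meta: dict | None = None
) -> None:
    df = pd.DataFrame(
        {
            "parameter": [r.parameter for r in results],
            "direction": [r.direction for r in results],
            "factor": [r.factor for r in results],
            "baseline": [r.baseline for r in results],
            "perturbed": [r.perturbed for r in results],
            "percent_change": [r.percent_change for r in results],
        }
    )
    path = Path(path)
    with path.open("w") as fh:
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)
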