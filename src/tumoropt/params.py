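"""Model parameter set, validation, and config-file (de)serialization.

All rate constants are per day; saturation constants carry the units of the
quantity they saturate (cells/L or IU/L).  Field names follow the ASCII form
of the conventional symbols (``alpha1``, ``gamma2``, ``dN``, ...).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ModelParameters",
    "PARAM_NAMES",
    "SUPPRESSION_PARAMS",
    "load_parameters",
    "save_parameters",
]

#: parameters zeroed when immunosuppression is switched off
SUPPRESSION_PARAMS = ("alpha3", "gamma2", "p1", "p2", "p3", "p4")

#: saturation / denominator constants that must be strictly positive
_POSITIVE = (
    "b", "e", "g1", "s1", "s2", "s3", "s4", "qN",
    "i1", "i2", "i3", "d1", "mE", "mG", "mH", "g2",
)


@dataclass(frozen=True)
class ModelParameters:
    """Rate and saturation constants of the 11-compartment model.

    Defaults are the published reference values.  ``vE``/``vM`` are optional
    continuous infusion rates (cells/L/day, mg/L/day) and default to zero —
    discrete bolus dosing is handled by therapy schedules, and the optimal
    control problem drives therapy exclusively through the weighted controls
    ``omega1*uE`` and ``omega2*uM``.

    The kill-term suppression constant ``s1`` is not given a value in the
    source tables; by default it shares the TGF-beta half-saturation ``s2``
    used for proliferation suppression.  Override it via config if needed.
    """

    # tumor
    a: float = 0.431            # logistic growth rate (1/day)
    b: float = 1.02e-9          # inverse carrying capacity (1/cells)
    c1: float = 3.177e-13       # NK-induced tumor death (1/cells/day)
    d: float = 0.9              # CD8-induced tumor death (1/day)
    e: float = 1.2              # kill-term saturation (dimensionless)
    g1: float = 1.2             # Treg suppression of killing (dimensionless)
    s1: float = 580000.0        # TGF-beta suppression of killing (IU/L)
    kT: float = 0.9             # chemo-induced tumor death (1/day)
    # NK cells
    b1: float = 3121875.0       # constant NK production (cells/L/day)
    dN: float = 0.0125          # NK turnover (1/day)
    c2: float = 3.177e-13       # NK exhaustion by tumor (1/cells/day)
    pN: float = 0.0668          # IL-2 stimulation of NK (1/day)
    qN: float = 250360.0        # IL-2 half-saturation for NK (IU/L)
    kN: float = 0.6             # chemo-induced NK death (1/day)
    # CD8+ T cells
    alpha1: float = 16.0        # activation rate (1/day)
    s2: float = 580000.0        # TGF-beta half-saturation (IU/L)
    i1: float = 4909.0          # IL-2 half-saturation (IU/L)
    d1: float = 579579.0        # licensed-DC half-saturation (cells/L)
    mE: float = 526800.0        # CD8 memory pool (cells/L)
    c3: float = 3.42e-10        # CD8 exhaustion by tumor (1/cells/day)
    kET: float = 0.6            # chemo-induced CD8 death (1/day)
    # unlicensed dendritic cells
    p: float = 0.1              # tumor-driven DC recruitment (1/day)
    i2: float = 1200.0          # IL-10 suppression constant (IU/L)
    g2: float = 2.0e7           # Treg suppression constant (cells/L)
    gamma1: float = 0.5         # licensing rate (1/day)
    mH: float = 1053600.0       # CD4 pool / licensing saturation (cells/L)
    dDU: float = 0.14           # unlicensed DC turnover (1/day)
    kDU: float = 0.05           # chemo-induced DC death (1/day)
    # licensed dendritic cells
    dDL: float = 0.5            # licensed DC turnover (1/day)
    # CD4+ T cells
    alpha2: float = 1.9         # activation rate (1/day)
    gamma2: float = 0.022       # TGF-beta-driven conversion to Treg (1/day)
    s3: float = 34000.0         # conversion half-saturation (IU/L)
    dHT: float = 0.1            # CD4 turnover (1/day)
    kHT: float = 0.6            # chemo-induced CD4 death (1/day)
    # regulatory T cells
    alpha3: float = 3.6         # activation rate (1/day)
    mG: float = 175900.0        # Treg memory pool (cells/L)
    dGT: float = 0.1            # Treg turnover (1/day)
    kGT: float = 0.6            # chemo-induced Treg death (1/day)
    # TGF-beta
    p1: float = 3.6e-4          # production by Treg (IU/L/cells/day)
    p2: float = 2.2e-3          # production by tumor (IU/L/cells/day)
    dS: float = 14.3            # turnover (1/day)
    # IL-2
    alpha4: float = 0.278       # production by CD4 (IU/L/cells/day)
    i3: float = 2250.0          # IL-10 suppression constant (IU/L)
    s4: float = 18000.0         # TGF-beta suppression constant (IU/L)
    dI2: float = 12.5           # turnover (1/day)
    # IL-10
    p3: float = 4.2e-5          # production by Treg (IU/L/cells/day)
    p4: float = 3.9e-7          # production by tumor (IU/L/cells/day)
    dI10: float = 20.0          # turnover (1/day)
    # chemotherapy drug
    dM: float = 0.9             # elimination (1/day)
    # therapy plumbing
    vE: float = 0.0             # continuous CD8 infusion (cells/L/day)
    vM: float = 0.0             # continuous drug infusion (mg/L/day)
    omega1: float = 3.5e6       # immunotherapy control weight (cells/L/day)
    omega2: float = 0.5         # chemotherapy control weight (mg/L/day)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                raise TypeError(f"parameter {f.name!r} must be numeric, got {type(v).__name__}")
            object.__setattr__(self, f.name, float(v))
            if v < 0:
                raise ValueError(f"parameter {f.name!r} must be >= 0, got {v}")
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be > 0")

    def replace(self, **kwargs: float) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def without_suppression(self) -> "ModelParameters":
        """Copy with the immunosuppressive pathways switched off."""
        return self.replace(**{name: 0.0 for name in SUPPRESSION_PARAMS})

    def with_suppression(self, enabled: bool) -> "ModelParameters":
        return self if enabled else self.without_suppression()

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ModelParameters":
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(data))

    def as_tuple(self) -> tuple[float, ...]:
        """Values in declaration order (the layout the fast kernels use)."""
        return tuple(getattr(self, name) for name in PARAM_NAMES)


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ModelParameters))


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a flat key->value YAML or JSON parameter file.

    Missing keys fall back to the defaults; unknown keys are an error.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a flat mapping of parameter values")
    return ModelParameters.from_dict(data)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
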