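"""State layout, model right-hand side, initial conditions, and unit helpers.

The state vector has a fixed ordering shared with the costate vector of the
optimal-control machinery::

    (T, N, ET, DU, DL, HT, GT, S, I2, I10, M)

T        tumor cells (cells/L)
N        NK cells (cells/L)
ET       CD8+ T cells (cells/L)
DU, DL   unlicensed / licensed dendritic cells (cells/L)
HT       CD4+ T cells (cells/L)
GT       regulatory T cells (cells/L)
S        TGF-beta (IU/L)
I2       IL-2 (IU/L)
I10      IL-10 (IU/L)
M        chemotherapy drug concentration (mg/L)
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .params import ModelParameters

__all__ = [
    "STATE_NAMES",
    "NSTATE",
    "rhs",
    "tumor_kill_term",
    "make_initial_state",
    "derive_tcell_initials",
    "derive_dendritic_initial",
    "ng_per_ml_to_iu_per_l",
    "control_weight_from_budget",
]

STATE_NAMES: tuple[str, ...] = ("T", "N", "ET", "DU", "DL", "HT", "GT", "S", "I2", "I10", "M")
NSTATE = len(STATE_NAMES)

# index constants
T, N, ET, DU, DL, HT, GT, S, I2, I10, M = range(NSTATE)

# reference initial values (all but the tumor burden, which is scenario input)
_N0 = 2.5e8
_ET0 = 5.268e5
_DU0 = 4.725e7
_DL0 = 10.0
_HT0 = 1.0536e6
_GT0 = 1.795e5
_I20 = 1173.0


def tumor_kill_term(T_: float, ET_: float, GT_: float, S_: float, params: ModelParameters) -> float:
    """CD8-mediated tumor kill rate, damped by Treg and TGF-beta (cells/L/day).

    ``d*T*ET/(ET + e*T) * 1/((1 + g1*GT/ET)*(1 + S/s1))``, with the removable
    ET -> 0 singularity closed by continuity: the term is 0 when ET or T is 0.
    """
    if ET_ == 0.0 or T_ == 0.0:
        return 0.0
    # equivalent smooth form d*T*ET^2 / ((ET + e*T)(ET + g1*GT)(1 + S/s1)),
    # evaluated factor-by-factor so extreme inputs cannot underflow the
    # denominator product to zero
    return (
        (params.d * T_ / (ET_ + params.e * T_))
        * (ET_ / (ET_ + params.g1 * GT_))
        * ET_
        / (1.0 + S_ / params.s1)
    )


def _rhs_core(y: Sequence[float], p: ModelParameters, uE: float, uM: float) -> tuple[float, ...]:
    """Unvalidated right-hand side; y is any length-11 sequence of floats."""
    T_, N_, ET_, DU_, DL_, HT_, GT_, S_, I2_, I10_, M_ = y

    chemo = 1.0 - math.exp(-M_)           # chemotherapy kill fraction
    kill = tumor_kill_term(T_, ET_, GT_, S_, p)
    il2_sat = I2_ / (p.i1 + I2_) if I2_ > 0.0 else 0.0
    tgfb_sup = 1.0 + S_ / p.s2

    dT = p.a * T_ * (1.0 - p.b * T_) - p.c1 * T_ * N_ - kill - p.kT * chemo * T_
    dN = p.b1 - p.dN * N_ - p.c2 * T_ * N_ + p.pN * N_ * I2_ / (p.qN + I2_) - p.kN * chemo * N_
    dET = (
        p.alpha1 * p.mE * il2_sat * DL_ / (tgfb_sup * (p.d1 + DL_))
        - p.c3 * ET_ * T_
        - p.kET * chemo * ET_
        + p.vE
        + p.omega1 * uE
    )
    licensing = p.gamma1 * DU_ / (1.0 + DU_ / p.mH)
    dDU = (
        p.p * T_ / ((1.0 + I10_ / p.i2) * (1.0 + GT_ / p.g2))
        - licensing
        - p.dDU * DU_
        - p.kDU * chemo * DU_
    )
    dDL = licensing - p.dDL * DL_
    dHT = (
        p.alpha2 * p.mH * il2_sat * (DL_ + DU_) / (tgfb_sup * (p.d1 + DL_ + DU_))
        - p.gamma2 * HT_ * S_ / (p.s3 + S_)
        - p.dHT * HT_
        - p.kHT * chemo * HT_
    )
    dGT = (
        p.gamma2 * HT_ * S_ / (p.s3 + S_)
        + p.alpha3 * p.mG * il2_sat * DL_ / (p.d1 + DL_)
        - p.dGT * GT_
        - p.kGT * chemo * GT_
    )
    dS = p.p1 * GT_ + p.p2 * T_ - p.dS * S_
    dI2 = p.alpha4 * HT_ / ((1.0 + I10_ / p.i3) * (1.0 + S_ / p.s4)) - p.dI2 * I2_
    dI10 = p.p3 * GT_ + p.p4 * T_ - p.dI10 * I10_
    dM = -p.dM * M_ + p.vM + p.omega2 * uM

    return (dT, dN, dET, dDU, dDL, dHT, dGT, dS, dI2, dI10, dM)


def rhs(
    state: Sequence[float],
    params: ModelParameters,
    uE: float = 0.0,
    uM: float = 0.0,
) -> np.ndarray:
    """Time derivative of the 11 compartments (per day).

    Parameters
    ----------
    state : length-11 array-like, componentwise nonnegative and finite.
    params : ModelParameters
    uE, uM : control signals in [0, 1]; therapy enters as ``omega1*uE`` in
        the CD8 equation and ``omega2*uM`` in the drug equation, on top of
        any continuous infusions ``vE``/``vM`` in `params`.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (NSTATE,):
        raise ValueError(f"state must have shape ({NSTATE},), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    if np.any(y < 0):
        raise ValueError("state components must be >= 0")
    if not (0.0 <= uE <= 1.0 and 0.0 <= uM <= 1.0):
        raise ValueError("controls must lie in [0, 1]")
    return np.array(_rhs_core(tuple(y), params, uE, uM))


def derive_tcell_initials(E0: float) -> tuple[float, float]:
    """CD4 and Treg initial counts from a CD8 count via the 3:6:1 ratio."""
    if E0 < 0:
        raise ValueError("E0 must be >= 0")
    return 2.0 * E0, E0 / 3.0


def derive_dendritic_initial(
    normal_count: float = 2.8e7,
    patient_per_ml: float = 108.0,
    control_per_ml: float = 64.0,
) -> float:
    """Scale a normal-volunteer dendritic count (cells/L) by the patient-to-
    control circulating-count ratio (cells/mL)."""
    if normal_count < 0 or patient_per_ml < 0 or control_per_ml <= 0:
        raise ValueError("counts must be nonnegative with a positive control count")
    return normal_count * (patient_per_ml / control_per_ml)


def make_initial_state(T0: float, suppression: bool = True) -> np.ndarray:
    """Reference initial state with tumor burden ``T0``.

    With ``suppression=False`` the suppressive compartments (GT, S, I10)
    start at zero, matching the suppression-off model configuration.

    Note the published Treg initial 1.795e5 differs slightly from the ratio
    arithmetic 5.268e5/3 = 1.756e5; the published value is used.
    """
    if T0 < 0:
        raise ValueError("T0 must be >= 0")
    y = np.zeros(NSTATE)
    y[T] = T0
    y[N] = _N0
    y[ET] = _ET0
    y[DU] = _DU0
    y[DL] = _DL0
    y[HT] = _HT0
    y[I2] = _I20
    if suppression:
        y[GT] = _GT0
        # S and I10 start at zero in both configurations
    return y


def ng_per_ml_to_iu_per_l(conc: float, specific_activity: float) -> float:
    """Convert a cytokine concentration in ng/mL to IU/L.

    ``conc [ng/mL] * 1e-6 [mg/ng] * 1000 [mL/L] * specific_activity [IU/mg]``
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if specific_activity <= 0:
        raise ValueError("specific activity must be > 0")
    return conc * 1e-6 * 1000.0 * specific_activity


def control_weight_from_budget(total: float, days: float) -> float:
    """Control weight factor from a total therapy budget spread over a period
    (e.g. 1.75e8 cells over 50 days -> 3.5e6 cells/day)."""
    if total < 0 or days <= 0:
        raise ValueError("need total >= 0 and days > 0")
    return total / days
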