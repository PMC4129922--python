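"""Regenerate src/tumoropt/_adjoint.py.

Derives the costate right-hand side as the exact negative state-gradient of
the Hamiltonian built from the implemented model dynamics, applies common
subexpression elimination, and emits plain-Python source.  Run from the repo
root:

    python tools/gen_adjoint.py
"""

from __future__ import annotations

from pathlib import Path

import sympy as sp
from sympy.printing.pycode import pycode

OUT = Path(__file__).resolve().parents[1] / "src" / "tumoropt" / "_adjoint.py"

STATE = sp.symbols("T_ N_ ET_ DU_ DL_ HT_ GT_ S_ I2_ I10_ M_", positive=False)
T_, N_, ET_, DU_, DL_, HT_, GT_, S_, I2_, I10_, M_ = STATE
LAM = sp.symbols("l1:12")
A = sp.Symbol("A")

PNAMES = [
    "a", "b", "c1", "d", "e", "g1", "s1", "kT",
    "b1", "dN", "c2", "pN", "qN", "kN",
    "alpha1", "s2", "i1", "d1", "mE", "c3", "kET",
    "p", "i2", "g2", "gamma1", "mH", "dDU", "kDU", "dDL",
    "alpha2", "gamma2", "s3", "dHT", "kHT",
    "alpha3", "mG", "dGT", "kGT",
    "p1", "p2", "dS", "alpha4", "i3", "s4", "dI2",
    "p3", "p4", "dI10", "dM",
]
P = {n: sp.Symbol(n) for n in PNAMES}
g = P  # shorthand


def dynamics():
    """Model RHS split into (kill-free part, CD8 kill term).

    Must mirror tumoropt.model._rhs_core exactly (control and infusion terms
    are state-independent and therefore omitted: they vanish in the gradient).
    """
    chemo = 1 - sp.exp(-M_)
    il2_sat = I2_ / (g["i1"] + I2_)
    tgfb_sup = 1 + S_ / g["s2"]
    kill = g["d"] * T_ * ET_**2 / ((ET_ + g["e"] * T_) * (ET_ + g["g1"] * GT_) * (1 + S_ / g["s1"]))
    licensing = g["gamma1"] * DU_ / (1 + DU_ / g["mH"])

    f = [
        g["a"] * T_ * (1 - g["b"] * T_) - g["c1"] * T_ * N_ - g["kT"] * chemo * T_,  # - kill
        g["b1"] - g["dN"] * N_ - g["c2"] * T_ * N_
        + g["pN"] * N_ * I2_ / (g["qN"] + I2_) - g["kN"] * chemo * N_,
        g["alpha1"] * g["mE"] * il2_sat * DL_ / (tgfb_sup * (g["d1"] + DL_))
        - g["c3"] * ET_ * T_ - g["kET"] * chemo * ET_,
        g["p"] * T_ / ((1 + I10_ / g["i2"]) * (1 + GT_ / g["g2"]))
        - licensing - g["dDU"] * DU_ - g["kDU"] * chemo * DU_,
        licensing - g["dDL"] * DL_,
        g["alpha2"] * g["mH"] * il2_sat * (DL_ + DU_) / (tgfb_sup * (g["d1"] + DL_ + DU_))
        - g["gamma2"] * HT_ * S_ / (g["s3"] + S_) - g["dHT"] * HT_ - g["kHT"] * chemo * HT_,
        g["gamma2"] * HT_ * S_ / (g["s3"] + S_)
        + g["alpha3"] * g["mG"] * il2_sat * DL_ / (g["d1"] + DL_)
        - g["dGT"] * GT_ - g["kGT"] * chemo * GT_,
        g["p1"] * GT_ + g["p2"] * T_ - g["dS"] * S_,
        g["alpha4"] * HT_ / ((1 + I10_ / g["i3"]) * (1 + S_ / g["s4"])) - g["dI2"] * I2_,
        g["p3"] * GT_ + g["p4"] * T_ - g["dI10"] * I10_,
        -g["dM"] * M_,
    ]
    return f, kill


def emit() -> str:
    f, kill = dynamics()
    H_rest = A * T_ + sum(l * fi for l, fi in zip(LAM, f))
    lamdot_rest = [sp.together(-sp.diff(H_rest, x)) for x in STATE]
    kill_grad = {x: sp.together(sp.diff(kill, x)) for x in (T_, ET_, GT_, S_)}

    reps, exprs = sp.cse(lamdot_rest, symbols=sp.numbered_symbols("c"))
    kreps, kexprs = sp.cse(
        [kill_grad[T_], kill_grad[ET_], kill_grad[GT_], kill_grad[S_]],
        symbols=sp.numbered_symbols("q"),
    )

    lines = []
    w = lines.append
    w('"""Costate right-hand side, generated by tools/gen_adjoint.py -- do not edit.')
    w("")
    w("lam' = -dH/dx for the Hamiltonian H = A*T + B*uE^2 + C*uM^2 + lam . f(x, u),")
    w("where f is the model right-hand side implemented in tumoropt.model.")
    w("Control-dependent terms are state-independent and drop out of the gradient.")
    w('"""')
    w("")
    w("import math")
    w("")
    w("")
    w("def adjoint_rhs_core(lam, y, params, A):")
    w('    """Return the 11 costate derivatives as a tuple of floats.')
    w("")
    w("    The CD8 kill-term contribution follows the same limit convention as")
    w("    the model RHS: it is treated as identically 0 when ET == 0 or T == 0,")
    w("    so its gradient rows are dropped there.")
    w('    """')
    w("    T_, N_, ET_, DU_, DL_, HT_, GT_, S_, I2_, I10_, M_ = y")
    w("    l1, l2, l3, l4, l5, l6, l7, l8, l9, l10, l11 = lam")
    for n in PNAMES:
        w(f"    {n} = params.{n}")
    w("")
    for sym, expr in reps:
        w(f"    {sym} = {pycode(expr)}")
    for i, expr in enumerate(exprs, start=1):
        w(f"    r{i} = {pycode(expr)}")
    w("")
    w("    if T_ > 0.0 and ET_ > 0.0:")
    for sym, expr in kreps:
        w(f"        {sym} = {pycode(expr)}")
    names = ["kg_T", "kg_ET", "kg_GT", "kg_S"]
    for nm, expr in zip(names, kexprs):
        w(f"        {nm} = {pycode(expr)}")
    w("        r1 += l1 * kg_T")
    w("        r3 += l1 * kg_ET")
    w("        r7 += l1 * kg_GT")
    w("        r8 += l1 * kg_S")
    w("")
    w("    return (r1, r2, r3, r4, r5, r6, r7, r8, r9, r10, r11)")
    w("")
    return "\n".join(lines)


if __name__ == "__main__":
    src = emit()
    compile(src, str(OUT), "exec")  # sanity: generated code parses
    OUT.write_text(src)
    print(f"wrote {OUT} ({len(src.splitlines())} lines)")
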