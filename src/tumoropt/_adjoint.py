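"""Costate right-hand side, generated by tools/gen_adjoint.py -- do not edit.

lam' = -dH/dx for the Hamiltonian H = A*T + B*uE^2 + C*uM^2 + lam . f(x, u),
where f is the model right-hand side implemented in tumoropt.model.
Control-dependent terms are state-independent and drop out of the gradient.
"""

import math


def adjoint_rhs_core(lam, y, params, A):
    """Return the 11 costate derivatives as a tuple of floats.

    The CD8 kill-term contribution follows the same limit convention as
    the model RHS: it is treated as identically 0 when ET == 0 or T == 0,
    so its gradient rows are dropped there.
    """
    T_, N_, ET_, DU_, DL_, HT_, GT_, S_, I2_, I10_, M_ = y
    l1, l2, l3, l4, l5, l6, l7, l8, l9, l10, l11 = lam
    a = params.a
    b = params.b
    c1 = params.c1
    d = params.d
    e = params.e
    g1 = params.g1
    s1 = params.s1
    kT = params.kT
    b1 = params.b1
    dN = params.dN
    c2 = params.c2
    pN = params.pN
    qN = params.qN
    kN = params.kN
    alpha1 = params.alpha1
    s2 = params.s2
    i1 = params.i1
    d1 = params.d1
    mE = params.mE
    c3 = params.c3
    kET = params.kET
    p = params.p
    i2 = params.i2
    g2 = params.g2
    gamma1 = params.gamma1
    mH = params.mH
    dDU = params.dDU
    kDU = params.kDU
    dDL = params.dDL
    alpha2 = params.alpha2
    gamma2 = params.gamma2
    s3 = params.s3
    dHT = params.dHT
    kHT = params.kHT
    alpha3 = params.alpha3
    mG = params.mG
    dGT = params.dGT
    kGT = params.kGT
    p1 = params.p1
    p2 = params.p2
    dS = params.dS
    alpha4 = params.alpha4
    i3 = params.i3
    s4 = params.s4
    dI2 = params.dI2
    p3 = params.p3
    p4 = params.p4
    dI10 = params.dI10
    dM = params.dM

    c0 = GT_ + g2
    c4 = 1/c0
    c5 = math.exp(M_)
    c6 = g2*i2*l4*p
    c7 = I10_ + i2
    c8 = c0*c7
    c9 = c5*c8
    c10 = c1*c5
    c11 = c5 - 1
    c12 = T_*b
    c13 = math.exp(-M_)
    c14 = c13/c7
    c15 = I2_ + qN
    c16 = T_*l1
    c17 = c15*c5
    c18 = DU_ + mH
    c19 = c18**2
    c20 = alpha2*mH
    c21 = c20*l6
    c22 = c5*gamma1
    c23 = I2_ + i1
    c24 = DL_ + d1
    c25 = DU_ + c24
    c26 = c25**2
    c27 = S_ + s2
    c28 = c26*c27
    c29 = c23*c28
    c30 = 1/c23
    c31 = 1/c27
    c32 = c30*c31/c26
    c33 = c24**2
    c34 = I2_*s2
    c35 = c34*d1
    c36 = alpha1*l3*mE
    c37 = alpha3*l7*mG
    c38 = I10_ + i3
    c39 = 1/c38
    c40 = S_ + s3
    c41 = S_ + s4
    c42 = 1/c41
    c43 = c40*c5
    c44 = alpha4*i3*l9*s4
    c45 = S_*c5*gamma2
    c46 = c38*l7
    c47 = c38*l6
    c48 = c0**2
    c49 = c48*c7
    c50 = c49*c5
    c51 = c27**2
    c52 = c40**2
    c53 = c41**2
    c54 = c34*c52
    c55 = DL_*c36
    c56 = c23*c25*c51
    c57 = HT_*c56
    c58 = c24*c53
    c59 = c57*gamma2
    c60 = c20*(DL_ + DU_)
    c61 = 1/(c24*c25)
    c62 = c23**2
    c63 = c15**2
    c64 = c25*c63
    c65 = i1*s2
    c66 = N_*l2
    c67 = c7**2
    c68 = c38**2
    c69 = c0*c67
    c70 = c41*c68
    r1 = c14*c4*(-A*c9 + ET_*c0*c3*c5*c7*l3 + N_*c0*c2*c5*c7*l2 - c5*c6 - c8*l1*(-N_*c10 - a*c12*c5 + a*c5*(1 - c12) - c11*kT) - c9*l10*p4 - c9*l8*p2)
    r2 = c13*(c10*c15*c16 - l2*(I2_*c5*pN - T_*c17*c2 - c11*c15*kN - c17*dN))/c15
    r3 = -c13*l3*(-T_*c3*c5 - c11*kET)
    r4 = c13*c32*(-I2_*c19*c21*c5*d1*s2 - c22*c29*l5*mH**2 - c29*l4*(DU_*c5*gamma1*mH - c11*c19*kDU - c18*c22*mH - c19*c5*dDU))/c19
    r5 = c32*(-I2_*c28*c37*d1 - c21*c33*c35 + c23*c26*c27*c33*dDL*l5 - c26*c35*c36)/c33
    r6 = c13*c39*c42*(-c41*c45*c46 - c41*c47*(-c11*c40*kHT - c43*dHT - c45) - c43*c44)/c40
    r7 = c14*(T_*c5*g2*i2*l4*p - c49*l7*(-c11*kGT - c5*dGT) - c50*l10*p3 - c50*l8*p1)/c48
    r8 = c30*c39*c61*(c24*c44*c52*c57 + c25*c38*c53*c54*c55 + c38*c52*c56*c58*dS*l8 - c46*c58*c59*s3 - c47*c58*(HT_*S_*c23*c25*c51*gamma2 - c40*c59 - c54*c60))/(c51*c52*c53)
    r9 = c31*c61*(-DL_*c27*c37*c64*i1 + c24*c25*c27*c62*c63*dI2*l9 - c24*c25*c27*c62*c66*pN*qN - c24*c60*c63*c65*l6 - c55*c64*c65)/(c62*c63)
    r10 = c4*c42*(HT_*c44*c69 + T_*c6*c70 + c69*c70*dI10*l10)/(c67*c68)
    r11 = c13*(DU_*kDU*l4 + ET_*kET*l3 + GT_*kGT*l7 + HT_*kHT*l6 + c16*kT + c5*dM*l11 + c66*kN)

    if T_ > 0.0 and ET_ > 0.0:
        q0 = ET_ + GT_*g1
        q1 = d*s1/q0
        q2 = S_ + s1
        q3 = 1/q2
        q4 = ET_ + T_*e
        q5 = q3/q4**2
        q6 = d*s1/q0**2
        q7 = ET_**2*T_/q4
        kg_T = ET_**3*q1*q5
        kg_ET = ET_*T_*q5*q6*(-ET_*q0 - ET_*q4 + 2*q0*q4)
        kg_GT = -g1*q3*q6*q7
        kg_S = -q1*q7/q2**2
        r1 += l1 * kg_T
        r3 += l1 * kg_ET
        r7 += l1 * kg_GT
        r8 += l1 * kg_S

    return (r1, r2, r3, r4, r5, r6, r7, r8, r9, r10, r11)
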