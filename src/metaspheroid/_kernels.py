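"""Numba kernels: the hot loops of the simulator.

Everything here operates on plain float64 arrays so the engine can run the
multirate loop (0.6 s diffusion / 1.2 s metabolism / 6 s mechanics) at
desk scale.  The public modules wrap these kernels behind typed APIs.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import params as P
from . import state as S

# ---------------------------------------------------------------------------
# counter-based RNG (splitmix64 + Box-Muller): reproducible per (seed, cell,
# tick, draw) regardless of iteration order.
# ---------------------------------------------------------------------------

MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & MASK64
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & MASK64
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & MASK64
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _counter_uniform(seed, a, b, c):
    """Uniform in (0, 1) from a 4-word counter."""
    x = _splitmix64(np.uint64(seed) ^ _splitmix64(np.uint64(a) ^ _splitmix64(np.uint64(b) ^ np.uint64(c))))
    return (np.float64(x >> np.uint64(11)) + 0.5) / 9007199254740992.0


@njit(cache=True, inline="always")
def counter_normal(seed, a, b, c):
    u1 = _counter_uniform(seed, a, b, 2 * c)
    u2 = _counter_uniform(seed, a, b, 2 * c + 1)
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


# ---------------------------------------------------------------------------
# pH helpers
# ---------------------------------------------------------------------------

LOG10 = math.log(10.0)


@njit(cache=True, inline="always")
def ph_of(h_mM):
    return -math.log(max(h_mM, 1e-15) * 1e-3) / LOG10


@njit(cache=True, inline="always")
def _ph_sigmoid(ph, mid, width, anchor):
    s = 1.0 / (1.0 + math.exp(-(ph - mid) / width))
    s0 = 1.0 / (1.0 + math.exp(-(anchor - mid) / width))
    f = s / s0
    return f if f < 1.0 else 1.0


@njit(cache=True, inline="always")
def ph_factor(ph_i, ph_e, p):
    """Multiplicative glycolysis inhibition in [0, 1]; 1 at physiological pH."""
    fe = _ph_sigmoid(ph_e, p[P.P_PH_MID_E], p[P.P_PH_WIDTH_E], p[P.P_PH_ANCHOR_E])
    fi = _ph_sigmoid(ph_i, p[P.P_PH_MID_I], p[P.P_PH_WIDTH_I], p[P.P_PH_ANCHOR_I])
    return fe * fi


@njit(cache=True, inline="always")
def _f(x, k):
    x = max(x, 0.0)
    return x / (x + k)


@njit(cache=True, inline="always")
def _hill2(x, k):
    x = max(x, 0.0)
    return x * x / (x * x + k * k)


@njit(cache=True, inline="always")
def _hill3(x, k):
    x = max(x, 0.0)
    return x * x * x / (x * x * x + k * k * k)


# ---------------------------------------------------------------------------
# metabolite network right-hand side
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def tick_factors(y, env, p):
    """Per-tick environmental factors: glycolysis pH modulation and the
    oxygen dependence of the electron transport chain (both vary on much
    slower scales than one 1.2 s metabolism step)."""
    ph_i = ph_of(max(y[S.H_I], 1e-12))
    ph_e = ph_of(max(env[3], 1e-12))
    return ph_factor(ph_i, ph_e, p), _hill3(max(env[0], 0.0), p[P.P_R28_KM_O2])


@njit(cache=True, fastmath={"reassoc", "contract", "arcp"})
def metab_rhs(y, env, p, dy, v, phi=-1.0, o2q=-1.0):
    """Evaluate all reaction rates (v, mM/min) and metabolite derivatives.

    ``env`` = (oxygen, glucose_e, lactate_e, proton_e) in mM.  Gene and
    protein coordinates of ``dy`` are left untouched (zeroed by caller);
    they evolve on the slower regulation clock.
    """
    o2 = max(env[0], 0.0)
    ge = max(env[1], 0.0)
    le = max(env[2], 0.0)
    he = max(env[3], 0.0)

    glc = max(y[S.GLC_I], 0.0)
    g6p = max(y[S.G6P], 0.0)
    f6p = max(y[S.F6P], 0.0)
    fbp = max(y[S.FBP], 0.0)
    dhap = max(y[S.DHAP], 0.0)
    gap = max(y[S.GAP], 0.0)
    bpg = max(y[S.BPG], 0.0)
    pg3 = max(y[S.PG3], 0.0)
    pg2 = max(y[S.PG2], 0.0)
    pep = max(y[S.PEP], 0.0)
    pyr = max(y[S.PYR], 0.0)
    lac = max(y[S.LAC_I], 0.0)
    h_i = max(y[S.H_I], 1e-12)
    gly = max(y[S.GLY], 0.0)
    accoa = max(y[S.ACCOA], 0.0)
    cit = max(y[S.CIT], 0.0)
    icit = max(y[S.ICIT], 0.0)
    akg = max(y[S.AKG], 0.0)
    succoa = max(y[S.SUCCOA], 0.0)
    suc = max(y[S.SUC], 0.0)
    fum = max(y[S.FUM], 0.0)
    mal = max(y[S.MAL], 0.0)
    oaa = max(y[S.OAA], 0.0)
    nad_c = max(y[S.NAD_C], 0.0)
    nadh_c = max(y[S.NADH_C], 0.0)
    nad_m = max(y[S.NAD_M], 0.0)
    nadh_m = max(y[S.NADH_M], 0.0)
    fad = max(y[S.FAD], 0.0)
    fadh2 = max(y[S.FADH2], 0.0)
    atp = max(y[S.ATP], 0.0)
    adp = max(y[S.ADP], 0.0)
    amp = max(y[S.AMP], 0.0)
    coa = max(y[S.COA], 0.0)

    glut_p = max(y[S.GLUT_P], 0.0)
    hk_p = max(y[S.HK_P], 0.0)
    pfk_p = max(y[S.PFK_P], 0.0)
    pk_p = max(y[S.PK_P], 0.0)
    ldh_p = max(y[S.LDH_P], 0.0)
    pdh_p = max(y[S.PDH_P], 0.0)
    mct_p = max(y[S.MCT_P], 0.0)
    etc_p = max(y[S.ETC_P], 0.0)
    atpase_p = max(y[S.ATPASE_P], 0.0)
    ampk = max(y[S.AMPK], 0.0)

    if phi < 0.0 or o2q < 0.0:
        phi, o2q = tick_factors(y, env, p)
    href = p[P.P_PROTON_HREF]

    v[0] = p[P.P_R1_VMAX] * glut_p * (_f(ge, p[P.P_R1_KM]) - _f(glc, p[P.P_R1_KM]))
    v[1] = (p[P.P_R2_K] * hk_p * _f(glc, p[P.P_R2_KM_GLC]) * _f(atp, p[P.P_R2_KM_ATP])
            / (1.0 + (g6p / p[P.P_R2_KI_G6P]) ** 2))
    v[2] = p[P.P_R3_K] * (g6p - f6p / p[P.P_R3_KEQ])
    hif_now = max(y[S.HIF1A], 0.0)
    h_hif_m = _hill2(hif_now, p[P.P_PDK_KM_HIF])
    ki_atp4 = p[P.P_R4_KI_ATP] * (1.0 + p[P.P_R4_HIF_RELAX] * h_hif_m)
    v[3] = (p[P.P_R4_K] * pfk_p * phi * _f(f6p, p[P.P_R4_KM_F6P]) * _f(atp, p[P.P_R4_KM_ATP])
            * (1.0 + p[P.P_R4_AMP_BOOST] * _f(amp, p[P.P_R4_KA_AMP]))
            * ki_atp4 * ki_atp4 / (ki_atp4 * ki_atp4 + atp * atp)
            * p[P.P_R4_KI_LAC] ** 2 / (p[P.P_R4_KI_LAC] ** 2 + lac * lac))
    v[4] = p[P.P_R5_K] * fbp
    v[5] = p[P.P_R6_K] * (dhap - gap / p[P.P_R6_KEQ])
    v[6] = p[P.P_R7_K] * gap * _f(nad_c, p[P.P_R7_KM_NAD])
    v[7] = p[P.P_R8_K] * bpg * _f(adp, p[P.P_R8_KM_ADP])
    v[8] = p[P.P_R9_K] * (pg3 - pg2 / p[P.P_R9_KEQ])
    v[9] = p[P.P_R10_K] * (pg2 - pep / p[P.P_R10_KEQ])
    v[10] = (p[P.P_R11_K] * pk_p * _f(pep, p[P.P_R11_KM_PEP]) * _f(adp, p[P.P_R11_KM_ADP])
             * (1.0 + p[P.P_R11_FBP_BOOST] * _f(fbp, p[P.P_R11_KA_FBP])))
    v[11] = (p[P.P_R12_KF] * ldh_p * (pyr * nadh_c - lac * nad_c / p[P.P_R12_KEQ])
             / ((1.0 + pyr / p[P.P_R12_KM_PYR]) * (1.0 + lac / p[P.P_R12_KM_LAC])))
    ki13 = p[P.P_R14_KI_GLC]
    v[12] = (p[P.P_R13_K] * _f(glc, p[P.P_R13_KM_GLC]) * _f(atp, p[P.P_R2_KM_ATP])
             * max(0.0, 1.0 - gly / p[P.P_R13_GLY_MAX]))
    v[13] = (p[P.P_R14_K] * _f(gly, p[P.P_R14_KM_GLY])
             * ki13 * ki13 / (ki13 * ki13 + glc * glc))
    v[14] = (p[P.P_R15_K] * (nadh_c * nad_m - nadh_m * nad_c / p[P.P_R15_KEQ])
             / p[P.P_POOL_NAD_M])
    v[15] = (p[P.P_R16_K] * atpase_p * _f(atp, p[P.P_R16_KM_ATP])
             * (1.0 - p[P.P_R16_AMPK_RELIEF] * _hill2(ampk, p[P.P_R16_KM_AMPK])))
    v[16] = p[P.P_R17_K] * (adp * adp - atp * amp / p[P.P_R17_KEQ])
    v[17] = (p[P.P_R18_K] * pdh_p * _f(pyr, p[P.P_R18_KM_PYR]) * _f(nad_m, p[P.P_R18_KM_NADM])
             * _f(coa, p[P.P_R18_KM_COA]))
    v[18] = p[P.P_R19_K] * _f(accoa, p[P.P_R19_KM_ACCOA]) * _f(oaa, p[P.P_R19_KM_OAA])
    v[19] = p[P.P_R20_K] * (cit - icit / p[P.P_R20_KEQ])
    prod_i = lac * (h_i / href)
    prod_e = le * (he / href)
    v[20] = (p[P.P_R21_VMAX] * mct_p * (prod_i - prod_e)
             / (p[P.P_R21_KM] + prod_i + prod_e))
    v[21] = p[P.P_R22_K] * _f(icit, p[P.P_R22_KM_ICIT]) * _f(nad_m, p[P.P_R22_KM_NADM])
    v[22] = (p[P.P_R23_K] * _f(akg, p[P.P_R23_KM_AKG]) * _f(nad_m, p[P.P_R23_KM_NADM])
             * _f(coa, p[P.P_R23_KM_COA]))
    v[23] = p[P.P_R24_K] * succoa * _f(adp, p[P.P_R24_KM_ADP])
    v[24] = p[P.P_R25_K] * _f(suc, p[P.P_R25_KM_SUC]) * _f(fad, p[P.P_R25_KM_FAD])
    v[25] = p[P.P_R26_K] * (fum - mal / p[P.P_R26_KEQ])
    v[26] = (p[P.P_R27_KF] * (mal * nad_m - oaa * nadh_m / p[P.P_R27_KEQ])
             / p[P.P_POOL_NAD_M])
    v[27] = (p[P.P_R28_K] * etc_p * _f(nadh_m, p[P.P_R28_KM_NADHM]) * o2q
             * _f(adp, p[P.P_R28_KM_ADP]))
    v[28] = (p[P.P_R29_K] * etc_p * _f(fadh2, p[P.P_R29_KM_FADH2]) * o2q
             * _f(adp, p[P.P_R29_KM_ADP]))
    h_set = math.pow(10.0, -p[P.P_R30_PH_SET]) * 1e3
    # total-acid equivalents moved per min: free-proton regulation with
    # time constant 1/k against the buffering capacity
    v[29] = p[P.P_R30_K] * (h_i - h_set) * p[P.P_PROTON_BUFFER_I]

    buf_i = p[P.P_PROTON_BUFFER_I]
    atp_n = p[P.P_R28_ATP_PER_NADH]
    atp_f = p[P.P_R29_ATP_PER_FADH2]

    dy[S.GLC_I] = v[0] - v[1]
    dy[S.G6P] = v[1] - v[2] - v[12] + v[13]
    dy[S.F6P] = v[2] - v[3]
    dy[S.FBP] = v[3] - v[4]
    dy[S.DHAP] = v[4] - v[5]
    dy[S.GAP] = v[4] + v[5] - v[6]
    dy[S.BPG] = v[6] - v[7]
    dy[S.PG3] = v[7] - v[8]
    dy[S.PG2] = v[8] - v[9]
    dy[S.PEP] = v[9] - v[10]
    dy[S.PYR] = v[10] - v[11] - v[17]
    dy[S.LAC_I] = v[11] - v[20]
    dy[S.H_I] = (v[11] - v[20] - v[29]) / buf_i
    dy[S.GLY] = v[12] - v[13]
    dy[S.ACCOA] = v[17] - v[18]
    dy[S.CIT] = v[18] - v[19]
    dy[S.ICIT] = v[19] - v[21]
    dy[S.AKG] = v[21] - v[22]
    dy[S.SUCCOA] = v[22] - v[23]
    dy[S.SUC] = v[23] - v[24]
    dy[S.FUM] = v[24] - v[25]
    dy[S.MAL] = v[25] - v[26]
    dy[S.OAA] = v[26] - v[18]
    dy[S.NADH_C] = v[6] - v[11] - v[14]
    dy[S.NAD_C] = -dy[S.NADH_C]
    dy[S.NADH_M] = v[17] + v[21] + v[22] + v[26] + v[14] - v[27]
    dy[S.NAD_M] = -dy[S.NADH_M]
    dy[S.FADH2] = v[24] - v[28]
    dy[S.FAD] = -dy[S.FADH2]
    dy[S.ATP] = (-v[1] - v[3] + v[7] + v[10] + v[23] + atp_n * v[27] + atp_f * v[28]
                 - v[15] + v[16])
    dy[S.ADP] = (v[1] + v[3] - v[7] - v[10] - v[23] - atp_n * v[27] - atp_f * v[28]
                 + v[15] - 2.0 * v[16])
    dy[S.AMP] = v[16]
    dy[S.COA] = -v[17] + v[18] - v[22] + v[23]


@njit(cache=True)
def exchange_from_fluxes(v, exch):
    """Cell-volume-referenced net release rates (mM/min), positive = release."""
    exch[0] = -0.5 * (v[27] + v[28])           # oxygen consumed
    exch[1] = -v[0]                            # glucose taken up
    exch[2] = v[20]                            # lactate exported via MCT
    exch[3] = v[20] + v[29]                    # protons co-exported + NHE


@njit(cache=True)
def _heun_try(y, env, p, dt_min, nsub, y_out, vacc, eacc, k1, k2, k3, k4, ytmp, vtmp):
    """Heun (explicit trapezoid) step with ``nsub`` substeps; returns False
    on positivity/finiteness failure.

    Time-averaged fluxes (trapezoid-weighted, so flux integrals match pool
    changes exactly) go into ``vacc``; exchange into ``eacc`` (caller
    zeroes both).  The scratch arrays k3/k4 are kept for signature
    stability with the callers.
    """
    h = dt_min / nsub
    nm = S.N_METABOLITES
    for i in range(S.N_VARS):
        y_out[i] = y[i]
    w = h / dt_min / 2.0
    ex = np.empty(4)
    for _ in range(nsub):
        phi, o2q = tick_factors(y_out, env, p)
        metab_rhs(y_out, env, p, k1, vtmp, phi, o2q)
        for i in range(S.N_FLUXES):
            vacc[i] += vtmp[i] * w
        exchange_from_fluxes(vtmp, ex)
        for i in range(4):
            eacc[i] += ex[i] * w
        for i in range(nm):
            ytmp[i] = y_out[i] + h * k1[i]
        for i in range(nm, S.N_VARS):
            ytmp[i] = y_out[i]
        metab_rhs(ytmp, env, p, k2, vtmp, phi, o2q)
        for i in range(S.N_FLUXES):
            vacc[i] += vtmp[i] * w
        exchange_from_fluxes(vtmp, ex)
        for i in range(4):
            eacc[i] += ex[i] * w
        bad = False
        for i in range(nm):
            yn = y_out[i] + 0.5 * h * (k1[i] + k2[i])
            if not math.isfinite(yn):
                return False
            if yn < -1e-6:
                bad = True
            y_out[i] = yn if yn > 0.0 else 0.0
        if bad:
            return False
    return True


@njit(cache=True)
def integrate_metabolism_population(states, envs, dt_s, p, flux_avg, exch_avg):
    """Advance the metabolite block of every row of ``states`` by ``dt_s``.

    Returns -1 on success, else the row index of the failing cell.
    ``flux_avg`` (n, N_FLUXES) and ``exch_avg`` (n, 4) receive the
    interval-averaged reaction rates and cell-referenced exchange rates.
    """
    n = states.shape[0]
    dt_min = dt_s / 60.0
    k1 = np.empty(S.N_VARS)
    k2 = np.empty(S.N_VARS)
    k3 = np.empty(S.N_VARS)
    k4 = np.empty(S.N_VARS)
    ytmp = np.empty(S.N_VARS)
    yout = np.empty(S.N_VARS)
    vtmp = np.empty(S.N_FLUXES)
    for c in range(n):
        y = states[c]
        env = envs[c]
        nsub = 1
        ok = False
        while nsub <= 64:
            for i in range(S.N_FLUXES):
                flux_avg[c, i] = 0.0
            for i in range(4):
                exch_avg[c, i] = 0.0
            ok = _heun_try(y, env, p, dt_min, nsub, yout, flux_avg[c], exch_avg[c],
                          k1, k2, k3, k4, ytmp, vtmp)
            if ok:
                break
            nsub *= 2
        if not ok:
            return c
        for i in range(S.N_METABOLITES):
            y[i] = yout[i]
    return -1


# ---------------------------------------------------------------------------
# gene regulation + protein translation (slow clock)
# ---------------------------------------------------------------------------


@njit(cache=True)
def gene_protein_step(states, envs, gammas, cell_ids, dt_min, p, sigma, seed, tick):
    """Euler-Maruyama step of the ten gene ODEs plus protein relaxation.

    gamma multiplies each gene's production term; noise is additive Gaussian
    from a counter-based stream keyed by (seed, cell_id, tick, gene).
    """
    n = states.shape[0]
    sq = math.sqrt(dt_min)
    for c in range(n):
        y = states[c]
        g = gammas[c]
        cid = cell_ids[c]
        o2 = max(envs[c, 0], 0.0)
        lac_eff = max(envs[c, 2], 0.0)

        hif = max(y[S.HIF1A], 0.0)
        ampk = max(y[S.AMPK], 0.0)
        p53 = max(y[S.P53], 0.0)
        myc = max(y[S.MYC], 0.0)
        pdkg = max(y[S.PDK_G], 0.0)
        atp = max(y[S.ATP], 0.0)

        h_hif = _hill2(hif, p[P.P_PDK_KM_HIF])
        h_myc = _hill2(myc, p[P.P_GLUT_KM_MYC])
        h_p53 = _hill2(p53, p[P.P_PDH_KM_P53])

        o2_sens = _hill2(o2, p[P.P_HIF1A_KM_O2])
        w = p[P.P_HIF1A_LAC_FLOOR]
        lac_stab = w + (1.0 - w) / (1.0 + (lac_eff / p[P.P_HIF1A_KM_LAC]) ** 2)
        deg_hif = p[P.P_HIF1A_KDEG] * (p[P.P_HIF1A_BASAL_FRAC]
                                       + (1.0 - p[P.P_HIF1A_BASAL_FRAC]) * o2_sens * lac_stab)
        d_hif = g * p[P.P_HIF1A_A] - deg_hif * hif

        d_ampk = (g * (p[P.P_AMPK_A0] + p[P.P_AMPK_A] * (1.0 - _hill2(atp * atp, p[P.P_AMPK_KM_ATP] ** 2)))
                  - p[P.P_AMPK_KDEG] * ampk)
        d_p53 = (g * (p[P.P_P53_A0] + p[P.P_P53_A] * _hill2(ampk, p[P.P_P53_KM_AMPK]))
                 - p[P.P_P53_KDEG] * p53)
        d_myc = (g * p[P.P_MYC_A] / (1.0 + (p53 / p[P.P_MYC_KI_P53]) ** 2)
                 - p[P.P_MYC_KDEG] * myc)
        d_pdk = (g * (p[P.P_PDK_A0] + p[P.P_PDK_A] * h_hif) - p[P.P_PDK_KDEG] * pdkg)
        d_glut = (g * (p[P.P_GLUT_A0]
                       + (p[P.P_GLUT_A_HIF] * h_hif + p[P.P_GLUT_A_MYC] * h_myc)
                       / (1.0 + (p53 / p[P.P_GLUT_KI_P53]) ** 2))
                  - p[P.P_GLUT_KDEG] * y[S.GLUT_G])
        d_ldh = (g * (p[P.P_LDH_A0] + p[P.P_LDH_A_HIF] * h_hif + p[P.P_LDH_A_MYC] * h_myc)
                 - p[P.P_LDH_KDEG] * y[S.LDH_G])
        d_pdh = (g * p[P.P_PDH_A] * (1.0 + p[P.P_PDH_A_P53] * h_p53)
                 / (1.0 + (pdkg / p[P.P_PDH_KI_PDK]) ** 2)
                 - p[P.P_PDH_KDEG] * y[S.PDH_G])
        d_mct = (g * (p[P.P_MCT_A0] + p[P.P_MCT_A_HIF] * h_hif) - p[P.P_MCT_KDEG] * y[S.MCT_G])
        d_pfk = (g * (p[P.P_PFK_A0] + p[P.P_PFK_A_HIF] * h_hif + p[P.P_PFK_A_MYC] * h_myc)
                 - p[P.P_PFK_KDEG] * y[S.PFK_G])

        y[S.HIF1A] = max(0.0, hif + d_hif * dt_min + sigma * sq * counter_normal(seed, cid, tick, 0))
        y[S.AMPK] = max(0.0, ampk + d_ampk * dt_min + sigma * sq * counter_normal(seed, cid, tick, 1))
        y[S.P53] = max(0.0, p53 + d_p53 * dt_min + sigma * sq * counter_normal(seed, cid, tick, 2))
        y[S.MYC] = max(0.0, myc + d_myc * dt_min + sigma * sq * counter_normal(seed, cid, tick, 3))
        y[S.PDK_G] = max(0.0, pdkg + d_pdk * dt_min + sigma * sq * counter_normal(seed, cid, tick, 4))
        y[S.GLUT_G] = max(0.0, y[S.GLUT_G] + d_glut * dt_min + sigma * sq * counter_normal(seed, cid, tick, 5))
        y[S.LDH_G] = max(0.0, y[S.LDH_G] + d_ldh * dt_min + sigma * sq * counter_normal(seed, cid, tick, 6))
        y[S.PDH_G] = max(0.0, y[S.PDH_G] + d_pdh * dt_min + sigma * sq * counter_normal(seed, cid, tick, 7))
        y[S.MCT_G] = max(0.0, y[S.MCT_G] + d_mct * dt_min + sigma * sq * counter_normal(seed, cid, tick, 8))
        y[S.PFK_G] = max(0.0, y[S.PFK_G] + d_pfk * dt_min + sigma * sq * counter_normal(seed, cid, tick, 9))

        # proteins relax toward their targets (no noise)
        ktr = p[P.P_PROTEIN_KTR]
        kdp = p[P.P_PROTEIN_KDP]
        hk_target = (p[P.P_PROTEIN_HK_BASE] + p[P.P_PROTEIN_HK_MYC] * y[S.MYC]
                     + p[P.P_PROTEIN_HK_HIF] * _hill2(y[S.HIF1A], p[P.P_PDK_KM_HIF]))
        etc_target = 1.0 + p[P.P_PROTEIN_ETC_P53] * _hill2(y[S.P53], p[P.P_PROTEIN_KM_P53])
        y[S.GLUT_P] = max(0.0, y[S.GLUT_P] + (ktr * y[S.GLUT_G] - kdp * y[S.GLUT_P]) * dt_min)
        y[S.HK_P] = max(0.0, y[S.HK_P] + (ktr * hk_target - kdp * y[S.HK_P]) * dt_min)
        y[S.PFK_P] = max(0.0, y[S.PFK_P] + (ktr * y[S.PFK_G] - kdp * y[S.PFK_P]) * dt_min)
        y[S.PK_P] = max(0.0, y[S.PK_P] + (ktr * hk_target - kdp * y[S.PK_P]) * dt_min)
        y[S.LDH_P] = max(0.0, y[S.LDH_P] + (ktr * y[S.LDH_G] - kdp * y[S.LDH_P]) * dt_min)
        y[S.PDH_P] = max(0.0, y[S.PDH_P] + (ktr * y[S.PDH_G] - kdp * y[S.PDH_P]) * dt_min)
        y[S.PDK_P] = max(0.0, y[S.PDK_P] + (ktr * y[S.PDK_G] - kdp * y[S.PDK_P]) * dt_min)
        y[S.MCT_P] = max(0.0, y[S.MCT_P] + (ktr * y[S.MCT_G] - kdp * y[S.MCT_P]) * dt_min)
        y[S.ETC_P] = max(0.0, y[S.ETC_P] + (ktr * etc_target - kdp * y[S.ETC_P]) * dt_min)
        y[S.ATPASE_P] = max(0.0, y[S.ATPASE_P] + (ktr * 1.0 - kdp * y[S.ATPASE_P]) * dt_min)


# ---------------------------------------------------------------------------
# locally-one-dimensional implicit diffusion (Thomas solves per axis)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _thomas_line(c_line, alpha, dirichlet, bc_value, cp, dp):
    """Solve (I - alpha * L) x = c_line in place for one grid line.

    ``L`` is the 1D Laplacian stencil with reflecting (zero-flux) ends;
    under Dirichlet the end entries are clamped to ``bc_value``.
    """
    n = c_line.shape[0]
    if dirichlet:
        c_line[0] = bc_value
        c_line[n - 1] = bc_value
        if n <= 2:
            return
        # interior unknowns 1..n-2 with known Dirichlet neighbors
        b = 1.0 + 2.0 * alpha
        rhs = c_line[1] + alpha * bc_value
        if n == 3:
            rhs += alpha * bc_value  # single unknown touches both ends
        cp[1] = -alpha / b
        dp[1] = rhs / b
        for i in range(2, n - 1):
            rhs = c_line[i]
            if i == n - 2:
                rhs += alpha * bc_value
            m = b + alpha * cp[i - 1]
            cp[i] = -alpha / m
            dp[i] = (rhs + alpha * dp[i - 1]) / m
        c_line[n - 2] = dp[n - 2]
        for i in range(n - 3, 0, -1):
            c_line[i] = dp[i] - cp[i] * c_line[i + 1]
    else:
        # zero-flux: reflecting ends, conservative
        if n == 1:
            return
        b0 = 1.0 + alpha
        cp[0] = -alpha / b0
        dp[0] = c_line[0] / b0
        for i in range(1, n):
            b = 1.0 + (alpha if (i == n - 1) else 2.0 * alpha)
            m = b + alpha * cp[i - 1]
            cp[i] = -alpha / m
            dp[i] = (c_line[i] + alpha * dp[i - 1]) / m
        c_line[n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            c_line[i] = dp[i] - cp[i] * c_line[i + 1]


@njit(cache=True)
def lod_diffusion_step(conc, diff_um2_min, dt_s, dx_um, dirichlet, bc_value, source_mM_min):
    """One operator-split implicit diffusion step with volumetric sources.

    Sources (mM/min) are applied explicitly first (clipping negatives and
    returning the clipped mass in mM-voxel units), then an implicit x sweep
    and an implicit y sweep advance diffusion.  Dirichlet boundary voxels
    are re-imposed exactly at the end.
    """
    nx, ny = conc.shape
    dt_min = dt_s / 60.0
    alpha = diff_um2_min * dt_min / (dx_um * dx_um)
    clipped = 0.0
    for i in range(nx):
        for j in range(ny):
            cnew = conc[i, j] + source_mM_min[i, j] * dt_min
            if cnew < 0.0:
                clipped += -cnew
                cnew = 0.0
            conc[i, j] = cnew
    cp = np.empty(max(nx, ny))
    dp = np.empty(max(nx, ny))
    line = np.empty(nx)
    for j in range(ny):
        for i in range(nx):
            line[i] = conc[i, j]
        _thomas_line(line[:nx], alpha, dirichlet, bc_value, cp, dp)
        for i in range(nx):
            conc[i, j] = line[i]
    line2 = np.empty(ny)
    for i in range(nx):
        for j in range(ny):
            line2[j] = conc[i, j]
        _thomas_line(line2[:ny], alpha, dirichlet, bc_value, cp, dp)
        for j in range(ny):
            conc[i, j] = line2[j]
    if dirichlet:
        for i in range(nx):
            conc[i, 0] = bc_value
            conc[i, ny - 1] = bc_value
        for j in range(ny):
            conc[0, j] = bc_value
            conc[nx - 1, j] = bc_value
    return clipped


# ---------------------------------------------------------------------------
# overdamped adhesion-repulsion mechanics
# ---------------------------------------------------------------------------


@njit(cache=True)
def mechanics_forces(pos, radii, rep, adh, adh_scale, extent, vel):
    """Pairwise polynomial adhesion/repulsion velocities plus wall repulsion."""
    n = pos.shape[0]
    for i in range(n):
        vel[i, 0] = 0.0
        vel[i, 1] = 0.0
    if n == 0:
        return
    rmax = 0.0
    for i in range(n):
        if radii[i] > rmax:
            rmax = radii[i]
    cell = max(2.0 * rmax * adh_scale, 1.0)
    nbx = max(1, int(extent / cell))
    nby = nbx
    bw = extent / nbx
    head = np.full(nbx * nby, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        bx = min(nbx - 1, max(0, int(pos[i, 0] / bw)))
        by = min(nby - 1, max(0, int(pos[i, 1] / bw)))
        b = bx * nby + by
        nxt[i] = head[b]
        head[b] = i
    for i in range(n):
        bx = min(nbx - 1, max(0, int(pos[i, 0] / bw)))
        by = min(nby - 1, max(0, int(pos[i, 1] / bw)))
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                cx = bx + dx
                cy = by + dy
                if cx < 0 or cx >= nbx or cy < 0 or cy >= nby:
                    continue
                j = head[cx * nby + cy]
                while j >= 0:
                    if j != i:
                        ddx = pos[i, 0] - pos[j, 0]
                        ddy = pos[i, 1] - pos[j, 1]
                        d = math.sqrt(ddx * ddx + ddy * ddy)
                        s = radii[i] + radii[j]
                        ra = adh_scale * s
                        if d < ra and d > 1e-9:
                            f = 0.0
                            if d < s:
                                u = 1.0 - d / s
                                f += rep * u * u
                            u2 = 1.0 - d / ra
                            f -= adh * u2 * u2
                            vel[i, 0] += f * ddx / d
                            vel[i, 1] += f * ddy / d
                    j = nxt[j]
        # domain walls repel within one radius
        r = radii[i]
        for ax in range(2):
            x = pos[i, ax]
            if x < r:
                u = 1.0 - x / r
                vel[i, ax] += rep * u * u
            if x > extent - r:
                u = 1.0 - (extent - x) / r
                vel[i, ax] -= rep * u * u


@njit(cache=True)
def mechanics_step_kernel(pos, radii, dt_min, rep, adh, adh_scale, extent, vel):
    mechanics_forces(pos, radii, rep, adh, adh_scale, extent, vel)
    n = pos.shape[0]
    for i in range(n):
        pos[i, 0] = min(max(pos[i, 0] + vel[i, 0] * dt_min, 0.0), extent)
        pos[i, 1] = min(max(pos[i, 1] + vel[i, 1] * dt_min, 0.0), extent)


# ---------------------------------------------------------------------------
# fused drivers
# ---------------------------------------------------------------------------


@njit(cache=True)
def run_cell_course(y, env, gamma, n_gene_ticks, metab_per_gene, dt_metab_s,
                    dt_gene_s, p, sigma, seed, cell_id,
                    traj_atp, traj_ldh, traj_pdh, traj_flux):
    """Single cell in a clamped environment: metabolite integration ticks interleaved
    with gene-regulation steps.

    Records per gene tick: ATP, LDH/PDH expression and the tick-averaged
    flux vector.  Returns -1 on success, the failing gene tick otherwise.
    """
    dt_min = dt_metab_s / 60.0
    k1 = np.empty(S.N_VARS)
    k2 = np.empty(S.N_VARS)
    k3 = np.empty(S.N_VARS)
    k4 = np.empty(S.N_VARS)
    ytmp = np.empty(S.N_VARS)
    yout = np.empty(S.N_VARS)
    vtmp = np.empty(S.N_FLUXES)
    vacc = np.empty(S.N_FLUXES)
    eacc = np.empty(4)
    states = y.reshape(1, S.N_VARS)
    envs = env.reshape(1, 4)
    gam = np.empty(1)
    gam[0] = gamma
    cid = np.empty(1, dtype=np.int64)
    cid[0] = cell_id
    for tick in range(n_gene_ticks):
        for i in range(S.N_FLUXES):
            traj_flux[tick, i] = 0.0
        for _ in range(metab_per_gene):
            nsub = 1
            ok = False
            while nsub <= 64:
                for i in range(S.N_FLUXES):
                    vacc[i] = 0.0
                for i in range(4):
                    eacc[i] = 0.0
                ok = _heun_try(y, env, p, dt_min, nsub, yout, vacc, eacc,
                              k1, k2, k3, k4, ytmp, vtmp)
                if ok:
                    break
                nsub *= 2
            if not ok:
                return tick
            for i in range(S.N_METABOLITES):
                y[i] = yout[i]
            for i in range(S.N_FLUXES):
                traj_flux[tick, i] += vacc[i] / metab_per_gene
        gene_protein_step(states, envs, gam, cid, dt_gene_s / 60.0, p, sigma, seed, tick)
        traj_atp[tick] = y[S.ATP]
        traj_ldh[tick] = y[S.LDH_G]
        traj_pdh[tick] = y[S.PDH_G]
    return -1


@njit(cache=True)
def metabolism_tick(states, living_idx, vox_i, vox_j, volumes, field_o2, field_glc,
                    field_lac, field_h, acc_o2, acc_glc, acc_lac, acc_h,
                    dt_s, p, flux_avg, voxel_vol_um3, buffer_e):
    """One 1.2 s metabolism tick for the whole living population.

    Reads the local environment from the voxel containing each cell,
    integrates the metabolite block, accumulates interval-average fluxes
    into ``flux_avg`` (added, caller averages over the phenotype window)
    and deposits exchange into the per-voxel accumulators (mM/min voxel
    units; the proton deposit is divided by the extracellular buffering
    capacity).  Returns -1 or the failing row.
    """
    n = living_idx.shape[0]
    dt_min = dt_s / 60.0
    k1 = np.empty(S.N_VARS)
    k2 = np.empty(S.N_VARS)
    k3 = np.empty(S.N_VARS)
    k4 = np.empty(S.N_VARS)
    ytmp = np.empty(S.N_VARS)
    yout = np.empty(S.N_VARS)
    vtmp = np.empty(S.N_FLUXES)
    vacc = np.empty(S.N_FLUXES)
    eacc = np.empty(4)
    env = np.empty(4)
    for q in range(n):
        c = living_idx[q]
        i = vox_i[c]
        j = vox_j[c]
        env[0] = field_o2[i, j]
        env[1] = field_glc[i, j]
        env[2] = field_lac[i, j]
        env[3] = field_h[i, j]
        y = states[c]
        nsub = 1
        ok = False
        while nsub <= 64:
            for w in range(S.N_FLUXES):
                vacc[w] = 0.0
            for w in range(4):
                eacc[w] = 0.0
            ok = _heun_try(y, env, p, dt_min, nsub, yout, vacc, eacc,
                          k1, k2, k3, k4, ytmp, vtmp)
            if ok:
                break
            nsub *= 2
        if not ok:
            return c
        for w in range(S.N_METABOLITES):
            y[w] = yout[w]
        for w in range(S.N_FLUXES):
            flux_avg[c, w] += vacc[w]
        scale = volumes[c] / voxel_vol_um3
        acc_o2[i, j] += eacc[0] * scale
        acc_glc[i, j] += eacc[1] * scale
        acc_lac[i, j] += eacc[2] * scale
        acc_h[i, j] += eacc[3] * scale / buffer_e
    return -1
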