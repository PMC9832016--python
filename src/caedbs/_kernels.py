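"""Compiled inner loops for the three-neuron plant and the closed control loop.

Everything here operates on packed float64 vectors so that numba can compile
the whole simulation (plant RK4, delay ring buffers, fuzzy inference and the
controller update) into a single machine-code loop.  The layout of the packed
parameter and state vectors is defined by the index constants below and
re-exported through :mod:`caedbs.params`.

Ionic kinetics follow the Destexhe-type single-compartment formulations for
thalamic relay, reticular and regular-spiking cortical cells (Traub-style
Na/K rates with a per-cell threshold shift, low-threshold Ca currents with
m2h gating, hyperpolarisation-activated and slow K currents for the relay
cell, a muscarinic K current for the cortical cell).
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# packed parameter vector layout (length P_LEN)
# ---------------------------------------------------------------------------
P_C_TC, P_C_CT, P_C_RT = 0, 1, 2
# ionic channels: (gbar, E_rev) pairs; these 28 slots are the drift targets
P_TC_GL, P_TC_EL = 3, 4
P_TC_GNA, P_TC_ENA = 5, 6
P_TC_GK, P_TC_EK = 7, 8
P_TC_GT, P_TC_ECA = 9, 10
P_TC_GH, P_TC_EH = 11, 12
P_TC_GK2, P_TC_EK2 = 13, 14
P_CT_GL, P_CT_EL = 15, 16
P_CT_GNA, P_CT_ENA = 17, 18
P_CT_GK, P_CT_EK = 19, 20
P_CT_GM, P_CT_EM = 21, 22
P_RT_GL, P_RT_EL = 23, 24
P_RT_GNA, P_RT_ENA = 25, 26
P_RT_GK, P_RT_EK = 27, 28
P_RT_GTS, P_RT_ECA = 29, 30
# synaptic maximal conductances
P_G_AMPA_CT_TC = 31
P_G_GABAA_RT_TC = 32
P_G_GABAB = 33
P_G_AMPA_TC_CT = 34
P_G_GABAA_RT_RT = 35
P_G_AMPA_TC_RT = 36
# synaptic reversal potentials and GABA_B half-activation
P_E_AMPA, P_E_GABAA, P_E_GABAB, P_KD = 37, 38, 39, 40
# external currents
P_IEXT_TC, P_IEXT_CT, P_IEXT_RT = 41, 42, 43
# synaptic rate constants
P_A_AMPA, P_B_AMPA, P_A_GABAA, P_B_GABAA = 44, 45, 46, 47
P_K1_GABAB, P_K2_GABAB, P_K3_GABAB, P_K4_GABAB = 48, 49, 50, 51
P_LEN = 52

# indices whose values drift under the parameter-uncertainty protocol
# (ionic maximal conductances and reversal potentials of the three neurons)
DRIFT_INDICES = np.arange(3, 31, dtype=np.int64)

# ---------------------------------------------------------------------------
# packed state vector layout (length S_LEN)
# ---------------------------------------------------------------------------
S_VTC, S_VCT, S_VRT = 0, 1, 2
S_TC_MNA, S_TC_HNA, S_TC_N, S_TC_HT, S_TC_MH, S_TC_MK2, S_TC_HK2 = range(3, 10)
S_CT_MNA, S_CT_HNA, S_CT_N, S_CT_P = range(10, 14)
S_RT_MNA, S_RT_HNA, S_RT_N, S_RT_MTS, S_RT_HTS = range(14, 19)
S_AMPA_CT_TC, S_GABAA_RT_TC, S_GABAB, R_GABAB = 19, 20, 21, 22
S_AMPA_TC_CT, S_GABAA_RT_RT, S_AMPA_TC_RT = 23, 24, 25
S_LEN = 26

# spike-generating Na/K rate threshold shifts (Traub-style), per cell
VT_TC = -52.0
VT_CT = -56.2
VT_RT = -52.0
TAU_MAX_M = 1000.0  # ms, I_M activation time-constant scale

V_GUARD = 150.0  # |V| beyond this is treated as divergence


@njit(cache=True, fastmath=True)
def _vtrap(x, y):
    # x / (exp(x/y) - 1) with the removable singularity at x = 0 patched
    if abs(x / y) < 1e-6:
        return y - 0.5 * x
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True, fastmath=True)
def t_conc(v_pre):
    """Neurotransmitter concentration released by a presynaptic voltage."""
    return 2.84 / (1.0 + math.exp((2.0 - v_pre) / 5.0))


@njit(cache=True, fastmath=True)
def na_k_rates(v, vt, out):
    """Traub-style Na/K rate constants (1/ms); out = (am,bm,ah,bh,an,bn)."""
    w = v - vt
    out[0] = 0.32 * _vtrap(13.0 - w, 4.0)
    out[1] = 0.28 * _vtrap(w - 40.0, 5.0)
    out[2] = 0.128 * math.exp((17.0 - w) / 18.0)
    out[3] = 4.0 / (1.0 + math.exp((40.0 - w) / 5.0))
    out[4] = 0.032 * _vtrap(15.0 - w, 5.0)
    out[5] = 0.5 * math.exp((10.0 - w) / 40.0)


@njit(cache=True, fastmath=True)
def it_tc_gates(v, out):
    """Low-threshold Ca (relay cell): m_inf (instantaneous), h_inf, tau_h."""
    out[0] = 1.0 / (1.0 + math.exp(-(v + 57.0) / 6.2))
    out[1] = 1.0 / (1.0 + math.exp((v + 81.0) / 4.0))
    out[2] = (30.8 + (211.4 + math.exp((v + 113.2) / 5.0))
              / (1.0 + math.exp((v + 84.0) / 3.2))) / 3.73


@njit(cache=True, fastmath=True)
def ih_gates(v, out):
    """Hyperpolarisation-activated mixed cation current: m_inf, tau_m."""
    out[0] = 1.0 / (1.0 + math.exp((v + 75.0) / 5.5))
    out[1] = 20.0 + 1000.0 / (math.exp((v + 71.5) / 14.2)
                              + math.exp(-(v + 89.0) / 11.6))


@njit(cache=True, fastmath=True)
def ik2_gates(v, out):
    """Slow K current (relay cell): m_inf, tau_m, h_inf, tau_h."""
    out[0] = 1.0 / (1.0 + math.exp(-(v + 43.0) / 17.0))
    out[1] = 9.9 + 1.0 / (math.exp((v - 81.0) / 25.6)
                          + math.exp(-(v + 132.0) / 18.0))
    out[2] = 1.0 / (1.0 + math.exp((v + 58.0) / 10.6))
    out[3] = 120.0 + 1.0 / (math.exp((v - 1329.0) / 200.0)
                            + math.exp(-(v + 130.0) / 7.1))


@njit(cache=True, fastmath=True)
def im_gates(v, out):
    """Muscarinic K current (cortical cell): p_inf, tau_p."""
    out[0] = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    out[1] = TAU_MAX_M / (3.3 * math.exp((v + 35.0) / 20.0)
                          + math.exp(-(v + 35.0) / 20.0))


@njit(cache=True, fastmath=True)
def its_rt_gates(v, out):
    """Low-threshold Ca (reticular cell): m_inf, tau_m, h_inf, tau_h."""
    out[0] = 1.0 / (1.0 + math.exp(-(v + 52.0) / 7.4))
    out[1] = 1.0 + 0.33 / (math.exp((v + 27.0) / 10.0)
                           + math.exp(-(v + 102.0) / 15.0))
    out[2] = 1.0 / (1.0 + math.exp((v + 80.0) / 5.0))
    out[3] = 28.3 + 0.33 / (math.exp((v + 48.0) / 4.0)
                            + math.exp(-(v + 407.0) / 50.0))


@njit(cache=True, fastmath=True)
def plant_deriv(y, p, td1, td2, u0, u1, u2, d0, d1, d2, dy):
    """Time derivative of the packed 26-state vector.

    td1 / td2 are the neurotransmitter concentrations driven by the delayed
    presynaptic voltages V_CT(t - tau1) and V_TC(t - tau2); they are frozen
    over an integration step (method of steps).  u* and d* are the control
    and disturbance currents entering each voltage equation additively.
    """
    vtc = y[S_VTC]
    vct = y[S_VCT]
    vrt = y[S_VRT]
    g6 = np.empty(6)
    g4 = np.empty(4)

    # ---- TC (thalamic relay) ionic currents
    i_l = p[P_TC_GL] * (vtc - p[P_TC_EL])
    na_k_rates(vtc, VT_TC, g6)
    m, h, n = y[S_TC_MNA], y[S_TC_HNA], y[S_TC_N]
    i_na = p[P_TC_GNA] * m * m * m * h * (vtc - p[P_TC_ENA])
    i_k = p[P_TC_GK] * n * n * n * n * (vtc - p[P_TC_EK])
    dy[S_TC_MNA] = g6[0] * (1.0 - m) - g6[1] * m
    dy[S_TC_HNA] = g6[2] * (1.0 - h) - g6[3] * h
    dy[S_TC_N] = g6[4] * (1.0 - n) - g6[5] * n
    it_tc_gates(vtc, g4)
    ht = y[S_TC_HT]
    i_t = p[P_TC_GT] * g4[0] * g4[0] * ht * (vtc - p[P_TC_ECA])
    dy[S_TC_HT] = (g4[1] - ht) / g4[2]
    ih_gates(vtc, g4)
    mh = y[S_TC_MH]
    i_h = p[P_TC_GH] * mh * (vtc - p[P_TC_EH])
    dy[S_TC_MH] = (g4[0] - mh) / g4[1]
    ik2_gates(vtc, g4)
    mk2, hk2 = y[S_TC_MK2], y[S_TC_HK2]
    i_k2 = p[P_TC_GK2] * mk2 * hk2 * (vtc - p[P_TC_EK2])
    dy[S_TC_MK2] = (g4[0] - mk2) / g4[1]
    dy[S_TC_HK2] = (g4[2] - hk2) / g4[3]
    i_ion_tc = i_l + i_na + i_k + i_t + i_h + i_k2

    # ---- CT (cortical) ionic currents
    i_l = p[P_CT_GL] * (vct - p[P_CT_EL])
    na_k_rates(vct, VT_CT, g6)
    m, h, n = y[S_CT_MNA], y[S_CT_HNA], y[S_CT_N]
    i_na = p[P_CT_GNA] * m * m * m * h * (vct - p[P_CT_ENA])
    i_k = p[P_CT_GK] * n * n * n * n * (vct - p[P_CT_EK])
    dy[S_CT_MNA] = g6[0] * (1.0 - m) - g6[1] * m
    dy[S_CT_HNA] = g6[2] * (1.0 - h) - g6[3] * h
    dy[S_CT_N] = g6[4] * (1.0 - n) - g6[5] * n
    im_gates(vct, g4)
    pm = y[S_CT_P]
    i_m = p[P_CT_GM] * pm * (vct - p[P_CT_EM])
    dy[S_CT_P] = (g4[0] - pm) / g4[1]
    i_ion_ct = i_l + i_na + i_k + i_m

    # ---- RT (reticular) ionic currents
    i_l = p[P_RT_GL] * (vrt - p[P_RT_EL])
    na_k_rates(vrt, VT_RT, g6)
    m, h, n = y[S_RT_MNA], y[S_RT_HNA], y[S_RT_N]
    i_na = p[P_RT_GNA] * m * m * m * h * (vrt - p[P_RT_ENA])
    i_k = p[P_RT_GK] * n * n * n * n * (vrt - p[P_RT_EK])
    dy[S_RT_MNA] = g6[0] * (1.0 - m) - g6[1] * m
    dy[S_RT_HNA] = g6[2] * (1.0 - h) - g6[3] * h
    dy[S_RT_N] = g6[4] * (1.0 - n) - g6[5] * n
    its_rt_gates(vrt, g4)
    mts, hts = y[S_RT_MTS], y[S_RT_HTS]
    i_ts = p[P_RT_GTS] * mts * mts * hts * (vrt - p[P_RT_ECA])
    dy[S_RT_MTS] = (g4[0] - mts) / g4[1]
    dy[S_RT_HTS] = (g4[2] - hts) / g4[3]
    i_ion_rt = i_l + i_na + i_k + i_ts

    # ---- synaptic gates
    t_rt = t_conc(vrt)
    t_tc = t_conc(vtc)
    a_a, b_a = p[P_A_AMPA], p[P_B_AMPA]
    a_g, b_g = p[P_A_GABAA], p[P_B_GABAA]
    dy[S_AMPA_CT_TC] = a_a * td1 * (1.0 - y[S_AMPA_CT_TC]) - b_a * y[S_AMPA_CT_TC]
    dy[S_GABAA_RT_TC] = a_g * t_rt * (1.0 - y[S_GABAA_RT_TC]) - b_g * y[S_GABAA_RT_TC]
    dy[S_GABAB] = p[P_K1_GABAB] * y[R_GABAB] - p[P_K2_GABAB] * y[S_GABAB]
    dy[R_GABAB] = p[P_K3_GABAB] * t_rt * (1.0 - y[R_GABAB]) - p[P_K4_GABAB] * y[R_GABAB]
    dy[S_AMPA_TC_CT] = a_a * td2 * (1.0 - y[S_AMPA_TC_CT]) - b_a * y[S_AMPA_TC_CT]
    dy[S_GABAA_RT_RT] = a_g * t_rt * (1.0 - y[S_GABAA_RT_RT]) - b_g * y[S_GABAA_RT_RT]
    dy[S_AMPA_TC_RT] = a_a * t_tc * (1.0 - y[S_AMPA_TC_RT]) - b_a * y[S_AMPA_TC_RT]

    # ---- synaptic currents
    s4 = y[S_GABAB] ** 4
    i_syn_tc = (p[P_G_AMPA_CT_TC] * y[S_AMPA_CT_TC] * (vtc - p[P_E_AMPA])
                + p[P_G_GABAA_RT_TC] * y[S_GABAA_RT_TC] * (vtc - p[P_E_GABAA])
                + p[P_G_GABAB] * s4 / (s4 + p[P_KD]) * (vtc - p[P_E_GABAB]))
    i_syn_ct = p[P_G_AMPA_TC_CT] * y[S_AMPA_TC_CT] * (vct - p[P_E_AMPA])
    i_syn_rt = (p[P_G_GABAA_RT_RT] * y[S_GABAA_RT_RT] * (vrt - p[P_E_GABAA])
                + p[P_G_AMPA_TC_RT] * y[S_AMPA_TC_RT] * (vrt - p[P_E_AMPA]))

    dy[S_VTC] = (-i_ion_tc - i_syn_tc + p[P_IEXT_TC] + u0 + d0) / p[P_C_TC]
    dy[S_VCT] = (-i_ion_ct - i_syn_ct + p[P_IEXT_CT] + u1 + d1) / p[P_C_CT]
    dy[S_VRT] = (-i_ion_rt - i_syn_rt + p[P_IEXT_RT] + u2 + d2) / p[P_C_RT]


@njit(cache=True, fastmath=True)
def rk4_step(y, p, td1, td2, u0, u1, u2, d0, d1, d2, dt, k1, k2, k3, k4, yt):
    """One classical RK4 step with delayed synaptic drive frozen."""
    plant_deriv(y, p, td1, td2, u0, u1, u2, d0, d1, d2, k1)
    for i in range(S_LEN):
        yt[i] = y[i] + 0.5 * dt * k1[i]
    plant_deriv(yt, p, td1, td2, u0, u1, u2, d0, d1, d2, k2)
    for i in range(S_LEN):
        yt[i] = y[i] + 0.5 * dt * k2[i]
    plant_deriv(yt, p, td1, td2, u0, u1, u2, d0, d1, d2, k3)
    for i in range(S_LEN):
        yt[i] = y[i] + dt * k3[i]
    plant_deriv(yt, p, td1, td2, u0, u1, u2, d0, d1, d2, k4)
    for i in range(S_LEN):
        y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True, fastmath=True)
def simulate_kernel(y, p, dt, n_steps, n1, n2, u_sched, d_sched, stride, rec):
    """Open-loop simulation with delay ring buffers; records every `stride` steps.

    u_sched / d_sched are (n_sched, 3) arrays sampled at the plant step (held
    at the last row beyond their length).  rec has one row per record of
    [t, state(26), u(3), d(3)].  Returns -1 on success or the step index at
    which the trajectory diverged.
    """
    l1 = max(n1, 1)
    l2 = max(n2, 1)
    vct_buf = np.full(l1, y[S_VCT])
    vtc_buf = np.full(l2, y[S_VTC])
    pos1 = 0
    pos2 = 0
    k1 = np.empty(S_LEN)
    k2 = np.empty(S_LEN)
    k3 = np.empty(S_LEN)
    k4 = np.empty(S_LEN)
    yt = np.empty(S_LEN)
    n_sched_u = u_sched.shape[0]
    n_sched_d = d_sched.shape[0]
    irec = 0
    for step in range(n_steps):
        iu = step if step < n_sched_u else n_sched_u - 1
        idd = step if step < n_sched_d else n_sched_d - 1
        u0, u1, u2 = u_sched[iu, 0], u_sched[iu, 1], u_sched[iu, 2]
        d0, d1, d2 = d_sched[idd, 0], d_sched[idd, 1], d_sched[idd, 2]
        vct_del = vct_buf[pos1] if n1 > 0 else y[S_VCT]
        vtc_del = vtc_buf[pos2] if n2 > 0 else y[S_VTC]
        td1 = t_conc(vct_del)
        td2 = t_conc(vtc_del)
        if step % stride == 0 and irec < rec.shape[0]:
            rec[irec, 0] = step * dt
            for i in range(S_LEN):
                rec[irec, 1 + i] = y[i]
            rec[irec, 27], rec[irec, 28], rec[irec, 29] = u0, u1, u2
            rec[irec, 30], rec[irec, 31], rec[irec, 32] = d0, d1, d2
            irec += 1
        rk4_step(y, p, td1, td2, u0, u1, u2, d0, d1, d2, dt, k1, k2, k3, k4, yt)
        if not (abs(y[S_VTC]) <= V_GUARD and abs(y[S_VCT]) <= V_GUARD
                and abs(y[S_VRT]) <= V_GUARD):
            return step
        if n1 > 0:
            vct_buf[pos1] = y[S_VCT]
            pos1 = (pos1 + 1) % l1
        if n2 > 0:
            vtc_buf[pos2] = y[S_VTC]
            pos2 = (pos2 + 1) % l2
    return -1


@njit(cache=True, fastmath=True)
def basis5(x, centers, inv_delta, mu):
    """Per-input normalized Gaussian membership vector (5,).

    The 125-rule product basis factorizes over the three inputs, so the full
    normalized basis is the outer product of the three per-input softmax-like
    vectors computed here; the max-shift keeps delta = 1 mV well defined.
    """
    mx = -1.0e300
    for i in range(5):
        z = (x - centers[i]) * inv_delta
        mu[i] = -0.5 * z * z
        if mu[i] > mx:
            mx = mu[i]
    ssum = 0.0
    for i in range(5):
        mu[i] = math.exp(mu[i] - mx)
        ssum += mu[i]
    for i in range(5):
        mu[i] /= ssum


@njit(cache=True, fastmath=True)
def build_zeta(x0, x1, x2, centers, inv_delta, mu0, mu1, mu2, zeta):
    basis5(x0, centers, inv_delta, mu0)
    basis5(x1, centers, inv_delta, mu1)
    basis5(x2, centers, inv_delta, mu2)
    k = 0
    for a in range(5):
        for b in range(5):
            w = mu0[a] * mu1[b]
            for c in range(5):
                zeta[k] = w * mu2[c]
                k += 1


@njit(cache=True, fastmath=True)
def _inv3_spd(m, out):
    """Inverse of a symmetric positive-definite 3x3 matrix via adjugate."""
    a, b, c = m[0, 0], m[0, 1], m[0, 2]
    d, e, f = m[1, 1], m[1, 2], m[2, 2]
    co00 = d * f - e * e
    co01 = c * e - b * f
    co02 = b * e - c * d
    det = a * co00 + b * co01 + c * co02
    inv = 1.0 / det
    out[0, 0] = co00 * inv
    out[0, 1] = co01 * inv
    out[0, 2] = co02 * inv
    out[1, 0] = co01 * inv
    out[1, 1] = (a * f - c * c) * inv
    out[1, 2] = (c * b - a * e) * inv
    out[2, 0] = co02 * inv
    out[2, 1] = (c * b - a * e) * inv
    out[2, 2] = (a * d - b * b) * inv


# controller-gain vector layout
CG_ETA, CG_RHO, CG_SIGMA, CG_EPS0, CG_SIGMA0 = 0, 1, 2, 3, 4
CG_KF, CG_KFT, CG_KG, CG_K0 = 5, 6, 7, 8
CG_G0, CG_G1, CG_G2, CG_G3 = 9, 10, 11, 12
CG_UPS0, CG_UPSMIN, CG_UMAX, CG_WCLIP = 13, 14, 15, 16
CG_LAM, CG_KSW, CG_AST, CG_BST = 17, 18, 19, 20
CG_K1AF = 21
CG_LEN = 22

MODE_NONE, MODE_AFTSMC, MODE_AFSMC, MODE_STSMC = 0, 1, 2, 3

# diag vector layout: err2(0:3), sum|du|(3:6), umin(6:9), umax(9:12),
# n_samples(12), diverged_step(13), min Upsilon(14), bound-monotonicity
# violation count(15)
DIAG_LEN = 16


@njit(cache=True, fastmath=True)
def closed_loop_kernel(y_a, y_d, p_a, p_a_nom, p_d, dt, n_steps, n1, n2,
                       mode, dist, dist_target, drift_mult, drift_stride,
                       k1v, k2v, cg, centers, delta,
                       psi_f, psi_ft, psi_g,
                       stride, rec, bounds_log, diag):
    """Run the full closed loop: desired (normal) plant, actual plant, controller.

    y_a/y_d: packed states, modified in place.  p_a is the working parameter
    vector of the actual plant (rewritten from p_a_nom * drift each coarse
    drift step when drift_mult has more than one row).  dist is the
    disturbance current sampled at the plant step (length 1 => none), applied
    to neuron `dist_target` of the actual plant.  rec rows:
    [t, V_a(3), V_d(3), u(3), d(3)]; bounds_log rows:
    [Upsilon, eps_f(3), eps_ft(3), eps_g, d_hat(3)].
    Returns -1 on success, else the divergence step.
    """
    eta = cg[CG_ETA]
    rho = cg[CG_RHO]
    sigma = cg[CG_SIGMA]
    eps0 = cg[CG_EPS0]
    sigma0 = cg[CG_SIGMA0]
    kf = cg[CG_KF]
    kft = cg[CG_KFT]
    kg = cg[CG_KG]
    k0 = cg[CG_K0]
    g0 = cg[CG_G0]
    g1 = cg[CG_G1]
    g2 = cg[CG_G2]
    g3 = cg[CG_G3]
    ups = cg[CG_UPS0]
    ups_min = cg[CG_UPSMIN]
    u_max = cg[CG_UMAX]
    w_clip = cg[CG_WCLIP]
    lam = cg[CG_LAM]
    k_sw = cg[CG_KSW]
    a_st = cg[CG_AST]
    b_st = cg[CG_BST]
    inv_delta = 1.0 / delta

    l1 = max(n1, 1)
    l2 = max(n2, 1)
    # actual-plant delay buffers (V_CT for tau1, V_TC for tau2, V_RT for the
    # delayed-state estimator input) and desired-plant buffers
    a_vct = np.full(l1, y_a[S_VCT])
    a_vtc = np.full(l2, y_a[S_VTC])
    a_vrt = np.full(l1, y_a[S_VRT])
    d_vct = np.full(l1, y_d[S_VCT])
    d_vtc = np.full(l2, y_d[S_VTC])
    pos1 = 0
    pos2 = 0

    k1 = np.empty(S_LEN)
    k2 = np.empty(S_LEN)
    k3 = np.empty(S_LEN)
    k4 = np.empty(S_LEN)
    yt = np.empty(S_LEN)
    xd_dot = np.empty(3)

    mu0 = np.empty(5)
    mu1 = np.empty(5)
    mu2 = np.empty(5)
    zx = np.empty(125)
    zt = np.empty(125)
    fhat = np.empty(3)
    fthat = np.empty(3)
    ghat = np.empty((3, 3))
    mreg = np.empty((3, 3))
    minv = np.empty((3, 3))
    br = np.empty(3)
    vv = np.empty(3)
    u_c = np.empty(3)
    u_0 = np.empty(3)
    u = np.zeros(3)
    u_prev = np.zeros(3)
    e = np.empty(3)
    s = np.empty(3)
    ie = np.zeros(3)
    eps_f = np.zeros(3)
    eps_ft = np.zeros(3)
    d_hat = np.zeros(3)
    eps_g = 0.0
    w_st = np.zeros(3)

    for i in range(3):
        diag[6 + i] = 1.0e300   # umin
        diag[9 + i] = -1.0e300  # umax
    diag[14] = ups

    n_dist = dist.shape[0]
    n_coarse = drift_mult.shape[0]
    have_drift = n_coarse > 1
    irec = 0
    diverged = -1

    for step in range(n_steps):
        if have_drift and step % drift_stride == 0:
            kd = step // drift_stride
            if kd >= n_coarse:
                kd = n_coarse - 1
            for j in range(DRIFT_INDICES.shape[0]):
                idx = DRIFT_INDICES[j]
                p_a[idx] = p_a_nom[idx] * drift_mult[kd, j]

        d_cur = dist[step] if step < n_dist else dist[n_dist - 1]

        # delayed voltages (constant pre-history)
        a_vct_del = a_vct[pos1] if n1 > 0 else y_a[S_VCT]
        a_vtc_del = a_vtc[pos2] if n2 > 0 else y_a[S_VTC]
        a_vrt_del = a_vrt[pos1] if n1 > 0 else y_a[S_VRT]
        d_vct_del = d_vct[pos1] if n1 > 0 else y_d[S_VCT]
        d_vtc_del = d_vtc[pos2] if n2 > 0 else y_d[S_VTC]
        td1_a = t_conc(a_vct_del)
        td2_a = t_conc(a_vtc_del)
        td1_d = t_conc(d_vct_del)
        td2_d = t_conc(d_vtc_del)

        # desired-plant derivative doubles as the exact feedforward xd_dot
        plant_deriv(y_d, p_d, td1_d, td2_d, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, k1)
        xd_dot[0] = k1[0]
        xd_dot[1] = k1[1]
        xd_dot[2] = k1[2]

        for i in range(3):
            e[i] = y_d[i] - y_a[i]
            diag[i] += e[i] * e[i]

        if mode == MODE_AFTSMC:
            ssq = 0.0
            for i in range(3):
                ae = abs(e[i])
                se = 1.0 if e[i] > 0.0 else (-1.0 if e[i] < 0.0 else 0.0)
                s[i] = ie[i] + sigma * ae ** eta * se
                ssq += s[i] * s[i]
            build_zeta(y_a[0], y_a[1], y_a[2], centers, inv_delta,
                       mu0, mu1, mu2, zx)
            build_zeta(a_vtc_del, a_vct_del, a_vrt_del, centers, inv_delta,
                       mu0, mu1, mu2, zt)
            for i in range(3):
                acc_f = 0.0
                acc_ft = 0.0
                for k in range(125):
                    acc_f += psi_f[i, k] * zx[k]
                    acc_ft += psi_ft[i, k] * zt[k]
                fhat[i] = acc_f
                fthat[i] = acc_ft
                for j in range(3):
                    acc_g = 0.0
                    for k in range(125):
                        acc_g += psi_g[i, j, k] * zx[k]
                    ghat[i, j] = acc_g
            inv_es = 1.0 / (eta * sigma)
            for i in range(3):
                ae = abs(e[i])
                se = 1.0 if e[i] > 0.0 else (-1.0 if e[i] < 0.0 else 0.0)
                ss = 1.0 if s[i] > 0.0 else (-1.0 if s[i] < 0.0 else 0.0)
                br[i] = (-fhat[i] - fthat[i] + xd_dot[i]
                         + inv_es * ae ** (2.0 - eta) * se
                         + k1v[i] * s[i] + k2v[i] * abs(s[i]) ** rho * ss)
            for i in range(3):
                for j in range(3):
                    acc = eps0 if i == j else 0.0
                    for k in range(3):
                        acc += ghat[i, k] * ghat[j, k]
                    mreg[i, j] = acc
            _inv3_spd(mreg, minv)
            for i in range(3):
                acc = 0.0
                for j in range(3):
                    acc += minv[i, j] * br[j]
                vv[i] = acc
            for i in range(3):
                acc = 0.0
                for j in range(3):
                    acc += ghat[j, i] * vv[j]
                u_c[i] = acc
                u_0[i] = eps0 * vv[i]
            den = sigma0 * ssq + ups
            sb = 0.0
            adapt_num = 0.0
            for i in range(3):
                ae = abs(e[i])
                wi = eta * sigma * ae ** (eta - 1.0)
                bi = eps_f[i] + eps_ft[i] + eps_g * abs(u_c[i]) + d_hat[i] + abs(u_0[i])
                sb += abs(s[i]) * bi
                adapt_num += abs(s[i]) * wi * bi
            for i in range(3):
                u[i] = u_c[i] + s[i] * sb / den
            # adaptive bound laws (terminal-weighted, all non-negative rates)
            eg_inc = 0.0
            for i in range(3):
                ae = abs(e[i])
                wi = eta * sigma * ae ** (eta - 1.0)
                ws = wi * abs(s[i])
                eps_f[i] += dt * g0 * ws
                eps_ft[i] += dt * g1 * ws
                d_hat[i] += dt * g3 * ws
                eg_inc += ws * abs(u_c[i])
            eps_g += dt * g2 * eg_inc
            ups -= dt * k0 * adapt_num / den
            if ups < ups_min:
                ups = ups_min
            if ups < diag[14]:
                diag[14] = ups
            # fuzzy weight adaptation (terminal gradient laws)
            for i in range(3):
                ae = abs(e[i])
                wi = eta * sigma * ae ** (eta - 1.0)
                cf = -kf * wi * s[i] * dt
                cft = -kft * wi * s[i] * dt
                for k in range(125):
                    wf = psi_f[i, k] + cf * zx[k]
                    psi_f[i, k] = min(max(wf, -w_clip), w_clip)
                    wt = psi_ft[i, k] + cft * zt[k]
                    psi_ft[i, k] = min(max(wt, -w_clip), w_clip)
                for j in range(3):
                    cgij = -kg * wi * s[i] * u_c[j] * dt
                    for k in range(125):
                        wg = psi_g[i, j, k] + cgij * zx[k]
                        psi_g[i, j, k] = min(max(wg, -w_clip), w_clip)
        elif mode == MODE_AFSMC:
            for i in range(3):
                s[i] = e[i] + lam * ie[i]
            build_zeta(y_a[0], y_a[1], y_a[2], centers, inv_delta,
                       mu0, mu1, mu2, zx)
            build_zeta(a_vtc_del, a_vct_del, a_vrt_del, centers, inv_delta,
                       mu0, mu1, mu2, zt)
            for i in range(3):
                acc_f = 0.0
                acc_ft = 0.0
                for k in range(125):
                    acc_f += psi_f[i, k] * zx[k]
                    acc_ft += psi_ft[i, k] * zt[k]
                fhat[i] = acc_f
                fthat[i] = acc_ft
                for j in range(3):
                    acc_g = 0.0
                    for k in range(125):
                        acc_g += psi_g[i, j, k] * zx[k]
                    ghat[i, j] = acc_g
            k1af = cg[CG_K1AF]
            for i in range(3):
                br[i] = (-fhat[i] - fthat[i] + xd_dot[i] + lam * e[i]
                         + k1af * s[i])
            for i in range(3):
                for j in range(3):
                    acc = eps0 if i == j else 0.0
                    for k in range(3):
                        acc += ghat[i, k] * ghat[j, k]
                    mreg[i, j] = acc
            _inv3_spd(mreg, minv)
            for i in range(3):
                acc = 0.0
                for j in range(3):
                    acc += minv[i, j] * br[j]
                vv[i] = acc
            for i in range(3):
                acc = 0.0
                for j in range(3):
                    acc += ghat[j, i] * vv[j]
                u_c[i] = acc
            for i in range(3):
                ss = 1.0 if s[i] > 0.0 else (-1.0 if s[i] < 0.0 else 0.0)
                u[i] = u_c[i] + k_sw * ss
            # classical gradient adaptation on the linear surface
            for i in range(3):
                cf = -kf * s[i] * dt
                cft = -kft * s[i] * dt
                for k in range(125):
                    wf = psi_f[i, k] + cf * zx[k]
                    psi_f[i, k] = min(max(wf, -w_clip), w_clip)
                    wt = psi_ft[i, k] + cft * zt[k]
                    psi_ft[i, k] = min(max(wt, -w_clip), w_clip)
                for j in range(3):
                    cgij = -kg * s[i] * u_c[j] * dt
                    for k in range(125):
                        wg = psi_g[i, j, k] + cgij * zx[k]
                        psi_g[i, j, k] = min(max(wg, -w_clip), w_clip)
        elif mode == MODE_STSMC:
            for i in range(3):
                s[i] = e[i] + lam * ie[i]
                ss = 1.0 if s[i] > 0.0 else (-1.0 if s[i] < 0.0 else 0.0)
                u[i] = a_st * math.sqrt(abs(s[i])) * ss + w_st[i]
                w_st[i] += dt * b_st * ss
        else:
            u[0] = 0.0
            u[1] = 0.0
            u[2] = 0.0

        if u_max > 0.0:
            for i in range(3):
                u[i] = min(max(u[i], -u_max), u_max)

        d0 = d_cur if dist_target == 0 else 0.0
        d1 = d_cur if dist_target == 1 else 0.0
        d2 = d_cur if dist_target == 2 else 0.0

        if step % stride == 0 and irec < rec.shape[0]:
            rec[irec, 0] = step * dt
            for i in range(3):
                rec[irec, 1 + i] = y_a[i]
                rec[irec, 4 + i] = y_d[i]
                rec[irec, 7 + i] = u[i]
            rec[irec, 10] = d0
            rec[irec, 11] = d1
            rec[irec, 12] = d2
            bounds_log[irec, 0] = ups
            for i in range(3):
                bounds_log[irec, 1 + i] = eps_f[i]
                bounds_log[irec, 4 + i] = eps_ft[i]
                bounds_log[irec, 8 + i] = d_hat[i]
            bounds_log[irec, 7] = eps_g
            irec += 1

        if step > 0:
            for i in range(3):
                diag[3 + i] += abs(u[i] - u_prev[i])
        for i in range(3):
            if u[i] < diag[6 + i]:
                diag[6 + i] = u[i]
            if u[i] > diag[9 + i]:
                diag[9 + i] = u[i]
            u_prev[i] = u[i]
            ie[i] += e[i] * dt

        # advance both plants (control and disturbance act on the actual one)
        rk4_step(y_d, p_d, td1_d, td2_d, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                 dt, k1, k2, k3, k4, yt)
        rk4_step(y_a, p_a, td1_a, td2_a, u[0], u[1], u[2], d0, d1, d2,
                 dt, k1, k2, k3, k4, yt)
        ok = True
        for i in range(3):
            if not (abs(y_a[i]) <= V_GUARD and abs(y_d[i]) <= V_GUARD):
                ok = False
        if not ok:
            diverged = step
            break
        if n1 > 0:
            a_vct[pos1] = y_a[S_VCT]
            a_vrt[pos1] = y_a[S_VRT]
            d_vct[pos1] = y_d[S_VCT]
            pos1 = (pos1 + 1) % l1
        if n2 > 0:
            a_vtc[pos2] = y_a[S_VTC]
            d_vtc[pos2] = y_d[S_VTC]
            pos2 = (pos2 + 1) % l2

    diag[12] = float(step + 1 if diverged >= 0 else n_steps)
    diag[13] = float(diverged)
    return diverged
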