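"""Terminal sliding-mode control laws and baselines.

The tracking problem: force the membrane voltages x = (V_TC, V_CT, V_RT) of
the epileptic (CAE) plant to follow the voltages x_d of the healthy plant by
injecting stimulation currents u.  The error e = x_d - x is driven onto the
nonsingular terminal sliding surface

    s_i = int_0^t e_i dt + sigma |e_i|^eta sign(e_i),   sigma > 0, 1 < eta < 2,

via the fast terminal reaching law  ds/dt = -K1 s - K2 |s|^rho sign(s)
(0 < rho < 1).  On the surface the error contracts in finite time
(|e|' = -|e|^(2-eta)/(sigma eta)), giving the settling-time expression
implemented in :func:`settling_time`.

Three controllers are provided:

* the ideal-knowledge law (:func:`ideal_control`) — requires the true f,
  f_tau, G, d and serves as the finite-time-convergence oracle;
* the adaptive fuzzy terminal controller (certainty-equivalent part
  :func:`certainty_control`, robustifying part :func:`robust_term`, adaptive
  bound laws :func:`adapt_bounds`) — deployable without plant knowledge;
* classical adaptive-fuzzy SMC and super-twisting SMC baselines.

All element-wise powers use sign(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K


@dataclass
class SurfaceParams:
    """Terminal surface and reaching-law gains."""
    sigma: float = 0.05
    eta: float = 1.5
    rho: float = 0.6
    k1: np.ndarray = field(default_factory=lambda: np.full(3, 2000.0))
    k2: np.ndarray = field(default_factory=lambda: np.full(3, 400.0))

    def __post_init__(self):
        self.k1 = np.atleast_1d(np.asarray(self.k1, float))
        self.k2 = np.atleast_1d(np.asarray(self.k2, float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (1.0 < self.eta < 2.0):
            raise ValueError("eta must lie in (1, 2)")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if np.any(self.k1 <= 0) or np.any(self.k2 <= 0):
            raise ValueError("K1 and K2 diagonals must be positive")

    @property
    def k1_min(self) -> float:
        return float(self.k1.min())

    @property
    def k2_min(self) -> float:
        return float(self.k2.min())


@dataclass
class AdaptiveBounds:
    """Adaptive estimates of approximation-error / disturbance bounds."""
    eps_f: np.ndarray = field(default_factory=lambda: np.zeros(3))
    eps_ftau: np.ndarray = field(default_factory=lambda: np.zeros(3))
    d_hat: np.ndarray = field(default_factory=lambda: np.zeros(3))
    eps_g: float = 0.0
    upsilon: float = 1.0
    kappa0: float = 0.1
    gamma0: float = 0.1
    gamma1: float = 0.1
    gamma2: float = 1e-3  # eps_g integrates |u_c|-weighted terms; a small
    # rate keeps this monotone bound from winding up over spike-dense runs
    gamma3: float = 0.1
    sigma0: float = 1.0
    eps0: float = 1.0        # regularization of the gain inversion
    upsilon_min: float = 1e-6


@dataclass
class ControllerGains:
    """Complete gain set for the closed-loop kernel (all overridable).

    The published study selected its gains by trial and error and did not
    print them; these defaults were tuned the same way against the nominal
    tracking scenario and are documented in the methods note.
    """
    surface: SurfaceParams = field(default_factory=SurfaceParams)
    bounds: AdaptiveBounds = field(default_factory=AdaptiveBounds)
    kappa_f: float = 10.0
    kappa_ftau: float = 10.0
    kappa_g: float = 10.0
    weight_clip: float = 1e6
    u_max: float = 0.0       # <= 0 disables saturation
    # baseline (AFSMC / STSMC) parameters
    lam: float = 1.0         # linear-surface slope, 1/ms
    k_sw: float = 20.0       # AFSMC switching gain
    k1_afsmc: float = 200.0  # AFSMC proportional surface gain
    a_st: float = 20.0       # super-twisting proportional gain
    b_st: float = 100.0      # super-twisting integral gain

    def pack(self) -> np.ndarray:
        cg = np.zeros(K.CG_LEN)
        sp, b = self.surface, self.bounds
        cg[K.CG_ETA] = sp.eta
        cg[K.CG_RHO] = sp.rho
        cg[K.CG_SIGMA] = sp.sigma
        cg[K.CG_EPS0] = b.eps0
        cg[K.CG_SIGMA0] = b.sigma0
        cg[K.CG_KF] = self.kappa_f
        cg[K.CG_KFT] = self.kappa_ftau
        cg[K.CG_KG] = self.kappa_g
        cg[K.CG_K0] = b.kappa0
        cg[K.CG_G0] = b.gamma0
        cg[K.CG_G1] = b.gamma1
        cg[K.CG_G2] = b.gamma2
        cg[K.CG_G3] = b.gamma3
        cg[K.CG_UPS0] = b.upsilon
        cg[K.CG_UPSMIN] = b.upsilon_min
        cg[K.CG_UMAX] = self.u_max
        cg[K.CG_WCLIP] = self.weight_clip
        cg[K.CG_LAM] = self.lam
        cg[K.CG_KSW] = self.k_sw
        cg[K.CG_AST] = self.a_st
        cg[K.CG_BST] = self.b_st
        cg[K.CG_K1AF] = self.k1_afsmc
        return cg


def sliding_surface(e, int_e, sigma: float, eta: float) -> np.ndarray:
    """Terminal sliding variable s = int_e + sigma |e|^eta sign(e)."""
    e = np.asarray(e, float)
    int_e = np.asarray(int_e, float)
    return int_e + sigma * np.abs(e) ** eta * np.sign(e)


def _reaching_bracket(e, s, sp: SurfaceParams):
    """Shared bracket: (1/(eta sigma))|e|^(2-eta) sign e + K1 s + K2|s|^rho sign s."""
    e = np.asarray(e, float)
    s = np.asarray(s, float)
    return (np.abs(e) ** (2.0 - sp.eta) * np.sign(e) / (sp.eta * sp.sigma)
            + sp.k1 * s + sp.k2 * np.abs(s) ** sp.rho * np.sign(s))


def ideal_control(f, f_tau, g_mat, d, xd_dot, e, s, sp: SurfaceParams
                  ) -> np.ndarray:
    """Exact-knowledge control law (testing oracle, never deployable).

    u = G^-1 (-f - f_tau - d + xd_dot + bracket); substituting it into the
    plant cancels everything but the reaching law.
    """
    g_mat = np.atleast_2d(np.asarray(g_mat, float))
    if abs(np.linalg.det(g_mat)) < 1e-300:
        raise np.linalg.LinAlgError("input-gain matrix G is singular")
    rhs = (-np.asarray(f, float) - np.asarray(f_tau, float)
           - np.asarray(d, float) + np.asarray(xd_dot, float)
           + _reaching_bracket(e, s, sp))
    return np.linalg.solve(g_mat, np.atleast_1d(rhs))


def _regularized_gain(g_hat, eps0: float):
    g_hat = np.atleast_2d(np.asarray(g_hat, float))
    m = g_hat.shape[0]
    return np.linalg.inv(eps0 * np.eye(m) + g_hat @ g_hat.T)


def certainty_control(f_hat, ftau_hat, g_hat, xd_dot, e, s,
                      sp: SurfaceParams, eps0: float) -> np.ndarray:
    """Certainty-equivalent input with regularized gain inversion.

    u_c = G_hat^T (eps0 I + G_hat G_hat^T)^-1 (-f_hat - ftau_hat + xd_dot
          + bracket); finite for any G_hat, including G_hat = 0.
    """
    if eps0 <= 0:
        raise ValueError("eps0 must be positive")
    g_hat = np.atleast_2d(np.asarray(g_hat, float))
    rhs = (-np.asarray(f_hat, float) - np.asarray(ftau_hat, float)
           + np.asarray(xd_dot, float) + _reaching_bracket(e, s, sp))
    return g_hat.T @ _regularized_gain(g_hat, eps0) @ np.atleast_1d(rhs)


def u0_term(f_hat, ftau_hat, g_hat, xd_dot, e, s, sp: SurfaceParams,
            eps0: float) -> np.ndarray:
    """Regularization remainder u0 = eps0 (eps0 I + G G^T)^-1 (bracket rhs)."""
    if eps0 < 0:
        raise ValueError("eps0 must be non-negative")
    g_hat = np.atleast_2d(np.asarray(g_hat, float))
    if eps0 == 0.0:
        return np.zeros(g_hat.shape[0])
    rhs = (-np.asarray(f_hat, float) - np.asarray(ftau_hat, float)
           + np.asarray(xd_dot, float) + _reaching_bracket(e, s, sp))
    return eps0 * _regularized_gain(g_hat, eps0) @ np.atleast_1d(rhs)


def robust_term(s, bounds: AdaptiveBounds, u_c, u_0) -> np.ndarray:
    """Continuous robustifying input.

    u_r = s |s|^T (eps_f + eps_ftau + eps_g |u_c| + d_hat + |u0|)
          / (sigma0 ||s||^2 + Upsilon);  zero at s = 0, signs follow s.
    """
    if bounds.upsilon <= 0:
        raise ValueError("Upsilon must be positive")
    s = np.atleast_1d(np.asarray(s, float))
    b = (bounds.eps_f + bounds.eps_ftau
         + bounds.eps_g * np.abs(np.atleast_1d(u_c))
         + bounds.d_hat + np.abs(np.atleast_1d(u_0)))
    den = bounds.sigma0 * float(s @ s) + bounds.upsilon
    return s * float(np.abs(s) @ b) / den


def total_control(u_c, u_r, u_max: float = 0.0) -> np.ndarray:
    """u = u_c + u_r, with optional symmetric saturation."""
    u = np.asarray(u_c, float) + np.asarray(u_r, float)
    if u_max > 0:
        u = np.clip(u, -u_max, u_max)
    return u


def adapt_bounds(bounds: AdaptiveBounds, e, s, u_c, u_0,
                 sigma: float, eta: float, dt: float) -> AdaptiveBounds:
    """Forward-Euler step of the adaptive bound laws (in place).

    eps_f, eps_ftau, d_hat and eps_g grow with terminal-weighted |s|;
    Upsilon shrinks monotonically and is floored at upsilon_min.
    """
    e = np.asarray(e, float)
    s = np.asarray(s, float)
    w = eta * sigma * np.abs(e) ** (eta - 1.0)
    ws = w * np.abs(s)
    b = (bounds.eps_f + bounds.eps_ftau
         + bounds.eps_g * np.abs(np.atleast_1d(u_c))
         + bounds.d_hat + np.abs(np.atleast_1d(u_0)))
    den = bounds.sigma0 * float(s @ s) + bounds.upsilon
    bounds.upsilon = max(bounds.upsilon - dt * bounds.kappa0 * float(ws @ b) / den,
                         bounds.upsilon_min)
    bounds.eps_f = bounds.eps_f + dt * bounds.gamma0 * ws
    bounds.eps_ftau = bounds.eps_ftau + dt * bounds.gamma1 * ws
    bounds.eps_g = bounds.eps_g + dt * bounds.gamma2 * float(ws @ np.abs(u_c))
    bounds.d_hat = bounds.d_hat + dt * bounds.gamma3 * ws
    return bounds


# ---------------------------------------------------------------------------
# analytic finite-time bounds
# ---------------------------------------------------------------------------

def reaching_time_bound(v0: float, k1_bar: float, k2_bar: float,
                        rho: float) -> float:
    """Upper bound on the time to reach s = 0 from Lyapunov level V(x0) = v0.

    t_r <= 1/(k1_bar (1-rho)) ln((k1_bar V0^((1-rho)/2) + 2^((rho-1)/2) k2_bar)
                                  / (2^((rho-1)/2) k2_bar))
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie in (0, 1)")
    if k1_bar <= 0 or k2_bar <= 0:
        raise ValueError("modified gains must be positive")
    c = 2.0 ** ((rho - 1.0) / 2.0) * k2_bar
    return float(np.log((k1_bar * v0 ** ((1.0 - rho) / 2.0) + c) / c)
                 / (k1_bar * (1.0 - rho)))


def settling_time(sigma: float, eta: float, x_tr: float) -> float:
    """On-surface finite settling time t_s = sigma eta/(eta-1) |x(t_r)|^(eta-1)."""
    if eta <= 1.0:
        raise ValueError("eta must exceed 1")
    return float(sigma * eta / (eta - 1.0) * abs(x_tr) ** (eta - 1.0))


def error_boundary(delta: float, sigma: float, eta: float) -> float:
    """Boundary layer of the tracking error: |e| <= (delta/sigma)^(1/eta)."""
    if eta <= 1.0:
        raise ValueError("eta must exceed 1")
    return float((delta / sigma) ** (1.0 / eta))


def time_bounds(sp: SurfaceParams, v0: float, x_tr: float,
                delta: float, e_scale: float = 1.0) -> dict:
    """Bundle of the three analytic bounds for given surface gains.

    e_scale sets the |e|^(eta-1) weighting entering the modified reaching
    gains k_bar = eta sigma |e|^(eta-1) k.
    """
    w = sp.eta * sp.sigma * abs(e_scale) ** (sp.eta - 1.0)
    return {
        "t_reach": reaching_time_bound(v0, w * sp.k1_min, w * sp.k2_min, sp.rho),
        "t_settle": settling_time(sp.sigma, sp.eta, x_tr),
        "e_bound": error_boundary(delta, sp.sigma, sp.eta),
    }


# ---------------------------------------------------------------------------
# baseline controllers (reconstructions of the comparison methods)
# ---------------------------------------------------------------------------

def afsmc_control(e, int_e, f_hat, ftau_hat, g_hat, xd_dot,
                  lam: float, k1, k_sw: float, eps0: float) -> np.ndarray:
    """Classical adaptive fuzzy SMC on the linear surface s = e + lam int_e.

    Shares the fuzzy estimator interface with the terminal controller but
    uses a discontinuous k_sw sign(s) reaching term (chattering by design).
    """
    if lam <= 0 or k_sw <= 0:
        raise ValueError("lam and k_sw must be positive")
    e = np.asarray(e, float)
    s = e + lam * np.asarray(int_e, float)
    g_hat = np.atleast_2d(np.asarray(g_hat, float))
    rhs = (-np.asarray(f_hat, float) - np.asarray(ftau_hat, float)
           + np.asarray(xd_dot, float) + lam * e + np.asarray(k1, float) * s)
    u_c = g_hat.T @ _regularized_gain(g_hat, eps0) @ np.atleast_1d(rhs)
    return u_c + k_sw * np.sign(s)


def stsmc_control(s, w, a: float, b: float, dt: float):
    """Super-twisting step: u = a sqrt|s| sign s + w,  w' = b sign s.

    Continuous in s; returns (u, w_next).  The sign convention matches the
    error definition e = x_d - x with u entering the plant additively.
    """
    if a <= 0 or b <= 0:
        raise ValueError("super-twisting gains must be positive")
    s = np.asarray(s, float)
    u = a * np.sqrt(np.abs(s)) * np.sign(s) + np.asarray(w, float)
    w_next = np.asarray(w, float) + dt * b * np.sign(s)
    return u, w_next
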