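"""Gaussian-membership fuzzy logic systems used as universal approximators.

The controller approximates the unknown non-delayed dynamics f, delayed
dynamics f_tau and input-gain matrix G of the voltage equations with a bank
of 15 fuzzy logic systems (3 + 3 + 9).  Each FLS takes the three membrane
voltages (current or delayed) as inputs, covers each input with five
Gaussian membership functions, and outputs the weighted average of its
5^3 = 125 rule activations:

    y(x) = psi^T zeta(x),   zeta_k(x) = prod_j mu_jk(x_j) / sum_l prod_j mu_jl

(singleton fuzzifier, product inference, center-average defuzzifier).  The
product basis factorizes over inputs, so zeta is computed exactly as the
outer product of three per-input normalized membership vectors — this keeps
the basis well defined even for the narrow default width (1 mV against
centers 40 mV apart), where the raw rule products underflow to zero between
centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_MF = 5  # membership functions per input
N_RULES = N_MF ** 3
DEFAULT_CENTERS = (-60.0, -40.0, 0.0, 40.0, 60.0)  # mV


@dataclass
class MembershipSpec:
    """Shared membership layout: 5 Gaussian centers per input, one width."""
    centers: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_CENTERS))
    delta: float = 1.0  # mV

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.shape != (N_MF,):
            raise ValueError(f"expected {N_MF} centers, got {self.centers.shape}")
        if self.delta <= 0:
            raise ValueError("membership width delta must be positive")


def membership(x: float, c: float, delta: float) -> float:
    """Gaussian membership grade mu = exp(-((x-c)/delta)^2 / 2)."""
    if delta <= 0:
        raise ValueError("membership width delta must be positive")
    z = (np.asarray(x, dtype=float) - c) / delta
    return np.exp(-0.5 * z * z)


def basis_vector(x, spec: MembershipSpec) -> np.ndarray:
    """Normalized 125-rule product-inference basis zeta(x); sums to 1.

    Computed per-input in the log domain with a max shift, then combined as
    an outer product — algebraically identical to global product
    normalization but immune to underflow at small delta.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (3,):
        raise ValueError("basis input must be a 3-vector of voltages")
    mus = []
    for j in range(3):
        logit = -0.5 * ((x[j] - spec.centers) / spec.delta) ** 2
        m = np.exp(logit - logit.max())
        mus.append(m / m.sum())
    zeta = np.einsum("a,b,c->abc", *mus).ravel()
    return zeta


def fls_eval(zeta: np.ndarray, psi: np.ndarray) -> float:
    """FLS output psi^T zeta (center-average defuzzification)."""
    zeta = np.asarray(zeta, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if zeta.shape != (N_RULES,) or psi.shape != (N_RULES,):
        raise ValueError(f"zeta and psi must both have length {N_RULES}")
    return float(psi @ zeta)


@dataclass
class EstimatorBank:
    """The 15 adaptive fuzzy estimators: f (3), f_tau (3), G entries (9)."""
    spec: MembershipSpec = field(default_factory=MembershipSpec)
    psi_f: np.ndarray = None       # (3, 125)
    psi_ftau: np.ndarray = None    # (3, 125)
    psi_g: np.ndarray = None       # (3, 3, 125)

    def __post_init__(self):
        if self.psi_f is None:
            self.psi_f = np.zeros((3, N_RULES))
        if self.psi_ftau is None:
            self.psi_ftau = np.zeros((3, N_RULES))
        if self.psi_g is None:
            self.psi_g = np.zeros((3, 3, N_RULES))

    @classmethod
    def random(cls, rng: np.random.Generator,
               spec: MembershipSpec | None = None) -> "EstimatorBank":
        """Weights initialized uniformly on [0, 1], the run-start protocol."""
        spec = spec or MembershipSpec()
        return cls(spec=spec,
                   psi_f=rng.uniform(0, 1, (3, N_RULES)),
                   psi_ftau=rng.uniform(0, 1, (3, N_RULES)),
                   psi_g=rng.uniform(0, 1, (3, 3, N_RULES)))

    @property
    def n_estimators(self) -> int:
        return self.psi_f.shape[0] + self.psi_ftau.shape[0] \
            + self.psi_g.shape[0] * self.psi_g.shape[1]

    def evaluate(self, x, x_tau):
        """(f_hat, f_tau_hat, G_hat) at the given inputs."""
        zx = basis_vector(x, self.spec)
        zt = basis_vector(x_tau, self.spec)
        f_hat = self.psi_f @ zx
        ftau_hat = self.psi_ftau @ zt
        g_hat = self.psi_g @ zx
        return f_hat, ftau_hat, g_hat

    def to_dict(self) -> dict:
        return {
            "centers": self.spec.centers.tolist(),
            "delta": self.spec.delta,
            "psi_f": self.psi_f.tolist(),
            "psi_ftau": self.psi_ftau.tolist(),
            "psi_g": self.psi_g.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EstimatorBank":
        return cls(spec=MembershipSpec(np.array(d["centers"]), d["delta"]),
                   psi_f=np.array(d["psi_f"]),
                   psi_ftau=np.array(d["psi_ftau"]),
                   psi_g=np.array(d["psi_g"]))


def adapt_weights(bank: EstimatorBank, e, s, u_c, x, x_tau,
                  kappa_f: float, kappa_ftau: float, kappa_g: float,
                  sigma: float, eta: float, dt: float,
                  clip: float = 1e6) -> None:
    """One forward-Euler step of the terminal-gradient adaptation laws.

    dpsi_f,i   = -kappa_f   * sigma*eta*|e_i|^(eta-1) * zeta(x)     * s_i
    dpsi_ft,i  = -kappa_ft  * sigma*eta*|e_i|^(eta-1) * zeta(x_tau) * s_i
    dpsi_g,ij  = -kappa_g   * sigma*eta*|e_i|^(eta-1) * zeta(x)     * s_i * u_c,j

    Updates vanish as e -> 0 (eta > 1) or s -> 0.  Weights are clipped to
    +-clip as a numerical safeguard for long runs.
    """
    if not (1.0 < eta < 2.0):
        raise ValueError("eta must lie in (1, 2)")
    if min(kappa_f, kappa_ftau, kappa_g) <= 0 or sigma <= 0:
        raise ValueError("adaptation gains and sigma must be positive")
    e = np.asarray(e, float)
    s = np.asarray(s, float)
    u_c = np.asarray(u_c, float)
    zx = basis_vector(x, bank.spec)
    zt = basis_vector(x_tau, bank.spec)
    w = sigma * eta * np.abs(e) ** (eta - 1.0)
    for i in range(3):
        bank.psi_f[i] += dt * (-kappa_f * w[i] * s[i]) * zx
        bank.psi_ftau[i] += dt * (-kappa_ftau * w[i] * s[i]) * zt
        for j in range(3):
            bank.psi_g[i, j] += dt * (-kappa_g * w[i] * s[i] * u_c[j]) * zx
    for arr in (bank.psi_f, bank.psi_ftau, bank.psi_g):
        np.clip(arr, -clip, clip, out=arr)
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError("fuzzy estimator weights became non-finite")
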