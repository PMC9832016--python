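"""Experimental conditions and closed-loop trial harness.

Replicates the study protocols: random initial voltages for the epileptic
and healthy plants on [-60, -20] mV, fuzzy weights uniform on [0, 1],
gamma-process rectangular disturbance pulse trains injected into one
neuron's voltage equation, slow filtered drift of the ionic maximal
conductances and reversal potentials, and tracking-RMSE / chattering
metrics over single trials and re-randomized batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .controller import ControllerGains
from .fuzzy import EstimatorBank, MembershipSpec
from .params import PlantParams, initial_state

CONTROLLER_MODES = {"none": K.MODE_NONE, "aftsmc": K.MODE_AFTSMC,
                    "afsmc": K.MODE_AFSMC, "stsmc": K.MODE_STSMC}
NEURON_INDEX = {"tc": 0, "ct": 1, "rt": 2}


@dataclass
class DisturbanceSpec:
    """Gamma-process rectangular pulse train injected as a current."""
    rate_hz: float = 0.0          # mean pulse onset rate
    amplitude: float = 1.75       # uA/cm2
    width_ms: float = 1.0
    target: str = "ct"            # neuron receiving the pulses
    shape: float = 2.0            # gamma shape parameter of the intervals


@dataclass
class UncertaintySpec:
    """Slow multiplicative drift of ionic gbar / E_rev around nominal."""
    level: float = 0.0            # fraction p in [0, 0.5]
    cutoff_hz: float = 0.05       # LPF natural frequency
    resample_ms: float = 2000.0   # raw uniform-sequence step
    sample_ms: float = 1.0        # drift-trace resolution fed to the kernel


@dataclass
class TrialConfig:
    duration_ms: float = 2000.0
    dt_ms: float = 1e-3
    seed: int = 0
    controller: str = "aftsmc"
    plant_preset: str = "cae"
    desired_preset: str = "normal"
    gains: ControllerGains = field(default_factory=ControllerGains)
    membership: MembershipSpec = field(default_factory=MembershipSpec)
    disturbance: DisturbanceSpec = field(default_factory=DisturbanceSpec)
    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec)
    init_v_range: tuple = (-60.0, -20.0)
    record_every_ms: float = 0.1
    tau1_ms: float = 10.0
    tau2_ms: float = 2.8
    mirror_init: bool = False  # start the actual plant exactly at the desired init

    def __post_init__(self):
        if self.controller not in CONTROLLER_MODES:
            raise ValueError(f"unknown controller {self.controller!r}")
        if not (0.0 <= self.uncertainty.level <= 0.5):
            raise ValueError("uncertainty level must lie in [0, 0.5]")
        if self.disturbance.rate_hz < 0:
            raise ValueError("disturbance rate must be non-negative")


@dataclass
class TrialResult:
    config: TrialConfig
    trajectory: pd.DataFrame      # t_ms, V_* actual/desired, u, d (decimated)
    bounds_log: pd.DataFrame      # adaptive bound trajectories (decimated)
    rmse: np.ndarray              # per-neuron tracking RMSE, mV (full rate)
    chattering: np.ndarray        # per-channel chattering index
    seed: int = 0
    diverged: bool = False
    diverged_at_ms: float | None = None

    def metrics(self) -> dict:
        return {
            "seed": self.seed,
            "rmse_tc_mv": float(self.rmse[0]),
            "rmse_ct_mv": float(self.rmse[1]),
            "rmse_rt_mv": float(self.rmse[2]),
            "chattering_tc": float(self.chattering[0]),
            "chattering_ct": float(self.chattering[1]),
            "chattering_rt": float(self.chattering[2]),
            "diverged": bool(self.diverged),
        }


def rmse(actual, desired=None) -> np.ndarray:
    """Root-mean-square tracking error per channel (columns)."""
    actual = np.asarray(actual, float)
    if desired is not None:
        desired = np.asarray(desired, float)
        if actual.shape != desired.shape:
            raise ValueError("series length mismatch")
        err = actual - desired
    else:
        err = actual
    return np.sqrt(np.mean(err * err, axis=0))


def chattering_index(u: np.ndarray, dt: float) -> np.ndarray:
    """Mean |step-to-step change| of u, normalized by dt and by u's range.

    Dimensionless measure of switching activity; 0 for constant input,
    large for sign-alternating input.  Channels with zero range return 0.
    """
    u = np.atleast_2d(np.asarray(u, float))
    if u.shape[0] < 2:
        raise ValueError("need at least two control samples")
    du = np.mean(np.abs(np.diff(u, axis=0)), axis=0)
    rng = u.max(axis=0) - u.min(axis=0)
    out = np.zeros(u.shape[1])
    nz = rng > 0
    out[nz] = du[nz] / (dt * rng[nz])
    return out


def gamma_pulse_train(rate_hz: float, amplitude: float, width_ms: float,
                      duration_ms: float, dt_ms: float,
                      rng: np.random.Generator,
                      shape: float = 2.0) -> np.ndarray:
    """Rectangular pulse train with gamma-distributed onset intervals.

    Onset intervals are i.i.d. Gamma(shape, scale) with mean 1/rate;
    overlapping pulses merge (the amplitude is set, not summed).
    """
    if width_ms <= 0 or duration_ms <= 0 or dt_ms <= 0:
        raise ValueError("width, duration and dt must be positive")
    n = int(round(duration_ms / dt_ms))
    sig = np.zeros(n)
    if rate_hz == 0.0:
        return sig
    if width_ms * rate_hz / 1000.0 >= 1.0:
        raise ValueError("width * rate >= 1: pulse train would be always on")
    mean_interval_ms = 1000.0 / rate_hz
    scale = mean_interval_ms / shape
    t = float(rng.gamma(shape, scale))
    wn = max(int(round(width_ms / dt_ms)), 1)
    while t < duration_ms:
        i0 = int(t / dt_ms)
        sig[i0: i0 + wn] = amplitude
        t += float(rng.gamma(shape, scale))
    return sig


def parameter_drift(level: float, duration_ms: float,
                    rng: np.random.Generator, n_params: int | None = None,
                    cutoff_hz: float = 0.05, resample_ms: float = 2000.0,
                    sample_ms: float = 1.0) -> np.ndarray:
    """Multiplier schedule (n_samples, n_params) for the ionic parameters.

    Each parameter follows an independent trace: a uniform sequence on
    [-1, 1] resampled every `resample_ms` (linearly interpolated between
    draws), passed through a second-order critically-damped low-pass filter
    with natural frequency `cutoff_hz`, clamped to [-1, 1], scaled by
    `level` and added to 1.  Every multiplier therefore stays within
    [1 - level, 1 + level] by construction.
    """
    if not (0.0 <= level <= 0.5):
        raise ValueError("uncertainty level must lie in [0, 0.5]")
    if n_params is None:
        n_params = len(K.DRIFT_INDICES)
    n = int(round(duration_ms / sample_ms))
    if level == 0.0:
        return np.ones((max(n, 1), n_params))
    n_raw = int(np.ceil(duration_ms / resample_ms)) + 2
    raw = rng.uniform(-1.0, 1.0, size=(n_raw, n_params))
    t_raw = np.arange(n_raw) * resample_ms
    t_out = np.arange(max(n, 1)) * sample_ms
    w0 = 2.0 * np.pi * cutoff_hz / 1000.0  # rad/ms
    y = raw[0].copy()      # start on the sequence: no spin-up transient
    yd = np.zeros(n_params)
    out = np.empty((max(n, 1), n_params))
    u_interp = np.empty_like(out)
    for j in range(n_params):
        u_interp[:, j] = np.interp(t_out, t_raw, raw[:, j])
    for i in range(max(n, 1)):
        ydd = w0 * w0 * (u_interp[i] - y) - 2.0 * w0 * yd
        y = y + sample_ms * yd
        yd = yd + sample_ms * ydd
        out[i] = y
    np.clip(out, -1.0, 1.0, out=out)
    return 1.0 + level * out


def random_initial_conditions(rng: np.random.Generator,
                              plant: PlantParams, desired: PlantParams,
                              v_range=(-60.0, -20.0),
                              spec: MembershipSpec | None = None):
    """Random study-protocol initialization.

    Initial voltages uniform on [v_lo, v_hi] (independently for the actual
    and the desired plant, three neurons each) with gating and synaptic
    gates at their voltage-dependent steady states; fuzzy weights uniform
    on [0, 1].
    """
    lo, hi = min(v_range), max(v_range)
    y_a = initial_state(rng.uniform(lo, hi, 3), plant)
    y_d = initial_state(rng.uniform(lo, hi, 3), desired)
    bank = EstimatorBank.random(rng, spec=spec)
    return y_a, y_d, bank


def run_trial(config: TrialConfig, bank: EstimatorBank | None = None
              ) -> TrialResult:
    """Run one closed-loop (or uncontrolled) trial; fully seeded."""
    rng = np.random.default_rng(config.seed)
    plant = PlantParams.preset(config.plant_preset,
                               tau1=config.tau1_ms, tau2=config.tau2_ms)
    desired = PlantParams.preset(config.desired_preset,
                                 tau1=config.tau1_ms, tau2=config.tau2_ms)
    dt = config.dt_ms
    n1, n2 = plant.delay_steps(dt)
    n_steps = int(round(config.duration_ms / dt))

    y_a, y_d, rand_bank = random_initial_conditions(
        rng, plant, desired, config.init_v_range, spec=config.membership)
    if config.mirror_init:
        y_a = y_d.copy()
    if bank is None:
        bank = rand_bank

    dist_spec = config.disturbance
    if dist_spec.rate_hz > 0:
        dist = gamma_pulse_train(dist_spec.rate_hz, dist_spec.amplitude,
                                 dist_spec.width_ms, config.duration_ms,
                                 dt, rng, dist_spec.shape)
    else:
        dist = np.zeros(1)

    unc = config.uncertainty
    if unc.level > 0:
        drift = parameter_drift(unc.level, config.duration_ms, rng,
                                cutoff_hz=unc.cutoff_hz,
                                resample_ms=unc.resample_ms,
                                sample_ms=unc.sample_ms)
        drift_stride = max(int(round(unc.sample_ms / dt)), 1)
    else:
        drift = np.ones((1, 1))
        drift_stride = 1

    stride = max(int(round(config.record_every_ms / dt)), 1)
    n_rec = (n_steps + stride - 1) // stride
    rec = np.zeros((n_rec, 13))
    bounds_log = np.zeros((n_rec, 11))
    diag = np.zeros(K.DIAG_LEN)
    gains = config.gains
    p_a = plant.pack()
    div = K.closed_loop_kernel(
        y_a, y_d, p_a.copy(), p_a, desired.pack(), dt, n_steps, n1, n2,
        CONTROLLER_MODES[config.controller], dist,
        NEURON_INDEX[dist_spec.target], drift, drift_stride,
        gains.surface.k1 * np.ones(3), gains.surface.k2 * np.ones(3),
        gains.pack(), config.membership.centers, config.membership.delta,
        bank.psi_f, bank.psi_ftau, bank.psi_g,
        stride, rec, bounds_log, diag)

    n_samples = int(diag[12])
    rmse_v = np.sqrt(diag[0:3] / max(n_samples, 1))
    du_mean = diag[3:6] / max(n_samples - 1, 1)
    u_range = diag[9:12] - diag[6:9]
    chat = np.where(u_range > 0, du_mean / (dt * np.maximum(u_range, 1e-300)), 0.0)

    traj_cols = ["t_ms", "V_TC", "V_CT", "V_RT", "Vd_TC", "Vd_CT", "Vd_RT",
                 "u_1", "u_2", "u_3", "d_1", "d_2", "d_3"]
    bl_cols = ["upsilon", "eps_f_1", "eps_f_2", "eps_f_3",
               "eps_ftau_1", "eps_ftau_2", "eps_ftau_3", "eps_g",
               "d_hat_1", "d_hat_2", "d_hat_3"]
    if div >= 0:
        keep = div // stride + 1
        rec = rec[:keep]
        bounds_log = bounds_log[:keep]
    return TrialResult(
        config=config,
        trajectory=pd.DataFrame(rec, columns=traj_cols),
        bounds_log=pd.DataFrame(bounds_log, columns=bl_cols),
        rmse=rmse_v, chattering=chat, seed=config.seed,
        diverged=div >= 0,
        diverged_at_ms=div * dt if div >= 0 else None)


def batch_experiment(base: TrialConfig, n_trials: int, seeds=None,
                     conditions: dict | None = None) -> pd.DataFrame:
    """Batch of independent trials over a condition grid.

    conditions maps a label -> dict of TrialConfig field overrides (dotted
    names reach into nested specs, e.g. "disturbance.amplitude").  Every
    random quantity (inits, weights, pulse onsets, drift) is re-drawn per
    trial from per-trial seeds.  Returns per-condition summary rows
    (mean +- population sd RMSE per neuron) plus per-trial rows.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if seeds is None:
        seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in np.random.SeedSequence(base.seed).spawn(n_trials)]
    if len(seeds) != n_trials:
        raise ValueError("seed list length must equal n_trials")
    conditions = conditions or {"base": {}}
    rows = []
    for label, overrides in conditions.items():
        per_trial = []
        n_div = 0
        for seed in seeds:
            cfg = _override(base, dict(overrides, seed=int(seed)))
            res = run_trial(cfg)
            if res.diverged:
                n_div += 1
                continue
            per_trial.append(res.rmse)
        arr = np.array(per_trial) if per_trial else np.zeros((0, 3))
        for j, neuron in enumerate(("tc", "ct", "rt")):
            rows.append({
                "condition": label, "controller": base.controller,
                "neuron": neuron,
                "mean_rmse_mv": float(arr[:, j].mean()) if len(arr) else np.nan,
                "sd_rmse_mv": float(arr[:, j].std()) if len(arr) else np.nan,
                "n": len(arr), "n_diverged": n_div,
            })
    return pd.DataFrame(rows)


def _override(base: TrialConfig, overrides: dict) -> TrialConfig:
    """Copy of a TrialConfig with (possibly dotted) field overrides."""
    import copy
    cfg = copy.deepcopy(base)
    for key, val in overrides.items():
        obj = cfg
        parts = key.split(".")
        for part in parts[:-1]:
            obj = getattr(obj, part)
        if not hasattr(obj, parts[-1]):
            raise ValueError(f"unknown config field {key!r}")
        setattr(obj, parts[-1], val)
    cfg.__post_init__()
    return cfg
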