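"""Reference API for the three-neuron conductance-based plant.

This module exposes the model as named, individually testable operations —
neurotransmitter release, synaptic gate kinetics, per-channel ionic currents,
the membrane-voltage derivative and its canonical split into non-delayed
dynamics f, delayed dynamics f_tau and the input-gain matrix G — together
with a fixed-step delay-aware simulator.  The heavy lifting for long
simulations is done by the compiled kernels in :mod:`caedbs._kernels`; the
pure-NumPy implementations here mirror that algebra and serve as its
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .params import (PlantParams, STATE_NAMES, TC_CHANNELS, CT_CHANNELS,
                     RT_CHANNELS, initial_state)


class DivergenceError(RuntimeError):
    """Raised when a membrane voltage leaves the +-150 mV guard band."""

    def __init__(self, t_ms):
        super().__init__(f"trajectory diverged at t = {t_ms:.6g} ms")
        self.t_ms = t_ms


class DelayLine:
    """Fixed-step ring buffer of past voltage samples.

    Lookups are restricted to delays that are exact grid multiples, so no
    interpolation is ever performed; queries reaching before t = 0 return the
    configured pre-history (initial) voltage.
    """

    def __init__(self, n_steps: int, fill: float):
        self.n = int(n_steps)
        self.buf = np.full(max(self.n, 1), float(fill))
        self.pos = 0
        self.fill = float(fill)

    def delayed(self) -> float:
        """Value from n_steps ago (the configured delay)."""
        if self.n == 0:
            raise ValueError("zero-delay line holds no history; use the current value")
        return float(self.buf[self.pos])

    def push(self, v: float):
        if self.n > 0:
            self.buf[self.pos] = v
            self.pos = (self.pos + 1) % self.n


@dataclass
class PlantState:
    """Packed model state (voltages, gating, synaptic gates) at time t."""
    y: np.ndarray  # shape (26,)
    t: float = 0.0  # ms

    def as_dict(self):
        return dict(zip(STATE_NAMES, self.y))

    @property
    def v(self) -> np.ndarray:
        return self.y[:3]


def neurotransmitter_release(v_pre: float) -> float:
    """Released transmitter concentration T = 2.84 / (1 + exp((2 - V)/5))."""
    if not np.isfinite(v_pre):
        raise ValueError("presynaptic voltage must be finite")
    return 2.84 / (1.0 + math.exp((2.0 - v_pre) / 5.0))


def synapse_kinetics(s, t_conc, alpha, beta, r=None, kind="first_order"):
    """Time derivatives of a synaptic gate.

    first_order: ds/dt = alpha*T*(1-s) - beta*s (AMPA / GABA_A).
    gabab:       ds/dt = 0.18 r - 0.034 s, dr/dt = 0.5 T (1-r) - 0.0012 r;
                 returns (ds, dr).
    """
    if kind == "first_order":
        if alpha < 0 or beta < 0:
            raise ValueError("rate constants must be non-negative")
        return alpha * t_conc * (1.0 - s) - beta * s
    if kind == "gabab":
        ds = 0.18 * r - 0.034 * s
        dr = 0.5 * t_conc * (1.0 - r) - 0.0012 * r
        return ds, dr
    raise ValueError(f"unknown synapse kind {kind!r}")


_GATE_POWERS = {
    # channel -> (gating-product function over the packed state, cell)
    ("TC", "L"): lambda y: 1.0,
    ("TC", "Na"): lambda y: y[K.S_TC_MNA] ** 3 * y[K.S_TC_HNA],
    ("TC", "K"): lambda y: y[K.S_TC_N] ** 4,
    ("TC", "h"): lambda y: y[K.S_TC_MH],
    ("TC", "K2"): lambda y: y[K.S_TC_MK2] * y[K.S_TC_HK2],
    ("CT", "L"): lambda y: 1.0,
    ("CT", "Na"): lambda y: y[K.S_CT_MNA] ** 3 * y[K.S_CT_HNA],
    ("CT", "K"): lambda y: y[K.S_CT_N] ** 4,
    ("CT", "M"): lambda y: y[K.S_CT_P],
    ("RT", "L"): lambda y: 1.0,
    ("RT", "Na"): lambda y: y[K.S_RT_MNA] ** 3 * y[K.S_RT_HNA],
    ("RT", "K"): lambda y: y[K.S_RT_N] ** 4,
    ("RT", "TS"): lambda y: y[K.S_RT_MTS] ** 2 * y[K.S_RT_HTS],
}
_V_INDEX = {"TC": 0, "CT": 1, "RT": 2}


def ionic_currents(state: PlantState, params: PlantParams, cell: str) -> dict:
    """Per-channel ionic currents (uA/cm2) of one neuron, plus their total.

    The T current of the relay cell uses an instantaneous activation
    m_inf(V)^2 with a gated inactivation state.
    """
    chans = {"TC": TC_CHANNELS, "CT": CT_CHANNELS, "RT": RT_CHANNELS}[cell]
    y = state.y
    v = y[_V_INDEX[cell]]
    out = {}
    for name in chans:
        ch = params.ionic[cell][name]
        if (cell, name) in _GATE_POWERS:
            gate = _GATE_POWERS[(cell, name)](y)
        elif (cell, name) == ("TC", "T"):
            g4 = np.empty(4)
            K.it_tc_gates(v, g4)
            gate = g4[0] ** 2 * y[K.S_TC_HT]
        else:
            raise KeyError(f"unknown channel {cell}/{name}")
        out[name] = ch.gbar * gate * (v - ch.e_rev)
    out["total"] = sum(out[name] for name in chans)
    return out


def synaptic_currents(state: PlantState, params: PlantParams) -> np.ndarray:
    """Total synaptic current per neuron (TC, CT, RT), uA/cm2.

    The presynaptic drives enter through the gate states; delayed voltages
    only affect the gate *kinetics*, so this function needs no delay lookup.
    """
    y = state.y
    s = params.syn
    s4 = y[K.S_GABAB] ** 4
    i_tc = (s.g_ampa_ct_tc * y[K.S_AMPA_CT_TC] * (y[0] - s.e_ampa)
            + s.g_gabaa_rt_tc * y[K.S_GABAA_RT_TC] * (y[0] - s.e_gabaa)
            + s.g_gabab * s4 / (s4 + s.kd) * (y[0] - s.e_gabab))
    i_ct = s.g_ampa_tc_ct * y[K.S_AMPA_TC_CT] * (y[1] - s.e_ampa)
    i_rt = (s.g_gabaa_rt_rt * y[K.S_GABAA_RT_RT] * (y[2] - s.e_gabaa)
            + s.g_ampa_tc_rt * y[K.S_AMPA_TC_RT] * (y[2] - s.e_ampa))
    return np.array([i_tc, i_ct, i_rt])


def membrane_derivative(state: PlantState, params: PlantParams,
                        u=None, d=None) -> np.ndarray:
    """dV/dt (mV/ms) of the three neurons; control/disturbance add as I/C."""
    if not np.all(np.isfinite(state.y)):
        raise DivergenceError(state.t)
    u = np.zeros(3) if u is None else np.asarray(u, dtype=float)
    d = np.zeros(3) if d is None else np.asarray(d, dtype=float)
    c = np.asarray(params.c_m)
    i_ion = np.array([ionic_currents(state, params, cell)["total"]
                      for cell in ("TC", "CT", "RT")])
    i_syn = synaptic_currents(state, params)
    i_ext = np.asarray(params.i_ext)
    return (-i_ion - i_syn + i_ext + u + d) / c


def true_dynamics_split(state: PlantState, params: PlantParams):
    """Canonical MIMO split: dV/dt = f + f_tau + G u + d.

    f_tau collects exactly the synaptic currents whose presynaptic drive is
    delayed (the CT->TC and TC->CT AMPA pathways, fed by V_CT(t-tau1) and
    V_TC(t-tau2) through their gate states); f collects everything else.
    G = diag(1/C) is constant and positive definite with G >= (1/max C) I.
    """
    y = state.y
    s = params.syn
    c = np.asarray(params.c_m)
    i_ampa_ct_tc = s.g_ampa_ct_tc * y[K.S_AMPA_CT_TC] * (y[0] - s.e_ampa)
    i_ampa_tc_ct = s.g_ampa_tc_ct * y[K.S_AMPA_TC_CT] * (y[1] - s.e_ampa)
    f_tau = np.array([-i_ampa_ct_tc, -i_ampa_tc_ct, 0.0]) / c
    f = membrane_derivative(state, params) - f_tau
    g_mat = np.diag(1.0 / c)
    return f, f_tau, g_mat


def step_plant(state: PlantState, params: PlantParams, dt: float,
               vct_line: DelayLine, vtc_line: DelayLine,
               u=None, d=None) -> PlantState:
    """Advance one RK4 step (delayed drives frozen over the step)."""
    u = np.zeros(3) if u is None else np.asarray(u, dtype=float)
    d = np.zeros(3) if d is None else np.asarray(d, dtype=float)
    y = state.y.copy()
    vct_del = vct_line.delayed() if vct_line.n > 0 else y[K.S_VCT]
    vtc_del = vtc_line.delayed() if vtc_line.n > 0 else y[K.S_VTC]
    td1 = neurotransmitter_release(vct_del)
    td2 = neurotransmitter_release(vtc_del)
    scratch = [np.empty(K.S_LEN) for _ in range(5)]
    K.rk4_step(y, params.pack(), td1, td2, u[0], u[1], u[2],
               d[0], d[1], d[2], dt, *scratch)
    if np.any(np.abs(y[:3]) > K.V_GUARD) or not np.all(np.isfinite(y)):
        raise DivergenceError(state.t + dt)
    vct_line.push(y[K.S_VCT])
    vtc_line.push(y[K.S_VTC])
    return PlantState(y=y, t=state.t + dt)


def simulate(params: PlantParams, init=None, duration: float = 2000.0,
             dt: float = 1e-3, u_schedule=None, d_schedule=None,
             record_every: float = 0.1, raise_on_divergence: bool = True
             ) -> pd.DataFrame:
    """Open-loop simulation returning a time-indexed trajectory table.

    init: initial voltages (scalar or 3-vector; gates start at their
    steady state) or a full packed 26-state.  Schedules are (n, 3) input
    current arrays sampled at the plant step, held at their last row.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if init is None:
        init = -65.0
    init = np.asarray(init, dtype=float)
    y = init.copy() if init.size == K.S_LEN else initial_state(init, params)
    n1, n2 = params.delay_steps(dt)
    n_steps = int(round(duration / dt))
    stride = max(int(round(record_every / dt)), 1)
    n_rec = (n_steps + stride - 1) // stride
    rec = np.zeros((n_rec, 1 + K.S_LEN + 6))
    u_sched = np.zeros((1, 3)) if u_schedule is None else np.asarray(u_schedule, float)
    d_sched = np.zeros((1, 3)) if d_schedule is None else np.asarray(d_schedule, float)
    div = K.simulate_kernel(y, params.pack(), dt, n_steps, n1, n2,
                            u_sched, d_sched, stride, rec)
    if div >= 0:
        if raise_on_divergence:
            raise DivergenceError(div * dt)
        rec = rec[: div // stride + 1]
    cols = (["t_ms"] + list(STATE_NAMES)
            + ["u_1", "u_2", "u_3", "d_1", "d_2", "d_3"])
    df = pd.DataFrame(rec, columns=cols)
    df.attrs["final_state"] = y
    df.attrs["diverged_at"] = div * dt if div >= 0 else None
    return df


def spike_times(v: np.ndarray, t: np.ndarray, threshold: float = 0.0
                ) -> np.ndarray:
    """Upward threshold-crossing times of a voltage trace (ms)."""
    v = np.asarray(v)
    idx = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    return np.asarray(t)[idx + 1]


def firing_rate(v: np.ndarray, t: np.ndarray, threshold: float = 0.0) -> float:
    """Mean firing rate in Hz over the trace."""
    st = spike_times(v, t, threshold)
    span_s = (t[-1] - t[0]) / 1000.0
    return len(st) / span_s if span_s > 0 else 0.0


def isi_stats(v: np.ndarray, t: np.ndarray, threshold: float = 0.0) -> dict:
    """Inter-spike-interval summary (ms): n_spikes, mean, cv."""
    st = spike_times(v, t, threshold)
    isi = np.diff(st)
    return {
        "n_spikes": len(st),
        "mean_isi": float(np.mean(isi)) if len(isi) else np.inf,
        "cv_isi": float(np.std(isi) / np.mean(isi)) if len(isi) > 1 else 0.0,
    }
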