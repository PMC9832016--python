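"""Plant parameters, named presets and state initialisation.

The three-neuron corticothalamic motif couples a thalamic relay cell (TC), a
cortical cell (CT) and a reticular thalamic cell (RT) through AMPA, GABA_A
and GABA_B synapses, with a corticothalamic conduction delay tau1 on the
CT->TC pathway and a thalamocortical delay tau2 on the TC->CT pathway.

Two presets are provided:

``normal``
    I_ext^TC = 5 uA/cm2, gbar_GABA_A(RT->TC) = 0.65 mS/cm2 — bursting /
    single-spiking rhythm.
``cae``
    I_ext^TC = 6 uA/cm2, gbar_GABA_A(RT->TC) = 0.32 mS/cm2 — the
    childhood-absence-epilepsy state with a faster tonic spiking rhythm.

The presets differ *only* in those two values.  All units: mV, ms, uA/cm2,
mS/cm2, uF/cm2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._kernels import (  # noqa: F401  (re-exported layout constants)
    DRIFT_INDICES, P_LEN, S_LEN,
)

# channel names per neuron (order matches the packed gbar/E pairs)
TC_CHANNELS = ("L", "Na", "K", "T", "h", "K2")
CT_CHANNELS = ("L", "Na", "K", "M")
RT_CHANNELS = ("L", "Na", "K", "TS")

STATE_NAMES = (
    "V_TC", "V_CT", "V_RT",
    "TC_mNa", "TC_hNa", "TC_n", "TC_hT", "TC_mh", "TC_mK2", "TC_hK2",
    "CT_mNa", "CT_hNa", "CT_n", "CT_p",
    "RT_mNa", "RT_hNa", "RT_n", "RT_mTS", "RT_hTS",
    "s_ampa_ct_tc", "s_gabaa_rt_tc", "s_gabab", "r_gabab",
    "s_ampa_tc_ct", "s_gabaa_rt_rt", "s_ampa_tc_rt",
)


@dataclass
class IonChannel:
    gbar: float  # mS/cm2
    e_rev: float  # mV


def _default_ionic() -> dict:
    # Destexhe-type single-compartment kinetics; conductances per cell type.
    return {
        "TC": {
            "L": IonChannel(0.05, -70.0),
            "Na": IonChannel(90.0, 50.0),
            "K": IonChannel(10.0, -100.0),
            "T": IonChannel(2.0, 120.0),
            "h": IonChannel(0.02, -40.0),
            "K2": IonChannel(0.2, -100.0),
        },
        "CT": {
            "L": IonChannel(0.0205, -70.3),
            "Na": IonChannel(56.0, 50.0),
            "K": IonChannel(6.0, -90.0),
            "M": IonChannel(0.075, -90.0),
        },
        "RT": {
            "L": IonChannel(0.05, -90.0),
            "Na": IonChannel(100.0, 50.0),
            "K": IonChannel(10.0, -100.0),
            "TS": IonChannel(2.3, 120.0),
        },
    }


@dataclass
class SynapseParams:
    """Maximal conductances / reversals of the six pathways (Table-style)."""
    g_ampa_ct_tc: float = 0.1
    g_gabaa_rt_tc: float = 0.65
    g_gabab: float = 0.13793
    g_ampa_tc_ct: float = 4.138
    g_gabaa_rt_rt: float = 6.0
    g_ampa_tc_rt: float = 1.428
    e_ampa: float = 0.0
    e_gabaa: float = -85.0
    e_gabab: float = -95.0
    kd: float = 100.0
    alpha_ampa: float = 0.94
    beta_ampa: float = 0.18
    alpha_gabaa: float = 5.0
    beta_gabaa: float = 0.18
    k1_gabab: float = 0.18
    k2_gabab: float = 0.034
    k3_gabab: float = 0.5
    k4_gabab: float = 0.0012


@dataclass
class PlantParams:
    """Full parameter set of the three-neuron plant."""
    c_m: tuple = (1.0, 1.0, 1.0)  # uF/cm2 (TC, CT, RT)
    ionic: dict = field(default_factory=_default_ionic)
    syn: SynapseParams = field(default_factory=SynapseParams)
    i_ext: tuple = (5.0, 0.0, 0.0)  # uA/cm2 (TC, CT, RT)
    tau1: float = 10.0  # ms, corticothalamic delay (CT -> TC), range 2-10
    tau2: float = 2.8   # ms, thalamocortical delay (TC -> CT)

    def __post_init__(self):
        if any(c <= 0 for c in self.c_m):
            raise ValueError("membrane capacitances must be positive")
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("delays must be non-negative")
        for cell, chans in self.ionic.items():
            for name, ch in chans.items():
                if ch.gbar < 0:
                    raise ValueError(f"gbar({cell}/{name}) must be >= 0")

    @classmethod
    def preset(cls, name: str, **overrides) -> "PlantParams":
        if name == "normal":
            p = cls(i_ext=(5.0, 0.0, 0.0))
            p.syn.g_gabaa_rt_tc = 0.65
        elif name == "cae":
            p = cls(i_ext=(6.0, 0.0, 0.0))
            p.syn.g_gabaa_rt_tc = 0.32
        else:
            raise ValueError(f"unknown preset {name!r} (expected 'normal' or 'cae')")
        for k, v in overrides.items():
            if not hasattr(p, k):
                raise ValueError(f"unknown PlantParams field {k!r}")
            setattr(p, k, v)
        return p

    def replace(self, **kw) -> "PlantParams":
        return dataclasses.replace(self, **kw)

    def pack(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the kernels."""
        p = np.zeros(P_LEN)
        p[K.P_C_TC], p[K.P_C_CT], p[K.P_C_RT] = self.c_m
        base = 3
        for cell, chans in (("TC", TC_CHANNELS), ("CT", CT_CHANNELS),
                            ("RT", RT_CHANNELS)):
            for name in chans:
                ch = self.ionic[cell][name]
                p[base] = ch.gbar
                p[base + 1] = ch.e_rev
                base += 2
        s = self.syn
        p[K.P_G_AMPA_CT_TC] = s.g_ampa_ct_tc
        p[K.P_G_GABAA_RT_TC] = s.g_gabaa_rt_tc
        p[K.P_G_GABAB] = s.g_gabab
        p[K.P_G_AMPA_TC_CT] = s.g_ampa_tc_ct
        p[K.P_G_GABAA_RT_RT] = s.g_gabaa_rt_rt
        p[K.P_G_AMPA_TC_RT] = s.g_ampa_tc_rt
        p[K.P_E_AMPA], p[K.P_E_GABAA], p[K.P_E_GABAB] = s.e_ampa, s.e_gabaa, s.e_gabab
        p[K.P_KD] = s.kd
        p[K.P_IEXT_TC], p[K.P_IEXT_CT], p[K.P_IEXT_RT] = self.i_ext
        p[K.P_A_AMPA], p[K.P_B_AMPA] = s.alpha_ampa, s.beta_ampa
        p[K.P_A_GABAA], p[K.P_B_GABAA] = s.alpha_gabaa, s.beta_gabaa
        p[K.P_K1_GABAB], p[K.P_K2_GABAB] = s.k1_gabab, s.k2_gabab
        p[K.P_K3_GABAB], p[K.P_K4_GABAB] = s.k3_gabab, s.k4_gabab
        return p

    def delay_steps(self, dt: float) -> tuple:
        """(n1, n2) delay buffer lengths; delays must be grid multiples."""
        out = []
        for name, tau in (("tau1", self.tau1), ("tau2", self.tau2)):
            n = tau / dt
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError(
                    f"{name} = {tau} ms is not an integer multiple of dt = {dt} ms")
            out.append(int(round(n)))
        return tuple(out)


def gate_steady_state(v: float, cell: str) -> dict:
    """Voltage-dependent steady states of the gating variables of one cell."""
    g6 = np.empty(6)
    g4 = np.empty(4)
    vt = {"TC": K.VT_TC, "CT": K.VT_CT, "RT": K.VT_RT}[cell]
    K.na_k_rates(v, vt, g6)
    out = {
        "mNa": g6[0] / (g6[0] + g6[1]),
        "hNa": g6[2] / (g6[2] + g6[3]),
        "n": g6[4] / (g6[4] + g6[5]),
    }
    if cell == "TC":
        K.it_tc_gates(v, g4)
        out["hT"] = g4[1]
        K.ih_gates(v, g4)
        out["mh"] = g4[0]
        K.ik2_gates(v, g4)
        out["mK2"] = g4[0]
        out["hK2"] = g4[2]
    elif cell == "CT":
        K.im_gates(v, g4)
        out["p"] = g4[0]
    elif cell == "RT":
        K.its_rt_gates(v, g4)
        out["mTS"] = g4[0]
        out["hTS"] = g4[2]
    return out


def synapse_steady_state(v_tc: float, v_ct: float, v_rt: float,
                         syn: SynapseParams) -> np.ndarray:
    """Fixed points of the seven synaptic gates at frozen voltages."""
    t_ct = float(K.t_conc(v_ct))
    t_tc = float(K.t_conc(v_tc))
    t_rt = float(K.t_conc(v_rt))

    def fo(alpha, t, beta):
        return alpha * t / (alpha * t + beta)

    r = syn.k3_gabab * t_rt / (syn.k3_gabab * t_rt + syn.k4_gabab)
    s_b = syn.k1_gabab * r / syn.k2_gabab
    return np.array([
        fo(syn.alpha_ampa, t_ct, syn.beta_ampa),   # CT -> TC AMPA
        fo(syn.alpha_gabaa, t_rt, syn.beta_gabaa),  # RT -> TC GABA_A
        s_b, r,
        fo(syn.alpha_ampa, t_tc, syn.beta_ampa),   # TC -> CT AMPA
        fo(syn.alpha_gabaa, t_rt, syn.beta_gabaa),  # RT -> RT GABA_A
        fo(syn.alpha_ampa, t_tc, syn.beta_ampa),   # TC -> RT AMPA
    ])


def initial_state(v_init, params: PlantParams) -> np.ndarray:
    """Packed state with gating and synaptic gates at steady state for v_init.

    v_init: scalar (all three voltages) or length-3 (V_TC, V_CT, V_RT).
    """
    v = np.broadcast_to(np.asarray(v_init, dtype=float), (3,)).copy()
    y = np.zeros(S_LEN)
    y[:3] = v
    tc = gate_steady_state(v[0], "TC")
    y[3:10] = [tc["mNa"], tc["hNa"], tc["n"], tc["hT"], tc["mh"],
               tc["mK2"], tc["hK2"]]
    ct = gate_steady_state(v[1], "CT")
    y[10:14] = [ct["mNa"], ct["hNa"], ct["n"], ct["p"]]
    rt = gate_steady_state(v[2], "RT")
    y[14:19] = [rt["mNa"], rt["hNa"], rt["n"], rt["mTS"], rt["hTS"]]
    y[19:26] = synapse_steady_state(v[0], v[1], v[2], params.syn)
    return y
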