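"""Run-configuration loading, validation and result export."""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import yaml

from .controller import AdaptiveBounds, ControllerGains, SurfaceParams
from .fuzzy import MembershipSpec
from .scenarios import (CONTROLLER_MODES, DisturbanceSpec, TrialConfig,
                        TrialResult, UncertaintySpec, NEURON_INDEX)


class ConfigError(ValueError):
    """Configuration problem, naming the offending key and constraint."""


_TOP_KEYS = {"plant", "controller", "scenario", "output", "seed"}
_PLANT_KEYS = {"preset", "desired_preset", "tau1_ms", "tau2_ms"}
_CTRL_KEYS = {"type", "sigma", "eta", "rho", "k1", "k2", "eps0", "sigma0",
              "kappa_f", "kappa_ftau", "kappa_g", "kappa0",
              "gamma0", "gamma1", "gamma2", "gamma3",
              "upsilon0", "upsilon_min", "u_max", "weight_clip",
              "lam", "k_sw", "k1_afsmc", "a_st", "b_st",
              "mf_centers", "mf_delta"}
_SCEN_KEYS = {"duration_ms", "dt_ms", "record_every_ms", "init_v_range",
              "disturbance", "uncertainty"}
_DIST_KEYS = {"rate_hz", "amplitude", "width_ms", "target", "shape"}
_UNC_KEYS = {"level", "cutoff_hz", "resample_ms", "sample_ms"}


def _check_keys(block: dict, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in '{where}' "
            f"(allowed: {sorted(allowed)})")


def load_config(path) -> TrialConfig:
    """Load and validate a YAML or TOML run configuration.

    Missing keys resolve to the documented defaults; unknown keys are
    rejected.  Units throughout: mV, ms, uA/cm2, mS/cm2, uF/cm2.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix in (".toml", ".tml"):
        raw = tomllib.loads(path.read_text())
    else:
        raw = yaml.safe_load(path.read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> TrialConfig:
    _check_keys(raw, _TOP_KEYS, "<top level>")
    plant = dict(raw.get("plant", {}))
    ctrl = dict(raw.get("controller", {}))
    scen = dict(raw.get("scenario", {}))
    _check_keys(plant, _PLANT_KEYS, "plant")
    _check_keys(ctrl, _CTRL_KEYS, "controller")
    _check_keys(scen, _SCEN_KEYS, "scenario")

    ctype = ctrl.pop("type", "aftsmc")
    if ctype not in CONTROLLER_MODES:
        raise ConfigError(
            f"controller.type = {ctype!r}: must be one of {sorted(CONTROLLER_MODES)}")

    try:
        surface = SurfaceParams(
            sigma=ctrl.pop("sigma", 0.05), eta=ctrl.pop("eta", 1.5),
            rho=ctrl.pop("rho", 0.6),
            k1=np.full(3, float(ctrl.pop("k1", 2000.0))),
            k2=np.full(3, float(ctrl.pop("k2", 400.0))))
        bounds = AdaptiveBounds(
            eps0=ctrl.pop("eps0", 1.0), sigma0=ctrl.pop("sigma0", 1.0),
            kappa0=ctrl.pop("kappa0", 0.1),
            gamma0=ctrl.pop("gamma0", 0.1), gamma1=ctrl.pop("gamma1", 0.1),
            gamma2=ctrl.pop("gamma2", 1e-3), gamma3=ctrl.pop("gamma3", 0.1),
            upsilon=ctrl.pop("upsilon0", 1.0),
            upsilon_min=ctrl.pop("upsilon_min", 1e-6))
        gains = ControllerGains(
            surface=surface, bounds=bounds,
            kappa_f=ctrl.pop("kappa_f", 10.0),
            kappa_ftau=ctrl.pop("kappa_ftau", 10.0),
            kappa_g=ctrl.pop("kappa_g", 10.0),
            weight_clip=ctrl.pop("weight_clip", 1e6),
            u_max=ctrl.pop("u_max", 0.0),
            lam=ctrl.pop("lam", 1.0), k_sw=ctrl.pop("k_sw", 20.0),
            k1_afsmc=ctrl.pop("k1_afsmc", 200.0),
            a_st=ctrl.pop("a_st", 20.0), b_st=ctrl.pop("b_st", 100.0))
        membership = MembershipSpec(
            centers=np.asarray(ctrl.pop("mf_centers",
                                        (-60.0, -40.0, 0.0, 40.0, 60.0))),
            delta=ctrl.pop("mf_delta", 1.0))
    except ValueError as exc:
        raise ConfigError(f"controller block: {exc}") from exc

    dist_raw = dict(scen.pop("disturbance", {}))
    unc_raw = dict(scen.pop("uncertainty", {}))
    _check_keys(dist_raw, _DIST_KEYS, "scenario.disturbance")
    _check_keys(unc_raw, _UNC_KEYS, "scenario.uncertainty")
    if dist_raw.get("target", "ct") not in NEURON_INDEX:
        raise ConfigError(
            f"scenario.disturbance.target must be one of {sorted(NEURON_INDEX)}")
    level = unc_raw.get("level", 0.0)
    if not (0.0 <= level <= 0.5):
        raise ConfigError(
            f"scenario.uncertainty.level = {level}: must lie in [0, 0.5]")

    cfg = TrialConfig(
        duration_ms=scen.pop("duration_ms", 2000.0),
        dt_ms=scen.pop("dt_ms", 1e-3),
        seed=int(raw.get("seed", 0)),
        controller=ctype,
        plant_preset=plant.get("preset", "cae"),
        desired_preset=plant.get("desired_preset", "normal"),
        gains=gains, membership=membership,
        disturbance=DisturbanceSpec(**dist_raw),
        uncertainty=UncertaintySpec(**unc_raw),
        init_v_range=tuple(scen.pop("init_v_range", (-60.0, -20.0))),
        record_every_ms=scen.pop("record_every_ms", 0.1),
        tau1_ms=plant.get("tau1_ms", 10.0),
        tau2_ms=plant.get("tau2_ms", 2.8))
    try:
        from .params import PlantParams
        PlantParams.preset(cfg.plant_preset, tau1=cfg.tau1_ms,
                           tau2=cfg.tau2_ms).delay_steps(cfg.dt_ms)
    except ValueError as exc:
        raise ConfigError(f"plant block: {exc}") from exc
    return cfg


def _config_echo(cfg: TrialConfig) -> dict:
    """Fully-resolved configuration for provenance files."""
    g, sp, b = cfg.gains, cfg.gains.surface, cfg.gains.bounds
    return {
        "seed": cfg.seed,
        "plant": {"preset": cfg.plant_preset,
                  "desired_preset": cfg.desired_preset,
                  "tau1_ms": cfg.tau1_ms, "tau2_ms": cfg.tau2_ms},
        "controller": {
            "type": cfg.controller, "sigma": sp.sigma, "eta": sp.eta,
            "rho": sp.rho, "k1": float(sp.k1[0]), "k2": float(sp.k2[0]),
            "eps0": b.eps0, "sigma0": b.sigma0, "kappa0": b.kappa0,
            "gamma0": b.gamma0, "gamma1": b.gamma1, "gamma2": b.gamma2,
            "gamma3": b.gamma3, "upsilon0": b.upsilon,
            "upsilon_min": b.upsilon_min, "kappa_f": g.kappa_f,
            "kappa_ftau": g.kappa_ftau, "kappa_g": g.kappa_g,
            "u_max": g.u_max, "lam": g.lam, "k_sw": g.k_sw,
            "k1_afsmc": g.k1_afsmc, "a_st": g.a_st, "b_st": g.b_st,
            "mf_centers": cfg.membership.centers.tolist(),
            "mf_delta": cfg.membership.delta},
        "scenario": {
            "duration_ms": cfg.duration_ms, "dt_ms": cfg.dt_ms,
            "record_every_ms": cfg.record_every_ms,
            "init_v_range": list(cfg.init_v_range),
            "disturbance": vars(cfg.disturbance).copy(),
            "uncertainty": vars(cfg.uncertainty).copy()},
    }


def export_results(result: TrialResult, outdir, write_hdf5: bool = False):
    """Write trajectory CSV, metrics JSON and the resolved config.

    Every output directory carries the resolved configuration and seed
    needed for exact replay.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        result.trajectory.to_csv(outdir / "trajectory.csv", index=False)
        metrics = result.metrics()
        metrics["diverged_at_ms"] = result.diverged_at_ms
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        (outdir / "config.json").write_text(
            json.dumps(_config_echo(result.config), indent=2))
        if write_hdf5:
            import h5py
            with h5py.File(outdir / "trajectory.h5", "w") as f:
                for col in result.trajectory.columns:
                    f.create_dataset(col, data=result.trajectory[col].values)
                for col in result.bounds_log.columns:
                    f.create_dataset(f"bounds/{col}",
                                     data=result.bounds_log[col].values)
    except OSError as exc:
        raise OSError(f"failed writing results under {outdir}: {exc}") from exc
    return outdir


def export_batch(table, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "summary.csv", index=False)
    return outdir / "summary.csv"
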