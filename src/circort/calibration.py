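"""Calibration of the small set of free coupling/scale parameters.

The committed defaults already satisfy the calibration phenotypes; this
module provides the machinery that produced them and lets a user re-run the
fit after changing pinned parameters.  The targets are the physiological
phenotypes of the entrained and free-running system:

* habitual wake just before 07:00 and sleep onset near 23:00, with a sleep
  episode of roughly 8 h;
* circadian sleep drive peaking near 16:00;
* free-running cortisol period between 24.1 and 24.5 h;
* cortisol peaking within a few hours after wake;
* peripheral GR occupancy near one half at the cortisol nadir.

The objective is a weighted quadratic penalty over target residuals
(each scaled by its tolerance), minimized with bounded Nelder-Mead; the
objective involves limit-cycle simulations and is non-smooth at switching
boundaries, so derivative-free search is the appropriate tool.  Weights
implement the priority order period > sleep timing > cortisol phase >
occupancy.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import yaml
from scipy.optimize import minimize

from . import metrics as metrics_mod
from .params import ModelParams, default_params, to_dict
from .sleepwake import wake_sleep_times

__all__ = ["CalibrationTarget", "CalibrationTargetSet", "measure_phenotypes",
           "calibrate", "CalibrationResult"]


@dataclass(frozen=True)
class CalibrationTarget:
    """One phenotype target: value, tolerance, and penalty weight."""

    value: float
    tol: float
    weight: float = 1.0
    kind: str = "eq"  # eq | le | ge | range (value is the band center)
    band: float = 0.0  # half-width for kind="range"

    def residual(self, measured: float) -> float:
        """Tolerance-scaled residual (0 inside the allowed region)."""
        if self.kind == "le":
            excess = max(0.0, measured - self.value)
        elif self.kind == "ge":
            excess = max(0.0, self.value - measured)
        elif self.kind == "range":
            excess = max(0.0, abs(measured - self.value) - self.band)
        else:
            excess = abs(measured - self.value)
        return excess / self.tol


def default_targets() -> dict[str, CalibrationTarget]:
    return {
        "nominal_wake_h": CalibrationTarget(7.0, 0.5, weight=3.0, kind="le"),
        "nominal_sleep_h": CalibrationTarget(23.0, 0.5, weight=3.0),
        "nominal_sleep_duration_h": CalibrationTarget(8.0, 0.5, weight=3.0),
        "circadian_sleep_drive_peak_h": CalibrationTarget(16.0, 1.0, weight=3.0),
        "free_run_period_h": CalibrationTarget(24.3, 0.2, weight=5.0,
                                               kind="range", band=0.2),
        "cortisol_peak_after_wake_h": CalibrationTarget(1.0, 2.0, weight=2.0,
                                                        kind="range", band=2.0),
        "gr_nadir_occupancy": CalibrationTarget(0.5, 0.15, weight=1.0),
    }


@dataclass(frozen=True)
class CalibrationTargetSet:
    targets: dict[str, CalibrationTarget] = field(default_factory=default_targets)

    def penalty(self, measured: dict[str, float]) -> float:
        total = 0.0
        for name, tgt in self.targets.items():
            if name in measured:
                total += tgt.weight * tgt.residual(measured[name]) ** 2
        return total

    def report(self, measured: dict[str, float]) -> dict[str, Any]:
        out = {}
        for name, tgt in self.targets.items():
            m = measured.get(name)
            r = None if m is None else tgt.residual(m)
            out[name] = {"measured": m, "target": tgt.value, "tol": tgt.tol,
                         "kind": tgt.kind, "residual": r,
                         "pass": None if r is None else bool(r <= 1.0)}
        return out


def measure_phenotypes(params: ModelParams | None = None,
                       settle_days: int = 12,
                       free_run_days: int = 30) -> dict[str, float]:
    """Simulate the phenotypes the calibration targets refer to.

    Uses moderately short horizons (the committed adapted state is a good
    starting point for any nearby parameter set, so a dozen settling days
    suffice for timing phenotypes; the free-running period uses the
    shortest horizon the peak-interval estimator accepts).
    """
    from . import engine, protocols
    from .hpa import free_running_period

    p = params if params is not None else default_params()
    st = engine.SimulationSettings(t0=0.0, t_end=24.0 * settle_days,
                                   output_dt=0.1)
    traj = engine.integrate(protocols.make_nominal_protocol(), p, st)
    df = traj.df[traj.df["time_h"] >= st.t_end - 72.0]
    wake, sleep = wake_sleep_times(df["time_h"], df["Qm"], df["Qv"])
    fd = traj.final_day()
    m = metrics_mod.rhythm_metrics(fd["clock_h"].to_numpy(),
                                   fd["CORT"].to_numpy())
    c_peak = float(fd["clock_h"].iloc[fd["C"].to_numpy().argmax()])
    i_nadir = int(fd["CORT"].to_numpy().argmin())
    out = {
        "nominal_wake_h": wake,
        "nominal_sleep_h": sleep,
        "nominal_sleep_duration_h": (wake - sleep) % 24.0,
        "circadian_sleep_drive_peak_h": c_peak,
        "cortisol_peak_after_wake_h": metrics_mod.circular_delay(m.peak_time,
                                                                 wake),
        "gr_nadir_occupancy": float(fd["occ_GR"].iloc[i_nadir]),
    }
    out["free_run_period_h"] = free_running_period(p,
                                                   horizon_days=free_run_days)
    return out


@dataclass
class CalibrationResult:
    params: ModelParams
    measured: dict[str, float]
    report: dict[str, Any]
    penalty: float
    n_evaluations: int

    def write(self, params_path, report_path) -> None:
        with open(params_path, "w") as fh:
            yaml.safe_dump(to_dict(self.params), fh, sort_keys=False)
        with open(report_path, "w") as fh:
            json.dump({"penalty": self.penalty, "targets": self.report,
                       "n_evaluations": self.n_evaluations}, fh, indent=2)


def _get(p: ModelParams, dotted: str) -> float:
    section, name = dotted.split(".")
    return getattr(getattr(p, section), name)


def _set(p: ModelParams, dotted: str, value: float) -> ModelParams:
    section, name = dotted.split(".")
    sub = replace(getattr(p, section), **{name: value})
    return replace(p, **{section: sub})


def calibrate(free_params: dict[str, tuple[float, float]] | None = None,
              targets: CalibrationTargetSet | None = None,
              start: ModelParams | None = None,
              max_iter: int = 60,
              settle_days: int = 12,
              free_run_days: int = 30) -> CalibrationResult:
    """Fit the named free parameters to the calibration targets.

    ``free_params`` maps dotted parameter names (e.g. ``"sleepwake.A_v"``)
    to ``(lower, upper)`` bounds; at most 10 are allowed.  With an empty
    set the current parameters are simply evaluated and reported.  The
    optimization is deterministic (fixed start, fixed Nelder-Mead
    settings), so repeated runs give identical parameter files.
    """
    free_params = free_params or {}
    if len(free_params) > 10:
        raise ValueError("free parameter subset must stay small (<= 10)")
    tset = targets if targets is not None else CalibrationTargetSet()
    p0 = start if start is not None else default_params()
    n_eval = 0

    def evaluate(p: ModelParams) -> tuple[float, dict[str, float]]:
        nonlocal n_eval
        n_eval += 1
        try:
            measured = measure_phenotypes(p, settle_days=settle_days,
                                          free_run_days=free_run_days)
        except (RuntimeError, ValueError):
            return 1e6, {}
        return tset.penalty(measured), measured

    if not free_params:
        pen, measured = evaluate(p0)
        return CalibrationResult(p0, measured, tset.report(measured), pen,
                                 n_eval)

    names = sorted(free_params)
    lo = np.array([free_params[n][0] for n in names])
    hi = np.array([free_params[n][1] for n in names])
    x0 = np.array([_get(p0, n) for n in names])
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("starting point outside bounds")

    def objective(x: np.ndarray) -> float:
        xc = np.clip(x, lo, hi)
        p = p0
        for name, val in zip(names, xc):
            p = _set(p, name, float(val))
        pen, _ = evaluate(p)
        # quadratic penalty for leaving the box keeps the simplex inside
        pen += float(np.sum(((x - xc) / (hi - lo)) ** 2)) * 100.0
        return pen

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 1e-3,
                            "fatol": 1e-3, "adaptive": True})
    x_best = np.clip(res.x, lo, hi)
    p_best = p0
    for name, val in zip(names, x_best):
        p_best = _set(p_best, name, float(val))
    pen, measured = evaluate(p_best)
    return CalibrationResult(p_best, measured, tset.report(measured), pen,
                             n_eval)
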