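"""Coupled integration of the full 19-state model under a protocol.

The state vector stacks the circadian pacemaker (x, y, n), the sleep/wake
switch (Vv, Vm, H), the central HPA axis (CRH, ACTH, CORT, GR mRNA, free GR,
DR, DRN), and the peripheral receptor pools (MR, GR and their bound
complexes).  The vector field is smooth except for three kinds of switching:
the behavioral sleep indicator (sign of Qm - Qv), the wake gate on light
(sign of Qm - Qth), and the time-scheduled forcing/stress windows.  The
integrator treats every switching instant as a breakpoint: state-dependent
switches are located by `solve_ivp` event detection and time-scheduled edges
are pre-computed, and integration restarts at each one so the stiff solver
never steps across a discontinuity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import circadian as cm
from . import hpa as hm
from . import receptors as rm
from . import sleepwake as sm
from .params import (ModelParams, STATE_NAMES, adapted_nominal_state,
                     default_params)
from .protocols import Protocol

__all__ = ["SimulationSettings", "Trajectory", "integrate",
           "run_to_steady_cycle"]

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
log = logging.getLogger("circort.engine")


@dataclass(frozen=True)
class SimulationSettings:
    """Integration and sampling controls (time in hours, t=0 is midnight)."""

    t0: float = 0.0
    t_end: float = 24.0 * 30
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    max_step: float = 0.25
    output_dt: float = 0.1
    transient_days: int = 0
    seed: int = 0          # reserved; all dynamics are deterministic
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.t_end <= self.t0:
            raise ValueError("t_end must exceed t0")
        if self.output_dt <= 0.0:
            raise ValueError("output_dt must be > 0")
        if self.transient_days * 24.0 >= self.t_end - self.t0:
            raise ValueError("transient longer than the simulation span")


class Trajectory:
    """Sampled solution: a DataFrame plus run metadata.

    Columns: ``time_h`` (hours since t=0 midnight), ``clock_h``, the 19
    state variables, and the derived signals ``I_raw``, ``I_eff``, ``C``,
    ``SCNdrive``, ``Qv``, ``Qm``, ``is_asleep``, ``occ_MR``, ``occ_GR``.
    """

    def __init__(self, df: pd.DataFrame, metadata: dict[str, Any]):
        t = df["time_h"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.isfinite(df.to_numpy()).all():
            raise ValueError("trajectory contains NaN/Inf")
        self.df = df
        self.metadata = metadata

    def final_day(self) -> pd.DataFrame:
        """Rows of the last full 24 h of the run."""
        t_end = self.df["time_h"].iloc[-1]
        return self.df[self.df["time_h"] >= t_end - 24.0].reset_index(drop=True)

    def day(self, i: int) -> pd.DataFrame:
        t0 = self.df["time_h"].iloc[0]
        lo = t0 + 24.0 * i
        sel = (self.df["time_h"] >= lo) & (self.df["time_h"] <= lo + 24.0)
        return self.df[sel].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _stress_windows(protocol: Protocol, t0: float, t_end: float):
    """Absolute-time stress windows [(start, end, gain), ...]."""
    n_days = max(1, int(np.ceil((t_end - t0) / 24.0 - 1e-9)))
    out = []
    for pulse in protocol.stress_pulses:
        if pulse.gain == 1.0:
            continue  # null stressor: identical to the base run
        day = pulse.day if pulse.day >= 0 else n_days + pulse.day
        start = t0 - (t0 % 24.0) + 24.0 * day + pulse.onset_h
        out.append((start, start + pulse.duration_h, pulse.gain))
    return out


def _stress_gain(t: float, windows) -> float:
    g = 1.0
    for start, end, gain in windows:
        if start <= t < end:
            g *= gain
    return g


def _schedule_breakpoints(protocol: Protocol, windows, t0: float,
                          t_end: float) -> np.ndarray:
    edges = set()
    day0 = int(np.floor(t0 / 24.0))
    day1 = int(np.ceil(t_end / 24.0))
    for onset, wake in protocol.forced_sleep_windows:
        for d in range(day0 - 1, day1 + 1):
            edges.add(24.0 * d + onset)
            edges.add(24.0 * d + (wake if wake > onset else wake + 24.0))
    for start, end, _ in windows:
        edges.add(start)
        edges.add(end)
    pts = sorted(e for e in edges if t0 < e < t_end)
    return np.array(pts + [t_end], dtype=float)


def _make_rhs(protocol: Protocol, p: ModelParams, windows, mode: dict):
    """Vector field with the discrete mode (asleep/gate) held fixed."""
    forced = not protocol.is_free
    swp, cp, hp, rp = p.sleepwake, p.circadian, p.hpa, p.receptors

    def rhs(t: float, yv: np.ndarray) -> np.ndarray:
        x, y, n = yv[0], yv[1], yv[2]
        Vv, Vm, H = yv[3], yv[4], yv[5]
        cstate = cm.CircadianState(x=x, y=y, n=min(max(n, 0.0), 1.0))
        sstate = sm.SleepWakeState(Vv=Vv, Vm=Vm, H=H)

        I_raw = float(protocol.light.raw_intensity(t))
        I_eff = I_raw if mode["gate_open"] else 0.0
        alpha = cm.photic_alpha(I_eff, cp)
        B = cm.photic_drive(cstate, I_eff, cp)
        dx, dy, dn = cm.circadian_derivatives(cstate, B, alpha, cp)

        C = cm.sleep_circadian_drive(cstate)
        if forced:
            if protocol.scheduled_asleep(t):
                forcing = sm.ForcingTerms(sleep_pressure=protocol.sleep_pressure)
            else:
                forcing = sm.ForcingTerms(wake_effort=protocol.wake_effort)
        else:
            forcing = None
        dVv, dVm, dH = sm.sleepwake_derivatives(sstate, C, forcing, swp)

        S = cm.scn_drive(cstate, cp)
        hstate = hm.HPAState(CRH=max(yv[6], 0.0), ACTH=max(yv[7], 0.0),
                             CORT=max(yv[8], 0.0), GR_mRNA=max(yv[9], 0.0),
                             GR_free=max(yv[10], 0.0), DR=max(yv[11], 0.0),
                             DRN=max(yv[12], 0.0))
        gain = _stress_gain(t, windows)
        dhpa = hm.hpa_derivatives(hstate, S, 1.0 if mode["asleep"] else 0.0,
                                  gain, hp)

        rstate = rm.PeripheralReceptorState(
            MR=yv[13], GR=yv[14], F_MR=yv[15], F_MR_N=yv[16],
            F_GR=yv[17], F_GR_N=yv[18])
        drec = rm.receptor_derivatives(rstate, max(yv[8], 0.0), rp)

        out = np.empty(19)
        out[0], out[1], out[2] = dx, dy, dn
        out[3], out[4], out[5] = dVv, dVm, dH
        out[6:13] = dhpa
        out[13:19] = drec
        return out

    return rhs


def _mode_from_state(yv: np.ndarray, p: ModelParams) -> dict:
    Qv = float(sm.firing_rate(yv[_IDX["Vv"]], p.sleepwake))
    Qm = float(sm.firing_rate(yv[_IDX["Vm"]], p.sleepwake))
    return {"asleep": not (Qm > Qv), "gate_open": Qm > p.sleepwake.Qth}


def integrate(protocol: Protocol, params: ModelParams | None = None,
              settings: SimulationSettings | None = None,
              initial_state: np.ndarray | None = None) -> Trajectory:
    """Integrate the coupled model over ``[t0, t_end]`` under ``protocol``.

    Returns a dense-sampled :class:`Trajectory`.  Light-gate and sleep/wake
    switching times are located by event detection and used as integration
    breakpoints together with the protocol's scheduled edges.
    """
    p = params if params is not None else default_params()
    st = settings if settings is not None else SimulationSettings()
    y_cur = (np.array(initial_state, dtype=float) if initial_state is not None
             else adapted_nominal_state())
    if y_cur.shape != (19,):
        raise ValueError("initial state must be a 19-vector")

    windows = _stress_windows(protocol, st.t0, st.t_end)
    breakpoints = _schedule_breakpoints(protocol, windows, st.t0, st.t_end)
    mode = _mode_from_state(y_cur, p)
    rhs = _make_rhs(protocol, p, windows, mode)
    swp = p.sleepwake

    def ev_switch(t, yv):
        return (sm.firing_rate(yv[4], swp) - sm.firing_rate(yv[3], swp))

    def ev_gate(t, yv):
        return sm.firing_rate(yv[4], swp) - swp.Qth

    ev_switch.terminal = True
    ev_gate.terminal = True

    grid = st.t0 + st.output_dt * np.arange(
        int(np.floor((st.t_end - st.t0) / st.output_dt + 1e-9)) + 1)
    times = [st.t0]
    states = [y_cur.copy()]
    n_transitions = 0
    next_grid = 1  # grid[0] already recorded

    t_cur = st.t0
    bp_iter = iter(breakpoints)
    t_next = next(bp_iter)
    while t_cur < st.t_end - 1e-10:
        # +1 when the zero is approached from below in the current mode
        ev_switch.direction = 1.0 if mode["asleep"] else -1.0
        ev_gate.direction = -1.0 if mode["gate_open"] else 1.0
        sol = solve_ivp(rhs, (t_cur, t_next), y_cur, method=st.method,
                        rtol=st.rel_tol, atol=st.abs_tol,
                        max_step=st.max_step, dense_output=True,
                        events=[ev_switch, ev_gate])
        if sol.status < 0:
            raise RuntimeError(f"solver failed near t={sol.t[-1]:.3f} h: "
                               f"{sol.message}")
        t_reached = sol.t[-1]
        while next_grid < grid.size and grid[next_grid] <= t_reached + 1e-12:
            ts = grid[next_grid]
            times.append(ts)
            states.append(sol.sol(min(ts, t_reached)))
            next_grid += 1
        y_cur = sol.y[:, -1].copy()
        if sol.status == 1:  # state event: flip the triggering mode bit
            if sol.t_events[0].size:
                mode["asleep"] = not mode["asleep"]
                n_transitions += 1
            if sol.t_events[1].size:
                mode["gate_open"] = not mode["gate_open"]
            t_cur = t_reached
        else:
            t_cur = t_next
        while t_next - t_cur < 1e-10 and t_cur < st.t_end - 1e-10:
            t_next = next(bp_iter)

    df = _assemble(np.array(times), np.vstack(states), protocol, p)
    meta = {"settings": st, "n_sleep_wake_transitions": n_transitions,
            "protocol": protocol}
    traj = Trajectory(df, meta)
    if st.transient_days:
        cut = st.t0 + 24.0 * st.transient_days
        traj.df = traj.df[traj.df["time_h"] >= cut].reset_index(drop=True)
    return traj


def _assemble(t: np.ndarray, y: np.ndarray, protocol: Protocol,
              p: ModelParams) -> pd.DataFrame:
    df = pd.DataFrame(y, columns=list(STATE_NAMES))
    df.insert(0, "time_h", t)
    df.insert(1, "clock_h", np.mod(t, 24.0))
    df["Qv"] = sm.firing_rate(df["Vv"].to_numpy(), p.sleepwake)
    df["Qm"] = sm.firing_rate(df["Vm"].to_numpy(), p.sleepwake)
    df["is_asleep"] = (~(df["Qm"].to_numpy() > df["Qv"].to_numpy())).astype(int)
    df["C"] = 0.55 * (1.0 + 0.8 * df["y"].to_numpy() - 0.47 * df["x"].to_numpy())
    df["SCNdrive"] = cm.scn_drive_xy(df["x"].to_numpy(), df["y"].to_numpy(),
                                     p.circadian)
    I_raw = np.asarray(protocol.light.raw_intensity(t), dtype=float)
    df["I_raw"] = I_raw
    df["I_eff"] = np.where(df["Qm"].to_numpy() > p.sleepwake.Qth, I_raw, 0.0)
    df["occ_MR"] = rm.occupancy_series(df["F_MR"], df["F_MR_N"], p.receptors.MR.R_T)
    df["occ_GR"] = rm.occupancy_series(df["F_GR"], df["F_GR_N"], p.receptors.GR.R_T)
    return df


def run_to_steady_cycle(protocol: Protocol, params: ModelParams | None = None,
                        settings: SimulationSettings | None = None,
                        start_state: np.ndarray | None = None,
                        tol: float = 1e-4, max_days: int = 120,
                        analysis_days: int = 2) -> Trajectory:
    """Integrate until the daily cycle has adapted, then return the final days.

    Adaptation is declared when the full state at two consecutive midnights
    agrees within ``tol`` (per-state relative sup-norm).  Stress pulses are
    withheld during adaptation and applied only in the final analysis
    window, matching their definition as acute perturbations of the adapted
    rhythm.  Raises ``RuntimeError`` if the cycle has not adapted within
    ``max_days``.
    """
    p = params if params is not None else default_params()
    st = settings if settings is not None else SimulationSettings()
    adapt_proto = replace(protocol, stress_pulses=())
    y = (np.array(start_state, dtype=float) if start_state is not None
         else adapted_nominal_state())

    scale = np.maximum(np.abs(y), 0.05)
    last_diff = np.inf
    adapted_at = None
    coarse = replace(st, t0=0.0, t_end=24.0, output_dt=1.0, transient_days=0)
    for day in range(max_days):
        seg = integrate(adapt_proto, p, replace(coarse, t0=24.0 * day,
                                                t_end=24.0 * (day + 1)),
                        initial_state=y)
        y_new = seg.df.iloc[-1][list(STATE_NAMES)].to_numpy(dtype=float)
        scale = np.maximum.reduce([scale, np.abs(y_new)])
        last_diff = float(np.max(np.abs(y_new - y) / scale))
        y = y_new
        log.debug("day %d: residual %.3e", day + 1, last_diff)
        if last_diff < tol:
            adapted_at = day + 1
            break
    if adapted_at is None:
        raise RuntimeError(
            f"no adapted cycle within {max_days} days "
            f"(last day-to-day discrepancy {last_diff:.2e})")

    t0 = 24.0 * adapted_at
    final = integrate(protocol, p,
                      replace(st, t0=t0, t_end=t0 + 24.0 * analysis_days,
                              transient_days=0),
                      initial_state=y)
    final.metadata["adaptation_day"] = adapted_at
    final.metadata["adaptation_residual"] = last_diff
    return final
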