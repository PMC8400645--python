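"""Mutual-inhibition sleep/wake switch with homeostatic sleep pressure.

Mean-field model of the sleep-promoting ventrolateral-preoptic (VLPO) and
wake-promoting monoaminergic (MA) neuronal populations.  Each population is
described by its mean membrane potential (mV); mutual inhibition plus a
slowly accumulating homeostatic pressure ``H`` and the circadian drive
``C(t)`` produce flip-flop switching between consolidated wake and sleep.
The behavioral state is wake whenever the MA firing rate exceeds the VLPO
firing rate.

Potentials are in mV, firing rates in 1/s, time in hours (the population
time constants are a few seconds, i.e. ~1e-3 h: the switch itself is fast
compared with everything it drives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SleepWakeParams",
    "SleepWakeState",
    "BehavioralState",
    "ForcingTerms",
    "firing_rate",
    "sleepwake_derivatives",
    "classify_state",
    "detect_transitions",
]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class SleepWakeParams:
    """Parameters of the VLPO/MA flip-flop.

    Defaults follow the Phillips-Robinson lineage, with the baseline drives
    and circadian coupling calibrated so that under the nominal 12 h / 1000
    lux photoperiod the model sleeps from about 23:00 to just before 07:00.
    """

    tau_v: float = 10.0 / SECONDS_PER_HOUR   # VLPO time constant (h)
    tau_m: float = 10.0 / SECONDS_PER_HOUR   # MA time constant (h)
    nu_vm: float = 2.1     # VLPO inhibition by MA (mV s)
    nu_mv: float = 1.8     # MA inhibition by VLPO (mV s)
    chi: float = 45.0      # homeostatic time constant (h)
    mu: float = 3.2        # homeostatic gain (nM s)
    A_v: float = -7.6      # VLPO baseline drive (mV)
    A_m: float = 1.3       # MA baseline drive (mV)
    nu_vc: float = -3.0    # circadian coupling to VLPO (mV per unit C)
    nu_vh: float = 1.0     # homeostatic coupling (mV/nM)
    Qmax: float = 100.0    # maximal firing rate (1/s)
    theta: float = 10.0    # sigmoid midpoint (mV)
    sigma: float = 3.0     # sigmoid width (mV)
    Qth: float = 1.0       # wake gate threshold (1/s), shared with the light gate

    def __post_init__(self) -> None:
        for name in ("tau_v", "tau_m", "chi", "Qmax", "sigma", "Qth"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SleepWakeState:
    Vv: float = -1.0   # VLPO mean potential (mV)
    Vm: float = 0.0    # MA mean potential (mV)
    H: float = 12.0    # homeostatic pressure (nM)


@dataclass(frozen=True)
class BehavioralState:
    is_asleep: bool


@dataclass(frozen=True)
class ForcingTerms:
    """Additive schedule-forcing drives (mV) used to impose sleep/wake times.

    ``sleep_pressure`` is added to the VLPO drive during scheduled sleep.
    ``wake_effort`` models arousal-mediated forced wakefulness as an equal
    *suppression* of the VLPO drive during scheduled wake: silencing the
    sleep-promoting population flips and holds the switch in the wake state
    without saturating the monoaminergic firing rate (which an excitatory
    drive of the required size would do, and with it the homeostatic
    pressure).  Both default to zero (free, endogenous sleep).
    """

    wake_effort: float = 0.0
    sleep_pressure: float = 0.0


def firing_rate(V, p: SleepWakeParams):
    """Sigmoidal mean firing rate ``Qmax / (1 + exp(-(V - theta)/sigma))``."""
    return p.Qmax / (1.0 + np.exp(-(np.asarray(V, dtype=float) - p.theta) / p.sigma))


def sleepwake_derivatives(s: SleepWakeState, C: float,
                          forcing: ForcingTerms | None,
                          p: SleepWakeParams) -> tuple[float, float, float]:
    """Time derivatives (dVv/dt, dVm/dt, dH/dt) in mV/h and nM/h.

    The VLPO drive is ``Dv = A_v + nu_vc C + nu_vh H`` plus any forced
    sleep pressure, minus any forced wake effort (see
    :class:`ForcingTerms`); the MA drive is the constant ``Dm = A_m``.
    """
    if forcing is None:
        forcing = ForcingTerms()
    Qv = float(firing_rate(s.Vv, p))
    Qm = float(firing_rate(s.Vm, p))
    Dv = (p.A_v + p.nu_vc * C + p.nu_vh * s.H
          + forcing.sleep_pressure - forcing.wake_effort)
    Dm = p.A_m
    dVv = (-s.Vv - p.nu_vm * Qm + Dv) / p.tau_v
    dVm = (-s.Vm - p.nu_mv * Qv + Dm) / p.tau_m
    dH = (-s.H + p.mu * Qm) / p.chi
    return dVv, dVm, dH


def classify_state(Qm: float, Qv: float) -> BehavioralState:
    """Wake iff ``Qm > Qv``; the tie ``Qm == Qv`` counts as sleep."""
    return BehavioralState(is_asleep=not (Qm > Qv))


def detect_transitions(time_h, Qm, Qv) -> list[tuple[float, str]]:
    """Locate sleep/wake transitions on a sampled trajectory.

    Finds sign changes of ``Qm - Qv`` and refines each crossing by linear
    root bracketing between the neighboring samples (well below 1 min error
    for the sampling grids used here).  Returns ``(clock_hour, kind)`` pairs
    with ``kind`` in {"sleep->wake", "wake->sleep"}; clock hours are the
    absolute times reduced modulo 24.

    Raises ``ValueError`` if the trajectory spans less than one full day.
    """
    time_h = np.asarray(time_h, dtype=float)
    d = np.asarray(Qm, dtype=float) - np.asarray(Qv, dtype=float)
    if time_h.size < 2 or time_h[-1] - time_h[0] < 24.0:
        raise ValueError("trajectory must span at least one full day")
    out: list[tuple[float, str]] = []
    sign = d > 0.0  # True = wake
    flips = np.nonzero(sign[1:] != sign[:-1])[0]
    for i in flips:
        t0, t1 = time_h[i], time_h[i + 1]
        d0, d1 = d[i], d[i + 1]
        t_cross = t0 if d1 == d0 else t0 - d0 * (t1 - t0) / (d1 - d0)
        kind = "sleep->wake" if sign[i + 1] else "wake->sleep"
        out.append((float(np.mod(t_cross, 24.0)), kind))
    return out


def wake_sleep_times(time_h, Qm, Qv) -> tuple[float, float]:
    """Clock hours of the last sleep->wake and wake->sleep transitions."""
    trans = detect_transitions(time_h, Qm, Qv)
    wake = [t for t, k in trans if k == "sleep->wake"]
    sleep = [t for t, k in trans if k == "wake->sleep"]
    if not wake or not sleep:
        raise ValueError("no complete sleep/wake cycle found")
    return wake[-1], sleep[-1]
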