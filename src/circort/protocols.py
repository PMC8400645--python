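"""Declarative experimental protocols: nominal entrainment, chronic sleep
restriction (CSR) schedules, evening-light exposure, and acute stress pulses.

A :class:`Protocol` bundles the light schedule, any forced sleep windows
(imposed schedules), and any stress pulses over the simulation horizon.  CSR
is imposed by schedule forcing on the VLPO drive: a strong wake-effort
suppression outside the allowed sleep window and an additive sleep-promoting
drive inside it, so all state variables stay continuous while the realized
behavioral state follows the imposed schedule.

The three CSR conditions restrict a habitual (23:00, 07:00) sleep episode by
``r`` hours: ``b1_symmetric`` delays sleep onset by r/2 and advances wake by
r/2 (window midpoint preserved), ``b2_delay_sleep`` delays onset by r with
wake unchanged, and ``b3_advance_wake`` advances wake by r with onset
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lightcycle import (LightSchedule, make_evening_light_schedule,
                         make_nominal_schedule)

__all__ = [
    "Protocol",
    "StressPulse",
    "CSRCondition",
    "make_nominal_protocol",
    "make_dark_protocol",
    "make_csr_protocol",
    "make_evening_light_protocol",
    "make_stress_protocol",
    "sweep",
]

#: Habitual sleep window (clock hours) realized by the adapted nominal model
#: (sleep just before 23:00, wake just before 07:00); CSR schedules restrict
#: this window.
HABITUAL_SLEEP = (22.8646, 6.6233)

#: Forcing drive magnitudes (mV); strong enough to dominate the endogenous
#: switch across the full CSR grid (homeostatic pressure reaches ~25 mV of
#: VLPO drive under 4 h restriction).
WAKE_EFFORT_MV = 30.0
SLEEP_PRESSURE_MV = 15.0


@dataclass(frozen=True)
class StressPulse:
    """Transient multiplicative increase of the CRH synthesis rate.

    ``day`` indexes simulation days; negative values count from the end of
    the run (default -1: the final, adapted day).
    """

    onset_h: float
    duration_h: float = 0.5
    gain: float = 3.0
    day: int = -1

    def __post_init__(self) -> None:
        if self.gain < 1.0:
            raise ValueError("stress gain must be >= 1")
        if self.duration_h <= 0.0:
            raise ValueError("stress duration must be > 0")


def _window_hours(window: tuple[float, float]) -> float:
    onset, wake = window
    return (wake - onset) % 24.0


@dataclass(frozen=True)
class Protocol:
    """Imposed light and sleep/wake schedule plus optional stress pulses."""

    light: LightSchedule = field(default_factory=make_nominal_schedule)
    forced_sleep_windows: tuple[tuple[float, float], ...] = ()
    stress_pulses: tuple[StressPulse, ...] = ()
    duration_days: int = 30
    wake_effort: float = WAKE_EFFORT_MV
    sleep_pressure: float = SLEEP_PRESSURE_MV

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        marks = np.zeros(24 * 60, dtype=bool)
        for onset, wake in self.forced_sleep_windows:
            dur = _window_hours((onset, wake))
            if dur <= 0.0 or dur >= 24.0:
                raise ValueError("forced sleep window must lie within one day")
            idx = (np.arange(int(round(dur * 60))) + int(round(onset * 60))) % (24 * 60)
            if marks[idx].any():
                raise ValueError("forced sleep windows overlap")
            marks[idx] = True

    @property
    def is_free(self) -> bool:
        return len(self.forced_sleep_windows) == 0

    def scheduled_asleep(self, t: float) -> bool:
        """Whether clock/absolute hour ``t`` lies in a forced sleep window."""
        clock = t % 24.0
        for onset, wake in self.forced_sleep_windows:
            if (clock - onset) % 24.0 < _window_hours((onset, wake)):
                return True
        return False


@dataclass(frozen=True)
class CSRCondition:
    """One chronic-sleep-restriction schedule manipulation."""

    kind: str  # b1_symmetric | b2_delay_sleep | b3_advance_wake
    restriction_hours: float

    KINDS = ("b1_symmetric", "b2_delay_sleep", "b3_advance_wake")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        if not (0.0 <= self.restriction_hours <= 5.0):
            raise ValueError("restriction_hours must lie in [0, 5]")


def make_nominal_protocol(duration_days: int = 30) -> Protocol:
    """Nominal light schedule, free (endogenous) sleep, no stress."""
    return Protocol(light=make_nominal_schedule(), duration_days=duration_days)


def make_dark_protocol(duration_days: int = 40) -> Protocol:
    """Constant darkness (0 lux) with free sleep: the free-running condition."""
    dark = replace(make_nominal_schedule(),
                   base=replace(make_nominal_schedule().base, l1=0.0, l2=0.0))
    return Protocol(light=dark, duration_days=duration_days)


def make_csr_protocol(cond: CSRCondition,
                      habitual: tuple[float, float] = HABITUAL_SLEEP,
                      duration_days: int = 30) -> Protocol:
    """Forced-schedule protocol for one CSR condition.

    A zero-restriction condition forces the habitual window itself (which,
    matching the endogenous schedule, reproduces the nominal trajectory to
    solver tolerance).
    """
    onset, wake = habitual
    habitual_dur = _window_hours(habitual)
    r = cond.restriction_hours
    if r >= habitual_dur:
        raise ValueError("restriction must be smaller than habitual sleep duration")
    if cond.kind == "b1_symmetric":
        window = ((onset + r / 2.0) % 24.0, (wake - r / 2.0) % 24.0)
    elif cond.kind == "b2_delay_sleep":
        window = ((onset + r) % 24.0, wake)
    else:  # b3_advance_wake
        window = (onset, (wake - r) % 24.0)
    return Protocol(light=make_nominal_schedule(),
                    forced_sleep_windows=(window,),
                    duration_days=duration_days)


def make_evening_light_protocol(evening_lux: float,
                                duration_days: int = 30) -> Protocol:
    """Free sleep under the nominal day profile plus evening light (0-40 lux)."""
    return Protocol(light=make_evening_light_schedule(evening_lux),
                    duration_days=duration_days)


def make_stress_protocol(base: Protocol, onset_clock_h: float,
                         duration_h: float = 0.5, gain: float = 3.0) -> Protocol:
    """``base`` plus one stress pulse on the final simulated (adapted) day."""
    pulse = StressPulse(onset_h=onset_clock_h, duration_h=duration_h,
                        gain=gain, day=-1)
    return replace(base, stress_pulses=base.stress_pulses + (pulse,))


def stress_response_curve(base: Protocol, onsets, params=None, settings=None,
                          gain: float = 3.0, duration_h: float = 0.5,
                          ) -> pd.DataFrame:
    """Cortisol stress responsivity (delta-AUC) versus stressor onset time.

    Adapts ``base`` to its steady cycle once, then for each onset clock hour
    integrates a stressed and an unstressed continuation over the same 28 h
    window and reports the 4 h cortisol AUC difference.
    """
    from dataclasses import replace as _replace

    from . import engine, metrics

    traj = engine.run_to_steady_cycle(base, params, settings)
    from .params import STATE_NAMES

    t0 = traj.df["time_h"].iloc[0]
    y0 = traj.df.iloc[0][list(STATE_NAMES)].to_numpy(dtype=float)
    st = settings if settings is not None else engine.SimulationSettings()
    st = _replace(st, t0=t0, t_end=t0 + 28.0, transient_days=0)
    plain = _replace(base, stress_pulses=())
    ref = engine.integrate(plain, params, st, initial_state=y0)
    rows = []
    for onset in onsets:
        stressed_proto = _replace(plain, stress_pulses=(
            StressPulse(onset_h=float(onset), duration_h=duration_h,
                        gain=gain, day=0),))
        stressed = engine.integrate(stressed_proto, params, st,
                                    initial_state=y0)
        resp = metrics.stress_delta_auc(stressed, ref, float(onset))
        rows.append({"onset_h": float(onset), "delta_auc": resp.delta_auc})
    out = pd.DataFrame(rows)
    out.attrs["gain"] = gain
    out.attrs["duration_h"] = duration_h
    return out


def sweep(conditions: dict[str, Protocol], params=None, settings=None,
          reference: str | None = None) -> pd.DataFrame:
    """Run each protocol to its steady cycle and tabulate rhythm metrics.

    Returns one row per condition with the cortisol rhythm metrics and the
    MR/GR occupancy extrema; if ``reference`` names a condition (default:
    ``"nominal"`` when present), cortisol peak-time phase delays are
    reported relative to it.
    """
    from . import engine, metrics

    if not conditions:
        raise ValueError("need at least one condition")
    if reference is None and "nominal" in conditions:
        reference = "nominal"
    rows = {}
    for name, proto in conditions.items():
        traj = engine.run_to_steady_cycle(proto, params, settings)
        day = traj.final_day()
        m = metrics.rhythm_metrics(day["clock_h"].to_numpy(),
                                   day["CORT"].to_numpy())
        rows[name] = {
            "peak_time": m.peak_time, "peak_level": m.peak_level,
            "nadir_time": m.nadir_time, "nadir_level": m.nadir_level,
            "amplitude": m.amplitude,
            "occ_MR_min": float(day["occ_MR"].min()),
            "occ_MR_max": float(day["occ_MR"].max()),
            "occ_GR_min": float(day["occ_GR"].min()),
            "occ_GR_max": float(day["occ_GR"].max()),
            "adaptation_day": traj.metadata.get("adaptation_day"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if reference is not None:
        ref_peak = table.loc[reference, "peak_time"]
        table["phase_delay_h"] = [
            metrics.circular_delay(pt, ref_peak) for pt in table["peak_time"]
        ]
    table.index.name = "condition"
    return table
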