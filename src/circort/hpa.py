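"""Goodwin-type HPA axis with central glucocorticoid-receptor feedback.

CRH -> ACTH -> CORT cascade with Michaelis-Menten degradation of each
hormone, driven by the rectified SCN signal (which multiplies CRH synthesis
through a saturating gain in [1, 2]) and inhibited by sleep (which raises
the CRH clearance rate).  Negative feedback closes through a central
glucocorticoid receptor compartment: cortisol binds free GR, the complex
translocates to the nucleus, and the nuclear complex DR(N) represses CRH and
ACTH synthesis as well as GR mRNA transcription.

Hormone concentrations are in arbitrary model units; all rates per hour.
Phase and amplitude readouts used elsewhere are unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HPAParams",
    "HPAState",
    "hpa_derivatives",
    "free_running_period",
]


@dataclass(frozen=True)
class HPAParams:
    """Rate constants of the central HPA cascade and GR feedback loop.

    ``Kp1`` and ``Kp2`` are the feedback inhibition constants (smaller
    values = stronger negative feedback); ``ks`` is the fractional increase
    in CRH clearance while asleep.
    """

    kp1: float = 0.4835        # zero-order CRH synthesis (conc/h)
    kp2: float = 0.967        # first-order ACTH synthesis (1/h)
    kp3: float = 0.6795        # first-order CORT synthesis (1/h)
    Kp1: float = 0.5        # CRH feedback inhibition constant (conc)
    Kp2: float = 0.5        # ACTH feedback inhibition constant (conc)
    Vd1: float = 0.42064        # max CRH degradation rate (conc/h)
    Vd2: float = 0.42064        # max ACTH degradation rate (conc/h)
    Vd3: float = 0.63097        # max CORT degradation rate (conc/h)
    Kd1: float = 0.37        # CRH degradation Michaelis constant (conc)
    Kd2: float = 0.37        # ACTH degradation Michaelis constant (conc)
    Kd3: float = 0.6        # CORT degradation Michaelis constant (conc)
    ks: float = 0.3         # sleep gain on CRH clearance (dimensionless)
    ksyn_GRm: float = 0.1963   # GR mRNA synthesis (1/h)
    IC50_GRm: float = 0.3   # DRN repression of GR mRNA (conc)
    kdeg_GRm: float = 0.10516   # GR mRNA degradation (1/h)
    ksyn_GR: float = 0.3914    # GR translation (1/h)
    rf: float = 0.49        # recycled receptor fraction
    kre: float = 0.8       # nuclear export/recycling (1/h)
    kon: float = 0.5714        # CORT-GR binding (1/(conc h))
    kdeg_GR: float = 0.07011   # free GR degradation (1/h)
    kT: float = 0.8        # nuclear translocation (1/h)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rf <= 1.0):
            raise ValueError("rf must lie in [0, 1]")
        for name in ("kp1", "kp2", "kp3", "Kp1", "Kp2", "Vd1", "Vd2", "Vd3",
                     "Kd1", "Kd2", "Kd3", "ksyn_GRm", "IC50_GRm", "kdeg_GRm",
                     "ksyn_GR", "kre", "kon", "kdeg_GR", "kT"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class HPAState:
    CRH: float = 0.5
    ACTH: float = 0.5
    CORT: float = 0.5
    GR_mRNA: float = 0.5
    GR_free: float = 0.5
    DR: float = 0.2      # cytosolic CORT-GR complex
    DRN: float = 0.2     # nuclear CORT-GR complex


def hpa_derivatives(s: HPAState, SCNdrive: float, is_asleep: float,
                    stress_gain: float, p: HPAParams) -> tuple[float, ...]:
    """Time derivatives of the seven central HPA states (conc/h).

    ``SCNdrive >= 0`` enters CRH synthesis through the saturating gain
    ``1 + S/(1+S)``; ``is_asleep`` (0/1) raises CRH clearance by the factor
    ``1 + ks``; ``stress_gain >= 1`` multiplies CRH synthesis only (an acute
    stressor is a transient rise in the CRH synthesis rate).
    """
    if min(s.CRH, s.ACTH, s.CORT, s.GR_mRNA, s.GR_free, s.DR, s.DRN) < 0.0:
        raise ValueError("negative HPA state component")
    if stress_gain < 1.0:
        raise ValueError("stress_gain must be >= 1")
    drive = 1.0 + SCNdrive / (1.0 + SCNdrive)
    dCRH = (stress_gain * p.kp1 * drive * p.Kp1 / (p.Kp1 + s.DRN)
            - p.Vd1 * s.CRH * (1.0 + p.ks * is_asleep) / (p.Kd1 + s.CRH))
    dACTH = (p.kp2 * s.CRH * p.Kp2 / (p.Kp2 + s.DRN)
             - p.Vd2 * s.ACTH / (p.Kd2 + s.ACTH))
    dCORT = p.kp3 * s.ACTH - p.Vd3 * s.CORT / (p.Kd3 + s.CORT)
    dGRm = (p.ksyn_GRm * (1.0 - s.DRN / (p.IC50_GRm + s.DRN))
            - p.kdeg_GRm * s.GR_mRNA)
    dGR = (p.ksyn_GR * s.GR_mRNA + p.rf * p.kre * s.DRN
           - p.kon * s.CORT * s.GR_free - p.kdeg_GR * s.GR_free)
    dDR = p.kon * s.CORT * s.GR_free - p.kT * s.DR
    dDRN = p.kT * s.DR - p.kre * s.DRN
    return dCRH, dACTH, dCORT, dGRm, dGR, dDR, dDRN


def _peak_intervals(time_h: np.ndarray, signal: np.ndarray,
                    discard_h: float) -> np.ndarray:
    """Intervals between successive interior maxima after a transient."""
    mask = time_h >= time_h[0] + discard_h
    t, v = time_h[mask], signal[mask]
    idx = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))[0] + 1
    peaks = []
    for i in idx:
        # quadratic refinement of the peak time
        t0, t1, t2 = t[i - 1], t[i], t[i + 1]
        y0, y1, y2 = v[i - 1], v[i], v[i + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.0 if denom == 0.0 else 0.5 * (y0 - y2) / denom
        peaks.append(t1 + shift * (t2 - t0) / 2.0)
    peaks = np.asarray(peaks)
    if peaks.size:
        # drop spurious closely-spaced maxima (numerical ripples)
        keep = np.concatenate([[True], np.diff(peaks) > 6.0])
        peaks = peaks[keep]
    return np.diff(peaks)


def free_running_period(params=None, horizon_days: int = 40,
                        discard_days: int = 10, trajectory=None) -> float:
    """Free-running cortisol period (h) with the entraining light removed.

    Integrates the full coupled model in constant darkness for
    ``horizon_days`` (unless a precomputed ``trajectory`` is supplied),
    discards ``discard_days`` of transient, and returns the mean interval
    between successive cortisol maxima.  Raises if fewer than 5 peaks are
    found.
    """
    if trajectory is None:
        from . import engine, protocols

        if horizon_days < 30:
            raise ValueError("free-run horizon must be >= 30 days")
        proto = protocols.make_dark_protocol(duration_days=horizon_days)
        settings = engine.SimulationSettings(t0=0.0, t_end=24.0 * horizon_days)
        if params is not None:
            trajectory = engine.integrate(proto, params, settings)
        else:
            trajectory = engine.integrate(proto, None, settings)
    df = trajectory.df if hasattr(trajectory, "df") else trajectory
    intervals = _peak_intervals(df["time_h"].to_numpy(),
                                df["CORT"].to_numpy(), 24.0 * discard_days)
    if intervals.size < 4:
        raise RuntimeError("fewer than 5 cortisol peaks after transient")
    return float(np.mean(intervals))
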