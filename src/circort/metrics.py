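"""Rhythm metrics: peak/nadir timing and level, amplitude, circular phase
delay, quiescent period, and the 4 h stress-response AUC difference.

All timing readouts operate on one adapted day sampled on a uniform grid;
peak and nadir times are refined off-grid by local quadratic interpolation,
which resolves the 1-2 h schedule effects studied here well below the
sampling interval.  Phase differences use the circular convention
(-12, +12] h with delays positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RhythmMetrics",
    "StressResponse",
    "rhythm_metrics",
    "circular_delay",
    "stress_delta_auc",
    "quiescent_period",
]

#: Fraction of the peak-to-nadir range defining "low" cortisol for the
#: quiescent period.
QUIESCENT_THRESHOLD = 0.25


@dataclass(frozen=True)
class RhythmMetrics:
    peak_time: float        # clock hours
    peak_level: float
    nadir_time: float       # clock hours
    nadir_level: float
    amplitude: float        # (peak - nadir) / 2
    phase_delay_vs_ref: float | None = None  # hours, circular
    period: float | None = None              # hours (free-running runs)
    quiescent_onset: float | None = None     # clock hours


@dataclass(frozen=True)
class StressResponse:
    onset_clock_h: float
    delta_auc: float        # conc * hours over the 4 h window


def _refine(clock: np.ndarray, v: np.ndarray, i: int, dt: float,
            sign: float) -> tuple[float, float]:
    """Quadratic (3-point) refinement of an extremum at grid index i."""
    n = v.size
    y0, y1, y2 = v[(i - 1) % n], v[i], v[(i + 1) % n]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.0 if denom == 0.0 else np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0)
    t = np.mod(clock[i] + shift * dt, 24.0)
    level = y1 - 0.25 * (y0 - y2) * shift
    return float(t), float(level)


def circular_delay(t: float, t_ref: float) -> float:
    """Circular time difference ``t - t_ref`` mapped to (-12, +12] h."""
    d = (t - t_ref) % 24.0
    return float(d if d <= 12.0 else d - 24.0)


def _local_maxima(v: np.ndarray) -> np.ndarray:
    """Indices of circular local maxima (strict on the left)."""
    prev = np.roll(v, 1)
    nxt = np.roll(v, -1)
    return np.nonzero((v > prev) & (v >= nxt))[0]


def rhythm_metrics(clock_h, values, reference=None,
                   ambiguity_fraction: float = 0.05) -> RhythmMetrics:
    """Peak/nadir metrics of one adapted day.

    ``clock_h``/``values`` must sample exactly one day uniformly.  The trace
    is treated as circular.  Raises ``ValueError`` if a secondary local
    maximum comes within ``ambiguity_fraction`` of the peak-to-nadir range
    of the primary peak (ambiguous, multimodal rhythm).  ``reference`` may
    be a second (clock, values) tuple; the phase delay of this trace's peak
    relative to the reference peak is then reported.
    """
    clock = np.mod(np.asarray(clock_h, dtype=float), 24.0)
    v = np.asarray(values, dtype=float)
    if clock.size != v.size or v.size < 8:
        raise ValueError("need a full sampled day")
    # drop a duplicated wrap-around sample (t and t+24 on the same clock hour)
    if np.isclose(clock[-1], clock[0]):
        clock, v = clock[:-1], v[:-1]
    order = np.argsort(clock, kind="stable")
    clock, v = clock[order], v[order]
    dt = 24.0 / v.size

    i_peak = int(np.argmax(v))
    i_nadir = int(np.argmin(v))
    peak_t, peak_v = _refine(clock, v, i_peak, dt, +1.0)
    nadir_t, nadir_v = _refine(clock, v, i_nadir, dt, -1.0)
    rng = peak_v - nadir_v

    if rng > 0.0:
        for j in _local_maxima(v):
            if j == i_peak:
                continue
            gap = min((clock[j] - clock[i_peak]) % 24.0,
                      (clock[i_peak] - clock[j]) % 24.0)
            if gap > 2.0 and v[j] > peak_v - ambiguity_fraction * rng:
                raise ValueError("ambiguous multimodal trace: secondary peak "
                                 f"at {clock[j]:.2f} h within "
                                 f"{ambiguity_fraction:.0%} of the primary")

    delay = None
    if reference is not None:
        ref = rhythm_metrics(reference[0], reference[1])
        delay = circular_delay(peak_t, ref.peak_time)

    q_onset = None
    if rng > 0.0:
        q_onset, _ = quiescent_period(clock, v, QUIESCENT_THRESHOLD)

    return RhythmMetrics(peak_time=peak_t, peak_level=peak_v,
                         nadir_time=nadir_t, nadir_level=nadir_v,
                         amplitude=0.5 * rng, phase_delay_vs_ref=delay,
                         quiescent_onset=q_onset)


def quiescent_period(clock_h, values,
                     threshold_fraction: float = QUIESCENT_THRESHOLD
                     ) -> tuple[float, float]:
    """Onset (clock h) and duration (h) of the low-cortisol window.

    The quiescent period is the longest contiguous (circular) stretch where
    the trace stays below ``nadir + threshold_fraction * (peak - nadir)``.
    Raises ``ValueError`` if no sample is below threshold.
    """
    clock = np.mod(np.asarray(clock_h, dtype=float), 24.0)
    v = np.asarray(values, dtype=float)
    if np.isclose(clock[-1], clock[0]):
        clock, v = clock[:-1], v[:-1]
    order = np.argsort(clock, kind="stable")
    clock, v = clock[order], v[order]
    dt = 24.0 / v.size

    lo, hi = float(np.min(v)), float(np.max(v))
    thresh = lo + threshold_fraction * (hi - lo)
    below = v <= thresh
    if not below.any():
        raise ValueError("no sub-threshold window exists")
    if below.all():
        return float(clock[0]), 24.0
    # longest circular run of True
    ext = np.concatenate([below, below])
    best_len, best_start, run, start = 0, 0, 0, 0
    for i, flag in enumerate(ext):
        if flag:
            if run == 0:
                start = i
            run += 1
            if run > best_len and start < v.size:
                best_len, best_start = run, start
        else:
            run = 0
    best_len = min(best_len, v.size)
    return float(clock[best_start % v.size]), float(best_len * dt)


def stress_delta_auc(stressed, unstressed, onset: float) -> StressResponse:
    """Difference in cortisol AUC over 4 h from stressor onset.

    Both trajectories must share the same time grid and differ only in the
    stress pulse.  ``onset`` is the clock hour of the stressor on the final
    simulated day (or an absolute hour within the trajectory span).
    """
    df_s = stressed.df if hasattr(stressed, "df") else stressed
    df_u = unstressed.df if hasattr(unstressed, "df") else unstressed
    t_s = df_s["time_h"].to_numpy()
    t_u = df_u["time_h"].to_numpy()
    if t_s.shape != t_u.shape or not np.allclose(t_s, t_u):
        raise ValueError("trajectories are on different time grids")
    t0 = t_s[0]
    onset_abs = onset
    if onset_abs < t0:  # clock hour: place it on the final day it fits in
        onset_abs = t_s[-1] - 24.0 - (t_s[-1] - 24.0) % 24.0 + onset
        while onset_abs + 4.0 > t_s[-1] + 1e-9:
            onset_abs -= 24.0
        if onset_abs < t0:
            raise ValueError("no complete 4 h window for this onset")
    sel = (t_s >= onset_abs - 1e-9) & (t_s <= onset_abs + 4.0 + 1e-9)
    if sel.sum() < 3:
        raise ValueError("stress window not covered by the trajectory")
    diff = df_s["CORT"].to_numpy()[sel] - df_u["CORT"].to_numpy()[sel]
    auc = float(np.trapezoid(diff, t_s[sel]))
    return StressResponse(onset_clock_h=float(onset % 24.0), delta_auc=auc)
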