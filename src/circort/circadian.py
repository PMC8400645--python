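"""Forced van der Pol circadian pacemaker with photic entrainment.

The pacemaker is the classic higher-order van der Pol oscillator of the
Kronauer/Forger lineage, forced by a light-driven process: light activates a
photoreceptor pool ``n`` (Process L), and the resulting drive ``B`` both
phase-shifts the oscillator and is suppressed by the oscillator state (the
``(1 - bx)(1 - by)`` sensitivity modulation).  Two readouts are exposed: the
circadian sleep drive ``C(t)`` that feeds the ventrolateral-preoptic
population, and a rectified SCN drive that paces CRH synthesis in the HPA
axis.

Time is measured in hours throughout; photoreceptor rates ``alpha0`` and
``beta`` are quoted per minute (their historical units) and converted by the
``lambda_`` = 60 scale factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircadianParams",
    "CircadianState",
    "photic_drive",
    "circadian_derivatives",
    "sleep_circadian_drive",
    "scn_drive",
]


@dataclass(frozen=True)
class CircadianParams:
    """Parameters of the forced van der Pol pacemaker.

    Defaults follow the published Kronauer-type parameterization used by the
    sleep-modeling lineage this package builds on, with the intrinsic period
    and light response calibrated so the entrained habitual schedule, the
    free-running period, and the evening-light phase delays all land in
    their physiological ranges.
    """

    gamma: float = 0.23            # van der Pol stiffness (dimensionless)
    kappa: float = 12.0 / math.pi  # time scale (h)
    f: float = 0.99669             # period-scaling factor
    tau_c: float = 24.35           # intrinsic period (h)
    k_B: float = 0.55              # light-drive coupling into the x-equation
    G_drive: float = 1.0           # photic drive gain in the y-equation
    G: float = 19.9                # photic drive gain inside B
    lambda_: float = 60.0          # converts per-minute rates to per-hour
    alpha0: float = 0.3            # maximal photic activation rate (1/min)
    beta: float = 0.0075           # photoreceptor recovery rate (1/min)
    p: float = 0.92                # light intensity exponent
    I0: float = 9500.0             # reference intensity (lux)
    b: float = 0.4                 # state-dependent light suppression
    # SCN drive readout (rectified, phase-rotated projection of (x, y)).
    scn_gain: float = 1.0
    scn_phase_rad: float = -2.2
    scn_offset: float = 0.2

    def __post_init__(self) -> None:
        for name in ("gamma", "kappa", "f", "tau_c", "lambda_", "alpha0",
                     "beta", "I0"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.b < 1.0):
            raise ValueError("b must lie in (0, 1)")


@dataclass
class CircadianState:
    """Oscillator variables (x, y) and activated photoreceptor fraction n."""

    x: float = -1.0
    y: float = 0.0
    n: float = 0.5


def photic_alpha(I_eff: float, p: CircadianParams) -> float:
    """Photoreceptor activation rate ``alpha0 (I/I0)^p`` (1/min)."""
    if I_eff <= 0.0:
        return 0.0
    return p.alpha0 * (I_eff / p.I0) ** p.p


def photic_drive(s: CircadianState, I_eff: float, p: CircadianParams) -> float:
    """Circadian light drive ``B = G alpha (1-n)(1-bx)(1-by)``.

    ``alpha = alpha0 (I_eff/I0)^p`` is the photoreceptor activation rate and
    the trailing factors implement the state-dependent suppression of light
    sensitivity.  The classical gain ``G`` is kept as a separate parameter
    rather than folded into ``alpha0`` so that the same ``alpha`` drives the
    photoreceptor kinetics.
    """
    alpha = photic_alpha(I_eff, p)
    return p.G * alpha * (1.0 - s.n) * (1.0 - p.b * s.x) * (1.0 - p.b * s.y)


def circadian_derivatives(s: CircadianState, B: float, alpha: float,
                          p: CircadianParams) -> tuple[float, float, float]:
    """Time derivatives (dx/dt, dy/dt, dn/dt) in 1/h.

    ``B`` is the photic drive and ``alpha`` the photoreceptor activation rate
    (1/min) for the same effective light level::

        kappa dx/dt = gamma (x - 4x^3/3) - y [(24/(f tau_c))^2 + k_B B]
        kappa dy/dt = x + G_drive B
        dn/dt       = lambda_ (alpha (1 - n) - beta n)
    """
    omega_sq = (24.0 / (p.f * p.tau_c)) ** 2
    dx = (p.gamma * (s.x - 4.0 * s.x ** 3 / 3.0)
          - s.y * (omega_sq + p.k_B * B)) / p.kappa
    dy = (s.x + p.G_drive * B) / p.kappa
    dn = p.lambda_ * (alpha * (1.0 - s.n) - p.beta * s.n)
    return dx, dy, dn


def sleep_circadian_drive(s: CircadianState) -> float:
    """Circadian drive to sleep, ``C(t) = 0.55 (1 + 0.8 y - 0.47 x)``."""
    return 0.55 * (1.0 + 0.8 * s.y - 0.47 * s.x)


def scn_drive(s: CircadianState, p: CircadianParams) -> float:
    """Rectified SCN drive to CRH synthesis.

    A phase-rotated projection of the oscillator state, clipped at zero::

        S = max(0, gain * (x cos(phi) + y sin(phi)) - offset)

    The phase offset ``phi`` is a calibration knob fixing where in the
    circadian cycle CRH synthesis is maximally stimulated; it is chosen so
    the entrained cortisol peak falls shortly after wake onset.
    """
    u = s.x * math.cos(p.scn_phase_rad) + s.y * math.sin(p.scn_phase_rad)
    return max(0.0, p.scn_gain * u - p.scn_offset)


def scn_drive_xy(x, y, p: CircadianParams):
    """Vectorized :func:`scn_drive` on raw (x, y) arrays."""
    u = x * np.cos(p.scn_phase_rad) + y * np.sin(p.scn_phase_rad)
    return np.maximum(0.0, p.scn_gain * u - p.scn_offset)
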