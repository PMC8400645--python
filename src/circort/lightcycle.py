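"""Environmental light schedules and the wake gate.

The entraining input to the circadian pacemaker is a 24 h-periodic light
profile built from hyperbolic-tangent dawn/dusk transitions, optionally with
a low-intensity evening plateau (0-40 lux) between scheduled dusk and the
model's own sleep onset.  Light only reaches the pacemaker while the model is
awake (eyes open): the raw profile is gated by a Heaviside function of the
wake-active firing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LightParams",
    "LightSchedule",
    "light_intensity",
    "gated_light",
    "make_nominal_schedule",
    "make_evening_light_schedule",
]

#: Sharpness (1/h) giving a dawn/dusk transition spanning roughly 15 min.
DEFAULT_SHARPNESS = 16.0

#: Clock hour after which any evening plateau is cut off even if the model
#: is still awake (a safety bound well past habitual sleep onset).
EVENING_CUTOFF_H = 28.0


@dataclass(frozen=True)
class LightParams:
    """Two-plateau tanh light profile.

    Attributes
    ----------
    l1, l2:
        Daytime and nighttime plateau intensities (lux), ``l1 >= l2 >= 0``.
    s1, s2:
        Clock hours of the light-onset and light-offset transition centers,
        ``0 <= s1 < s2 < 24``.
    c:
        Transition sharpness (1/h); larger values give squarer profiles.
    """

    l1: float = 1000.0
    l2: float = 0.0
    s1: float = 6.0
    s2: float = 18.0
    c: float = DEFAULT_SHARPNESS

    def __post_init__(self) -> None:
        if not (self.l1 >= self.l2 >= 0.0):
            raise ValueError("require l1 >= l2 >= 0")
        if not (0.0 <= self.s1 < self.s2 < 24.0):
            raise ValueError("require 0 <= s1 < s2 < 24")
        if self.c <= 0.0:
            raise ValueError("sharpness c must be > 0")


@dataclass(frozen=True)
class LightSchedule:
    """A base day/night profile plus an optional evening plateau.

    ``evening_lux`` is held from scheduled dusk until the wake gate closes at
    the model's sleep onset (the paper's evening-light manipulation); the
    gate threshold ``Qth`` is the wake-active firing rate below which the
    eyes are considered closed and the pacemaker sees 0 lux.
    """

    base: LightParams = field(default_factory=LightParams)
    evening_lux: float = 0.0
    Qth: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.evening_lux <= self.base.l1):
            raise ValueError("require 0 <= evening_lux <= l1")
        if self.Qth <= 0.0:
            raise ValueError("gate threshold Qth must be > 0")

    def raw_intensity(self, t):
        """Ungated light intensity (lux) at clock/absolute hour ``t``."""
        day = light_intensity(t, self.base)
        if self.evening_lux <= 0.0:
            return day
        evening = _periodic_profile(
            t, self.evening_lux, 0.0, self.base.s2, EVENING_CUTOFF_H, self.base.c
        )
        return np.maximum(day, evening)


def _profile(t, l1, l2, s1, s2, c):
    return l2 + 0.5 * (l1 - l2) * (np.tanh(c * (t - s1)) - np.tanh(c * (t - s2)))


def _periodic_profile(t, l1, l2, s1, s2, c):
    # Evaluate the (non-periodic) tanh profile at t mod 24 and at +/-24 h and
    # take the max so transitions straddling midnight are not clipped.
    tm = np.mod(t, 24.0)
    out = _profile(tm, l1, l2, s1, s2, c)
    out = np.maximum(out, _profile(tm + 24.0, l1, l2, s1, s2, c))
    out = np.maximum(out, _profile(tm - 24.0, l1, l2, s1, s2, c))
    return out


def light_intensity(t, p: LightParams):
    """24 h-periodic light intensity (lux) at clock hour ``t``.

    Implements the two-tanh day/night profile
    ``I(t) = l2 + (l1-l2)/2 [tanh(c(t-s1)) - tanh(c(t-s2))]`` with ``t``
    interpreted modulo 24 h.
    """
    return _periodic_profile(t, p.l1, p.l2, p.s1, p.s2, p.c)


def gated_light(I_raw, Qm, Qth):
    """Light actually seen by the pacemaker: ``H(Qm - Qth) * I_raw``.

    The Heaviside convention is ``H(0) = 0`` (the boundary counts as
    sleep/eyes closed), so the gate is open strictly when ``Qm > Qth``.
    """
    return np.where(Qm > Qth, I_raw, 0.0)


def make_nominal_schedule() -> LightSchedule:
    """The idealized 12 h photoperiod: 1000 lux 06:00-18:00, 0 lux otherwise."""
    return LightSchedule(base=LightParams(), evening_lux=0.0)


def make_evening_light_schedule(evening_lux: float) -> LightSchedule:
    """Nominal day profile plus a constant evening plateau of 0-40 lux.

    The plateau is held from scheduled dusk onward; effective lights-off is
    produced by the wake gate at the model's own sleep onset.
    """
    if not (0.0 <= evening_lux <= 40.0):
        raise ValueError("evening_lux must be within [0, 40] lux")
    nominal = make_nominal_schedule()
    return replace(nominal, evening_lux=float(evening_lux))
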