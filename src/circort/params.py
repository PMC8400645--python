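"""Aggregate model parameter bundle and committed initial states.

The four physiological sub-models (circadian pacemaker, sleep/wake switch,
central HPA axis, peripheral receptors) each own their parameter dataclass;
:class:`ModelParams` bundles them so the engine, protocols, and CLI can pass
one object around.  The dataclass defaults are the calibrated nominal
parameterization; :func:`to_dict`/:func:`from_dict` give a YAML-friendly
round trip for parameter files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .circadian import CircadianParams
from .hpa import HPAParams
from .receptors import PeripheralParams, ReceptorParams
from .sleepwake import SleepWakeParams

__all__ = ["ModelParams", "default_params", "to_dict", "from_dict",
           "STATE_NAMES", "cold_start_state", "adapted_nominal_state"]


@dataclass(frozen=True)
class ModelParams:
    circadian: CircadianParams = field(default_factory=CircadianParams)
    sleepwake: SleepWakeParams = field(default_factory=SleepWakeParams)
    hpa: HPAParams = field(default_factory=HPAParams)
    receptors: PeripheralParams = field(default_factory=PeripheralParams)


def default_params() -> ModelParams:
    """The calibrated nominal parameter set."""
    return ModelParams()


def to_dict(p: ModelParams) -> dict[str, Any]:
    return {
        "circadian": dataclasses.asdict(p.circadian),
        "sleepwake": dataclasses.asdict(p.sleepwake),
        "hpa": dataclasses.asdict(p.hpa),
        "receptors": dataclasses.asdict(p.receptors),
    }


def from_dict(d: dict[str, Any]) -> ModelParams:
    """Build a :class:`ModelParams` from a (possibly partial) nested dict."""
    base = to_dict(ModelParams())
    for section, values in d.items():
        if section not in base:
            raise KeyError(f"unknown parameter section: {section!r}")
        for key, val in values.items():
            if key not in base[section]:
                raise KeyError(f"unknown key {section}.{key}")
            if isinstance(base[section][key], dict):
                base[section][key].update(val)
            else:
                base[section][key] = val
    rec = base["receptors"]
    return ModelParams(
        circadian=CircadianParams(**base["circadian"]),
        sleepwake=SleepWakeParams(**base["sleepwake"]),
        hpa=HPAParams(**base["hpa"]),
        receptors=PeripheralParams(MR=ReceptorParams(**rec["MR"]),
                                   GR=ReceptorParams(**rec["GR"])),
    )


#: State-vector layout used by the engine (19 coupled ODE states).
STATE_NAMES = (
    "x", "y", "n",                                   # circadian
    "Vv", "Vm", "H",                                 # sleep/wake
    "CRH", "ACTH", "CORT", "GR_mRNA", "GR_free", "DR", "DRN",   # central HPA
    "MR", "GRp", "F_MR", "F_MR_N", "F_GR", "F_GR_N",  # peripheral receptors
)

# A physiologically sensible state at midnight (asleep) used when no better
# initial condition is available; every study run starts from the adapted
# nominal cycle instead.
_COLD_START = {
    "x": -0.8, "y": -0.6, "n": 0.0,
    "Vv": 2.0, "Vm": -8.0, "H": 12.0,
    "CRH": 0.4, "ACTH": 0.4, "CORT": 0.3, "GR_mRNA": 0.5, "GR_free": 0.8,
    "DR": 0.2, "DRN": 0.2,
    "MR": 0.3, "GRp": 0.5, "F_MR": 0.3, "F_MR_N": 0.3,
    "F_GR": 0.2, "F_GR_N": 0.2,
}

# State on the adapted nominal limit cycle at midnight (t mod 24 == 0),
# produced by running the nominal protocol to its steady cycle with the
# default parameters (see scripts in the calibration module).  Committed so
# study runs re-adapt in a few simulated days.
_ADAPTED_NOMINAL = {
    "x": -0.40980709999060616, "y": -1.0171151751671228, "n": 0.05630354686018689,
    "Vv": 2.563949558107785, "Vm": -12.624620838330147, "H": 10.900824313694086,
    "CRH": 0.879583828828012, "ACTH": 1.0445985645985836, "CORT": 1.2698424836242255,
    "GR_mRNA": 0.7092935489598922, "GR_free": 0.709086074673829,
    "DR": 0.5609853385695482, "DRN": 0.49423692195355823,
    "MR": 0.022842046146022133, "GRp": 0.15673901240241422,
    "F_MR": 0.45142906445891273, "F_MR_N": 0.4464604918289783,
    "F_GR": 0.27727612141550373, "F_GR_N": 0.25478750079791834,
}


def _vec(d: dict[str, float]) -> np.ndarray:
    return np.array([d[k] for k in STATE_NAMES], dtype=float)


def cold_start_state() -> np.ndarray:
    return _vec(_COLD_START)


def adapted_nominal_state() -> np.ndarray:
    return _vec(_ADAPTED_NOMINAL)
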