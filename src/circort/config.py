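"""Run configuration: a single YAML file with one section per sub-model.

Sections: ``light``, ``circadian``, ``sleepwake``, ``hpa``, ``receptors``,
``protocol``, ``engine``.  Every key is optional and overrides the
calibrated default.  The ``protocol`` section understands::

    protocol:
      kind: nominal | dark | csr | evening_light
      csr_condition: b1_symmetric | b2_delay_sleep | b3_advance_wake
      restriction_hours: 4.0
      evening_lux: 20.0
      duration_days: 30
      stress: [{onset_h: 21.0, duration_h: 0.5, gain: 3.0}]
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import yaml

from . import protocols as proto_mod
from .engine import SimulationSettings
from .lightcycle import LightParams, LightSchedule
from .params import ModelParams, from_dict

__all__ = ["RunConfig", "load_config"]

_ENGINE_KEYS = {"t0", "t_end", "rel_tol", "abs_tol", "max_step", "output_dt",
                "transient_days", "seed", "method"}


@dataclass
class RunConfig:
    params: ModelParams = field(default_factory=ModelParams)
    protocol: proto_mod.Protocol = field(
        default_factory=proto_mod.make_nominal_protocol)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    raw: dict[str, Any] = field(default_factory=dict)


def _build_light(cfg: dict[str, Any], evening_lux: float) -> LightSchedule:
    base = LightParams(
        l1=cfg.get("l1_lux", 1000.0),
        l2=cfg.get("l2_lux", 0.0),
        s1=cfg.get("dawn_h", 6.0),
        s2=cfg.get("dusk_h", 18.0),
        c=cfg.get("sharpness_per_h", 16.0),
    )
    return LightSchedule(base=base,
                         evening_lux=cfg.get("evening_lux", evening_lux),
                         Qth=cfg.get("gate_threshold", 1.0))


def _build_protocol(cfg: dict[str, Any], light_cfg: dict[str, Any]
                    ) -> proto_mod.Protocol:
    kind = cfg.get("kind", "nominal")
    days = int(cfg.get("duration_days", 30))
    evening_lux = float(cfg.get("evening_lux", 0.0))
    if kind == "nominal":
        proto = proto_mod.make_nominal_protocol(days)
    elif kind == "dark":
        proto = proto_mod.make_dark_protocol(days)
    elif kind == "evening_light":
        proto = proto_mod.make_evening_light_protocol(evening_lux, days)
    elif kind == "csr":
        cond = proto_mod.CSRCondition(cfg.get("csr_condition", "b1_symmetric"),
                                      float(cfg.get("restriction_hours", 0.0)))
        proto = proto_mod.make_csr_protocol(cond, duration_days=days)
    else:
        raise ValueError(f"unknown protocol kind: {kind!r}")
    if light_cfg or evening_lux:
        proto = replace(proto, light=_build_light(light_cfg, evening_lux))
    for pulse in cfg.get("stress", []):
        proto = proto_mod.make_stress_protocol(
            proto, pulse["onset_h"], pulse.get("duration_h", 0.5),
            pulse.get("gain", 3.0))
    return proto


def load_config(path_or_dict) -> RunConfig:
    """Load a YAML config file (or an equivalent dict)."""
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - {"light", "circadian", "sleepwake", "hpa",
                          "receptors", "protocol", "engine"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    params = from_dict({k: v for k, v in cfg.items()
                        if k in ("circadian", "sleepwake", "hpa", "receptors")})
    engine_cfg = dict(cfg.get("engine", {}))
    bad = set(engine_cfg) - _ENGINE_KEYS
    if bad:
        raise ValueError(f"unknown engine keys: {sorted(bad)}")
    settings = SimulationSettings(**engine_cfg)
    protocol = _build_protocol(dict(cfg.get("protocol", {})),
                               dict(cfg.get("light", {})))
    return RunConfig(params=params, protocol=protocol, settings=settings,
                     raw=cfg)
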