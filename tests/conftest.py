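"""Shared fixtures: adapted runs are expensive, so they are computed once
per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from circort import engine, metrics, protocols
from circort.params import default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def nominal_traj():
    """Adapted nominal run: two analysis days at 6 min sampling."""
    return engine.run_to_steady_cycle(protocols.make_nominal_protocol())


@pytest.fixture(scope="session")
def nominal_day(nominal_traj):
    return nominal_traj.final_day()


@pytest.fixture(scope="session")
def nominal_cort_metrics(nominal_day):
    return metrics.rhythm_metrics(nominal_day["clock_h"].to_numpy(),
                                  nominal_day["CORT"].to_numpy())


@pytest.fixture(scope="session")
def habitual_times(nominal_traj):
    """Realized (wake, sleep) clock hours of the adapted nominal cycle."""
    from circort.sleepwake import wake_sleep_times

    df = nominal_traj.df
    return wake_sleep_times(df["time_h"], df["Qm"], df["Qv"])


def run_csr(kind: str, hours: float, **kw):
    proto = protocols.make_csr_protocol(protocols.CSRCondition(kind, hours))
    return engine.run_to_steady_cycle(proto, **kw)


@pytest.fixture(scope="session")
def csr_b1_sweep():
    """Adapted cortisol metrics and occupancy minima for the
    symmetric-restriction grid."""
    out = {}
    for r in (0.0, 1.0, 2.0, 3.0, 4.0):
        traj = run_csr("b1_symmetric", r)
        day = traj.final_day()
        out[r] = {
            "cort": metrics.rhythm_metrics(day["clock_h"].to_numpy(),
                                           day["CORT"].to_numpy()),
            "occ_MR_min": float(day["occ_MR"].min()),
            "occ_GR_min": float(day["occ_GR"].min()),
        }
    return out


@pytest.fixture(scope="session")
def csr_matched():
    """b1/b2/b3 metrics at matched 2 h and 4 h restrictions."""
    out = {}
    for kind, tag in (("b1_symmetric", "b1"), ("b2_delay_sleep", "b2"),
                      ("b3_advance_wake", "b3")):
        for r in (2.0, 4.0):
            traj = run_csr(kind, r)
            day = traj.final_day()
            out[(tag, r)] = metrics.rhythm_metrics(
                day["clock_h"].to_numpy(), day["CORT"].to_numpy())
    return out


@pytest.fixture(scope="session")
def evening_light_runs():
    """Adapted runs for the evening-light grid (0 handled by nominal)."""
    out = {}
    for lux in (20.0, 40.0):
        proto = protocols.make_evening_light_protocol(lux)
        traj = engine.run_to_steady_cycle(proto, tol=5e-4, max_days=160)
        day = traj.final_day()
        out[lux] = metrics.rhythm_metrics(day["clock_h"].to_numpy(),
                                          day["CORT"].to_numpy())
    return out
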