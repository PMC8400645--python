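"""Peripheral mineralocorticoid (MR) and glucocorticoid (GR) receptor pools.

Each receptor pool follows the corticosteroid pharmacodynamic scheme:
saturable production from the inactive remainder of a fixed total pool
(stimulated indirectly by cortisol), saturable degradation, second-order
cortisol binding into a cytosolic complex, translocation of the complex to
the nucleus, and partial recycling of the nuclear complex back to the free
pool.  The high-affinity MR binds cortisol an order of magnitude more
avidly than GR, so MR stays majority-occupied even at the circadian nadir
of cortisol while GR occupancy drops to about half.

Concentrations share the arbitrary units of the central cortisol signal;
rates are per hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReceptorParams",
    "PeripheralParams",
    "PeripheralReceptorState",
    "receptor_derivatives",
    "occupancy_fraction",
]


@dataclass(frozen=True)
class ReceptorParams:
    """Kinetic constants for one receptor species."""

    k: float          # base production (conc/h)
    kF: float         # cortisol stimulation efficiency (dimensionless)
    KF: float         # Michaelis constant of cortisol-induced activation (conc)
    R_T: float        # total receptor pool (conc)
    K: float          # Michaelis constant of production (conc)
    kdeg: float       # max degradation rate (conc/h)
    Kdeg: float       # degradation Michaelis constant (conc)
    kb: float         # cortisol binding (1/(conc h))
    kr: float         # nuclear complex return to free pool (1/h)
    kT: float         # translocation (1/h)
    kre: float        # nuclear export/elimination (1/h)

    def __post_init__(self) -> None:
        for name in ("k", "KF", "R_T", "K", "kdeg", "Kdeg", "kb", "kT", "kre"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.kF < 0.0 or self.kr < 0.0:
            raise ValueError("kF and kr must be >= 0")


def _default_mr() -> ReceptorParams:
    return ReceptorParams(k=0.09, kF=1.0, KF=0.5, R_T=1.0, K=0.1,
                          kdeg=0.05, Kdeg=0.5, kb=8.0, kr=0.2,
                          kT=0.5, kre=0.5)


def _default_gr() -> ReceptorParams:
    return ReceptorParams(k=0.12, kF=1.0, KF=0.5, R_T=1.0, K=1.0,
                          kdeg=0.05, Kdeg=0.5, kb=0.8, kr=0.2,
                          kT=0.5, kre=0.5)


@dataclass(frozen=True)
class PeripheralParams:
    """MR and GR kinetics; the invariant ``K_MR < K_GR`` (and the larger MR
    binding rate) encodes the higher affinity of the mineralocorticoid
    receptor."""

    MR: ReceptorParams = None  # type: ignore[assignment]
    GR: ReceptorParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.MR is None:
            object.__setattr__(self, "MR", _default_mr())
        if self.GR is None:
            object.__setattr__(self, "GR", _default_gr())
        if not self.MR.K < self.GR.K:
            raise ValueError("require K_MR < K_GR (MR is the high-affinity receptor)")


@dataclass
class PeripheralReceptorState:
    MR: float = 0.5      # activated free MR
    GR: float = 0.5      # activated free GR
    F_MR: float = 0.0    # cytosolic cortisol-MR complex
    F_MR_N: float = 0.0  # nuclear cortisol-MR complex
    F_GR: float = 0.0    # cytosolic cortisol-GR complex
    F_GR_N: float = 0.0  # nuclear cortisol-GR complex


def _one_receptor(R: float, F: float, FN: float, CORT: float,
                  q: ReceptorParams) -> tuple[float, float, float]:
    prod = (q.k * (1.0 + q.kF * CORT / (q.KF + CORT))
            * (q.R_T - R) / (q.K + q.R_T - R))
    dR = (prod - q.kdeg * R / (q.Kdeg + R)
          - q.kb * CORT * R + q.kr * FN)
    dF = q.kb * CORT * R - q.kT * F
    dFN = q.kT * F - q.kre * FN
    return dR, dF, dFN


def receptor_derivatives(s: PeripheralReceptorState, CORT: float,
                         p: PeripheralParams) -> tuple[float, ...]:
    """Time derivatives of the six peripheral receptor states (conc/h)."""
    if CORT < 0.0:
        raise ValueError("CORT must be >= 0")
    dMR, dFMR, dFMRN = _one_receptor(s.MR, s.F_MR, s.F_MR_N, CORT, p.MR)
    dGR, dFGR, dFGRN = _one_receptor(s.GR, s.F_GR, s.F_GR_N, CORT, p.GR)
    return dMR, dGR, dFMR, dFMRN, dFGR, dFGRN


def occupancy_fraction(s: PeripheralReceptorState, receptor: str,
                       p: PeripheralParams, nuclear_only: bool = False) -> float:
    """Fraction of the total receptor pool bound to cortisol.

    Default readout is ``(F_R + F_R_N) / R_T`` (cytosolic + nuclear bound
    complexes over the total pool); ``nuclear_only=True`` gives the
    alternative ``F_R_N / R_T`` readout.
    """
    if receptor == "MR":
        bound = s.F_MR_N if nuclear_only else s.F_MR + s.F_MR_N
        total = p.MR.R_T
    elif receptor == "GR":
        bound = s.F_GR_N if nuclear_only else s.F_GR + s.F_GR_N
        total = p.GR.R_T
    else:
        raise ValueError("receptor must be 'MR' or 'GR'")
    return bound / total


def occupancy_series(F, FN, R_T):
    """Vectorized bound-fraction readout ``(F + FN) / R_T``."""
    return (np.asarray(F, dtype=float) + np.asarray(FN, dtype=float)) / R_T
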