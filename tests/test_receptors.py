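import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from circort.receptors import (PeripheralParams, PeripheralReceptorState,
                               ReceptorParams, occupancy_fraction,
                               receptor_derivatives)


@pytest.fixture(scope="module")
def rp():
    return PeripheralParams()


def _rhs(y, cort, rp):
    # state order: MR, GR, F_MR, F_MR_N, F_GR, F_GR_N
    s = PeripheralReceptorState(MR=y[0], GR=y[1], F_MR=y[2], F_MR_N=y[3],
                                F_GR=y[4], F_GR_N=y[5])
    dMR, dGR, dFMR, dFMRN, dFGR, dFGRN = receptor_derivatives(s, cort, rp)
    return [dMR, dGR, dFMR, dFMRN, dFGR, dFGRN]


class TestDerivatives:
    def test_no_cortisol_no_binding_terms(self, rp):
        s = PeripheralReceptorState(MR=0.4, GR=0.4, F_MR=0.0, F_MR_N=0.0,
                                    F_GR=0.0, F_GR_N=0.0)
        d = receptor_derivatives(s, 0.0, rp)
        q = rp.MR
        expected = (q.k * (q.R_T - 0.4) / (q.K + q.R_T - 0.4)
                    - q.kdeg * 0.4 / (q.Kdeg + 0.4))
        assert d[0] == pytest.approx(expected, rel=1e-12)

    def test_exhausted_pool_stops_production(self, rp):
        s = PeripheralReceptorState(MR=rp.MR.R_T, GR=0.0)
        d = receptor_derivatives(s, 0.0, rp)
        q = rp.MR
        assert d[0] == pytest.approx(-q.kdeg * q.R_T / (q.Kdeg + q.R_T),
                                     rel=1e-12)

    def test_chain_flux_balance_at_steady_state(self, rp):
        """At the fixed point under constant cortisol the binding,
        translocation, and export fluxes of each receptor are equal."""
        cort = 1.0
        ss = fsolve(lambda y: _rhs(np.maximum(y, 0), cort, rp),
                    [0.1, 0.3, 0.5, 0.5, 0.3, 0.3], xtol=1e-13)
        for (R, F, FN), q in (((ss[0], ss[2], ss[3]), rp.MR),
                              ((ss[1], ss[4], ss[5]), rp.GR)):
            bind = q.kb * cort * R
            assert q.kT * F == pytest.approx(bind, rel=1e-6)
            assert q.kre * FN == pytest.approx(bind, rel=1e-6)

    def test_negative_cortisol_rejected(self, rp):
        with pytest.raises(ValueError):
            receptor_derivatives(PeripheralReceptorState(), -0.1, rp)


class TestOccupancy:
    def test_zero_bound_pool_zero_occupancy(self, rp):
        s = PeripheralReceptorState(MR=0.5, GR=0.5)
        assert occupancy_fraction(s, "MR", rp) == 0.0
        assert occupancy_fraction(s, "GR", rp) == 0.0

    def test_nuclear_only_readout(self, rp):
        s = PeripheralReceptorState(F_MR=0.2, F_MR_N=0.3)
        assert occupancy_fraction(s, "MR", rp) == pytest.approx(0.5)
        assert occupancy_fraction(s, "MR", rp, nuclear_only=True) == \
            pytest.approx(0.3)

    def test_unknown_receptor_rejected(self, rp):
        with pytest.raises(ValueError):
            occupancy_fraction(PeripheralReceptorState(), "XX", rp)

    def test_zero_input_decay(self, rp):
        """With no cortisol the bound pools drain to zero from any start."""
        y0 = [0.5, 0.5, 0.8, 0.8, 0.8, 0.8]
        sol = solve_ivp(lambda t, y: _rhs(np.maximum(y, 0), 0.0, rp),
                        (0.0, 400.0), y0, rtol=1e-9, atol=1e-12)
        assert np.all(sol.y[2:, -1] < 1e-6)

    def test_affinity_invariant(self, rp):
        assert rp.MR.K < rp.GR.K
        with pytest.raises(ValueError):
            PeripheralParams(MR=ReceptorParams(k=1, kF=1, KF=1, R_T=1, K=2.0,
                                               kdeg=1, Kdeg=1, kb=1, kr=0,
                                               kT=1, kre=1),
                             GR=ReceptorParams(k=1, kF=1, KF=1, R_T=1, K=1.0,
                                               kdeg=1, Kdeg=1, kb=1, kr=0,
                                               kT=1, kre=1))


class TestEntrainedOccupancy:
    def test_occupancies_within_unit_interval(self, nominal_traj):
        df = nominal_traj.df
        for col in ("occ_MR", "occ_GR"):
            assert df[col].min() >= 0.0
            assert df[col].max() <= 1.0

    def test_mr_dominates_gr_pointwise(self, nominal_traj):
        """The high-affinity MR is more occupied than GR at every sampled
        instant of the adapted nominal day."""
        df = nominal_traj.final_day()
        assert np.all(df["occ_MR"].to_numpy() > df["occ_GR"].to_numpy())

    def test_mr_majority_bound_at_cortisol_nadir(self, nominal_day):
        i = int(nominal_day["CORT"].to_numpy().argmin())
        assert nominal_day["occ_MR"].iloc[i] > 0.5

    def test_gr_about_half_bound_at_cortisol_nadir(self, nominal_day):
        i = int(nominal_day["CORT"].to_numpy().argmin())
        assert abs(nominal_day["occ_GR"].iloc[i] - 0.5) <= 0.15

    def test_csr_raises_minimum_mr_occupancy(self, csr_b1_sweep):
        """Raised cortisol minima under symmetric CSR push the daily MR
        occupancy minimum upward, toward complete occupancy."""
        mins = [csr_b1_sweep[r]["occ_MR_min"] for r in sorted(csr_b1_sweep)]
        assert np.all(np.diff(mins) > 0)
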