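import numpy as np
import pytest

from circort import engine, protocols
from circort.engine import SimulationSettings, Trajectory
from circort.params import STATE_NAMES, adapted_nominal_state


class TestSettingsAndTrajectory:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SimulationSettings(t0=10.0, t_end=5.0)
        with pytest.raises(ValueError):
            SimulationSettings(output_dt=0.0)
        with pytest.raises(ValueError):
            SimulationSettings(t_end=24.0, transient_days=2)

    def test_trajectory_grid_and_columns(self, nominal_traj):
        df = nominal_traj.df
        t = df["time_h"].to_numpy()
        assert np.all(np.diff(t) > 0)
        assert np.isfinite(df.select_dtypes("number").to_numpy()).all()
        for col in STATE_NAMES + ("I_eff", "C", "SCNdrive", "Qv", "Qm",
                                  "is_asleep", "occ_MR", "occ_GR"):
            assert col in df.columns


class TestIntegrate:
    def test_determinism_bit_identical(self):
        st = SimulationSettings(t0=0.0, t_end=48.0, output_dt=0.1)
        a = engine.integrate(protocols.make_nominal_protocol(), None, st)
        b = engine.integrate(protocols.make_nominal_protocol(), None, st)
        assert (a.df.to_numpy() == b.df.to_numpy()).all()

    def test_bad_initial_state_rejected(self):
        st = SimulationSettings(t0=0.0, t_end=48.0)
        with pytest.raises(ValueError):
            engine.integrate(protocols.make_nominal_protocol(), None, st,
                             initial_state=np.zeros(5))

    def test_light_gate_follows_wake_threshold(self, nominal_traj):
        df = nominal_traj.df
        gate_open = df["Qm"].to_numpy() > 1.0
        i_eff = df["I_eff"].to_numpy()
        assert np.all(i_eff[~gate_open] == 0.0)
        assert np.all(i_eff <= df["I_raw"].to_numpy() + 1e-12)
        # outside the minutes-long switching transients, sleep means darkness
        asleep = df["is_asleep"].to_numpy().astype(bool)
        lit_asleep = np.mean(i_eff[asleep] > 0.0)
        assert lit_asleep < 0.02

    def test_tolerance_halving_convergence(self):
        """Halving rel/abs tolerances changes the final-day cortisol trace
        by less than 0.1% in sup-norm."""
        proto = protocols.make_nominal_protocol()
        base = SimulationSettings(t0=0.0, t_end=24.0 * 3, output_dt=0.1)
        tight = SimulationSettings(t0=0.0, t_end=24.0 * 3, output_dt=0.1,
                                   rel_tol=base.rel_tol / 2,
                                   abs_tol=base.abs_tol / 2)
        a = engine.integrate(proto, None, base).final_day()["CORT"].to_numpy()
        b = engine.integrate(proto, None, tight).final_day()["CORT"].to_numpy()
        assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 1e-3

    def test_transient_days_discarded(self):
        st = SimulationSettings(t0=0.0, t_end=24.0 * 3, output_dt=0.5,
                                transient_days=2)
        traj = engine.integrate(protocols.make_nominal_protocol(), None, st)
        assert traj.df["time_h"].iloc[0] >= 48.0


class TestSteadyCycle:
    def test_nominal_adapts_quickly_from_committed_state(self, nominal_traj):
        assert nominal_traj.metadata["adaptation_day"] <= 5

    def test_event_hygiene_two_transitions_per_day(self, nominal_traj):
        from circort.sleepwake import detect_transitions

        df = nominal_traj.df
        trans = detect_transitions(df["time_h"], df["Qm"], df["Qv"])
        days = (df["time_h"].iloc[-1] - df["time_h"].iloc[0]) / 24.0
        assert len(trans) == pytest.approx(2 * days, abs=1.0)

    def test_nonconvergent_protocol_raises(self):
        with pytest.raises(RuntimeError, match="adapted"):
            engine.run_to_steady_cycle(protocols.make_nominal_protocol(),
                                       max_days=1, tol=1e-12)

    def test_states_bounded_over_long_run(self):
        """No hormone or receptor state blows up over 100 simulated days
        under the strongest restriction protocol."""
        proto = protocols.make_csr_protocol(
            protocols.CSRCondition("b1_symmetric", 4.0))
        st = SimulationSettings(t0=0.0, t_end=24.0 * 100, output_dt=0.5)
        traj = engine.integrate(proto, None, st)
        states = traj.df[list(STATE_NAMES)].to_numpy()
        assert np.isfinite(states).all()
        hormone_cols = [STATE_NAMES.index(c) for c in
                        ("CRH", "ACTH", "CORT", "GR_mRNA", "GR_free",
                         "DR", "DRN", "MR", "GRp", "F_MR", "F_MR_N",
                         "F_GR", "F_GR_N")]
        assert np.abs(states[:, hormone_cols]).max() < 50.0

    def test_nonnegativity_of_hormone_states(self, nominal_traj):
        df = nominal_traj.df
        for col in ("CRH", "ACTH", "CORT", "GR_mRNA", "GR_free", "DR",
                    "DRN", "F_MR", "F_MR_N", "F_GR", "F_GR_N"):
            assert df[col].min() >= -1e-8
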