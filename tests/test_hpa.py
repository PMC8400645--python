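import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from circort.hpa import HPAParams, HPAState, free_running_period, hpa_derivatives


@pytest.fixture(scope="module")
def hp():
    return HPAParams()


class TestDerivatives:
    def test_collapsed_drive_and_feedback(self, hp):
        """With DRN = 0, awake, no SCN drive and no stress the CRH balance
        reduces to kp1 - Vd1*CRH/(Kd1+CRH)."""
        s = HPAState(CRH=0.4, ACTH=0.0, CORT=0.0, GR_mRNA=0.0, GR_free=0.0,
                     DR=0.0, DRN=0.0)
        d = hpa_derivatives(s, 0.0, 0.0, 1.0, hp)
        expected = hp.kp1 - hp.Vd1 * 0.4 / (hp.Kd1 + 0.4)
        assert d[0] == pytest.approx(expected, rel=1e-12)

    def test_sleep_doubles_clearance_at_half_saturation(self, hp):
        """At CRH = Kd1 the degradation term is Vd1*(1+ks*sleep)/2."""
        s = HPAState(CRH=hp.Kd1, ACTH=0.0, CORT=0.0, GR_mRNA=0.0,
                     GR_free=0.0, DR=0.0, DRN=0.0)
        awake = hpa_derivatives(s, 0.0, 0.0, 1.0, hp)[0]
        asleep = hpa_derivatives(s, 0.0, 1.0, 1.0, hp)[0]
        assert awake - asleep == pytest.approx(hp.Vd1 * hp.ks / 2.0, rel=1e-12)

    def test_cort_steady_state_algebra(self, hp):
        """CORT* solves kp3*ACTH = Vd3*CORT*/(Kd3+CORT*)."""
        acth = 0.5
        cort_star = brentq(
            lambda c: hp.kp3 * acth - hp.Vd3 * c / (hp.Kd3 + c), 1e-9, 50.0)
        s = HPAState(CRH=0.0, ACTH=acth, CORT=cort_star, GR_mRNA=0.0,
                     GR_free=0.0, DR=0.0, DRN=0.0)
        assert hpa_derivatives(s, 0.0, 0.0, 1.0, hp)[2] == \
            pytest.approx(0.0, abs=1e-12)

    def test_stress_multiplies_synthesis_only(self, hp):
        s = HPAState()
        base = np.array(hpa_derivatives(s, 0.4, 0.0, 1.0, hp))
        stressed = np.array(hpa_derivatives(s, 0.4, 0.0, 3.0, hp))
        synth = hp.kp1 * (1 + 0.4 / 1.4) * hp.Kp1 / (hp.Kp1 + s.DRN)
        assert stressed[0] - base[0] == pytest.approx(2.0 * synth, rel=1e-12)
        assert np.allclose(stressed[1:], base[1:])

    def test_drive_gain_saturates_below_two(self, hp):
        s = HPAState()
        lo = hpa_derivatives(s, 0.0, 0.0, 1.0, hp)[0]
        hi = hpa_derivatives(s, 1e9, 0.0, 1.0, hp)[0]
        synth = hp.kp1 * hp.Kp1 / (hp.Kp1 + s.DRN)
        assert hi - lo == pytest.approx(synth, rel=1e-6)  # factor 2 vs 1

    def test_negative_state_rejected(self, hp):
        s = HPAState(CRH=-0.1)
        with pytest.raises(ValueError):
            hpa_derivatives(s, 0.0, 0.0, 1.0, hp)
        with pytest.raises(ValueError):
            hpa_derivatives(HPAState(), 0.0, 0.0, 0.5, hp)


class TestSleepInhibitionSanity:
    def test_ks_zero_removes_sleep_effect(self):
        hp0 = HPAParams(ks=1e-12)
        s = HPAState(CRH=0.6, ACTH=0.4, CORT=0.8, GR_mRNA=0.5, GR_free=0.7,
                     DR=0.3, DRN=0.4)
        awake = hpa_derivatives(s, 0.3, 0.0, 1.0, hp0)
        asleep = hpa_derivatives(s, 0.3, 1.0, 1.0, hp0)
        assert np.allclose(awake, asleep, rtol=1e-9)


class TestFreeRunningPeriod:
    def test_synthetic_sinusoid_period_recovered(self):
        """A pure 24.3 h sinusoid injected as the cortisol trace must be
        measured as 24.30 +/- 0.01 h."""
        t = np.arange(0.0, 24.0 * 40, 0.05)
        df = pd.DataFrame({"time_h": t,
                           "CORT": 1.0 + np.sin(2 * np.pi * t / 24.3)})
        per = free_running_period(trajectory=df, discard_days=10)
        assert per == pytest.approx(24.30, abs=0.01)

    def test_too_few_peaks_raises(self):
        t = np.arange(0.0, 24.0 * 12, 0.05)
        df = pd.DataFrame({"time_h": t,
                           "CORT": 1.0 + np.sin(2 * np.pi * t / 24.3)})
        with pytest.raises(RuntimeError):
            free_running_period(trajectory=df, discard_days=10)

    def test_short_horizon_rejected(self):
        with pytest.raises(ValueError):
            free_running_period(horizon_days=10)


class TestEntrainedCortisolPhase:
    def test_peak_shortly_after_wake(self, nominal_cort_metrics,
                                     habitual_times):
        wake, sleep = habitual_times
        delta = (nominal_cort_metrics.peak_time - wake) % 24.0
        if delta > 12.0:
            delta -= 24.0
        assert -1.0 <= delta <= 3.0

    def test_nadir_shortly_before_sleep(self, nominal_cort_metrics,
                                        habitual_times):
        wake, sleep = habitual_times
        delta = (nominal_cort_metrics.nadir_time - sleep) % 24.0
        if delta > 12.0:
            delta -= 24.0
        assert -3.0 <= delta <= 1.0

    def test_rising_phase_shorter_than_falling(self, nominal_cort_metrics):
        m = nominal_cort_metrics
        rise = (m.peak_time - m.nadir_time) % 24.0
        assert rise < 24.0 - rise


class TestFeedbackSanity:
    def test_weaker_feedback_raises_mean_cortisol(self):
        """Increasing Kp1 (weaker DRN repression of CRH synthesis) must
        raise the daily mean of cortisol."""
        from dataclasses import replace

        from circort import engine, protocols
        from circort.params import default_params

        st = engine.SimulationSettings(t0=0.0, t_end=24.0 * 10, output_dt=0.2)
        proto = protocols.make_nominal_protocol()
        means = []
        for kp1_scale in (1.0, 1.6):
            p = default_params()
            p = replace(p, hpa=replace(p.hpa, Kp1=p.hpa.Kp1 * kp1_scale))
            traj = engine.integrate(proto, p, st)
            means.append(traj.final_day()["CORT"].mean())
        assert means[1] > means[0]
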