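import numpy as np
import pytest

from ceftazpk import (
    ConcentrationProfile,
    DoseEvent,
    IndividualParameters,
    PopulationParameters,
    Regimen,
    individual_parameters,
    typical_clearance,
)
from conftest import random_subject
import oracles


class TestTypicalClearance:
    def test_reference_value(self, pop):
        # at the reference eGFR without co-antibiotics the equation returns
        # the typical clearance itself
        assert typical_clearance(76.86, 0, pop) == pytest.approx(3.74, abs=1e-12)

    def test_antibiotic_factor(self, pop):
        assert typical_clearance(76.86, 1, pop) == pytest.approx(3.74 * 1.56, rel=1e-12)

    def test_severe_impairment_value(self, pop):
        # 3.74 * (18.6/76.86)^0.75, evaluated by hand beforehand
        assert typical_clearance(18.6, 0, pop) == pytest.approx(1.2904, rel=1e-4)

    def test_monotone_in_egfr(self, pop):
        egfr = np.linspace(5, 150, 60)
        cl = typical_clearance(egfr, 0, pop)
        assert np.all(np.diff(cl) > 0)

    def test_domain_error(self, pop):
        with pytest.raises(ValueError):
            typical_clearance(0.0, 0, pop)
        with pytest.raises(ValueError):
            typical_clearance(-5.0, 1, pop)


class TestIndividualParameters:
    def test_zero_eta_gives_typical_values(self, pop):
        ip = individual_parameters(76.86, 0, 0.0, 0.0, pop)
        assert ip.cl == pytest.approx(3.74)
        assert ip.v == pytest.approx(21.8)
        assert ip.ke == pytest.approx(3.74 / 21.8)

    def test_lognormal_construction(self, pop):
        base = individual_parameters(60.0, 1, 0.0, 0.0, pop)
        doubled = individual_parameters(60.0, 1, np.log(2.0), 0.0, pop)
        assert doubled.cl == pytest.approx(2 * base.cl, rel=1e-12)

    def test_non_finite_eta_rejected(self, pop):
        with pytest.raises(ValueError):
            individual_parameters(60.0, 0, np.inf, 0.0, pop)


class TestCvConvention:
    def test_sd_convention_reports_omega_directly(self):
        pop = PopulationParameters()  # default convention
        assert pop.cv_cl_percent == pytest.approx(31.3)
        assert pop.cv_v_percent == pytest.approx(40.2)

    def test_geometric_convention_matches_monte_carlo(self, rng):
        # under the geometric convention the realised coefficient of
        # variation of CL equals the reported %CV
        omega = PopulationParameters.omega_from_cv(31.3, "geometric")
        pop = PopulationParameters(omega_cl=omega, cv_convention="geometric")
        cl = 3.74 * np.exp(rng.normal(0.0, pop.omega_cl, size=100_000))
        cv = 100.0 * cl.std() / cl.mean()
        assert cv == pytest.approx(31.3, rel=0.01)
        assert pop.cv_cl_percent == pytest.approx(31.3, rel=1e-9)


class TestConcentration:
    def test_zero_before_first_dose(self, pop):
        ip = individual_parameters(76.86, 0, 0, 0, pop)
        prof = ConcentrationProfile(ip, Regimen.uniform(2000, 8, 3, start=2.0))
        assert prof.concentration(0.0) == 0.0
        assert prof.concentration(1.999) == 0.0
        assert prof.concentration(2.5) > 0.0

    def test_bolus_limit(self, pop):
        # as the infusion duration shrinks the post-dose concentration
        # approaches amount / V
        ip = individual_parameters(76.86, 0, 0, 0, pop)
        prof = ConcentrationProfile(
            ip, Regimen((DoseEvent(0.0, 2000.0, 1e-9),))
        )
        assert prof.concentration(1e-9) == pytest.approx(2000.0 / 21.8, rel=1e-5)

    def test_matches_ode_integration(self, rng):
        for _ in range(5):
            ip, reg = random_subject(rng)
            prof = ConcentrationProfile(ip, reg)
            t = np.sort(rng.uniform(0.0, 48.0, size=12))
            ours = prof.concentration(t)
            ode = oracles.ode_concentrations(ip, reg, t)
            assert np.allclose(ours, ode, rtol=1e-6, atol=1e-9)

    def test_dose_linearity(self, rng):
        for _ in range(20):
            ip, reg = random_subject(rng)
            k = float(rng.uniform(0.2, 5.0))
            t = np.sort(rng.uniform(0.0, 48.0, size=20))
            c1 = ConcentrationProfile(ip, reg).concentration(t)
            ck = ConcentrationProfile(ip, reg.scaled(k)).concentration(t)
            assert np.allclose(ck, k * c1, rtol=1e-12, atol=1e-12)

    def test_superposition(self, rng):
        for _ in range(10):
            ip, reg = random_subject(rng)
            t = np.sort(rng.uniform(0.0, 48.0, size=20))
            total = ConcentrationProfile(ip, reg).concentration(t)
            parts = sum(
                ConcentrationProfile(ip, Regimen((d,))).concentration(t)
                for d in reg.doses
            )
            assert np.allclose(total, parts, rtol=1e-10, atol=1e-12)


class TestAuc:
    def test_additive_over_adjacent_windows(self, rng):
        for _ in range(10):
            ip, reg = random_subject(rng)
            prof = ConcentrationProfile(ip, reg)
            assert prof.auc(0, 24) + prof.auc(24, 48) == pytest.approx(
                prof.auc(0, 48), rel=1e-12
            )

    def test_steady_state_interval_equals_dose_over_cl(self, pop):
        # mass balance for a fully (renally) cleared drug at steady state
        ip = individual_parameters(102.8, 1, 0.1, -0.1, pop)
        reg = Regimen.uniform(2000, 8, 60)
        prof = ConcentrationProfile(ip, reg)
        assert prof.auc(400, 408) == pytest.approx(2000.0 / ip.cl, rel=1e-6)

    def test_reversed_window_rejected(self, pop):
        ip = individual_parameters(76.86, 0, 0, 0, pop)
        prof = ConcentrationProfile(ip, Regimen.uniform(2000, 8, 3))
        with pytest.raises(ValueError):
            prof.auc(10.0, 2.0)


class TestTimeAboveMic:
    def test_zero_mic_gives_window_past_first_dose(self, pop):
        ip = individual_parameters(76.86, 0, 0, 0, pop)
        prof = ConcentrationProfile(ip, Regimen.uniform(2000, 8, 3, start=3.0))
        assert prof.time_above_mic(0.0, 0.0, 24.0) == pytest.approx(21.0, abs=1e-9)

    def test_mic_above_cmax_gives_zero(self, pop):
        ip = individual_parameters(76.86, 0, 0, 0, pop)
        prof = ConcentrationProfile(ip, Regimen.uniform(2000, 8, 3))
        cmax = prof.max_concentration(0, 24)
        assert prof.time_above_mic(cmax * 1.01, 0, 24) == 0.0

    def test_negative_mic_rejected(self, pop):
        ip = individual_parameters(76.86, 0, 0, 0, pop)
        prof = ConcentrationProfile(ip, Regimen.uniform(2000, 8, 3))
        with pytest.raises(ValueError):
            prof.time_above_mic(-1.0, 0, 24)

    def test_monotone_in_mic_and_dose(self, rng):
        for _ in range(20):
            ip, reg = random_subject(rng)
            prof = ConcentrationProfile(ip, reg)
            mics = [0.125, 0.5, 2.0, 8.0, 32.0]
            t = [prof.time_above_mic(m, 0, 24) for m in mics]
            assert all(a >= b - 1e-12 for a, b in zip(t, t[1:]))
            bigger = ConcentrationProfile(ip, reg.scaled(1.5))
            for m in mics:
                assert bigger.time_above_mic(m, 0, 24) >= prof.time_above_mic(
                    m, 0, 24
                ) - 1e-12


class TestRegimenValidation:
    def test_bad_doses_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, -100.0, 0.5)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 100.0, 0.0)
        with pytest.raises(ValueError):
            Regimen((DoseEvent(8.0, 100.0), DoseEvent(0.0, 100.0)))

    def test_overlapping_infusions_warn_but_superpose(self, pop):
        with pytest.warns(UserWarning, match="overlapping"):
            reg = Regimen((DoseEvent(0.0, 1000.0, 1.0), DoseEvent(0.5, 1000.0, 1.0)))
        ip = individual_parameters(76.86, 0, 0, 0, pop)
        assert ConcentrationProfile(ip, reg).concentration(0.75) > 0
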