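import numpy as np
import pandas as pd
import pytest

from ceftazpk import (
    ConcentrationProfile,
    IndividualParameters,
    Regimen,
    individual_parameters,
)
from ceftazpk.targets import (
    TARGET_50_0_24,
    TARGET_50_24_48,
    TARGET_100_0_24,
    TargetDefinition,
    attains_target,
    exposure_summary,
    pta_table,
)


class _StubProfile:
    """Duck-typed profile returning a prescribed time above MIC."""

    def __init__(self, hours, auc=100.0):
        self._hours = hours
        self._auc = auc

    def time_above_mic(self, mic, t0, t1):
        return self._hours

    def auc(self, t0, t1):
        return self._auc


class TestAttainsTarget:
    def test_always_above_mic_attains_everything(self, pop):
        ip = individual_parameters(18.6, 0, 0, 0, pop)
        prof = ConcentrationProfile(ip, Regimen.uniform(2000, 8, 6))
        for target in (TARGET_50_0_24, TARGET_100_0_24, TARGET_50_24_48):
            assert attains_target(prof, 0.125, target)

    def test_exactly_twelve_hours_fails_strict_target(self):
        # the 50% targets require strictly more than 12 h
        assert not attains_target(_StubProfile(12.0), 8.0, TARGET_50_0_24)
        assert attains_target(_StubProfile(12.0 + 1e-9), 8.0, TARGET_50_0_24)

    def test_100_percent_target_at_boundary(self):
        # 23.5 h of the first 24 h, inclusive
        assert attains_target(_StubProfile(23.5), 8.0, TARGET_100_0_24)
        assert not attains_target(_StubProfile(23.49), 8.0, TARGET_100_0_24)

    def test_typical_severe_subject_verified_against_grid(self, pop, rng):
        import oracles

        ip = individual_parameters(18.6, 0, 0, 0, pop)
        reg = Regimen.uniform(1000, 24, 1)
        prof = ConcentrationProfile(ip, reg)
        t_closed = prof.time_above_mic(8.0, 0, 24)
        times, conc = oracles.grid_concentrations(ip, reg, 24.0)
        t_grid = oracles.grid_time_above(times, conc, 8.0, 0, 24)
        assert t_closed == pytest.approx(t_grid, abs=2e-3)
        assert attains_target(prof, 8.0, TARGET_50_0_24)

    def test_invalid_target_definition(self):
        with pytest.raises(ValueError):
            TargetDefinition("bad", (0.0, 24.0), 25.0)
        with pytest.raises(ValueError):
            TargetDefinition("bad", (24.0, 24.0), 1.0)


def _toy_cohort(n_attain, n_total, group="II"):
    subjects = pd.DataFrame(
        {"ID": range(1, n_total + 1), "GROUP": group,
         "MISDOSE": 0, "SHORT_COURSE": 0}
    )
    profiles = {
        i: _StubProfile(20.0 if i <= n_attain else 5.0)
        for i in range(1, n_total + 1)
    }
    return subjects, profiles


class TestPtaTable:
    def test_nine_of_ten_is_ninety_percent(self):
        subjects, profiles = _toy_cohort(9, 10)
        out = pta_table(subjects, profiles, TARGET_50_0_24, mic_grid=(8.0,))
        row = out.iloc[0]
        assert (row["attained"], row["eligible"]) == (9, 10)
        assert row["pta"] == pytest.approx(0.9)
        assert bool(row["adequate"])

    def test_fraction_monotone_over_mic_grid(self, pop, rng):
        subjects = pd.DataFrame({"ID": range(1, 11), "GROUP": "I",
                                 "MISDOSE": 0, "SHORT_COURSE": 0})
        profiles = {}
        for i in range(1, 11):
            ip = individual_parameters(
                float(rng.uniform(55, 130)), int(rng.random() < 0.5),
                float(rng.normal(0, 0.3)), float(rng.normal(0, 0.4)), pop,
            )
            profiles[i] = ConcentrationProfile(ip, Regimen.uniform(2000, 8, 3))
        out = pta_table(subjects, profiles, TARGET_50_0_24)
        assert (out.groupby("group")["pta"].apply(
            lambda s: (s.diff().dropna() <= 1e-12).all()
        )).all()

    def test_misdose_counts_for_primary_but_not_secondary(self):
        subjects = pd.DataFrame(
            {"ID": [1, 2], "GROUP": "III", "MISDOSE": [1, 0], "SHORT_COURSE": 0}
        )
        profiles = {1: _StubProfile(24.0), 2: _StubProfile(24.0)}
        primary = pta_table(subjects, profiles, TARGET_50_0_24, mic_grid=(8.0,))
        secondary = pta_table(subjects, profiles, TARGET_100_0_24, mic_grid=(8.0,))
        assert primary.iloc[0]["eligible"] == 2
        assert secondary.iloc[0]["eligible"] == 1


class TestExposureSummary:
    def test_identical_groups_give_null_statistic(self):
        subjects = pd.DataFrame({"ID": range(1, 7),
                                 "GROUP": ["I", "I", "II", "II", "III", "III"],
                                 "MISDOSE": 0, "SHORT_COURSE": 0})
        profiles = {i: _StubProfile(20.0, auc=500.0) for i in range(1, 7)}
        out = exposure_summary(subjects, profiles)
        assert out["auc_0_24"]["kruskal_statistic"] == 0.0
        assert out["auc_0_24"]["p_value"] == 1.0

    def test_kruskal_statistic_matches_hand_rank_computation(self):
        # groups with AUCs {1,2}, {3,4}, {5,6}: mean ranks 1.5 / 3.5 / 5.5,
        # H = 12/(6*7) * 2*((1.5-3.5)^2 + 0 + (5.5-3.5)^2) = 32/7
        subjects = pd.DataFrame({"ID": range(1, 7),
                                 "GROUP": ["I", "I", "II", "II", "III", "III"],
                                 "MISDOSE": 0, "SHORT_COURSE": 0})
        profiles = {i: _StubProfile(20.0, auc=float(i)) for i in range(1, 7)}
        out = exposure_summary(subjects, profiles)
        assert out["auc_0_24"]["kruskal_statistic"] == pytest.approx(32 / 7)

    def test_steady_state_auc_equals_dose_over_clearance(self, pop):
        ip = individual_parameters(34.3, 0, 0.0, 0.0, pop)
        prof = ConcentrationProfile(ip, Regimen.uniform(1000, 12, 40))
        assert prof.auc(240, 252) == pytest.approx(1000.0 / ip.cl, rel=1e-6)

    def test_single_group_rejected(self):
        subjects = pd.DataFrame({"ID": [1, 2], "GROUP": "I",
                                 "MISDOSE": 0, "SHORT_COURSE": 0})
        profiles = {1: _StubProfile(20.0), 2: _StubProfile(20.0)}
        with pytest.raises(ValueError):
            exposure_summary(subjects, profiles)
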