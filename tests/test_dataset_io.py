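import numpy as np
import pandas as pd
import pytest

from ceftazpk.dataset_io import (
    Dataset,
    apply_blq_rule,
    clean_dataset,
    drop_duplicate_timepoints,
    egfr_ckdepi,
    egfr_cockcroft_gault,
    egfr_mdrd,
    read_dataset,
    renal_group,
    write_dataset,
)


def _toy_dataset(obs_rows=None):
    """Three-subject dataset built programmatically."""
    base_cov = {"EGFR_CKDEPI": 90.0, "ABX": 0}
    rows = []
    for sid in (1, 2, 3):
        rows.append({"ID": sid, "TIME": 0.0, "EVID": 1, "AMT": 2000.0, "DUR": 0.5,
                     "DV": np.nan, "BLQ": 0, **base_cov})
        for t, dv, blq in (obs_rows or [(2.0, 30.0, 0), (7.5, 10.0, 0)]):
            rows.append({"ID": sid, "TIME": t, "EVID": 0, "AMT": np.nan,
                         "DUR": np.nan, "DV": dv, "BLQ": blq, **base_cov})
    return Dataset(pd.DataFrame(rows))


class TestReadWrite:
    def test_round_trip(self, tmp_path, default_cohort):
        ds, _ = default_cohort
        path = tmp_path / "ds.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.n_subjects == ds.n_subjects
        pd.testing.assert_frame_equal(
            back.events[["ID", "TIME", "EVID", "AMT", "DV"]],
            ds.events[["ID", "TIME", "EVID", "AMT", "DV"]],
        )

    def test_fixture_dataset_has_three_subjects(self):
        assert _toy_dataset().n_subjects == 3

    def test_missing_column_named_in_error(self, tmp_path):
        df = _toy_dataset().events.drop(columns=["DV"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="DV"):
            read_dataset(path)

    def test_non_monotone_times_rejected(self):
        ev = _toy_dataset().events.copy()
        ev.loc[ev.index[-1], "TIME"] = 0.5  # observation before previous one
        with pytest.raises(ValueError, match="non-monotone"):
            Dataset(ev)

    def test_column_remapping(self, tmp_path):
        df = _toy_dataset().events.rename(columns={"DV": "CONC"})
        path = tmp_path / "remap.csv"
        df.to_csv(path, index=False)
        ds = read_dataset(path, column_map={"CONC": "DV"})
        assert "DV" in ds.events.columns


class TestBlqRule:
    def test_single_blq_imputed_at_half_lloq(self):
        ds = _toy_dataset(obs_rows=[(2.0, 30.0, 0), (7.5, np.nan, 1)])
        out = apply_blq_rule(ds)
        blq = out.events[(out.events["EVID"] == 0) & (out.events["BLQ"] == 1)]
        assert np.allclose(blq["DV"], 0.05)

    def test_consecutive_blq_dropped(self):
        ds = _toy_dataset(
            obs_rows=[(2.0, 30.0, 0), (7.0, np.nan, 1), (8.0, np.nan, 1)]
        )
        out = apply_blq_rule(ds)
        per_subject = out.observations().groupby("ID").size()
        assert (per_subject == 2).all()  # one of three observations dropped
        kept_blq = out.events[out.events["BLQ"] == 1]
        assert np.allclose(kept_blq["DV"], 0.05)
        assert np.allclose(kept_blq["TIME"], 7.0)

    def test_no_blq_unchanged(self):
        ds = _toy_dataset()
        out = apply_blq_rule(ds)
        pd.testing.assert_frame_equal(out.events, ds.events)


class TestDuplicateRule:
    def test_duplicate_keeps_first(self):
        ds = _toy_dataset(obs_rows=[(2.0, 30.0, 0), (2.0, 29.0, 0)])
        out = drop_duplicate_timepoints(ds)
        obs = out.observations()
        assert (obs.groupby("ID").size() == 1).all()
        assert np.allclose(obs["DV"], 30.0)

    def test_triple_duplicate_leaves_one(self):
        ds = _toy_dataset(obs_rows=[(2.0, 30.0, 0), (2.0, 29.0, 0), (2.0, 28.0, 0)])
        out = drop_duplicate_timepoints(ds)
        assert (out.observations().groupby("ID").size() == 1).all()

    def test_distinct_times_unchanged(self):
        ds = _toy_dataset()
        out = drop_duplicate_timepoints(ds)
        pd.testing.assert_frame_equal(out.events, ds.events)


class TestCleaningProperties:
    def test_cleaning_is_idempotent(self):
        ds = _toy_dataset(
            obs_rows=[(2.0, 30.0, 0), (2.0, 29.0, 0), (7.0, np.nan, 1), (8.0, np.nan, 1)]
        )
        once = clean_dataset(ds)
        twice = clean_dataset(once)
        pd.testing.assert_frame_equal(once.events, twice.events)

    def test_cleaning_never_touches_dose_rows(self):
        ds = _toy_dataset(obs_rows=[(2.0, np.nan, 1), (3.0, np.nan, 1)])
        out = clean_dataset(ds)
        pd.testing.assert_frame_equal(
            out.doses().reset_index(drop=True), ds.doses().reset_index(drop=True)
        )


class TestRenalFormulas:
    def test_ckdepi_hand_value(self):
        # female, 60 y, creatinine 70.72 umol/L (= 0.8 mg/dL):
        # 141 * (0.8/0.7)^-1.209 * 0.993^60 * 1.018, evaluated by hand
        expected = 141.0 * (0.8 / 0.7) ** -1.209 * 0.993**60 * 1.018
        assert egfr_ckdepi(70.72, 60, "F") == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(80.1, abs=1.0)

    def test_monotone_decreasing_in_creatinine(self):
        for fn in (egfr_ckdepi, egfr_mdrd):
            assert fn(160.0, 55, "M") < fn(80.0, 55, "M")
        assert egfr_cockcroft_gault(160.0, 55, 80.0, "M") < egfr_cockcroft_gault(
            80.0, 55, 80.0, "M"
        )

    def test_race_term_is_optional(self):
        without = egfr_ckdepi(100.0, 50, "M", black=True, race_term=False)
        with_term = egfr_ckdepi(100.0, 50, "M", black=True, race_term=True)
        assert with_term == pytest.approx(1.159 * without)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            egfr_ckdepi(-1.0, 50, "M")
        with pytest.raises(ValueError):
            egfr_mdrd(80.0, 10, "F")

    def test_renal_group_assignment(self):
        assert renal_group(102.8) == "I"
        assert renal_group(50.0) == "I"  # boundary belongs to group I
        assert renal_group(34.3) == "II"
        assert renal_group(29.99) == "III"
        with pytest.raises(ValueError):
            renal_group(0.0)
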