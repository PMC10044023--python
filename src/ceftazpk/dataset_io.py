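"""Longitudinal analysis-dataset handling.

The on-disk format is a NONMEM-flavoured CSV: one row per event, ``EVID=1``
for dose rows (with ``AMT`` mg and ``DUR`` h) and ``EVID=0`` for observation
rows (with ``DV`` mg/L and a ``BLQ`` flag), plus subject-constant covariate
columns.  Times are hours since the subject's first dose.

Sample-handling rules applied before model fitting:

* observations below the lower limit of quantification (LLOQ, 0.1 mg/L) are
  imputed at half the LLOQ, but a BLQ observation immediately following
  another BLQ observation from the same subject is excluded;
* duplicate observations at the same time point in the same subject keep the
  first occurrence only.

Renal-function grouping (eGFR, CKD-EPI, mL/min/1.73 m^2): group I >= 50,
group II [30, 50), group III < 30; the boundary value 50 belongs to group I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

LLOQ_DEFAULT = 0.1  # mg/L
ULOQ_DEFAULT = 40.0  # mg/L

#: required event columns of the CSV dialect
EVENT_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "BLQ"]

#: covariate columns (subject-constant); all optional except EGFR_CKDEPI and ABX
COVARIATE_COLUMNS = [
    "EGFR_CKDEPI",
    "EGFR_MDRD",
    "EGFR_CG",
    "SCR",
    "AGE",
    "WT",
    "HT",
    "BMI",
    "SEX",
    "ETHNICITY",
    "WARD_ORTHO",
    "WARD_HEMA",
    "FEVER",
    "ABX",
    "MISDOSE",
    "SHORT_COURSE",
]

REQUIRED_COLUMNS = EVENT_COLUMNS + ["EGFR_CKDEPI", "ABX"]


@dataclass
class Dataset:
    """Event rows grouped by subject plus assay limits."""

    events: pd.DataFrame
    lloq: float = LLOQ_DEFAULT
    uloq: float = ULOQ_DEFAULT

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"dataset missing required column(s): {', '.join(missing)}")
        ev = self.events
        if (ev["TIME"] < 0).any():
            row = int(ev.index[ev["TIME"] < 0][0])
            raise ValueError(f"negative TIME at row {row}")
        for sid, grp in ev.groupby("ID", sort=False):
            t = grp["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError(f"non-monotone TIME for subject {sid!r}")
            if not (grp["EVID"] == 1).any():
                raise ValueError(f"subject {sid!r} has no dose rows")

    # ------------------------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(self.events["ID"].drop_duplicates())

    @property
    def n_subjects(self) -> int:
        return self.events["ID"].nunique()

    def subject(self, sid) -> pd.DataFrame:
        return self.events[self.events["ID"] == sid]

    def observations(self) -> pd.DataFrame:
        return self.events[self.events["EVID"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.events[self.events["EVID"] == 1]

    def covariates(self) -> pd.DataFrame:
        """One row per subject with the subject-constant covariate columns."""
        cols = [c for c in COVARIATE_COLUMNS if c in self.events.columns]
        return self.events.groupby("ID", sort=False)[cols].first()

    def subset(self, subject_ids) -> "Dataset":
        keep = self.events["ID"].isin(list(subject_ids))
        return Dataset(self.events[keep].reset_index(drop=True), self.lloq, self.uloq)

    def copy(self) -> "Dataset":
        return Dataset(self.events.copy(), self.lloq, self.uloq)


def read_dataset(
    path,
    column_map: dict | None = None,
    lloq: float = LLOQ_DEFAULT,
    uloq: float = ULOQ_DEFAULT,
) -> Dataset:
    """Read the CSV dialect; ``column_map`` renames external headers to ours."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    for col in ("TIME", "EVID"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(df.index[bad | df[col].isna()][0])
            raise ValueError(f"{path.name}: unparseable {col} at row {row}")
        df[col] = pd.to_numeric(df[col])
    return Dataset(df.reset_index(drop=True), lloq=lloq, uloq=uloq)


def write_dataset(ds: Dataset, path) -> None:
    ds.events.to_csv(path, index=False)


def load_io_config(path) -> dict:
    """YAML config with keys ``lloq``, ``uloq`` and ``column_map``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return {
        "lloq": float(cfg.get("lloq", LLOQ_DEFAULT)),
        "uloq": float(cfg.get("uloq", ULOQ_DEFAULT)),
        "column_map": cfg.get("column_map") or None,
    }


# ----------------------------------------------------------------------
# cleaning rules
# ----------------------------------------------------------------------

def apply_blq_rule(ds: Dataset) -> Dataset:
    """Impute the first BLQ observation of a run at 0.5*LLOQ; drop later ones.

    A BLQ observation whose immediately preceding observation from the same
    subject was also BLQ carries no additional information and is excluded.
    """
    ev = ds.events.copy()
    drop_idx = []
    for sid, grp in ev[ev["EVID"] == 0].groupby("ID", sort=False):
        prev_blq = False
        for idx, row in grp.iterrows():
            is_blq = bool(row["BLQ"])
            if is_blq and prev_blq:
                drop_idx.append(idx)
                logger.info("BLQ rule: dropping consecutive BLQ row %s (subject %s)", idx, sid)
            elif is_blq:
                ev.loc[idx, "DV"] = 0.5 * ds.lloq
                logger.info(
                    "BLQ rule: imputing row %s (subject %s) at %.3g mg/L",
                    idx, sid, 0.5 * ds.lloq,
                )
            prev_blq = is_blq
    ev = ev.drop(index=drop_idx).reset_index(drop=True)
    return Dataset(ev, ds.lloq, ds.uloq)


def drop_duplicate_timepoints(ds: Dataset) -> Dataset:
    """Keep the first observation for exact (subject, time) duplicates."""
    ev = ds.events
    obs = ev["EVID"] == 0
    dup = obs & ev.duplicated(subset=["ID", "TIME", "EVID"], keep="first")
    for idx in ev.index[dup]:
        logger.info(
            "duplicate-timepoint rule: dropping row %s (subject %s, t=%.3g h)",
            idx, ev.loc[idx, "ID"], ev.loc[idx, "TIME"],
        )
    return Dataset(ev[~dup].reset_index(drop=True), ds.lloq, ds.uloq)


def clean_dataset(ds: Dataset) -> Dataset:
    """Duplicate-timepoint rule followed by the BLQ rule (both idempotent)."""
    return apply_blq_rule(drop_duplicate_timepoints(ds))


# ----------------------------------------------------------------------
# renal-function formulas and grouping
# ----------------------------------------------------------------------

UMOL_PER_MGDL = 88.4  # creatinine unit conversion


def _check_renal_inputs(scr: float, age: float) -> None:
    if scr <= 0:
        raise ValueError("serum creatinine must be positive")
    if age < 18:
        raise ValueError("formulas are for adults (age >= 18)")


def egfr_ckdepi(
    scr: float, age: float, sex: str, black: bool = False, race_term: bool = False
) -> float:
    """2009 CKD-EPI eGFR (mL/min/1.73 m^2) from creatinine in umol/L.

    The race coefficient is off by default; set ``race_term=True`` to apply
    the original 1.159 factor for Black patients.
    """
    _check_renal_inputs(scr, age)
    scr_mgdl = scr / UMOL_PER_MGDL
    female = str(sex).upper().startswith("F")
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    ratio = scr_mgdl / kappa
    out = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993**age
    if female:
        out *= 1.018
    if race_term and black:
        out *= 1.159
    return out


def egfr_mdrd(
    scr: float, age: float, sex: str, black: bool = False, race_term: bool = True
) -> float:
    """4-variable MDRD (IDMS-traceable, 175 coefficient), creatinine in umol/L."""
    _check_renal_inputs(scr, age)
    scr_mgdl = scr / UMOL_PER_MGDL
    out = 175.0 * scr_mgdl**-1.154 * age**-0.203
    if str(sex).upper().startswith("F"):
        out *= 0.742
    if race_term and black:
        out *= 1.212
    return out


def egfr_cockcroft_gault(scr: float, age: float, weight: float, sex: str) -> float:
    """Cockcroft–Gault creatinine clearance (mL/min), creatinine in umol/L."""
    _check_renal_inputs(scr, age)
    if weight <= 0:
        raise ValueError("weight must be positive")
    out = (140.0 - age) * weight / (0.815 * scr)
    if str(sex).upper().startswith("F"):
        out *= 0.85
    return out


RENAL_GROUPS = ("I", "II", "III")


def renal_group(egfr: float) -> str:
    """Assign the guideline renal-function group from eGFR (CKD-EPI)."""
    if egfr <= 0:
        raise ValueError("egfr must be positive")
    if egfr >= 50:
        return "I"
    if egfr >= 30:
        return "II"
    return "III"


#: guideline ceftazidime regimen per renal group: (amount mg, interval h)
GUIDELINE_DOSING = {"I": (2000.0, 8.0), "II": (1000.0, 12.0), "III": (1000.0, 24.0)}
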