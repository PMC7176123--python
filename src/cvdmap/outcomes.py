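"""Derive the four binary cardiovascular outcomes and model covariates.

Each condition is a composite OR-rule over clinical measurements and
self-reports.  Missingness propagates conservatively: any positive piece of
evidence yields 1 even when other fields are missing; a 0 requires at least
one observed field with all observed evidence negative; when every
contributing field is missing the outcome is missing.  This is the unique
monotone completion of the printed definitions, and no imputation is done.

Cut-offs (all inclusive on the adverse side unless noted):
  hypertension     SBP >= 140 mmHg or DBP >= 90 mmHg, or self-report/medication
  dyslipidaemia    TC >= 6.22, TG >= 1.69, LDL >= 4.14 mmol/L,
                   HDL < 1.04 (men) / < 1.29 (women), or drugs/diagnosis
  diabetes         HbA1c >= 6.5 %, or history/treatment
  BMI class        underweight < 18.5 <= normal < 25.0 <= overweight
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# thresholds, mmHg / mmol/L / % / kg/m^2
SBP_CUTOFF = 140.0
DBP_CUTOFF = 90.0
TC_CUTOFF = 6.22
TG_CUTOFF = 1.69
LDL_CUTOFF = 4.14
HDL_CUTOFF_MALE = 1.04
HDL_CUTOFF_FEMALE = 1.29
HBA1C_CUTOFF = 6.5
BMI_UNDERWEIGHT = 18.5
BMI_OVERWEIGHT = 25.0

#: physiologic sanity ranges applied at record load (min, max, inclusive)
SANITY_RANGES: dict[str, tuple[float, float]] = {
    "sbp": (60.0, 300.0),
    "dbp": (30.0, 200.0),
    "tc": (1.0, 20.0),
    "tg": (0.1, 30.0),
    "ldl": (0.3, 15.0),
    "hdl": (0.1, 5.0),
    "hba1c": (2.0, 20.0),
    "bmi": (10.0, 80.0),
}

#: column dictionary for the participant CSV
COLUMNS = {
    "district": "district code (joins the adjacency structure)",
    "interview_weight": "survey design weight, all interviewed participants",
    "biomarker_weight": "design weight for the biomarker-consenting subset (NA otherwise)",
    "sex": "male / female",
    "age_group": "15-24 / 25-34 / 35-44 / 45-54 / 55-64 / 65+",
    "education": "no_school / primary / secondary / matric / higher",
    "race": "african / white / coloured / indian_asian / other",
    "locality": "urban_formal / urban_informal / rural_tribal / rural_formal",
    "smoking": "never / ex_smoker / current",
    "alcohol": "never / current",
    "wealth_quintile": "Q1..Q5",
    "sbp": "systolic blood pressure, mmHg",
    "dbp": "diastolic blood pressure, mmHg",
    "self_hbp": "self-reported history of high blood pressure {1,0,NA}",
    "hbp_medication": "on blood-pressure medication {1,0,NA}",
    "self_ihd": "self-reported heart attack / angina / chest pain {1,0,NA}",
    "self_stroke": "self-reported history of stroke {1,0,NA}",
    "lipid_drugs": "on lipid-lowering drugs {1,0,NA}",
    "dyslip_diagnosis": "diagnosed dyslipidaemia {1,0,NA}",
    "tc": "total cholesterol, mmol/L",
    "tg": "triglycerides, mmol/L",
    "ldl": "LDL cholesterol, mmol/L",
    "hdl": "HDL cholesterol, mmol/L",
    "hba1c": "glycated haemoglobin, %",
    "diabetes_history": "diagnosed diabetes {1,0,NA}",
    "diabetes_treatment": "on diabetes treatment {1,0,NA}",
    "bmi": "body-mass index, kg/m^2",
}

OUTCOME_NAMES = ["hbp", "ihd", "stroke", "dyslip"]


class RecordValidationError(ValueError):
    """A participant record violates a sanity range or typing contract."""


@dataclass
class DerivationReport:
    """Missingness and error bookkeeping from a derivation pass."""

    n_records: int
    missing_counts: dict[str, int]
    errors: list[str]

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "missing_counts": self.missing_counts,
            "errors": self.errors,
        }


def _or_rule(*evidence: np.ndarray) -> np.ndarray:
    """Composite OR over tri-state {1, 0, nan} evidence columns.

    1 if any evidence is 1; 0 if at least one observed and none positive;
    nan if everything is missing.
    """
    ev = np.vstack([np.asarray(e, dtype=float) for e in evidence])
    any_pos = np.nanmax(np.where(np.isnan(ev), -np.inf, ev), axis=0) >= 1
    all_missing = np.isnan(ev).all(axis=0)
    out = np.where(any_pos, 1.0, 0.0)
    out[all_missing & ~any_pos] = np.nan
    return out


def _ge(x: np.ndarray, cutoff: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.where(x >= cutoff, 1.0, 0.0)
    out[np.isnan(x)] = np.nan
    return out


def _lt(x: np.ndarray, cutoff: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.where(x < cutoff, 1.0, 0.0)
    out[np.isnan(x)] = np.nan
    return out


def derive_hypertension(df: pd.DataFrame) -> np.ndarray:
    """High blood pressure: measured SBP/DBP over cut-off, history, or medication."""
    return _or_rule(
        _ge(df["sbp"], SBP_CUTOFF),
        _ge(df["dbp"], DBP_CUTOFF),
        df["self_hbp"],
        df["hbp_medication"],
    )


def derive_dyslipidaemia(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Dyslipidaemia composite; HDL evidence is sex-specific.

    Returns (outcome, error_mask); the error mask flags records whose only
    interpretable HDL evidence is blocked by a missing sex.
    """
    sex = df["sex"].astype("string").str.lower()
    hdl = np.asarray(df["hdl"], dtype=float)
    hdl_low = np.full(len(df), np.nan)
    male = (sex == "male").fillna(False).to_numpy(dtype=bool)
    female = (sex == "female").fillna(False).to_numpy(dtype=bool)
    hdl_low[male] = _lt(hdl[male], HDL_CUTOFF_MALE)
    hdl_low[female] = _lt(hdl[female], HDL_CUTOFF_FEMALE)
    errors = ~np.isnan(hdl) & ~(male | female)
    out = _or_rule(
        df["lipid_drugs"],
        df["dyslip_diagnosis"],
        _ge(df["tc"], TC_CUTOFF),
        _ge(df["tg"], TG_CUTOFF),
        _ge(df["ldl"], LDL_CUTOFF),
        hdl_low,
    )
    return out, errors


def derive_diabetes(df: pd.DataFrame) -> np.ndarray:
    """Diabetes / impaired glucose metabolism: HbA1c >= 6.5 %, history, or treatment."""
    return _or_rule(
        _ge(df["hba1c"], HBA1C_CUTOFF),
        df["diabetes_history"],
        df["diabetes_treatment"],
    )


def classify_bmi(bmi) -> np.ndarray:
    """Map BMI to {underweight, normal, overweight}; missing stays missing."""
    bmi = np.asarray(bmi, dtype=float)
    out = np.full(bmi.shape, None, dtype=object)
    out[bmi < BMI_UNDERWEIGHT] = "underweight"
    out[(bmi >= BMI_UNDERWEIGHT) & (bmi < BMI_OVERWEIGHT)] = "normal"
    out[bmi >= BMI_OVERWEIGHT] = "overweight"
    return out


def validate_records(df: pd.DataFrame, ranges: dict | None = None) -> pd.DataFrame:
    """Check sanity ranges and weight positivity; returns the frame unchanged."""
    ranges = {**SANITY_RANGES, **(ranges or {})}
    problems = []
    for col, (lo, hi) in ranges.items():
        if col not in df.columns:
            continue
        x = pd.to_numeric(df[col], errors="coerce")
        bad = x.notna() & ((x < lo) | (x > hi))
        if bad.any():
            problems.append(f"{col}: {int(bad.sum())} value(s) outside [{lo}, {hi}]")
    for wcol in ("interview_weight", "biomarker_weight", "weight"):
        if wcol in df.columns:
            w = pd.to_numeric(df[wcol], errors="coerce")
            if ((w <= 0) & w.notna()).any() or np.isinf(w).any():
                problems.append(f"{wcol}: weights must be finite and > 0")
    if problems:
        raise RecordValidationError("; ".join(problems))
    return df


def derive_outcomes(
    records: pd.DataFrame, validate: bool = True
) -> tuple[pd.DataFrame, DerivationReport]:
    """Vectorised derivation of all outcomes and derived covariates.

    IHD and stroke are self-report pass-throughs; hypertension,
    dyslipidaemia and diabetes are composite rules.  Returns the outcome
    frame (indexed like *records*) and a missingness/error report.
    """
    if validate:
        validate_records(records)
    dyslip, dyslip_err = derive_dyslipidaemia(records)
    out = pd.DataFrame(
        {
            "hbp": derive_hypertension(records),
            "ihd": np.asarray(records["self_ihd"], dtype=float),
            "stroke": np.asarray(records["self_stroke"], dtype=float),
            "dyslip": dyslip,
            "diabetes": derive_diabetes(records),
            "bmi_class": classify_bmi(records["bmi"]),
        },
        index=records.index,
    )
    missing = {
        c: int(out[c].isna().sum()) for c in ["hbp", "ihd", "stroke", "dyslip", "diabetes"]
    }
    missing["bmi_class"] = int(out["bmi_class"].isna().sum())
    errors = [
        f"record {i}: HDL observed but sex missing; HDL evidence unusable"
        for i in records.index[dyslip_err]
    ]
    report = DerivationReport(
        n_records=len(records), missing_counts=missing, errors=errors
    )
    return out, report


def read_participants(path) -> pd.DataFrame:
    """Read the participant CSV using the documented column dictionary."""
    df = pd.read_csv(path)
    return validate_records(df)
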