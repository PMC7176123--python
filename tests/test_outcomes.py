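"""Clinical cut-off rules, missingness propagation, and monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvdmap import outcomes as oc

EPS = 1e-9


def record(**kw) -> pd.DataFrame:
    base = {
        "sbp": np.nan, "dbp": np.nan, "self_hbp": np.nan, "hbp_medication": np.nan,
        "self_ihd": np.nan, "self_stroke": np.nan, "lipid_drugs": np.nan,
        "dyslip_diagnosis": np.nan, "tc": np.nan, "tg": np.nan, "ldl": np.nan,
        "hdl": np.nan, "hba1c": np.nan, "diabetes_history": np.nan,
        "diabetes_treatment": np.nan, "sex": "female", "bmi": np.nan,
    }
    base.update(kw)
    return pd.DataFrame([base])


class TestHypertension:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(sbp=145, dbp=80, self_hbp=0, hbp_medication=0), 1),
            (dict(sbp=139, dbp=89, self_hbp=0, hbp_medication=0), 0),
            (dict(sbp=120, dbp=70, self_hbp=1), 1),
            (dict(sbp=140.0, dbp=70, self_hbp=0, hbp_medication=0), 1),  # inclusive
            (dict(sbp=140 - EPS, dbp=90 - EPS, self_hbp=0, hbp_medication=0), 0),
            (dict(sbp=120, dbp=90.0, self_hbp=0, hbp_medication=0), 1),
            (dict(hbp_medication=1), 1),  # positive evidence beats missingness
        ],
    )
    def test_rule(self, kw, expected):
        assert oc.derive_hypertension(record(**kw))[0] == expected

    def test_all_missing_propagates(self):
        assert np.isnan(oc.derive_hypertension(record())[0])


class TestDyslipidaemia:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(tc=6.3, tg=1.0, ldl=3.0, hdl=1.5, lipid_drugs=0, dyslip_diagnosis=0), 1),
            (dict(sex="male", hdl=1.10, tc=5.0, tg=1.0, ldl=3.0,
                  lipid_drugs=0, dyslip_diagnosis=0), 0),
            (dict(sex="female", hdl=1.10, tc=5.0, tg=1.0, ldl=3.0,
                  lipid_drugs=0, dyslip_diagnosis=0), 1),
            (dict(tc=5.0, tg=1.0, ldl=3.0, hdl=1.5, lipid_drugs=0, dyslip_diagnosis=0), 0),
            (dict(tc=6.22), 1),          # inclusive at the printed cut-off
            (dict(tg=1.69), 1),
            (dict(ldl=4.14), 1),
            (dict(sex="male", hdl=1.04), 0),    # strict < for HDL
            (dict(sex="male", hdl=1.04 - EPS), 1),
            (dict(sex="female", hdl=1.29), 0),
            (dict(sex="female", hdl=1.29 - EPS), 1),
        ],
    )
    def test_rule(self, kw, expected):
        out, _ = oc.derive_dyslipidaemia(record(**kw))
        assert out[0] == expected

    def test_hdl_without_sex_flags_error(self):
        df = record(hdl=1.0)
        df["sex"] = np.nan
        out, err = oc.derive_dyslipidaemia(df)
        assert err[0]


class TestDiabetes:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(hba1c=6.5, diabetes_history=0), 1),
            (dict(hba1c=6.4, diabetes_history=0, diabetes_treatment=0), 0),
            (dict(diabetes_history=1), 1),
            (dict(hba1c=6.5 - EPS, diabetes_history=0, diabetes_treatment=0), 0),
        ],
    )
    def test_rule(self, kw, expected):
        assert oc.derive_diabetes(record(**kw))[0] == expected


class TestBmi:
    @pytest.mark.parametrize(
        "bmi, expected",
        [
            (18.5, "normal"),
            (25.0, "overweight"),
            (18.4, "underweight"),
            (18.5 - EPS, "underweight"),
            (25.0 - EPS, "normal"),
        ],
    )
    def test_boundaries(self, bmi, expected):
        assert oc.classify_bmi([bmi])[0] == expected

    def test_missing(self):
        assert oc.classify_bmi([np.nan])[0] is None


class TestDeriveOutcomes:
    def test_composition_of_hbp_cases(self):
        df = pd.concat(
            [
                record(sbp=145, dbp=80, self_hbp=0, hbp_medication=0),
                record(sbp=139, dbp=89, self_hbp=0, hbp_medication=0),
                record(sbp=120, dbp=70, self_hbp=1),
            ],
            ignore_index=True,
        )
        out, _ = oc.derive_outcomes(df)
        assert list(out["hbp"]) == [1, 0, 1]

    def test_all_missing_record(self):
        out, report = oc.derive_outcomes(record())
        assert out[["hbp", "ihd", "stroke", "dyslip", "diabetes"]].isna().all().all()
        assert report.missing_counts["hbp"] == 1

    def test_stroke_and_ihd_pass_through(self):
        out, _ = oc.derive_outcomes(record(self_stroke=1, self_ihd=0))
        assert out["stroke"][0] == 1 and out["ihd"][0] == 0

    def test_sanity_range_enforced(self):
        with pytest.raises(oc.RecordValidationError, match="sbp"):
            oc.derive_outcomes(record(sbp=500))

    def test_nonpositive_weight_rejected(self):
        df = record(sbp=120)
        df["interview_weight"] = -1.0
        with pytest.raises(oc.RecordValidationError, match="interview_weight"):
            oc.validate_records(df)


POSITIVE_FIELDS = {
    "sbp": 150.0, "dbp": 95.0, "self_hbp": 1, "hbp_medication": 1,
    "tc": 6.5, "tg": 2.0, "ldl": 4.5, "lipid_drugs": 1, "dyslip_diagnosis": 1,
    "hba1c": 7.0, "diabetes_history": 1, "diabetes_treatment": 1,
}

#: observed-but-negative value for each field (measurements stay in range)
NEGATIVE_FIELDS = {
    "sbp": 120.0, "dbp": 70.0, "self_hbp": 0, "hbp_medication": 0,
    "tc": 5.0, "tg": 1.0, "ldl": 3.0, "lipid_drugs": 0, "dyslip_diagnosis": 0,
    "hba1c": 5.5, "diabetes_history": 0, "diabetes_treatment": 0,
}


@given(
    st.dictionaries(
        st.sampled_from(sorted(POSITIVE_FIELDS)),
        st.booleans(),
        min_size=0, max_size=6,
    ),
    st.sampled_from(sorted(POSITIVE_FIELDS)),
)
def test_positive_evidence_is_monotone(present, extra):
    """Adding one positive-evidence field can never flip a derived 1 to 0."""
    kw = {f: (POSITIVE_FIELDS[f] if pos else NEGATIVE_FIELDS[f])
          for f, pos in present.items()}
    base = record(**kw)
    more = record(**{**kw, extra: POSITIVE_FIELDS[extra]})
    out0, _ = oc.derive_outcomes(base)
    out1, _ = oc.derive_outcomes(more)
    for cond in ("hbp", "dyslip", "diabetes"):
        if out0[cond][0] == 1:
            assert out1[cond][0] == 1


def test_derivation_is_deterministic():
    df = record(sbp=145, tc=6.3, hba1c=7.0, bmi=27.0)
    a, _ = oc.derive_outcomes(df)
    b, _ = oc.derive_outcomes(df)
    pd.testing.assert_frame_equal(a, b)
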