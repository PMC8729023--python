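"""Refractive-state labels, anisometropia typing/severity, and the
mutually exclusive person-level partition."""

import numpy as np
import pandas as pd
import pytest

from anisoprev.classify import (AnisoMetrics, AnisoProfile, EyeState,
                                IncompleteRecordError, RefractiveCriteria,
                                SeverityNotApplicableError, classify_aniso,
                                classify_eye, classify_frame, classify_person,
                                compute_aniso, severity, CATEGORIES)
from anisoprev.vectors import PowerVector


def eye(se_state, astig=False, se=0.0):
    return EyeState(se_state=se_state, astigmatic=astig, se=se)


# ---------------------------------------------------------------------------
# per-eye classification (age-dependent thresholds)


@pytest.mark.parametrize(
    "age, se, cyl, exp_state, exp_astig",
    [
        (7, -1.00, 0.0, "myope", False),        # myopia boundary inclusive
        (5, 1.20, -1.10, "emmetrope", True),    # under-6 column
        (10, 1.00, -1.20, "hyperope", False),   # 6-and-over column
        (5, 1.25, -0.99, "hyperope", False),    # under-6 hyperopia boundary
        (6, 1.00, -1.25, "hyperope", True),     # age exactly 6 uses >=6 column
        (5, 1.24, 0.0, "emmetrope", False),
        (9, -0.99, 0.0, "emmetrope", False),
    ],
)
def test_classify_eye_table_thresholds(criteria, age, se, cyl, exp_state,
                                       exp_astig):
    state = classify_eye(PowerVector(se, 0, 0), cyl, age, criteria)
    assert state.se_state == exp_state
    assert state.astigmatic is exp_astig


def test_classify_eye_rejects_negative_age(criteria):
    with pytest.raises(ValueError):
        classify_eye(PowerVector(0, 0, 0), 0.0, -1, criteria)


# ---------------------------------------------------------------------------
# interocular differences


def test_compute_aniso_hand_examples():
    m = compute_aniso(PowerVector(-2.5, 0, 0), PowerVector(-1.0, 0, 0))
    assert m.sa == pytest.approx(1.5)
    # cylinders -2.50 vs -1.00 via J0 components
    m2 = compute_aniso(PowerVector(0, 1.25, 0), PowerVector(0, 0.5, 0))
    assert m2.ma == pytest.approx(1.5)
    ident = compute_aniso(PowerVector(1, 0.3, -0.2), PowerVector(1, 0.3, -0.2))
    assert (ident.sa, ident.ma) == (0.0, 0.0)


def test_compute_aniso_requires_both_eyes():
    with pytest.raises(IncompleteRecordError):
        compute_aniso(PowerVector(0, 0, 0), None)


# ---------------------------------------------------------------------------
# anisometropia typing and severity


@pytest.mark.parametrize(
    "sa, ma, re_st, le_st, exp_type, exp_sev",
    [
        (1.50, 0.0, "myope", "emmetrope", "myopic", "low"),
        (1.24, 0.0, "myope", "myope", "none", "none"),      # below cutoff
        (0.50, 1.50, "emmetrope", "emmetrope", "sMA", "low"),
        (2.25, 0.0, "myope", "hyperope", "antimetropic", "high"),
        (1.30, 0.0, "hyperope", "emmetrope", "hyperopic", "low"),
        (2.00, 0.0, "myope", "myope", "myopic", "high"),    # 2.00 -> high
        (6.50, 0.0, "myope", "emmetrope", "myopic", "very_high"),
        # MA alongside SA is not "simple": falls through to the SE typing
        (1.30, 1.40, "emmetrope", "emmetrope", "myopic", "low"),
    ],
)
def test_classify_aniso_truth_table(criteria, sa, ma, re_st, le_st, exp_type,
                                    exp_sev):
    prof = classify_aniso(AnisoMetrics(sa, ma), eye(re_st, se=-2.0),
                          eye(le_st, se=-0.5), criteria)
    assert prof.aniso_type == exp_type
    assert prof.severity == exp_sev
    assert prof.is_ta == (prof.aniso_type != "none")
    assert prof.is_sma == (prof.has_ma and not prof.has_sa)


def test_classify_aniso_fallback_both_emmetropic(criteria):
    """SA over the cutoff with both eyes inside the emmetrope band: the
    more ametropic eye's SE sign decides the type."""
    prof = classify_aniso(AnisoMetrics(1.30, 0.0),
                          eye("emmetrope", se=-0.9), eye("emmetrope", se=0.4),
                          criteria)
    assert prof.aniso_type == "myopic"
    prof = classify_aniso(AnisoMetrics(1.30, 0.0),
                          eye("emmetrope", se=0.9), eye("emmetrope", se=-0.4),
                          criteria)
    assert prof.aniso_type == "hyperopic"


@pytest.mark.parametrize("d, exp", [(1.25, "low"), (1.99, "low"),
                                    (2.00, "high"), (6.00, "high"),
                                    (6.01, "very_high")])
def test_severity_band_edges(criteria, d, exp):
    assert severity(d, criteria) == exp


def test_severity_below_cutoff_not_applicable(criteria):
    with pytest.raises(SeverityNotApplicableError):
        severity(1.0, criteria)


# ---------------------------------------------------------------------------
# person-level partition


NO_TA = AnisoProfile(False, False, False, False, "none", "none")
TA_MYO = AnisoProfile(True, False, False, True, "myopic", "low")


def test_person_null_case(criteria):
    cat = classify_person(eye("emmetrope"), eye("emmetrope"), NO_TA, criteria)
    assert cat.category == "emmetrope" and not cat.compound_astigmat


def test_person_compound_astigmat_folds_into_se_category(criteria):
    cat = classify_person(eye("myope", astig=True, se=-2.0),
                          eye("emmetrope"), NO_TA, criteria)
    assert cat.category == "myope"
    assert cat.compound_astigmat


def test_person_anisometrope_trumps_myope(criteria):
    cat = classify_person(eye("myope", se=-2.5), eye("myope", se=-1.0),
                          TA_MYO, criteria)
    assert cat.category == "anisometrope"


def test_person_simple_astigmat_requires_emmetropic_se(criteria):
    cat = classify_person(eye("emmetrope", astig=True), eye("emmetrope"),
                          NO_TA, criteria)
    assert cat.category == "simple_astigmat" and not cat.compound_astigmat


def test_person_worse_eye_decides_conflict(criteria):
    cat = classify_person(eye("myope", se=-2.0), eye("hyperope", se=1.5),
                          NO_TA, criteria)
    assert cat.category == "myope"
    cat = classify_person(eye("myope", se=-1.0), eye("hyperope", se=1.5),
                          NO_TA, criteria)
    assert cat.category == "hyperope"


def test_person_right_eye_rule_switch():
    crit = RefractiveCriteria(person_rule="right_eye")
    cat = classify_person(eye("emmetrope", se=0.0), eye("myope", se=-3.0),
                          NO_TA, crit)
    assert cat.category == "emmetrope"


# ---------------------------------------------------------------------------
# frame-level equivalence and cohort invariants


def _random_frame(n, rng):
    return pd.DataFrame({
        "age": rng.integers(3, 16, n),
        "se_re": rng.uniform(-7, 5, n).round(2),
        "se_le": rng.uniform(-7, 5, n).round(2),
        "c_re": -rng.uniform(0, 4, n).round(2),
        "c_le": -rng.uniform(0, 4, n).round(2),
    })


def test_frame_matches_scalar_path(criteria):
    rng = np.random.default_rng(5)
    frame = _random_frame(400, rng)
    labeled = classify_frame(frame, criteria)
    for i, row in frame.iterrows():
        re_state = classify_eye(PowerVector(row.se_re, -row.c_re / 2, 0),
                                row.c_re, row.age, criteria)
        le_state = classify_eye(PowerVector(row.se_le, -row.c_le / 2, 0),
                                row.c_le, row.age, criteria)
        metrics = AnisoMetrics(abs(row.se_re - row.se_le),
                               abs(row.c_re - row.c_le))
        prof = classify_aniso(metrics, re_state, le_state, criteria)
        cat = classify_person(re_state, le_state, prof, criteria)
        got = labeled.iloc[i]
        assert got["re_state"] == re_state.se_state
        assert got["aniso_type"] == prof.aniso_type
        assert got["severity"] == prof.severity
        assert got["category"] == cat.category
        assert bool(got["compound_astigmat"]) == cat.compound_astigmat


def test_eye_swap_symmetry(criteria):
    rng = np.random.default_rng(9)
    frame = _random_frame(500, rng)
    swapped = frame.rename(columns={"se_re": "se_le", "se_le": "se_re",
                                    "c_re": "c_le", "c_le": "c_re"})
    a = classify_frame(frame, criteria)
    b = classify_frame(swapped, criteria)
    for col in ("sa", "ma", "is_ta", "is_sma", "aniso_type", "severity",
                "category", "compound_astigmat"):
        assert (a[col].values == b[col].values).all(), col


def test_partition_and_ta_decomposition(sim_labeled):
    counts = sim_labeled["category"].value_counts()
    assert counts.sum() == len(sim_labeled)
    assert set(counts.index) <= set(CATEGORIES)
    ta = int(sim_labeled["is_ta"].sum())
    assert ta == int(sim_labeled["has_sa"].sum()) + int(sim_labeled["is_sma"].sum())


def test_raising_cutoff_never_increases_ta(sim_cohort):
    from anisoprev.cohort_io import average_frame

    avg = average_frame(sim_cohort.data)
    previous = None
    for cutoff in (1.0, 1.25, 1.5, 2.0 - 1e-9):
        ta = int(classify_frame(
            avg, RefractiveCriteria(aniso_cutoff=cutoff))["is_ta"].sum())
        if previous is not None:
            assert ta <= previous
        previous = ta


def test_fixture_labels_match_hand_derived_truth(labeled_fixture):
    for col in ("category", "is_ta", "aniso_type", "severity", "re_state",
                "le_state", "compound_astigmat"):
        mismatch = labeled_fixture[
            labeled_fixture[col] != labeled_fixture[f"{col}_exp"]]
        assert mismatch.empty, f"{col}: {mismatch['id'].tolist()}"


def test_criteria_validation():
    with pytest.raises(ValueError):
        RefractiveCriteria(aniso_cutoff=0.0)
    with pytest.raises(ValueError):
        RefractiveCriteria(severity_low_high=7.0)
    with pytest.raises(ValueError):
        RefractiveCriteria(person_rule="left_eye")
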