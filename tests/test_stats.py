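"""Prevalence estimation, chi-square association and the sample-size
formula, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from anisoprev.stats import (DegenerateTableError, SmallCellWarning,
                             chi_square, prevalence, round_half_up,
                             sample_size, stratified_prevalence)
import pandas as pd


def pearson_brute_force(table):
    """Independent oracle: Sum (O-E)^2 / E from the margin products."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = ((obs - expected) ** 2 / expected).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, sps.chi2.sf(stat, df)


# ---------------------------------------------------------------------------
# prevalence


@pytest.mark.parametrize("k, n, ndigits, exp", [
    (46, 749, 1, 6.1),
    (533, 749, 2, 71.16),
    (37, 749, 1, 4.9),
    (0, 100, 1, 0.0),
])
def test_prevalence_reported_percentages(k, n, ndigits, exp):
    est = prevalence(k, n)
    assert est.pct(ndigits) == exp
    assert est.ci_low <= est.proportion <= est.ci_high
    assert 0.0 <= est.ci_low and est.ci_high <= 1.0


def test_prevalence_zero_numerator_ci_starts_at_zero():
    est = prevalence(0, 100)
    assert est.ci_low == 0.0


def test_prevalence_undefined_for_empty_denominator():
    with pytest.raises(ValueError):
        prevalence(0, 0)


def test_wilson_ci_coverage_at_study_conditions():
    """Over 2,000 binomial draws at p = 0.06, n = 749, the Wilson interval
    should cover the truth 93-97% of the time."""
    rng = np.random.default_rng(2024)
    p, n, sims = 0.06, 749, 2000
    ks = rng.binomial(n, p, size=sims)
    covered = 0
    for k in np.unique(ks):
        est = prevalence(int(k), n)
        if est.ci_low <= p <= est.ci_high:
            covered += int((ks == k).sum())
    assert 0.93 <= covered / sims <= 0.97


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(19.565, 1) == 19.6
    assert round_half_up(0.5) == 1.0
    assert round_half_up(2.5) == 3.0  # built-in round() would give 2


# ---------------------------------------------------------------------------
# chi-square


def test_chi_square_gender_tables():
    res = chi_square([[25, 325], [21, 378]])
    assert res.statistic == pytest.approx(1.14, abs=0.005)
    assert res.p_value == pytest.approx(0.285, abs=0.0005)
    assert res.df == 1 and not res.significant
    assert round_half_up(chi_square([[21, 329], [16, 383]]).p_value, 2) == 0.21


def test_chi_square_identical_rows_is_zero():
    res = chi_square([[10, 90], [10, 90]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_degenerate_table():
    with pytest.raises(DegenerateTableError):
        chi_square([[0, 0], [5, 3]])


def test_chi_square_small_expected_cell_warns():
    with pytest.warns(SmallCellWarning):
        res = chi_square([[1, 500], [1, 2]])
    assert res.small_cells


tables_2xk = st.integers(2, 5).flatmap(
    lambda k: st.lists(
        st.tuples(st.integers(0, 40), st.integers(0, 40)),
        min_size=k, max_size=k))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(tables_2xk)
def test_chi_square_matches_brute_force(cols):
    table = np.array(cols).T  # 2 x K
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallCellWarning)
        res = chi_square(table)
    stat, p = pearson_brute_force(table)
    assert res.statistic == pytest.approx(stat, abs=1e-9)
    assert res.p_value == pytest.approx(p, abs=1e-9)
    assert res.df == table.shape[1] - 1


def test_scaling_counts_sharpens_unequal_tables():
    base = np.array([[25, 325], [21, 378]])
    p_prev = chi_square(base).p_value
    for m in (2, 4, 8):
        p = chi_square(base * m).p_value
        assert p <= p_prev
        p_prev = p


# ---------------------------------------------------------------------------
# stratified prevalence


def _toy_cohort():
    rows = []
    for gender, k, n in (("female", 25, 350), ("male", 21, 399)):
        rows += [{"gender": gender, "is_ta": True}] * k
        rows += [{"gender": gender, "is_ta": False}] * (n - k)
    rows += [{"gender": "missing", "is_ta": True}] * 3
    return pd.DataFrame(rows)


def test_stratified_prevalence_with_association():
    res = stratified_prevalence(_toy_cohort(), "is_ta", "gender",
                                levels=["female", "male"])
    by = {e.stratum: e for e in res.estimates}
    assert by["female"].pct(1) == 7.1 and by["male"].pct(1) == 5.3
    # records with a missing stratifier are dropped from this test only
    assert by["female"].denominator + by["male"].denominator == 749
    assert round_half_up(res.association.p_value, 2) == 0.29


def test_stratified_prevalence_homogeneous_levels():
    df = pd.DataFrame({"flag": [True] * 10 + [False] * 90 + [True] * 10
                       + [False] * 90,
                       "site": ["a"] * 100 + ["b"] * 100})
    res = stratified_prevalence(df, "flag", "site")
    assert res.association.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.association.p_value == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# sample size


def test_sample_size_conventions():
    res = sample_size(0.95, 0.05, 0.5)
    assert res.minimum == 384
    assert res.conservative == 385
    assert res.raw == pytest.approx(384.146, abs=0.001)
    assert sample_size(0.99, 0.05, 0.5).minimum == 663


def test_sample_size_vanishes_with_p():
    assert sample_size(0.95, 0.05, 1e-9).raw < 1e-5


@pytest.mark.parametrize("kwargs", [dict(margin=0.0), dict(p=0.0),
                                    dict(p=1.0), dict(confidence=1.0)])
def test_sample_size_rejects_degenerate_inputs(kwargs):
    with pytest.raises(ValueError):
        sample_size(**{**dict(confidence=0.95, margin=0.05, p=0.5), **kwargs})
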