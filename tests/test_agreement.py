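"""Percent agreement, Cohen's kappa and the Brennan-Prediger kappa."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mbwqc.agreement import (RatingMatrix, brennan_prediger_kappa, cohen_kappa,
                             interpret_kappa, percent_agreement)
from mbwqc.errors import ValidationError


def matrix(columns: dict, phase="washout") -> RatingMatrix:
    return RatingMatrix(pd.DataFrame(columns), phase=phase)


def two_rater(n_agree: int, n_total: int) -> RatingMatrix:
    a = ["accept"] * n_total
    b = ["accept"] * n_agree + ["reject"] * (n_total - n_agree)
    return matrix({"r1": a, "r2": b})


def test_percent_agreement_examples():
    assert percent_agreement(matrix({"a": ["accept"] * 5, "b": ["accept"] * 5})) == 1.0
    assert percent_agreement(two_rater(8, 10)) == pytest.approx(0.8)


def test_percent_agreement_matches_pairwise_enumeration():
    """Four raters: equals the brute-force mean over all 6 pairs."""
    rng = np.random.default_rng(7)
    ratings = pd.DataFrame(
        rng.choice(["accept", "reject"], size=(40, 4)),
        columns=["r1", "r2", "r3", "r4"])
    m = RatingMatrix(ratings)
    oracle = np.mean([
        (ratings[a].to_numpy() == ratings[b].to_numpy()).mean()
        for a, b in itertools.combinations(ratings.columns, 2)])
    assert percent_agreement(m) == pytest.approx(float(oracle), abs=1e-12)


def test_cohen_kappa_from_confusion_table():
    """Confusion [[40,10],[10,40]] -> p_o 0.8, p_e 0.5, kappa 0.6."""
    a = ["accept"] * 50 + ["reject"] * 50
    b = ["accept"] * 40 + ["reject"] * 10 + ["accept"] * 10 + ["reject"] * 40
    res = cohen_kappa(matrix({"r1": a, "r2": b}))
    assert res.p_o == pytest.approx(0.8)
    assert res.kappa == pytest.approx(0.6)
    assert res.ci_low < 0.6 < res.ci_high


def test_cohen_perfect_agreement():
    a = ["accept"] * 30 + ["reject"] * 20
    res = cohen_kappa(matrix({"r1": a, "r2": list(a)}))
    assert res.kappa == pytest.approx(1.0)


def test_cohen_chance_level_near_zero():
    """Independent random ratings over 10,000 trials give kappa ~= 0."""
    rng = np.random.default_rng(123)
    m = matrix({"r1": rng.choice(["accept", "reject"], 10_000),
                "r2": rng.choice(["accept", "reject"], 10_000)})
    assert abs(cohen_kappa(m).kappa) < 0.03


def test_cohen_undefined_for_constant_raters():
    res = cohen_kappa(matrix({"r1": ["accept"] * 10, "r2": ["accept"] * 10}))
    assert res.kappa is None and res.p_o == 1.0


def test_cohen_matches_statsmodels():
    """Independent oracle: statsmodels' Cohen kappa on random tables."""
    from statsmodels.stats.inter_rater import cohens_kappa

    rng = np.random.default_rng(5)
    for _ in range(20):
        a = rng.choice(["accept", "reject"], 60, p=[0.7, 0.3])
        b = np.where(rng.random(60) < 0.75, a, rng.choice(["accept", "reject"], 60))
        m = matrix({"r1": a, "r2": b})
        table = pd.crosstab(pd.Categorical(a, ["accept", "reject"]),
                            pd.Categorical(b, ["accept", "reject"]),
                            dropna=False).to_numpy()
        expected = cohens_kappa(table, return_results=False)
        assert cohen_kappa(m).kappa == pytest.approx(float(expected), abs=1e-12)


@pytest.mark.parametrize("p_o, expected", [
    (0.846, 0.69),   # published overall washin agreement, first setup
    (0.5, 0.0),
    (1.0, 1.0),
])
def test_brennan_prediger_point_values(p_o, expected):
    n = 1000
    m = two_rater(round(p_o * n), n)
    res = brennan_prediger_kappa(m, q=2, n_boot=0)
    assert res.p_o == pytest.approx(p_o)
    assert round(res.kappa, 2) == expected


@given(st.lists(st.tuples(st.sampled_from("ar"), st.sampled_from("ar"),
                          st.sampled_from("ar")), min_size=2, max_size=60))
def test_bp_identity_two_categories(rows):
    """kappa_BP = 2 p_o - 1 exactly for q = 2 on every matrix."""
    m = RatingMatrix(pd.DataFrame(rows, columns=["r1", "r2", "r3"]))
    res = brennan_prediger_kappa(m, q=2, n_boot=0)
    assert res.kappa == pytest.approx(2 * res.p_o - 1, abs=1e-12)


def test_bp_equals_cohen_on_uniform_marginals():
    """With uniform marginals p_e = 1/q, so the two corrections agree."""
    a = ["accept"] * 40 + ["reject"] * 10 + ["accept"] * 10 + ["reject"] * 40
    b = ["accept"] * 50 + ["reject"] * 50
    m = matrix({"r1": a, "r2": b})
    assert (brennan_prediger_kappa(m, n_boot=0).kappa
            == pytest.approx(cohen_kappa(m).kappa, abs=1e-12))


def test_statistics_invariant_to_permutations():
    rng = np.random.default_rng(11)
    ratings = pd.DataFrame(rng.choice(["accept", "reject"], size=(30, 3)),
                           columns=["r1", "r2", "r3"])
    m = RatingMatrix(ratings)
    shuffled = RatingMatrix(
        ratings.sample(frac=1, random_state=4)[["r3", "r1", "r2"]])
    assert percent_agreement(m) == pytest.approx(percent_agreement(shuffled))
    assert (brennan_prediger_kappa(m, n_boot=0).kappa
            == pytest.approx(brennan_prediger_kappa(shuffled, n_boot=0).kappa))


def test_bootstrap_ci_brackets_kappa():
    rng = np.random.default_rng(2)
    ratings = pd.DataFrame(rng.choice(["accept", "reject"], size=(80, 3), p=[0.8, 0.2]),
                           columns=["r1", "r2", "r3"])
    res = brennan_prediger_kappa(RatingMatrix(ratings), n_boot=500, seed=1)
    assert res.ci_low <= res.kappa <= res.ci_high
    # seeded: reproducible
    res2 = brennan_prediger_kappa(RatingMatrix(ratings), n_boot=500, seed=1)
    assert (res.ci_low, res.ci_high) == (res2.ci_low, res2.ci_high)


def test_matrix_validation():
    with pytest.raises(ValidationError):
        RatingMatrix(pd.DataFrame({"r1": ["accept", None], "r2": ["accept", "reject"]}))
    with pytest.raises(ValidationError):
        RatingMatrix(pd.DataFrame({"r1": ["accept"]}))
    with pytest.raises(ValidationError):
        cohen_kappa(RatingMatrix(pd.DataFrame(
            {"r1": ["a"], "r2": ["a"], "r3": ["a"]})))


def test_kappa_interpretation_bands():
    assert interpret_kappa(0.5) == "moderate"
    assert interpret_kappa(0.69) == "substantial"
    assert interpret_kappa(0.9) == "almost perfect"
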