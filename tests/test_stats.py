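"""Statistical layer vs closed-form hand computations and calibration."""

import math

import numpy as np
import pandas as pd
import pytest

import oracles
from gazepipe.errors import ValidationError
from gazepipe.stats import (
    classify_cohort,
    correlation_matrix,
    one_sample_t,
    orient_variables,
    paired_t,
    pairwise_correlation,
    skewness,
    two_sample_t,
)


def test_one_sample_t_closed_form():
    r = one_sample_t([1.0, 2.0, 3.0], mu=0.0)
    assert r.t == pytest.approx(2.0 / (1.0 / math.sqrt(3)), abs=1e-9)
    assert r.t == pytest.approx(3.4641016151, abs=1e-9)
    assert r.df == 2
    t_ref, df_ref, p_ref = oracles.closed_form_one_sample_t([1.0, 2.0, 3.0])
    assert r.t == pytest.approx(t_ref, abs=1e-12)
    assert r.p == pytest.approx(p_ref, abs=1e-12)


def test_symmetric_values_give_t_zero_p_one():
    r = one_sample_t([-2.0, -1.0, 1.0, 2.0], mu=0.0)
    assert r.t == pytest.approx(0.0, abs=1e-12)
    assert r.p == pytest.approx(1.0, abs=1e-12)


def test_zero_variance_raises():
    with pytest.raises(ValidationError):
        one_sample_t([3.0, 3.0, 3.0])


def test_one_sample_t_calibration_under_null():
    """~95% of null replicates satisfy |t| < the 0.975 quantile."""
    from scipy import stats as sps

    crit = sps.t.ppf(0.975, 79)
    rng = np.random.default_rng(123)
    inside = sum(abs(one_sample_t(rng.normal(0, 1, 80)).t) < crit for _ in range(1000))
    assert 920 <= inside <= 975


def test_paired_t_closed_form_on_differences():
    x = [2.0, 3.0, 4.0, 8.0]
    y = [1.0, 2.0, 3.0, 5.0]  # differences {1, 1, 1, 3}
    r = paired_t(x, y)
    t_ref, df_ref, _ = oracles.closed_form_one_sample_t([1.0, 1.0, 1.0, 3.0])
    assert r.t == pytest.approx(t_ref, abs=1e-12)
    assert r.t == pytest.approx(3.0, abs=1e-12)
    assert r.df == 3


def test_paired_t_drops_incomplete_pairs():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [0.0, 1.0, 1.0, np.nan, 3.0]
    r = paired_t(x, y)
    t_ref, df_ref, _ = oracles.closed_form_one_sample_t([1.0, 1.0, 2.0])
    assert r.df == 2
    assert r.t == pytest.approx(t_ref, abs=1e-12)


def test_identical_paired_vectors_zero_variance_error():
    with pytest.raises(ValidationError):
        paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_two_sample_t_closed_form_pooled():
    r = two_sample_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    t_ref, df_ref, p_ref = oracles.closed_form_two_sample_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert r.t == pytest.approx(t_ref, abs=1e-12)
    assert r.t == pytest.approx(-1.224744871, abs=1e-9)
    assert r.df == 4
    assert r.p == pytest.approx(p_ref, abs=1e-12)


def test_identical_groups_t_zero_df_rule():
    r = two_sample_t([1.0, 2.0, 5.0], [1.0, 2.0, 5.0, 3.0])
    assert r.df == 5  # n1 + n2 - 2 always, pooled


def test_pearson_perfect_and_anti():
    assert pairwise_correlation([1, 2, 3], [1, 2, 3]).r == pytest.approx(1.0)
    assert pairwise_correlation([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)


def test_pearson_closed_form_with_pairwise_deletion():
    x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
    y = [1.5, 2.0, 9.0, np.nan, 4.0, 7.0]
    r = pairwise_correlation(x, y)
    r_ref, n_ref, p_ref = oracles.closed_form_pearson(x, y)
    assert r.n == n_ref == 4
    assert r.r == pytest.approx(r_ref, abs=1e-12)
    assert r.p == pytest.approx(p_ref, abs=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_correlation_matrix_matches_per_pair_recomputation(seed):
    rng = np.random.default_rng(seed)
    n = 40
    df = pd.DataFrame(
        {k: rng.normal(size=n) for k in ("a", "b", "c")}
    )
    for k in df.columns:
        df.loc[rng.random(n) < 0.25, k] = np.nan
    cells = correlation_matrix(df, ["a", "b", "c"])
    for i in ("a", "b", "c"):
        for j in ("a", "b", "c"):
            cell = cells[(i, j)]
            if i == j:
                assert cell.r == 1.0
                continue
            r_ref, n_ref, _ = oracles.closed_form_pearson(df[i], df[j])
            assert cell.n == n_ref
            assert cell.r == pytest.approx(r_ref, abs=1e-12)
            assert cells[(j, i)].r == cell.r  # symmetry
            assert abs(cell.r) <= 1.0


def test_correlation_cell_with_too_few_pairs_not_computable():
    df = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan], "b": [1.0, np.nan, 2.0, 3.0]})
    assert correlation_matrix(df, ["a", "b"])[("a", "b")] is None


def test_orientation_flips_latencies_only():
    df = pd.DataFrame(
        {"prediction_latency_ms": [-379.0], "dilation_difference_mm": [0.063],
         "reach_latency_s": [-0.38]}
    )
    out, signs = orient_variables(df)
    assert out["prediction_latency_ms"].iloc[0] == pytest.approx(379.0)
    assert out["dilation_difference_mm"].iloc[0] == pytest.approx(0.063)
    assert out["reach_latency_s"].iloc[0] == pytest.approx(0.38)
    twice, _ = orient_variables(out)
    assert twice["prediction_latency_ms"].iloc[0] == pytest.approx(-379.0)
    assert signs["prediction_latency_ms"] == -1 and signs["dilation_difference_mm"] == 1


def test_orientation_negates_cross_correlations():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(
        {"prediction_latency_ms": rng.normal(size=30), "dilation_difference_mm": rng.normal(size=30)}
    )
    before = pairwise_correlation(df["prediction_latency_ms"], df["dilation_difference_mm"])
    oriented, _ = orient_variables(df)
    after = pairwise_correlation(oriented["prediction_latency_ms"], oriented["dilation_difference_mm"])
    assert after.r == pytest.approx(-before.r, abs=1e-12)


class _S:
    def __init__(self, c):
        self.classification = c


def test_classification_counts_and_percentages():
    scores = [_S("predictive")] * 3 + [_S("reactive")] + [_S("excluded")]
    c = classify_cohort(scores)
    assert (c.n_predictive, c.n_reactive, c.n_excluded) == (3, 1, 1)
    assert c.pct_predictive == pytest.approx(60.0)
    assert c.pct_reactive == pytest.approx(20.0)
    assert c.pct_excluded == pytest.approx(20.0)
    assert c.pct_predictive_of_included == pytest.approx(75.0)


def test_all_excluded_included_percentage_undefined():
    c = classify_cohort([_S("excluded")] * 4)
    assert c.pct_predictive_of_included is None
    assert c.pct_excluded == pytest.approx(100.0)


def test_empty_cohort_reports_zeros():
    c = classify_cohort([])
    assert c.n_predictive == c.n_reactive == c.n_excluded == 0
    assert c.pct_predictive == 0.0


def test_skewness_closed_form_and_antisymmetry():
    vals = [1.0, 2.0, 10.0]
    got = skewness(vals)
    assert got == pytest.approx(oracles.closed_form_skewness(vals), abs=1e-9)
    assert got > 0
    assert skewness([-v for v in vals]) == pytest.approx(-got, abs=1e-12)


def test_symmetric_values_skewness_zero():
    assert skewness([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(0.0, abs=1e-12)
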