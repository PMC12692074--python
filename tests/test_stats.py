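"""Statistical battery: effect sizes, power, ROC, correlations.

Brute-force oracles: pairwise win counting for the AUC, an exhaustive
power scan for sample-size minimality, and direct rank computation for
Spearman.  The published effect sizes (0.617 for the sacral base angle,
0.471 for the Cobb lordosis, 72 per group required for the latter) are
frozen as exact expectations.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sagspine.presets import GROUP_SUMMARY_STATS
from sagspine.stats import (CohortComparison, cohens_d, cohens_d_from_samples,
                            describe, normality_flags, required_sample_size,
                            roc_analysis, spearman_matrix, two_sample_power)


def brute_force_auc(x0, x1):
    """AUC as the win fraction over all (negative, positive) pairs,
    half-credit for ties."""
    wins = sum(1.0 if b > a else 0.5 if b == a else 0.0
               for a, b in itertools.product(x0, x1))
    return wins / (len(x0) * len(x1))


# ---------------------------------------------------------------------- d

def test_cohens_d_published_values():
    sba_n = GROUP_SUMMARY_STATS["normal"]["SBA"]
    sba_a = GROUP_SUMMARY_STATS["albp"]["SBA"]
    es = cohens_d(sba_n["mean"], sba_n["sd"], 50, sba_a["mean"], sba_a["sd"], 50)
    assert es.d == pytest.approx(0.617, abs=0.001)
    cb_n = GROUP_SUMMARY_STATS["normal"]["Cobb_T12S1"]
    cb_a = GROUP_SUMMARY_STATS["albp"]["Cobb_T12S1"]
    es2 = cohens_d(abs(cb_n["mean"]), cb_n["sd"], 50,
                   abs(cb_a["mean"]), cb_a["sd"], 50)
    assert es2.d == pytest.approx(0.471, abs=0.001)


def test_cohens_d_zero_for_equal_means():
    assert cohens_d(10.0, 2.0, 20, 10.0, 3.0, 20).d == 0.0


def test_cohens_d_affine_invariance(rng):
    x0 = rng.normal(10, 2, 30)
    x1 = rng.normal(12, 3, 25)
    d1 = cohens_d_from_samples(x0, x1).d
    d2 = cohens_d_from_samples(5.0 * x0 - 7.0, 5.0 * x1 - 7.0).d
    assert d2 == pytest.approx(d1, rel=1e-12)


def test_cohens_d_degenerate():
    with pytest.raises(ValueError):
        cohens_d(1.0, 0.0, 10, 1.0, 0.0, 10)
    with pytest.raises(ValueError):
        cohens_d(1.0, 1.0, 1, 2.0, 1.0, 10)


# ------------------------------------------------------------- sample size

def test_required_sample_size_published_value_and_minimality():
    """d = 0.471 (Cobb) needs 72 per group; exhaustive scan confirms 72 is
    the smallest n in [2, 200] reaching 80% power."""
    cb_n = GROUP_SUMMARY_STATS["normal"]["Cobb_T12S1"]
    cb_a = GROUP_SUMMARY_STATS["albp"]["Cobb_T12S1"]
    d = cohens_d(abs(cb_n["mean"]), cb_n["sd"], 50,
                 abs(cb_a["mean"]), cb_a["sd"], 50).d
    n = required_sample_size(d)
    assert n == 72
    powers = {m: two_sample_power(d, m) for m in range(2, 201)}
    assert min(m for m, p in powers.items() if p >= 0.80) == n


def test_required_sample_size_monotone_in_effect():
    n1 = required_sample_size(1.0)
    n2 = required_sample_size(2.0)
    assert n2 <= 7
    assert n2 <= n1
    assert required_sample_size(-1.0) == n1  # magnitude only


def test_required_sample_size_guards():
    with pytest.raises(ValueError):
        required_sample_size(0.0)
    with pytest.raises(ValueError):
        required_sample_size(1e-6, n_max=10_000)


# --------------------------------------------------------------------- ROC

def test_roc_perfect_separation():
    r = roc_analysis([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert r.auc == 1.0
    assert r.youden_j == pytest.approx(1.0)
    assert r.sens_at_cutoff == 1.0
    assert r.spec_at_cutoff == 1.0


def test_roc_overlapping_with_ties_matches_pair_counting():
    """{1,2,3} vs {2,3,4}: 6 wins + 2 ties of 9 pairs -> AUC 7/9."""
    r = roc_analysis([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert r.auc == pytest.approx(7.0 / 9.0, abs=1e-12)


def test_roc_auc_equals_mann_whitney_u(rng):
    for _ in range(30):
        n0 = int(rng.integers(1, 30))
        n1 = int(rng.integers(1, 30))
        x0 = np.round(rng.normal(0, 1, n0), 1)  # rounding forces ties
        x1 = np.round(rng.normal(0.5, 1, n1), 1)
        r = roc_analysis(x0, x1)
        assert r.auc == pytest.approx(brute_force_auc(x0, x1), abs=1e-12)


def test_roc_auc_against_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    x0 = rng.normal(0, 1, 200)
    x1 = rng.normal(0.7, 1.3, 150)
    r = roc_analysis(x0, x1)
    ref = roc_auc_score(np.r_[np.zeros(200), np.ones(150)], np.r_[x0, x1])
    assert r.auc == pytest.approx(ref, abs=1e-12)


def test_youden_equals_ks_statistic(rng):
    """Max Youden J equals the oriented two-sample K-S separation
    max(F0 - F1); scipy's one-sided statistic is the reference."""
    from scipy.stats import ks_2samp

    for _ in range(20):
        x0 = np.round(rng.normal(0, 1, int(rng.integers(5, 40))), 1)
        x1 = np.round(rng.normal(0.4, 1.2, int(rng.integers(5, 40))), 1)
        r = roc_analysis(x0, x1)
        assert r.youden_j == pytest.approx(r.ks_metric, abs=1e-12)
        assert r.ks_metric == pytest.approx(
            ks_2samp(x0, x1, alternative="greater").statistic, abs=1e-12)


def test_roc_orientation_fixed_reports_auc_below_half():
    """A variable lower in patients is reported with AUC < 0.5, never
    silently flipped."""
    r = roc_analysis([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
    assert r.auc == 0.0
    assert r.orientation == "higher-predicts-positive"


def test_roc_tie_rule_largest_cutoff():
    # J is maximal (=1) over the whole gap between the samples: both 3.5
    # and 4.0 separate perfectly; the largest observed cutoff is reported
    r = roc_analysis([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert r.optimal_cutoff == 4.0
    # duplicated maximal-J thresholds inside overlapping samples
    r2 = roc_analysis([1.0, 1.0, 5.0], [2.0, 6.0, 6.0])
    js = r2.sensitivity + r2.specificity - 1.0
    ties = r2.thresholds[np.isclose(js, js.max())]
    assert r2.optimal_cutoff == ties.max()


def test_roc_invariant_under_monotone_transform(rng):
    x0 = rng.normal(0, 1, 50)
    x1 = rng.normal(0.5, 1, 60)
    r1 = roc_analysis(x0, x1)
    r2 = roc_analysis(np.exp(x0), np.exp(x1))
    assert r2.auc == pytest.approx(r1.auc, abs=1e-12)
    assert r2.youden_j == pytest.approx(r1.youden_j, abs=1e-12)


def test_roc_empty_input_rejected():
    with pytest.raises(ValueError):
        roc_analysis([], [1.0])


@given(st.lists(st.integers(0, 8), min_size=1, max_size=12),
       st.lists(st.integers(0, 8), min_size=1, max_size=12))
def test_roc_auc_pair_counting_property(a, b):
    x0 = np.array(a, dtype=float)
    x1 = np.array(b, dtype=float)
    r = roc_analysis(x0, x1)
    assert r.auc == pytest.approx(brute_force_auc(x0, x1), abs=1e-12)
    assert r.youden_j == pytest.approx(r.ks_metric, abs=1e-12)


# ---------------------------------------------------------------- spearman

def test_spearman_perfect_monotone():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                       "y": [10.0, 20.0, 25.0, 100.0],
                       "z": [5.0, 4.0, 2.0, 1.0]})
    rho, p = spearman_matrix(df, ("x", "y", "z"))
    assert rho.loc["x", "y"] == pytest.approx(1.0)
    assert rho.loc["x", "z"] == pytest.approx(-1.0)
    assert np.allclose(rho.values, rho.values.T)


def test_spearman_matches_brute_force_ranks(rng):
    """Direct average-rank computation on a 10-row table equals the
    implementation exactly (including ties)."""
    df = pd.DataFrame({"u": np.round(rng.normal(0, 1, 10), 1),
                       "v": np.round(rng.normal(0, 1, 10), 1)})
    rho, _ = spearman_matrix(df, ("u", "v"))

    def avg_ranks(x):
        order = sorted(range(len(x)), key=lambda i: x[i])
        ranks = [0.0] * len(x)
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            for k in range(i, j + 1):
                ranks[order[k]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx = avg_ranks(list(df["u"]))
    ry = avg_ranks(list(df["v"]))
    expected = np.corrcoef(rx, ry)[0, 1]
    assert rho.loc["u", "v"] == pytest.approx(expected, abs=1e-12)


def test_spearman_agrees_with_scipy(rng):
    from scipy.stats import spearmanr

    df = pd.DataFrame({"u": np.round(rng.normal(0, 1, 40), 1),
                       "v": np.round(rng.normal(0, 1, 40), 1)})
    rho, p = spearman_matrix(df, ("u", "v"))
    ref = spearmanr(df["u"], df["v"])
    assert rho.loc["u", "v"] == pytest.approx(ref.statistic, abs=1e-12)
    assert p.loc["u", "v"] == pytest.approx(ref.pvalue, abs=1e-9)


def test_spearman_constant_column_flagged_nan():
    df = pd.DataFrame({"u": [1.0, 2.0, 3.0, 4.0], "c": [5.0] * 4})
    rho, _ = spearman_matrix(df, ("u", "c"))
    assert math.isnan(rho.loc["u", "c"])


def test_spearman_too_few_observations():
    df = pd.DataFrame({"u": [1.0, 2.0], "v": [2.0, 1.0]})
    with pytest.raises(ValueError):
        spearman_matrix(df, ("u", "v"))


# ---------------------------------------------------------------- describe

def _two_group_frame(rng, delta=0.0, n=30):
    x0 = rng.normal(40, 7, n)
    x1 = rng.normal(40 + delta, 9, n)
    return pd.DataFrame({"group": ["normal"] * n + ["albp"] * n,
                         "SBA": np.r_[x0, x1]})


def test_describe_identical_groups(rng):
    x = rng.normal(40, 7, 25)
    df = pd.DataFrame({"group": ["normal"] * 25 + ["albp"] * 25,
                       "SBA": np.r_[x, x]})
    out = describe(df, variables=("SBA",))
    row = out.iloc[0]
    assert row["mean_normal"] == pytest.approx(row["mean_albp"])
    assert row["p"] == pytest.approx(1.0, abs=1e-12)


def test_describe_matches_scipy_ttest(rng):
    from scipy.stats import ttest_ind

    df = _two_group_frame(rng, delta=5.0)
    out = describe(df, variables=("SBA",))
    x0 = df.loc[df.group == "normal", "SBA"]
    x1 = df.loc[df.group == "albp", "SBA"]
    assert out.iloc[0]["p"] == pytest.approx(ttest_ind(x1, x0).pvalue, abs=1e-12)
    w = describe(df, variables=("SBA",), equal_var=False)
    assert w.iloc[0]["p"] == pytest.approx(
        ttest_ind(x1, x0, equal_var=False).pvalue, abs=1e-12)


def test_describe_requires_two_observations(rng):
    df = pd.DataFrame({"group": ["normal", "albp", "albp"],
                       "SBA": [40.0, 44.0, 45.0]})
    with pytest.raises(ValueError):
        describe(df, variables=("SBA",))


def test_describe_zero_variance_flag():
    df = pd.DataFrame({"group": ["normal"] * 3 + ["albp"] * 3,
                       "SBA": [40.0] * 3 + [44.0] * 3})
    out = describe(df, variables=("SBA",))
    assert bool(out.iloc[0]["undefined_t"])


def test_sba_direction_and_significance_at_published_parameters(rng):
    """Groups drawn at the published sacral-base-angle parameters separate
    in the published direction; the median p over repeated draws sits in
    the small-p regime implied by the summary t of ~3.1."""
    ps = []
    diffs = []
    for seed in range(40):
        r = np.random.default_rng(seed)
        df = pd.DataFrame({
            "group": ["normal"] * 50 + ["albp"] * 50,
            "SBA": np.r_[r.normal(39.4, 7.2, 50), r.normal(44.5, 9.2, 50)]})
        out = describe(df, variables=("SBA",))
        diffs.append(out.iloc[0]["mean_albp"] - out.iloc[0]["mean_normal"])
        ps.append(out.iloc[0]["p"])
    assert np.mean(np.array(diffs) > 0) > 0.9  # ALBP above normal
    assert np.median(ps) < 0.05


# ------------------------------------------------------- model object

def test_cohort_comparison_end_to_end(rng):
    df = _two_group_frame(rng, delta=5.0, n=50)
    res = CohortComparison(df, positive_group="albp",
                           variables=("SBA",)).fit()
    assert 0.5 < res.roc["SBA"].auc <= 1.0
    assert res.effect_sizes["SBA"].d > 0
    assert res.sample_sizes["SBA"] >= 2
    assert "SBA" in res.summary()
    d = res.to_dict()
    assert d["positive_group"] == "albp"
    assert "auc" in d["roc"]["SBA"]


def test_cohort_comparison_identical_groups_null(rng):
    x = rng.normal(40, 7, 40)
    df = pd.DataFrame({"group": ["normal"] * 40 + ["albp"] * 40,
                       "SBA": np.r_[x, x]})
    res = CohortComparison(df, variables=("SBA",)).fit()
    assert res.effect_sizes["SBA"].d == pytest.approx(0.0, abs=1e-12)
    assert res.roc["SBA"].auc == pytest.approx(0.5, abs=1e-12)


def test_cohort_comparison_rejects_single_group(rng):
    df = pd.DataFrame({"group": ["albp"] * 10, "SBA": rng.normal(44, 9, 10)})
    with pytest.raises(ValueError, match="two groups"):
        CohortComparison(df)


def test_normality_flags_shape(rng):
    df = _two_group_frame(rng, delta=5.0, n=30)
    out = normality_flags(df, variables=("SBA",))
    assert set(out.columns) >= {"variable", "group", "shapiro_p", "ks_p",
                                "nonnormal"}
    assert len(out) == 2
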