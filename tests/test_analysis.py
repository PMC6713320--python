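import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sonolift import analysis
from sonolift.analysis import (compare_between, compare_within,
                               fit_expertise_models, holm_adjust,
                               homogeneity_chisq, improvements, rating_tests)

check_normality = analysis.test_normality  # avoid pytest collecting the library name
from sonolift.errors import (DegenerateTableError, PairingError,
                             SampleSizeError, SingularDesignError)


# --- normality ---------------------------------------------------------------

def test_normality_accepts_gaussian_at_nominal_rate():
    rng = np.random.default_rng(0)
    accepted = sum(check_normality(rng.normal(size=20)).is_normal
                   for _ in range(500))
    assert accepted / 500 == pytest.approx(0.95, abs=0.03)


def test_normality_rejects_heavy_tails():
    rng = np.random.default_rng(1)
    rejected = sum(not check_normality(rng.standard_t(df=1, size=20)).is_normal
                   for _ in range(300))
    assert rejected / 300 > 0.8


def test_normality_degenerate_constant_sample():
    r = check_normality(np.full(10, 3.0))
    assert not r.is_normal
    assert r.warning is not None


def test_normality_requires_three_points():
    with pytest.raises(SampleSizeError):
        check_normality([1.0, 2.0])


# --- within-group comparison ---------------------------------------------------

def test_within_zero_mean_symmetric_differences():
    ctrl = np.array([0.0, 0.0, 0.0, 0.0])
    fb = np.array([1.0, -1.0, 2.0, -2.0])
    r = compare_within(fb, ctrl)
    assert r.test_name == "paired_t"
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == pytest.approx(1.0, abs=1e-12)


def test_within_detects_consistent_shift():
    rng = np.random.default_rng(2)
    ctrl = rng.normal(size=10)
    fb = ctrl + 0.5 + rng.normal(0, 0.01, size=10)
    r = compare_within(fb, ctrl)
    assert r.p_value < 0.001
    assert r.direction == 1


def test_within_identical_samples_degenerate():
    x = np.arange(8, dtype=float)
    r = compare_within(x, x)
    assert r.p_value == 1.0
    assert r.warning is not None


def test_within_branches_to_wilcoxon_on_non_normal_differences():
    rng = np.random.default_rng(3)
    ctrl = np.zeros(25)
    fb = np.exp(rng.normal(0, 2, size=25))  # heavily skewed differences
    r = compare_within(fb, ctrl)
    assert r.test_name == "wilcoxon_signed_rank"
    assert r.normality_used == (False,)


def test_within_length_mismatch():
    with pytest.raises(PairingError):
        compare_within([1, 2, 3], [1, 2])


# --- between-group comparison --------------------------------------------------

def test_between_identical_samples():
    x = np.array([0.3, 1.2, -0.5, 0.9, 0.0])
    r = compare_between(x, x)
    assert r.statistic == 0.0 and r.p_value == 1.0


def test_between_power_on_separated_gaussians():
    rng = np.random.default_rng(4)
    hits = 0
    for _ in range(200):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        if compare_between(a, b).p_value < 0.01:
            hits += 1
    assert hits / 200 > 0.95


def test_between_records_rank_sum_branch():
    rng = np.random.default_rng(5)
    a = np.exp(rng.normal(0, 2, size=30))   # log-normal: fails Shapiro-Wilk
    b = rng.normal(size=30)
    r = compare_between(a, b)
    assert r.test_name == "rank_sum"
    assert r.normality_used[0] is False


# --- chi-square homogeneity -----------------------------------------------------

def brute_force_chi2(table):
    t = np.asarray(table, float)
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    return float(((t - expected) ** 2 / expected).sum())


def test_chi2_degrees_of_freedom():
    r = homogeneity_chisq([[2, 9, 5], [3, 6, 6]])
    assert r.df == 2.0


def test_chi2_proportional_table_is_independent():
    r = homogeneity_chisq([[2, 4, 6], [1, 2, 3]])
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == pytest.approx(1.0, abs=1e-12)


def test_chi2_matches_brute_force_oracle():
    table = [[2, 9, 5], [3, 6, 6]]
    r = homogeneity_chisq(table)
    assert r.statistic == pytest.approx(brute_force_chi2(table), abs=1e-9)


def test_chi2_zero_marginal_rejected():
    with pytest.raises(DegenerateTableError):
        homogeneity_chisq([[0, 0, 0], [1, 2, 3]])


# --- improvements ----------------------------------------------------------------

def _cohort_rows(pid, group, expertise, ctrl, fb, condition="combination"):
    return [
        {"participant_id": pid, "group": group, "expertise": expertise,
         "condition": "control", "mean_sb": ctrl[0], "mean_bfd": ctrl[1]},
        {"participant_id": pid, "group": group, "expertise": expertise,
         "condition": condition, "mean_sb": fb[0], "mean_bfd": fb[1]},
    ]


def test_improvement_signs():
    cohort = pd.DataFrame(
        _cohort_rows("P0", "instruction", "B", (0.3, 0.4), (0.1, 1.0)))
    imp = improvements(cohort)
    assert imp["delta_sb"].iloc[0] == pytest.approx(-0.2)   # improvement
    assert imp["delta_bfd"].iloc[0] == pytest.approx(0.6)   # improvement


def test_identical_summaries_give_zero_deltas():
    cohort = pd.DataFrame(
        _cohort_rows("P0", "instruction", "B", (0.2, 0.5), (0.2, 0.5)))
    imp = improvements(cohort)
    assert imp["delta_sb"].iloc[0] == 0.0 and imp["delta_bfd"].iloc[0] == 0.0


def test_missing_condition_skips_with_warning():
    rows = _cohort_rows("P0", "instruction", "B", (0.2, 0.5), (0.1, 0.9))
    rows += _cohort_rows("P1", "instruction", "A", (0.2, 0.5), (0.1, 0.9))[:1]
    with pytest.warns(UserWarning):
        imp = improvements(pd.DataFrame(rows))
    assert list(imp["participant_id"]) == ["P0"]


# --- expertise models -------------------------------------------------------------

def _imp_table(outcomes, expertise, groups=None):
    n = len(outcomes)
    groups = groups or (["instruction", "sonification"] * n)[:n]
    return pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "group": groups, "expertise": expertise, "delta_bfd": outcomes,
        "delta_sb": outcomes,
    })


def test_exact_level_dependence_recovers_means():
    levels = ["A", "B", "C"] * 6
    gen = {"A": 1.0, "B": 0.2, "C": 0.5}
    imp = _imp_table([gen[l] for l in levels], levels)
    res = fit_expertise_models(imp, "delta_bfd")
    row = res.comparisons.set_index("model").loc["EXP"]
    assert row["p_value"] < 1e-10
    for lvl, mean in gen.items():
        assert res.level_predictions[lvl] == pytest.approx(mean, abs=1e-9)


def test_single_expertise_level_is_singular():
    imp = _imp_table(list(np.arange(10.0)), ["B"] * 10)
    with pytest.raises(SingularDesignError):
        fit_expertise_models(imp, "delta_bfd")


def test_expertise_null_model_type_one_error():
    rng = np.random.default_rng(6)
    levels = np.array(["A", "B", "C"])
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        imp = _imp_table(list(rng.normal(size=30)),
                         list(rng.choice(levels, size=30)))
        res = fit_expertise_models(imp, "delta_bfd")
        p = res.comparisons.set_index("model").loc["EXP", "p_value"]
        rejections += p < 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


# --- ratings ---------------------------------------------------------------------

def _rating_cohort(a_ratings, b_ratings, improvements_a=None):
    rows = []
    for i, r in enumerate(a_ratings):
        rows.append({"participant_id": f"A{i}", "group": "instruction",
                     "expertise": "B", "condition": "control",
                     "mean_sb": 0, "mean_bfd": 0, "rating_clarity": r})
    for i, r in enumerate(b_ratings):
        rows.append({"participant_id": f"B{i}", "group": "sonification",
                     "expertise": "B", "condition": "control",
                     "mean_sb": 0, "mean_bfd": 0, "rating_clarity": r})
    return pd.DataFrame(rows)


def test_identical_rating_vectors_give_p_one():
    cohort = _rating_cohort([3, 4, 5, 6], [3, 4, 5, 6])
    res = rating_tests(cohort)
    assert res["clarity"]["mann_whitney_u"].p_value == 1.0


def test_zero_ratings_are_excluded():
    cohort = _rating_cohort([3, 4, 5, 6, 0, 0], [3, 4, 5, 6])
    res = rating_tests(cohort)
    assert res["clarity"]["mann_whitney_u"].n == 8


def test_kendall_tau_perfect_concordance_and_discordance():
    ratings = [1, 2, 3, 4, 5, 6]
    cohort = _rating_cohort(ratings, [2, 3, 4])
    imp = pd.DataFrame({"participant_id": [f"A{i}" for i in range(6)],
                        "delta_sb": np.linspace(0.1, 0.6, 6)})
    res = rating_tests(cohort, imp)
    assert res["clarity"]["kendall_tau_b"].statistic == pytest.approx(1.0)
    imp_rev = imp.assign(delta_sb=imp["delta_sb"].to_numpy()[::-1])
    res_rev = rating_tests(cohort, imp_rev)
    assert res_rev["clarity"]["kendall_tau_b"].statistic == pytest.approx(-1.0)


def test_holm_adjustment_monotone():
    from sonolift.analysis import ComparisonResult
    results = {
        "a": ComparisonResult("rank_sum", 1.0, 0.01, n=10),
        "b": ComparisonResult("rank_sum", 1.0, 0.04, n=10),
        "c": ComparisonResult("rank_sum", 1.0, 0.30, n=10),
    }
    adj = holm_adjust(results)
    assert adj["a"] == pytest.approx(0.03)
    assert adj["a"] <= adj["b"] <= adj["c"]
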