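"""Cohort-level statistical evaluation of biofeedback sessions.

The evaluation pipeline works on a tidy cohort table (one row per participant
x condition, columns ``participant_id, group, expertise, sex, condition,
mean_sb, mean_bfd`` plus optional ``rating_*`` columns) and mirrors a
normality-branched testing scheme:

* within-group comparisons (feedback vs control, same participants) use a
  paired t-test when the Shapiro-Wilk test accepts normality of the paired
  differences, a Wilcoxon signed-rank test otherwise;
* between-group comparisons use a pooled two-sample t-test when both samples
  pass Shapiro-Wilk, a Wilcoxon rank-sum test otherwise;
* group homogeneity over expertise levels uses a Pearson chi-square without
  continuity correction;
* the effect of expertise on movement improvement is assessed with four
  nested ordinary-least-squares models (intercept only; + feedback type;
  + expertise; + both) compared by F-tests against the null model;
* feedback ratings are compared with Mann-Whitney U tests, and their relation
  to movement improvement with Kendall's tau-b.

Improvements are per-participant deltas feedback - control: a *negative*
delta of mean sb is an improvement (less forward bending), a *positive* delta
of mean bfd is an improvement (bar kept closer to the body, away from the
toes).  All tests are two-sided at alpha = 0.05; no multiple-testing
correction is applied by default (a Holm option is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .errors import (DegenerateTableError, PairingError, SampleSizeError,
                     SingularDesignError)

__all__ = [
    "NormalityResult",
    "ComparisonResult",
    "ExpertiseModelResult",
    "test_normality",
    "compare_within",
    "compare_between",
    "homogeneity_chisq",
    "improvements",
    "fit_expertise_models",
    "rating_tests",
    "holm_adjust",
]

ALPHA = 0.05
EXPERTISE_LEVELS = ("A", "B", "C")  # <6 months, 6 months-2 years, >2 years


@dataclass(frozen=True)
class NormalityResult:
    is_normal: bool
    statistic: float   # Shapiro-Wilk W
    p_value: float
    warning: str | None = None


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one branched two-sample (or one-sample) comparison."""

    test_name: str      # paired_t | wilcoxon_signed_rank | independent_t |
                        # rank_sum | mann_whitney_u | chi_square | kendall_tau_b | anova_F
    statistic: float
    p_value: float
    n: int
    df: float | None = None
    direction: int = 0           # sign of the effect (median/mean shift)
    normality_used: tuple[bool, ...] | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def test_normality(sample, alpha: float = ALPHA) -> NormalityResult:
    """Shapiro-Wilk normality check; ``is_normal`` iff p > alpha.

    Zero-variance samples cannot be tested and are flagged non-normal with a
    warning rather than raising.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise SampleSizeError(f"Shapiro-Wilk needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        return NormalityResult(False, np.nan, np.nan,
                               warning="constant sample; treated as non-normal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = stats.shapiro(x)
    return NormalityResult(bool(p > alpha), float(w), float(p))


def compare_within(x_feedback, x_control, alpha: float = ALPHA) -> ComparisonResult:
    """Paired comparison of a feedback condition against control.

    The paired differences are tested for normality; a paired t-test is used
    when they pass, a Wilcoxon signed-rank test otherwise.  Identical samples
    (zero-variance differences) return a degenerate p = 1 result with a
    warning instead of crashing.
    """
    x = np.asarray(x_feedback, dtype=float)
    y = np.asarray(x_control, dtype=float)
    if len(x) != len(y):
        raise PairingError(f"paired samples of lengths {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise SampleSizeError(f"paired comparison needs n >= 3, got {len(x)}")
    d = x - y
    direction = int(np.sign(np.mean(d))) if np.any(d != 0) else 0
    if np.ptp(d) == 0 and d[0] == 0:
        return ComparisonResult("paired_t", 0.0, 1.0, n=len(d), df=len(d) - 1,
                                direction=0, normality_used=(False,),
                                warning="zero-variance differences; degenerate")
    norm = test_normality(d, alpha)
    if norm.is_normal:
        res = stats.ttest_rel(x, y)
        return ComparisonResult("paired_t", float(res.statistic),
                                float(res.pvalue), n=len(d), df=float(res.df),
                                direction=direction, normality_used=(True,))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(d)
    return ComparisonResult("wilcoxon_signed_rank", float(res.statistic),
                            float(res.pvalue), n=int(np.count_nonzero(d)),
                            direction=direction, normality_used=(False,),
                            warning=norm.warning)


def compare_between(a, b, alpha: float = ALPHA, pooled: bool = True) -> ComparisonResult:
    """Independent two-sample comparison.

    Both samples must pass Shapiro-Wilk for a t-test (pooled variance by
    default, Welch with ``pooled=False``); otherwise a Wilcoxon rank-sum test
    (normal approximation) is used and the branch is recorded in
    ``normality_used``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 3:
        raise SampleSizeError("both samples need n >= 3")
    na, nb = test_normality(a, alpha), test_normality(b, alpha)
    direction = int(np.sign(np.mean(a) - np.mean(b))) if not np.array_equal(a, b) else 0
    if np.array_equal(a, b):
        return ComparisonResult("independent_t" if na.is_normal else "rank_sum",
                                0.0, 1.0, n=len(a) + len(b),
                                normality_used=(na.is_normal, nb.is_normal),
                                warning="identical samples; degenerate")
    if na.is_normal and nb.is_normal:
        res = stats.ttest_ind(a, b, equal_var=pooled)
        return ComparisonResult("independent_t", float(res.statistic),
                                float(res.pvalue), n=len(a) + len(b),
                                df=float(res.df), direction=direction,
                                normality_used=(True, True))
    res = stats.ranksums(a, b)
    return ComparisonResult("rank_sum", float(res.statistic), float(res.pvalue),
                            n=len(a) + len(b), direction=direction,
                            normality_used=(na.is_normal, nb.is_normal))


def homogeneity_chisq(table) -> ComparisonResult:
    """Pearson chi-square of independence on a groups x levels count table.

    No continuity correction; df = (rows - 1)(cols - 1).  A zero row or
    column marginal makes the table degenerate and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise DegenerateTableError("contingency table must be 2-D")
    if np.any(t < 0):
        raise DegenerateTableError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("zero marginal in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return ComparisonResult("chi_square", float(chi2), float(p),
                            n=int(t.sum()), df=float(dof))


def improvements(cohort: pd.DataFrame, condition: str = "combination") -> pd.DataFrame:
    """Per-participant deltas (feedback - control) of mean_sb and mean_bfd.

    Returns a frame with participant_id, group, expertise, delta_sb, delta_bfd.
    Participants missing either condition are skipped with a warning.  Sign
    conventions: delta_sb < 0 and delta_bfd > 0 are improvements.
    """
    out = []
    for pid, sub in cohort.groupby("participant_id", sort=False):
        ctrl = sub[sub["condition"] == "control"]
        fb = sub[sub["condition"] == condition]
        if len(ctrl) != 1 or len(fb) != 1:
            warnings.warn(f"participant {pid}: missing control or {condition} "
                          f"summary; skipped")
            continue
        out.append({
            "participant_id": pid,
            "group": sub["group"].iloc[0],
            "expertise": sub["expertise"].iloc[0],
            "delta_sb": float(fb["mean_sb"].iloc[0] - ctrl["mean_sb"].iloc[0]),
            "delta_bfd": float(fb["mean_bfd"].iloc[0] - ctrl["mean_bfd"].iloc[0]),
        })
    return pd.DataFrame(out)


@dataclass
class ExpertiseModelResult:
    """Nested OLS model comparison for one improvement outcome."""

    outcome: str
    comparisons: pd.DataFrame          # rows FB / EXP / FULL vs the null model
    level_predictions: dict[str, float]  # fitted mean improvement per expertise level
    models: dict = field(repr=False, default_factory=dict)


def fit_expertise_models(imp: pd.DataFrame, outcome: str = "delta_bfd",
                         ordinal: bool = False) -> ExpertiseModelResult:
    """Fit the four nested linear models of movement improvement and compare
    them against the null model with F-tests.

    Models: 0 (intercept only), FB (+feedback type), EXP (+expertise), FULL
    (+both).  Expertise enters as an unordered 3-level factor by default
    (``ordinal=True`` switches to polynomial contrasts for the ordered
    reading).  Per-level fitted means come from model EXP.
    """
    data = imp.copy()
    for col in ("group", "expertise", outcome):
        if col not in data.columns:
            raise KeyError(f"improvement table lacks column {col!r}")
    levels = sorted(data["expertise"].unique())
    if len(levels) < 2:
        raise SingularDesignError(
            f"expertise has a single level ({levels}); term 'expertise' aliased"
        )
    if data["group"].nunique() < 2:
        raise SingularDesignError("feedback type has a single level; term 'group' aliased")
    n_params_full = 1 + (data["group"].nunique() - 1) + (len(levels) - 1)
    if len(data) <= n_params_full:
        raise SampleSizeError(f"n = {len(data)} too small for {n_params_full} parameters")

    exp_term = "C(expertise, Poly)" if ordinal else "C(expertise)"
    formulas = {
        "0": f"{outcome} ~ 1",
        "FB": f"{outcome} ~ C(group)",
        "EXP": f"{outcome} ~ {exp_term}",
        "FULL": f"{outcome} ~ C(group) + {exp_term}",
    }
    models = {name: smf.ols(f, data=data).fit() for name, f in formulas.items()}

    rows = []
    for name in ("FB", "EXP", "FULL"):
        m0, m1 = models["0"], models[name]
        df_diff = m0.df_resid - m1.df_resid
        if m1.ssr <= 1e-12 * max(m0.ssr, 1.0):  # exact fit: F -> inf
            f_val, p_val = np.inf, 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tbl = anova_lm(m0, m1)
            f_val = float(tbl["F"].iloc[1])
            p_val = float(tbl["Pr(>F)"].iloc[1])
        rows.append({"model": name, "df_num": float(df_diff),
                     "df_den": float(m1.df_resid), "F": f_val, "p_value": p_val})
    comparisons = pd.DataFrame(rows)

    grid = pd.DataFrame({"expertise": levels})
    preds = models["EXP"].predict(grid)
    level_predictions = {lvl: float(v) for lvl, v in zip(levels, preds)}
    return ExpertiseModelResult(outcome=outcome, comparisons=comparisons,
                                level_predictions=level_predictions, models=models)


def rating_tests(cohort: pd.DataFrame, imp: pd.DataFrame | None = None,
                 characteristics: list[str] | None = None,
                 improvement_col: str = "delta_sb") -> dict[str, dict[str, ComparisonResult]]:
    """Compare feedback ratings between groups and correlate them with improvement.

    Rating columns are named ``rating_<characteristic>`` on a 1-7 scale with 0
    meaning "no feedback perceived"; zeros are excluded before testing.  Per
    characteristic: a two-sided Mann-Whitney U between the two groups, and
    (when an improvement table is supplied) Kendall's tau-b between the
    improvement and the rating.  Characteristics left empty after zero
    exclusion are skipped with a warning.
    """
    if characteristics is None:
        characteristics = [c.removeprefix("rating_") for c in cohort.columns
                           if c.startswith("rating_")]
    per_participant = cohort.drop_duplicates("participant_id")
    groups = sorted(per_participant["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"rating comparison needs exactly 2 groups, got {groups}")
    results: dict[str, dict[str, ComparisonResult]] = {}
    for char in characteristics:
        col = f"rating_{char}"
        sub = per_participant[["participant_id", "group", col]].dropna()
        sub = sub[sub[col] != 0]  # 0 = no feedback perceived
        a = sub.loc[sub["group"] == groups[0], col].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == groups[1], col].to_numpy(dtype=float)
        if min(len(a), len(b)) < 3:
            warnings.warn(f"rating {char!r}: fewer than 3 ratings per group "
                          f"after zero exclusion; skipped")
            continue
        entry: dict[str, ComparisonResult] = {}
        if np.array_equal(np.sort(a), np.sort(b)):
            entry["mann_whitney_u"] = ComparisonResult(
                "mann_whitney_u", float(len(a) * len(b) / 2), 1.0,
                n=len(a) + len(b), warning="identical rating vectors")
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            entry["mann_whitney_u"] = ComparisonResult(
                "mann_whitney_u", float(u), float(p), n=len(a) + len(b))
        if imp is not None:
            merged = sub.merge(imp[["participant_id", improvement_col]],
                               on="participant_id").dropna()
            if len(merged) >= 3:
                tau, p = stats.kendalltau(merged[improvement_col], merged[col],
                                          variant="b")
                entry["kendall_tau_b"] = ComparisonResult(
                    "kendall_tau_b", float(tau), float(p), n=len(merged))
        results[char] = entry
    return results


def holm_adjust(results: dict[str, ComparisonResult]) -> dict[str, float]:
    """Optional Holm step-down adjustment over a family of comparisons."""
    names = list(results)
    pvals = [results[n].p_value for n in names]
    _, adj, _, _ = multipletests(pvals, method="holm")
    return dict(zip(names, adj))
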