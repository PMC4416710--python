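"""Cohort comparisons from printed summary statistics.

Group-level demographic and behavioral comparisons in case/control
studies are usually reported as mean +/- SD per group with a two-sample
t-test p-value, plus a chi-square test for categorical variables such as
gender.  These can be recomputed exactly from the printed summaries, which
is what this module does: a pooled-variance (or Welch) two-sample t-test
from (n, mean, sd) pairs and a Pearson chi-square on a 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupSummary", "t_test_from_summary", "chi2_2x2", "STUDY_COHORT",
           "cohort_report"]


@dataclass(frozen=True)
class GroupSummary:
    """Printed per-group summary: sample size, mean, SD (variable units)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def t_test_from_summary(a: GroupSummary, b: GroupSummary,
                        variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    variant="pooled": classical equal-variance test, df = n_a + n_b - 2;
    variant="welch": unequal variances with Satterthwaite df.  Returns
    (t, df, two-tailed p).  Both SDs zero with equal means is undefined
    and reported as (nan, df, nan).
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        df = a.n + b.n - 2 if variant == "pooled" else float("nan")
        return float("nan"), float(df), float("nan")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi2_2x2(a_yes: int, a_no: int, b_yes: int, b_no: int,
             correction: str = "none") -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table; optional Yates continuity correction.

    Returns (statistic, p).  A table with identical group proportions gives
    statistic 0 and p = 1.
    """
    for c in (a_yes, a_no, b_yes, b_no):
        if c < 0:
            raise ValueError("counts must be non-negative")
    if correction not in ("none", "yates"):
        raise ValueError("correction must be 'none' or 'yates'")
    table = np.array([[a_yes, a_no], [b_yes, b_no]], dtype=float)
    res = stats.chi2_contingency(table, correction=(correction == "yates"))
    return float(res.statistic), float(res.pvalue)


#: Cohort summaries of the depression study this pipeline targets:
#: 31 controls vs 31 first-episode, drug-naive MDD patients, with verbal
#: fluency task behavior.  Each row: (control summary, patient summary).
STUDY_COHORT: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "age": (GroupSummary(31, 33.45, 12.0), GroupSummary(31, 38.81, 9.76)),
    "reading_test_jart": (GroupSummary(31, 113.33, 8.51), GroupSummary(31, 109.29, 10.19)),
    "semantic_successful_trials": (GroupSummary(31, 29.19, 1.51), GroupSummary(31, 27.81, 3.12)),
    "semantic_reaction_time_s": (GroupSummary(31, 1.28, 0.32), GroupSummary(31, 1.50, 0.33)),
    "phonological_successful_trials": (GroupSummary(31, 29.19, 1.54), GroupSummary(31, 26.58, 2.86)),
    "phonological_reaction_time_s": (GroupSummary(31, 1.39, 0.36), GroupSummary(31, 1.65, 0.34)),
}

#: gender counts: (males_control, total_control, males_patient, total_patient)
STUDY_GENDER = (15, 31, 16, 31)


def cohort_report(rows: dict[str, tuple[GroupSummary, GroupSummary]] | None = None,
                  gender: tuple[int, int, int, int] | None = None) -> pd.DataFrame:
    """Both t-test variants per continuous row plus the gender chi-square.

    p-values are reported to 4 significant figures in the ``p_*_4sf``
    columns alongside the full-precision values.
    """
    rows = STUDY_COHORT if rows is None else rows
    gender = STUDY_GENDER if gender is None else gender
    out = []
    for name, (ctrl, pat) in rows.items():
        t_p, df_p, p_p = t_test_from_summary(ctrl, pat, "pooled")
        t_w, df_w, p_w = t_test_from_summary(ctrl, pat, "welch")
        out.append(
            {
                "variable": name, "test": "t",
                "t_pooled": t_p, "df_pooled": df_p, "p_pooled": p_p,
                "t_welch": t_w, "df_welch": df_w, "p_welch": p_w,
                "p_pooled_4sf": float(f"{p_p:.4g}"), "p_welch_4sf": float(f"{p_w:.4g}"),
            }
        )
    m_c, n_c, m_p, n_p = gender
    chi, p = chi2_2x2(m_c, n_c - m_c, m_p, n_p - m_p, correction="none")
    out.append({"variable": "gender_male", "test": "chi2", "t_pooled": chi,
                "p_pooled": p, "p_pooled_4sf": float(f"{p:.4g}")})
    return pd.DataFrame(out)
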