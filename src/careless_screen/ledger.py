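"""Variable-appropriateness grading from Shapley contribution comparisons.

Each predictor variable is graded by three criteria and the grades are
merged into an overall appropriateness level:

* **Comparison 1** — correctly predicted careless (TP) vs correctly
  predicted regular (TN) respondents. Opposite-signed mean contributions
  are *good*: the variable separates the two populations.
* **Comparison 2** — correctly (TP) vs incorrectly (FN) predicted
  careless respondents. Opposite-signed contributions are *bad*: the
  variable flips sign exactly where the model fails, a likely driver of
  misclassifications.
* **Criterion 3** — contribution stability when the careless-responding
  indices are added to the predictor set (model with vs without the index
  block). Stable mean contribution earns +1, a significant shift -1;
  variables whose mean contribution is below 0.01 in both fits (rounded
  to three decimals) are not rated.

Sign magnitudes for Comparisons 1-2: a variable inside the *influence
set* (union of the top-5 and bottom-5 variables by the reference group's
mean contribution) earns three signs when the group difference is not
significant and two when it is; variables outside the influence set earn
a single sign. Significance defaults to non-overlap of the 95% CIs.

Merging: the signed criterion values are summed and clamped to [-3, +3]
("---" ... "+++", with 0 neutral). A variable with fewer than two rated
criteria gets no overall level (rendered X).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .shapley import ContributionSummary

logger = logging.getLogger(__name__)

NOT_RATED = None
OPPOSITE_IS_GOOD = "opposite_is_good"
OPPOSITE_IS_BAD = "opposite_is_bad"

_RENDER = {-3: "---", -2: "--", -1: "-", 0: "0", 1: "+", 2: "++", 3: "+++"}
_PARSE = {v: k for k, v in _RENDER.items()}


def render_grade(value: int | None) -> str:
    """Render a sign grade (-3..+3) as '---'..'+++'; NOT_RATED as ''."""
    if value is NOT_RATED:
        return ""
    if value not in _RENDER:
        raise ValueError(f"grade {value!r} outside [-3, 3]")
    return _RENDER[value]


def parse_grade(text: str) -> int | None:
    if text == "":
        return NOT_RATED
    if text not in _PARSE:
        raise ValueError(f"unparseable grade {text!r}")
    return _PARSE[text]


@dataclass(frozen=True)
class LedgerRow:
    variable: str
    meaning: str
    comparison1: int | None
    comparison2: int | None
    criterion3: int | None
    overall: int | None          # None when rendered as X
    overall_is_x: bool

    def rendered(self) -> dict[str, str]:
        return {
            "variable": self.variable,
            "meaning": self.meaning,
            "comparison_1": render_grade(self.comparison1),
            "comparison_2": render_grade(self.comparison2),
            "criterion_3": render_grade(self.criterion3),
            "overall": "X" if self.overall_is_x else render_grade(self.overall),
        }


# ---------------------------------------------------------------------------
# influence ranking and significance
# ---------------------------------------------------------------------------

def rank_influential(summary: ContributionSummary, reference_group: str,
                     k: int = 5) -> pd.DataFrame:
    """Variables ordered by the reference group's mean contribution, with
    top-k / bottom-k flags. Ties break by variable id, deterministically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    frame = summary.group_frame(reference_group).reset_index()
    if k > len(frame):
        logger.warning("k=%d exceeds %d variables; clamped", k, len(frame))
        k = len(frame)
    frame = frame.sort_values(["mean", "variable"],
                              ascending=[False, True], kind="stable")
    frame = frame.reset_index(drop=True)
    n = len(frame)
    frame["rank"] = np.arange(1, n + 1)
    frame["top"] = frame["rank"] <= k
    # bottom-k by ascending mean with the same lexical tie-break
    bottom_order = frame.sort_values(["mean", "variable"],
                                     ascending=[True, True], kind="stable")
    bottom_ids = set(bottom_order["variable"].iloc[:k])
    frame["bottom"] = frame["variable"].isin(bottom_ids)
    return frame[["variable", "mean", "rank", "top", "bottom"]]


def influence_set(summary: ContributionSummary, reference_group: str,
                  k: int = 5) -> set[str]:
    """Union of top-k and bottom-k variables for the reference group."""
    ranked = rank_influential(summary, reference_group, k)
    return set(ranked.loc[ranked["top"] | ranked["bottom"], "variable"])


def significant_difference(mean_a: float, ci_a: tuple[float, float],
                           mean_b: float, ci_b: tuple[float, float]) -> bool:
    """True iff the two 95% CIs do not overlap."""
    (lo_a, hi_a), (lo_b, hi_b) = ci_a, ci_b
    if not (lo_a <= mean_a <= hi_a and lo_b <= mean_b <= hi_b):
        raise ValueError("means must lie inside their CIs")
    return hi_a < lo_b or hi_b < lo_a


def welch_significant(values_a: Sequence[float], values_b: Sequence[float],
                      alpha: float = 0.05) -> bool:
    """Alternative significance rule: Welch two-sample t-test."""
    _, p = stats.ttest_ind(values_a, values_b, equal_var=False)
    return bool(p < alpha)


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

def _signs_opposite(a: float, b: float) -> bool:
    return a * b < 0


def grade_comparison(summary_a: ContributionSummary, group_a: str,
                     summary_b: ContributionSummary, group_b: str,
                     polarity: str, influence: set[str]
                     ) -> dict[str, int | None]:
    """Sign grade per variable for a two-group contribution comparison.

    Direction is + when the evidence matches the polarity's good pattern
    (opposite-signed means under ``opposite_is_good``, same-signed under
    ``opposite_is_bad``), - otherwise. Magnitude is 3 for influence-set
    variables without a significant group difference, 2 with one, and 1
    outside the influence set.
    """
    if polarity not in (OPPOSITE_IS_GOOD, OPPOSITE_IS_BAD):
        raise ValueError(f"unknown polarity {polarity!r}")
    fa = summary_a.group_frame(group_a)
    fb = summary_b.group_frame(group_b)
    grades: dict[str, int | None] = {}
    for v in fa.index.union(fb.index):
        if v not in fa.index or v not in fb.index:
            grades[v] = NOT_RATED
            continue
        ra, rb = fa.loc[v], fb.loc[v]
        opposite = _signs_opposite(ra["mean"], rb["mean"])
        good = opposite if polarity == OPPOSITE_IS_GOOD else not opposite
        direction = 1 if good else -1
        if v in influence:
            sig = significant_difference(ra["mean"], (ra["ci_lo"], ra["ci_hi"]),
                                         rb["mean"], (rb["ci_lo"], rb["ci_hi"]))
            magnitude = 2 if sig else 3
        else:
            magnitude = 1
        grades[v] = direction * magnitude
    return grades


def grade_criterion3(summary_all: ContributionSummary,
                     summary_extracted: ContributionSummary,
                     min_abs: float = 0.01) -> dict[str, int | None]:
    """Stability grade for the with/without-indices comparison.

    Rated only when the absolute mean contribution, rounded to three
    decimals, reaches ``min_abs`` in either fit. +1 when the CIs overlap
    (stable), -1 when they are disjoint (significant shift). Variables
    absent from the without-indices fit (the index columns themselves)
    are NOT_RATED.
    """
    fa = summary_all.group_frame("all")
    fb = summary_extracted.group_frame("all")
    grades: dict[str, int | None] = {}
    for v in fb.index:
        if v not in fa.index:
            grades[v] = NOT_RATED
            continue
        ra, rb = fa.loc[v], fb.loc[v]
        if max(round(abs(ra["mean"]), 3), round(abs(rb["mean"]), 3)) < min_abs:
            grades[v] = NOT_RATED
            continue
        sig = significant_difference(ra["mean"], (ra["ci_lo"], ra["ci_hi"]),
                                     rb["mean"], (rb["ci_lo"], rb["ci_hi"]))
        grades[v] = -1 if sig else 1
    return grades


def merge_grades(comparison1: int | None, comparison2: int | None,
                 criterion3: int | None) -> tuple[int | None, bool]:
    """Merged overall level: (value, is_x).

    X (no overall level) when fewer than two criteria are rated;
    otherwise the signed sum of rated values clamped to [-3, +3].
    """
    rated = [c for c in (comparison1, comparison2, criterion3)
             if c is not NOT_RATED]
    if len(rated) < 2:
        return NOT_RATED, True
    return int(np.clip(sum(rated), -3, 3)), False


def build_ledger(records_extracted: pd.DataFrame,
                 records_all: pd.DataFrame,
                 meanings: Mapping[str, str] | None = None,
                 k: int = 5, min_abs: float = 0.01) -> pd.DataFrame:
    """Full appropriateness ledger from contribution records of the fits
    with (``records_extracted``) and without (``records_all``) the
    careless-responding index block.

    Comparison 1 grades TP vs TN and Comparison 2 TP vs FN, both on the
    with-indices fit; reference groups for the influence sets are TP and
    FN respectively. Criterion 3 compares all-respondent means across the
    two fits. An empty comparison group skips that criterion for every
    variable, with a logged warning.
    """
    from .shapley import summarize_group_contributions

    meanings = dict(meanings or {})
    by_group = summarize_group_contributions(records_extracted,
                                             groups=("TP", "TN", "FN"))
    present = set(by_group.groups())
    var_cols = [c for c in records_extracted.columns
                if c not in ("respondent", "group", "model_output")]

    if {"TP", "TN"} <= present:
        c1 = grade_comparison(by_group, "TP", by_group, "TN",
                              OPPOSITE_IS_GOOD,
                              influence_set(by_group, "TP", k))
    else:
        logger.warning("comparison 1 skipped: TP or TN group empty")
        c1 = {v: NOT_RATED for v in var_cols}
    if {"TP", "FN"} <= present:
        c2 = grade_comparison(by_group, "TP", by_group, "FN",
                              OPPOSITE_IS_BAD,
                              influence_set(by_group, "FN", k))
    else:
        logger.warning("comparison 2 skipped: TP or FN group empty")
        c2 = {v: NOT_RATED for v in var_cols}
    c3 = grade_criterion3(summarize_group_contributions(records_all),
                          summarize_group_contributions(records_extracted),
                          min_abs=min_abs)

    rows = []
    for v in var_cols:
        g1, g2, g3 = c1.get(v, NOT_RATED), c2.get(v, NOT_RATED), c3.get(v, NOT_RATED)
        overall, is_x = merge_grades(g1, g2, g3)
        row = LedgerRow(variable=v, meaning=meanings.get(v, ""),
                        comparison1=g1, comparison2=g2, criterion3=g3,
                        overall=overall, overall_is_x=is_x)
        rows.append(row.rendered() | {
            "_c1": g1, "_c2": g2, "_c3": g3,
            "_overall": overall if not is_x else np.nan})
    return pd.DataFrame(rows)


def render_ledger_text(ledger: pd.DataFrame) -> str:
    """Human-readable fixed-width table of the ledger."""
    cols = ["variable", "meaning", "comparison_1", "comparison_2",
            "criterion_3", "overall"]
    sub = ledger[cols].astype(str)
    widths = {c: max(len(c), sub[c].str.len().max()) for c in cols}
    head = "  ".join(c.ljust(widths[c]) for c in cols)
    lines = [head, "-" * len(head)]
    for _, r in sub.iterrows():
        lines.append("  ".join(r[c].ljust(widths[c]) for c in cols))
    return "\n".join(lines) + "\n"
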