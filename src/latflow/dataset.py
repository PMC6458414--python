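"""Subject x condition laterality tables, QC, and descriptive statistics.

The central container is :class:`LateralityTable`: one laterality index (LI)
per subject per condition, where a condition is a task (``"A"``..``"F"``)
crossed with a test session (1 or 2), labelled ``"A1"`` .. ``"F2"``.  Cells
excluded by quality control are explicit missing values and stay missing all
the way into the likelihood (they are never imputed).

Also here: the Hoaglin-Iglewicz standard-error outlier rule used to drop
unreliable LI estimates, the pairwise-complete correlation matrix across the
twelve conditions, per-condition group laterality tests, and summaries of the
behavioural trial logs (accuracy, reaction time, words spoken).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TASKS = ("A", "B", "C", "D", "E", "F")
SESSIONS = (1, 2)


def condition_label(task: str, session: int) -> str:
    return f"{task}{session}"


def condition_task(condition: str) -> str:
    return condition[:-1]


def condition_session(condition: str) -> int:
    return int(condition[-1])


def condition_labels(tasks: Iterable[str] = TASKS,
                     sessions: Iterable[int] = SESSIONS) -> list[str]:
    """Condition labels ordered session-major: A1..F1, A2..F2."""
    return [condition_label(t, s) for s in sessions for t in tasks]


@dataclass
class LateralityTable:
    """Subjects x conditions LI matrix with per-cell standard errors.

    Parameters
    ----------
    li
        DataFrame indexed by subject id with one column per condition label.
        Missing cells are NaN.
    se
        Same shape as ``li``; per-cell trial standard error.  Optional.
    subjects
        Per-subject metadata (``handedness`` in {"left", "right"} and
        ``age``).  If omitted, right-handed adults are assumed.
    exclusions
        Mapping ``(subject, condition) -> reason`` recording why a cell was
        set missing.
    """

    li: pd.DataFrame
    se: pd.DataFrame | None = None
    subjects: pd.DataFrame | None = None
    exclusions: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.li = self.li.astype(float)
        if self.se is not None:
            if self.se.shape != self.li.shape:
                raise ValueError("se matrix must match li matrix shape")
            self.se = self.se.astype(float)
            self.se.index = self.li.index
            self.se.columns = self.li.columns
        if self.subjects is None:
            self.subjects = pd.DataFrame(
                {"handedness": "right", "age": np.nan}, index=self.li.index
            )
        if "handedness" not in self.subjects.columns:
            raise ValueError("subject metadata must record handedness")
        self.subjects = self.subjects.loc[self.li.index]

    # -- structure ---------------------------------------------------------
    @property
    def conditions(self) -> list[str]:
        return list(self.li.columns)

    @property
    def tasks(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            t = condition_task(c)
            if t not in seen:
                seen.append(t)
        return seen

    @property
    def sessions(self) -> list[int]:
        return sorted({condition_session(c) for c in self.conditions})

    @property
    def n_subjects(self) -> int:
        return len(self.li)

    def test_retest_pairs(self) -> list[tuple[str, str]]:
        """Pairs of condition labels measuring the same task in two sessions."""
        pairs = []
        for t in self.tasks:
            conds = [c for c in self.conditions if condition_task(c) == t]
            if len(conds) == 2:
                pairs.append((conds[0], conds[1]))
        return pairs

    # -- mutation ----------------------------------------------------------
    def exclude_cell(self, subject: str, condition: str, reason: str) -> None:
        if not reason:
            raise ValueError("exclusion reason must be non-empty")
        self.li.loc[subject, condition] = np.nan
        self.exclusions[(subject, condition)] = reason

    def copy(self) -> "LateralityTable":
        return LateralityTable(
            li=self.li.copy(),
            se=None if self.se is None else self.se.copy(),
            subjects=self.subjects.copy(),
            exclusions=dict(self.exclusions),
        )

    # -- serialization -----------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        rows = []
        for subj in self.li.index:
            for cond in self.conditions:
                rows.append(
                    {
                        "subject": subj,
                        "task": condition_task(cond),
                        "session": condition_session(cond),
                        "li": self.li.loc[subj, cond],
                        "se": np.nan if self.se is None else self.se.loc[subj, cond],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_long(cls, df: pd.DataFrame,
                  subjects: pd.DataFrame | None = None) -> "LateralityTable":
        df = df.copy()
        df["condition"] = [
            condition_label(t, int(s)) for t, s in zip(df["task"], df["session"])
        ]
        li = df.pivot_table(index="subject", columns="condition", values="li",
                            dropna=False, aggfunc="first")
        order = condition_labels(
            tasks=sorted(df["task"].unique()),
            sessions=sorted(df["session"].astype(int).unique()),
        )
        li = li.reindex(columns=[c for c in order if c in li.columns])
        se = None
        if "se" in df.columns and df["se"].notna().any():
            se = df.pivot_table(index="subject", columns="condition", values="se",
                                dropna=False, aggfunc="first")
            se = se.reindex(columns=li.columns)
        return cls(li=li, se=se, subjects=subjects)


# ---------------------------------------------------------------------------
# Standard-error outlier exclusion (Hoaglin-Iglewicz rule)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcConfig:
    """Configuration of the SE outlier rule.

    ``threshold = Q3 + iqr_multiplier * (Q3 - Q1)`` computed over the standard
    errors of *all* cells pooled across subjects, tasks and sessions; quartiles
    use linearly interpolated order statistics (numpy's default).
    """

    iqr_multiplier: float = 2.2
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be positive")


@dataclass
class QcResult:
    table: LateralityTable
    threshold: float
    q1: float
    q3: float
    excluded: list[tuple[str, str]]

    def report(self) -> dict:
        return {
            "rule": "se > Q3 + k*(Q3 - Q1), pooled over all cells",
            "q1": self.q1,
            "q3": self.q3,
            "threshold": self.threshold,
            "n_excluded": len(self.excluded),
            "excluded_cells": [list(c) for c in self.excluded],
        }


def se_outlier_exclusion(table: LateralityTable,
                         qc: QcConfig = QcConfig()) -> QcResult:
    """Drop LI cells whose trial standard error is an outlier.

    The SE values of every cell (all subjects, tasks and sessions) are pooled
    into a single vector; cells strictly above ``Q3 + k*(Q3 - Q1)`` have their
    LI set missing with reason ``"se_outlier"``.  The threshold is a single
    number for the whole dataset, not per task.
    """
    if table.se is None:
        raise ValueError("table has no standard errors to screen")
    pooled = table.se.to_numpy(float).ravel()
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("all standard errors are missing")
    q1 = float(np.quantile(pooled, 0.25, method=qc.quantile_method))
    q3 = float(np.quantile(pooled, 0.75, method=qc.quantile_method))
    threshold = q3 + qc.iqr_multiplier * (q3 - q1)

    out = table.copy()
    excluded = []
    for subj in out.li.index:
        for cond in out.conditions:
            se = out.se.loc[subj, cond]
            if np.isfinite(se) and se > threshold and np.isfinite(out.li.loc[subj, cond]):
                out.exclude_cell(subj, cond, "se_outlier")
                excluded.append((subj, cond))
    return QcResult(table=out, threshold=threshold, q1=q1, q3=q3,
                    excluded=excluded)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def correlation_matrix(table: LateralityTable,
                       min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations across the 12 conditions.

    Entries with fewer than ``min_pairs`` complete pairs are NaN and logged.
    Missingness is handled cell-wise, not subject-wise.
    """
    corr = table.li.corr(method="pearson", min_periods=min_pairs)
    counts = table.li.notna().astype(int)
    pair_n = counts.T @ counts
    short = [(a, b) for a in corr.index for b in corr.columns
             if a < b and pair_n.loc[a, b] < min_pairs]
    for a, b in short:
        logger.warning("correlation %s-%s: only %d complete pairs", a, b,
                       pair_n.loc[a, b])
    return corr


def test_retest(table: LateralityTable,
                corr: pd.DataFrame | None = None) -> pd.Series:
    """Per-task test-retest correlation (same task, different session)."""
    if corr is None:
        corr = correlation_matrix(table)
    vals = {}
    for c1, c2 in table.test_retest_pairs():
        vals[condition_task(c1)] = corr.loc[c1, c2]
    return pd.Series(vals, name="test_retest_r")


def group_laterality_tests(table: LateralityTable,
                           wilcoxon_alternative: str = "two-sided"
                           ) -> pd.DataFrame:
    """Per-condition tests of group-level left lateralization.

    For each condition: a one-sided one-sample t-test of mean > 0 (df = n-1),
    a Wilcoxon signed-rank test against zero, and a Shapiro-Wilk normality
    statistic.  Degenerate (constant) conditions are flagged undefined.
    """
    rows = []
    for cond in table.conditions:
        x = table.li[cond].dropna().to_numpy()
        row: dict = {"condition": cond, "n": len(x),
                     "mean": np.nan, "sd": np.nan, "t": np.nan, "df": np.nan,
                     "p_t": np.nan, "wilcoxon": np.nan, "p_wilcoxon": np.nan,
                     "shapiro_w": np.nan, "p_shapiro": np.nan, "note": ""}
        if len(x) < 3:
            row["note"] = "insufficient_data"
        elif np.ptp(x) == 0:
            row.update(mean=float(x.mean()), sd=0.0, note="degenerate_constant")
        else:
            t_res = stats.ttest_1samp(x, 0.0, alternative="greater")
            w_res = stats.wilcoxon(x, alternative=wilcoxon_alternative)
            s_res = stats.shapiro(x)
            row.update(
                mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)),
                t=float(t_res.statistic), df=len(x) - 1,
                p_t=float(t_res.pvalue),
                wilcoxon=float(w_res.statistic), p_wilcoxon=float(w_res.pvalue),
                shapiro_w=float(s_res.statistic), p_shapiro=float(s_res.pvalue),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")


# ---------------------------------------------------------------------------
# Behavioural trial logs
# ---------------------------------------------------------------------------

class BehaviouralLog:
    """Per-trial behavioural records.

    ``trials`` must have columns: subject, task, session, correct (bool),
    rt (seconds; NaN for production tasks), omitted (bool), words (count;
    NaN for decision tasks).  Omitted trials are scored incorrect.
    """

    REQUIRED = ("subject", "task", "session", "correct", "rt", "omitted", "words")

    def __init__(self, trials: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in trials.columns]
        if missing:
            raise ValueError(f"behavioural log missing columns: {missing}")
        trials = trials.copy()
        if bool((trials["omitted"] & trials["correct"]).any()):
            raise ValueError("omitted trials must be scored incorrect")
        if bool((trials["rt"].dropna() < 0).any()):
            raise ValueError("reaction times must be non-negative")
        self.trials = trials


def _trimmed_rt(rts: np.ndarray) -> float:
    """Mean RT over correct trials after a single +/-2 s.d. trim.

    The mean and s.d. are computed once over the untrimmed correct-trial RTs;
    trials beyond two s.d. of that mean are dropped; the rule is not iterated.
    """
    rts = rts[np.isfinite(rts)]
    if rts.size == 0:
        return np.nan
    if rts.size == 1:
        return float(rts[0])
    m, sd = rts.mean(), rts.std(ddof=1)
    keep = np.abs(rts - m) <= 2 * sd
    return float(rts[keep].mean())


@dataclass
class BehaviouralSummary:
    per_subject: pd.DataFrame     # subject x task x session level measures
    summary: pd.DataFrame         # task x session means
    session_tests: pd.DataFrame   # paired t-tests session 1 vs 2
    words_anova: pd.DataFrame | None  # 2x2 repeated-measures ANOVA (task x session)


def behavioural_summaries(log: BehaviouralLog) -> BehaviouralSummary:
    """Accuracy, trimmed reaction times, omissions and word counts.

    Accuracy counts omissions as incorrect.  RT means are taken over correct
    trials after excluding trials more than 2 s.d. from the subject x task x
    session mean (single pass).  Word counts are averaged per trial for
    production tasks.  Session 1 vs session 2 paired t-tests are run per task
    and measure, and word counts enter a task x session repeated-measures
    ANOVA when two production tasks are present.
    """
    df = log.trials
    if df.empty:
        raise ValueError("behavioural log is empty")

    recs = []
    for (subj, task, sess), g in df.groupby(["subject", "task", "session"]):
        correct_rts = g.loc[g["correct"].astype(bool), "rt"].to_numpy(float)
        recs.append({
            "subject": subj, "task": task, "session": int(sess),
            "accuracy_pct": 100.0 * g["correct"].astype(bool).mean(),
            "omission_pct": 100.0 * g["omitted"].astype(bool).mean(),
            "rt_mean": _trimmed_rt(correct_rts),
            "words_mean": float(g["words"].mean()) if g["words"].notna().any() else np.nan,
        })
    per_subject = pd.DataFrame(recs)

    summary = (per_subject
               .groupby(["task", "session"])[["accuracy_pct", "omission_pct",
                                              "rt_mean", "words_mean"]]
               .mean())

    tests = []
    for task, g in per_subject.groupby("task"):
        wide = g.pivot(index="subject", columns="session",
                       values=["accuracy_pct", "rt_mean", "words_mean"])
        for measure in ("accuracy_pct", "rt_mean", "words_mean"):
            if measure not in wide.columns.get_level_values(0):
                continue
            sub = wide[measure].dropna()
            if sub.shape[1] < 2 or len(sub) < 2:
                continue
            s1, s2 = sub.iloc[:, 0], sub.iloc[:, 1]
            if np.allclose(s1, s2):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(s1, s2)
            tests.append({"task": task, "measure": measure, "n": len(sub),
                          "t": float(t), "p": float(p)})
    session_tests = pd.DataFrame(tests)

    words_anova = None
    prod = per_subject.dropna(subset=["words_mean"])
    if prod["task"].nunique() >= 2:
        complete = prod.groupby("subject").size()
        keep = complete[complete == prod["task"].nunique() * prod["session"].nunique()]
        prod = prod[prod["subject"].isin(keep.index)]
        if len(keep) >= 3:
            from statsmodels.stats.anova import AnovaRM
            res = AnovaRM(prod, depvar="words_mean", subject="subject",
                          within=["task", "session"]).fit()
            words_anova = res.anova_table

    return BehaviouralSummary(per_subject=per_subject, summary=summary,
                              session_tests=session_tests,
                              words_anova=words_anova)
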