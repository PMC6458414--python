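"""Stability and heterogeneity checks around the winning covariance model.

Leave-one-out refits of the one-factor and bifactor models, Thomson
(regression-method) factor scores from the bifactor fit, Cook's-distance
bivariate outliers in the factor-score plane, and battery refits after
excluding flagged subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import LateralityTable
from .sem import (BatteryResult, SemFitResult, SemModelSpec, _Layout,
                  embed_start, fit, fit_battery)


@dataclass
class FactorScores:
    """Per-subject factor scores with outlier annotations."""

    scores: pd.DataFrame          # columns F1 (+ F2), index subject
    handedness: pd.Series
    cooks_distance: pd.Series | None = None
    outlier: pd.Series | None = None

    def frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["handedness"] = self.handedness
        if self.cooks_distance is not None:
            out["cooks_distance"] = self.cooks_distance
            out["outlier"] = self.outlier
        return out


def factor_scores(fit_result: SemFitResult,
                  table: LateralityTable) -> FactorScores:
    """Regression-method (Thomson) factor scores from a factor-model fit.

    Scores are ``Phi Lambda' Sigma_oo^{-1} (y_o - mu_o)`` using the
    model-implied covariance, restricted per subject to that subject's
    observed cells.  A subject exactly at the fitted means with complete data
    scores zero on every factor; a subject with no observed cells gets
    missing scores.
    """
    if not fit_result.converged:
        raise ValueError("refusing to score a non-converged fit")
    if fit_result.loadings is None:
        raise ValueError("fit has no latent factors to score")
    layout = _Layout(fit_result.spec, list(table.li.columns))
    lam_task = fit_result.loadings
    lam = np.array([[lam_task.loc[layout.tasks[i], col]
                     for col in lam_task.columns]
                    for i in layout.task_of_cond])   # k x n_factors
    phi = np.diag(fit_result.factor_variances)
    mu, sigma = fit_result.mu, fit_result.sigma
    y = table.li.to_numpy(float)

    nf = lam.shape[1]
    out = np.full((len(y), nf), np.nan)
    for j in range(len(y)):
        obs = np.isfinite(y[j])
        if not obs.any():
            continue
        sub = sigma[np.ix_(obs, obs)]
        resid = y[j, obs] - mu[obs]
        out[j] = phi @ lam[obs].T @ np.linalg.solve(sub, resid)
    cols = list(lam_task.columns)
    scores = pd.DataFrame(out, index=table.li.index, columns=cols)
    return FactorScores(scores=scores,
                        handedness=table.subjects["handedness"])


def bivariate_outliers(scores: FactorScores,
                       threshold: float | None = None) -> FactorScores:
    """Flag influential subjects by Cook's distance in the score plane.

    Distances come from the simple regression of F2 on F1; the default
    threshold is 4/n.  Requires at least five scored subjects and a
    non-degenerate regression.
    """
    df = scores.scores.dropna()
    if len(df) < 5:
        raise ValueError("need at least 5 scored subjects")
    if "F2" not in df.columns:
        raise ValueError("bifactor scores (F1, F2) required")
    if np.ptp(df["F1"].to_numpy()) == 0:
        raise ValueError("degenerate regression: F1 scores are constant")
    model = sm.OLS(df["F2"], sm.add_constant(df["F1"])).fit()
    cooks = pd.Series(model.get_influence().cooks_distance[0], index=df.index)
    thr = 4.0 / len(df) if threshold is None else threshold
    cooks = cooks.reindex(scores.scores.index)
    scores.cooks_distance = cooks
    scores.outlier = cooks > thr
    return scores


def leave_one_out(table: LateralityTable, anchor_task: str = "D",
                  starts: int = 4, seed: int = 42) -> pd.DataFrame:
    """Refit the one-factor and bifactor models once per omitted subject.

    Reports, per run, the BIC winner and the largest drift of any loading
    relative to the full-sample bifactor fit.  Runs with a non-converged
    refit are flagged.
    """
    if table.n_subjects < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    from .sem import CovStructure, MeanStructure

    per_task = MeanStructure(groups={t: t for t in table.tasks})
    one_spec = SemModelSpec("Person Effect", per_task,
                            CovStructure("one_factor", anchor_task))
    two_spec = SemModelSpec("Task x Person Effect", per_task,
                            CovStructure("bifactor", anchor_task))

    full_two = _fit_pair(one_spec, two_spec, table, starts, seed)[1]
    rows = []
    for subj in table.li.index:
        sub = table.copy()
        sub.li = sub.li.drop(index=subj)
        sub.se = None if sub.se is None else sub.se.drop(index=subj)
        sub.subjects = sub.subjects.drop(index=subj)
        f1, f2 = _fit_pair(one_spec, two_spec, sub, starts, seed)
        drift = np.nan
        if f2.loadings is not None and full_two.loadings is not None:
            drift = float((f2.loadings - full_two.loadings).abs().to_numpy().max())
        rows.append({
            "omitted": subj,
            "one_factor_bic": f1.bic, "bifactor_bic": f2.bic,
            "winner": ("bifactor" if f2.bic < f1.bic else "one_factor"),
            "max_loading_drift": drift,
            "converged": bool(f1.converged and f2.converged),
        })
    return pd.DataFrame(rows).set_index("omitted")


def _fit_pair(one_spec: SemModelSpec, two_spec: SemModelSpec,
              table: LateralityTable, starts: int,
              seed: int) -> tuple[SemFitResult, SemFitResult]:
    f1 = fit(one_spec, table, starts=starts, seed=seed)
    warm = embed_start(two_spec, f1, table.conditions)
    f2 = fit(two_spec, table, starts=starts, seed=seed, extra_starts=[warm])
    return f1, f2


def refit_excluding(table: LateralityTable, excluded_subjects: list[str],
                    anchor_task: str = "D", starts: int = 10,
                    seed: int = 42) -> BatteryResult:
    """Re-run the full battery with the given subjects removed."""
    keep = [s for s in table.li.index if s not in set(excluded_subjects)]
    if len(keep) < 3:
        raise ValueError("fewer than 3 subjects left after exclusion")
    sub = table.copy()
    sub.li = sub.li.loc[keep]
    sub.se = None if sub.se is None else sub.se.loc[keep]
    sub.subjects = sub.subjects.loc[keep]
    return fit_battery(sub, anchor_task=anchor_task, starts=starts, seed=seed)
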