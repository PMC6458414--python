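"""Structured mean/covariance models for the LI table, fit by FIML.

The battery of seven canonical models operates on the 12-variable
(6 tasks x 2 sessions) laterality table:

======================  =========================================  =======
model                   structure                                  params
======================  =========================================  =======
Fully Saturated         free means and variances, no covariances      24
Task Effect             means/variances tied across sessions          12
Population Bias         one mean, one variance                         2
Dorsal Stream           mean groups {A,B}, {C}, {D,E,F}                6
Lexical Retrieval       mean groups {B,D}, {A,C,F}, {E}                6
Person Effect           one common factor over all 12 variables       18
Task x Person Effect    bifactor (two uncorrelated factors)           23
======================  =========================================  =======

All factor models tie loadings, means and residual variances across the two
sessions of a task.  The one-factor model fixes the anchor task's loading to
1 and frees the factor variance; the bifactor model additionally frees five
Factor-2 loadings (anchor fixed to 0), fixes the Factor-2 variance to 1 and
the inter-factor covariance to 0.  Sentence Generation (task D) is the
default anchor.

Estimation is full-information maximum likelihood: each subject contributes
the multivariate-normal -2 log density restricted to that subject's observed
cells (including the k*ln(2*pi) constant), so missing cells are handled
without imputation.  Degrees of freedom are counted as the total number of
observed values minus the number of free parameters, and
``BIC = -2logL - df * ln(N_subjects)``.  CFI and RMSEA reference a fully
saturated mean+covariance model and the no-covariance (independence) model:

    chi2_m = dev_m - dev_sat,      df_m = params_sat - params_m
    CFI    = 1 - max(chi2_m - df_m, 0) / max(chi2_0 - df_0, 0)
    RMSEA  = sqrt(max(chi2_m - df_m, 0) / (df_m * (N - 1)))

Nested models are compared by chi-square tests on the deviance difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .dataset import LateralityTable, condition_task
from .synthetic import GenerativeParams, simulate_li_dataset

logger = logging.getLogger(__name__)

_LN_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanStructure:
    """Task -> group label; variances are grouped identically to means.

    With ``by_session=True`` every task-session condition gets its own group
    (the Fully Saturated case); otherwise the two sessions of a task always
    share a group.
    """

    groups: Mapping[str, str] | None = None
    by_session: bool = False


@dataclass(frozen=True)
class CovStructure:
    """Covariance family: diagonal, one_factor, bifactor or unstructured."""

    kind: str = "diagonal"
    anchor_task: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("diagonal", "one_factor", "bifactor", "unstructured"):
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        if self.kind in ("one_factor", "bifactor") and self.anchor_task is None:
            raise ValueError("factor models need an anchor task")


@dataclass(frozen=True)
class SemModelSpec:
    name: str
    mean_structure: MeanStructure
    cov_structure: CovStructure

    def n_free_params(self, conditions: Sequence[str]) -> int:
        return len(_Layout(self, list(conditions)).names)


class _Layout:
    """Maps a spec + condition list to a flat parameter vector.

    Order: group means, group log-variances, then (factor models) free
    Factor-1 loadings, log factor-1 variance, free Factor-2 loadings; or
    (unstructured) log Cholesky diagonal followed by sub-diagonal entries.
    Variances are optimized on the log scale, loadings unconstrained.
    """

    def __init__(self, spec: SemModelSpec, conditions: list[str]):
        self.spec = spec
        self.conditions = conditions
        self.k = len(conditions)
        tasks: list[str] = []
        for c in conditions:
            t = condition_task(c)
            if t not in tasks:
                tasks.append(t)
        self.tasks = tasks

        ms = spec.mean_structure
        if ms.by_session:
            labels = conditions
        else:
            groups = ms.groups or {t: t for t in tasks}
            labels = [groups[condition_task(c)] for c in conditions]
        self.group_labels: list[str] = []
        for lab in labels:
            if lab not in self.group_labels:
                self.group_labels.append(lab)
        # condition index -> group index
        self.group_of = np.array([self.group_labels.index(lab) for lab in labels])
        self.n_groups = len(self.group_labels)

        kind = spec.cov_structure.kind
        self.kind = kind
        self.anchor = spec.cov_structure.anchor_task
        if kind in ("one_factor", "bifactor"):
            if self.anchor not in tasks:
                raise ValueError(f"anchor task {self.anchor!r} not in table")
            self.free_tasks = [t for t in tasks if t != self.anchor]
            self.task_of_cond = np.array(
                [tasks.index(condition_task(c)) for c in conditions])
            free_index = {t: j for j, t in enumerate(self.free_tasks)}
            self._free_idx = np.array(
                [free_index.get(tasks[i], -1) for i in self.task_of_cond])
            self._is_free = self._free_idx >= 0

        names = [f"mean[{g}]" for g in self.group_labels]
        if kind != "unstructured":
            names += [f"logvar[{g}]" for g in self.group_labels]
        if kind == "one_factor":
            names += [f"lambda1[{t}]" for t in self.free_tasks]
            names += ["log_phi1"]
        elif kind == "bifactor":
            names += [f"lambda1[{t}]" for t in self.free_tasks]
            names += ["log_phi1"]
            names += [f"lambda2[{t}]" for t in self.free_tasks]
        elif kind == "unstructured":
            names += [f"chol_diag[{c}]" for c in conditions]
            names += [f"chol_offdiag[{i}]" for i in range(self.k * (self.k - 1) // 2)]
        self.names = names
        self._tril = np.tril_indices(self.k, -1)

    # -- packing -----------------------------------------------------------
    def pack(self, mean_vals: np.ndarray, var_vals: np.ndarray,
             lam1: np.ndarray | None = None, phi1: float | None = None,
             lam2: np.ndarray | None = None,
             chol: np.ndarray | None = None) -> np.ndarray:
        parts = [np.asarray(mean_vals, float), np.log(np.asarray(var_vals, float))]
        if self.kind == "one_factor":
            parts += [np.asarray(lam1, float), [np.log(phi1)]]
        elif self.kind == "bifactor":
            parts += [np.asarray(lam1, float), [np.log(phi1)],
                      np.asarray(lam2, float)]
        elif self.kind == "unstructured":
            parts = [np.asarray(mean_vals, float),
                     np.log(np.diag(chol)), chol[self._tril]]
        return np.concatenate([np.atleast_1d(p) for p in parts])

    # -- unpacking ---------------------------------------------------------
    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = self.n_groups
        mu = np.asarray(theta[:g])[self.group_of]
        if self.kind == "unstructured":
            L = np.zeros((self.k, self.k))
            np.fill_diagonal(L, np.exp(theta[g:g + self.k]))
            L[self._tril] = theta[g + self.k:]
            return mu, L @ L.T
        var = np.exp(np.asarray(theta[g:2 * g]))[self.group_of]
        sigma = np.diag(var)
        if self.kind in ("one_factor", "bifactor"):
            pos = 2 * g
            nf = len(self.free_tasks)
            lam1 = np.ones(self.k)
            lam1[self._is_free] = np.asarray(
                theta[pos:pos + nf])[self._free_idx[self._is_free]]
            phi1 = np.exp(theta[pos + nf])
            sigma = sigma + phi1 * np.outer(lam1, lam1)
            if self.kind == "bifactor":
                lam2 = np.zeros(self.k)
                lam2[self._is_free] = np.asarray(
                    theta[pos + nf + 1:pos + 2 * nf + 1])[self._free_idx[self._is_free]]
                sigma = sigma + np.outer(lam2, lam2)  # factor-2 variance fixed to 1
        return mu, sigma

    def loadings_frame(self, theta: np.ndarray) -> pd.DataFrame | None:
        if self.kind not in ("one_factor", "bifactor"):
            return None
        g = self.n_groups
        nf = len(self.free_tasks)
        lam1 = {self.anchor: 1.0}
        lam1.update(zip(self.free_tasks, theta[2 * g:2 * g + nf]))
        data = {"F1": [lam1[t] for t in self.tasks]}
        if self.kind == "bifactor":
            lam2 = {self.anchor: 0.0}
            lam2.update(zip(self.free_tasks, theta[2 * g + nf + 1:]))
            data["F2"] = [lam2[t] for t in self.tasks]
        return pd.DataFrame(data, index=self.tasks)


def build_battery(anchor_task: str = "D",
                  tasks: Sequence[str] = ("A", "B", "C", "D", "E", "F")
                  ) -> list[SemModelSpec]:
    """The seven canonical model specifications, in reporting order.

    Dorsal Stream groups tasks by dorsal ({A,B}), ventral ({C}) and mixed
    ({D,E,F}) stream involvement; Lexical Retrieval by lexical-retrieval
    demand ({B,D} vs {A,C,F}) with Sentence Comprehension (E) left
    independent.  The subset models impose equality within subsets only — the
    predicted orderings are descriptive, not inequality constraints.
    """
    if anchor_task not in tasks:
        raise ValueError(f"unknown anchor task {anchor_task!r}")
    free = MeanStructure(by_session=True)
    per_task = MeanStructure(groups={t: t for t in tasks})
    pooled = MeanStructure(groups={t: "all" for t in tasks})
    dorsal = MeanStructure(groups={"A": "X", "B": "X", "C": "Z",
                                   "D": "Y", "E": "Y", "F": "Y"})
    lexical = MeanStructure(groups={"B": "X", "D": "X",
                                    "A": "Y", "C": "Y", "F": "Y", "E": "E"})
    diag = CovStructure("diagonal")
    return [
        SemModelSpec("Fully Saturated", free, diag),
        SemModelSpec("Task Effect", per_task, diag),
        SemModelSpec("Population Bias", pooled, diag),
        SemModelSpec("Dorsal Stream", dorsal, diag),
        SemModelSpec("Lexical Retrieval", lexical, diag),
        SemModelSpec("Person Effect", per_task,
                     CovStructure("one_factor", anchor_task)),
        SemModelSpec("Task x Person Effect", per_task,
                     CovStructure("bifactor", anchor_task)),
    ]


def saturated_full_spec() -> SemModelSpec:
    """Free means + unstructured covariance; the chi-square reference model."""
    return SemModelSpec("Saturated (full covariance)",
                        MeanStructure(by_session=True),
                        CovStructure("unstructured"))


# ---------------------------------------------------------------------------
# FIML deviance
# ---------------------------------------------------------------------------

class _PatternGroups:
    """Rows of a data matrix grouped by missingness pattern (computed once)."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        missing = np.isnan(y)
        patterns, inverse = np.unique(missing, axis=0, return_inverse=True)
        self.groups: list[tuple[np.ndarray, np.ndarray]] = []
        for p_idx in range(len(patterns)):
            obs = ~patterns[p_idx]
            if not obs.any():
                continue
            rows = y[inverse == p_idx][:, obs]
            self.groups.append((obs, np.ascontiguousarray(rows)))

    def deviance(self, mu: np.ndarray, sigma: np.ndarray) -> float:
        total = 0.0
        for obs, rows in self.groups:
            k = rows.shape[1]
            sub = sigma[np.ix_(obs, obs)]
            try:
                chol = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return np.inf
            logdet = 2.0 * float(np.log(np.diag(chol)).sum())
            z = solve_triangular(chol, (rows - mu[obs]).T, lower=True,
                                 check_finite=False)
            total += len(rows) * (k * _LN_2PI + logdet) + float((z * z).sum())
        return total


def mvn_missing_deviance(mu: np.ndarray, sigma: np.ndarray,
                         y: np.ndarray) -> float:
    """-2 log likelihood of rows of ``y`` (NaN = missing) under N(mu, sigma).

    Rows are grouped by missingness pattern; each row contributes the
    multivariate-normal -2 log density restricted to its observed cells,
    including the k*ln(2*pi) constant.  Returns +inf when the restricted
    covariance is not positive definite (optimizer penalty contract).
    """
    return _PatternGroups(y).deviance(np.asarray(mu, float),
                                      np.asarray(sigma, float))


def fiml_minus2logL(spec: SemModelSpec, params: np.ndarray,
                    table: LateralityTable) -> float:
    """Deviance of a model spec at a parameter vector on an LI table."""
    layout = _Layout(spec, list(table.li.columns))
    mu, sigma = layout.implied(np.asarray(params, float))
    return mvn_missing_deviance(mu, sigma, table.li.to_numpy(float))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class SemFitResult:
    spec: SemModelSpec
    theta: np.ndarray
    param_names: list[str]
    minus2logL: float
    n_observed_values: int
    n_free_params: int
    df: int
    bic: float
    n_subjects: int
    converged: bool
    mu: np.ndarray
    sigma: np.ndarray
    means: pd.Series
    variances: pd.Series
    loadings: pd.DataFrame | None
    factor_variances: tuple[float, ...] | None
    loading_se: pd.DataFrame | None = None

    @property
    def name(self) -> str:
        return self.spec.name

    def loading_ci(self, level: float = 0.95) -> pd.DataFrame | None:
        """Wald confidence intervals for the factor loadings."""
        if self.loadings is None or self.loading_se is None:
            return None
        z = stats.norm.ppf(0.5 + level / 2)
        lo = self.loadings - z * self.loading_se
        hi = self.loadings + z * self.loading_se
        out = {}
        for col in self.loadings.columns:
            out[(col, "estimate")] = self.loadings[col]
            out[(col, "lo")] = lo[col]
            out[(col, "hi")] = hi[col]
        return pd.DataFrame(out)


def _moment_estimates(table: LateralityTable) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete sample mean vector and covariance matrix."""
    mu = table.li.mean(skipna=True).to_numpy(float)
    mu = np.where(np.isfinite(mu), mu, np.nanmean(mu))
    cov = table.li.cov(min_periods=2).to_numpy(float)
    bad = ~np.isfinite(cov)
    cov[bad] = 0.0
    d = np.diag(cov).copy()
    d[d <= 0] = max(np.nanmean(d[d > 0]) if (d > 0).any() else 1.0, 1e-3)
    np.fill_diagonal(cov, d)
    return mu, cov


def _start_from_moments(layout: _Layout, mu_hat: np.ndarray,
                        cov_hat: np.ndarray) -> np.ndarray:
    """Data-driven starting values obtained from sample moments."""
    g = layout.n_groups
    means = np.array([mu_hat[layout.group_of == i].mean() for i in range(g)])
    diag = np.diag(cov_hat)
    var = np.array([diag[layout.group_of == i].mean() for i in range(g)])
    var = np.clip(var, 1e-4, None)
    if layout.kind == "diagonal":
        return layout.pack(means, var)
    if layout.kind == "unstructured":
        sig = cov_hat.copy()
        for _ in range(20):
            try:
                chol = np.linalg.cholesky(sig)
                break
            except np.linalg.LinAlgError:
                sig = sig + 0.05 * np.mean(np.diag(sig)) * np.eye(len(sig))
        else:  # pragma: no cover - pathological input
            chol = np.diag(np.sqrt(np.clip(np.diag(sig), 1e-4, None)))
        return layout.pack(means, var, chol=chol)

    # factor models: anchor the scale on the anchor task's cross-session cov
    anchor_idx = [i for i, c in enumerate(layout.conditions)
                  if condition_task(c) == layout.anchor]
    if len(anchor_idx) == 2:
        phi1 = cov_hat[anchor_idx[0], anchor_idx[1]]
    else:
        phi1 = 0.0
    mean_var = float(np.mean(diag))
    phi1 = float(np.clip(phi1, 0.1 * mean_var, None))
    lam1 = []
    for t in layout.free_tasks:
        t_idx = [i for i, c in enumerate(layout.conditions)
                 if condition_task(c) == t]
        cross = cov_hat[np.ix_(t_idx, anchor_idx)]
        lam1.append(float(np.mean(cross)) / phi1)
    lam1 = np.clip(np.asarray(lam1), -3.0, 3.0)
    resid = np.clip(var - phi1 * np.array(
        [np.mean([(1.0 if layout.tasks[i] == layout.anchor else
                   lam1[layout.free_tasks.index(layout.tasks[i])]) ** 2
                  for i in layout.task_of_cond[layout.group_of == gi]])
         for gi in range(g)]), 0.05 * var, None)
    if layout.kind == "one_factor":
        return layout.pack(means, resid, lam1=lam1, phi1=phi1)
    lam2 = np.full(len(layout.free_tasks), 0.1)
    return layout.pack(means, resid, lam1=lam1, phi1=phi1, lam2=lam2)


def embed_start(to_spec: SemModelSpec, from_fit: "SemFitResult",
                conditions: Sequence[str]) -> np.ndarray:
    """Parameter vector for ``to_spec`` reproducing a nested fit's optimum.

    Used to warm-start a more general model at (essentially) the restricted
    model's solution, which guarantees the deviance nesting chain up to
    optimizer tolerance.
    """
    layout = _Layout(to_spec, list(conditions))
    g = layout.n_groups
    mu, sigma = from_fit.mu, from_fit.sigma
    means = np.array([mu[layout.group_of == i].mean() for i in range(g)])
    diag_from = np.diag(sigma)

    if layout.kind == "unstructured":
        sig = sigma.copy()
        for _ in range(20):
            try:
                chol = np.linalg.cholesky(sig)
                break
            except np.linalg.LinAlgError:
                sig = sig + 1e-8 * np.mean(np.diag(sig)) * np.eye(len(sig))
        var = np.array([diag_from[layout.group_of == i].mean() for i in range(g)])
        return layout.pack(means, np.clip(var, 1e-8, None), chol=chol)

    from_kind = from_fit.spec.cov_structure.kind
    if layout.kind == "diagonal":
        var = np.array([diag_from[layout.group_of == i].mean() for i in range(g)])
        return layout.pack(means, np.clip(var, 1e-8, None))

    nf = len(layout.free_tasks)
    if from_kind == "diagonal":
        # factor contributes nothing: zero free loadings, tiny factor variance
        resid = np.array([diag_from[layout.group_of == i].mean() for i in range(g)])
        lam1 = np.zeros(nf)
        phi1 = 1e-8
        if layout.kind == "one_factor":
            return layout.pack(means, resid, lam1=lam1, phi1=phi1)
        return layout.pack(means, resid, lam1=lam1, phi1=phi1,
                           lam2=np.zeros(nf))
    if from_kind == "one_factor" and layout.kind == "bifactor":
        from_layout = _Layout(from_fit.spec, list(conditions))
        fg = from_layout.n_groups
        resid = np.exp(from_fit.theta[fg:2 * fg])
        lam1 = from_fit.theta[2 * fg:2 * fg + nf]
        phi1 = float(np.exp(from_fit.theta[2 * fg + nf]))
        return layout.pack(means, resid, lam1=lam1, phi1=phi1,
                           lam2=np.zeros(nf))
    raise ValueError(
        f"no embedding from {from_kind!r} into {layout.kind!r}")


def fit(spec: SemModelSpec, table: LateralityTable, starts: int = 10,
        seed: int = 42, extra_starts: Sequence[np.ndarray] = (),
        compute_se: bool = False) -> SemFitResult:
    """Multi-start quasi-Newton FIML fit of one model spec.

    The first start is data-driven (sample moments); further starts perturb
    it with seeded Gaussian noise; callers may supply additional warm starts
    (e.g. embedded nested solutions).  Deterministic given the seed.
    """
    if table.n_subjects == 0:
        raise ValueError("empty laterality table")
    conditions = list(table.li.columns)
    layout = _Layout(spec, conditions)
    y = table.li.to_numpy(float)
    n_obs = int(np.isfinite(y).sum())
    n_subjects = int((np.isfinite(y).any(axis=1)).sum())
    if n_obs == 0:
        raise ValueError("table has no observed values")

    groups = _PatternGroups(y)

    def objective(theta: np.ndarray) -> float:
        mu, sigma = layout.implied(theta)
        dev = groups.deviance(mu, sigma)
        return dev if np.isfinite(dev) else 1e12

    rng = np.random.default_rng(seed)
    mu_hat, cov_hat = _moment_estimates(table)
    theta0 = _start_from_moments(layout, mu_hat, cov_hat)
    start_list = [theta0] + [np.asarray(s, float) for s in extra_starts]
    while len(start_list) < max(starts, 1) + len(extra_starts):
        start_list.append(theta0 + rng.normal(0.0, 0.3, size=theta0.shape))

    best = None
    any_success = False
    for th in start_list:
        res = optimize.minimize(objective, th, method="L-BFGS-B",
                                options={"maxiter": 5000, "maxfun": 100000,
                                         "ftol": 1e-13, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or bool(res.success)

    theta = np.asarray(best.x, float)
    dev = float(best.fun)
    converged = bool(np.isfinite(dev) and dev < 1e11 and any_success)
    mu, sigma = layout.implied(theta)
    n_free = len(layout.names)
    df = n_obs - n_free
    bic = dev - df * np.log(n_subjects)

    g = layout.n_groups
    means = pd.Series(mu, index=conditions, name="mean")
    variances = pd.Series(
        np.diag(sigma) if layout.kind == "unstructured"
        else np.exp(theta[g:2 * g])[layout.group_of],
        index=conditions, name="residual_variance")
    loadings = layout.loadings_frame(theta)
    factor_vars = None
    if layout.kind == "one_factor":
        factor_vars = (float(np.exp(theta[2 * g + len(layout.free_tasks)])),)
    elif layout.kind == "bifactor":
        factor_vars = (float(np.exp(theta[2 * g + len(layout.free_tasks)])), 1.0)

    result = SemFitResult(
        spec=spec, theta=theta, param_names=list(layout.names),
        minus2logL=dev, n_observed_values=n_obs, n_free_params=n_free,
        df=df, bic=float(bic), n_subjects=n_subjects, converged=converged,
        mu=mu, sigma=sigma, means=means, variances=variances,
        loadings=loadings, factor_variances=factor_vars)
    if compute_se and loadings is not None:
        result.loading_se = _loading_se(layout, objective, theta)
    return result


def _loading_se(layout: _Layout, objective, theta: np.ndarray,
                step: float = 1e-4) -> pd.DataFrame | None:
    """Wald standard errors from the observed information (central differences)."""
    p = len(theta)
    hess = np.zeros((p, p))
    f = lambda th: 0.5 * objective(th)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = step
            ej = np.zeros(p); ej[j] = step
            val = (f(theta + ei + ej) - f(theta + ei - ej)
                   - f(theta - ei + ej) + f(theta - ei - ej)) / (4 * step * step)
            hess[i, j] = hess[j, i] = val
    try:
        cov = np.linalg.pinv(hess)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    g = layout.n_groups
    nf = len(layout.free_tasks)
    se1 = dict(zip(layout.free_tasks, se[2 * g:2 * g + nf]))
    se1[layout.anchor] = 0.0
    data = {"F1": [se1[t] for t in layout.tasks]}
    if layout.kind == "bifactor":
        se2 = dict(zip(layout.free_tasks, se[2 * g + nf + 1:2 * g + 2 * nf + 1]))
        se2[layout.anchor] = 0.0
        data["F2"] = [se2[t] for t in layout.tasks]
    return pd.DataFrame(data, index=layout.tasks)


# ---------------------------------------------------------------------------
# Fit indices and model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitIndices:
    bic: float
    cfi: float
    rmsea: float
    chi2: float
    chi2_df: int


def fit_indices(fit_result: SemFitResult, saturated_full: SemFitResult,
                independence: SemFitResult,
                n_subjects: int | None = None) -> FitIndices:
    """BIC, CFI and RMSEA for one fitted model.

    ``saturated_full`` is the free-means + unstructured-covariance reference;
    ``independence`` is the free-means + free-variances, zero-covariance
    model.  A model with zero chi-square degrees of freedom gets CFI 1 and
    RMSEA 0 by convention.
    """
    n = n_subjects if n_subjects is not None else fit_result.n_subjects
    chi2_m = fit_result.minus2logL - saturated_full.minus2logL
    df_m = fit_result.df - saturated_full.df
    chi2_0 = independence.minus2logL - saturated_full.minus2logL
    df_0 = independence.df - saturated_full.df
    if df_m <= 0:
        return FitIndices(bic=fit_result.bic, cfi=1.0, rmsea=0.0,
                          chi2=float(chi2_m), chi2_df=int(df_m))
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_0 - df_0, 0.0)
    cfi = 1.0 if den == 0 else float(np.clip(1.0 - num / den, 0.0, 1.0))
    rmsea = float(np.sqrt(num / (df_m * (n - 1))))
    return FitIndices(bic=fit_result.bic, cfi=cfi, rmsea=rmsea,
                      chi2=float(chi2_m), chi2_df=int(df_m))


@dataclass(frozen=True)
class ComparisonResult:
    restricted: str
    general: str
    delta_minus2logL: float
    delta_df: int
    p: float


def lrt(restricted: SemFitResult, general: SemFitResult,
        tol: float = 1e-3) -> ComparisonResult:
    """Chi-square likelihood-ratio test of two nested fits.

    A deviance difference more negative than ``-tol`` signals optimizer
    failure and raises.
    """
    if not (restricted.converged and general.converged):
        raise ValueError("refusing to compare non-converged fits")
    delta = restricted.minus2logL - general.minus2logL
    if delta < -tol:
        raise ValueError(
            f"restricted model fits better by {-delta:.4g}; optimizer failure?")
    delta = max(delta, 0.0)
    ddf = restricted.df - general.df
    if ddf <= 0:
        p = 1.0 if delta <= tol else 0.0
    else:
        p = float(stats.chi2.sf(delta, ddf))
    return ComparisonResult(restricted=restricted.name, general=general.name,
                            delta_minus2logL=float(delta), delta_df=int(ddf),
                            p=p)


# ---------------------------------------------------------------------------
# Battery driver
# ---------------------------------------------------------------------------

# (restricted, general, row model): each canonical comparison is
# attributed to the model it newly introduces; the other is its baseline.
_CANONICAL_COMPARISONS = [
    ("Task Effect", "Fully Saturated", "Task Effect"),
    ("Population Bias", "Task Effect", "Population Bias"),
    ("Dorsal Stream", "Task Effect", "Dorsal Stream"),
    ("Lexical Retrieval", "Task Effect", "Lexical Retrieval"),
    ("Task Effect", "Person Effect", "Person Effect"),
    ("Person Effect", "Task x Person Effect", "Task x Person Effect"),
]


@dataclass
class BatteryResult:
    fits: dict[str, SemFitResult]
    saturated_full: SemFitResult
    indices: dict[str, FitIndices]
    comparisons: list[ComparisonResult]

    def summary(self) -> pd.DataFrame:
        rows = []
        comp = {}
        for (r, g, row_model), c in zip(_CANONICAL_COMPARISONS, self.comparisons):
            other = g if row_model == r else r
            comp[row_model] = (c, other)
        for name, f in self.fits.items():
            idx = self.indices[name]
            c, other = comp.get(name, (None, ""))
            rows.append({
                "model": name, "minus2logL": f.minus2logL, "df": f.df,
                "n_free_params": f.n_free_params, "BIC": f.bic,
                "CFI": idx.cfi, "RMSEA": idx.rmsea,
                "compared_to": other,
                "p": c.p if c else np.nan,
                "converged": f.converged,
            })
        return pd.DataFrame(rows).set_index("model")

    def to_dict(self) -> dict:
        out = {"models": {}, "comparisons": []}
        for name, f in self.fits.items():
            idx = self.indices[name]
            entry = {
                "minus2logL": f.minus2logL, "df": f.df, "BIC": f.bic,
                "CFI": idx.cfi, "RMSEA": idx.rmsea,
                "n_free_params": f.n_free_params, "converged": f.converged,
                "means": f.means.to_dict(),
            }
            if f.loadings is not None:
                entry["loadings"] = f.loadings.to_dict()
                ci = f.loading_ci()
                if ci is not None:
                    entry["loading_ci95"] = {
                        f"{a}.{b}": ci[(a, b)].to_dict() for a, b in ci.columns}
            out["models"][name] = entry
        for c in self.comparisons:
            out["comparisons"].append(
                {"restricted": c.restricted, "general": c.general,
                 "delta_minus2logL": c.delta_minus2logL,
                 "delta_df": c.delta_df, "p": c.p})
        return out


def fit_battery(table: LateralityTable, anchor_task: str = "D",
                starts: int = 10, seed: int = 42,
                compute_se: bool = False) -> BatteryResult:
    """Fit the full seven-model battery plus the saturated reference.

    Models are fitted restricted-first, and each more general model receives
    the embedded solutions of its nested predecessors as warm starts, so the
    deviance nesting chain holds up to optimizer tolerance.
    """
    specs = {s.name: s for s in build_battery(anchor_task,
                                              tuple(table.tasks))}
    conditions = table.conditions
    fits: dict[str, SemFitResult] = {}

    def run(name: str, embed_from: Sequence[str] = (), **kw) -> SemFitResult:
        extra = [embed_start(specs.get(name) or saturated_full_spec(),
                             fits[src], conditions) for src in embed_from]
        spec = specs.get(name) or saturated_full_spec()
        res = fit(spec, table, starts=starts, seed=seed, extra_starts=extra,
                  **kw)
        fits[name] = res
        return res

    run("Population Bias")
    run("Dorsal Stream", embed_from=["Population Bias"])
    run("Lexical Retrieval", embed_from=["Population Bias"])
    run("Task Effect", embed_from=["Dorsal Stream", "Lexical Retrieval"])
    run("Fully Saturated", embed_from=["Task Effect"])
    run("Person Effect", embed_from=["Task Effect"],
        compute_se=compute_se)
    run("Task x Person Effect", embed_from=["Person Effect"],
        compute_se=compute_se)

    sat_spec = saturated_full_spec()
    sat_extra = [embed_start(sat_spec, fits[n], conditions)
                 for n in ("Fully Saturated", "Task x Person Effect")]
    saturated_full = fit(sat_spec, table, starts=starts, seed=seed,
                         extra_starts=sat_extra)

    independence = fits["Fully Saturated"]
    indices = {name: fit_indices(f, saturated_full, independence)
               for name, f in fits.items()}
    comparisons = [lrt(fits[r], fits[g]) for r, g, _ in _CANONICAL_COMPARISONS]
    battery_order = [s.name for s in build_battery(anchor_task,
                                                   tuple(table.tasks))]
    fits = {name: fits[name] for name in battery_order}
    return BatteryResult(fits=fits, saturated_full=saturated_full,
                         indices=indices, comparisons=comparisons)


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------

def default_power_truths() -> tuple[GenerativeParams, GenerativeParams]:
    """(one-factor truth, two-factor truth) for factor-structure power runs.

    The one-factor truth has stable person effects with test-retest
    reliability around 0.64; the two-factor truth adds a well-separated
    second factor loading on the comprehension/syntactic tasks (E, F) with
    the anchor task D kept clean for identification.
    """
    one = GenerativeParams.person_effect(sd_person=0.8, sd_error=0.6)
    two = GenerativeParams.task_by_person(
        sd_person=0.8, sd_interaction=0.8, sd_error=0.6,
        interaction_structure={"E": 1.0, "F": 1.0})
    return one, two


def power_simulation(n_grid: Sequence[int],
                     truths: "dict[str, GenerativeParams] | tuple | None" = None,
                     reps: int = 100, seed: int = 42, alpha: float = 0.05,
                     anchor_task: str = "D", starts: int = 2) -> pd.DataFrame:
    """Rate of preferring the bifactor model under each generative truth.

    For every sample size in ``n_grid`` and each truth (by default the
    one-factor and two-factor configurations of
    :func:`default_power_truths`; a ``{name: params}`` mapping restricts or
    renames the arms), ``reps`` datasets of six tasks by two sessions are
    drawn; the one-factor and bifactor models are fitted to each and the
    bifactor model is scored as preferred by the likelihood-ratio test at
    ``alpha`` and by BIC.  Under the one-factor truth the LRT column
    estimates the type-I error rate; the chi-square reference is asymptotic,
    so calibration should be read at large n (at small n the test
    over-rejects slightly).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if truths is None:
        truths = default_power_truths()
    if not isinstance(truths, dict):
        truths = dict(zip(("one_factor", "two_factor"), truths))
    tasks = next(iter(truths.values())).tasks
    one_spec = SemModelSpec("Person Effect",
                            MeanStructure(groups={t: t for t in tasks}),
                            CovStructure("one_factor", anchor_task))
    two_spec = SemModelSpec("Task x Person Effect",
                            MeanStructure(groups={t: t for t in tasks}),
                            CovStructure("bifactor", anchor_task))
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        for truth_name, gen in truths.items():
            lrt_hits = 0
            bic_hits = 0
            used = 0
            for _ in range(reps):
                data_seed = int(rng.integers(0, 2**31 - 1))
                ds = simulate_li_dataset(gen, n, seed=data_seed)
                f1 = fit(one_spec, ds.table, starts=starts, seed=data_seed)
                warm = embed_start(two_spec, f1, ds.table.conditions)
                f2 = fit(two_spec, ds.table, starts=starts, seed=data_seed,
                         extra_starts=[warm])
                if not (f1.converged and f2.converged):
                    continue
                used += 1
                comp = lrt(f1, f2)
                lrt_hits += comp.p < alpha
                bic_hits += f2.bic < f1.bic
            rows.append({"n": n, "truth": truth_name, "reps": used,
                         "lrt_bifactor_rate": lrt_hits / max(used, 1),
                         "bic_bifactor_rate": bic_hits / max(used, 1)})
    return pd.DataFrame(rows)
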