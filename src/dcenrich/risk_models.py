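"""Outcome models and contingency-table tests.

Logistic fits (used downstream for reclassification statistics) are
estimated by iteratively reweighted least squares with a step-halving
guard, so the log-likelihood trace is monotone and available for
inspection.  Cox proportional-hazards fits, Kaplan-Meier curves and the
multi-group log-rank test are delegated to ``lifelines`` (Efron tie
handling).  Chi-square tests come in both the Pearson and the
likelihood-ratio (G) flavours because clinical tables rarely say which was
used; both are reported wherever a categorical variable is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, xlogy

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


class ModelError(RuntimeError):
    """A model could not be fitted on the given data."""


class SeparationError(ModelError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass
class TestResult:
    statistic: float
    df: object  # int, or tuple for F tests; None for rank tests
    p_value: float
    method: str
    degenerate: bool = False


@dataclass
class ContingencyTable:
    """Observed counts with labels; margins are implied by the cells."""

    observed: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed)
        if self.observed.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if (self.observed < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class FittedBinaryModel:
    covariates: list[str]
    coef: np.ndarray  # log-odds per unit, aligned with covariates
    intercept: float
    log_likelihood: float
    n: int
    k: int  # estimated parameters incl. intercept
    predicted: np.ndarray  # per-patient event probability
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    outcome: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class FittedCoxModel:
    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    ci95: np.ndarray  # (p, 2) exp(beta -/+ 1.96 se)
    partial_log_likelihood: float
    wald_p: np.ndarray
    concordance: float
    n: int


# ------------------------------------------------------------- logistic


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    outcome: Sequence[int],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> FittedBinaryModel:
    """Maximum-likelihood logistic regression via monotone IRLS.

    ``design`` holds the covariates only; an intercept is always added.
    Convergence: relative log-likelihood change below ``tol`` (default
    1e-10) or ``max_iter`` iterations.  Perfect separation raises
    :class:`SeparationError` instead of silently diverging.
    """
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        if X.shape[0] == 1 and X.size > X.shape[1]:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ModelError("design and outcome lengths differ")
    if not (0 < y.sum() < n):
        raise ModelError("outcome must contain both classes")
    Xd = np.column_stack([np.ones(n), X])
    k = p + 1
    if n <= k:
        raise ModelError(f"need n > k (n={n}, k={k})")

    beta = np.zeros(k)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    eta = Xd @ beta

    def ll(e):
        # log-lik = sum y*eta - log(1+exp(eta)), computed stably
        return float(np.sum(y * e) - np.sum(np.logaddexp(0.0, e)))

    cur = ll(eta)
    trace = [cur]
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1 - mu)
        if np.max(np.abs(eta)) > 30 and np.min(w) < 1e-12:
            raise SeparationError("perfect separation detected (diverging fit)")
        z = y - mu
        XtW = Xd.T * w
        try:
            step = np.linalg.solve(XtW @ Xd, Xd.T @ z)
        except np.linalg.LinAlgError as e:
            raise ModelError(f"singular information matrix: {e}") from e
        # step halving keeps the trace monotone
        lam, new, new_eta = 1.0, cur - 1.0, eta
        for _h in range(30):
            cand = beta + lam * step
            cand_eta = Xd @ cand
            new = ll(cand_eta)
            if new >= cur - 1e-13:
                beta, new_eta = cand, cand_eta
                break
            lam /= 2.0
        else:
            break
        eta = new_eta
        trace.append(new)
        if abs(new - cur) <= tol * (abs(cur) + 1e-300):
            cur = new
            break
        cur = new
    if np.max(np.abs(eta)) > 30:
        mu = expit(eta)
        if np.min(mu[y == 1]) > 1 - 1e-8 or np.max(mu[y == 0]) < 1e-8:
            raise SeparationError("perfect separation detected")
    pred = np.clip(expit(eta), 1e-15, 1 - 1e-15)
    return FittedBinaryModel(
        covariates=names,
        coef=beta[1:],
        intercept=float(beta[0]),
        log_likelihood=cur,
        n=n,
        k=k,
        predicted=pred,
        ll_trace=np.asarray(trace),
        outcome=y.astype(int),
    )


# ------------------------------------------------------------------ Cox


def fit_cox(
    design: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    tie_method: str = "efron",
) -> FittedCoxModel:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Hazard ratios with Wald 95% CIs exp(beta +/- 1.96 SE) and Harrell's
    concordance over comparable pairs are attached.
    """
    if tie_method != "efron":
        raise ModelError("only Efron tie handling is available")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ModelError("Cox regression requires at least one event")
    if (times <= 0).any():
        raise ModelError("all times must be positive")
    df = design.copy()
    names = [str(c) for c in df.columns]
    df["_T"], df["_E"] = times, events
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_T", event_col="_E")
    except Exception as e:  # lifelines raises ConvergenceError subclasses
        raise ModelError(f"Cox fit failed: {e}") from e
    beta = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    ci = np.column_stack([np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)])
    return FittedCoxModel(
        covariates=names,
        coef=beta,
        se=se,
        hazard_ratios=np.exp(beta),
        ci95=ci,
        partial_log_likelihood=float(cph.log_likelihood_),
        wald_p=cph.summary["p"].to_numpy(),
        concordance=float(cph.concordance_index_),
        n=len(df),
    )


def km_logrank(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> tuple[dict, TestResult]:
    """Kaplan-Meier curves per group and the k-group log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    curves: dict = {}
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ModelError("log-rank needs >= 2 groups")
    for lab in labels:
        sel = groups == lab
        if sel.sum() == 0:
            raise ModelError(f"group {lab!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        curves[str(lab)] = {
            "t": sf.index.to_numpy().tolist(),
            "survival": sf.iloc[:, 0].to_numpy().tolist(),
            "n": int(sel.sum()),
            "events": int(events[sel].sum()),
        }
    res = multivariate_logrank_test(times, groups, events)
    tr = TestResult(
        statistic=float(res.test_statistic),
        df=int(len(labels) - 1),
        p_value=float(res.p_value),
        method="log-rank",
    )
    return curves, tr


# ------------------------------------------------------- categorical tests


def _expected(table: ContingencyTable) -> np.ndarray:
    obs = table.observed.astype(float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ModelError("contingency table has a zero margin")
    return stats.contingency.expected_freq(obs)


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    obs = table.observed.astype(float)
    exp = _expected(table)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(chi2, df, float(stats.chi2.sf(chi2, df)), "pearson_chi2")


def g_test(table: ContingencyTable) -> TestResult:
    """Likelihood-ratio chi-square, G = 2 sum O ln(O/E); zero cells contribute 0."""
    obs = table.observed.astype(float)
    exp = _expected(table)
    g = float(2.0 * xlogy(obs, obs / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(g, df, float(stats.chi2.sf(g, df)), "g_test")


def group_comparison(
    groups: Sequence[Sequence[float]], method: str = "anova"
) -> TestResult:
    """Compare >= 2 samples: one-way ANOVA, Kruskal-Wallis or Mann-Whitney U."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size == 0 for a in arrs):
        raise ModelError("need >= 2 non-empty groups")
    if method == "anova":
        st, p = stats.f_oneway(*arrs)
        df = (len(arrs) - 1, sum(a.size for a in arrs) - len(arrs))
    elif method == "kruskal":
        if all(np.ptp(np.concatenate(arrs)) == 0 for _ in [0]):
            # all values identical: H is 0 by midrank convention
            return TestResult(0.0, len(arrs) - 1, 1.0, "kruskal", degenerate=True)
        st, p = stats.kruskal(*arrs)
        df = len(arrs) - 1
    elif method == "mann_whitney":
        if len(arrs) != 2:
            raise ModelError("Mann-Whitney requires exactly 2 groups")
        st, p = stats.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided")
        df = None
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(float(st), df, float(p), method)
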