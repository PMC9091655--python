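"""Incremental value of adding a marker to a risk model.

Given a base model (e.g. GRACE score only) and an updated model (GRACE +
DC), this module quantifies the improvement with the nested
likelihood-ratio test, small-sample AIC (AICc) with Akaike weights, the
category-free continuous net reclassification improvement (NRI>0), the
integrated discrimination improvement (IDI), and ROC analysis (AUC with
DeLong variance, Youden-optimal cutoff, Harrell's C when survival times
are supplied).

Conventions.  NRIe = (up_e - down_e)/n_e among events, NRIne =
(down_ne - up_ne)/n_ne among non-events, NRI = NRIe + NRIne; exact ties
count as no movement but stay in the denominators.  IDI is the gain in
discrimination slope, equal to the sum of the mean risk increase among
events and the mean risk decrease among non-events.  Significance of both
uses the Pencina-style asymptotic z tests; percentile-bootstrap CIs are
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .risk_models import FittedBinaryModel, ModelError


@dataclass
class LRTResult:
    chi2: float
    df: int
    p_value: float


@dataclass
class AICcTable:
    """Per-model AICc = -2 ll + 2k + 2k(k+1)/(n-k-1), deltas and Akaike weights."""

    rows: list[dict] = field(default_factory=list)  # sorted by aicc ascending

    def __getitem__(self, label: str) -> dict:
        for row in self.rows:
            if row["label"] == label:
                return row
        raise KeyError(label)


@dataclass
class ReclassResult:
    """Reclassification counts with NRI and/or IDI statistics."""

    n_e: int = 0
    n_ne: int = 0
    up_e: int = 0
    down_e: int = 0
    tie_e: int = 0
    up_ne: int = 0
    down_ne: int = 0
    tie_ne: int = 0
    nri_e: float | None = None
    nri_ne: float | None = None
    nri: float | None = None
    nri_se: float | None = None
    nri_z: float | None = None
    nri_p: float | None = None
    idi_e: float | None = None
    idi_ne: float | None = None
    idi: float | None = None
    idi_se: float | None = None
    idi_z: float | None = None
    idi_p: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    youden_cutoff: float
    youden_j: float
    c_statistic: float | None = None
    degenerate: bool = False


# --------------------------------------------------------------- LRT/AICc


def likelihood_ratio_test(
    full: FittedBinaryModel, reduced: FittedBinaryModel
) -> LRTResult:
    """Chi-square LRT of nested logistic models fitted on the same patients."""
    if not set(reduced.covariates) <= set(full.covariates):
        raise ModelError("models are not nested")
    if full.n != reduced.n:
        raise ModelError(f"models fitted on different n ({full.n} vs {reduced.n})")
    df = full.k - reduced.k
    chi2 = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=float(chi2), df=int(df), p_value=p)


def aicc_table(models: Sequence[tuple[str, FittedBinaryModel]]) -> AICcTable:
    """AICc, delta-AICc, relative likelihood exp(-delta/2) and Akaike weights."""
    if not models:
        raise ModelError("need at least one model")
    ns = {m.n for _, m in models}
    if len(ns) != 1:
        raise ModelError("models fitted on different patient sets")
    rows = []
    for label, m in models:
        if m.n - m.k - 1 <= 0:
            raise ModelError(f"AICc undefined for model {label!r}: n - k - 1 <= 0")
        aicc = -2.0 * m.log_likelihood + 2.0 * m.k \
            + 2.0 * m.k * (m.k + 1) / (m.n - m.k - 1)
        rows.append({"label": label, "k": m.k, "log_likelihood": m.log_likelihood,
                     "aicc": aicc})
    amin = min(r["aicc"] for r in rows)
    for r in rows:
        r["delta"] = r["aicc"] - amin
        r["rel_likelihood"] = float(np.exp(-r["delta"] / 2.0))
    total = sum(r["rel_likelihood"] for r in rows)
    for r in rows:
        r["weight"] = r["rel_likelihood"] / total
    rows.sort(key=lambda r: r["aicc"])
    return AICcTable(rows=rows)


# ---------------------------------------------------------------- NRI/IDI


def _nri_core(up_e, down_e, n_e, up_ne, down_ne, n_ne) -> dict:
    nri_e = (up_e - down_e) / n_e
    nri_ne = (down_ne - up_ne) / n_ne
    se_e2 = (up_e + down_e) / n_e**2 - (up_e - down_e) ** 2 / n_e**3
    se_ne2 = (up_ne + down_ne) / n_ne**2 - (up_ne - down_ne) ** 2 / n_ne**3
    se = float(np.sqrt(max(se_e2, 0.0) + max(se_ne2, 0.0)))
    nri = nri_e + nri_ne
    if se > 0:
        z = nri / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = 0.0, 1.0
    return {"nri_e": nri_e, "nri_ne": nri_ne, "nri": nri,
            "nri_se": se, "nri_z": z, "nri_p": p}


def nri_from_counts(
    up_e: int, down_e: int, n_e: int, up_ne: int, down_ne: int, n_ne: int
) -> ReclassResult:
    """Continuous NRI directly from reclassification counts."""
    for v in (up_e, down_e, n_e, up_ne, down_ne, n_ne):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if up_e + down_e > n_e or up_ne + down_ne > n_ne:
        raise ValueError("up + down exceeds class size")
    core = _nri_core(up_e, down_e, n_e, up_ne, down_ne, n_ne)
    return ReclassResult(
        n_e=n_e, n_ne=n_ne, up_e=up_e, down_e=down_e, tie_e=n_e - up_e - down_e,
        up_ne=up_ne, down_ne=down_ne, tie_ne=n_ne - up_ne - down_ne, **core,
        degenerate=(core["nri_se"] == 0.0),
    )


def _split(p_old, p_new, outcome):
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if not (len(p_old) == len(p_new) == len(y)):
        raise ValueError("p_old, p_new and outcome must have equal length")
    if not (0 < y.sum() < len(y)):
        raise ValueError("both outcome classes must be present")
    return p_old, p_new, y == 1


def continuous_nri(
    p_old: Sequence[float], p_new: Sequence[float], outcome: Sequence[int]
) -> ReclassResult:
    """Category-free NRI>0 from predicted probabilities of two models.

    Any risk increase counts as "up", any decrease as "down"; exact ties do
    not move but remain in the denominators.
    """
    p_old, p_new, ev = _split(p_old, p_new, outcome)
    d = p_new - p_old
    up_e = int(np.sum(d[ev] > 0))
    down_e = int(np.sum(d[ev] < 0))
    up_ne = int(np.sum(d[~ev] > 0))
    down_ne = int(np.sum(d[~ev] < 0))
    return nri_from_counts(up_e, down_e, int(ev.sum()),
                           up_ne, down_ne, int((~ev).sum()))


def idi(
    p_old: Sequence[float], p_new: Sequence[float], outcome: Sequence[int]
) -> ReclassResult:
    """Integrated discrimination improvement (gain in discrimination slope).

    Computed both as the component sum mean_e(d) + mean_ne(-d) and as the
    slope difference [mean_e(p_new) - mean_ne(p_new)] - [mean_e(p_old) -
    mean_ne(p_old)]; the two must agree to 1e-12.
    """
    p_old, p_new, ev = _split(p_old, p_new, outcome)
    d = p_new - p_old
    n_e, n_ne = int(ev.sum()), int((~ev).sum())
    idi_e = float(np.mean(d[ev]))
    idi_ne = float(-np.mean(d[~ev]))
    total = idi_e + idi_ne
    slope_new = p_new[ev].mean() - p_new[~ev].mean()
    slope_old = p_old[ev].mean() - p_old[~ev].mean()
    if abs((slope_new - slope_old) - total) > 1e-12:
        raise AssertionError("IDI formulations disagree beyond 1e-12")
    var_e = float(np.var(d[ev], ddof=1)) if n_e > 1 else 0.0
    var_ne = float(np.var(d[~ev], ddof=1)) if n_ne > 1 else 0.0
    se = float(np.sqrt(var_e / n_e + var_ne / n_ne))
    if se > 0:
        z = total / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = 0.0, 1.0
    return ReclassResult(
        n_e=n_e, n_ne=n_ne, idi_e=idi_e, idi_ne=idi_ne, idi=total,
        idi_se=se, idi_z=z, idi_p=p, degenerate=(se == 0.0),
    )


def bootstrap_ci(
    statistic, p_old, p_new, outcome, n_boot: int = 2000, seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for an NRI/IDI-style statistic.

    ``statistic(p_old, p_new, outcome)`` must return a float.
    """
    rng = np.random.default_rng(seed)
    p_old = np.asarray(p_old, float)
    p_new = np.asarray(p_new, float)
    y = np.asarray(outcome, int)
    n = len(y)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if 0 < y[idx].sum() < n:
            vals.append(statistic(p_old[idx], p_new[idx], y[idx]))
    return tuple(np.quantile(vals, [alpha / 2, 1 - alpha / 2]))


# -------------------------------------------------------------------- ROC


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1 (fractions in [0, 1])."""
    return sensitivity + specificity - 1.0


def _delong_se(score, ev) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    x, yv = score[ev], score[~ev]
    m, n = len(x), len(yv)
    # placements: P(Y < x) + 0.5 P(Y = x) and vice versa
    v10 = np.array([(np.sum(yv < xi) + 0.5 * np.sum(yv == xi)) / n for xi in x])
    v01 = np.array([(np.sum(x > yi) + 0.5 * np.sum(x == yi)) / m for yi in yv])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def _hanley_mcneil_se(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return float(np.sqrt(
        (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2))
        / (m * n)
    ))


def roc_analysis(
    score: Sequence[float],
    outcome: Sequence[int],
    times: Sequence[float] | None = None,
    se_method: str = "delong",
) -> ROCCurve:
    """ROC curve, tie-corrected Mann-Whitney AUC, DeLong CI and Youden cutoff.

    ``score`` is oriented so that larger values predict the event.  When
    ``times`` are given, Harrell's C of the score against the survival
    ordering is attached (events taken from ``outcome``).
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if not (0 < y.sum() < len(y)):
        raise ValueError("both outcome classes must be present")
    ev = y == 1
    m, n = int(ev.sum()), int((~ev).sum())

    degenerate = bool(np.ptp(score) == 0)
    if degenerate:
        auc = 0.5
    else:
        ranks = stats.rankdata(score)  # midranks handle ties
        auc = float((ranks[ev].sum() - m * (m + 1) / 2) / (m * n))

    if se_method == "delong":
        se = _delong_se(score, ev) if not degenerate else 0.5 / np.sqrt(m * n)
    elif se_method == "hanley":
        se = _hanley_mcneil_se(auc, m, n)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    # threshold sweep over unique score values (>= threshold predicts event)
    thr = np.unique(score)[::-1]
    sens = np.array([np.mean(score[ev] >= t) for t in thr])
    spec = np.array([np.mean(score[~ev] < t) for t in thr])
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    cut_idx = best[np.argmin(thr[best])]  # ties -> lowest threshold
    c_stat = None
    if times is not None:
        from lifelines.utils import concordance_index

        c_stat = float(concordance_index(np.asarray(times, float), -score, y))
    return ROCCurve(
        thresholds=thr, sensitivity=sens, specificity=spec,
        auc=auc, auc_se=se, ci95=ci,
        youden_cutoff=float(thr[cut_idx]), youden_j=float(j[cut_idx]),
        c_statistic=c_stat, degenerate=degenerate,
    )
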