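"""Full study orchestration.

``run_study`` replays the complete analysis on a cohort: per-patient DC
and HRV from RR files, stratification at the 2.5/4.5 ms DC thresholds, a
baseline characteristics table with normality-gated tests, Kaplan-Meier /
log-rank across the DC groups, a univariate Cox screen followed by a
multivariate Cox model of the survivors (p < 0.05 by default), and the
enrichment comparison of GRACE-only vs GRACE+DC vs GRACE+LF/HF logistic
models (LRT, AICc/Akaike weights, continuous NRI, IDI, ROC with Harrell's
C).  Everything lands in a :class:`~dcenrich.io_formats.StudyReport`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import (
    aicc_table,
    continuous_nri,
    idi,
    likelihood_ratio_test,
    roc_analysis,
)
from .hrv import spectral_powers, time_domain
from .io_formats import CohortTable, StudyReport, read_cohort_table, read_rr_file, write_report
from .prsa import PRSAConfig, dc_risk_group, filter_nn, prsa_profile, select_anchors
from .risk_models import (
    ContingencyTable,
    ModelError,
    fit_cox,
    fit_logistic,
    g_test,
    km_logrank,
    group_comparison,
    pearson_chi2,
)


class StageError(RuntimeError):
    """An analysis stage failed; carries stage and patient context."""

    def __init__(self, stage: str, msg: str, patient_id: str | None = None):
        ctx = f" [patient {patient_id}]" if patient_id else ""
        super().__init__(f"stage '{stage}'{ctx}: {msg}")
        self.stage, self.patient_id = stage, patient_id


@dataclass
class RunConfig:
    """Run configuration (YAML-serialisable)."""

    cohort_path: str | None = None
    rr_dir: str | None = None
    output_dir: str | None = None
    screen_alpha: float = 0.05
    normality_alpha: float = 0.05
    prsa_convention: str = "signed"
    max_relative_increase: float = 0.05
    nn_bounds: tuple[float, float] = (300.0, 2000.0)
    nn_max_rel_change: float = 0.20
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    screen_covariates: list[str] = field(default_factory=list)  # empty = auto
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for key in ("nn_bounds", "lf_band", "hf_band"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


_ID_COLS = {"id", "event", "event_type", "time_months", "dc_group",
            "grace_risk_category", "presentation"}


def _compute_signal_metrics(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Per-patient DC + HRV columns from the RR files in ``cfg.rr_dir``."""
    rr_dir = Path(cfg.rr_dir)
    prsa_cfg = PRSAConfig(max_relative_increase=cfg.max_relative_increase,
                          formula_convention=cfg.prsa_convention)
    rows = []
    for pid in df["id"]:
        path = rr_dir / f"{pid}.csv"
        try:
            rr = read_rr_file(path)
            nn = filter_nn(rr, bounds=cfg.nn_bounds,
                           max_rel_change=cfg.nn_max_rel_change)
            profile = prsa_profile(nn, select_anchors(nn, prsa_cfg), prsa_cfg)
            td = time_domain(nn)
            fd = spectral_powers(nn, lf_band=cfg.lf_band, hf_band=cfg.hf_band)
        except Exception as e:
            raise StageError("signal_metrics", str(e), patient_id=str(pid)) from e
        rows.append({
            "id": pid, "dc_ms": profile.dc_ms, "sdnn": td.sdnn,
            "sdann": td.sdann, "rmssd": td.rmssd, "pnn50": td.pnn50,
            "mean_hr": td.mean_hr, "lf": fd.lf, "hf": fd.hf,
            "lf_hf": fd.lf_hf if fd.lf_hf is not None else np.nan,
        })
    metrics = pd.DataFrame(rows)
    df = df.drop(columns=[c for c in metrics.columns if c != "id"
                          and c in df.columns])
    return df.merge(metrics, on="id", how="left")


def baseline_table(
    cohort: pd.DataFrame,
    group_col: str = "dc_group",
    variables: list[str] | None = None,
    normality_alpha: float = 0.05,
) -> list[dict]:
    """Per-variable group summaries plus the appropriate test.

    Continuous variables: Shapiro-Wilk per group at ``normality_alpha``
    gates ANOVA (mean +/- SD) vs Kruskal-Wallis (median, IQR).
    Categorical variables: per-group counts with both Pearson chi-square
    and the likelihood-ratio G.
    """
    df = cohort
    group_labels = [g for g in ("low", "intermediate", "high")
                    if g in set(df[group_col])]
    if not group_labels:
        group_labels = sorted(set(df[group_col].astype(str)))
    if len(group_labels) < 2:
        raise ModelError("baseline table needs >= 2 non-empty groups")
    if variables is None:
        excluded = {"id", "time_months", "event_type", group_col}
        variables = [c for c in df.columns if c not in excluded]
    rows: list[dict] = []
    for var in variables:
        col = df[var]
        if col.isna().all():
            rows.append({"variable": var, "kind": "missing", "groups": {},
                         "test": None, "statistic": None, "p_value": None})
            continue
        groups = [col[df[group_col] == g].dropna() for g in group_labels]
        numeric = pd.api.types.is_numeric_dtype(col)
        binary = numeric and set(pd.unique(col.dropna())) <= {0, 1}
        if numeric and not binary:
            if any(len(g) < 2 for g in groups):
                continue
            if any(float(np.ptp(g)) == 0 for g in groups):
                normal = False
                degenerate = any(float(np.std(g)) == 0 for g in groups)
            else:
                normal = all(
                    len(g) >= 3 and stats.shapiro(g)[1] > normality_alpha
                    for g in groups
                )
                degenerate = False
            method = "anova" if normal else "kruskal"
            tr = group_comparison([g.to_numpy() for g in groups], method=method)
            summ = {}
            for lab, g in zip(group_labels, groups):
                if normal:
                    summ[lab] = {"mean": float(g.mean()), "sd": float(g.std())}
                else:
                    q1, med, q3 = np.percentile(g, [25, 50, 75])
                    summ[lab] = {"median": float(med), "q1": float(q1),
                                 "q3": float(q3)}
            rows.append({"variable": var, "kind": "continuous",
                         "normality_gate": "normal" if normal else "skewed",
                         "groups": summ, "test": method,
                         "statistic": tr.statistic, "p_value": tr.p_value,
                         "degenerate": degenerate or tr.degenerate})
        else:
            levels = sorted(pd.unique(col.dropna()).astype(str))
            counts = np.array([
                [int((col[df[group_col] == g].astype(str) == lev).sum())
                 for g in group_labels]
                for lev in levels
            ])
            row: dict = {"variable": var, "kind": "categorical",
                         "levels": levels,
                         "groups": {g: counts[:, j].tolist()
                                    for j, g in enumerate(group_labels)}}
            table = ContingencyTable(counts, row_labels=levels,
                                     col_labels=group_labels)
            try:
                pe, ge = pearson_chi2(table), g_test(table)
                row.update(test="pearson_chi2", statistic=pe.statistic,
                           p_value=pe.p_value, g_statistic=ge.statistic,
                           g_p_value=ge.p_value)
            except ModelError:
                row.update(test=None, statistic=None, p_value=None,
                           degenerate=True)
            rows.append(row)
    return rows


def _cox_screen(df: pd.DataFrame, covariates: list[str], alpha: float) -> tuple[list, list, list]:
    times, events = df["time_months"].to_numpy(), df["event"].to_numpy()
    uni_rows, keep = [], []
    for cov in covariates:
        sub = df[[cov]].dropna()
        if sub[cov].nunique() < 2:
            continue
        idx = sub.index
        try:
            m = fit_cox(sub, df.loc[idx, "time_months"], df.loc[idx, "event"])
        except ModelError as e:
            uni_rows.append({"covariate": cov, "error": str(e)})
            continue
        row = {"covariate": cov, "hr": float(m.hazard_ratios[0]),
               "ci_low": float(m.ci95[0, 0]), "ci_high": float(m.ci95[0, 1]),
               "p_value": float(m.wald_p[0])}
        uni_rows.append(row)
        if row["p_value"] < alpha:
            keep.append(cov)
    multi_rows = []
    if keep:
        sub = df[keep + ["time_months", "event"]].dropna()
        m = fit_cox(sub[keep], sub["time_months"], sub["event"])
        for j, cov in enumerate(keep):
            multi_rows.append({
                "covariate": cov, "hr": float(m.hazard_ratios[j]),
                "ci_low": float(m.ci95[j, 0]), "ci_high": float(m.ci95[j, 1]),
                "p_value": float(m.wald_p[j]),
            })
    return uni_rows, multi_rows, keep


def _enrichment_block(df: pd.DataFrame, base: str, added: str) -> dict:
    sub = df[[base, added, "event", "time_months"]].dropna()
    y = sub["event"].to_numpy()
    m_base = fit_logistic(sub[[base]], y)
    m_full = fit_logistic(sub[[base, added]], y)
    m_added_only = fit_logistic(sub[[added]], y)
    lrt = likelihood_ratio_test(m_full, m_base)
    aicc = aicc_table([(base, m_base), (f"{base}+{added}", m_full)])
    nri = continuous_nri(m_base.predicted, m_full.predicted, y)
    idi_res = idi(m_base.predicted, m_full.predicted, y)
    times = sub["time_months"].to_numpy()
    rocs = {
        base: roc_analysis(m_base.predicted, y, times=times),
        added: roc_analysis(m_added_only.predicted, y, times=times),
        f"{base}+{added}": roc_analysis(m_full.predicted, y, times=times),
    }
    return {
        "n": int(len(sub)),
        "lrt": {"chi2": lrt.chi2, "df": lrt.df, "p_value": lrt.p_value},
        "aicc_table": {"rows": aicc.rows},
        "nri": nri.to_dict(),
        "idi": idi_res.to_dict(),
        "roc": {
            lab: {
                "auc": r.auc, "auc_se": r.auc_se, "ci95": list(r.ci95),
                "youden_cutoff": r.youden_cutoff, "youden_j": r.youden_j,
                "sensitivity_at_cutoff": float(
                    r.sensitivity[np.flatnonzero(r.thresholds == r.youden_cutoff)[0]]
                ),
                "specificity_at_cutoff": float(
                    r.specificity[np.flatnonzero(r.thresholds == r.youden_cutoff)[0]]
                ),
                "c_statistic": r.c_statistic,
            }
            for lab, r in rocs.items()
        },
    }


def run_study(config: RunConfig | str | Path, cohort: CohortTable | None = None
              ) -> StudyReport:
    """Execute the full pipeline and return (and optionally write) the report."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    cfg = config
    if cohort is None:
        if not cfg.cohort_path:
            raise StageError("inputs", "no cohort table given")
        cohort = read_cohort_table(cfg.cohort_path)
    df = cohort.data.copy()

    if cfg.rr_dir:
        df = _compute_signal_metrics(df, cfg)
    if "dc_ms" not in df.columns:
        raise StageError("stratify", "no dc_ms column and no RR files to compute it")
    df["dc_group"] = [dc_risk_group(v) for v in df["dc_ms"]]

    try:
        base_rows = baseline_table(df, normality_alpha=cfg.normality_alpha)
    except ModelError as e:
        raise StageError("baseline_table", str(e)) from e

    curves, lr = km_logrank(df["time_months"], df["event"], df["dc_group"])
    km_block = {"curves": curves,
                "logrank": {"chi2": lr.statistic, "df": lr.df,
                            "p_value": lr.p_value}}

    covs = cfg.screen_covariates or [
        c for c in df.columns
        if c not in _ID_COLS and c != "id"
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    uni, multi, kept = _cox_screen(df, covs, cfg.screen_alpha)

    enrichment = {}
    if "grace_score" in df.columns:
        for added in ("dc_ms", "lf_hf"):
            if added in df.columns and df[added].notna().sum() > 10:
                try:
                    enrichment[f"grace+{added}"] = _enrichment_block(
                        df, "grace_score", added)
                except (ModelError, ValueError) as e:
                    raise StageError("enrichment", f"{added}: {e}") from e

    subgroups = {}
    if "presentation" in df.columns:
        for level in sorted(df["presentation"].dropna().unique()):
            sdf = df[df["presentation"] == level]
            if sdf["event"].sum() >= 5:
                u, m, _ = _cox_screen(sdf, covs, cfg.screen_alpha)
                subgroups[str(level)] = {"n": int(len(sdf)),
                                         "univariate": u, "multivariate": m}

    cfg_dict = asdict(cfg)
    meta = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": cfg.seed,
        "n_patients": int(len(df)),
        "n_events": int(df["event"].sum()),
        "screen_survivors": kept,
        "multiple_testing_correction": "none",
        "version": _version(),
    }
    report = StudyReport(
        baseline_table=base_rows, km_logrank=km_block, univariate=uni,
        multivariate=multi, enrichment=enrichment, subgroups=subgroups,
        metadata=meta,
    )
    if cfg.output_dir:
        write_report(report, cfg.output_dir)
    return report


def _version() -> str:
    from . import __version__

    return __version__
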