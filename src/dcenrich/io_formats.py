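"""File formats: per-patient RR-interval CSVs, the cohort table, and the study report.

The RR file dialect is a plain CSV ``t_sec,rr_ms,label`` with beat-onset
times in seconds from recording start, interval lengths in milliseconds and
an optional beat label (``normal``/``ectopic``/``artifact``/``unknown``;
missing label column defaults to ``normal``).  Commercial Holter exports
must be converted to this dialect upstream; vendor formats are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

BEAT_LABELS = ("normal", "ectopic", "artifact", "unknown")

#: canonical column order of the cohort CSV; extra columns are preserved
COHORT_REQUIRED = ("id", "grace_score", "event", "time_months")


class FormatError(ValueError):
    """A file violated the expected dialect or an invariant of its type."""


@dataclass
class RRSeries:
    """A raw beat-interval sequence for one patient.

    ``beat_times`` are interval-onset times in seconds (0-based, strictly
    increasing), ``intervals`` are in milliseconds, ``labels`` annotate each
    beat.  The three arrays have equal length.
    """

    patient_id: str
    beat_times: np.ndarray
    intervals: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U8")
        n = len(self.beat_times)
        if not (len(self.intervals) == len(self.labels) == n):
            raise FormatError("beat_times, intervals and labels must have equal length")
        if n > 1 and not np.all(np.diff(self.beat_times) > 0):
            bad = int(np.argmax(np.diff(self.beat_times) <= 0)) + 1
            raise FormatError(f"beat_times not strictly increasing at row {bad}")
        unknown = set(np.unique(self.labels)) - set(BEAT_LABELS)
        if unknown:
            raise FormatError(f"unknown beat labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.beat_times)


@dataclass
class CohortTable:
    """One row per patient: id, GRACE score, outcome, follow-up time, covariates."""

    data: pd.DataFrame
    column_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        for col in COHORT_REQUIRED:
            if col not in df.columns:
                raise FormatError(f"cohort table missing required column '{col}'")
        dup = df["id"][df["id"].duplicated()].tolist()
        if dup:
            raise FormatError(f"duplicate patient ids: {dup}")
        ev = set(pd.unique(df["event"]))
        if not ev <= {0, 1}:
            raise FormatError(f"event indicator must be 0/1, got {sorted(ev)}")
        if (df["time_months"] <= 0).any():
            bad = df.loc[df["time_months"] <= 0, "id"].tolist()
            raise FormatError(f"non-positive follow-up time for ids {bad}")
        if not self.column_types:
            self.column_types = {
                c: ("numeric" if pd.api.types.is_numeric_dtype(df[c]) else "categorical")
                for c in df.columns
            }

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class StudyReport:
    """Machine-readable results of a full study run (JSON-serialisable dicts)."""

    baseline_table: list = field(default_factory=list)
    km_logrank: dict = field(default_factory=dict)
    univariate: list = field(default_factory=list)
    multivariate: list = field(default_factory=list)
    enrichment: dict = field(default_factory=dict)
    subgroups: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "baseline_table": self.baseline_table,
            "km_logrank": self.km_logrank,
            "univariate": self.univariate,
            "multivariate": self.multivariate,
            "enrichment": self.enrichment,
            "subgroups": self.subgroups,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyReport":
        return cls(**{k: d.get(k, cls.__dataclass_fields__[k].default_factory())
                      for k in cls.__dataclass_fields__})


REPORT_SCHEMA = {
    "baseline_table": list,
    "km_logrank": dict,
    "univariate": list,
    "multivariate": list,
    "enrichment": dict,
    "subgroups": dict,
    "metadata": dict,
}


def validate_report(d: dict[str, Any]) -> None:
    """Check the report dictionary against the bundled section schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in d:
            raise FormatError(f"report missing section '{key}'")
        if not isinstance(d[key], typ):
            raise FormatError(f"report section '{key}' must be {typ.__name__}")
    for row in d["baseline_table"]:
        if "variable" not in row:
            raise FormatError("baseline_table rows need a 'variable' key")


# ---------------------------------------------------------------- RR files


def read_rr_file(path: str | Path) -> RRSeries:
    """Read a per-patient RR CSV.

    Rows with non-positive ``rr_ms`` are kept but relabelled ``artifact``
    (readers never silently drop data); non-monotone times raise.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_sec", "rr_ms"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column '{col}'")
    labels = (
        df["label"].fillna("normal").astype(str).to_numpy()
        if "label" in df.columns
        else np.full(len(df), "normal", dtype="U8")
    )
    rr = df["rr_ms"].to_numpy(dtype=float)
    labels = np.asarray(labels, dtype="U8").copy()
    labels[rr <= 0] = "artifact"
    return RRSeries(
        patient_id=path.stem,
        beat_times=df["t_sec"].to_numpy(dtype=float),
        intervals=rr,
        labels=labels,
    )


def write_rr_file(series: RRSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"t_sec": series.beat_times, "rr_ms": series.intervals, "label": series.labels}
    ).to_csv(path, index=False)
    return path


# ------------------------------------------------------------ cohort table


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c) for c in df.columns]
    if "id" in df.columns:
        df["id"] = df["id"].astype(str)
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


# ----------------------------------------------------------------- report


def _rows_to_csv(rows: list, path: Path, columns: list[str] | None = None) -> None:
    df = pd.DataFrame(rows)
    if columns:
        cols = [c for c in columns if c in df.columns]
        cols += [c for c in df.columns if c not in cols]
        df = df[cols] if len(df) else df
    df.to_csv(path, index=False)


def write_report(report: StudyReport, directory: str | Path) -> list[Path]:
    """Write ``report.json`` plus CSV analogues of the main result tables.

    Returns the list of files written.  CSV column orders are fixed so the
    tables diff cleanly between runs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    d = report.to_dict()
    validate_report(d)
    files = []

    p = directory / "report.json"
    p.write_text(json.dumps(d, indent=2, sort_keys=True, default=_json_default))
    files.append(p)

    p = directory / "baseline_table.csv"
    _rows_to_csv(d["baseline_table"], p,
                 ["variable", "kind", "test", "statistic", "p_value"])
    files.append(p)

    for name, key, cols in [
        ("cox_univariate.csv", "univariate",
         ["covariate", "hr", "ci_low", "ci_high", "p_value"]),
        ("cox_multivariate.csv", "multivariate",
         ["covariate", "hr", "ci_low", "ci_high", "p_value"]),
    ]:
        p = directory / name
        _rows_to_csv(d[key], p, cols)
        files.append(p)

    aicc_rows, reclass_rows = [], []
    for marker, block in d["enrichment"].items():
        for row in block.get("aicc_table", {}).get("rows", []):
            aicc_rows.append({"comparison": marker, **row})
        for key in ("nri", "idi"):
            if key in block:
                reclass_rows.append({"comparison": marker, "measure": key,
                                     **block[key]})
    p = directory / "model_comparison.csv"
    _rows_to_csv(aicc_rows, p,
                 ["comparison", "label", "aicc", "delta", "rel_likelihood", "weight"])
    files.append(p)
    p = directory / "reclassification.csv"
    _rows_to_csv(reclass_rows, p, ["comparison", "measure"])
    files.append(p)
    return files


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def read_report(directory: str | Path) -> StudyReport:
    d = json.loads((Path(directory) / "report.json").read_text())
    validate_report(d)
    return StudyReport.from_dict(d)
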