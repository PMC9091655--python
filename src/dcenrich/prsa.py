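"""Phase-rectified signal averaging (PRSA) and deceleration capacity (DC).

DC quantifies vagally mediated heart-rate deceleration from a 24-h RR
series.  The series is first reduced to normal-to-normal (NN) intervals,
"anchor" beats at which the heart rate decelerates (RR lengthens by at most
a small fraction) are located, windows of +/- L beats around each anchor are
averaged into the PRSA profile X(k), and the capacity is the Haar-wavelet
coefficient at the anchor,

    DC = [X(0) + X(1) - X(-1) - X(-2)] / 4   (ms).

Some clinical reports print the formula with four plus signs; that variant
averages the profile itself (~mean RR) rather than the wavelet contrast and
is retained behind ``formula_convention="as_printed"`` purely for audits.
Patients are conventionally stratified at 2.5 and 4.5 ms: DC > 4.5 low
risk, 2.5 < DC <= 4.5 intermediate, DC <= 2.5 high risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import RRSeries

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (a and callable(a[0])) else a[0]


class AnalysisError(RuntimeError):
    """A signal-processing stage could not produce a result."""


class NoAnchorsError(AnalysisError):
    """No valid PRSA anchors were found (e.g. a constant series)."""

    def __init__(self, msg: str = "no anchors", anchor_count: int = 0):
        super().__init__(msg)
        self.anchor_count = anchor_count


@dataclass
class NNSeries:
    """Artifact-filtered normal-to-normal intervals for one patient.

    ``gap_flags[i]`` is True when one or more beats were removed (or the
    recording is discontinuous) immediately before beat ``i``.
    """

    patient_id: str
    times: np.ndarray
    intervals: np.ndarray
    gap_flags: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.gap_flags = np.asarray(self.gap_flags, dtype=bool)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def span_seconds(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) > 1 else 0.0


@dataclass
class PRSAConfig:
    """Anchor rule and window geometry for PRSA.

    ``max_relative_increase`` rejects anchors whose RR lengthening exceeds
    the given fraction of the preceding interval (artifact guard, default
    5%).  ``window_half_length`` L is the number of beats kept either side
    of the anchor; L = 2 is the minimum housing the wavelet indices
    k in {-2, -1, 0, 1}.
    """

    direction: str = "deceleration"
    max_relative_increase: float = 0.05
    window_half_length: int = 2
    formula_convention: str = "signed"

    def __post_init__(self) -> None:
        if self.direction != "deceleration":
            raise ValueError("only direction='deceleration' is supported")
        if not 0 < self.max_relative_increase < 1:
            raise ValueError("max_relative_increase must be in (0, 1)")
        if self.window_half_length < 2:
            raise ValueError("window_half_length must be >= 2")
        if self.formula_convention not in ("signed", "as_printed"):
            raise ValueError("formula_convention must be 'signed' or 'as_printed'")


@dataclass
class PRSAProfile:
    """Anchor-averaged profile X(k), k in [-L, L-1], and the derived DC."""

    X: dict[int, float]
    anchor_count: int
    dc_ms: float
    config: PRSAConfig = field(default_factory=PRSAConfig)


# physiologic NN bounds (ms) used as filter defaults: standard Holter practice
DEFAULT_NN_BOUNDS = (300.0, 2000.0)
DEFAULT_MAX_REL_CHANGE = 0.20


@njit(cache=True)
def _filter_core(rr, is_normal, lo, hi, max_rel):  # pragma: no cover - jitted
    n = rr.shape[0]
    keep = np.zeros(n, dtype=np.bool_)
    gap_after_removed = np.zeros(n, dtype=np.bool_)
    last = -1.0
    pending_gap = False
    rejected_run = 0
    for i in range(n):
        ok = is_normal[i] and lo <= rr[i] <= hi
        if ok and last > 0.0:
            ok = abs(rr[i] - last) / last <= max_rel
        if ok:
            keep[i] = True
            gap_after_removed[i] = pending_gap
            pending_gap = False
            last = rr[i]
            rejected_run = 0
        else:
            pending_gap = True
            rejected_run += 1
            if rejected_run >= 10:
                # reference beat was itself aberrant (e.g. a compensatory
                # pause accepted cold): drop it and re-seed on the next
                # in-bounds normal beat instead of rejecting forever
                last = -1.0
                rejected_run = 0
    return keep, gap_after_removed


def filter_nn(
    rr: RRSeries,
    bounds: tuple[float, float] = DEFAULT_NN_BOUNDS,
    max_rel_change: float = DEFAULT_MAX_REL_CHANGE,
) -> NNSeries:
    """Reduce a raw RR series to normal-to-normal intervals.

    A beat is kept when it is labelled ``normal``, its interval lies within
    ``bounds`` (ms), and it differs from the last *accepted* interval by at
    most ``max_rel_change`` (fraction).  Removed beats set the gap flag on
    the next kept beat; order is preserved and nothing else is altered.
    """
    lo, hi = bounds
    is_normal = rr.labels == "normal"
    keep, gaps = _filter_core(
        np.ascontiguousarray(rr.intervals, dtype=np.float64),
        np.ascontiguousarray(is_normal),
        float(lo),
        float(hi),
        float(max_rel_change),
    )
    if not keep.any():
        raise AnalysisError("no analyzable NN intervals")
    return NNSeries(
        patient_id=rr.patient_id,
        times=rr.beat_times[keep],
        intervals=rr.intervals[keep],
        gap_flags=gaps[keep],
    )


def select_anchors(nn: NNSeries, cfg: PRSAConfig | None = None) -> np.ndarray:
    """Indices of deceleration anchors in the NN series.

    Beat ``i`` is an anchor iff RR_i > RR_{i-1}, the relative increase is at
    most ``cfg.max_relative_increase``, and the full window
    ``[i-L, i+L-1]`` exists without crossing any gap.  May be empty.
    """
    cfg = cfg or PRSAConfig()
    L = cfg.window_half_length
    x = nn.intervals
    n = len(x)
    if n < 2 * L:
        return np.empty(0, dtype=int)
    cand = np.zeros(n, dtype=bool)
    prev = x[:-1]
    cand[1:] = (x[1:] > prev) & (x[1:] <= (1.0 + cfg.max_relative_increase) * prev)
    # window [i-L, i+L-1] must exist ...
    idx = np.arange(n)
    cand &= (idx >= L) & (idx <= n - L)
    # ... and contain no gap: gap_flags[j] marks a discontinuity *before* j,
    # so no j in (i-L, i+L-1] may be flagged.
    g = np.cumsum(nn.gap_flags.astype(np.int64))
    valid = np.zeros(n, dtype=bool)
    inner = idx[(idx >= L) & (idx <= n - L)]
    if inner.size:
        valid[inner] = g[inner + L - 1] - g[inner - L] == 0
    return np.flatnonzero(cand & valid)


def prsa_profile(
    nn: NNSeries, anchors: Sequence[int], cfg: PRSAConfig | None = None
) -> PRSAProfile:
    """Average windows around the anchors and evaluate the DC formula."""
    cfg = cfg or PRSAConfig()
    anchors = np.asarray(anchors, dtype=int)
    if anchors.size == 0:
        raise NoAnchorsError()
    L = cfg.window_half_length
    X = {
        int(k): float(np.mean(nn.intervals[anchors + k])) for k in range(-L, L)
    }
    if cfg.formula_convention == "signed":
        dc = (X[0] + X[1] - X[-1] - X[-2]) / 4.0
    else:  # as_printed: four plus signs; ~ mean RR, kept for audits only
        dc = (X[0] + X[1] + X[-1] + X[-2]) / 4.0
    return PRSAProfile(X=X, anchor_count=int(anchors.size), dc_ms=float(dc), config=cfg)


def deceleration_capacity(
    rr: RRSeries,
    cfg: PRSAConfig | None = None,
    bounds: tuple[float, float] = DEFAULT_NN_BOUNDS,
    max_rel_change: float = DEFAULT_MAX_REL_CHANGE,
    min_span_seconds: float = 60.0,
) -> PRSAProfile:
    """Full pipeline: NN filtering -> anchor selection -> PRSA profile.

    Deterministic for fixed input and configuration.  Raises
    :class:`AnalysisError` when fewer than ``min_span_seconds`` of usable
    beats remain, :class:`NoAnchorsError` when no anchors exist.
    """
    cfg = cfg or PRSAConfig()
    nn = filter_nn(rr, bounds=bounds, max_rel_change=max_rel_change)
    if nn.span_seconds < min_span_seconds:
        raise AnalysisError(
            f"usable NN span {nn.span_seconds:.1f}s < required {min_span_seconds:.1f}s"
        )
    anchors = select_anchors(nn, cfg)
    return prsa_profile(nn, anchors, cfg)


def dc_risk_group(dc_ms: float) -> str:
    """Stratify DC at 2.5/4.5 ms: ``low`` (>4.5), ``intermediate``, ``high`` (<=2.5)."""
    if not np.isfinite(dc_ms):
        raise ValueError(f"DC must be finite, got {dc_ms}")
    if dc_ms > 4.5:
        return "low"
    if dc_ms > 2.5:
        return "intermediate"
    return "high"
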