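"""24-h heart-rate-variability panel.

Time domain: SDNN, SDANN (5-min segment means), rMSSD, pNN50, mean heart
rate.  Frequency domain: LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) band
powers in ms^2 and their ratio, estimated with Lomb-Scargle periodograms of
the irregularly sampled NN tachogram - no interpolation or resampling of
the beat series is performed.  Long recordings are analysed as consecutive
5-min segments whose band powers are averaged, the conventional way 24-h
spectral indices are produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .prsa import AnalysisError, NNSeries


@dataclass
class HRVTimeDomain:
    sdnn: float  # ms
    sdann: float  # ms
    rmssd: float  # ms
    pnn50: float  # percent
    mean_hr: float  # beats per minute


@dataclass
class HRVFreqDomain:
    lf: float  # ms^2
    hf: float  # ms^2
    lf_hf: float | None  # None when hf == 0
    band_edges: tuple[float, float, float, float] = (0.04, 0.15, 0.15, 0.40)


def time_domain(nn: NNSeries, segment_length: float = 300.0) -> HRVTimeDomain:
    """Standard time-domain panel.

    SDANN uses consecutive ``segment_length``-second windows anchored at the
    first beat; a final incomplete window is dropped.  Successive-difference
    statistics (rMSSD, pNN50) skip pairs that span a gap.
    """
    x = nn.intervals
    if len(x) < 2:
        raise AnalysisError("time-domain HRV requires >= 2 NN intervals")
    sdnn = float(np.std(x, ddof=1))
    mean_hr = 60000.0 / float(np.mean(x))

    rel_t = nn.times - nn.times[0]
    seg = np.floor(rel_t / segment_length).astype(int)
    n_complete = int(np.floor((rel_t[-1]) / segment_length))
    if n_complete < 2:
        raise AnalysisError(
            f"SDANN requires >= 2 complete {segment_length:.0f}s segments"
        )
    means = np.array(
        [x[seg == s].mean() for s in range(n_complete) if np.any(seg == s)]
    )
    if len(means) < 2:
        raise AnalysisError("SDANN requires >= 2 populated segments")
    sdann = float(np.std(means, ddof=1))

    diffs = np.diff(x)
    ok = ~nn.gap_flags[1:]  # pair (i-1, i) invalid when a gap precedes i
    diffs = diffs[ok]
    if diffs.size == 0:
        raise AnalysisError("rMSSD requires at least one gap-free successive pair")
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    pnn50 = float(100.0 * np.mean(np.abs(diffs) > 50.0))
    return HRVTimeDomain(sdnn=sdnn, sdann=sdann, rmssd=rmssd, pnn50=pnn50,
                         mean_hr=mean_hr)


def _segment_band_powers(
    t: np.ndarray, y: np.ndarray, bands: list[tuple[float, float]]
) -> list[float]:
    """Band powers of one segment via a variance-normalised Lomb-Scargle.

    The raw periodogram on a dense grid is rescaled so its integral over the
    full analysed range (up to 0.5 Hz) equals the segment variance; band
    powers are the shares of that variance (Parseval by construction, so a
    single in-band sinusoid of amplitude A yields ~A^2/2).
    """
    var = float(np.var(y))
    if var == 0.0 or len(y) < 4:
        return [0.0 for _ in bands]
    span = t[-1] - t[0]
    f_lo, f_hi = 1.0 / span, 0.5
    df = 1.0 / (4.0 * span)  # 4x oversampled natural resolution
    freqs = np.arange(f_lo, f_hi, df)
    if freqs.size < 8:
        return [0.0 for _ in bands]
    pgram = lombscargle(t, y - y.mean(), 2.0 * np.pi * freqs)
    total = pgram.sum()
    if total <= 0:
        return [0.0 for _ in bands]
    out = []
    for lo, hi in bands:
        sel = (freqs >= lo) & (freqs < hi)
        out.append(var * float(pgram[sel].sum()) / total)
    return out


def spectral_powers(
    nn: NNSeries,
    lf_band: tuple[float, float] = (0.04, 0.15),
    hf_band: tuple[float, float] = (0.15, 0.40),
    segment_length: float = 300.0,
) -> HRVFreqDomain:
    """LF/HF band powers of the NN tachogram (value vs beat time), in ms^2.

    Requires >= 5 minutes of usable data.  Records longer than two segments
    are split into consecutive ``segment_length``-second windows and the
    per-segment powers averaged; shorter records use one window.  The
    estimate is deterministic.  When HF is zero the ratio is reported as
    missing (None), never infinity.
    """
    t, y = nn.times, nn.intervals
    span = t[-1] - t[0] if len(t) > 1 else 0.0
    if span < 300.0:
        raise AnalysisError("spectral HRV requires >= 5 minutes of NN data")
    bands = [lf_band, hf_band]
    if span < 2 * segment_length:
        powers = [_segment_band_powers(t, y, bands)]
    else:
        n_seg = int(np.floor(span / segment_length))
        rel = t - t[0]
        powers = []
        for s in range(n_seg):
            sel = (rel >= s * segment_length) & (rel < (s + 1) * segment_length)
            if sel.sum() >= 16:
                powers.append(_segment_band_powers(t[sel], y[sel], bands))
        if not powers:
            raise AnalysisError("no populated segments for spectral HRV")
    arr = np.asarray(powers)
    lf, hf = float(arr[:, 0].mean()), float(arr[:, 1].mean())
    lf_hf = lf / hf if hf > 0 else None
    return HRVFreqDomain(lf=lf, hf=hf, lf_hf=lf_hf,
                         band_edges=(*lf_band, *hf_band))
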