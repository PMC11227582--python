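"""Two-channel fiber-photometry processing and MAD-threshold event detection.

The processing chain mirrors the standard workflow for a fluorescent
neurotransmitter sensor recorded against an isosbestic control channel:

1. mean-bin downsampling,
2. subtraction of a per-channel autofluorescence scalar (fluorescence
   measured with the patch cord disconnected from the animal),
3. exponential photobleaching detrend per channel, restoring the pre-detrend
   channel mean as an offset,
4. ΔF/F against the fitted baseline,
5. subtraction of the control-channel ΔF/F from the signal ΔF/F,
6. z-scoring.

Event detection is a robust two-stage median-absolute-deviation (MAD) rule:
samples rising more than ``filter_k`` MAD above a 10 s rolling median are
excluded, the median and MAD of the remaining ("filtered") trace anchor a
``peak_k``-MAD peak threshold, and local maxima above it are events. MADs are
unscaled (no 1.4826 normal-consistency factor): thresholds are expressed in
raw MAD units.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from striakit.exceptions import DataError, DetectionError

__all__ = [
    "PhotometryRecording",
    "ProcessedTrace",
    "EventTrain",
    "EventSummary",
    "preprocess_trace",
    "rolling_median",
    "detect_events",
    "summarize_events",
    "compare_event_trains",
]


@dataclass(frozen=True)
class PhotometryRecording:
    """Time-aligned 465 nm signal and 405 nm control fluorescence channels."""

    time_s: np.ndarray
    f_signal: np.ndarray
    f_control: np.ndarray
    rate_hz: float
    autofluorescence_signal: float = 0.0
    autofluorescence_control: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.f_signal, dtype=float)
        c = np.asarray(self.f_control, dtype=float)
        if not (len(t) == len(s) == len(c)):
            raise DataError("channel lengths differ")
        if len(t) == 0:
            raise DataError("empty recording")
        if np.any(np.diff(t) <= 0):
            raise DataError("time must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "f_signal", s)
        object.__setattr__(self, "f_control", c)

    @property
    def duration_s(self) -> float:
        return len(self.time_s) / self.rate_hz


@dataclass(frozen=True)
class ProcessedTrace:
    """z-scored, control-subtracted ΔF/F trace with a provenance record."""

    time_s: np.ndarray
    z: np.ndarray
    rate_hz: float
    dff: np.ndarray | None = None  # control-subtracted ΔF/F before z-scoring
    provenance: tuple = ()

    @property
    def duration_s(self) -> float:
        return len(self.time_s) / self.rate_hz


@dataclass(frozen=True)
class EventTrain:
    """Detected transient peak times and amplitudes (z units above the
    filtered-trace median), plus detector diagnostics."""

    peak_times_s: np.ndarray
    peak_amplitudes: np.ndarray
    duration_s: float
    threshold: float = np.nan
    filtered_median: float = np.nan
    mad_residual: float = np.nan
    mad_filtered: float = np.nan

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times_s, dtype=float)
        a = np.asarray(self.peak_amplitudes, dtype=float)
        if len(t) != len(a):
            raise DataError("times and amplitudes differ in length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise DataError("peak times must be strictly increasing")
        object.__setattr__(self, "peak_times_s", t)
        object.__setattr__(self, "peak_amplitudes", a)

    def __len__(self) -> int:
        return len(self.peak_times_s)


@dataclass(frozen=True)
class EventSummary:
    """Per-recording event summary: mean amplitude, frequency, IEIs."""

    mean_amplitude: float
    frequency_per_min: float
    ieis_s: np.ndarray
    n_events: int


# ---------------------------------------------------------------------------
# preprocessing


def _mean_bin(x: np.ndarray, factor: int) -> np.ndarray:
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def _fit_exponential(t: np.ndarray, x: np.ndarray):
    """Least-squares fit of a*exp(-t/tau) + c; returns (a, tau, c) or None."""

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    span = t[-1] - t[0] if len(t) > 1 else 1.0
    ptp = max(float(np.ptp(x)), 1e-12)
    a0 = x[0] - x[-1]
    if a0 == 0:
        a0 = ptp
    # keep the asymptote c within the data range: for recordings much shorter
    # than the bleach time constant the (a, tau, c) surface is nearly flat
    # along a trade-off direction and an unconstrained c can run away,
    # producing a meaningless (even negative) Delta-F/F baseline
    c_lo, c_hi = float(np.min(x)) - ptp, float(np.max(x)) + ptp
    p0 = (a0, span / 3.0, float(np.clip(x[-1], c_lo, c_hi)))
    try:
        popt, _ = optimize.curve_fit(
            model, t, x, p0=p0,
            bounds=([-10 * ptp, 1e-9, c_lo], [10 * ptp, np.inf, c_hi]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        return None
    return tuple(float(p) for p in popt)


def preprocess_trace(
    rec: PhotometryRecording,
    target_rate_hz: float = 120.0,
    lowpass_hz: float | None = None,
) -> ProcessedTrace:
    """Run the full processing chain on a two-channel recording.

    Parameters
    ----------
    rec
        The raw recording.
    target_rate_hz
        Rate after mean-bin downsampling (default 120 Hz; the downsample
        factor is ``round(rec.rate_hz / target_rate_hz)``).
    lowpass_hz
        Optional zero-phase Butterworth low-pass applied to both channels at
        the original rate before downsampling, emulating an acquisition
        filter. ``None`` (default) relies on mean binning alone.

    Returns
    -------
    ProcessedTrace
        z-scored control-subtracted ΔF/F with per-stage provenance.

    Raises
    ------
    DataError
        If the downsample target exceeds the recording rate, a fitted
        baseline F0 is non-positive, or the control-subtracted trace has zero
        variance (z-score undefined).
    """
    if target_rate_hz > rec.rate_hz:
        raise DataError("target_rate_hz exceeds recording rate")
    provenance: list[dict] = []

    sig = rec.f_signal.astype(float).copy()
    ctl = rec.f_control.astype(float).copy()
    t = rec.time_s.astype(float).copy()

    if lowpass_hz is not None:
        from scipy.signal import butter, filtfilt

        b, a = butter(4, lowpass_hz / (rec.rate_hz / 2.0))
        sig, ctl = filtfilt(b, a, sig), filtfilt(b, a, ctl)
        provenance.append({"step": "lowpass", "cutoff_hz": lowpass_hz})

    factor = max(int(round(rec.rate_hz / target_rate_hz)), 1)
    rate = rec.rate_hz / factor
    if factor > 1:
        sig, ctl, t = _mean_bin(sig, factor), _mean_bin(ctl, factor), _mean_bin(t, factor)
    provenance.append({"step": "downsample", "factor": factor, "rate_hz": rate})

    sig -= rec.autofluorescence_signal
    ctl -= rec.autofluorescence_control
    provenance.append({
        "step": "autofluorescence_subtraction",
        "signal": rec.autofluorescence_signal,
        "control": rec.autofluorescence_control,
    })

    dffs = []
    for name, x in (("signal", sig), ("control", ctl)):
        offset = float(np.mean(x))
        fit = _fit_exponential(t, x)
        if fit is not None:
            a, tau, c = fit
            detrended = x - (a * np.exp(-t / tau) + c) + offset
            f0 = c + offset
            provenance.append({"step": "detrend", "channel": name,
                               "kind": "exponential", "a": a, "tau_s": tau,
                               "c": c, "offset": offset})
        else:
            coeffs = np.polyfit(t, x, 1)
            detrended = x - np.polyval(coeffs, t) + offset
            f0 = offset
            provenance.append({"step": "detrend", "channel": name,
                               "kind": "linear_fallback",
                               "slope": float(coeffs[0]), "offset": offset})
        if f0 <= 0:
            raise DataError(f"non-positive baseline F0 for {name} channel")
        dffs.append((detrended - f0) / f0)
        provenance.append({"step": "dff", "channel": name, "f0": f0})

    dff = dffs[0] - dffs[1]
    provenance.append({"step": "control_subtraction"})

    sd = float(np.std(dff))
    if sd < 1e-15:
        raise DataError("control-subtracted trace has zero variance; "
                        "z-score undefined")
    z = (dff - np.mean(dff)) / sd
    provenance.append({"step": "zscore", "mean": float(np.mean(dff)), "sd": sd})

    return ProcessedTrace(time_s=t, z=z, rate_hz=rate, dff=dff,
                          provenance=tuple(provenance))


# ---------------------------------------------------------------------------
# rolling median


def rolling_median(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered rolling median with edge-truncated (shrunk) windows.

    Even ``window_samples`` are rounded up to the next odd count so the
    window is symmetric; output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise DataError("empty input")
    w = int(window_samples)
    if w < 1:
        raise DataError("window must cover at least one sample")
    if w % 2 == 0:
        w += 1
    return (
        pd.Series(x).rolling(window=w, center=True, min_periods=1)
        .median().to_numpy()
    )


def rolling_median_s(x: np.ndarray, rate_hz: float, window_s: float = 10.0) -> np.ndarray:
    """:func:`rolling_median` with the window given in seconds."""
    return rolling_median(x, int(round(window_s * rate_hz)))


# ---------------------------------------------------------------------------
# event detection


def _local_maxima(z: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat plateau that is higher than its
    surroundings is resolved to its first sample. Endpoints are never maxima."""
    n = len(z)
    if n < 3:
        return np.array([], dtype=int)
    d = np.diff(z)
    # run-length encode plateaus: candidate plateau starts where d>0, and the
    # next nonzero step after the plateau must be negative
    rises = np.flatnonzero(d > 0)
    if len(rises) == 0:
        return np.array([], dtype=int)
    nz = np.flatnonzero(d)
    # for each index i with d[i] > 0, the plateau starts at i+1; it is a
    # maximum iff the next nonzero step at or after i+1 is a fall
    pos = np.searchsorted(nz, rises + 1)
    valid = pos < len(nz)
    rises, pos = rises[valid], pos[valid]
    falls_next = d[nz[pos]] < 0
    return rises[falls_next] + 1


def detect_events(
    p: ProcessedTrace,
    window_s: float = 10.0,
    filter_k: float = 2.0,
    peak_k: float = 3.0,
    min_sep_s: float = 0.5,
    peak_mad: str = "filtered",
) -> EventTrain:
    """Detect transients with the two-stage MAD rule.

    Algorithm: with ``r = z - rolling_median(z, window_s)``, compute the
    unscaled global ``MAD1 = median(|r - median(r)|)``; drop samples with
    ``r > filter_k * MAD1`` (high-amplitude events); let ``m_f`` and ``MAD2``
    be the median and MAD of the remaining z values. Events are strict local
    maxima of z exceeding ``m_f + peak_k * MAD``, where ``MAD`` is ``MAD2``
    (default) or ``MAD1`` (``peak_mad="residual"``, for sensitivity
    analyses). Peaks closer than ``min_sep_s`` are resolved keeping the
    larger peak (earlier on exact tie). Amplitudes are ``z - m_f`` at the
    peak.
    """
    if filter_k <= 0 or peak_k <= 0:
        raise DataError("filter_k and peak_k must be positive")
    if peak_mad not in ("filtered", "residual"):
        raise DataError("peak_mad must be 'filtered' or 'residual'")
    z = np.asarray(p.z, dtype=float)
    r = z - rolling_median_s(z, p.rate_hz, window_s)
    mad1 = float(np.median(np.abs(r - np.median(r))))
    keep = r <= filter_k * mad1
    if not np.any(keep):
        raise DetectionError(
            "filtered trace is empty; review filter_k / window_s")
    zf = z[keep]
    m_f = float(np.median(zf))
    mad2 = float(np.median(np.abs(zf - m_f)))
    mad = mad2 if peak_mad == "filtered" else mad1
    threshold = m_f + peak_k * mad

    cand = _local_maxima(z)
    cand = cand[z[cand] > threshold]

    # enforce min separation: larger peak wins, earlier peak on exact tie
    min_sep = min_sep_s * p.rate_hz
    order = cand[np.lexsort((cand, -z[cand]))]
    accepted: list[int] = []  # kept sorted by index
    for i in order:
        i = int(i)
        k = bisect.bisect_left(accepted, i)
        if k > 0 and i - accepted[k - 1] < min_sep:
            continue
        if k < len(accepted) and accepted[k] - i < min_sep:
            continue
        accepted.insert(k, i)
    accepted_arr = np.asarray(accepted, dtype=int)

    return EventTrain(
        peak_times_s=p.time_s[accepted_arr],
        peak_amplitudes=z[accepted_arr] - m_f,
        duration_s=p.duration_s,
        threshold=threshold,
        filtered_median=m_f,
        mad_residual=mad1,
        mad_filtered=mad2,
    )


def summarize_events(e: EventTrain) -> EventSummary:
    """Frequency (events/min), mean amplitude and inter-event intervals."""
    if e.duration_s <= 0:
        raise DataError("duration must be positive")
    n = len(e)
    ieis = np.diff(e.peak_times_s) if n > 1 else np.array([])
    return EventSummary(
        mean_amplitude=float(np.mean(e.peak_amplitudes)) if n else float("nan"),
        frequency_per_min=n / e.duration_s * 60.0,
        ieis_s=ieis,
        n_events=n,
    )


def compare_event_trains(a, b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on two IEI samples.

    Returns (D, asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("KS comparison requires non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
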