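"""ECG analysis: R-peak detection, ST-segment measurement, onset detection.

ST elevation — the displacement of the segment between the J point and the T
wave relative to the isoelectric line — is the functional marker of
myocardial ischemia here, its magnitude a proxy for infarct size.  Each
beat's ST amplitude is the mean signal over [J+10 ms, J+30 ms] minus the
isoelectric level, itself the mean over a 20-ms PR window ending 10 ms
before QRS onset; J and QRS onset are located by slope flattening around the
R peak.  Beats are aggregated into per-minute medians (robust to missed
beats) and a sustained elevation — three consecutive minutes above baseline
mean + 3 SD — defines the onset.

All measurements are baseline-relative, hence invariant to a DC offset of
the whole ECG.  A positive-R lead convention is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import Recording, TimeWindowSpec

__all__ = [
    "STMeasurement",
    "STSeries",
    "detect_r_peaks",
    "measure_st",
    "measure_st_batch",
    "st_series",
    "peak_st_elevation",
    "detect_st_onset",
]

# Fiducial search geometry (seconds); rat beats are short, windows tight.
_PRE_S = 0.070          # extraction before R
_POST_S = 0.110         # extraction after R
_S_SEARCH_S = 0.030     # S trough search after R
_J_SEARCH_S = 0.040     # J search after S
_ONSET_SEARCH_S = 0.040 # QRS-onset search before R
_FLAT_FRACTION = 0.08   # slope-flatness threshold vs peak QRS slope
_FLAT_RUN_S = 0.008     # required flat run
_ST_LO_S, _ST_HI_S = 0.010, 0.030   # ST window after J
_ISO_GAP_S, _ISO_LEN_S = 0.010, 0.020  # PR window before QRS onset


@dataclass
class STMeasurement:
    """Single-beat ST amplitude (mV, isoelectric-relative)."""

    beat_time_s: float
    st_amplitude_mv: float
    quality: bool


@dataclass
class STSeries:
    """Per-minute median ST amplitude, minutes relative to the injection.

    ``minute_start_s[i]`` is the start (seconds relative to injection) of the
    minute whose median is ``values_mv[i]``; minutes without quality beats
    are absent.  Baseline statistics come from the baseline window only.
    """

    minute_start_s: np.ndarray
    values_mv: np.ndarray
    baseline_mean_mv: float
    baseline_sd_mv: float
    n_beats: np.ndarray

    def minute_index(self) -> np.ndarray:
        return np.round(self.minute_start_s / 60.0).astype(int)


def detect_r_peaks(ecg: Recording) -> np.ndarray:
    """Detect R waves via band-passed QRS energy and an adaptive threshold.

    Requires rate >= 250 Hz.  The threshold is relative to the energy
    distribution, so the peak set is invariant to rescaling the signal; a
    flat recording yields an empty list.  A 60-ms refractory period
    (rat-appropriate) suppresses double detections.  Returns sorted, unique
    sample indices of R peaks.
    """
    fs = ecg.rate_hz
    if fs < 250:
        raise ValueError(f"R-peak detection needs rate >= 250 Hz, got {fs}")
    x = ecg.samples
    if x.size < int(fs) or np.ptp(x) == 0:
        return np.empty(0, dtype=int)

    nyq = fs / 2.0
    hi = min(90.0, 0.9 * nyq)
    sos = sps.butter(2, [15.0, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    energy = y * y
    win = max(1, int(round(0.020 * fs)))
    energy = np.convolve(energy, np.ones(win) / win, mode="same")

    height = 0.3 * np.percentile(energy, 99)
    if height <= 0:
        return np.empty(0, dtype=int)
    refractory = int(round(0.060 * fs))
    peaks, _ = sps.find_peaks(energy, height=height, distance=refractory)

    # refine to the local maximum of the mean-removed raw signal
    half = int(round(0.020 * fs))
    refined = np.empty(peaks.size, dtype=int)
    for k, p in enumerate(peaks):
        i0, i1 = max(0, p - half), min(x.size, p + half + 1)
        seg = x[i0:i1] - np.mean(x[i0:i1])
        refined[k] = i0 + int(np.argmax(seg))
    refined = np.unique(refined)
    # re-impose the refractory period after refinement
    if refined.size > 1:
        keep = [0]
        for i in range(1, refined.size):
            if refined[i] - refined[keep[-1]] >= refractory:
                keep.append(i)
        refined = refined[keep]
    return refined


def measure_st_batch(ecg: Recording, r_indices: np.ndarray) -> list[STMeasurement]:
    """Vectorised per-beat ST measurement (see module docstring for the rule).

    Beats whose fiducials cannot be located, or that lack full context at the
    recording edges (e.g. a truncated final beat), get ``quality=False`` and
    are excluded from aggregates; no exception is raised.
    """
    fs = ecg.rate_hz
    x = ecg.samples
    r_indices = np.asarray(r_indices, dtype=int)
    n = r_indices.size
    out: list[STMeasurement] = []
    if n == 0:
        return out

    pre = int(round(_PRE_S * fs))
    post = int(round(_POST_S * fs))
    width = pre + post + 1
    ok = (r_indices - pre >= 0) & (r_indices + post < x.size)

    beats = np.zeros((n, width))
    idx = r_indices[ok, None] + np.arange(-pre, post + 1)[None, :]
    beats[ok] = x[idx]

    d = np.diff(beats, axis=1) * fs  # mV/s, d[:, i] = slope between i and i+1
    r_col = pre
    qrs_lo = max(0, r_col - int(round(0.030 * fs)))
    qrs_hi = min(d.shape[1], r_col + int(round(0.030 * fs)))
    slope_scale = np.max(np.abs(d[:, qrs_lo:qrs_hi]), axis=1)
    flat = np.abs(d) < (_FLAT_FRACTION * np.maximum(slope_scale, 1e-12))[:, None]
    run = max(2, int(round(_FLAT_RUN_S * fs)))
    flat_run = flat.copy()
    for k in range(1, run):
        flat_run[:, : flat.shape[1] - k] &= flat[:, k:]

    cols = np.arange(width)

    # S trough: minimum in (R, R + 30 ms]
    s_hi = min(width, r_col + int(round(_S_SEARCH_S * fs)) + 1)
    s_idx = r_col + 1 + np.argmin(beats[:, r_col + 1 : s_hi], axis=1)

    # J point: first flat run strictly after S, within 40 ms
    j_limit = s_idx + int(round(_J_SEARCH_S * fs))
    j_idx = np.full(n, -1)
    for i in range(n):
        if not ok[i]:
            continue
        lo = s_idx[i] + 1
        hi = min(flat_run.shape[1], j_limit[i])
        seg = flat_run[i, lo:hi]
        w = np.flatnonzero(seg)
        if w.size:
            j_idx[i] = lo + w[0]

    # QRS onset: first flat run scanning backward from R - 4 ms, within 40 ms
    on_idx = np.full(n, -1)
    back_hi = r_col - int(round(0.004 * fs))
    back_lo = max(0, r_col - int(round(_ONSET_SEARCH_S * fs)))
    for i in range(n):
        if not ok[i] or j_idx[i] < 0:
            continue
        seg = flat_run[i, back_lo:back_hi]
        w = np.flatnonzero(seg[::-1])
        if w.size:
            on_idx[i] = back_hi - 1 - w[0]

    st_lo = (j_idx + int(round(_ST_LO_S * fs))).clip(0, width - 1)
    st_hi = (j_idx + int(round(_ST_HI_S * fs))).clip(0, width - 1)
    iso_hi = on_idx - int(round(_ISO_GAP_S * fs))
    iso_lo = iso_hi - int(round(_ISO_LEN_S * fs))

    valid = ok & (j_idx >= 0) & (on_idx >= 0) & (st_hi > st_lo) & (iso_lo >= 0) & (st_hi < width)
    for i in range(n):
        t = r_indices[i] / fs
        if not valid[i]:
            out.append(STMeasurement(t, float("nan"), False))
            continue
        st = float(np.mean(beats[i, st_lo[i] : st_hi[i] + 1]))
        iso = float(np.mean(beats[i, iso_lo[i] : iso_hi[i] + 1]))
        out.append(STMeasurement(t, st - iso, True))
    return out


def measure_st(ecg: Recording, r_index: int) -> STMeasurement:
    """ST amplitude of the single beat at ``r_index`` (see :func:`measure_st_batch`)."""
    return measure_st_batch(ecg, np.asarray([r_index]))[0]


def st_series(
    ecg: Recording,
    peaks: np.ndarray | None = None,
    baseline_window: TimeWindowSpec | None = None,
) -> STSeries:
    """Per-minute median ST amplitude, anchored to the injection time.

    Minute ``m`` covers ``[60m, 60(m+1))`` seconds relative to injection
    (negative minutes are the baseline).  Baseline mean/SD are computed from
    minutes fully inside ``baseline_window`` (default: everything before the
    injection).
    """
    t0 = ecg.require_injection()
    if peaks is None:
        peaks = detect_r_peaks(ecg)
    meas = measure_st_batch(ecg, peaks)
    times = np.array([m.beat_time_s for m in meas if m.quality])
    vals = np.array([m.st_amplitude_mv for m in meas if m.quality])

    if times.size == 0:
        return STSeries(np.empty(0), np.empty(0), float("nan"), float("nan"), np.empty(0, int))

    minute = np.floor((times - t0) / 60.0).astype(int)
    uniq = np.unique(minute)
    med = np.array([np.median(vals[minute == m]) for m in uniq])
    cnt = np.array([int(np.sum(minute == m)) for m in uniq])
    starts = uniq * 60.0

    if baseline_window is not None:
        b_lo, b_hi = baseline_window.start_s, baseline_window.end_s
    else:
        b_lo, b_hi = -np.inf, 0.0
    in_b = (starts >= b_lo) & (starts + 60.0 <= b_hi)
    if in_b.any():
        b_mean = float(np.mean(med[in_b]))
        b_sd = float(np.std(med[in_b], ddof=1)) if in_b.sum() > 1 else 0.0
    else:
        b_mean, b_sd = float("nan"), float("nan")
    return STSeries(starts, med, b_mean, b_sd, cnt)


def peak_st_elevation(series: STSeries, window: TimeWindowSpec) -> float | None:
    """Maximum per-minute median ST inside the window, minus the baseline mean."""
    sel = (series.minute_start_s >= window.start_s) & (series.minute_start_s + 60.0 <= window.end_s)
    if not sel.any():
        return None
    return float(np.max(series.values_mv[sel]) - series.baseline_mean_mv)


def detect_st_onset(series: STSeries) -> int | None:
    """First post-injection minute starting a sustained (3-minute) elevation.

    Returns the minute index ``m >= 0`` such that minutes ``m, m+1, m+2`` all
    exceed ``baseline_mean + 3*baseline_sd``, or ``None`` if elevation is
    never sustained.  Requires baseline statistics.
    """
    if not np.isfinite(series.baseline_mean_mv) or not np.isfinite(series.baseline_sd_mv):
        raise ValueError("baseline statistics required for onset detection")
    thr = series.baseline_mean_mv + 3.0 * series.baseline_sd_mv
    idx = series.minute_index()
    above = {int(m) for m, v in zip(idx, series.values_mv) if m >= 0 and v > thr}
    for m in sorted(above):
        if m + 1 in above and m + 2 in above:
            return m
    return None
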