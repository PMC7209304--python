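"""Spectrogram, band power and peak-frequency estimation.

Time–frequency power is a short-time Fourier spectrogram (2-s Hann window,
0.5-s overlap, i.e. a 1.5-s hop, density scaling in μV²/Hz).  A band's power
series is the mean of the spectrogram bins inside the band per frame, bands
being half-open intervals so shared edges belong to exactly one band; the
per-window summary is the median over retained frames.  Peak frequency is
estimated per 1-s epoch as the argmax of a single Hann-tapered periodogram
zero-padded fourfold (0.25 Hz grid), the per-window summary again a median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocessing import EpochSet
from .signal_io import Recording

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "TOTAL_BAND",
    "Spectrogram",
    "BandPowerSeries",
    "AnimalSummary",
    "compute_spectrogram",
    "band_power_series",
    "median_band_power",
    "epoch_peak_frequency",
    "median_peak_frequency",
    "total_median_power",
]


@dataclass(frozen=True)
class BandDefinition:
    """A canonical EEG frequency band, half-open ``[f_low, f_high)`` Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_low < self.f_high:
            raise ValueError(f"band {self.name}: need 0 <= f_low < f_high")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.f_low) & (freqs < self.f_high)


DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 7.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 35.0),
}

#: Broadband interval used for "total" power.
TOTAL_BAND = BandDefinition("total", 0.5, 35.0)


@dataclass
class Spectrogram:
    """Short-time power density estimates, frames × frequency bins."""

    frame_times_s: np.ndarray  # frame centers, seconds from recording start
    freqs_hz: np.ndarray
    power: np.ndarray  # shape (n_frames, n_freqs), μV²/Hz
    window_len_s: float = 2.0
    overlap_s: float = 0.5

    @property
    def n_frames(self) -> int:
        return int(self.power.shape[0])

    def to_csv(self, path) -> None:
        """Export as CSV for inspection: one row per frame, one column per
        frequency bin, frame times in the first column."""
        import pandas as pd

        df = pd.DataFrame(self.power, columns=[f"{f:g}Hz" for f in self.freqs_hz])
        df.insert(0, "frame_time_s", self.frame_times_s)
        df.to_csv(path, index=False)


@dataclass
class BandPowerSeries:
    """Mean in-band power density per spectrogram frame, with a retained mask."""

    band: BandDefinition
    frame_times_s: np.ndarray
    values: np.ndarray
    retained_mask: np.ndarray


def compute_spectrogram(
    rec_or_samples,
    rate_hz: float | None = None,
    window_len_s: float = 2.0,
    overlap_s: float = 0.5,
    t_offset_s: float = 0.0,
) -> Spectrogram:
    """Hann-tapered short-time power spectral density of a recording.

    ``window_len_s * rate`` must be integral and ``0 <= overlap < window_len``;
    the hop is ``window_len - overlap`` (1.5 s by default).  A signal shorter
    than one window is rejected.  ``t_offset_s`` shifts the reported frame
    times (used when analysing a window slice of a longer recording).
    """
    if isinstance(rec_or_samples, Recording):
        x = rec_or_samples.samples
        fs = rec_or_samples.rate_hz
    else:
        x = np.asarray(rec_or_samples, dtype=np.float64)
        if rate_hz is None:
            raise ValueError("rate_hz required when passing a bare array")
        fs = float(rate_hz)

    nperseg = window_len_s * fs
    if abs(nperseg - round(nperseg)) > 1e-9:
        raise ValueError(f"window_len_s*rate must be integral, got {nperseg}")
    nperseg = int(round(nperseg))
    if not 0 <= overlap_s < window_len_s:
        raise ValueError("need 0 <= overlap_s < window_len_s")
    noverlap = int(round(overlap_s * fs))
    if x.size < nperseg:
        raise ValueError(f"recording shorter than one spectrogram window ({x.size} < {nperseg} samples)")

    freqs, times, sxx = sps.spectrogram(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return Spectrogram(
        frame_times_s=times + t_offset_s,
        freqs_hz=freqs,
        power=sxx.T.copy(),
        window_len_s=window_len_s,
        overlap_s=overlap_s,
    )


def _frame_retained_mask(spec: Spectrogram, epochs: EpochSet) -> np.ndarray:
    """A frame is retained iff its full taper interval lies inside a retained epoch."""
    half = spec.window_len_s / 2.0
    lo = spec.frame_times_s - half
    hi = spec.frame_times_s + half
    mask = np.zeros(spec.n_frames, dtype=bool)
    eps = 1e-9
    for start, keep in zip(epochs.starts_s, epochs.retained):
        if keep:
            mask |= (lo >= start - eps) & (hi <= start + epochs.epoch_len_s + eps)
    return mask


def band_power_series(spec: Spectrogram, band: BandDefinition, epochs: EpochSet) -> BandPowerSeries:
    """Per-frame mean power density over the band's bins, masked by retained epochs."""
    bins = band.contains(spec.freqs_hz)
    if not bins.any():
        raise ValueError(f"band {band.name} [{band.f_low}, {band.f_high}) contains no frequency bins")
    values = spec.power[:, bins].mean(axis=1)
    return BandPowerSeries(band, spec.frame_times_s.copy(), values, _frame_retained_mask(spec, epochs))


def _window_frame_mask(series: BandPowerSeries, span: tuple[float, float], window_len_s: float) -> np.ndarray:
    half = window_len_s / 2.0
    eps = 1e-9
    return (series.frame_times_s - half >= span[0] - eps) & (series.frame_times_s + half <= span[1] + eps)


def median_band_power(
    series: BandPowerSeries, window_span: tuple[float, float], window_len_s: float = 2.0
) -> float | None:
    """Median retained-frame power over frames fully inside the window span.

    ``window_span`` is in recording time (seconds).  Returns ``None`` when no
    retained frame falls in the window; callers drop such animals pairwise.
    """
    sel = series.retained_mask & _window_frame_mask(series, window_span, window_len_s)
    if not sel.any():
        return None
    return float(np.median(series.values[sel]))


def epoch_peak_frequency(
    segment: np.ndarray, rate_hz: float, band: BandDefinition, pad_factor: int = 4
) -> float | None:
    """Peak frequency of a 1-s epoch within a band.

    A single Hann-tapered periodogram of the epoch, zero-padded
    ``pad_factor``-fold (0.25 Hz grid for 1-s epochs at the default 4), is
    maximised over bins inside the band; ties break toward the lower
    frequency.  An all-zero segment has no peak (``None``).
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.size != int(round(rate_hz)):
        raise ValueError(f"segment must be 1 s long ({int(round(rate_hz))} samples), got {x.size}")
    if not np.any(x):
        return None
    freqs, psd = _batch_periodogram(x[None, :], rate_hz, pad_factor)
    return float(_peak_in_band(freqs, psd, band)[0])


def _batch_periodogram(blocks: np.ndarray, rate_hz: float, pad_factor: int = 4):
    """Hann-tapered zero-padded periodograms for rows of ``blocks``."""
    n = blocks.shape[1]
    taper = sps.get_window("hann", n)
    nfft = n * pad_factor
    spec = np.fft.rfft(blocks * taper, n=nfft, axis=1)
    psd = (np.abs(spec) ** 2) / (rate_hz * np.sum(taper ** 2))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate_hz)
    return freqs, psd


def _peak_in_band(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    bins = band.contains(freqs)
    if not bins.any():
        raise ValueError(f"band {band.name} contains no bins on the PSD grid")
    sub = psd[:, bins]
    # np.argmax returns the first maximum: the tie-break toward lower frequency
    return freqs[bins][np.argmax(sub, axis=1)]


def median_peak_frequency(
    rec: Recording,
    window_span: tuple[float, float],
    band: BandDefinition,
    epochs: EpochSet,
    pad_factor: int = 4,
) -> float | None:
    """Median peak frequency over all non-overlapping 1-s blocks of the window.

    Blocks are taken inside retained epochs that lie fully within
    ``window_span`` (recording time).  Returns ``None`` if nothing is
    retained; all-zero blocks are skipped.
    """
    n = int(round(rec.rate_hz))
    eps = 1e-9
    blocks = []
    for start, keep in zip(epochs.starts_s, epochs.retained):
        if not keep:
            continue
        if start < window_span[0] - eps or start + epochs.epoch_len_s > window_span[1] + eps:
            continue
        i0 = int(round(start * rec.rate_hz))
        n_blocks = int(np.floor(epochs.epoch_len_s + 1e-9))
        for b in range(n_blocks):
            seg = rec.samples[i0 + b * n : i0 + (b + 1) * n]
            if seg.size == n:
                blocks.append(seg)
    if not blocks:
        return None
    arr = np.asarray(blocks)
    nonzero = np.any(arr != 0, axis=1)
    if not nonzero.any():
        return None
    freqs, psd = _batch_periodogram(arr[nonzero], rec.rate_hz, pad_factor)
    peaks = _peak_in_band(freqs, psd, band)
    return float(np.median(peaks))


def total_median_power(
    spec: Spectrogram, epochs: EpochSet, window_span: tuple[float, float]
) -> float | None:
    """Median broadband (0.5–35 Hz) power over retained frames in the window."""
    series = band_power_series(spec, TOTAL_BAND, epochs)
    return median_band_power(series, window_span, spec.window_len_s)


@dataclass
class AnimalSummary:
    """Per-animal, per-window summary feeding the group statistics.

    ``median_band_power[window][band]`` and ``median_peak_freq_hz[window][band]``
    may hold ``None`` when a window retained nothing; ``peak_st_mv[window]``
    is the ECG's peak ST elevation over that window (mV, baseline-relative).
    """

    animal_id: str
    group: str
    median_band_power: dict[str, dict[str, float | None]] = field(default_factory=dict)
    median_peak_freq_hz: dict[str, dict[str, float | None]] = field(default_factory=dict)
    peak_st_mv: dict[str, float | None] = field(default_factory=dict)
    total_median_power: dict[str, float | None] = field(default_factory=dict)
    st_onset_min: float | None = None
    n_epochs: dict[str, int] = field(default_factory=dict)
    n_epochs_rejected: dict[str, int] = field(default_factory=dict)
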