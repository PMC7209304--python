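"""Filtering, epoching and amplitude-based artifact rejection.

The acquisition chain is emulated digitally: a 0.3–100 Hz band-pass plus a
50 Hz notch, both applied zero-phase (forward–backward) so epoch timing is
preserved.  Continuous ECoG is then cut into non-overlapping 60-s epochs and
any epoch containing a sample whose absolute value exceeds 500 μV is marked
noisy; further exclusions can be supplied as an explicit index list, the
reproducible stand-in for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import Recording, TimeWindowSpec

__all__ = [
    "EpochSet",
    "REJECT_NONE",
    "REJECT_AMPLITUDE",
    "REJECT_MANUAL",
    "apply_filters",
    "segment_epochs",
    "reject_noisy_epochs",
    "mark_manual",
]

REJECT_NONE = "none"
REJECT_AMPLITUDE = "amplitude"
REJECT_MANUAL = "manual"


@dataclass
class EpochSet:
    """Contiguous fixed-length epochs of one recording window.

    ``starts_s`` are epoch start times in seconds from *recording start*;
    epochs are half-open ``[start, start + epoch_len_s)``, non-overlapping
    and fully inside the recording.  ``retained[i]`` is False iff
    ``reject_reason[i] != "none"``.
    """

    epoch_len_s: float
    starts_s: np.ndarray
    retained: np.ndarray
    reject_reason: list[str]
    window: str | None = None
    empty_window: bool = False  # window fell entirely outside the recording

    def __post_init__(self) -> None:
        self.starts_s = np.asarray(self.starts_s, dtype=np.float64)
        self.retained = np.asarray(self.retained, dtype=bool)
        if not (len(self.starts_s) == len(self.retained) == len(self.reject_reason)):
            raise ValueError("inconsistent epoch arrays")
        for r, reason in zip(self.retained, self.reject_reason):
            if r != (reason == REJECT_NONE):
                raise ValueError("retained flag inconsistent with reject_reason")

    @property
    def n_epochs(self) -> int:
        return int(len(self.starts_s))

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.epoch_len_s,
            self.starts_s.copy(),
            self.retained.copy(),
            list(self.reject_reason),
            self.window,
            self.empty_window,
        )


def apply_filters(
    rec: Recording,
    hp_hz: float = 0.3,
    lp_hz: float = 100.0,
    notch_hz: float | None = 50.0,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase band-pass (Butterworth order 4) plus notch (order 2, Q=30).

    Length is preserved.  Corner frequencies must satisfy
    ``0 < hp < lp < rate/2``; violations are rejected.
    """
    nyq = rec.rate_hz / 2.0
    if not 0 < hp_hz < lp_hz:
        raise ValueError(f"need 0 < hp_hz < lp_hz, got {hp_hz}, {lp_hz}")
    if lp_hz >= nyq:
        raise ValueError(f"lp_hz={lp_hz} must be below Nyquist ({nyq} Hz)")
    if notch_hz is not None and notch_hz >= nyq:
        raise ValueError(f"notch_hz={notch_hz} must be below Nyquist ({nyq} Hz)")

    sos = sps.butter(4, [hp_hz, lp_hz], btype="bandpass", fs=rec.rate_hz, output="sos")
    x = sps.sosfiltfilt(sos, rec.samples)
    if notch_hz is not None:
        b, a = sps.iirnotch(notch_hz, notch_q, fs=rec.rate_hz)
        x = sps.filtfilt(b, a, x)
    return rec.copy_with(x)


def segment_epochs(rec: Recording, window: TimeWindowSpec, epoch_len_s: float = 60.0) -> EpochSet:
    """Cut ``window`` into non-overlapping epochs; the trailing remainder is dropped.

    The window is intersected with the recording span; a window entirely
    outside the recording yields an empty set flagged ``empty_window``.
    """
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be > 0")
    lo, hi = rec.window_span(window)
    if hi <= lo:
        return EpochSet(epoch_len_s, np.empty(0), np.empty(0, bool), [], window.name, empty_window=True)
    n = int(np.floor((hi - lo) / epoch_len_s + 1e-9))
    starts = lo + epoch_len_s * np.arange(n)
    return EpochSet(epoch_len_s, starts, np.ones(n, bool), [REJECT_NONE] * n, window.name)


def reject_noisy_epochs(rec: Recording, epochs: EpochSet, threshold_uv: float = 500.0) -> EpochSet:
    """Mark epochs whose maximum absolute sample strictly exceeds the threshold.

    The comparison is strict (an epoch peaking at exactly the threshold is
    retained) and applied to single-sample absolute values of ``rec`` —
    conventionally the filtered signal.  Idempotent; manual marks survive.
    """
    out = epochs.copy()
    rate = rec.rate_hz
    for i, start in enumerate(out.starts_s):
        i0 = int(round(start * rate))
        i1 = int(round((start + out.epoch_len_s) * rate))
        seg = rec.samples[i0:i1]
        if seg.size and np.max(np.abs(seg)) > threshold_uv:
            if out.reject_reason[i] == REJECT_NONE:
                out.reject_reason[i] = REJECT_AMPLITUDE
                out.retained[i] = False
        elif out.reject_reason[i] == REJECT_AMPLITUDE:
            # re-running with a higher threshold un-marks amplitude rejections
            out.reject_reason[i] = REJECT_NONE
            out.retained[i] = True
    return out


def mark_manual(epochs: EpochSet, indices: Sequence[int]) -> EpochSet:
    """Mark the listed epochs as manually excluded (duplicates tolerated)."""
    out = epochs.copy()
    for idx in indices:
        if not 0 <= idx < out.n_epochs:
            raise IndexError(f"epoch index {idx} out of range [0, {out.n_epochs})")
        if out.reject_reason[idx] != REJECT_MANUAL:
            out.reject_reason[idx] = REJECT_MANUAL
            out.retained[idx] = False
    return out
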