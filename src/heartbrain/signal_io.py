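"""Recordings, analysis time windows, and file I/O.

A :class:`Recording` is one physiological channel (ECoG in microvolts or ECG
in millivolts) with a fixed sampling rate and an optional injection anchor.
All analysis windows are expressed in seconds relative to the injection
timestamp; sample indexing is 0-based and intervals are half-open
``[start, end)``.

Interchange formats are EDF+ (16-bit, one data record per second, the
injection time stored as an annotation named ``"injection"``) and
single-column CSV.  Result tables are written as CSV plus a JSON bundle.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Recording",
    "TimeWindowSpec",
    "WINDOW_NAMES",
    "default_windows",
    "session_windows",
    "read_edf",
    "write_edf",
    "read_csv_signal",
    "write_results",
]

#: Canonical window names: baseline hour, first post-injection hour,
#: post-injection hours 2-4, and the hour recorded on day 2.
WINDOW_NAMES = ("B", "H1", "D1", "D2")


@dataclass(frozen=True)
class TimeWindowSpec:
    """A named analysis window in seconds relative to the injection."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.name not in WINDOW_NAMES:
            raise ValueError(f"unknown window name {self.name!r}; expected one of {WINDOW_NAMES}")
        if not self.start_s < self.end_s:
            raise ValueError(f"window {self.name}: start_s ({self.start_s}) must be < end_s ({self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def default_windows() -> dict[str, TimeWindowSpec]:
    """Real-time window table: D2 sits 24 h after the injection."""
    return {
        "B": TimeWindowSpec("B", -3600.0, 0.0),
        "H1": TimeWindowSpec("H1", 0.0, 3600.0),
        "D1": TimeWindowSpec("D1", 3600.0, 14400.0),
        "D2": TimeWindowSpec("D2", 86400.0, 90000.0),
    }


def session_windows(scale: float = 1.0) -> dict[str, TimeWindowSpec]:
    """Session-time window table for recordings stored contiguously.

    The day-2 hour is appended directly after the day-1 session, so D2
    occupies [14400, 18000) s relative to injection.  ``scale`` shrinks
    every window duration proportionally (used for reduced-size runs).
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    b, h = 3600.0 * scale, 3600.0 * scale
    d1 = 10800.0 * scale
    d2 = 3600.0 * scale
    return {
        "B": TimeWindowSpec("B", -b, 0.0),
        "H1": TimeWindowSpec("H1", 0.0, h),
        "D1": TimeWindowSpec("D1", h, h + d1),
        "D2": TimeWindowSpec("D2", h + d1, h + d1 + d2),
    }


@dataclass
class Recording:
    """One channel of samples at a fixed rate.

    Parameters
    ----------
    samples
        1-D float array in ``units``.
    rate_hz
        Sampling rate, > 0 (the acquisition default is 512 Hz).
    label
        Channel label, e.g. ``"ECOG"`` or ``"ECG"``.
    units
        Physical units of the samples (``"uV"`` for ECoG, ``"mV"`` for ECG).
    t_injection_s
        Injection time in seconds from recording start, or ``None`` when the
        file carries no anchor (the caller must then supply one).
    """

    samples: np.ndarray
    rate_hz: float = 512.0
    label: str = "signal"
    units: str = "uV"
    t_injection_s: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be > 0")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.t_injection_s is not None and not 0 <= self.t_injection_s <= self.duration_s:
            raise ValueError(
                f"t_injection_s={self.t_injection_s} outside recording span [0, {self.duration_s}]"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def require_injection(self) -> float:
        if self.t_injection_s is None:
            raise ValueError(f"recording {self.label!r} has no injection timestamp")
        return self.t_injection_s

    def window_span(self, window: TimeWindowSpec) -> tuple[float, float]:
        """Absolute (recording-time) span of ``window``, clipped to the recording."""
        t0 = self.require_injection()
        return max(0.0, t0 + window.start_s), min(self.duration_s, t0 + window.end_s)

    def slice_window(self, window: TimeWindowSpec) -> np.ndarray:
        """Samples falling in ``window`` (half-open, relative to injection)."""
        lo, hi = self.window_span(window)
        i0 = int(round(lo * self.rate_hz))
        i1 = int(round(hi * self.rate_hz))
        return self.samples[i0:i1]

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return dataclasses.replace(self, samples=np.asarray(samples, dtype=np.float64))


# ---------------------------------------------------------------------------
# EDF I/O
#
# Reading goes through mne; writing is a small EDF+C emitter (16-bit samples,
# one data record per second, one EDF-annotations channel carrying the
# injection anchor) because no EDF writer ships with the analysis stack.
# ---------------------------------------------------------------------------

_EDF_ANNOTATION_LABEL = "EDF Annotations"


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def write_edf(recordings: Sequence[Recording], path: str | os.PathLike) -> None:
    """Write recordings to an EDF+C file, one data record per second.

    All recordings must share the same duration (rates may differ).  The
    physical range of each signal is set to cover its observed range, so the
    round-trip error is bounded by that range divided by 2**16.  The
    injection time of the first recording that has one is written as an
    annotation named ``"injection"``.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("write_edf: empty recording list")
    durations = {round(r.duration_s, 9) for r in recordings}
    if len(durations) > 1:
        raise ValueError(f"write_edf: recordings have mismatched durations {sorted(durations)}")
    dur = recordings[0].duration_s
    if dur <= 0 or abs(dur - round(dur)) > 1e-9:
        raise ValueError("write_edf: duration must be a positive whole number of seconds")
    n_records = int(round(dur))
    for r in recordings:
        if abs(r.rate_hz - round(r.rate_hz)) > 1e-9:
            raise ValueError("write_edf: rate must be an integer number of samples per second")

    t_inj = next((r.t_injection_s for r in recordings if r.t_injection_s is not None), None)

    # Per-signal scaling to the int16 range.
    phys_min, phys_max, digital = [], [], []
    for r in recordings:
        lo = float(np.min(r.samples)) if r.n_samples else -1.0
        hi = float(np.max(r.samples)) if r.n_samples else 1.0
        if hi <= lo:
            hi = lo + 1.0
        # pad the range slightly so extremes stay inside it
        span = hi - lo
        lo -= 0.005 * span
        hi += 0.005 * span
        phys_min.append(lo)
        phys_max.append(hi)
        scale = (hi - lo) / (2 ** 16 - 1)
        dig = np.round((r.samples - lo) / scale - 32768.0).astype("<i2")
        digital.append(dig)

    # Annotation channel: timekeeping TAL per record, plus the injection event.
    ann_records: list[bytes] = []
    for rec_i in range(n_records):
        tal = f"+{rec_i}\x14\x14\x00".encode("ascii")
        if t_inj is not None and rec_i == 0:
            tal += f"+{t_inj:g}\x14\x14injection\x14\x00".encode("ascii")
        ann_records.append(tal)
    ann_len = max(len(b) for b in ann_records)
    ann_len += (-ann_len) % 2  # int16-sized slots
    ann_samples_per_record = ann_len // 2

    n_signals = len(recordings) + 1
    header_bytes = 256 * (n_signals + 1)

    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))
        f.write(_edf_field("Startdate X X X X", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(str(header_bytes), 8))
        f.write(_edf_field("EDF+C", 44))
        f.write(_edf_field(str(n_records), 8))
        f.write(_edf_field("1", 8))  # record duration, seconds
        f.write(_edf_field(str(n_signals), 4))

        labels = [r.label[:16] for r in recordings] + [_EDF_ANNOTATION_LABEL]
        for lab in labels:
            f.write(_edf_field(lab, 16))
        for _ in range(n_signals):
            f.write(_edf_field("", 80))  # transducer
        for r in recordings:
            f.write(_edf_field(r.units[:8], 8))
        f.write(_edf_field("", 8))
        for v in phys_min:
            f.write(_edf_field(f"{v:.8g}"[:8], 8))
        f.write(_edf_field("-1", 8))
        for v in phys_max:
            f.write(_edf_field(f"{v:.8g}"[:8], 8))
        f.write(_edf_field("1", 8))
        for _ in range(n_signals - 1):
            f.write(_edf_field("-32768", 8))
        f.write(_edf_field("-32768", 8))
        for _ in range(n_signals - 1):
            f.write(_edf_field("32767", 8))
        f.write(_edf_field("32767", 8))
        for _ in range(n_signals):
            f.write(_edf_field("", 80))  # prefiltering
        for r in recordings:
            f.write(_edf_field(str(int(round(r.rate_hz))), 8))
        f.write(_edf_field(str(ann_samples_per_record), 8))
        for _ in range(n_signals):
            f.write(_edf_field("", 32))

        for rec_i in range(n_records):
            for r, dig in zip(recordings, digital):
                spr = int(round(r.rate_hz))
                f.write(dig[rec_i * spr : (rec_i + 1) * spr].tobytes())
            f.write(ann_records[rec_i].ljust(ann_len, b"\x00"))


def read_edf(path: str | os.PathLike) -> list[Recording]:
    """Read an EDF/EDF+ file into one :class:`Recording` per signal.

    Physical units and sampling rate come from the header; an annotation
    whose description is ``"injection"`` populates ``t_injection_s`` on every
    returned recording.  A malformed or truncated file raises ``ValueError``.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for bad headers
        raise ValueError(f"not a readable EDF file: {path} ({exc})") from exc

    t_inj: float | None = None
    for ann in raw.annotations:
        if str(ann["description"]).strip().lower() == "injection":
            t_inj = float(ann["onset"])
            break

    orig_units = getattr(raw, "_orig_units", {}) or {}
    out: list[Recording] = []
    data = raw.get_data()  # SI units (V for voltage channels)
    for idx, name in enumerate(raw.ch_names):
        unit = str(orig_units.get(name, "")) or "uV"
        x = data[idx]
        u = unit.replace("µ", "u").lower()
        if u in ("uv", "µv"):
            x = x * 1e6
        elif u == "mv":
            x = x * 1e3
        elif u == "v":
            pass
        out.append(
            Recording(
                samples=np.asarray(x, dtype=np.float64),
                rate_hz=float(raw.info["sfreq"]),
                label=name,
                units=unit,
                t_injection_s=t_inj,
            )
        )
    return out


def read_csv_signal(path: str | os.PathLike, rate_hz: float, units: str, label: str = "signal") -> Recording:
    """Read a one-column CSV of samples; an optional non-numeric header row is skipped."""
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            if "," in line:
                raise ValueError(f"{path}:{lineno}: expected a single column, got {line!r}")
            try:
                values.append(float(line))
            except ValueError:
                if lineno == 1:  # header row tolerated
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric value {line!r}") from None
    return Recording(np.asarray(values), rate_hz=rate_hz, label=label, units=units)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def _summary_rows(animal_summaries: Iterable) -> list[dict]:
    rows = []
    for s in animal_summaries:
        for window in WINDOW_NAMES:
            for band in list(s.median_band_power.get(window, {})) or []:
                rows.append(
                    {
                        "animal_id": s.animal_id,
                        "group": s.group,
                        "window": window,
                        "band": band,
                        "median_band_power": s.median_band_power[window][band],
                        "median_peak_freq_hz": s.median_peak_freq_hz.get(window, {}).get(band),
                        "peak_st_mv": s.peak_st_mv.get(window),
                        "total_median_power": s.total_median_power.get(window),
                    }
                )
    return rows


def _test_rows(cohort_result) -> list[dict]:
    rows = []
    for t in cohort_result.paired_tests:
        rows.append(
            {
                "kind": "wilcoxon",
                "measure": t.measure,
                "band": t.band,
                "comparison": f"{t.window_pair[0]}-vs-{t.window_pair[1]}",
                "n": t.n_pairs,
                "statistic": t.w,
                "p": t.p_two_sided,
                "direction": t.direction,
                "significant": bool(t.p_two_sided <= cohort_result.alpha),
            }
        )
    for c in cohort_result.correlations:
        rows.append(
            {
                "kind": "pearson",
                "measure": "relative_change_vs_st",
                "band": c.band,
                "comparison": c.window,
                "n": c.n,
                "statistic": c.r,
                "p": c.p_two_sided,
                "direction": int(np.sign(c.r)) if np.isfinite(c.r) else 0,
                "significant": bool(c.p_two_sided <= cohort_result.alpha),
            }
        )
    return rows


def write_results(cohort_result, animal_summaries, path_prefix: str | os.PathLike, force: bool = False) -> dict:
    """Write per-animal summaries and test statistics.

    Emits ``<prefix>_animals.csv``, ``<prefix>_tests.csv`` and
    ``<prefix>.json`` (a bundle holding both tables plus the group label and
    alpha).  Refuses to overwrite existing files unless ``force``.
    Returns the JSON bundle as a dict.
    """
    import pandas as pd

    prefix = os.fspath(path_prefix)
    paths = [f"{prefix}_animals.csv", f"{prefix}_tests.csv", f"{prefix}.json"]
    if not force:
        for p in paths:
            if os.path.exists(p):
                raise FileExistsError(f"{p} exists; pass force=True (--force) to overwrite")

    a_rows = _summary_rows(animal_summaries)
    t_rows = _test_rows(cohort_result)
    a_cols = [
        "animal_id", "group", "window", "band", "median_band_power",
        "median_peak_freq_hz", "peak_st_mv", "total_median_power",
    ]
    t_cols = ["kind", "measure", "band", "comparison", "n", "statistic", "p", "direction", "significant"]
    pd.DataFrame(a_rows, columns=a_cols).to_csv(paths[0], index=False)
    pd.DataFrame(t_rows, columns=t_cols).to_csv(paths[1], index=False)

    def _clean(v):
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        if isinstance(v, float) and not math.isfinite(v):
            return None
        return v

    bundle = {
        "group": cohort_result.group,
        "alpha": cohort_result.alpha,
        "animal_summaries": [{k: _clean(v) for k, v in r.items()} for r in a_rows],
        "tests": [{k: _clean(v) for k, v in r.items()} for r in t_rows],
    }
    with open(paths[2], "w", encoding="utf-8") as f:
        json.dump(bundle, f, indent=1)
    return bundle
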