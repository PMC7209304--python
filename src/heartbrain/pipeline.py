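"""End-to-end orchestration: simulate/load → preprocess → spectral + ECG → statistics.

``run_pipeline`` is deterministic given its config (all randomness is seeded
from ``config.seed``) and writes per-animal summary and statistics tables
plus a JSON bundle echoing the config and per-stage audit counts (epochs
total/rejected, beats total/quality-failed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import ecg_analysis as ecg_mod
from . import preprocessing as prep
from . import signal_io
from . import spectral_analysis as spec_mod
from . import synthetic_data as synth
from .group_statistics import CohortResult, summarize_cohort
from .signal_io import Recording, TimeWindowSpec, WINDOW_NAMES
from .spectral_analysis import DEFAULT_BANDS, AnimalSummary

logger = logging.getLogger("heartbrain")

__all__ = ["PipelineConfig", "analyze_animal", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serialisable for provenance.

    Either ``simulate_group`` is set (a synthetic cohort is generated) or
    ``input_dir`` points to per-animal EDF files each holding an ECOG and an
    ECG channel with an ``injection`` annotation.
    """

    simulate_group: str | None = "experimental"
    n_animals: int = 6
    seed: int = 1
    input_dir: str | None = None
    rate_hz: float | None = None          # None: the preset's 512 Hz
    window_scale: float = 1.0             # proportional shrink of all windows
    preset_overrides: dict = field(default_factory=dict)
    epoch_len_s: float = 60.0
    reject_threshold_uv: float = 500.0
    hp_hz: float = 0.3
    lp_hz: float = 100.0
    notch_hz: float | None = 50.0
    spec_window_len_s: float = 2.0
    spec_overlap_s: float = 0.5
    bands: dict = field(default_factory=dict)  # name -> [f_low, f_high]; empty = canonical
    alpha: float = 0.05
    manual_exclusions: dict = field(default_factory=dict)  # animal_id -> window -> [indices]
    output_prefix: str | None = None
    force_overwrite: bool = False

    def validate(self) -> None:
        if (self.simulate_group is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulate_group / input_dir must be set")
        if self.simulate_group is not None and self.simulate_group not in ("experimental", "control"):
            raise ValueError(f"unknown group {self.simulate_group!r}")
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        if not 0 < self.window_scale <= 1:
            raise ValueError("window_scale must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def band_definitions(self) -> dict[str, spec_mod.BandDefinition]:
        if not self.bands:
            return DEFAULT_BANDS
        return {
            name: spec_mod.BandDefinition(name, float(lo), float(hi))
            for name, (lo, hi) in self.bands.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def _window_peak_freqs(
    rec: Recording,
    span: tuple[float, float],
    epochs: prep.EpochSet,
    bands: dict[str, spec_mod.BandDefinition],
) -> dict[str, float | None]:
    """Median per-band peak frequency over all 1-s blocks, one shared PSD pass."""
    n = int(round(rec.rate_hz))
    eps = 1e-9
    blocks = []
    for start, keep in zip(epochs.starts_s, epochs.retained):
        if not keep or start < span[0] - eps or start + epochs.epoch_len_s > span[1] + eps:
            continue
        i0 = int(round(start * rec.rate_hz))
        for b in range(int(np.floor(epochs.epoch_len_s + 1e-9))):
            seg = rec.samples[i0 + b * n : i0 + (b + 1) * n]
            if seg.size == n:
                blocks.append(seg)
    if not blocks:
        return {name: None for name in bands}
    arr = np.asarray(blocks)
    arr = arr[np.any(arr != 0, axis=1)]
    if arr.size == 0:
        return {name: None for name in bands}
    freqs, psd = spec_mod._batch_periodogram(arr, rec.rate_hz)
    return {
        name: float(np.median(spec_mod._peak_in_band(freqs, psd, band)))
        for name, band in bands.items()
    }


def analyze_animal(
    animal_id: str,
    group: str,
    ecog: Recording,
    ecg: Recording,
    windows: dict[str, TimeWindowSpec],
    config: PipelineConfig,
    bands: dict[str, spec_mod.BandDefinition] | None = None,
) -> AnimalSummary:
    """Full single-animal analysis producing an :class:`AnimalSummary`."""
    bands = bands if bands is not None else config.band_definitions()
    filtered = prep.apply_filters(ecog, config.hp_hz, config.lp_hz, config.notch_hz)
    summary = AnimalSummary(animal_id=animal_id, group=group)
    manual = config.manual_exclusions.get(animal_id, {})

    for name in WINDOW_NAMES:
        if name not in windows:
            continue
        w = windows[name]
        epochs = prep.segment_epochs(filtered, w, config.epoch_len_s)
        if epochs.empty_window:
            logger.warning("%s: window %s outside recording; skipped", animal_id, name)
            continue
        epochs = prep.reject_noisy_epochs(filtered, epochs, config.reject_threshold_uv)
        if manual.get(name):
            epochs = prep.mark_manual(epochs, manual[name])
        summary.n_epochs[name] = epochs.n_epochs
        summary.n_epochs_rejected[name] = epochs.n_epochs - epochs.n_retained

        span = filtered.window_span(w)
        sg = spec_mod.compute_spectrogram(
            filtered.samples[int(round(span[0] * filtered.rate_hz)) : int(round(span[1] * filtered.rate_hz))],
            rate_hz=filtered.rate_hz,
            window_len_s=config.spec_window_len_s,
            overlap_s=config.spec_overlap_s,
            t_offset_s=span[0],
        )
        summary.median_band_power[name] = {}
        for bname, band in bands.items():
            series = spec_mod.band_power_series(sg, band, epochs)
            summary.median_band_power[name][bname] = spec_mod.median_band_power(
                series, span, config.spec_window_len_s
            )
        summary.total_median_power[name] = spec_mod.total_median_power(sg, epochs, span)
        summary.median_peak_freq_hz[name] = _window_peak_freqs(filtered, span, epochs, bands)

    peaks = ecg_mod.detect_r_peaks(ecg)
    series = ecg_mod.st_series(ecg, peaks, baseline_window=windows.get("B"))
    n_quality = int(series.n_beats.sum()) if series.n_beats.size else 0
    logger.info("%s: %d beats detected, %d quality", animal_id, peaks.size, n_quality)
    for name in WINDOW_NAMES:
        if name in windows:
            summary.peak_st_mv[name] = ecg_mod.peak_st_elevation(series, windows[name])
    summary.st_onset_min = ecg_mod.detect_st_onset(series) if np.isfinite(series.baseline_sd_mv) else None
    return summary


def _load_animals(config: PipelineConfig):
    """Yield (animal_id, group, ecog, ecg, windows) from EDF files in input_dir."""
    files = sorted(
        f for f in os.listdir(config.input_dir) if f.lower().endswith(".edf")
    )
    if not files:
        raise ValueError(f"no EDF files in {config.input_dir}")
    windows = signal_io.session_windows(config.window_scale)
    for fname in files:
        recs = signal_io.read_edf(os.path.join(config.input_dir, fname))
        ecog = next((r for r in recs if "ecog" in r.label.lower() or "eeg" in r.label.lower()), None)
        ecg = next((r for r in recs if r is not ecog and "ecg" in r.label.lower()), None)
        if ecog is None or ecg is None:
            raise ValueError(f"{fname}: need one ECOG and one ECG channel, got {[r.label for r in recs]}")
        if ecog.t_injection_s is None:
            raise ValueError(f"{fname}: missing injection timestamp (annotation or config)")
        animal_id = os.path.splitext(fname)[0]
        yield animal_id, "unknown", ecog, ecg, windows


def run_pipeline(config: PipelineConfig) -> tuple[CohortResult, list[AnimalSummary]]:
    """Run the configured cohort end to end; optionally write result tables."""
    config.validate()
    summaries: list[AnimalSummary] = []

    if config.simulate_group is not None:
        preset = synth.make_preset(config.simulate_group, config.preset_overrides)
        windows = signal_io.session_windows(config.window_scale)
        cohort = synth.generate_cohort(
            preset, config.n_animals, config.seed, windows=windows, rate_hz=config.rate_hz
        )
        for a in cohort:
            summaries.append(
                analyze_animal(a.animal_id, a.group, a.ecog, a.ecg, a.windows, config)
            )
        group = config.simulate_group
    else:
        group = "unknown"
        for animal_id, grp, ecog, ecg, windows in _load_animals(config):
            summaries.append(analyze_animal(animal_id, grp, ecog, ecg, windows, config))

    result = summarize_cohort(
        summaries, bands=tuple(config.band_definitions()), alpha=config.alpha
    )
    result.group = group

    if config.output_prefix:
        bundle = signal_io.write_results(
            result, summaries, config.output_prefix, force=config.force_overwrite
        )
        bundle["config"] = config.to_dict()
        bundle["audit"] = {
            s.animal_id: {
                "epochs_total": s.n_epochs,
                "epochs_rejected": s.n_epochs_rejected,
                "st_onset_min": s.st_onset_min,
            }
            for s in summaries
        }
        with open(f"{config.output_prefix}.json", "w", encoding="utf-8") as f:
            json.dump(bundle, f, indent=1)
    return result, summaries
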