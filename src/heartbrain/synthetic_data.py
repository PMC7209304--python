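"""Synthetic ECoG/ECG cohorts with the reported myocardial-infarction effect structure.

The generator emulates the study conditions this pipeline analyses: per
animal, a baseline hour, four post-injection hours and a day-2 hour of
parallel cortical (ECoG, μV) and cardiac (ECG, mV) signal at 512 Hz.  The
ECoG is 1/f "pink" background plus band-limited Gaussian noise components in
the four canonical EEG bands (filtered noise rather than pure tones, so
spectrogram statistics resemble real EEG); multiplicative per-window
amplitude gains encode the reported band-power pattern — theta elevated in
the first post-injection hour (H1), alpha in hours 2–4 (D1), beta in both,
nothing on day 2 — and the theta component's centre frequency shifts upward
in H1.  The ECG is a train of parametric P-QRS-T template beats; from
``st_onset_s`` (default 840 s ≈ 14 min) the ST segment is offset by the
animal's ST magnitude, ramped in over 60 s and sustained to the end of
day 1.

Across a cohort, per-animal ST magnitudes are drawn from Uniform(0.1, 0.4)
mV and the per-animal increments to the elevated band gains are a linear
function of the standardised ST magnitude plus Gaussian noise — the
heart-brain coupling that downstream correlation analysis recovers.

Recordings are stored in *session time*: the day-2 hour follows the day-1
session contiguously (a sample array cannot carry the 20-h pause), so the
generator's window table places D2 at [14400, 18000) s after injection.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .signal_io import Recording, TimeWindowSpec, WINDOW_NAMES, session_windows

__all__ = [
    "SyntheticPreset",
    "AnimalDataset",
    "make_preset",
    "generate_ecog",
    "generate_ecg",
    "generate_cohort",
    "inject_artifacts",
]

_BANDS_HZ = {"delta": (0.5, 4.0), "theta": (4.0, 7.0), "alpha": (7.0, 13.0), "beta": (13.0, 35.0)}
_THETA_HALF_WIDTH_HZ = 0.4  # half-width of the narrowband theta component


def _unit_gains() -> dict[str, dict[str, float]]:
    return {band: {w: 1.0 for w in WINDOW_NAMES} for band in _BANDS_HZ}


@dataclass
class SyntheticPreset:
    """Parameters of the synthetic cohort generator.

    ``window_gains[band][window]`` are amplitude gains (power scales as
    gain²); a control preset is the identity everywhere with zero ST
    magnitude.  ``coupling_c`` is the slope linking the standardised
    per-animal ST magnitude to the increments added to every elevated band
    gain; ``coupling_noise_sd`` is the SD of the Gaussian noise on those
    increments.
    """

    group: str = "experimental"
    window_gains: dict[str, dict[str, float]] = field(default_factory=_unit_gains)
    theta_center_hz: dict[str, float] = field(
        default_factory=lambda: {w: 5.0 for w in WINDOW_NAMES}
    )
    st_onset_s: float = 840.0
    st_magnitude_mv: float = 0.25
    st_ramp_s: float = 60.0
    coupling_c: float = 0.3
    coupling_noise_sd: float = 0.1
    background_sd_uv: float = 15.0
    pink_alpha: float = 1.0
    band_sd_uv: dict[str, float] = field(
        default_factory=lambda: {"delta": 30.0, "theta": 20.0, "alpha": 15.0, "beta": 20.0}
    )
    heart_rate_bpm: float = 400.0
    ecg_noise_sd_mv: float = 0.01
    rate_hz: float = 512.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("experimental", "control"):
            raise ValueError(f"group must be experimental or control, got {self.group!r}")
        for band, per_window in self.window_gains.items():
            for w, g in per_window.items():
                if g < 0:
                    raise ValueError(f"window_gains[{band}][{w}] must be >= 0, got {g}")
        for w, c in self.theta_center_hz.items():
            if not 4.0 <= c < 7.0:
                raise ValueError(f"theta_center_hz[{w}]={c} must lie in [4, 7) Hz")
        if not self.st_onset_s > 0:
            raise ValueError("st_onset_s must be > 0")
        if self.group == "control":
            if self.st_magnitude_mv != 0:
                raise ValueError("control preset must have st_magnitude_mv = 0")
            for band, per_window in self.window_gains.items():
                for w, g in per_window.items():
                    if g != 1.0:
                        raise ValueError(f"control preset must have unit gains ({band}/{w} = {g})")


@dataclass
class TrueParams:
    """Per-animal ground truth retained for recovery tests."""

    preset: SyntheticPreset
    st_magnitude_mv: float
    gain_increment: float


@dataclass
class AnimalDataset:
    animal_id: str
    group: str
    ecog: Recording
    ecg: Recording
    true_params: TrueParams
    windows: dict[str, TimeWindowSpec]

    def __post_init__(self) -> None:
        if self.ecog.t_injection_s != self.ecg.t_injection_s:
            raise ValueError("ECoG and ECG must share the injection timestamp")


def make_preset(group: str, overrides: dict | None = None) -> SyntheticPreset:
    """Default preset for a group, with field overrides.

    The experimental default encodes the reported pattern: theta gain > 1 in
    H1 only, alpha in D1 only, beta in H1 and D1, unit gains in D2, and a
    theta centre upshift (5.0 → 5.75 Hz) in H1.  The control default is the
    identity.  ``overrides`` must reference existing preset fields; nested
    dicts (gains, centres) are replaced wholesale.
    """
    if group == "experimental":
        gains = _unit_gains()
        gains["theta"]["H1"] = 1.8
        gains["alpha"]["D1"] = 1.8
        gains["beta"]["H1"] = 2.0
        gains["beta"]["D1"] = 2.0
        preset = SyntheticPreset(
            group="experimental",
            window_gains=gains,
            theta_center_hz={"B": 5.0, "H1": 5.75, "D1": 5.0, "D2": 5.0},
        )
    elif group == "control":
        preset = SyntheticPreset(group="control", st_magnitude_mv=0.0)
    else:
        raise ValueError(f"unknown group {group!r}")

    if overrides:
        known = {f.name for f in dataclasses.fields(SyntheticPreset)}
        for key in overrides:
            if key not in known:
                raise KeyError(f"unknown preset field {key!r}")
        preset = dataclasses.replace(preset, **copy.deepcopy(overrides))
    return preset


def _normalize_windows(windows) -> dict[str, TimeWindowSpec]:
    if isinstance(windows, dict):
        ws = dict(windows)
    else:
        ws = {w.name: w for w in windows}
    if not ws:
        raise ValueError("empty window list")
    return ws


def _timeline(windows: dict[str, TimeWindowSpec], rate_hz: float):
    t_lo = min(w.start_s for w in windows.values())
    t_hi = max(w.end_s for w in windows.values())
    n = int(round((t_hi - t_lo) * rate_hz))
    return t_lo, t_hi, n


def _pink_noise(rng: np.random.Generator, n: int, alpha: float, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _bandlimited_noise(white: np.ndarray, f_lo: float, f_hi: float, rate_hz: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a brick-wall spectrum on [f_lo, f_hi).

    Hard band edges keep each component's power inside its own analysis
    band (an IIR transition band would smear power across the half-open
    band boundaries).
    """
    n = white.size
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    spec[(freqs < f_lo) | (freqs >= min(f_hi, 0.99 * rate_hz / 2.0))] = 0.0
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    return x / s if s > 0 else x


def _gain_profile(
    n: int, rate_hz: float, t_lo: float, windows: dict[str, TimeWindowSpec], per_window: dict[str, float]
) -> np.ndarray:
    prof = np.ones(n)
    for name, w in windows.items():
        g = per_window.get(name, 1.0)
        if g != 1.0:
            i0 = max(0, int(round((w.start_s - t_lo) * rate_hz)))
            i1 = min(n, int(round((w.end_s - t_lo) * rate_hz)))
            prof[i0:i1] = g
    return prof


def generate_ecog(
    preset: SyntheticPreset, windows, seed: int, rate_hz: float | None = None
) -> Recording:
    """Synthesize the cortical channel over the span of ``windows``.

    1/f^alpha background plus per-band band-limited Gaussian noise, the
    theta component centred at the window's ``theta_center_hz`` and every
    component scaled by its window gain.  Deterministic given
    (preset, windows, seed); units μV, rate ``preset.rate_hz`` unless
    overridden.
    """
    ws = _normalize_windows(windows)
    fs = float(rate_hz if rate_hz is not None else preset.rate_hz)
    t_lo, t_hi, n = _timeline(ws, fs)
    rng = np.random.default_rng(np.random.SeedSequence([1001, preset.seed, int(seed)]))

    x = _pink_noise(rng, n, preset.pink_alpha, preset.background_sd_uv)

    for band, (f_lo, f_hi) in _BANDS_HZ.items():
        sd = preset.band_sd_uv.get(band, 0.0)
        if sd <= 0:
            continue
        gains = preset.window_gains.get(band, {})
        if band == "theta":
            # centre frequency may differ per window: filter the same white
            # noise per distinct centre and splice window segments together.
            # The component band is clipped 0.85 Hz short of the alpha
            # boundary so an upshifted centre cannot bleed power into the
            # 7-Hz bins through the 2-s Hann main lobe (calibrated against
            # the spectrogram resolution, not against any test outcome).
            white = rng.standard_normal(n)
            comp = np.zeros(n)
            centers = {name: preset.theta_center_hz.get(name, 5.0) for name in ws}
            filtered_by_center: dict[float, np.ndarray] = {}
            default_center = 5.0
            for c in set(centers.values()) | {default_center}:
                lo = max(f_lo, c - _THETA_HALF_WIDTH_HZ)
                hi = min(f_hi - 0.85, c + _THETA_HALF_WIDTH_HZ)
                filtered_by_center[c] = _bandlimited_noise(white, lo, hi, fs)
            comp[:] = filtered_by_center[default_center]
            for name, w in ws.items():
                i0 = max(0, int(round((w.start_s - t_lo) * fs)))
                i1 = min(n, int(round((w.end_s - t_lo) * fs)))
                comp[i0:i1] = filtered_by_center[centers[name]][i0:i1]
        else:
            comp = _bandlimited_noise(rng.standard_normal(n), f_lo, f_hi, fs)
        x += comp * sd * _gain_profile(n, fs, t_lo, ws, gains)

    return Recording(x, rate_hz=fs, label="ECOG", units="uV", t_injection_s=-t_lo)


# --- ECG template ----------------------------------------------------------
#
# Parametric rodent beat: P, Q, R, S and T as Gaussian lobes on a 150-ms
# nominal beat (400 bpm), compressed proportionally at faster rates.  Times
# in ms from beat start.
_TEMPLATE_LOBES = (  # (centre_ms, sd_ms, amplitude_mv)
    (8.0, 3.0, 0.07),     # P
    (52.0, 2.5, -0.12),   # Q
    (58.0, 3.0, 1.0),     # R
    (64.0, 2.5, -0.30),   # S
    (125.0, 7.0, 0.25),   # T
)
_TEMPLATE_SPAN_MS = 147.0
_ST_REGION_MS = (70.0, 112.0)  # J point to T onset
_ST_TAPER_MS = 4.0


def _ecg_template(fs: float, rr_s: float):
    """Beat template and ST-offset mask at rate ``fs`` for beat period ``rr_s``.

    The template is compressed so it occupies at most 92% of the beat
    period, leaving room for inter-beat timing jitter.
    """
    c = min(1.0, 0.92 * (rr_s * 1000.0) / _TEMPLATE_SPAN_MS)
    span = _TEMPLATE_SPAN_MS * c
    n = min(int(round(rr_s * fs)), int(round(span / 1000.0 * fs)))
    t_ms = np.arange(n) / fs * 1000.0
    beat = np.zeros(n)
    for mu, sd, amp in _TEMPLATE_LOBES:
        beat += amp * np.exp(-0.5 * ((t_ms - mu * c) / (sd * c)) ** 2)
    lo, hi = _ST_REGION_MS[0] * c, _ST_REGION_MS[1] * c
    taper = _ST_TAPER_MS * c
    mask = np.clip((t_ms - lo) / taper, 0, 1) * np.clip((hi - t_ms) / taper, 0, 1)
    return beat, np.clip(mask, 0, 1)


def generate_ecg(
    preset: SyntheticPreset, windows, seed: int, rate_hz: float | None = None
) -> Recording:
    """Synthesize the cardiac channel over the span of ``windows``.

    Template beats at ``heart_rate_bpm`` (rat physiological range 250–500,
    enforced) with per-beat timing jitter; from ``st_onset_s`` after the
    injection the ST segment is offset by ``st_magnitude_mv``, ramped to
    full over ``st_ramp_s`` and sustained until the end of the day-1
    windows; additive measurement noise.  Units mV.
    """
    ws = _normalize_windows(windows)
    if "B" not in ws:
        raise ValueError("windows must include the baseline window B")
    if not 250 <= preset.heart_rate_bpm <= 500:
        raise ValueError(
            f"heart_rate_bpm={preset.heart_rate_bpm} outside the rat physiological range [250, 500]"
        )
    fs = float(rate_hz if rate_hz is not None else preset.rate_hz)
    t_lo, t_hi, n = _timeline(ws, fs)
    rng = np.random.default_rng(np.random.SeedSequence([2002, preset.seed, int(seed)]))

    rr_s = 60.0 / preset.heart_rate_bpm
    beat, st_mask = _ecg_template(fs, rr_s)
    blen = beat.size
    period_f = rr_s * fs  # samples, non-integral in general

    # integer beat lengths whose running mean tracks the exact period
    # (error diffusion), plus zero-mean jitter bounded so beats never overlap
    n_beats = int(np.ceil(n / period_f)) + 2
    base = int(np.floor(period_f))
    frac = period_f - base
    k = np.arange(n_beats)
    extra = (np.floor((k + 1) * frac) - np.floor(k * frac)).astype(int)
    jmax = max(0, (base - blen) // 2)
    jitter = rng.integers(-jmax, jmax + 1, size=n_beats) if jmax else np.zeros(n_beats, int)
    lengths = np.maximum(blen, base + extra + jitter)
    starts = np.concatenate([[0], np.cumsum(lengths[:-1])])
    keep = starts + blen <= n
    starts = starts[keep]

    # ST offset per beat: ramp in after onset, sustained through day 1
    t_beat = starts / fs + t_lo  # seconds relative to injection
    day1_end = max((w.end_s for name, w in ws.items() if name in ("H1", "D1")), default=t_hi)
    ramp = np.clip((t_beat - preset.st_onset_s) / max(preset.st_ramp_s, 1e-9), 0.0, 1.0)
    ramp[t_beat >= day1_end] = 0.0
    offsets = preset.st_magnitude_mv * ramp

    x = np.zeros(n)
    idx = starts[:, None] + np.arange(blen)[None, :]
    x[idx.reshape(-1)] = (beat[None, :] + st_mask[None, :] * offsets[:, None]).reshape(-1)

    x += preset.ecg_noise_sd_mv * rng.standard_normal(n)
    # slow baseline wander, well below the QRS band
    t = np.arange(n) / fs
    x += 0.02 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))

    return Recording(x, rate_hz=fs, label="ECG", units="mV", t_injection_s=-t_lo)


def generate_cohort(
    preset: SyntheticPreset,
    n: int,
    seed: int,
    windows=None,
    rate_hz: float | None = None,
) -> list[AnimalDataset]:
    """Generate ``n`` animals with coupled per-animal effect sizes.

    Experimental animals draw their ST magnitude from Uniform(0.1, 0.4) mV;
    the increment added to every elevated band gain (cells with preset gain
    > 1) is ``coupling_c * z(ST) + N(0, coupling_noise_sd)`` with z the
    within-cohort standardised ST magnitude.  Control animals have zero ST
    magnitude and zero increments.  Ground truth is kept in ``true_params``.
    """
    if n < 2:
        raise ValueError("need n >= 2 animals (paired statistics undefined below)")
    ws = _normalize_windows(windows if windows is not None else session_windows())
    missing = set(WINDOW_NAMES) - set(ws)
    if missing:
        raise ValueError(f"cohort windows must include all of {WINDOW_NAMES}; missing {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence([3003, preset.seed, int(seed)]))
    if preset.group == "experimental":
        st_mags = rng.uniform(0.1, 0.4, size=n)
        z = (st_mags - st_mags.mean()) / st_mags.std()
        incr = preset.coupling_c * z + rng.normal(0.0, preset.coupling_noise_sd, size=n)
    else:
        st_mags = np.zeros(n)
        incr = np.zeros(n)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=(n, 2))

    animals: list[AnimalDataset] = []
    for i in range(n):
        gains = copy.deepcopy(preset.window_gains)
        for band, per_window in gains.items():
            for w, g in per_window.items():
                if g > 1.0:
                    per_window[w] = max(0.05, g + float(incr[i]))
        preset_i = dataclasses.replace(
            preset,
            window_gains=gains,
            st_magnitude_mv=float(st_mags[i]),
        )
        ecog = generate_ecog(preset_i, ws, int(sub_seeds[i, 0]), rate_hz=rate_hz)
        ecg = generate_ecg(preset_i, ws, int(sub_seeds[i, 1]), rate_hz=rate_hz)
        animals.append(
            AnimalDataset(
                animal_id=f"{preset.group}_{i + 1:02d}",
                group=preset.group,
                ecog=ecog,
                ecg=ecg,
                true_params=TrueParams(preset_i, float(st_mags[i]), float(incr[i])),
                windows=ws,
            )
        )
    return animals


def inject_artifacts(
    rec: Recording, times: list[float], amplitude: float, duration_s: float = 0.1
) -> Recording:
    """Add short raised-cosine transients of peak ``amplitude`` at ``times``.

    ``times`` are seconds from recording start and must lie inside the
    recording span; the original recording is left untouched.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    x = rec.samples.copy()
    npulse = max(3, int(round(duration_s * rec.rate_hz)))
    pulse = amplitude * 0.5 * (1 - np.cos(2 * np.pi * np.arange(npulse) / (npulse - 1)))
    for t in times:
        i0 = int(round(t * rec.rate_hz))
        if not (0 <= i0 and i0 + npulse <= x.size):
            raise ValueError(f"artifact time {t} s outside the recording span [0, {rec.duration_s}]")
        x[i0 : i0 + npulse] += pulse
    return rec.copy_with(x)
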