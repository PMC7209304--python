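# Methods

`heartbrain` implements a parallel ECoG/ECG analysis of pharmacologically
induced acute myocardial infarction (AMI) in rats: isoprenaline, a
peripherally acting beta-adrenergic agonist, produces myocardial necrosis
whose electrocardiographic signature is ST-segment elevation, while a
prefrontal ECoG channel tracks the cortical response.  The package covers
the full chain — signal conditioning, epoching and artifact rejection,
time–frequency band power, peak-frequency estimation, ST quantification,
and the small-n statistics that couple heart and brain — plus a synthetic
cohort generator that encodes the studied effect structure so every stage
is testable without animal data.

## Analysis windows and conventions

Recordings are anchored to the injection time; all windows are in seconds
relative to it:

| window | meaning                        | default span (s)   |
|--------|--------------------------------|--------------------|
| B      | baseline hour                  | [−3600, 0)         |
| H1     | first post-injection hour      | [0, 3600)          |
| D1     | post-injection hours 2–4       | [3600, 14400)      |
| D2     | hour recorded 24 h later       | [86400, 90000)     |

Sample indexing is 0-based with half-open intervals.  Synthetic recordings
are stored in *session time*: the day-2 hour follows the day-1 session
contiguously (a sample array cannot represent the 20-h pause), so the
generator's window table places D2 at [14400, 18000).  For real EDF data
the real-time table above applies.  `session_windows(scale)` shrinks every
window proportionally for reduced-size runs; scaling changes only the
amount of data per window, never a filter, band, threshold or statistic.

## Preprocessing

The acquisition chain is emulated digitally: zero-phase (forward–backward)
Butterworth band-pass, order 4, corners 0.3 and 100 Hz, plus a 50 Hz notch
(order 2, Q = 30).  Zero-phase filtering is chosen so epoch boundaries are
not shifted; the corner frequencies are the analog-filter settings of the
recording chain.  Continuous ECoG is segmented into non-overlapping 60-s
epochs per window (trailing remainder dropped) and an epoch is rejected
when any single filtered sample exceeds 500 μV in absolute value.  The
comparison is strict (an epoch peaking exactly at 500 μV is retained) and
single-sample, the literal reading of an "exceeding 500 μV" criterion;
whether the original criterion was peak-to-peak, or applied before
digital filtering, is not recoverable, so the simplest testable rule was
fixed.  Visual artifact screening is modelled as an explicit per-window
exclusion-index list — reproducibility over interactivity.

## Spectral analysis

Time–frequency power is a short-time Fourier spectrogram: 2-s Hann window,
0.5-s overlap read literally (hop 1.5 s, configurable to fractional overlap),
density scaling (μV²/Hz), no detrending.  Band power per frame is the mean
over spectrogram bins inside the band; bands are half-open —
delta [0.5, 4), theta [4, 7), alpha [7, 13), beta [13, 35) — so the shared
edges 4, 7 and 13 Hz belong to exactly one band.  A frame enters a window's
summary only if its full 2-s taper interval lies inside a retained epoch
inside the window; the summary is the median over those frames ("total"
power uses the broadband interval [0.5, 35)).  Medians are robust to the
heavy right tail of few-bin χ² power estimates; note the consequence that
for a band dominated by a very narrow component the median of H1/B band
power sits below the mean-power ratio gain², while for bands wider than a
few bins the two agree (the beta gain-2 recovery test asserts gain² ± 15%).

Peak frequency per 1-s epoch is the argmax of a single Hann-tapered
periodogram over the band's bins.  A 1-s epoch has 1-Hz native resolution —
too coarse for sub-Hz theta shifts — so the FFT is zero-padded fourfold,
giving a 0.25-Hz argmax grid; a 1-s segment admits no meaningful Welch
sub-averaging, so one tapered segment per epoch is the estimator.  Ties
break toward the lower frequency (determinism); all-zero segments have no
peak.  The per-window summary is the median over all non-overlapping 1-s
blocks inside retained epochs.

## ECG analysis

R peaks: 15–90 Hz band-passed energy, 20-ms smoothing, adaptive threshold
(relative to the energy distribution, hence amplitude-scale invariant),
60-ms refractory period (rat heart rates reach ~8 beats/s), peak refined to
the local maximum of the mean-removed raw signal.

ST amplitude per beat: mean signal over [J+10 ms, J+30 ms] minus the
isoelectric level, the mean over a 20-ms PR window ending 10 ms before QRS
onset.  J is the first slope-flattening (8-ms run below 8% of the peak QRS
slope) after the S trough; QRS onset is the symmetric backward search from
R.  A fixed-latency J-point rule with a PR isoelectric reference is the
standard rodent convention; beats whose fiducials cannot be located, or
that lack full context at a recording edge, are flagged low-quality and
excluded from aggregates rather than raising.  All quantities are
baseline-relative, hence exactly invariant to a DC offset.

Quality beats are aggregated into per-minute medians (minutes anchored to
the injection; medians rather than means so missed or ectopic-looking beats
do not leak in).  Baseline mean and SD come from complete minutes inside B.
Peak ST elevation per window is the maximum per-minute median minus the
baseline mean.  Onset is the first post-injection minute beginning three
consecutive minutes above baseline mean + 3 SD — sustained elevation, so a
single noisy minute cannot declare an infarction.

## Group statistics

Pairwise window comparisons use an exact two-sided Wilcoxon signed-rank
test: zero differences discarded (the classical rule; Pratt's variant is a
noted alternative), mid-ranks for ties, and the exact sign-flip null
distribution of the positive-rank sum computed by convolution over the rank
multiset (identical to 2^n enumeration, verified against literal
enumeration for n ≤ 10).  At n = 6 the smallest attainable two-sided p is
2/2⁶ = 0.03125: significance at α = 0.05 requires all six animals to move
together, and significance at 0.01 is unattainable.  No multiple-testing
correction is applied by default, mirroring the fixed 0.05 threshold of the
analysis this package reproduces; Holm adjustment can be layered on the
returned p-values.  Correlations relate each animal's peak ST elevation
(maximum over the day-1 windows H1 and D1 — the ST window entering the
original correlations is not stated, and day-1 peak is the natural infarct
size proxy) to the relative band-power change (X−B)/B via the Pearson
coefficient with a t-distributed two-sided p (n−2 df).  Correlations are
computed within groups that show ST variance (a control group with zero ST
everywhere has an undefined correlation and is skipped).

## Synthetic cohorts

The generator defines the study conditions; its defaults are fixed, not
tuned per run.

**ECoG** = 1/f^α pink background (α = 1, SD 15 μV — the canonical EEG-like
spectrum) plus per-band Gaussian noise components with brick-wall spectra
(band-limited noise, not pure tones, so spectrogram statistics resemble
EEG; hard band edges keep each component's power inside its own analysis
band).  Component SDs: delta 30, theta 20, alpha 15, beta 20 μV — band
power well above the background in every band so gain recovery is
unambiguous.  Multiplicative per-window amplitude gains encode the effect
pattern: theta ×1.8 in H1, alpha ×1.8 in D1, beta ×2.0 in H1 and D1, unit
gains everywhere else (in particular all of D2).  The theta component is
narrowband (half-width 0.4 Hz) with centre 5.0 Hz shifting to 5.75 Hz in H1;
the component band is kept ≥ 0.85 Hz below the 7-Hz alpha edge because the
2-s Hann kernel would otherwise smear a near-edge component into the 7-Hz
bins and masquerade as an alpha increase (the guard was set from per-bin
leakage measurements of the spectrogram kernel).  Centres are sub-Hz on the
0.25-Hz peak grid, and upshift recovery is asserted to one grid step.

**ECG** = parametric P-QRS-T template beats (R amplitude 1 mV, rat-like
intervals compressed proportionally at fast rates), heart rate 400 bpm by
default (generator refuses rates outside the physiological 250–500), beat
lengths error-diffused so the mean period is exact, with ±1-sample jitter,
0.01 mV white noise and a small 0.25-Hz baseline wander.  From
`st_onset_s = 840` (≈ 14 min) the segment between J point and T onset is
offset by the animal's ST magnitude, ramped in over 60 s — a discontinuous
onset would make detection trivially exact and unphysiological — and
sustained to the end of day 1 (day 2 is back at baseline).

**Cohorts**: experimental ST magnitudes ~ Uniform(0.1, 0.4) mV (detection
stays unambiguous while leaving correlation spread); the increment added to
every *elevated* band gain is `coupling_c · z(ST) + N(0, coupling_noise_sd)`
with z the within-cohort standardised ST magnitude (defaults 0.3 and 0.1).
Increments touch only cells with preset gain > 1 so null cells (all of D2,
delta everywhere) remain exactly null.  Control animals have unit gains,
zero ST and zero increments.  Ground truth is retained per animal for
recovery tests.  Everything is deterministic given (preset, windows, seed).

What the generator does *not* emulate: behavioural state transitions
(sleep/wake), heart-rate-variability structure, electrode drift, movement
artifacts beyond injected transients, or biophysical cortical/cardiac
dynamics.  Passing tests therefore demonstrate that the pipeline recovers
the encoded effect structure under realistic spectral statistics — not that
it would be robust to every artifact of a live recording.

## Problem sizes

Full-scale conditions are 512 Hz with the table above (six hours of
two-channel signal per animal).  The test suite and the acceptance script
use a reduced profile chosen as the package's standard verification size:
256 Hz sampling (every filter corner still below Nyquist) with
quarter-duration windows (B/H1 900 s, D1 2700 s, D2 900 s) for cohort-level
results, and 1/20-duration windows for the 200-seed control false-positive
simulation.  Only the amount of data per window changes; per-window medians
at quarter scale still average hundreds of spectrogram frames, and measured
effects agree in direction and closely in size with full-scale runs.

## Known limitations

- EDF writing is a minimal EDF+C emitter (16-bit, 1-s records, one
  annotation channel); it round-trips against the reader to within
  quantization but does not cover the full EDF+ feature set.
- The exact Wilcoxon engine enumerates up to n = 25 nonzero differences;
  beyond that a normal approximation would be needed (out of scope for
  6-animal designs).
- ST measurement assumes a positive-R lead convention and template-like
  beat morphology; grossly abnormal morphologies (bundle-branch-like
  beats, fusion beats) would fail quality checks rather than be measured.
- The theta band-power median under-reads gain² when the band is dominated
  by a very narrow component (median vs mean of a skewed distribution);
  directionality and significance are unaffected.
- Synthetic cohorts show two peak-frequency side effects that are artifacts
  of the generator interacting with the coarse 1-s periodogram (1-Hz main
  lobe): the strong H1 theta component leaks into the lowest alpha bins and
  pulls the alpha peak-frequency median toward 7 Hz, and raising a wide
  band's gain flattens the pink-background tilt so the band's argmax median
  shifts upward (visible for beta in H1/D1).  Both can reach significance
  at n = 6.  Only the theta peak shift is an encoded effect; conclusions
  about other bands' peak frequencies should not be drawn from synthetic
  cohorts.
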