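# Methods

This note documents the model assumptions, parameter choices and
numerical conventions of the `leadpop` detector, and what the synthetic
test bed does and does not demonstrate.

## Detection model

The detector treats the six PSG EEG channels as noisy observations of
largely shared cortical activity.  Its working statistic is, per 1 s
segment, the Spearman correlation between the 128-band power vectors of
two channels; an electrode that pops or a movement that disturbs a
single lead replaces that channel's spectrum with something unrelated
to its neighbours, so every pairwise correlation involving the channel
collapses while pairs among the healthy channels are unaffected.
Averaging the five pairwise series per index channel concentrates the
evidence channel-wise.

Two adaptive thresholds classify segments of each average series:

* **Local rule.** Within every 60 s window (1 s slide) a defined
  segment is *bad* when its value is strictly below
  `local_fraction × median(window)`, `local_fraction = 0.5`.  The
  window median tracks the slow, stage-driven drift of absolute
  correlation levels through the night, which is what makes a fixed
  global floor inappropriate for non-stationary sleep EEG.
* **Global rule.** Bad segments are outliers by definition.  The
  remaining *good* pool sets a per-channel floor
  `global_fraction × P(global_percentile)` (defaults ¼ × P75); good
  segments strictly below it are also outliers.  This second pass
  catches isolated deep drops that are too brief to move a window
  median.

Outliers separated by strictly fewer than `merge_gap_s = 300` seconds
are bridged, on the reasoning that lead problems are sustained: two
nearby collapses almost surely belong to one physical event.  A channel
whose merged outliers exceed `channel_exclude_fraction = 5%` of its
post-preprocessing length is removed from all averages and the scan
repeats; this matters because one sick channel depresses the average
series of all five partners.  Exclusion is one channel per iteration
(the worst fraction first); a config switch (`exclusion_mode`)
removes all offenders at once instead.  Termination is guaranteed —
each continuing iteration removes at least one channel — and excluded
channels are re-scored once against the survivors so their annotations
reflect clean references.

## Preprocessing conventions

Re-referencing uses the contralateral mastoid (F3−M2, C3−M2, O1−M2,
F4−M1, C4−M1, O2−M1), the standard AASM derivation.  The notch is a
second-order IIR at 60 Hz (quality factor 30) and the band-pass a
4th-order Butterworth over 0.5–32.5 Hz, both applied
forward–backward (zero phase); the contract is behavioural — ≥ 99%
RMS attenuation at the notch frequency and ≤ 5% RMS error in the
pass-band, verified in tests — not a particular topology.  Non-finite
spans are zero-filled during filtering only and re-masked afterwards,
so NaN cannot contaminate neighbouring samples through the filter
state.

The flat-epoch rule's published wording is ambiguous ("amplitudes one
standard deviation less than 1 μV or less than 0.2 μV for five
consecutive second").  Both clauses are implemented as standard
deviation criteria by default — SD over the 30 s epoch < 1 μV, or SD
within some 5 s sub-window (1 s stride) < 0.2 μV — for parallelism
with the first clause, which is unambiguously an SD rule.  A config
switch (`flat_sub_mode="amplitude"`) reads the second clause as peak
absolute amplitude instead.  The 500 μV amplitude rule is strict
(`> 500` removes; exactly 500 does not).

Epochs removed here are excluded from every correlation pool and from
the denominator of the 5% rule (the channel's "length after
preprocessing").

## Spectral conventions

4 s windows, 3 s overlap, seven DPSS tapers with time-half-bandwidth
NW = 4 (the standard choice for which 2·NW − 1 = 7 tapers have good
energy concentration), uniform taper averaging (eigenvalue-adaptive
weighting deliberately omitted: with NW = 4 the first seven
eigenvalues are all ≈ 1 and the added state makes runs harder to
reproduce).  Power is one-sided PSD in μV²/Hz read off the FFT grid,
which at a 4 s window is exactly 0.25 Hz.  The band grid is the
half-open interval [0.5, 32.5) — centers 0.5, 0.75, …, 32.25 —
giving exactly 128 bands; the closed interval would give 129.

A record of T whole seconds yields T segments, indexed to the initial
second of their window.  The trailing three segments have no complete
4 s window and are emitted but marked invalid, as is any segment whose
window overlaps a removed or non-finite sample.  Invalid segments are
excluded from all pools — they are missing data, not evidence of
artifact.

A segment is judged by the local rule in every window that covers it
(flagged bad if any covering window flags it); `window_membership =
"center"` restricts judgement to the centred window.  Truncated edge
windows are evaluated when they contain at least 30 defined segments.
If a window median is ≤ 0, the local threshold is clamped to 0 so the
"below half the median" comparison cannot invert.  Percentiles use
linear interpolation between closest ranks (the numpy default).
Spearman ranks use mid-ranks for ties, which occur in quantized power
data; a constant power vector has undefined rank correlation and the
segment is treated as undefined rather than ρ = 0.

## Stage-separate mode

`stage_mode = "nrem_rem_separate"` pools NREM (N1+N2+N3) and REM
segments separately: the local/global thresholds and the merge step run
within each pool and the resulting outlier masks are unioned.  Wake and
unscored segments belong to neither pool in this mode.  The default
processes the whole record in one pool.

## Synthetic test bed

The generator emulates exactly the statistical structure the detector
assumes, no more.  Each EEG channel is `gain_c × latent(t) + noise_c(t)`
with per-channel gains drawn from U(0.8, 1.2) (electrode-distance
variation) and independent white noise of SD 3 μV against a latent
signal of roughly 15–45 μV SD, a noise share chosen so that clean
cross-channel spectral correlations sit around 0.9 — comparable to
what the correlation premise requires of real sleep EEG.  The latent
signal is a sum of band-limited Gaussian processes (delta, theta,
alpha, sigma, beta) whose amplitudes switch with the stage of each
30 s epoch (N3 delta-dominant, N2 with raised sigma for spindle-band
power, REM theta-rich, wake alpha/beta-raised).  Mastoids are 2 μV
noise.  The reference fixture ("default night") is 2 h at 256 Hz with
an N2→N3→N2→REM cycle and one 15 min `pop_noise` artifact on C3.

Artifact kinds map to the failure modes the detector targets:
`pop_noise` (independent broadband noise at normal amplitude — the
pure lead-pop signature, invisible to amplitude screens),
`flatline`, `movement_drift` (> 500 μV slow excursions) and
`high_amplitude` (scaled latent).  Ground truth is defined at segment
resolution with the same window convention as the spectrogram: a
segment is truly artifactual iff its 4 s window intersects an
injected interval, which removes off-by-one ambiguity from
sensitivity/specificity.

What passing these tests shows: the pipeline's thresholds, merging,
iteration and bookkeeping recover injected single-channel correlation
collapses with high segment-level accuracy under realistic stage
non-stationarity.  What it does not show: performance on real
recordings, where artifacts have richer morphology (bruxism, arousals,
sweat sway), channels share artifact sources, and the latent-plus-noise
model understates inter-channel spectral diversity.  The generator also
omits K-complex/spindle morphology and ocular contamination by design.

Problem sizes in the shipped test suite and acceptance script — 2 h
nights at 256 Hz, 20 seeds for recovery, 3 clean nights — were chosen
as the smallest sets that exercise multiple sleep cycles and give
stable (±1 segment-level percentage point) recovery statistics.

## Interfaces and formats

EDF reading delegates to MNE (mixed per-channel rates are unified by
the reader); the synthetic module writes plain 16-bit EDF itself, with
a per-channel symmetric physical range, so round trips are exact to
half a quantization step.  Stage files are accepted as one code per
line or as `start duration stage` triples; unknown codes become
`unknown` with a warning.  The output annotation file is tab-separated
7-bit ASCII — `channel, start_s, end_s, n_segments, source` — with
0-based, closed-on-both-ends second intervals, ordered by channel then
start.  All parameters are exposed as CLI flags and as a JSON config
file with `preprocess` / `spectral` / `detection` sections.

## Known limitations

* A disturbance hitting all channels simultaneously preserves
  cross-channel correlation and is invisible to this statistic.
* Artifact edges are localized only to within the 4 s window support
  (≈ 3 s smear).
* The mastoid references are assumed healthy; a popped reference
  contaminates three channels at once and will surface as multiple
  channel exclusions rather than a reference-specific diagnosis.
* With fewer than ~30 defined segments in every window position the
  local rule cannot operate and the record is rejected as having no
  analyzable data.
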