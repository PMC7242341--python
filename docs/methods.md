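# Methods

## Problem and pipeline overview

Focal childhood epilepsies of the Rolandic type localize to the
centrotemporal (CT) electrodes of the 10–20 scalp montage, yet routine
awake EEGs of affected children often look visually normal. The working
hypothesis behind this package is that the epileptogenic region still
carries a measurable *reduction in signal complexity* — more
self-similar, more regular dynamics — detectable with nonlinear
time-series measures even when no spikes are visible.

The pipeline turns that hypothesis into a fixed sequence of computations:

1. **Input.** Multichannel scalp EEG in EDF, 19 electrodes on the
   standard 10–20 montage, with a cohort manifest assigning each subject
   to `case` or `contrast`. One 30-second awake segment per subject is
   selected uniformly at random on a 1-second grid (seeded). No
   filtering and no artifact rejection are applied by default.
2. **Multiscale decomposition.** Each channel segment is split by a
   multilevel DWT (db4, 6 levels by default) into 7 time-domain band
   signals that tile (0, fs/2] dyadically — at 256 Hz: 0–2, 2–4, 4–8,
   8–16, 16–32, 32–64, 64–128 Hz. Bands are per-level reconstructions,
   so they all have the segment's length and sum back to it exactly.
3. **Nonlinear measures per sensor × band.** Sample entropy SampEn(m=2,
   r=0.2·SD, Chebyshev), and recurrence quantification on a delay
   embedding (m=3, τ=1) thresholded at a fixed 10% recurrence rate:
   maximum and mean diagonal line length (Lmax, Lmean), trapping time
   (TT, mean vertical line length), plus DET, LAM, RR and a DFA-1
   scaling exponent as optional extras.
4. **Group statistics.** Per (measure, sensor, group): the multiscale
   curve of per-band means with 95% CIs. Per (measure, subject, sensor):
   the area under the multiscale curve (trapezoid over band index). The
   AUC observations are pooled into four (group × region) cells —
   CT = {C3, C4, Cz, T7, T8, P7, P8}, non-CT = the other 12 — and a
   classical one-way ANOVA (df = 3, n−4) tests the effect of cell.

## Model assumptions and conventions

- **Recurrence thresholding.** The radius ε is calibrated per band
  signal to a target recurrence rate of 0.10 rather than fixed in
  signal units; this removes amplitude-scale differences between
  subjects, sensors and bands. The recurrence rate is a step function of
  ε, so the calibration is solved exactly by an order statistic (the
  smallest pairwise distance whose empirical rate reaches the target);
  this is deterministic and is what a bisection on the step function
  converges to.
- **Theiler window.** Diagonal statistics exclude the band |i−j| < w
  around the line of identity (default w=1: exactly the LOI); vertical
  statistics use the full matrix. Minimum line lengths lmin = vmin = 2.
- **Line-statistic conventions.** Lmax is 0 when no qualifying diagonal
  exists; Lmean and TT are *missing* (NaN) in that case — never zero,
  which would silently bias the AUC downward. DET is the fraction of
  off-Theiler recurrence points on diagonals ≥ lmin; LAM the analogue
  for verticals.
- **Sample entropy.** −ln(A/B) with template pairs counted over i < j
  only (no self-matches), both A and B over the N−m windows whose
  (m+1)-point continuation exists. B = 0 or A = 0 yields a missing
  value with a logged reason; constant signals are an error.
- **Multiscale x-axis.** Band index with unit spacing, not Hz: band
  widths are dyadic, and curves are compared by scale. For fs ≠ 256 the
  nominal Hz ranges follow fs; the index remains the axis.
- **ANOVA unit of analysis.** AUC is computed per subject × sensor and
  those observations fill the four cells. Sensors within a subject are
  correlated, so this is deliberate pseudo-replication, retained because
  the region contrast is defined at the sensor level; the caveat applies
  to any p-value read from the four-cell ANOVA on real data. p-values
  are reported exactly with no multiple-testing correction by default
  (a Bonferroni option exists).
- **Confidence bands.** 95% CI = 1.96·SEM (normal approximation);
  t-based half-widths available via config. A band with one observation
  gets half-width 0 and a logged warning.

## Desk-scale analysis windows

SampEn and recurrence computations are O(N²) in the analyzed length. A
30-s segment at 256 Hz has 7680 samples per band; computing on all of
them for 19 sensors × 7 bands per subject is possible but wasteful,
because both estimators stabilize well below that length. The package
therefore analyzes a contiguous, centered window of each band signal:

- `SampEnConfig.max_samples = 1024` (4 s at 256 Hz). SampEn(m=2,
  r=0.2·SD) is considered reliable from a few hundred samples.
- `RecurrenceConfig.max_points = 400` embedded points. At the 10%
  target rate this leaves ~8,000 recurrence pairs per matrix, ample for
  stable line statistics.

Both caps are configuration fields; `None` analyzes the full signal.
All oracle-equivalence guarantees are independent of the caps (the caps
only choose *which* samples are analyzed, not *how*).

## The synthetic cohort generator

Real clinical EEGs cannot ship with the package, so every stage is
validated against a generator whose ground truth is known by
construction. Each channel is

    x = (1 − w) · n_β + w · s,    n_β ~ 1/f^β noise,  s = jittered sine

with both components standardized to unit variance before mixing and the
result scaled to a 20 µV amplitude. Defaults: β = 1 (pink background,
the canonical large-scale EEG spectrum), oscillation at 9 Hz
(alpha-range) with random-walk phase jitter (SD 0.05 rad/sample) so the
periodic component is quasi-periodic rather than a degenerate pure tone.
Case subjects receive w = `osc_mix + ct_deficit` (default 0.1 + 0.3) on
CT channels and `osc_mix` elsewhere; contrast subjects receive
`osc_mix` everywhere. Each subject × channel weight gets independent
N(0, 0.02) jitter, modelling electrode-level variability. Cohorts
default to 10 + 10 subjects, 60-s recordings at 256 Hz — a deliberately
small, clinical-study-sized design.

The knob's core promise is verified empirically: broadband SampEn falls
monotonically as w rises (from ≈1.8 at w=0 to ≈0.7 at w=0.8 under
defaults) and broadband DET rises — more oscillation means more regular,
lower-complexity signals.

### Direction of the injected contrast under the banded reduction

An important subtlety, discovered during calibration and retained as a
documented property rather than papered over: the *banded* multiscale
AUC of SampEn responds to the deficit with the **opposite sign** of the
broadband SampEn. The oscillation occupies one dyadic band (8–16 Hz),
and each band signal is renormalized by its own SD before entropy is
taken, so the sine's regularity barely registers in its own band; what
dominates is spectral leakage of the oscillation into the neighbouring
4–8 Hz band, where the beat between the two incommensurate components
*raises* the band's entropy. The net effect: case-CT channels have
slightly **higher** SampEn-AUC, while remaining clearly lower-complexity
broadband.

For this reason, recovery tests do not assume a sign. The generator
exposes `calibrate_complexity_knob(..., banded=True)`, which sweeps w
through the pipeline's own banded-AUC measuring device, and
`injected_auc_direction()`, which compares the dose-response at the two
weights the cohort actually uses. The sweep uses common random numbers
(every weight sees the same noise and oscillation realizations), so the
dose-response is a paired contrast; without pairing, the modest banded
shift would be masked by between-signal variance. Recovery is then asserted as: the
four-cell ANOVA rejects (p < 0.01) *and* the (case, CT) cell is the
extreme cell in the calibrated direction. Localization — the right cell,
predicted direction — is the recovered ground truth.

### What the generator does and does not emulate

It reproduces: channel count and montage, clinical sampling rate and
durations, 1/f-like spectra, quasi-periodic rhythms, a region-localized
regularity contrast, and EDF round-tripping with clinical-style channel
labels ("EEG C3-REF"). It does **not** contain epileptiform spikes,
artifacts, volume-conduction correlations between channels, non-
stationarity, or any forward head model. Passing recovery tests
therefore shows the *pipeline* can detect and localize a known contrast
at clinical cohort sizes — it says nothing about effect sizes in real
patients.

## Numerical choices and degenerate inputs

- EDF writing uses 16-bit quantization with per-channel symmetric
  physical ranges (5% headroom), keeping round-trip error ~1e-4
  relative RMS; start date/time are fixed constants so identical data
  produce identical bytes. Reading goes through mne; channels with
  differing sampling rates are rejected (no resampling), annotation
  channels dropped.
- Segment starts lie on a 1-s grid so the candidate set is enumerable;
  selection uses `numpy.random.default_rng(seed)`; per-subject seeds
  derive from the run seed via `SeedSequence([run_seed, index])`.
- Wavelet reconstruction trims the one-sample surplus pywt produces for
  odd lengths; band count is always levels + 1.
- Degenerate signals: constant band signals yield missing SampEn (error
  at the call level, caught and logged as NaN by the extractor);
  zero-diameter trajectories yield all-NaN recurrence results.
- Ties in radius calibration resolve to the smallest ε reaching the
  target rate.
- The four-cell ANOVA refuses empty cells and all-zero within-cell
  variance; the SS decomposition (SS_total = SS_between + SS_within) is
  maintained to 1e-9 relative and checked in tests.

## Known limitations

- The pseudo-replication caveat above: four-cell ANOVA p-values on real
  data are anti-conservative because sensors within a subject correlate.
  A mixed model with subject random effects would be the corrected
  analysis; it is out of scope here.
- Band-wise measures after per-band SD normalization are insensitive to
  narrowband power shifts by design; contrasts that are purely spectral
  (not dynamical) can be invisible or sign-flipped relative to broadband
  intuition (see the direction discussion above).
- DFA on short dyadic band signals (≤ 30 s) has wide sampling
  variability; it is an optional measure, not part of the default set.
- The EDF writer emits plain EDF (not EDF+), integer sampling rates,
  whole-second record counts — sufficient for the synthetic cohorts and
  round-trip testing, not a general-purpose exporter.
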