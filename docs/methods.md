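# Methods

This note documents the models and numerical choices behind each module:
what is computed, which parameters matter, what the synthetic generator
does and does not emulate, and where design decisions were genuinely open.

## Data model

A locomotion record is a uniformly sampled binary series (dt = 0.5 s by
default): 1 if the animal ambulated during the interval, 0 if immobile.
Housekeeping gaps are carried as a boolean exclusion mask; excluded samples
are removed from every numerator *and* denominator, and analyses receive
the record with gaps spliced out (concatenated) rather than bridged or
imputed. This treatment is appropriate because the gaps are short (< 2 % of
a week-long record) and global DFA exponents are known to be robust to far
larger data loss (tested here up to 30 % random deletion: α shifts by
< 0.05). Records with ≥ 65 % exclusion are rejected outright.

Actograms are percent-time-ambulating per fixed bin (6 min for wavelet and
Enright analyses, 30 s for EMD, to trade noise suppression against the
number of points available for period estimation). Trailing partial bins
are dropped, never padded — padding would bias the percent estimate of the
last bin. Bins are addressed by their left edge; the fold for the median
actogram uses midnight as the day boundary. A bin whose samples are all
excluded is missing (NaN), never zero: zero means "observed immobile".

## Synthetic generator

The generator produces each structural ingredient separately and a binary
record combining all three.

* **Rhythms** — `gen_sum_of_sines` evaluates Σ A_k sin(2π t / P_k + φ_k)
  exactly; the default rhythm set is 24, 12, 8, 6, 4.8 and 4 h with equal
  amplitudes and zero phases. Real amplitudes and phases per animal are
  unknown — they are free parameters, and tests that depend on them say so.
* **Long-range noise** — `gen_fgn` shapes a white Gaussian spectrum by
  f^(−β/2) with β = 2α − 1 and inverse-transforms. This spectral synthesis
  is adequate at the ±0.05 exponent tolerance used throughout; the DFA
  estimator itself is validated against the β = 2α − 1 identity rather
  than against the generator alone, so the two cannot fail jointly without
  detection. Minimum length 2¹⁰ samples; below that the shaped spectrum is
  too coarse to fix the exponent.
* **Binary record** — `gen_fractal_locomotion` is an alternating renewal
  process. Immobility bout durations are drawn i.i.d. from a discrete
  power law ∝ d^S (S = −1.5) on the 0.5 s grid between 1 and 250 s —
  truncation mirroring the range over which the bout law is fitted.
  Mobility bouts are geometric with a time-varying mean m(t) =
  E[imm] · p(t)/(1 − p(t)), where p(t) = logistic(c + rhythms + noise)
  is the local activity target. This construction (rather than
  thresholding a continuous signal) guarantees a controllable bout law.

  The offset c cannot be set analytically: long mobility bouts
  oversample high-activity epochs (raising realized activity) while cycle
  starts oversample low-activity epochs (lowering it), and the two biases
  do not cancel. c is therefore calibrated by two secant corrections on
  the logit scale, each evaluated with a full-length pilot simulation on
  an independent substream; realized mean activity lands within ±0.01 of
  target. Defaults `rhythm_strength = 0.4` and `noise_strength = 1.0`
  (log-odds units) were fixed once so that the realized record satisfies
  the generator's contract — hourly ambulation ≈ 25 %, DFA3 α ≈ 0.85 over
  30 s–4.4 h, bout slope ≈ −1.5 — and produce day/night activity swings
  comparable to diurnal birds.

  What the generator does *not* emulate: measurement artefacts, the
  asymmetric day/night waveform of real activity (its rhythms are pure
  sinusoids), inter-animal parameter variability unless requested, and
  mobility-bout statistics beyond the geometric family. Its
  fluctuation function also shows a mild knee near the 250 s bout-law
  truncation that real records need not show (see DFA below). Passing
  tests on this generator therefore demonstrates correctness of the
  estimators under controlled conditions, not fidelity of any particular
  animal's record.
* **Randomisation control** — `randomize_series` applies a uniform
  permutation of samples (sample-level, not event-level), preserving the
  activity level while destroying all temporal structure.

All generators are bit-reproducible given (spec, seed); pilot calibration
uses seed offsets (seed + 1000 + k) so the delivered record depends only on
the spec.

## Fourier spectrum and significance

The one-sided periodogram is scaled so the ordinates sum to the series
variance (Parseval, checked to 1e-6 in tests and cross-checked against an
independent periodogram implementation). Significance of an ordinate is
assessed against the exponential null of normalised white-noise
periodogram ordinates, *pointwise* at the stated level by default — on
white noise the flagged fraction then matches the level (verified by
simulation at 0.001). A Šidák family-wise correction is available
(`correction="sidak"`) when a single record is screened across all
frequencies. The spectral decay exponent β is the negated least-squares
slope of log S(f) vs log f over a caller-chosen period range (≥ 10
frequencies required).

Dominant periods are refined by parabolic interpolation of log-power
around the argmax: the discrete Fourier grid of a 6.5-day record does not
contain 24 h exactly (156 h/6 = 26 h, 156 h/7 = 22.3 h), and interpolation
recovers the true tone period to well under one bin.

## Enright (χ²) periodogram

For trial period P (in bins) the actogram is folded into K = ⌊N/P⌋ rows
and Q_P = N_fold · var(column means)/var(series) computed on the folded
part. Q_P/N_fold is the fraction of variance explained by the fold; under
a Gaussian white null it follows Beta((P−1)/2, P(K−1)/2) *exactly*, which
is the default significance null. The classical χ²_{P−1} approximation
(available as `null="chi2"`) is the K → ∞ limit of the same law; over the
full trial range 2..N/2 it is conservative by roughly 3× at the 0.001
level, because the largest trial periods fold only two rows. The Beta
null restores the nominal type-I error (0.0009 measured at 0.001 across
1000 white actograms). Trial periods run from 2 bins (the single-bin fold
is degenerate) to N/2.

Peak selection follows the rule used in circadian practice: local maxima
with Q_P above 10 % of the global maximum, ascending by period, then every
period that is an integer multiple (within half a bin — the resolution of
the discrete trial grid) of a retained shorter period is removed, since
the fold statistic cannot distinguish a rhythm from its harmonics. When a
period and its multiple are both significant the *shorter* is kept; this
is the reading implied by ascending-order processing, and it is flagged
here as an interpretation. Consequence (visible in the README example):
with a full ultradian set present, 12 h and 24 h are removed as multiples
of retained 6 h/4 h peaks even when genuinely rhythmic — a known
limitation of harmonic removal, not a defect of the detector.

## Empirical mode decomposition

Classic sifting: natural cubic splines through local maxima and minima
(plateaus contribute their midpoint), envelope-mean subtraction, iterate.
Two stopping rules are provided. The default is the envelope-amplitude
criterion of the classical open-source EMD tooling: stop when
|mean envelope| < 0.05 × local envelope amplitude on at least 95 % of
samples and < 0.5 everywhere. Huang's global SD criterion (threshold 0.2)
is available as `stop="sd"`; it terminates after very few passes on
intermittent locomotion actograms and leaves the mode bank underresolved
(9 vs 14–15 IMFs on the same input), so it is not the default.
Decomposition ends when the residual retains fewer than three extrema.
Per-IMF iteration cap: 200.

Boundary handling matters more than any other detail: envelopes are fitted
through extrema extended past both ends by symmetry — mirrored about the
terminal extremum, or about the boundary sample itself when the signal
protrudes beyond the would-be envelope. (A simpler scheme that anchored
the endpoints as spline knots corrupted slow IMFs badly enough to split a
pure sine into three modes; the symmetrised scheme decomposes a pure sine
into exactly one IMF with zero residual.) No detrending or denoising is
applied before sifting.

On quail-like synthetic 30 s actograms (18 720 bins) the decomposition
yields 13–15 IMFs depending on seed; real records, whose fine-scale
extrema density is somewhat higher than the generator's, sit at the top of
that range. This seed dependence is a limitation of the synthetic
emulation, not of the decomposition.

Principal peaks: within a contiguous window of four IMF spectra (by
default placed so the window ends at the IMF whose dominant period is
nearest 24 h, i.e. spanning the circadian-to-ultradian band), spectral
local maxima above 30 % of each spectrum's own maximum are pooled and the
ten largest retained. Histograms across animals snap periods to the
canonical rhythm set within 15 % relative tolerance — the coarse Fourier
grid of a one-week record makes finer binning meaningless.

## Wavelet analysis

The continuous transform uses the complex Morlet atom with bandwidth 1 and
centre frequency 1.5 (`cmor1-1.5`, via PyWavelets) on integer scales
1–400; on 6-min bins the period map is period = scale × 360 s/(3600 × 1.5)
= 0.067–26.7 h. Input actograms are mean-subtracted (the DC offset would
dominate large scales); missing bins take the mean value. The transform is
cross-checked in tests against direct convolution with the analytic atom.

Rhythm confirmation uses the real part of the coefficients: local maxima
of Re(cwt) at the row nearest a target period, with prominence ≥ 10 % of
the row's range and minimum separation of half the period. The interval
between successive peaks (the lag time) equals the period when the rhythm
is real: a 12 h component over 6.5 days yields exactly 13 peaks (2/day),
a 24 h component 7. Peak counting and lag statistics use the full row
including the edges — the expected peak counts include peaks within one
period of the record boundary.

Synchrony between two animals is the Spearman rank correlation of their
Re(cwt) rows, per scale, excluding ⌈period/bin⌉ bins at each edge (cone of
influence): edge coefficients reflect the boundary, not behaviour. Rank
correlation makes the profile invariant to monotone per-scale
normalisation, so correlating raw Re(cwt) or its relative intensity gives
the same ρ. Group profiles are the mean ± SEM over all unordered pairs.
Note the effective sample size at the largest scales is small (a 26 h row
of a 6.5-day record holds ~4 cycles inside the cone of influence), so
single-pair ρ values there scatter widely under the null (±0.5 is
routine); only group means are interpretable at those scales.

## Detrended fluctuation analysis

Peng's procedure: integrate the mean-subtracted series, partition into
non-overlapping windows of n samples from the front *and* from the back
(using all data when N is not a multiple of n), detrend each window with a
polynomial (order 3 by default — the lowest order that removes the slow
trends of week-long records; orders 2–4 agree within 0.05 on trend-free
noise, and only order ≥ 3 removes a cubic trend), F(n) = RMS residual.
α is the least-squares slope of log F vs log n. The default window grid is
~20 log-spaced sizes from 60 samples (30 s at 0.5 s sampling) to N/4;
above N/4 too few windows contribute for a stable estimate.

Scaling-range selection operationalises "stable local slopes, minimal
residuals": local slopes are measured by a centred five-point regression
(adjacent-point slopes at the largest windows have sampling noise several
times the stability tolerance, because only ~8 segments contribute there);
candidate intervals are contiguous runs of ≥ 6 window sizes whose local
slopes all lie within ±0.1 of their own median; among the longest
qualifying intervals the one with the smallest fit SSR per point wins. The
coefficient of variation of the local slopes is reported as a diagnostic,
not used as an objective — maximising it would oppose stability, so it is
treated as descriptive. If no
interval qualifies, the full range is returned with an explicit warning
flag.

On the synthetic binary records the selector reliably finds the knee near
the 250 s bout-law truncation and stops there; the pipeline therefore
reports α over the conventional 30 s–4.4 h window (the range over which
locomotion records scale) and attaches the selector's interval as a
diagnostic.

The circadian control: `moving_average_filter` subtracts the across-cycle
mean waveform at 23.5 h — the average of samples one filter-period apart —
which exactly nulls any component periodic at the filter period (and its
harmonics) and maps constants to zero, while passing broadband noise
essentially unchanged. (A centred moving average with a window *equal* to
the period cannot serve here: its frequency response is exactly zero at
that period, so subtracting it would leave the rhythm intact.) On
rhythm + noise composites, α from filtered and unfiltered series agree
within 0.05 and correlate > 0.9 across seeds, demonstrating that
polynomial detrending already absorbs the circadian component.

## Bout-duration distributions

An immobility event is a maximal run of zeros strictly longer than 1 s;
mobility events are maximal runs of ones with no threshold. Runs touching
an excluded gap are censored (dropped): bridging would fabricate long
events across the gap. Frequencies are raw histogram counts (not
densities), so the fitted slope S depends on the bin width; the bin width
is always recorded with S and a sensitivity helper sweeps it (the slope
regime changes once the bin width exceeds the mean event duration). Fits
are least squares on the log-log (power law) or lin-log (exponential)
histogram with zero-count bins excluded, over durations of 1–250 s by
default — beyond that the sparse tail dominates the regression. This
regression-based S is deliberate (it is the convention the quantity is
defined by); maximum-likelihood tail estimation is out of scope. The
discriminating control: a randomised series keeps the same activity level
but its bout durations become geometric, and the exponential fit then
beats the power law in r².

## Pipeline

`run_full_analysis` executes the enabled stages per animal (actogram,
Fourier + Enright, EMD principal peaks, wavelet lag times, DFA, FDD-I) and
the group stage (pairwise synchrony profile; mean ± SEM of α and S — SEM
matching the cohort reporting convention), recording per-stage errors
without aborting the cohort. Reports carry the package version and a
config hash; runs are deterministic given (config, seed), with synthetic
animal k seeded as seed + k.

## Problem sizes used in the test suite

Exponent-recovery checks use series of 2¹⁷ samples and 10 seeds;
significance-calibration checks use 1000 white-noise replicates (512
samples for Fourier, 480 bins for Enright); bout-law recovery uses 10⁴
events; synchrony and wavelet checks use 6.5-day records at 6-min bins
(1560 bins); EMD depth checks use two full 6.5-day records at 30 s bins.
These sizes give sampling error comfortably below each asserted tolerance.
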