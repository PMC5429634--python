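# ultrarhythm

Joint rhythm and fractal analysis of high-resolution binary locomotion time
series, plus a synthetic-data generator that emulates the statistical
structure such records carry.

## The problem

Week-long home-cage locomotion records — one 0/1 value per 0.5 s interval
(1 = the animal was ambulating, 0 = immobile; about 1.1 × 10⁶ samples over
6.5 days) — carry two kinds of temporal organisation at once:

* **rhythms** — a circadian (≈24 h) component plus ultradian components at
  12, 8, 6, 4.8, 4 h and shorter, partially synchronised across animals;
* **fractal dynamics** — long-range temporal correlations (DFA exponent
  α ≈ 0.85 over scales of ~30 s to >4 h) and immobility bouts whose
  durations follow an inverse power law, frequency ∝ duration^S with
  S ≈ −1.5 up to a few minutes.

No single method sees both. `ultrarhythm` implements the complementary
toolbox used in behavioural chronobiology to characterise them together:

| module | method |
| --- | --- |
| `io_timeseries` | series I/O, hourly Amb% = (Σxᵢ/N)·100, 6-min/30-s actograms, median (folded) actogram |
| `periodogram` | FFT power spectrum with white-noise significance; spectral slope β of S(f) ∝ f^−β (β = 2α − 1); Enright χ² periodogram Q_P with peak sorting and harmonic removal |
| `emd` | empirical mode decomposition by cubic-spline sifting; IMF power spectra; principal-peak histograms |
| `wavelet` | complex-Morlet (cmor1-1.5) CWT on scales 1–400 (periods 0.067–26.7 h on 6-min bins); peak lag times; per-scale Spearman synchrony between animals |
| `fractal` | detrended fluctuation analysis (order 3), scaling-range selection, circadian phase-average filter control |
| `events` | immobility/mobility bout extraction; power-law vs exponential fits of the duration distribution; bin-size sensitivity |
| `synthetic_data` | sum-of-sines rhythms, fractional-Gaussian-noise generator, and a modulated alternating-renewal binary generator with controllable bout law, activity level and DFA exponent |
| `pipeline` / CLI | per-animal and group analysis from a YAML config |

## Worked example

Generate one synthetic animal with the default study-like conditions
(6.5 days at 0.5 s; rhythm set 24/12/8/6/4.8/4 h; target α = 0.85;
immobility-bout law slope −1.5 on 1–250 s; mean activity 0.25) and run the
main analyses:

```python
import numpy as np
from ultrarhythm import SyntheticSpec, gen_fractal_locomotion, \
    bin_to_actogram, percent_ambulating_hourly
from ultrarhythm.periodogram import enright_periodogram, enright_select_peaks
from ultrarhythm.fractal import dfa, default_window_sizes
from ultrarhythm.events import extract_events, fdd_fit
from ultrarhythm.wavelet import cwt_morlet, peak_lag_times

series = gen_fractal_locomotion(SyntheticSpec(seed=0))
print(f"mean hourly ambulation: {np.nanmean(percent_ambulating_hourly(series)):.1f}%")

acto = bin_to_actogram(series, 360.0)
peaks = enright_select_peaks(enright_periodogram(acto))
sig = peaks[peaks.significant]
print("significant Enright periods (h):", [round(p, 1) for p in sig.period_hours][:5])

res = dfa(series.values.astype(float), order=3,
          window_sizes=default_window_sizes(series.n_samples), dt=0.5)
res = res.refit((60, 31680))  # 30 s - 4.4 h in samples
print(f"DFA3 alpha = {res.alpha:.3f} (r2 = {res.r_squared:.4f}) over 30 s - 4.4 h")

durations = extract_events(series, "immobile")
fit = fdd_fit(durations, fit_range=(1.0, 250.0))
print(f"FDD-I: {durations.size} events, S = {fit.slope_S:.2f} (r2 = {fit.r_squared:.2f})")

field = cwt_morlet(acto)
lags, mean, sem = peak_lag_times(field, 24.0)
print(f"lag between Re(cwt) peaks at the 24 h row: {mean:.1f} +/- {sem:.1f} h")
```

Output:

```
mean hourly ambulation: 25.0%
significant Enright periods (h): [4.0, 4.8, 6.0, 23.9, 24.1]
DFA3 alpha = 0.843 (r2 = 0.9889) over 30 s - 4.4 h
FDD-I: 23436 events, S = -1.53 (r2 = 0.95)
lag between Re(cwt) peaks at the 24 h row: 24.0 +/- 0.4 h
```

Reading the numbers: the realized activity level matches the requested 25 %;
the Enright periodogram recovers the circadian component (≈24 h) and the
short ultradian set, with 12 h and 8 h removed by the harmonic rule because
they are integer multiples of retained shorter periods; the DFA exponent
reproduces the generator's target (long-range correlated, α ≈ 0.85); the
bout-duration slope matches the −1.5 power law; and the mean lag between
wavelet coefficient peaks at the 24 h scale equals the period itself, the
analytical signature of a real rhythm at that scale.

The same stages run from the shell:

```bash
ultrarhythm simulate spec.yaml series.txt
ultrarhythm enright series.txt --bin-seconds 360
ultrarhythm dfa series.txt --order 3
ultrarhythm events series.txt --kind immobile --fit power_law
ultrarhythm run config.yaml        # full per-animal + group report
```

Real deposited series in the same one-sample-per-row text format are read
with `read_series(path, dt=0.5)`.

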