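# buzzfield

Acoustic monitoring of bumble bee activity and pollination services.

Bumble bees in flight emit a harmonic buzz whose first harmonic — the
*characteristic frequency*, equal to the wingbeat frequency — lies between
roughly 120 and 400 Hz and falls with body size. `buzzfield` turns passive
audio recordings of flowering meadows into ecological quantities, for
pollination ecologists, conservation monitors and agronomists who want
pollinator data without catching bees:

1. **Buzz detection** (`buzzfield.casa`). A computational auditory scene
   analysis (CASA) pipeline: *focal templates* keep only time–frequency
   bins in harmonic relation to a candidate fundamental in the 120–400 Hz
   band; the retained bins are grouped by normalized spectral clustering
   (Gaussian affinity `exp(−Δt²/2σ_t² − Δf²/2σ_f²)`, k-means on the
   eigenvectors of the symmetric normalized Laplacian, k = 3); a cluster is
   a buzz if its point density is ≥ 1.0 points per spanned frame **and**
   its frequency-collapsed, 20-element-smoothed "smashed cluster" profile
   peaks at ≥ 1.0. Buzz density = detected buzzes per hour.
2. **Characteristic-frequency read-off** (`buzzfield.charfreq`). Averaged
   Hamming-window spectra (FFT 8192), per-bin noise-profile subtraction, a
   centred 3-bin sliding average, and peak picking in the search band.
3. **Trait inference** (`buzzfield.traits`). Linear mixed models
   `f₀ = β₀ + β₁·trait + u_bee + ε` (REML, per-bee random intercept) for
   wing length and tongue length, with Nakagawa–Schielzeth marginal r²;
   a type III ANCOVA of tongue length controlling for wing length; and a
   cross-species log-linear literature model `log f₀ = a + b·tongue` on
   sample-size-weighted species × caste means.
4. **Pollination services** (`buzzfield.survey`). One-tailed correlation of
   acoustic against visual/manual counts; a one-tailed one-sample t-test on
   open-minus-caged seed set per plot × species cell (pollinator
   exclusion); ANCOVA of plot-mean seed set on buzz density with plant
   species as covariate.
5. **Synthetic field data** (`buzzfield.synth`). Harmonic buzzes, Poisson
   soundscapes over white noise at fixed SNR, bee populations drawn from
   trait lines, and plot-level survey/seed tables — each with exact ground
   truth for every downstream stage.

## Worked example

```python
import numpy as np
from buzzfield import *

# two minutes of synthetic meadow audio: buzzes at 300/h over 20 dB SNR noise
cfg = ScenarioConfig(buzz_rate=300.0, snr_db=20.0, seed=42)
rec, truth = synth_soundscape(cfg, 2 / 60)
events = BuzzDetector().fit().predict(rec)
print(f"truth buzzes: {len(truth)}, detected: {len(events)}")
print(f"buzz density: {buzz_density(events, rec.duration / 3600):.0f} buzzes/h")
first = events[0]
print(f"first event: {first.start:.2f}-{first.end:.2f} s, f0 = {first.f0:.1f} Hz")

# wingbeat frequency vs body size, then trait inference from a detection
bees = synth_bee_population(28, WING_LINE, rng=np.random.default_rng(42))
fit = fit_mixed_freq_trait(bees, "wing_length")
print(f"slope {fit.slope:.2f} Hz/mm, intercept {fit.intercept:.1f} Hz, r2m {fit.marginal_r2:.2f}")
wing, extrap = predict_trait_from_frequency(fit, first.f0)
print(f"implied wing length at {first.f0:.0f} Hz: {wing:.1f} mm")

# pollinator exclusion: did bees add seeds?
surveys, seeds = synth_survey_and_seeds(ScenarioConfig(seed=42))
diff, t, df, p = exclusion_ttest(seeds)
print(f"open - caged = {diff:.2f} seeds/plant (t_{df} = {t:.2f}, one-tailed p = {p:.3f})")
```

prints

```
truth buzzes: 13, detected: 13
buzz density: 390 buzzes/h
first event: 11.21-11.79 s, f0 = 177.6 Hz
slope -7.81 Hz/mm, intercept 262.0 Hz, r2m 0.74
implied wing length at 178 Hz: 10.8 mm
open - caged = 4.60 seeds/plant (t_5 = 5.01, one-tailed p = 0.002)
```

The detector found all 13 inserted buzzes; the mixed model recovers the
generating trait line (slope −7.57 Hz/mm, intercept 259.2 Hz) to within
sampling error of a 28-bee study; inverting the line converts a detected
177.6 Hz buzz into a ~11 mm wing length — a queen-sized bee; and the
exclusion contrast attributes ~4 extra seeds per plant to bee visits.

A `buzz` console script exposes the same pipelines
(`buzz detect`, `buzz charfreq`, `buzz density`, `buzz traits`,
`buzz survey`, `buzz synth`); every file-writing command leaves a JSON
manifest recording parameters and input hashes.

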