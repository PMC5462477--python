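# Methods

## Signal model

A flight buzz is modelled as a harmonic series at the wingbeat frequency
f₀ ∈ [120, 400] Hz: harmonics h = 1…H (default H = 5) with amplitudes
decaying geometrically (default ratio 0.5 per harmonic, or explicit
amplitudes such as 1/h), a raised-cosine attack/release over 10% of the
buzz duration, and optionally a slow random-walk jitter of f₀ (harmonics
stay integer-locked because jitter enters the shared phase). Buzzes are
RMS-normalized (default 0.1 full scale). Typical bumble bee buzzes last a
few tenths of a second; the generator default is 0.5 s.

All spectral analysis is short-time Fourier: frames start at hop
multiples, no padding, Hamming window; frame times are window centres,
frequencies are bin centres with spacing `sample_rate / fft_size`, time
intervals are half-open `[t0, t1)`. Two STFT geometries are used:

* **read-off**: FFT 8192, half-window hop — ≈1.35 Hz bins at 11.025 kHz,
  for characteristic-frequency measurement;
* **detection**: FFT 1024, hop 256 — ≈10.8 Hz × 23 ms bins, coarse enough
  that a harmonic stack is a handful of bins per frame.

11.025 kHz is the reference field sample rate; nothing is resampled and
any rate works as long as `f₀·H` stays below Nyquist.

## Noise handling

The read-off path follows the classic manual workflow: a per-bin noise
magnitude profile is the mean over a designated stretch of pure noise
(typically one second); magnitudes are spectrally subtracted and floored at
zero (no over-subtraction factor — the subtraction never increases any
magnitude and is the identity for a zero profile). Spectra are then
smoothed with a centred 3-bin sliding average whose window shrinks at the
edges (averaging only available neighbours avoids biasing edge amplitudes
downward, constants are fixed points).

The automated detector cannot rely on a hand-picked noise second, so each
analysis chunk estimates its own profile as the per-bin median plus 2
robust standard deviations (1.4826 × MAD) across the chunk's frames. The
median/MAD pair stays calibrated while buzzes occupy up to about half the
frames of a chunk, which a mean or a high percentile does not; with the
default ×2.0 template threshold this places the acceptance bar near five
noise standard deviations per bin, where Rayleigh-distributed noise
magnitudes essentially never produce three aligned harmonics.

## Characteristic frequency

f₀ is the bin-centre frequency of the maximal smoothed magnitude within the
search band (default 120–400 Hz; configurable because queens of large
species approach the low edge). Ties break toward the lower frequency. An
all-zero band returns a distinct "no peak" result rather than an error. No
sub-bin interpolation is applied by default — peaks are reported at bin
resolution. Octave-error guard: when the magnitude at f₀/2 (if inside the
band) exceeds 0.5 × the peak, f₀/2 is reported instead; harmonic series can
carry a weak fundamental, and 0.5 is a deliberate, conservative choice.
Detection is invariant under uniform amplitude scaling of the recording.

## CASA detector

Pipeline per 3 s chunk (0.5 s overlap, so any buzz up to 0.5 s is wholly
inside some chunk): STFT → robust noise profile → focal template → affinity
→ spectral clustering → density gate → smashed-cluster gate → event
shaping; overlap duplicates are merged.

**Focal template.** Candidate fundamentals are the STFT bins nearest the
120–400 Hz band. Per frame, a candidate scores the number of its first 5
harmonics that have, within ±1 bin, a spectral **local maximum** exceeding
both 2.0 × the noise profile and an absolute floor of 0.01 × the chunk's
maximum magnitude. The local-maximum requirement keeps mainlobe leakage a
few bins off-harmonic from counting as harmonic evidence, which sharpens
the band edges to one-bin resolution; the relative floor gives the
threshold meaning in near-noiseless audio while preserving scale
invariance. A frame accepts its best-scoring candidate (ties toward the
lower fundamental) when ≥ 3 harmonics score; the retained set is then the
above-threshold bins within ±1 bin of that candidate's harmonics. Silence
retains nothing; an isolated pure tone without harmonic partners retains
nothing.

**Clustering.** Retained (frame, bin) points get a Gaussian affinity with
σ_t = 3 frames, σ_f = 2 bins. Standard normalized spectral clustering is
applied: eigenvectors of the k = 3 smallest eigenvalues of the symmetric
normalized Laplacian, rows normalized, k-means (10 restarts, fixed seed,
deterministic). A literal mode clustering on the raw affinity matrix's
smallest eigenvectors is available behind `mode="affinity"` for fidelity
experiments; it is not the default because that construction is degenerate
on typical affinities, while the Laplacian form is the accepted realization
of "cluster the affinity's eigenvectors" and provably approximates the
normalized cut (the test suite checks exact agreement with an exhaustive
normalized-cut search on small instances). k = 3 lets up to three
concurrent sources separate; with fewer points than k every point is its
own cluster.

**Gates.** Density = points / spanned frames, prospective buzz iff ≥ 1.0
(inclusive). The smashed cluster is the per-frame point count convolved
with a length-20 moving average (entries 1/20, "same" alignment); the
cluster is recorded as a buzz iff the peak ≥ 1.0 — i.e. at least one
harmonic point per frame sustained across a 20-frame (~0.46 s) window. The
kernel entries and the density units are design choices; both thresholds
then read "one point per frame on average".

**Event shaping.** Boundaries are the contiguous frames that actually hold
cluster points (extended by the half-window), not the smashed-score support:
the length-20 smoothing kernel would smear each boundary by ~10 frames
(~0.23 s at the default hop), an artefact of the gate, not of the buzz.
Events closer than 0.1 s merge; events shorter than 0.05 s are dropped;
chunk-overlap duplicates merge when they overlap by more than half the
shorter event. Each event's f₀ is read off its own span with a smaller FFT
(2048 by default, halved further for very short events) since events are
typically shorter than the 8192-sample read-off window. Sonication
(pollination) buzzes are not separately classified; every event carries a
`kind="flight"` flag reserved for future use.

Multiple microphones per plot are summed, not deduplicated — acoustic
counts intentionally accumulate repeat flights.

## Inference layer

**Mixed trait model.** `freq ~ trait` with a per-bee random intercept,
REML (conventional for variance components), buzzes kept as repeated
measures because the random effect is bee-level; a per-bee-mean OLS mode
exists for sensitivity checks. Marginal r² follows Nakagawa–Schielzeth:
`var(β₁·trait) / (var(β₁·trait) + σ²_bee + σ²_resid)`. The F statistic is
the squared Wald t of the slope with containment denominator df
(bees − 2, since the trait varies between bees); containment is reported
deliberately rather than matching any particular software's convention.
The ANCOVA (`freq ~ tongue + wing`, random intercept) reports type III
marginal tests, which for continuous covariates are the Wald tests of each
coefficient adjusted for the other; denominator df = bees − 3.

**Literature model.** Replicate published values per species × caste are
collapsed by sample-size-weighted means, then `log(freq) = a + b·tongue`
by OLS (the log transform handles the right-skewed frequency distribution
across species); predictions back-transform to Hz. Weighted means are
invariant to rescaling all weights.

**Survey statistics.** All seed-set analyses run on plot means. Pearson r
with `p` from `t = r√(df/(1−r²))`, df = n − 2, one-tailed for the
directional hypothesis. The exclusion test is a one-sample one-tailed t on
the plot × species open-minus-caged differences (df = cells − 1 = 5 in the
standard 3-plot × 2-species design); the pairing is by cell, and an
incomplete cell is an explicit error. The seed-set ANCOVA is OLS
`mean_seeds ~ density + C(species, Sum)` (optional density × species
interaction) with type III tests; terms whose sum of squares is numerically
zero over an exactly fitting model report F = 0, p = 1 rather than 0/0.
Outputs from 3-plot designs are flagged low-n; no multiple-testing
correction is applied.

## Synthetic generators: what they emulate, and what not

Defaults encode a realistic alpine field study: buzz rate 417/h per plot,
SNR 20 dB, wing-length line `f₀ = 259.2 − 7.57·wing` over 8–16 mm,
tongue-length line `f₀ = 238.2 − 7.96·tongue` over 5–14 mm, between-bee SD
5 Hz, within-bee SD 10 Hz, 28 bees × 5 buzzes; seed-set baseline 8
seeds/plant, bee contribution +3.89 seeds/plant in the open treatment,
density slope 0.02 seeds per buzz/h centred on the mean plot density,
species offsets ±1 seed, cell noise SD 1 seed; visual counts are a
binomial thinning (p = 0.5) of acoustic counts, reflecting that acoustic
counts accumulate repeat flights of the same forager (≈2:1 ratio).

Background noise is white (Gaussian). Real meadows have wind gusts,
birdsong, footsteps and codec artefacts (field recorders often store
compressed audio); none of that is modelled, so passing tests demonstrate
the pipeline's correctness and its behavior at a stated SNR, not field
robustness to structured interference. Bee flight acoustics (Doppler,
directivity, amplitude modulation from approach/retreat) are likewise out
of scope. Everything is bit-reproducible under a fixed seed, and every
synthesized buzz appears exactly once in the truth table.

## Problem sizes and numerical choices

The recovery experiments use 200 seeded populations (trait lines) and 500
seeded field datasets (exclusion effect), sizes at which the Monte Carlo
standard error of the reported means is an order of magnitude below the
tolerances of interest; the detector evaluation uses a ~200-buzz soundscape
(20 min at 600 buzzes/h) scored with the standard interval-overlap hit
criterion (a detection and a truth event match when they overlap by more
than 0.1 s). At arrival rates this high, adjacent Poisson arrivals
occasionally fall within the detector's 0.1 s merge gap and are reported as
one event — a property of the merge rule, not a miss, which is why overlap
matching rather than strict one-to-one pairing is the right score.

Numerical details: eigendecompositions use dense symmetric solvers
(affinity matrices are bounded by chunking); k-means ties resolve by best
inertia over 10 seeded restarts; spectral-subtraction floors at zero;
degenerate detector inputs (silent chunks, chunks with no retained bins,
fewer points than k) yield zero events rather than errors; the
characteristic-frequency tie rule is "lower frequency wins"; recordings
shorter than one window raise explicit errors.

## Known limitations

* The detector's thresholds are calibrated against stationary white noise;
  strongly harmonic interference (birdsong) inside 120–400 Hz would pass
  the focal template and must be handled upstream or by band tuning.
* Mixed-model df conventions differ across software; reported p-values at
  n = 28 bees shift slightly under other conventions.
* With 3 plots, the survey correlations and ANCOVAs have very low power;
  outputs are flagged accordingly.
* MP3 ingestion is not implemented; transcode to WAV first.
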