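"""Computational auditory scene analysis (CASA) detector for flight buzzes.

The detector decomposes a field recording the way a listener singles out a
bee from wind and birdsong:

1. **Focal templates.** For each STFT frame, candidate fundamentals on a
   120-400 Hz grid are scored by how many of their first harmonics carry
   energy well above the noise profile. Frames where some candidate lights
   up enough harmonics contribute those harmonic bins to a *focused*
   spectrogram; everything else is pushed to the background.
2. **Spectral clustering.** Retained time-frequency bins are grouped with a
   Gaussian time/frequency affinity kernel and normalized spectral
   clustering into k = 3 clusters, so that up to three concurrent buzzes
   separate from each other and from residual noise.
3. **Gates.** A cluster is a *prospective* buzz if its point density is at
   least 1.0 point per spanned frame; it is *recorded* as a buzz if its
   per-frame point counts, convolved with a 20-element moving-average
   kernel and summed across frequency (the "smashed cluster"), peak at 1.0
   or above — i.e. the harmonic evidence is sustained, not a single noisy
   frame.

Long recordings are processed in overlapping chunks to bound the affinity
matrix; duplicate detections in the overlap are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .audio_io import NoiseProfile, Recording, Spectrogram, stft_spectrogram
from .charfreq import characteristic_frequency, smooth_spectrum

__all__ = [
    "FocalTemplateConfig",
    "FocusedSpectrogram",
    "TFCluster",
    "BuzzEvent",
    "BuzzDetector",
    "apply_focal_template",
    "build_affinity",
    "spectral_cluster",
    "cluster_density",
    "smash_cluster",
    "detect_buzzes",
    "buzz_density",
]


@dataclass
class FocalTemplateConfig:
    """Harmonic-stack template parameters.

    The fundamental grid spans the bumble bee flight-buzz band at one STFT
    bin per step. A frame accepts a candidate when at least
    ``accept_min_harmonics`` of its first ``n_harmonics`` harmonics (each
    searched within ``harmonic_tol`` bins) exceed ``magnitude_threshold``
    times the noise profile; among accepting candidates the one lighting up
    the most harmonics wins, ties toward the lower fundamental.

    ``floor_ratio`` adds an absolute reference — a harmonic must also exceed
    ``floor_ratio`` x the maximum magnitude of the analyzed spectrogram — so
    that spectral leakage in very quiet audio cannot masquerade as harmonic
    energy. Both references scale with the signal, keeping detection
    invariant under uniform amplitude scaling.
    """

    band: tuple = (120.0, 400.0)  # Hz, fundamental search range
    n_harmonics: int = 5
    harmonic_tol: int = 1  # bins searched either side of each harmonic
    accept_min_harmonics: int = 3
    magnitude_threshold: float = 2.0  # multiple of the per-bin noise profile
    floor_ratio: float = 0.01  # fraction of max magnitude, absolute floor

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not (1 <= self.accept_min_harmonics <= self.n_harmonics):
            raise ValueError("accept_min_harmonics must be in [1, n_harmonics]")
        if self.magnitude_threshold <= 0 or self.floor_ratio < 0:
            raise ValueError("thresholds must be positive")

    def f0_grid_bins(self, bin_freqs: np.ndarray) -> np.ndarray:
        """Candidate fundamentals as bin indices (nearest bins to the band)."""
        df = float(bin_freqs[1] - bin_freqs[0])
        lo, hi = self.band
        k_lo = max(int(round(lo / df)), 1)
        k_hi = min(int(round(hi / df)), len(bin_freqs) - 1)
        if k_hi < k_lo:
            raise ValueError("band does not contain any frequency bin")
        return np.arange(k_lo, k_hi + 1)


@dataclass
class FocusedSpectrogram:
    """Retained (frame, bin) points of a spectrogram after focal templates."""

    parent: Spectrogram
    frames: np.ndarray  # int indices, one per retained point
    bins: np.ndarray
    frame_f0: dict = field(default_factory=dict)  # frame -> accepted fundamental (Hz)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.frames, self.bins])


@dataclass
class TFCluster:
    """One spectral cluster of retained time-frequency points."""

    frames: np.ndarray
    bins: np.ndarray

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("empty cluster")
        order = np.lexsort((self.bins, self.frames))
        self.frames = np.asarray(self.frames)[order]
        self.bins = np.asarray(self.bins)[order]

    @property
    def span(self) -> tuple:
        return int(self.frames.min()), int(self.frames.max())

    @property
    def span_frames(self) -> int:
        lo, hi = self.span
        return hi - lo + 1

    def frame_counts(self) -> np.ndarray:
        """Points per frame across the cluster span (zeros where absent)."""
        lo, _ = self.span
        counts = np.zeros(self.span_frames)
        np.add.at(counts, self.frames - lo, 1.0)
        return counts


@dataclass
class BuzzEvent:
    """A detected flight buzz."""

    start: float  # s
    end: float  # s
    f0: float  # Hz characteristic frequency (nan if unresolvable)
    peak_score: float  # smashed-cluster peak
    cluster_density: float  # points per spanned frame
    kind: str = "flight"  # sonication buzzes are not separately classified

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("event must have positive duration")


def apply_focal_template(
    spec: Spectrogram,
    noise: NoiseProfile,
    cfg: FocalTemplateConfig | None = None,
) -> FocusedSpectrogram:
    """Retain the time-frequency bins in harmonic relation to some accepted
    fundamental; push everything else to the background.

    Per frame, each candidate fundamental is scored by the number of
    harmonics whose best bin (within ``harmonic_tol``) clears the threshold;
    the best-scoring accepting candidate (ties toward lower f0) contributes
    the harmonic bins within tolerance that themselves clear the threshold.
    """
    cfg = cfg or FocalTemplateConfig()
    if len(noise.magnitudes) != spec.n_bins:
        raise ValueError("noise profile is not aligned with the spectrogram")
    mags = spec.magnitudes
    n_frames, n_bins = mags.shape
    thresh = cfg.magnitude_threshold * noise.magnitudes  # per bin
    floor = cfg.floor_ratio * mags.max() if mags.size else 0.0
    above = mags > np.maximum(thresh[None, :], floor)  # strict: silence never passes
    # a harmonic only counts where the spectrum actually peaks: off-harmonic
    # mainlobe spread clears the floor but is never a local maximum
    peak = above.copy()
    peak[:, 1:] &= mags[:, 1:] >= mags[:, :-1]
    peak[:, :-1] &= mags[:, :-1] >= mags[:, 1:]

    candidates = cfg.f0_grid_bins(spec.bin_freqs)
    tol = cfg.harmonic_tol
    # harmonic bin indices per candidate: [cand, harmonic]
    harm = candidates[:, None] * np.arange(1, cfg.n_harmonics + 1)[None, :]
    valid = harm < n_bins

    # hit[frame, cand, harmonic] = a spectral peak within +/-tol above threshold
    hit = np.zeros((n_frames, len(candidates), cfg.n_harmonics), dtype=bool)
    for off in range(-tol, tol + 1):
        idx = np.clip(harm + off, 0, n_bins - 1)
        hit |= peak[:, idx] & valid[None, :, :] & (np.abs(harm + off - idx) == 0)[None, :, :]
    scores = hit.sum(axis=2)  # [frame, cand]

    frames_out, bins_out = [], []
    frame_f0 = {}
    best_cand = np.argmax(scores, axis=1)  # first max = lowest f0 on ties
    best_score = scores[np.arange(n_frames), best_cand]
    for t in np.nonzero(best_score >= cfg.accept_min_harmonics)[0]:
        c = best_cand[t]
        frame_f0[int(t)] = float(spec.bin_freqs[candidates[c]])
        for h in range(cfg.n_harmonics):
            if not valid[c, h]:
                continue
            b0 = harm[c, h]
            for b in range(max(b0 - tol, 0), min(b0 + tol, n_bins - 1) + 1):
                if above[t, b]:
                    frames_out.append(t)
                    bins_out.append(b)
    if frames_out:
        pts = np.unique(np.column_stack([frames_out, bins_out]), axis=0)
        frames_arr, bins_arr = pts[:, 0], pts[:, 1]
    else:
        frames_arr = np.empty(0, dtype=int)
        bins_arr = np.empty(0, dtype=int)
    return FocusedSpectrogram(spec, frames_arr, bins_arr, frame_f0)


def build_affinity(points: np.ndarray, sigma_t: float = 3.0, sigma_f: float = 2.0) -> np.ndarray:
    """Gaussian time/frequency affinity between retained bins.

    ``affinity(i, j) = exp(-(dframe^2/(2 sigma_t^2) + dbin^2/(2 sigma_f^2)))``;
    symmetric, unit diagonal, entries in (0, 1].
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (frame, bin)")
    if len(pts) == 0:
        raise ValueError("nothing to cluster: no retained bins")
    dt = pts[:, 0:1] - pts[:, 0:1].T
    db = pts[:, 1:2] - pts[:, 1:2].T
    return np.exp(-(dt ** 2 / (2 * sigma_t ** 2) + db ** 2 / (2 * sigma_f ** 2)))


def spectral_cluster(
    affinity: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    mode: str = "laplacian",
) -> np.ndarray:
    """Partition points by k-means on a spectral embedding of the affinity.

    ``mode="laplacian"`` (default) embeds with the eigenvectors of the
    symmetric normalized Laplacian belonging to its k smallest eigenvalues —
    standard normalized spectral clustering, which approximately minimizes
    the normalized cut. ``mode="affinity"`` instead uses the eigenvectors of
    the raw affinity matrix with smallest eigenvalues, for fidelity
    experiments with the literal construction.

    Deterministic for a fixed ``seed``. If ``k`` exceeds the number of
    points, each point becomes its own cluster.
    """
    A = np.asarray(affinity, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    n = A.shape[0]
    if k >= n:
        return np.arange(n)
    if mode == "laplacian":
        d = A.sum(axis=1)
        d_isqrt = 1.0 / np.sqrt(np.maximum(d, 1e-300))
        lap = np.eye(n) - d_isqrt[:, None] * A * d_isqrt[None, :]
        _, vecs = eigh(lap, subset_by_index=(0, k - 1))
        emb = vecs
        norms = np.linalg.norm(emb, axis=1, keepdims=True)
        emb = emb / np.maximum(norms, 1e-300)
    elif mode == "affinity":
        _, vecs = eigh(A, subset_by_index=(0, k - 1))
        emb = vecs
    else:
        raise ValueError(f"unknown mode {mode!r}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(emb)


def cluster_density(cluster: TFCluster) -> float:
    """Points per spanned frame; >= 1.0 flags a prospective buzz."""
    return len(cluster.frames) / cluster.span_frames


def smash_cluster(cluster: TFCluster, kernel_len: int = 20) -> tuple:
    """Collapse a cluster across frequency into a smoothed time profile.

    Per-frame point counts over the cluster span are convolved (same
    alignment) with a length-``kernel_len`` moving-average kernel. Returns
    ``(smashed, peak)``; a peak of at least 1.0 records the cluster as a
    buzz, i.e. on average one harmonic point per frame sustained across the
    kernel window.
    """
    counts = cluster.frame_counts()
    kernel = np.ones(kernel_len) / kernel_len
    smashed = np.convolve(counts, kernel, mode="same")
    return smashed, float(smashed.max())


class BuzzDetector(BaseEstimator):
    """Flight-buzz detector over long recordings.

    Pipeline per chunk: STFT -> per-bin noise profile -> focal template ->
    affinity -> spectral clustering (k clusters) -> density gate (>= 1.0
    point/frame) -> smashed-cluster gate (peak >= 1.0) -> event shaping.
    Chunk overlaps are deduplicated. Stateless apart from parameters; `fit`
    validates and returns self so the detector composes with sklearn
    pipelines.

    Parameters
    ----------
    fft_size, hop : STFT geometry for detection (defaults suit ~11 kHz
        field audio: ~10.8 Hz bins, ~23 ms hop).
    chunk_s, chunk_overlap_s : chunk length and overlap in seconds.
    noise_mad_k : the detection noise profile is the per-bin median plus
        ``noise_mad_k`` robust standard deviations (1.4826 x MAD) over chunk
        frames — a noise ceiling that stays valid while buzzes occupy up to
        about half of the chunk.
    k : number of spectral clusters per chunk, letting concurrent buzzes
        separate.
    density_threshold, peak_threshold : the two gates.
    min_event_s, merge_gap_s : drop events shorter than, merge events
        closer than, these durations.
    charfreq_fft : FFT length for each event's characteristic frequency.
    """

    def __init__(
        self,
        fft_size: int = 1024,
        hop: int = 256,
        window: str = "hamming",
        chunk_s: float = 3.0,
        chunk_overlap_s: float = 0.5,
        noise_mad_k: float = 2.0,
        template: FocalTemplateConfig | None = None,
        sigma_t: float = 3.0,
        sigma_f: float = 2.0,
        k: int = 3,
        seed: int = 0,
        n_restarts: int = 10,
        density_threshold: float = 1.0,
        peak_threshold: float = 1.0,
        smash_kernel: int = 20,
        min_event_s: float = 0.05,
        merge_gap_s: float = 0.1,
        charfreq_fft: int = 2048,
    ):
        self.fft_size = fft_size
        self.hop = hop
        self.window = window
        self.chunk_s = chunk_s
        self.chunk_overlap_s = chunk_overlap_s
        self.noise_mad_k = noise_mad_k
        self.template = template
        self.sigma_t = sigma_t
        self.sigma_f = sigma_f
        self.k = k
        self.seed = seed
        self.n_restarts = n_restarts
        self.density_threshold = density_threshold
        self.peak_threshold = peak_threshold
        self.smash_kernel = smash_kernel
        self.min_event_s = min_event_s
        self.merge_gap_s = merge_gap_s
        self.charfreq_fft = charfreq_fft

    # stateless: nothing is learned from data
    def fit(self, X=None, y=None):
        self._template_ = self.template or FocalTemplateConfig()
        return self

    def predict(self, rec: Recording) -> list:
        """Detect buzzes; returns a time-sorted list of :class:`BuzzEvent`."""
        if not hasattr(self, "_template_"):
            self.fit()
        events = []
        for offset, chunk in self._chunks(rec):
            events.extend(self._detect_chunk(chunk, offset))
        events = self._dedupe(sorted(events, key=lambda e: e.start))
        for ev in events:
            ev.f0 = self._event_f0(rec, ev)
        return events

    detect = predict

    def _chunks(self, rec: Recording):
        step = self.chunk_s - self.chunk_overlap_s
        if step <= 0:
            raise ValueError("chunk overlap must be smaller than the chunk")
        n = len(rec.samples)
        sr = rec.sample_rate
        t = 0.0
        while True:
            i0 = int(round(t * sr))
            if i0 >= n:
                break
            i1 = min(int(round((t + self.chunk_s) * sr)), n)
            if i1 - i0 >= self.fft_size:
                yield t, Recording(rec.samples[i0:i1], sr, rec.source_id)
            if i1 >= n:
                break
            t += step

    def _detect_chunk(self, chunk: Recording, offset: float) -> list:
        spec = stft_spectrogram(chunk, self.fft_size, self.hop, self.window)
        med = np.median(spec.magnitudes, axis=0)
        mad = np.median(np.abs(spec.magnitudes - med[None, :]), axis=0)
        noise = NoiseProfile(med + self.noise_mad_k * 1.4826 * mad, spec.bin_freqs)
        focused = apply_focal_template(spec, noise, self._template_)
        if len(focused) == 0:
            return []
        labels = spectral_cluster(
            build_affinity(focused.points, self.sigma_t, self.sigma_f),
            k=min(self.k, len(focused)),
            seed=self.seed,
            n_restarts=self.n_restarts,
        )
        events = []
        for lbl in np.unique(labels):
            mask = labels == lbl
            cluster = TFCluster(focused.frames[mask], focused.bins[mask])
            density = cluster_density(cluster)
            if density < self.density_threshold:
                continue
            smashed, peak = smash_cluster(cluster, self.smash_kernel)
            if peak < self.peak_threshold:
                continue
            events.extend(self._shape_events(cluster, spec, offset, peak, density))
        return events

    def _shape_events(self, cluster, spec, offset, peak, density) -> list:
        # boundaries from contiguous runs of frames that actually hold points;
        # the smashed score gates but would smear edges by ~kernel/2 frames
        lo, _ = cluster.span
        counts = cluster.frame_counts()
        events = []
        active = counts > 0
        edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            t_start = spec.frame_times[lo + a] + offset - 0.5 * self.fft_size / self._sr(spec)
            t_end = spec.frame_times[lo + b - 1] + offset + 0.5 * self.fft_size / self._sr(spec)
            events.append(
                BuzzEvent(start=float(t_start), end=float(t_end), f0=float("nan"),
                          peak_score=peak, cluster_density=density)
            )
        return self._merge_close(events)

    @staticmethod
    def _sr(spec: Spectrogram) -> float:
        return float(spec.fft_size * (spec.bin_freqs[1] - spec.bin_freqs[0]))

    def _merge_close(self, events: list) -> list:
        events = sorted(events, key=lambda e: e.start)
        merged: list = []
        for ev in events:
            if merged and ev.start - merged[-1].end < self.merge_gap_s:
                prev = merged[-1]
                merged[-1] = BuzzEvent(
                    start=prev.start,
                    end=max(prev.end, ev.end),
                    f0=float("nan"),
                    peak_score=max(prev.peak_score, ev.peak_score),
                    cluster_density=max(prev.cluster_density, ev.cluster_density),
                )
            else:
                merged.append(ev)
        return [e for e in merged if e.end - e.start >= self.min_event_s]

    def _dedupe(self, events: list) -> list:
        """Merge duplicate detections across chunk overlaps (>50% overlap of
        the shorter event) and re-apply the proximity merge."""
        out: list = []
        for ev in events:
            if out:
                prev = out[-1]
                overlap = min(prev.end, ev.end) - max(prev.start, ev.start)
                shorter = min(prev.end - prev.start, ev.end - ev.start)
                if overlap > 0.5 * shorter or ev.start - prev.end < self.merge_gap_s:
                    out[-1] = BuzzEvent(
                        start=min(prev.start, ev.start),
                        end=max(prev.end, ev.end),
                        f0=float("nan"),
                        peak_score=max(prev.peak_score, ev.peak_score),
                        cluster_density=max(prev.cluster_density, ev.cluster_density),
                    )
                    continue
            out.append(ev)
        return [e for e in out if e.end - e.start >= self.min_event_s]

    def _event_f0(self, rec: Recording, ev: BuzzEvent) -> float:
        sr = rec.sample_rate
        i0 = max(int(ev.start * sr), 0)
        i1 = min(int(np.ceil(ev.end * sr)), len(rec.samples))
        fft = self.charfreq_fft
        while fft > 64 and i1 - i0 < fft:
            fft //= 2
        if i1 - i0 < fft:
            return float("nan")
        seg = Recording(rec.samples[i0:i1], sr)
        spec = stft_spectrogram(seg, fft_size=fft, hop=max(fft // 2, 1), window="hamming")
        tpl = self._template_
        cf = characteristic_frequency(
            smooth_spectrum(spec.magnitudes.mean(axis=0)), spec.bin_freqs, band=tpl.band
        )
        return float("nan") if cf is None else cf.f0


def detect_buzzes(rec: Recording, detector: BuzzDetector | None = None, **params) -> list:
    """Functional front end to :class:`BuzzDetector`."""
    det = detector or BuzzDetector(**params)
    return det.fit().predict(rec)


def buzz_density(events, duration_h: float) -> float:
    """Buzzes per hour: event count over recording duration in hours.

    Additive across recordings: pooling counts and durations gives the
    duration-weighted mean density.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive (hours)")
    n = len(events) if hasattr(events, "__len__") else int(events)
    return n / duration_h
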