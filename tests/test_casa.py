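"""CASA detector: focal templates, spectral clustering, gates, events."""

import itertools

import numpy as np
import pytest

from buzzfield import (
    BuzzDetector,
    BuzzSpec,
    FocalTemplateConfig,
    NoiseProfile,
    Recording,
    apply_focal_template,
    build_affinity,
    buzz_density,
    cluster_density,
    smash_cluster,
    spectral_cluster,
    stft_spectrogram,
    synth_buzz,
)
from buzzfield.casa import TFCluster

from conftest import place_buzzes

SR = 11025.0


def focused_for(f0, duration=0.5, pad=0.75):
    buzz = synth_buzz(BuzzSpec(f0=f0, duration=duration), SR)
    sil = np.zeros(int(pad * SR))
    rec = Recording(np.concatenate([sil, buzz.samples, sil]), SR)
    spec = stft_spectrogram(rec, 1024, 256)
    noise = NoiseProfile(np.zeros(spec.n_bins), spec.bin_freqs)
    return spec, apply_focal_template(spec, noise)


class TestFocalTemplate:
    def test_silence_retains_nothing(self):
        spec = stft_spectrogram(Recording(np.zeros(int(SR)), SR), 1024, 256)
        noise = NoiseProfile(np.zeros(spec.n_bins), spec.bin_freqs)
        assert len(apply_focal_template(spec, noise)) == 0

    def test_retained_bins_lie_on_harmonic_stacks(self):
        """Retained set matches a brute-force scan over (frame, candidate)."""
        spec, focused = focused_for(200.0)
        assert len(focused) > 0
        cfg = FocalTemplateConfig()
        mags = spec.magnitudes
        floor = cfg.floor_ratio * mags.max()
        cands = cfg.f0_grid_bins(spec.bin_freqs)
        retained = set(map(tuple, focused.points))
        oracle = set()
        for t in range(spec.n_frames):
            m = spec.magnitudes[t]
            above = m > floor
            peak = above.copy()
            peak[1:] &= m[1:] >= m[:-1]
            peak[:-1] &= m[:-1] >= m[1:]
            best, best_hits = None, 0
            for c in cands:
                hits = 0
                for h in range(1, cfg.n_harmonics + 1):
                    b0 = c * h
                    if b0 >= len(m):
                        continue
                    lo, hi = max(b0 - 1, 0), min(b0 + 1, len(m) - 1)
                    if any(peak[b] for b in range(lo, hi + 1)):
                        hits += 1
                if hits > best_hits:  # strict > keeps the lower-f0 tie rule
                    best, best_hits = c, hits
            if best_hits >= cfg.accept_min_harmonics:
                for h in range(1, cfg.n_harmonics + 1):
                    b0 = best * h
                    if b0 >= len(m):
                        continue
                    for b in range(max(b0 - 1, 0), min(b0 + 1, len(m) - 1) + 1):
                        if above[b]:
                            oracle.add((t, b))
        assert retained == oracle

    def test_retained_bins_near_true_harmonics(self):
        spec, focused = focused_for(200.0)
        df = spec.bin_width
        for t, b in focused.points:
            harmonic = round(spec.bin_freqs[b] / 200.0)
            assert 1 <= harmonic <= 5
            assert abs(spec.bin_freqs[b] - harmonic * 200.0) <= 2.5 * df

    def test_out_of_band_tone_rejected(self):
        buzz = synth_buzz(BuzzSpec(f0=1000.0, duration=0.5, n_harmonics=1), SR)
        rec = Recording(np.concatenate([np.zeros(8000), buzz.samples, np.zeros(8000)]), SR)
        spec = stft_spectrogram(rec, 1024, 256)
        noise = NoiseProfile(np.zeros(spec.n_bins), spec.bin_freqs)
        assert len(apply_focal_template(spec, noise)) == 0

    @pytest.mark.parametrize("f0,expected", [(150.0, True), (300.0, True), (90.0, False), (430.0, False)])
    def test_band_membership(self, f0, expected):
        _, focused = focused_for(f0)
        assert (len(focused) > 0) is expected


class TestAffinity:
    def test_identical_coordinates_give_unit_affinity(self):
        A = build_affinity(np.array([[3, 5], [3, 5]]))
        assert np.allclose(A, 1.0)

    def test_one_sigma_separation_closed_form(self):
        A = build_affinity(np.array([[0, 0], [3, 0]]), sigma_t=3.0, sigma_f=2.0)
        assert A[0, 1] == pytest.approx(np.exp(-0.5))

    def test_matches_hand_evaluated_kernel_on_five_points(self):
        pts = np.array([[0, 1], [1, 1], [4, 2], [0, 6], [2, 3]], dtype=float)
        st_, sf = 2.0, 1.5
        A = build_affinity(pts, sigma_t=st_, sigma_f=sf)
        for i, j in itertools.product(range(5), repeat=2):
            dt, db = pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]
            assert A[i, j] == pytest.approx(np.exp(-(dt ** 2 / (2 * st_ ** 2) + db ** 2 / (2 * sf ** 2))))
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 1.0)
        assert np.all((A > 0) & (A <= 1))

    def test_empty_input_signals_nothing_to_cluster(self):
        with pytest.raises(ValueError, match="[Nn]othing to cluster"):
            build_affinity(np.empty((0, 2)))


def normalized_cut(A, labels, k):
    """Exhaustive-search objective: sum of cut(c, rest)/vol(c) over clusters."""
    total = 0.0
    for c in range(k):
        inside = labels == c
        if not inside.any():
            return np.inf
        cut = A[inside][:, ~inside].sum()
        vol = A[inside].sum()
        total += cut / vol
    return total


def best_partition_bruteforce(A, k):
    n = A.shape[0]
    best, best_obj = None, np.inf
    for assign in itertools.product(range(k), repeat=n):
        labels = np.array(assign)
        if len(set(assign)) < k:
            continue
        obj = normalized_cut(A, labels, k)
        if obj < best_obj - 1e-12:
            best, best_obj = labels, obj
    return best


def as_partition(labels):
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


class TestSpectralClustering:
    def test_block_diagonal_groups_recovered(self):
        A = np.full((6, 6), 0.01)
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        labels = spectral_cluster(A, k=2, seed=0)
        assert as_partition(labels) == as_partition([0, 0, 0, 1, 1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_normalized_cut_oracle(self, seed):
        """On small well-separated instances the embedding + k-means solution
        equals the exhaustive minimum-normalized-cut partition."""
        rng = np.random.default_rng(seed)
        centers = [(0, 0), (12, 0), (5, 14)][: 2 + seed % 2]
        pts = np.concatenate(
            [c + rng.uniform(-1, 1, (2 + seed % 3, 2)) for c in np.array(centers, dtype=float)]
        )
        pts = pts[:8]
        A = build_affinity(pts, sigma_t=2.0, sigma_f=2.0)
        k = len(centers)
        ours = spectral_cluster(A, k=k, seed=0)
        oracle = best_partition_bruteforce(A, k)
        assert as_partition(ours) == as_partition(oracle)

    def test_single_group_splits_into_partition(self):
        pts = np.column_stack([np.arange(8), np.zeros(8)])
        A = build_affinity(pts)
        labels = spectral_cluster(A, k=3, seed=0)
        assert set(labels) == {0, 1, 2}
        assert len(labels) == 8  # disjoint and exhaustive by construction

    def test_k_exceeding_points_gives_singletons(self):
        A = build_affinity(np.array([[0, 0], [1, 1]], dtype=float))
        labels = spectral_cluster(A, k=5)
        assert sorted(labels) == [0, 1]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        A = build_affinity(rng.uniform(0, 20, (12, 2)))
        l1 = spectral_cluster(A, k=3, seed=7)
        l2 = spectral_cluster(A, k=3, seed=7)
        assert np.array_equal(l1, l2)

    def test_asymmetric_affinity_rejected(self):
        A = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            spectral_cluster(A, k=1)


class TestGates:
    def test_density_boundary_inclusive(self):
        cl = TFCluster(np.arange(10), np.zeros(10, dtype=int))
        assert cluster_density(cl) == 1.0  # 10 points over 10 frames

    def test_density_half(self):
        cl = TFCluster(np.arange(0, 10, 2), np.zeros(5, dtype=int))
        assert cluster_density(cl) == pytest.approx(5 / 9)

    def test_density_five_harmonics_per_frame(self):
        frames = np.repeat(np.arange(10), 5)
        cl = TFCluster(frames, np.tile(np.arange(5), 10))
        assert cluster_density(cl) == 5.0

    def test_empty_cluster_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            TFCluster(np.array([]), np.array([]))

    def test_sustained_run_passes_smash_gate(self):
        cl = TFCluster(np.arange(25), np.zeros(25, dtype=int))
        _, peak = smash_cluster(cl)
        assert peak >= 1.0

    def test_single_point_peak_is_one_twentieth(self):
        cl = TFCluster(np.array([5]), np.array([3]))
        _, peak = smash_cluster(cl)
        assert peak == pytest.approx(1 / 20)

    def test_dense_burst_inside_long_span(self):
        frames = np.concatenate([np.repeat(np.arange(15, 25), 3), [0, 39]])
        cl = TFCluster(frames, np.zeros(len(frames), dtype=int))
        _, peak = smash_cluster(cl)
        assert peak == pytest.approx(30 / 20)  # 3 points/frame x 10 frames in one window
        assert peak >= 1.0


class TestDetector:
    def test_noise_only_recording_has_no_events(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.normal(0, 0.01, int(30 * SR)), SR)
        assert BuzzDetector().fit().predict(rec) == []

    def test_seven_buzzes_detected_with_accurate_times(self):
        onsets = [2.0, 7.5, 14.0, 22.0, 31.0, 40.0, 49.0]
        f0s = [150, 180, 210, 240, 280, 320, 360]
        rec = place_buzzes(onsets, f0s, total_s=60.0, snr_db=20.0, seed=1)
        events = BuzzDetector().fit().predict(rec)
        assert len(events) == 7
        for ev, onset, f0 in zip(events, onsets, f0s):
            assert abs(ev.start - onset) <= 0.1
            assert abs(ev.end - (onset + 0.5)) <= 0.1
            assert abs(ev.f0 - f0) <= 2 * SR / 2048  # within 2 bins of truth

    def test_amplitude_scaling_preserves_event_count(self):
        rec = place_buzzes([1.0, 4.0], [200, 300], total_s=8.0, snr_db=20.0, seed=2)
        half = Recording(rec.samples * 0.5, SR)
        n_full = len(BuzzDetector().fit().predict(rec))
        n_half = len(BuzzDetector().fit().predict(half))
        assert n_full == n_half == 2

    def test_gate_soundness_of_emitted_events(self):
        rec = place_buzzes([1.0, 3.5, 6.5], [160, 250, 340], total_s=10.0, snr_db=20.0, seed=3)
        for ev in BuzzDetector().fit().predict(rec):
            assert ev.cluster_density >= 1.0
            assert ev.peak_score >= 1.0

    def test_inserting_one_buzz_adds_exactly_one_event(self):
        base_onsets, base_f0s = [2.0, 8.0], [180, 300]
        rec0 = place_buzzes(base_onsets, base_f0s, total_s=16.0, snr_db=20.0, seed=4)
        rec1 = place_buzzes(base_onsets + [12.5], base_f0s + [240], total_s=16.0,
                            snr_db=20.0, seed=4)
        det = BuzzDetector().fit()
        assert len(det.predict(rec1)) == len(det.predict(rec0)) + 1


class TestBuzzDensity:
    def test_zero_events(self):
        assert buzz_density([], 2.0) == 0.0

    def test_rate_arithmetic(self):
        assert buzz_density(range(100), 0.25) == 400.0

    def test_pooling_is_weighted_mean(self):
        d = buzz_density(range(100 + 40), 0.25 + 0.5)
        w = (100 / 0.25 * 0.25 + 40 / 0.5 * 0.5) / 0.75
        assert d == pytest.approx(w)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            buzz_density([], 0.0)
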