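import numpy as np
import pytest

from buzzfield import BuzzSpec, Recording, synth_buzz


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def buzz_175():
    """1 s harmonic buzz at the canonical 175 Hz example, amplitudes 1/h."""
    return synth_buzz(
        BuzzSpec(f0=175.0, duration=1.0, amplitudes=(1, 1 / 2, 1 / 3, 1 / 4, 1 / 5)),
        sample_rate=11025.0,
    )


def place_buzzes(onsets, f0s, total_s, sr=11025.0, snr_db=20.0, seed=0, duration=0.5):
    """Scene with buzzes at known onsets over white noise; returns Recording."""
    rng = np.random.default_rng(seed)
    n = int(total_s * sr)
    buzz_rms = 0.1
    noise_rms = 0.0 if np.isinf(snr_db) else buzz_rms / 10 ** (snr_db / 20)
    scene = rng.normal(0.0, noise_rms, n) if noise_rms else np.zeros(n)
    for onset, f0 in zip(onsets, f0s):
        b = synth_buzz(BuzzSpec(f0=f0, duration=duration, f0_jitter_sd=1.0), sr, rng=rng,
                       rms=buzz_rms)
        i0 = int(onset * sr)
        scene[i0:i0 + len(b.samples)] += b.samples[: n - i0]
    return Recording(scene, sr, source_id="placed_scene")
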