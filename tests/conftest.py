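import numpy as np
import pytest

from ecghorizon import synthetic_data as sd
from ecghorizon.signal_io import FeatureSample


@pytest.fixture(scope="session")
def small_corpus():
    """~900 feature samples from three 240 s stress-profile records, horizons 1..10."""
    horizons = list(range(1, 11))
    cfg = sd.stress_profile(duration_s=240.0, seed=5, mean_dwell_s=25.0,
                            pre_transition_drift_s=8.0)
    samples, manifest = sd.generate_dataset(cfg, 3, horizons=horizons)
    return samples, manifest, horizons


@pytest.fixture(scope="session")
def separable_samples():
    """Linearly separable single-horizon fixture: three well-separated Gaussian
    clusters in feature space, one sample per record id (windows self-repeat)."""
    rng = np.random.default_rng(42)
    dim, per_class = 20, 60
    centers = np.zeros((3, dim))
    centers[0, 0], centers[1, 1], centers[2, 2] = 8.0, 8.0, 8.0
    samples = []
    for cls in range(3):
        pts = centers[cls] + rng.normal(0, 0.5, size=(per_class, dim))
        for i, p in enumerate(pts):
            samples.append(FeatureSample(features=p, labels=np.array([cls]),
                                         record_id=f"sep-{cls}-{i}", t_ref_s=0.0))
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]
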