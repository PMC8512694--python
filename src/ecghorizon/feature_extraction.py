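"""Beat-pair features: full convolution and cross-correlation.

Two consecutive beats X1, X2 (each standardized to length L) are combined
into a single feature vector: the full linear convolution (2L-1 terms,
capturing symmetric morphology overlap) concatenated with the full
cross-correlation over lags -(L-1)..(L-1) (2L-1 terms, capturing
asymmetric shift structure).  For L=100 this gives 199+199 = 398 inputs.
Each feature vector carries one class label per prediction horizon,
looked up at the pair's terminating R-wave time plus the lead time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .beat_segmentation import Beat, zscore_beat
from .signal_io import EcgRecord, FeatureSample, class_at


@dataclass
class BeatPair:
    """Two immediately consecutive beats; ``t_ref_s`` is x2's closing R time."""

    x1: Beat
    x2: Beat

    def __post_init__(self) -> None:
        if abs(self.x1.r_end_s - self.x2.r_start_s) > 1e-9:
            raise ValueError("beats in a pair must be consecutive (shared R wave)")

    @property
    def t_ref_s(self) -> float:
        return self.x2.r_end_s


def full_convolution(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Full linear convolution: out[n] = sum_k x1[k] x2[n-k], n = 0..2L-2."""
    x1, x2 = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError(f"inputs must be equal-length 1-D, got {x1.shape} vs {x2.shape}")
    return np.convolve(x1, x2, mode="full")


def full_cross_correlation(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Full cross-correlation, lags -(L-1)..(L-1) stored left to right.

    out[k + L - 1] = sum_n x1[n] x2[n + k].  Equivalent to convolving x1
    with the reversal of x2 and reading the result back to front.
    """
    x1, x2 = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError(f"inputs must be equal-length 1-D, got {x1.shape} vs {x2.shape}")
    # np.correlate(x1, x2, 'full')[i] = sum_n x1[n + i - (L-1)] x2[n]
    #                                 = sum_m x1[m] x2[m - (i - (L-1))]
    # i.e. lag k = -(i-(L-1)); reverse to store lag k at index k + L - 1.
    return np.correlate(x1, x2, mode="full")[::-1]


def pair_features(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Concatenate convolution and cross-correlation of a z-scored beat pair."""
    z1, z2 = zscore_beat(x1), zscore_beat(x2)
    return np.concatenate([full_convolution(z1, z2), full_cross_correlation(z1, z2)])


def build_samples(
    beats: Sequence[Beat],
    record: EcgRecord,
    horizons: Sequence[int],
    L: int = 100,
) -> list[FeatureSample]:
    """Featurize every consecutive beat pair with full horizon label coverage.

    The pair anchored at terminating R time t gets labels class_at(t + k)
    for each horizon k; any pair with an unlabeled horizon time is dropped
    (no imputation at record boundaries).
    """
    horizons = [int(h) for h in horizons]
    out: list[FeatureSample] = []
    for b1, b2 in zip(beats, beats[1:]):
        pair = BeatPair(b1, b2)
        labels = [class_at(record, pair.t_ref_s + k) for k in horizons]
        if any(lab is None for lab in labels):
            continue
        out.append(
            FeatureSample(
                features=pair_features(b1.samples, b2.samples),
                labels=np.array(labels, dtype=int),
                record_id=record.record_id,
                t_ref_s=pair.t_ref_s,
            )
        )
    return out
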