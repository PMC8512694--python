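"""QRS detection and beat segmentation.

Classic energy-based QRS chain: DC-offset removal, 10–30 Hz zero-phase
bandpass (the band where QRS energy concentrates), five-point derivative,
squaring, moving-window integration, then adaptive dual-threshold peak
picking with a refractory period (Pan–Tompkins conventions).  A beat is
the signal between two consecutive R waves, standardized to a fixed
length L with zero padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .signal_io import EcgRecord

#: standardized beat length (samples) after resampling/padding
DEFAULT_L = 100
#: resampling grid for the raw R-to-R slice before padding/truncation
BEAT_GRID_HZ = 100.0

REFRACTORY_S = 0.200
INTEGRATION_WINDOW_S = 0.150
THRESHOLD_FRACTION = 0.25
SEARCH_TOL_S = 0.050  # refine peaks to the bandpassed local max within ±50 ms


@dataclass
class RPeakList:
    """Strictly increasing R-wave times (seconds) for one record."""

    record_id: str
    peaks_s: np.ndarray

    def __post_init__(self) -> None:
        self.peaks_s = np.asarray(self.peaks_s, dtype=float)
        if self.peaks_s.size > 1 and not np.all(np.diff(self.peaks_s) > 0):
            raise ValueError("R-peak times must be strictly increasing")


@dataclass
class Beat:
    """One R-to-R segment standardized to length L."""

    record_id: str
    r_start_s: float
    r_end_s: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.r_end_s > self.r_start_s:
            raise ValueError("beat end must exceed start")


# ---------------------------------------------------------------------------
# Filter chain
# ---------------------------------------------------------------------------


def remove_dc(x: np.ndarray) -> np.ndarray:
    """Subtract the arithmetic mean (DC offset)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return x - x.mean()


def bandpass_10_30(x: np.ndarray, fs: float, low_hz: float = 10.0,
                   high_hz: float = 30.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass isolating the QRS band."""
    x = np.asarray(x, dtype=float)
    if fs <= 2 * high_hz:
        raise ValueError(f"fs={fs} too low: passband edge {high_hz} Hz needs fs > {2*high_hz}")
    sos = sig.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    padlen = min(x.size - 1, 3 * 2 * order * 10)
    return sig.sosfiltfilt(sos, x, padlen=padlen)


def derivative_filter(x: np.ndarray, fs: float) -> np.ndarray:
    """Five-point derivative (1/8)[-1,-2,0,2,1] scaled by fs; amplifies QR/RS slopes."""
    x = np.asarray(x, dtype=float)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    # np.convolve flips the kernel, so pass it reversed relative to the tap order
    return np.convolve(x, kernel[::-1], mode="same")


def squaring(x: np.ndarray) -> np.ndarray:
    return np.square(np.asarray(x, dtype=float))


def moving_window_integrate(x: np.ndarray, fs: float,
                            width_s: float = INTEGRATION_WINDOW_S) -> np.ndarray:
    """Centered moving average over a window of round(width_s*fs) samples."""
    x = np.asarray(x, dtype=float)
    if width_s <= 0:
        raise ValueError("window width must be positive")
    w = max(1, int(round(width_s * fs)))
    if w > x.size:
        raise ValueError(f"window of {w} samples longer than signal ({x.size})")
    kernel = np.full(w, 1.0 / w)
    return np.convolve(x, kernel, mode="same")


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------


def detect_r_peaks(record: EcgRecord, refractory_s: float = REFRACTORY_S,
                   threshold_fraction: float = THRESHOLD_FRACTION) -> RPeakList:
    """Locate R waves via the integrate-and-threshold chain.

    Candidate peaks of the integrated energy envelope are accepted by an
    adaptive dual threshold (running signal/noise level estimates); each
    accepted candidate is refined to the local maximum of the bandpassed
    signal within ±50 ms.  Returns an empty list when nothing crosses
    threshold (e.g. a flat line).
    """
    fs = record.fs
    if record.duration_s < 2.0:
        raise ValueError("record must be at least 2 s long")
    x = remove_dc(record.samples)
    if np.allclose(x, 0.0):
        return RPeakList(record.record_id, np.empty(0))
    bp = bandpass_10_30(x, fs)
    integ = moving_window_integrate(squaring(derivative_filter(bp, fs)), fs)

    min_dist = max(1, int(round(refractory_s * fs)))
    cand, _ = sig.find_peaks(integ, distance=min_dist)
    if cand.size == 0:
        return RPeakList(record.record_id, np.empty(0))

    # Adaptive dual threshold (Pan–Tompkins style running estimates),
    # initialized from the first two seconds of the envelope.
    lead = integ[: int(2 * fs)]
    spki = 0.875 * float(lead.max())
    npki = float(lead.mean()) * 0.5
    accepted: list[int] = []
    for idx in cand:
        pk = integ[idx]
        thr = npki + threshold_fraction * (spki - npki)
        if pk > thr:
            spki = 0.125 * pk + 0.875 * spki
            accepted.append(idx)
        else:
            npki = 0.125 * pk + 0.875 * npki

    if not accepted:
        return RPeakList(record.record_id, np.empty(0))

    # Refine each envelope peak to the bandpassed local maximum within ±50 ms.
    half = int(round(SEARCH_TOL_S * fs))
    refined: list[int] = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(bp.size, idx + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))

    # Dedupe refined positions that collapsed within the refractory period.
    refined = sorted(set(refined))
    kept: list[int] = []
    for idx in refined:
        if kept and idx - kept[-1] < min_dist:
            if bp[idx] > bp[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    return RPeakList(record.record_id, np.array(kept, dtype=float) / fs)


# ---------------------------------------------------------------------------
# Beat segmentation
# ---------------------------------------------------------------------------


def standardize_beat(raw: np.ndarray, fs: float, L: int = DEFAULT_L,
                     grid_hz: float = BEAT_GRID_HZ) -> np.ndarray:
    """Resample an R-to-R slice to the beat grid, then zero-pad or truncate to L.

    The slice is linearly resampled to ``grid_hz`` (so typical 0.6–1.0 s
    beats occupy 60–100 samples); shorter results are right-padded with
    zeros, longer ones truncated at the tail.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return np.zeros(L)
    n_out = max(1, int(round(raw.size * grid_hz / fs)))
    t_in = np.arange(raw.size) / fs
    t_out = np.arange(n_out) / grid_hz
    resampled = np.interp(t_out, t_in, raw)
    if n_out >= L:
        return resampled[:L]
    return np.concatenate([resampled, np.zeros(L - n_out)])


def zscore_beat(samples: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-beat amplitude normalization (mean 0, unit variance, ε guard)."""
    samples = np.asarray(samples, dtype=float)
    return (samples - samples.mean()) / (samples.std() + eps)


def segment_beats(record: EcgRecord, peaks: RPeakList, L: int = DEFAULT_L) -> list[Beat]:
    """Cut the record into R-to-R beats; beat i spans [peaks[i], peaks[i+1])."""
    times = peaks.peaks_s
    if times.size < 2:
        raise ValueError("need at least 2 R peaks to form a beat")
    fs = record.fs
    beats = []
    for t0, t1 in zip(times, times[1:]):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        raw = record.samples[i0:i1]
        beats.append(
            Beat(record.record_id, float(t0), float(t1), standardize_beat(raw, fs, L))
        )
    return beats
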