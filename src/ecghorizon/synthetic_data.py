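"""Synthetic labeled ECG records with class-dependent dynamics.

The generator emulates the structure the forecaster assumes: a driver (or
sleeper) moves between three states under a semi-Markov chain; each state
has its own mean heart rate and R-wave amplitude; in a configurable window
before each state switch, heart rate and amplitude drift linearly toward
the next state's values, so future labels are partially predictable from
current beats.  Beats are rendered as a derivative-of-Gaussian QRS plus
small P/T bumps and white noise — enough morphology for a 10–30 Hz QRS
detector, with exact ground-truth R times and state paths for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import beat_segmentation as seg
from . import feature_extraction as fx
from .signal_io import EcgRecord, FeatureSample, LabelInterval

#: class mixing ratios of the two emulated study corpora (majority-first),
#: scaled from published per-class sample counts (40k/38k/16k and 76k/35k/20k)
STRESS_MIX = (0.425, 0.404, 0.170)
DROWSINESS_MIX = (0.580, 0.267, 0.153)

STRESS_HR_BPM = (70.0, 85.0, 100.0)       # LSL, MSL, HSL
DROWSINESS_HR_BPM = (72.0, 62.0, 55.0)    # alert, sleep stage 1, sleep stage 2


@dataclass
class GeneratorConfig:
    duration_s: float = 600.0
    fs: float = 250.0
    class_hr_bpm: tuple[float, float, float] = STRESS_HR_BPM
    hr_jitter_cv: float = 0.03
    class_amp: tuple[float, float, float] = (1.0, 1.15, 1.3)
    dwell_mean_s: Optional[tuple[float, float, float]] = None
    mean_dwell_s: float = 40.0
    transition_matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
    )
    pre_transition_drift_s: float = 10.0
    noise_sd: float = 0.05
    dc_offset: float = 0.2
    class_mix: tuple[float, float, float] = STRESS_MIX
    fixed_dwell: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.diag(self.transition_matrix) != 0):
            raise ValueError("transition matrix diagonal must be zero")
        if not self.fs > 60:
            raise ValueError("fs must exceed 60 Hz")
        if self.dwell_mean_s is None:
            # occupancy of a semi-Markov chain ∝ embedded stationary × dwell;
            # with a symmetric embedded chain the dwell means set the mix.
            mix = np.asarray(self.class_mix, dtype=float)
            dwell = mix / mix.mean() * self.mean_dwell_s
            self.dwell_mean_s = tuple(dwell)
        if any(d <= 0 for d in self.dwell_mean_s):
            raise ValueError("dwell means must be positive")


@dataclass
class GroundTruth:
    r_peak_times_s: np.ndarray
    state_path: list[LabelInterval]
    beat_classes: np.ndarray


def stress_profile(**overrides) -> GeneratorConfig:
    return GeneratorConfig(class_hr_bpm=STRESS_HR_BPM, class_mix=STRESS_MIX, **overrides)


def drowsiness_profile(**overrides) -> GeneratorConfig:
    return GeneratorConfig(
        class_hr_bpm=DROWSINESS_HR_BPM, class_mix=DROWSINESS_MIX, **overrides
    )


# ---------------------------------------------------------------------------
# State path
# ---------------------------------------------------------------------------


def _sample_state_path(cfg: GeneratorConfig, rng: np.random.Generator) -> list[LabelInterval]:
    mix = np.asarray(cfg.class_mix, dtype=float)
    state = int(rng.choice(3, p=mix / mix.sum()))
    t = 0.0
    path: list[LabelInterval] = []
    while t < cfg.duration_s:
        mean = cfg.dwell_mean_s[state]
        dwell = mean if cfg.fixed_dwell else float(rng.exponential(mean))
        dwell = max(dwell, 1.0)  # avoid zero-length states
        end = min(t + dwell, cfg.duration_s)
        path.append(LabelInterval(t, end, state))
        t = end
        state = int(rng.choice(3, p=cfg.transition_matrix[state]))
    return path


def _state_at(path: list[LabelInterval], t: float) -> int:
    for iv in path:
        if iv.start_s <= t < iv.end_s:
            return iv.cls
    return path[-1].cls


def _drifted_params(cfg: GeneratorConfig, path: list[LabelInterval], t: float
                    ) -> tuple[float, float]:
    """HR (bpm) and amplitude at time t, drifting toward the next state."""
    for i, iv in enumerate(path):
        if iv.start_s <= t < iv.end_s:
            hr = cfg.class_hr_bpm[iv.cls]
            amp = cfg.class_amp[iv.cls]
            remain = iv.end_s - t
            drift = cfg.pre_transition_drift_s
            if drift > 0 and remain < drift and i + 1 < len(path):
                nxt = path[i + 1].cls
                frac = 1.0 - remain / drift
                hr = (1 - frac) * hr + frac * cfg.class_hr_bpm[nxt]
                amp = (1 - frac) * amp + frac * cfg.class_amp[nxt]
            return hr, amp
    last = path[-1].cls
    return cfg.class_hr_bpm[last], cfg.class_amp[last]


# ---------------------------------------------------------------------------
# Signal rendering
# ---------------------------------------------------------------------------

_QRS_SIGMA_S = 0.010   # 40 ms QRS width ~ ±2 sigma
_P_DELAY_S, _P_SIGMA_S, _P_AMP = -0.16, 0.025, 0.12
_T_DELAY_S, _T_SIGMA_S, _T_AMP = 0.30, 0.050, 0.25


def _add_bump(samples: np.ndarray, fs: float, center_s: float, sigma_s: float,
              amp: float) -> None:
    half = int(4 * sigma_s * fs)
    c = int(round(center_s * fs))
    lo, hi = max(0, c - half), min(samples.size, c + half + 1)
    if lo >= hi:
        return
    t = (np.arange(lo, hi) / fs) - center_s
    samples[lo:hi] += amp * np.exp(-0.5 * (t / sigma_s) ** 2)


def _add_qrs(samples: np.ndarray, fs: float, r_time_s: float, amp: float) -> None:
    """Derivative-of-Gaussian QRS whose positive lobe peaks at ``r_time_s``."""
    s = _QRS_SIGMA_S
    half = int(5 * s * fs)
    c = int(round(r_time_s * fs))
    lo, hi = max(0, c - half), min(samples.size, c + half + 1)
    if lo >= hi:
        return
    t = (np.arange(lo, hi) / fs) - r_time_s
    u = t - s  # shift so the positive lobe of -u·exp(-u²/2s²) sits at t=0
    samples[lo:hi] += amp * (-(u / s) * np.exp(-0.5 * (u / s) ** 2)) / np.exp(-0.5)


def generate_record(cfg: GeneratorConfig) -> tuple[EcgRecord, GroundTruth]:
    """Render one labeled synthetic record with exact ground truth."""
    rng = np.random.default_rng(cfg.seed)
    path = _sample_state_path(cfg, rng)

    r_times: list[float] = []
    t = 0.25  # leave room for the first P wave
    while t < cfg.duration_s - 0.35:
        r_times.append(t)
        hr, _ = _drifted_params(cfg, path, t)
        rr = 60.0 / hr
        if cfg.hr_jitter_cv > 0:
            rr *= float(np.exp(rng.normal(0.0, cfg.hr_jitter_cv)))
        t += rr

    n = int(round(cfg.duration_s * cfg.fs))
    samples = np.full(n, cfg.dc_offset)
    for rt in r_times:
        _, amp = _drifted_params(cfg, path, rt)
        _add_qrs(samples, cfg.fs, rt, amp)
        _add_bump(samples, cfg.fs, rt + _P_DELAY_S, _P_SIGMA_S, _P_AMP * amp)
        _add_bump(samples, cfg.fs, rt + _T_DELAY_S, _T_SIGMA_S, _T_AMP * amp)
    if cfg.noise_sd > 0:
        samples += rng.normal(0.0, cfg.noise_sd, size=n)

    record = EcgRecord(
        record_id=f"synth-{cfg.seed}", fs=cfg.fs, samples=samples, labels=path
    )
    truth = GroundTruth(
        r_peak_times_s=np.array(r_times),
        state_path=path,
        beat_classes=np.array([_state_at(path, rt) for rt in r_times], dtype=int),
    )
    return record, truth


# ---------------------------------------------------------------------------
# Corpus generation and detector scoring
# ---------------------------------------------------------------------------


def score_r_detection(detected_s: np.ndarray, truth_s: np.ndarray,
                      tol_s: float = 0.050) -> tuple[float, float]:
    """(sensitivity, positive predictivity) of detected vs true R times.

    Greedy one-to-one matching in time order within ±tol_s.
    """
    detected = np.sort(np.asarray(detected_s, dtype=float))
    truth = np.sort(np.asarray(truth_s, dtype=float))
    i = j = matches = 0
    while i < detected.size and j < truth.size:
        d = detected[i] - truth[j]
        if abs(d) <= tol_s:
            matches += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    sens = matches / truth.size if truth.size else 1.0
    ppv = matches / detected.size if detected.size else 1.0
    return sens, ppv


def generate_dataset(
    cfg: GeneratorConfig,
    n_records: int,
    horizons: Sequence[int] = tuple(range(1, 61)),
    L: int = 100,
) -> tuple[list[FeatureSample], dict]:
    """Generate records, run segmentation + featurization, return corpus + manifest.

    Record ``i`` uses seed ``cfg.seed + i``.  The manifest carries per-record
    seeds, ground-truth R counts/times and label paths so detectors and
    forecasters can be scored against construction truth.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    import dataclasses as _dc

    samples: list[FeatureSample] = []
    manifest: dict = {"seed": cfg.seed, "n_records": n_records, "records": []}
    for i in range(n_records):
        sub = _dc.replace(cfg, seed=cfg.seed + i)
        record, truth = generate_record(sub)
        peaks = seg.detect_r_peaks(record)
        entry = {
            "record_id": record.record_id,
            "seed": sub.seed,
            "true_r_count": int(truth.r_peak_times_s.size),
            "true_r_times_s": truth.r_peak_times_s.tolist(),
            "detected_r_count": int(peaks.peaks_s.size),
            "labels": [(iv.start_s, iv.end_s, iv.cls) for iv in truth.state_path],
        }
        manifest["records"].append(entry)
        if peaks.peaks_s.size >= 2:
            beats = seg.segment_beats(record, peaks, L)
            samples.extend(fx.build_samples(beats, record, horizons, L))
    return samples, manifest
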