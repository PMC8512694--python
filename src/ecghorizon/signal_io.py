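"""Record and table I/O for the ECG state-forecasting pipeline.

The unit of input is a single-lead ECG record: a sample array, its sampling
rate and a track of labeled class intervals (three classes, e.g. low /
medium / high stress level, or alert / sleep stage 1 / sleep stage 2).
Records and annotations travel as small delimited-text files; feature
tables carry a JSON sidecar header so that they round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

N_CLASSES = 3


class ValidationError(ValueError):
    """A parsed object violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed under the requested dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelInterval:
    """Half-open labeled time span ``[start_s, end_s)`` with class id 0–2."""

    start_s: float
    end_s: float
    cls: int

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"interval end {self.end_s} must exceed start {self.start_s}"
            )
        if self.cls not in range(N_CLASSES):
            raise ValidationError(f"class id {self.cls} not in 0..{N_CLASSES - 1}")


@dataclass
class EcgRecord:
    """Single-lead ECG: samples, sampling rate and labeled class intervals.

    Time zero is the first sample.  Label intervals must be sorted,
    non-overlapping and contained in ``[0, duration]``.
    """

    record_id: str
    fs: float
    samples: np.ndarray
    labels: list[LabelInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValidationError("record has no samples")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        validate_intervals(self.labels, self.duration_s)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def validate_intervals(labels: Sequence[LabelInterval], duration_s: float) -> None:
    for a, b in zip(labels, labels[1:]):
        if b.start_s < a.end_s:
            raise ValidationError(
                f"label intervals overlap or are unsorted: "
                f"[{a.start_s},{a.end_s}) then [{b.start_s},{b.end_s})"
            )
    for iv in labels:
        if iv.start_s < 0 or iv.end_s > duration_s + 1e-9:
            raise ValidationError(
                f"interval [{iv.start_s},{iv.end_s}) outside record [0,{duration_s:.3f}]"
            )


def class_at(record: EcgRecord, t: float) -> Optional[int]:
    """Class id of the interval containing time ``t`` (half-open), else None."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    starts = [iv.start_s for iv in record.labels]
    i = int(np.searchsorted(starts, t, side="right")) - 1
    if i >= 0 and t < record.labels[i].end_s:
        return record.labels[i].cls
    return None


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run parameters.

    ``L`` is the standardized beat length; ``horizons`` the in-advance
    prediction lead times in seconds (default 1..60 s, 1 s step).  Nested
    dicts carry the filter / detector / training / optimizer blocks so a
    YAML file can override any subset.
    """

    L: int = 100
    horizons: tuple[int, ...] = tuple(range(1, 61))
    k_folds: int = 10
    rng_seed: int = 0
    filter: dict = field(
        default_factory=lambda: {"low_hz": 10.0, "high_hz": 30.0, "order": 4}
    )
    detector: dict = field(
        default_factory=lambda: {
            "integration_window_s": 0.150,
            "refractory_s": 0.200,
            "threshold_fraction": 0.25,
        }
    )
    training: dict = field(
        default_factory=lambda: {
            "hidden_size": 32,
            "window": 8,
            "epochs": 30,
            "learning_rate": 1e-3,
            "batch_size": 32,
            "clip_norm": 1.0,
        }
    )
    nsga3: dict = field(
        default_factory=lambda: {
            "pop_size": 92,
            "generations": 50,
            "divisions_p": 6,
            "sbx_eta": 30.0,
            "mutation_eta": 20.0,
            "mutation_rate": None,  # default 1/genome_length
        }
    )

    def __post_init__(self) -> None:
        self.horizons = tuple(int(h) for h in self.horizons)
        if self.L < 2:
            raise ValidationError("L must be >= 2")
        if any(h <= 0 for h in self.horizons) or any(
            b <= a for a, b in zip(self.horizons, self.horizons[1:])
        ):
            raise ValidationError("horizons must be strictly increasing positive ints")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key in ("filter", "detector", "training", "nsga3"):
            if key in raw:
                merged = dict(getattr(base, key))
                merged.update(raw[key])
                raw[key] = merged
        return dataclasses.replace(base, **raw)


# ---------------------------------------------------------------------------
# Record / annotation readers and writers
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> list[LabelInterval]:
    """Read a ``start_s,end_s,class`` CSV into sorted label intervals."""
    out: list[LabelInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if lineno == 1 and not _is_number(parts[0]):
            continue  # header row
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        try:
            out.append(LabelInterval(float(parts[0]), float(parts[1]), int(parts[2])))
        except ValidationError:
            raise
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    for a, b in zip(out, out[1:]):
        if b.start_s < a.end_s:
            raise ValidationError(
                f"{path}: intervals [{a.start_s},{a.end_s}) and "
                f"[{b.start_s},{b.end_s}) overlap or are unsorted"
            )
    return out


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_record(
    path: str | Path,
    dialect: str = "csv",
    fs: Optional[float] = None,
    annotations: Optional[str | Path] = None,
    time_column: str = "seconds",
) -> EcgRecord:
    """Read an ECG record.

    ``csv`` dialect: two columns, time (seconds or sample index, per
    ``time_column``) and amplitude.  With ``time_column='seconds'`` the
    sampling rate is inferred from the median time step unless ``fs`` is
    given; with ``'index'`` an explicit ``fs`` is required.  ``wfdb``
    dialect delegates to the optional :mod:`wfdb` package.
    """
    path = Path(path)
    if dialect == "wfdb":
        return _read_wfdb(path, annotations)
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")

    times: list[float] = []
    amps: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if lineno == 1 and not _is_number(parts[0]):
            continue
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
        try:
            times.append(float(parts[0]))
            amps.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not amps:
        raise ParseError(f"{path}: no data rows")

    if fs is None:
        if time_column != "seconds":
            raise ValueError("fs is required when the time column is a sample index")
        dt = np.median(np.diff(times))
        if dt <= 0:
            raise ParseError(f"{path}: time column is not increasing")
        fs = 1.0 / float(dt)

    labels = read_annotations(annotations) if annotations is not None else []
    return EcgRecord(record_id=path.stem, fs=fs, samples=np.array(amps), labels=labels)


def write_record(record: EcgRecord, path: str | Path,
                 annotations: Optional[str | Path] = None) -> None:
    path = Path(path)
    t = np.arange(record.samples.size) / record.fs
    lines = ["t_s,amplitude"]
    lines += [f"{ti:.9f},{ai:.17g}" for ti, ai in zip(t, record.samples)]
    path.write_text("\n".join(lines) + "\n")
    if annotations is not None:
        alines = ["start_s,end_s,class"]
        alines += [f"{iv.start_s:.9f},{iv.end_s:.9f},{iv.cls}" for iv in record.labels]
        Path(annotations).write_text("\n".join(alines) + "\n")


def _read_wfdb(path: Path, annotations) -> EcgRecord:
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the 'wfdb' dialect requires the optional wfdb package; "
            "use the csv dialect otherwise"
        ) from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover
    labels = read_annotations(annotations) if annotations is not None else []
    return EcgRecord(  # pragma: no cover
        record_id=rec.record_name, fs=float(rec.fs),
        samples=np.asarray(rec.p_signal[:, 0], dtype=float), labels=labels,
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureSample:
    """One training sample: 2(2L-1) features plus one class label per horizon."""

    features: np.ndarray
    labels: np.ndarray  # int class per configured horizon
    record_id: str
    t_ref_s: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.features.ndim != 1:
            raise ValidationError("features and labels must be 1-D")
        if not np.all((self.labels >= 0) & (self.labels < N_CLASSES)):
            raise ValidationError("labels must be class ids in 0..2")


def write_feature_table(
    samples: Sequence[FeatureSample],
    path: str | Path,
    L: int,
    horizons: Sequence[int],
    seed: Optional[int] = None,
) -> None:
    """Write samples as CSV plus a ``<path>.json`` sidecar header.

    The sidecar records L, the horizon list and the generator seed so the
    table round-trips exactly (labels/ids) or to float precision (features).
    """
    path = Path(path)
    horizons = [int(h) for h in horizons]
    n_feat = 2 * (2 * L - 1)
    for s in samples:
        if s.features.size != n_feat:
            raise ValidationError(
                f"sample has {s.features.size} features, expected {n_feat} for L={L}"
            )
        if s.labels.size != len(horizons):
            raise ValidationError(
                f"sample has {s.labels.size} labels, header lists {len(horizons)} horizons"
            )
    header = ["record_id", "t_ref_s"]
    header += [f"f{i}" for i in range(n_feat)]
    header += [f"y{h}" for h in horizons]
    lines = [",".join(header)]
    for s in samples:
        row = [s.record_id, f"{s.t_ref_s:.9f}"]
        row += [f"{v:.17g}" for v in s.features]
        row += [str(int(v)) for v in s.labels]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")
    sidecar = {"L": int(L), "horizons": horizons, "seed": seed,
               "n_samples": len(samples)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_feature_table(path: str | Path) -> tuple[list[FeatureSample], dict]:
    """Inverse of :func:`write_feature_table`; returns (samples, header)."""
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ParseError(f"missing sidecar header {sidecar_path}")
    header = json.loads(sidecar_path.read_text())
    L, horizons = int(header["L"]), [int(h) for h in header["horizons"]]
    n_feat = 2 * (2 * L - 1)

    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty feature table")
    cols = lines[0].split(",")
    expected_cols = 2 + n_feat + len(horizons)
    if len(cols) != expected_cols:
        raise ParseError(
            f"{path}: {len(cols)} columns but header implies {expected_cols} "
            f"(L={L}, {len(horizons)} horizons)"
        )
    samples = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != expected_cols:
            raise ParseError(f"{path}:{lineno}: expected {expected_cols} fields")
        feats = np.array([float(v) for v in parts[2 : 2 + n_feat]])
        labels = np.array([int(v) for v in parts[2 + n_feat :]])
        samples.append(
            FeatureSample(features=feats, labels=labels,
                          record_id=parts[0], t_ref_s=float(parts[1]))
        )
    if header.get("n_samples") is not None and header["n_samples"] != len(samples):
        raise ParseError(
            f"{path}: sidecar lists {header['n_samples']} samples, file has {len(samples)}"
        )
    return samples, header
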