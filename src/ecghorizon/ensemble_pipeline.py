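"""Merging the three recurrent forecasters with NSGA-III.

The search space is a per-horizon soft weighting of the RNN, GRU and LSTM
class scores (one simplex-normalized triple per horizon).  For each
cross-validation fold the three base models are trained once and their
validation scores cached; a candidate weighting is then evaluated in
microseconds as a weighted argmax.  The four maximized objectives are the
overall accuracy and the three per-class accuracies (class-wise recalls),
averaged over folds and horizons — the per-class objectives counteract
the class imbalance of the emulated corpora.  The one-hot corners of the
simplex reproduce the stand-alone baselines exactly and seed the initial
population, so the selected merge can never fall below the best
stand-alone model on the selection folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold

from . import nsga3
from .recurrent_models import HorizonClassifier, TrainConfig, make_sequences
from .signal_io import N_CLASSES, FeatureSample

CELLS = ("rnn", "gru", "lstm")

#: classes whose prediction should raise a warning flag (medium/high stress,
#: or sleep stages 1/2 in the drowsiness profile)
WARN_CLASSES = frozenset({1, 2})


# ---------------------------------------------------------------------------
# Accuracy metrics
# ---------------------------------------------------------------------------


def per_class_accuracy(y_true: np.ndarray, y_pred: np.ndarray, cls: int
                       ) -> Optional[float]:
    """Recall of class ``cls``: fraction of its true samples predicted as it.

    Returns None (with a warning) when the class is absent from y_true.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal shapes")
    mask = y_true == cls
    if not mask.any():
        warnings.warn(f"class {cls} absent from y_true; accuracy undefined",
                      stacklevel=2)
        return None
    return float((y_pred[mask] == cls).mean())


def overall_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Matching fraction; equals the support-weighted mean of class recalls."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal shapes")
    return float((y_true == y_pred).mean())


# ---------------------------------------------------------------------------
# Genome handling and ensemble prediction
# ---------------------------------------------------------------------------


def normalize_genome(raw: np.ndarray, n_horizons: int) -> np.ndarray:
    """Reshape a flat [0,1] genome to (n_horizons, 3) rows on the simplex."""
    w = np.asarray(raw, dtype=float).reshape(n_horizons, len(CELLS))
    w = np.clip(w, 0.0, None)
    sums = w.sum(axis=1, keepdims=True)
    uniform = np.full_like(w, 1.0 / len(CELLS))
    return np.where(sums > 1e-12, w / np.where(sums > 0, sums, 1.0), uniform)


def one_hot_genome(model_index: int, n_horizons: int) -> np.ndarray:
    g = np.zeros((n_horizons, len(CELLS)))
    g[:, model_index] = 1.0
    return g.ravel()


def ensemble_predict(genome: np.ndarray, base_scores: np.ndarray) -> np.ndarray:
    """Weighted-score argmax.

    base_scores: (3 models, N samples, n_horizons, 3 classes).  Per horizon
    h the combined score is sum_m w[h, m] * scores[m, :, h, :]; ties break
    toward the lowest class id.
    """
    base_scores = np.asarray(base_scores, dtype=float)
    if base_scores.ndim != 4 or base_scores.shape[0] != len(CELLS):
        raise ValueError(f"base_scores must be (3, N, H, {N_CLASSES})")
    n_h = base_scores.shape[2]
    w = normalize_genome(genome, n_h)  # (H, 3 models)
    combined = np.einsum("hm,mnhc->nhc", w, base_scores)
    return combined.argmax(axis=2)  # (N, H)


# ---------------------------------------------------------------------------
# Cross-validation fold cache
# ---------------------------------------------------------------------------


@dataclass
class FoldCache:
    """Per-fold validation scores of the three base models.

    scores[fold] has shape (3, n_val, n_horizons, 3); y[fold] the matching
    (n_val, n_horizons) labels.
    """

    scores: list[np.ndarray]
    y_true: list[np.ndarray]
    n_horizons: int
    fold_index_sets: list[np.ndarray]


def make_folds(samples: Sequence[FeatureSample], k: int, seed: int,
               group_by_record: bool = False) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition sample indices into k folds.

    Default: stratified on the first-horizon label at the sample level.
    ``group_by_record`` switches to grouped folds (no record straddles a
    train/validation boundary), preventing within-record leakage.
    """
    y = np.array([s.labels[0] for s in samples])
    idx = np.arange(len(samples))
    if group_by_record:
        groups = np.array([s.record_id for s in samples])
        splitter = GroupKFold(n_splits=k)
        return [(tr, va) for tr, va in splitter.split(idx, y, groups)]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in splitter.split(idx, y)]


def build_fold_cache(
    samples: Sequence[FeatureSample],
    k_folds: int,
    train_config: TrainConfig,
    seed: int = 0,
    group_by_record: bool = False,
    boosting_rounds: int = 1,
) -> FoldCache:
    """Train RNN/GRU/LSTM per fold and cache validation scores.

    With ``boosting_rounds`` B > 1 each cached "model" is itself a
    committee of B independently seeded models of that cell kind, their
    scores averaged with validation-accuracy weights (the boosting
    baseline); B = 1 is the plain stand-alone model.
    """
    samples = list(samples)
    n_h = samples[0].labels.size
    input_size = samples[0].features.size
    folds = make_folds(samples, k_folds, seed, group_by_record)
    scores_per_fold: list[np.ndarray] = []
    y_per_fold: list[np.ndarray] = []
    for fold_i, (tr, va) in enumerate(folds):
        train_set = [samples[i] for i in tr]
        val_set = [samples[i] for i in va]
        Xv, Yv = make_sequences(val_set, train_config.window)
        fold_scores = []
        for m_i, cell in enumerate(CELLS):
            member_scores = []
            member_acc = []
            for b in range(boosting_rounds):
                cfg = TrainConfig(**{**train_config.__dict__,
                                     "seed": seed + 1000 * fold_i + 10 * m_i + b})
                model = HorizonClassifier(cell, n_h, input_size, cfg).fit(train_set)
                sc = model.predict_scores(Xv)
                member_scores.append(sc)
                member_acc.append(overall_accuracy(Yv.ravel(),
                                                   sc.argmax(axis=2).ravel()))
            if boosting_rounds == 1:
                fold_scores.append(member_scores[0])
            else:
                wts = np.asarray(member_acc)
                wts = wts / wts.sum() if wts.sum() > 0 else np.full_like(wts, 1 / len(wts))
                fold_scores.append(np.einsum("b,bnhc->nhc", wts,
                                             np.stack(member_scores)))
        scores_per_fold.append(np.stack(fold_scores))
        y_per_fold.append(Yv)
    return FoldCache(scores=scores_per_fold, y_true=y_per_fold,
                     n_horizons=n_h, fold_index_sets=[va for _, va in folds])


# ---------------------------------------------------------------------------
# Objective evaluation
# ---------------------------------------------------------------------------


def evaluate_genome(genome: np.ndarray, cache: FoldCache) -> np.ndarray:
    """Four maximized objectives: OA_all and the three class recalls.

    Each is the mean over folds of the pooled-over-horizons accuracy of
    the ensemble's validation predictions.  A class absent from a fold's
    labels is skipped in that fold's mean for its objective.
    """
    oa = []
    per_cls: list[list[float]] = [[] for _ in range(N_CLASSES)]
    for sc, y in zip(cache.scores, cache.y_true):
        pred = ensemble_predict(genome, sc)
        oa.append(overall_accuracy(y.ravel(), pred.ravel()))
        for c in range(N_CLASSES):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                acc = per_class_accuracy(y.ravel(), pred.ravel(), c)
            if acc is not None:
                per_cls[c].append(acc)
    objs = [float(np.mean(oa))]
    for c in range(N_CLASSES):
        objs.append(float(np.mean(per_cls[c])) if per_cls[c] else 0.0)
    return np.array(objs)


@dataclass
class EvaluationReport:
    """Horizon-wise accuracies with a fold-wise breakdown.

    ``rows`` is a list of dicts with keys: fold, horizon, OA_all,
    OA_class0, OA_class1, OA_class2 (None where a class is absent).
    """

    rows: list[dict]
    config: dict = field(default_factory=dict)

    def horizon_curve(self, metric: str = "OA_all") -> tuple[np.ndarray, np.ndarray]:
        """(horizons, mean metric over folds) for plotting/trend tests."""
        horizons = sorted({r["horizon"] for r in self.rows})
        means = []
        for h in horizons:
            vals = [r[metric] for r in self.rows
                    if r["horizon"] == h and r[metric] is not None]
            means.append(float(np.mean(vals)) if vals else np.nan)
        return np.array(horizons), np.array(means)


def report_from_predictions(
    preds_per_fold: list[np.ndarray],
    y_per_fold: list[np.ndarray],
    horizons: Sequence[int],
    config: Optional[dict] = None,
) -> EvaluationReport:
    rows = []
    for fold_i, (pred, y) in enumerate(zip(preds_per_fold, y_per_fold)):
        for h_i, h in enumerate(horizons):
            row = {"fold": fold_i, "horizon": int(h),
                   "OA_all": overall_accuracy(y[:, h_i], pred[:, h_i])}
            for c in range(N_CLASSES):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row[f"OA_class{c}"] = per_class_accuracy(y[:, h_i], pred[:, h_i], c)
            rows.append(row)
    return EvaluationReport(rows=rows, config=config or {})


# ---------------------------------------------------------------------------
# Top-level runs
# ---------------------------------------------------------------------------


@dataclass
class OptimizeResult:
    archive_genomes: np.ndarray
    archive_objectives: np.ndarray
    selected_genome: np.ndarray      # (n_horizons, 3) simplex rows
    selected_objectives: np.ndarray
    report: EvaluationReport
    baseline_objectives: dict[str, np.ndarray]
    log: list[dict]


def _require_all_classes(samples: Sequence[FeatureSample]) -> None:
    present = np.unique(np.concatenate([s.labels for s in samples]))
    missing = set(range(N_CLASSES)) - set(int(c) for c in present)
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from the data; "
                         "the four-objective merge needs all three classes")


def optimize_ensemble(
    samples: Sequence[FeatureSample],
    horizons: Sequence[int],
    k_folds: int = 10,
    train_config: Optional[TrainConfig] = None,
    nsga_config: Optional[nsga3.Nsga3Config] = None,
    seed: int = 0,
    group_by_record: bool = False,
    cache: Optional[FoldCache] = None,
) -> OptimizeResult:
    """Train base models per fold, search merge weights, pick the final model.

    The initial NSGA-III population is seeded with the three one-hot
    genomes (pure RNN / GRU / LSTM) plus random simplex points; selection
    from the Pareto archive maximizes OA_all, ties broken by the maximal
    minimum per-class accuracy.
    """
    samples = list(samples)
    _require_all_classes(samples)
    train_config = train_config or TrainConfig()
    nsga_config = nsga_config or nsga3.Nsga3Config(seed=seed)
    if cache is None:
        cache = build_fold_cache(samples, k_folds, train_config, seed,
                                 group_by_record)
    n_h = cache.n_horizons
    genome_len = n_h * len(CELLS)

    one_hots = np.stack([one_hot_genome(m, n_h) for m in range(len(CELLS))])
    baseline_objs = {cell: evaluate_genome(one_hots[m], cache)
                     for m, cell in enumerate(CELLS)}

    result = nsga3.evolve(
        evaluate=lambda g: evaluate_genome(g, cache),
        genome_length=genome_len,
        n_objectives=4,
        config=nsga_config,
        initial_genomes=one_hots,
    )

    arch_f = result.archive_objectives
    best_oa = arch_f[:, 0].max()
    tied = np.nonzero(arch_f[:, 0] >= best_oa - 1e-12)[0]
    pick = tied[np.argmax(arch_f[tied, 1:].min(axis=1))]
    selected_raw = result.archive_genomes[pick]
    selected = normalize_genome(selected_raw, n_h)

    preds = [ensemble_predict(selected_raw, sc) for sc in cache.scores]
    report = report_from_predictions(preds, cache.y_true, horizons,
                                     {"k_folds": k_folds, "seed": seed})
    return OptimizeResult(
        archive_genomes=result.archive_genomes,
        archive_objectives=arch_f,
        selected_genome=selected,
        selected_objectives=arch_f[pick],
        report=report,
        baseline_objectives=baseline_objs,
        log=result.log,
    )


def run_baselines(
    samples: Sequence[FeatureSample],
    horizons: Sequence[int],
    k_folds: int = 10,
    train_config: Optional[TrainConfig] = None,
    seed: int = 0,
    boosting_rounds: int = 0,
    group_by_record: bool = False,
    cache: Optional[FoldCache] = None,
) -> dict[str, EvaluationReport]:
    """Stand-alone (and optionally boosting) baselines per cell kind.

    Returns reports keyed by 'rnn', 'gru', 'lstm' and, when
    ``boosting_rounds`` B >= 1, 'boost_rnn' etc. (B = 1 reduces the
    boosting committee to the stand-alone model).
    """
    samples = list(samples)
    _require_all_classes(samples)
    train_config = train_config or TrainConfig()
    if cache is None:
        cache = build_fold_cache(samples, k_folds, train_config, seed,
                                 group_by_record)
    n_h = cache.n_horizons
    out: dict[str, EvaluationReport] = {}
    for m, cell in enumerate(CELLS):
        g = one_hot_genome(m, n_h)
        preds = [ensemble_predict(g, sc) for sc in cache.scores]
        out[cell] = report_from_predictions(preds, cache.y_true, horizons,
                                            {"baseline": cell})
    if boosting_rounds >= 1:
        boost_cache = build_fold_cache(samples, k_folds, train_config, seed,
                                       group_by_record,
                                       boosting_rounds=boosting_rounds)
        for m, cell in enumerate(CELLS):
            g = one_hot_genome(m, n_h)
            preds = [ensemble_predict(g, sc) for sc in boost_cache.scores]
            out[f"boost_{cell}"] = report_from_predictions(
                preds, boost_cache.y_true, horizons,
                {"baseline": f"boost_{cell}", "B": boosting_rounds})
    return out


def warn_flags(predictions: np.ndarray) -> np.ndarray:
    """Boolean warning flag per prediction (classes 1 and 2 trigger it)."""
    return np.isin(np.asarray(predictions), list(WARN_CLASSES))
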