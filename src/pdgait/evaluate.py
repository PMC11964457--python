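"""Cross-validated metrics, augmentation comparison, significance testing and
sensor ablation.

Metrics follow the usual one-vs-rest decomposition of a confusion matrix:
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean, and
accuracy = trace/total; weighted averages are support-weighted means.  The
evaluation unit for the headline numbers is the majority-voted *walk*;
segment-level counts are kept alongside for transparency.

Augmentation recipes are compared on bit-identical fold manifests so the
comparison is fair, and the effect of augmentation is tested with a Welch
(unequal-variance) two-sample t-test on per-walk correctness indicators
pooled over folds.  Sensor ablation removes one symmetric channel pair at a
time (18 -> 16 inputs) and reruns the cross-validation; pairs are ranked by
ascending accuracy (lower accuracy after removal = more important pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .augment import AugmentationConfig
from .errors import DegenerateInputWarning
from .io import GaitDataset
from .lpr import LPRConfig
from .models import TrainConfig, build_model, predict_segments, train
from .windowing import FoldAssignment, assign_folds, build_fold_data, majority_vote

METRIC_NAMES = ("precision", "recall", "f1")

#: The nine symmetric channel pairs eligible for ablation.
SENSOR_PAIRS: dict[str, tuple[str, str]] = {
    **{f"L{i}&R{i}": (f"L{i}", f"R{i}") for i in range(1, 9)},
    "TotalL&TotalR": ("TotalL", "TotalR"),
}


def classification_metrics(confusion: np.ndarray) -> dict:
    """Per-class and weighted precision/recall/F1 plus accuracy from a
    confusion matrix (rows = true class, columns = predicted).

    Zero-denominator metrics are defined as 0 with a warning.
    """
    cm = np.asarray(confusion)
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = float(cm.sum())
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    support = cm.sum(axis=1).astype(float)

    def safe_div(num, den, name):
        out = np.zeros_like(num, dtype=float)
        bad = den == 0
        if np.any(bad):
            warnings.warn(
                f"{name}: zero denominator for class(es) {np.where(bad)[0].tolist()}; "
                "defining metric as 0",
                DegenerateInputWarning,
                stacklevel=3,
            )
        np.divide(num, den, out=out, where=~bad)
        return out

    precision = safe_div(tp, tp + fp, "precision")
    recall = safe_div(tp, tp + fn, "recall")
    f1 = safe_div(2 * precision * recall, precision + recall, "f1")
    weights = support / total if total else support
    per_class = [
        {"precision": float(p), "recall": float(r), "f1": float(f), "support": int(s)}
        for p, r, f, s in zip(precision, recall, f1, support)
    ]
    weighted = {
        "precision": float(precision @ weights),
        "recall": float(recall @ weights),
        "f1": float(f1 @ weights),
    }
    return {
        "per_class": per_class,
        "weighted": weighted,
        "accuracy": float(tp.sum() / total) if total else 0.0,
    }


@dataclass
class EvaluationReport:
    """Pooled cross-validation result at the majority-voted walk level."""

    confusion: np.ndarray  # (n_classes, n_classes), walk level
    segment_confusion: np.ndarray
    fold_accuracies: list[float]
    walk_results: list[dict]  # subject_id, walk_id, fold, true, pred
    metadata: dict = field(default_factory=dict)

    @property
    def metrics(self) -> dict:
        return classification_metrics(self.confusion)

    @property
    def accuracy(self) -> float:
        return self.metrics["accuracy"]

    @property
    def correctness(self) -> np.ndarray:
        """Per-walk 0/1 correctness indicators pooled over folds."""
        return np.array([int(r["true"] == r["pred"]) for r in self.walk_results])

    def to_dict(self) -> dict:
        m = self.metrics
        return {
            "accuracy": m["accuracy"],
            "weighted": m["weighted"],
            "per_class": m["per_class"],
            "confusion": self.confusion.tolist(),
            "segment_confusion": self.segment_confusion.tolist(),
            "fold_accuracies": self.fold_accuracies,
            "metadata": self.metadata,
        }


def _fold_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def cross_validate(
    dataset: GaitDataset,
    model_spec="convnet",
    aug_config: AugmentationConfig | None = None,
    k: int = 10,
    seed: int = 0,
    *,
    lpr_config: LPRConfig | None = None,
    train_config: TrainConfig | None = None,
    window: int = 100,
    overlap: float = 0.5,
    train_fraction: float = 1.0,
    folds: FoldAssignment | None = None,
    vote: str = "walk",
) -> EvaluationReport:
    """k-fold subject-independent cross-validation with majority voting.

    Each fold trains a fresh classifier on the (optionally augmented)
    training subjects' segments and scores the held-out subjects' walks by
    majority vote over their segment predictions.  ``vote='subject'`` pools
    all of a subject's segments instead.
    """
    dataset = dataset.labelled()
    n_classes = 4
    if folds is None:
        folds = assign_folds(dataset.subject_list, k, seed)
    n_channels = dataset.walks[0].n_channels
    cm = np.zeros((n_classes, n_classes), dtype=int)
    seg_cm = np.zeros((n_classes, n_classes), dtype=int)
    fold_accs: list[float] = []
    walk_results: list[dict] = []
    tc = train_config or TrainConfig()
    for fi, fold in enumerate(folds.folds):
        rng = np.random.default_rng(_fold_seed(seed, fi, 0))
        train_batch, val_batch = build_fold_data(
            dataset, fold, aug_config, lpr_config, window, overlap, train_fraction, rng
        )
        model = build_model(model_spec, n_channels=n_channels,
                            rng=np.random.default_rng(_fold_seed(seed, fi, 1)))
        train(model, train_batch, val_batch,
              dc_replace(tc, seed=_fold_seed(seed, fi, 2)))
        preds, _ = predict_segments(model, val_batch)
        np.add.at(seg_cm, (val_batch.labels, preds), 1)
        units: dict[tuple, list[int]] = {}
        truths: dict[tuple, int] = {}
        for p, (sid, wid, _start), label in zip(preds, val_batch.provenance, val_batch.labels):
            key = (sid,) if vote == "subject" else (sid, wid)
            units.setdefault(key, []).append(int(p))
            truths[key] = int(label)
        fold_cm = np.zeros((n_classes, n_classes), dtype=int)
        for key, plist in units.items():
            voted = majority_vote(plist)
            fold_cm[truths[key], voted] += 1
            walk_results.append(
                {"subject_id": key[0], "walk_id": key[1] if len(key) > 1 else "*",
                 "fold": fi, "true": truths[key], "pred": voted}
            )
        cm += fold_cm
        fold_accs.append(float(np.trace(fold_cm) / fold_cm.sum()))
    return EvaluationReport(
        confusion=cm,
        segment_confusion=seg_cm,
        fold_accuracies=fold_accs,
        walk_results=walk_results,
        metadata={
            "model": model_spec if isinstance(model_spec, str) else type(model_spec).__name__,
            "recipe": aug_config.recipe if aug_config else "none",
            "lpr": lpr_config.tag if lpr_config else None,
            "k": folds.k,
            "seed": seed,
            "train_fraction": train_fraction,
            "vote": vote,
            "fold_manifest_hash": folds.manifest_hash(),
        },
    )


def compare_augmentations(
    dataset: GaitDataset,
    recipes: Mapping[str, AugmentationConfig | None],
    model_spec="convnet",
    k: int = 10,
    seed: int = 0,
    **kwargs,
) -> dict[str, EvaluationReport]:
    """One cross-validation per recipe on *shared* fold manifests.

    The identical manifest hash across reports is asserted, so any
    difference between columns is attributable to the recipe alone.
    """
    if not recipes:
        raise ValueError("need at least one recipe")
    ds = dataset.labelled()
    folds = assign_folds(ds.subject_list, k, seed)
    reports = {
        name: cross_validate(ds, model_spec, cfg, k, seed, folds=folds, **kwargs)
        for name, cfg in recipes.items()
    }
    hashes = {r.metadata["fold_manifest_hash"] for r in reports.values()}
    assert len(hashes) == 1, "fold manifests differ across recipes"
    return reports


def comparison_table(reports: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """Render reports as a classes × metrics grid with one column per recipe."""
    from .io import SEVERITY_CLASSES

    rows = []
    for metric in METRIC_NAMES:
        for ci, cls in enumerate(SEVERITY_CLASSES):
            rows.append(
                {"metric": metric, "label": cls,
                 **{name: r.metrics["per_class"][ci][metric] for name, r in reports.items()}}
            )
        rows.append(
            {"metric": metric, "label": "Weighted Avg",
             **{name: r.metrics["weighted"][metric] for name, r in reports.items()}}
        )
    rows.append(
        {"metric": "accuracy", "label": "-",
         **{name: r.accuracy for name, r in reports.items()}}
    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def augmentation_effect_ttest(
    results_no_da: Sequence[float], results_da: Sequence[float]
) -> TTestResult:
    """Welch two-sample t-test (unequal variances) on per-unit results.

    Identical zero-variance samples return p = 1 rather than NaN.
    """
    a = np.asarray(results_no_da, dtype=float)
    b = np.asarray(results_da, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        same = float(a.mean()) == float(b.mean())
        return TTestResult(t=0.0 if same else np.inf, df=float(a.size + b.size - 2),
                           p=1.0 if same else 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    se_a, se_b = va / a.size, vb / b.size
    df = (se_a + se_b) ** 2 / (se_a**2 / (a.size - 1) + se_b**2 / (b.size - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def _resolve_pair(pair) -> tuple[str, tuple[str, str]]:
    if isinstance(pair, str):
        if pair not in SENSOR_PAIRS:
            raise ValueError(f"unknown sensor pair {pair!r}; known: {list(SENSOR_PAIRS)}")
        return pair, SENSOR_PAIRS[pair]
    a, b = pair
    name = f"{a}&{b}"
    if name not in SENSOR_PAIRS:
        raise ValueError(f"unknown sensor pair {name!r}; known: {list(SENSOR_PAIRS)}")
    return name, (a, b)


def sensor_ablation(
    dataset: GaitDataset,
    model_spec="convnet",
    pairs: Sequence = tuple(SENSOR_PAIRS),
    k: int = 10,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, EvaluationReport]]:
    """Drop one symmetric channel pair at a time and rerun cross-validation.

    Returns the ablation table sorted by ascending accuracy (top row = most
    important pair) and the full per-pair reports.
    """
    rows, reports = [], {}
    for pair in pairs:
        name, channels = _resolve_pair(pair)
        reduced = dataset.drop_channels(channels)
        rep = cross_validate(reduced, model_spec, None, k, seed, **kwargs)
        reports[name] = rep
        m = rep.metrics
        rows.append(
            {"pair": name, "precision": m["weighted"]["precision"],
             "recall": m["weighted"]["recall"], "f1": m["weighted"]["f1"],
             "accuracy": m["accuracy"]}
        )
    table = pd.DataFrame(rows).sort_values("accuracy", kind="stable").reset_index(drop=True)
    return table, reports
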