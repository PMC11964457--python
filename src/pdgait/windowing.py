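"""Segmentation into fixed windows, subject-independent folds and vote pooling.

Walks are cut into 100-time-step segments with 50% overlap; each segment
inherits its subject's severity label.  Cross-validation folds are built at
the *subject* level — every record of a subject lands entirely in the
training or the validation side, never both — with controls and patients
split into 1/k chunks separately so each fold's validation set holds about
1/k of each group.  Segment predictions are pooled per walk by majority
vote; ties break toward the lowest class index (deterministic, and
deliberately under-calls severity).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .augment import AugmentationConfig, augment_walk
from .io import GaitDataset, SubjectInfo, WalkRecord
from .lpr import LPRConfig, lpr_transform

log = logging.getLogger(__name__)

WINDOW = 100
OVERLAP = 0.5


def segment(record: WalkRecord, window: int = WINDOW, overlap: float = OVERLAP) -> list[np.ndarray]:
    """Cut one walk into windows of ``window`` samples with the given overlap.

    Segments start at 0, stride, 2*stride, ... while start+window <= T, with
    stride = window * (1 - overlap).  A record shorter than one window yields
    an empty list.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    stride = max(int(round(window * (1 - overlap))), 1)
    T = record.n_samples
    if T < window:
        return []
    return [record.forces[s : s + window] for s in range(0, T - window + 1, stride)]


@dataclass
class SegmentBatch:
    """A stack of windows with labels and per-segment provenance."""

    segments: np.ndarray  # (N, window, C)
    labels: np.ndarray  # (N,) class indices
    provenance: list[tuple[str, str, int]]  # (subject_id, walk_id, start_index)

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.labels) or len(self.labels) != len(self.segments):
            raise ValueError("segments, labels and provenance lengths disagree")

    def __len__(self) -> int:
        return int(self.segments.shape[0])

    @property
    def subject_ids(self) -> set[str]:
        return {p[0] for p in self.provenance}


def segment_walks(
    walks: Sequence[WalkRecord], window: int = WINDOW, overlap: float = OVERLAP
) -> SegmentBatch:
    """Segment many walks into one batch; walks shorter than a window are
    skipped with a logged count.  Every walk must carry a severity label."""
    segs, labels, prov = [], [], []
    n_short = 0
    stride = max(int(round(window * (1 - overlap))), 1)
    for w in walks:
        pieces = segment(w, window, overlap)
        if not pieces:
            n_short += 1
            continue
        if w.severity_class is None:
            raise ValueError(f"walk {w.subject_id}/{w.walk_id} has no severity label")
        for i, p in enumerate(pieces):
            segs.append(p)
            labels.append(w.severity_class)
            prov.append((w.subject_id, w.walk_id, i * stride))
    if n_short:
        log.info("skipped %d walk(s) shorter than one window", n_short)
    if not segs:
        return SegmentBatch(np.zeros((0, window, 0)), np.zeros(0, dtype=int), [])
    return SegmentBatch(np.stack(segs), np.asarray(labels, dtype=int), prov)


@dataclass
class FoldAssignment:
    """k subject-level folds; validation sets partition the subject pool."""

    k: int
    folds: list[tuple[frozenset, frozenset]]  # (train_subjects, val_subjects)
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set = set()
        for train, val in self.folds:
            if train & val:
                raise ValueError("train and validation subjects overlap in a fold")
            if val & seen:
                raise ValueError("a subject appears in two validation folds")
            seen |= val
        self._all_subjects = seen

    def check_partition(self, subjects: Iterable[str]) -> None:
        missing = set(subjects) - self._all_subjects
        if missing:
            raise ValueError(f"subjects never validated: {sorted(missing)}")

    def manifest(self) -> str:
        """Canonical JSON of the assignment (used to prove fair comparisons)."""
        return json.dumps(
            [[sorted(t), sorted(v)] for t, v in self.folds], separators=(",", ":")
        )

    def manifest_hash(self) -> str:
        return hashlib.sha256(self.manifest().encode()).hexdigest()[:16]


def assign_folds(subjects: Sequence[SubjectInfo], k: int, seed: int) -> FoldAssignment:
    """Build k subject-independent folds stratified by group.

    Control and PD subject lists are shuffled with the seed and split into k
    near-equal chunks; fold i's validation set is chunk i of each group.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    groups = {
        "control": sorted(s.subject_id for s in subjects if s.group == "control"),
        "PD": sorted(s.subject_id for s in subjects if s.group != "control"),
    }
    chunks: dict[str, list[np.ndarray]] = {}
    for name, ids in groups.items():
        if len(ids) < k:
            raise ValueError(f"group {name!r} has {len(ids)} subjects, fewer than k={k}")
        order = rng.permutation(len(ids))
        chunks[name] = np.array_split(np.asarray(ids, dtype=object)[order], k)
    all_ids = frozenset(groups["control"]) | frozenset(groups["PD"])
    folds = []
    for i in range(k):
        val = frozenset(chunks["control"][i]) | frozenset(chunks["PD"][i])
        folds.append((all_ids - val, val))
    fa = FoldAssignment(k=k, folds=folds, seed=seed)
    fa.check_partition(all_ids)
    return fa


def majority_vote(segment_predictions: Sequence[int]) -> int:
    """Most frequent class; ties break toward the lowest class index."""
    preds = np.asarray(segment_predictions, dtype=int)
    if preds.size == 0:
        raise ValueError("cannot vote on an empty prediction list")
    return int(np.bincount(preds).argmax())


def build_fold_data(
    dataset: GaitDataset,
    fold: tuple[frozenset, frozenset],
    aug_config: AugmentationConfig | None = None,
    lpr_config: LPRConfig | None = None,
    window: int = WINDOW,
    overlap: float = OVERLAP,
    train_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[SegmentBatch, SegmentBatch]:
    """Materialise (train, validation) segment batches for one fold.

    Training walks are optionally subsampled (stratified by class, at least
    one walk per class kept), then augmented — augmented copies are appended
    to the originals, never substituted — then segmented.  Validation walks
    are segmented as-is.  Any LPR transform applies to both sides.
    """
    if rng is None:
        rng = np.random.default_rng()
    train_subj, val_subj = fold
    train_walks = dataset.walks_of(train_subj)
    val_walks = dataset.walks_of(val_subj)

    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    if train_fraction < 1.0:
        kept: list[WalkRecord] = []
        by_class: dict[int, list[WalkRecord]] = {}
        for w in train_walks:
            by_class.setdefault(int(w.severity_class), []).append(w)
        for cls in sorted(by_class):
            ws = by_class[cls]
            n_keep = max(1, int(round(train_fraction * len(ws))))
            idx = rng.choice(len(ws), size=n_keep, replace=False)
            kept.extend(ws[i] for i in sorted(idx))
        train_walks = kept

    if aug_config is not None and aug_config.operators:
        augmented = []
        for w in train_walks:
            for _ in range(aug_config.copies):
                augmented.append(augment_walk(w, aug_config, rng))
        train_walks = list(train_walks) + augmented

    if lpr_config is not None:
        train_walks = [lpr_transform(w, lpr_config) for w in train_walks]
        val_walks = [lpr_transform(w, lpr_config) for w in val_walks]

    train_batch = segment_walks(train_walks, window, overlap)
    val_batch = segment_walks(val_walks, window, overlap)
    leaked = train_batch.subject_ids & val_batch.subject_ids
    if leaked:
        raise AssertionError(f"subject leakage across fold roles: {sorted(leaked)}")
    return train_batch, val_batch
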