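"""Reading and writing plantar VGRF walk records and subject demographics.

The walk-file dialect is whitespace-delimited numeric text with 19 columns:
time (s, 100 Hz), 8 left-foot sensors L1..L8, 8 right-foot sensors R1..R8,
and two composite channels TotalL / TotalR that are the sums of the 8
sensors of the corresponding foot.  Demographics come as a CSV/TSV with
named columns carrying group (PD / control) and Hoehn–Yahr stage; a small
YAML/JSON manifest maps walk files to subjects so real and synthetic
cohorts share one loader.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, TotalsMismatchWarning, ValidationError

log = logging.getLogger(__name__)

#: Channel order of the 18 force columns (time excluded).
CHANNEL_NAMES: tuple[str, ...] = tuple(
    [f"L{i}" for i in range(1, 9)] + [f"R{i}" for i in range(1, 9)] + ["TotalL", "TotalR"]
)
N_CHANNELS = len(CHANNEL_NAMES)

#: Hoehn–Yahr stages forming the 4-class severity task, in label order.
SEVERITY_CLASSES: tuple[str, ...] = ("Healthy", "Severity2", "Severity2.5", "Severity3")

_STAGE_TO_INDEX = {"healthy": 0, "2": 1, "2.5": 2, "3": 3}


def label_map(hoehn_yahr) -> int:
    """Map a Hoehn–Yahr stage to its class index.

    ``healthy`` -> 0, ``2`` -> 1, ``2.5`` -> 2, ``3`` -> 3.  Any other stage
    (e.g. 4, present in the archive but outside the 4-class task) raises.
    """
    key = str(hoehn_yahr).strip().lower()
    if key in ("0", "control"):
        key = "healthy"
    if key.endswith(".0"):
        key = key[:-2]
    if key not in _STAGE_TO_INDEX:
        raise ValueError(f"Hoehn–Yahr stage {hoehn_yahr!r} is outside the 4-class task")
    return _STAGE_TO_INDEX[key]


@dataclass
class SubjectInfo:
    """One demographics row: identity, group and Hoehn–Yahr stage plus covariates."""

    subject_id: str
    group: str  # "PD" | "control"
    hoehn_yahr: str  # "healthy", "2", "2.5", "3" or any other stage string
    study: str = "Ga"
    age: float | None = None
    sex: str | None = None
    height: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("PD", "control"):
            raise SchemaError(f"unknown group {self.group!r} for subject {self.subject_id}")
        stage = str(self.hoehn_yahr).strip().lower()
        if self.group == "control" and stage not in ("healthy", "0", "control"):
            raise ValidationError(
                f"control subject {self.subject_id} carries Hoehn–Yahr stage {self.hoehn_yahr!r}"
            )
        if self.group == "PD" and stage in ("healthy", "0", "control"):
            raise ValidationError(f"PD subject {self.subject_id} labelled healthy")

    @property
    def severity_known(self) -> bool:
        """True when the stage falls inside the 4-class task."""
        try:
            label_map(self.hoehn_yahr)
        except ValueError:
            return False
        return True

    @property
    def severity_class(self) -> int | None:
        """Class index 0..3, or None for stages outside the task."""
        try:
            return label_map(self.hoehn_yahr)
        except ValueError:
            return None


@dataclass
class WalkRecord:
    """One walk: time vector, T×18 force matrix and subject metadata."""

    subject_id: str
    time: np.ndarray  # (T,) seconds
    forces: np.ndarray  # (T, 18) newtons, order CHANNEL_NAMES
    study: str = "Ga"
    walk_id: str = "01"
    walk_type: str = "normal"  # "normal" | "dual"
    group: str | None = None
    severity_class: int | None = None
    sampling_rate: float = 100.0
    tag: str = "raw"  # provenance tag, e.g. "raw", "jitter", "lp_50"
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    @property
    def n_samples(self) -> int:
        return int(self.forces.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.forces.shape[1])

    def validate(self, totals_tol: float = 1.0, time_tol: float = 1e-6) -> None:
        """Check time monotonicity (hard) and totals consistency (warning).

        Totals disagreement only warns because real archive files carry
        rounded values; ``totals_tol`` is an absolute tolerance in newtons.
        """
        t = np.asarray(self.time, float)
        if t.size != self.forces.shape[0]:
            raise ValidationError("time and forces length mismatch")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0))
                raise ValidationError(
                    f"time not strictly increasing at sample {bad + 1} (dt={dt[bad]:.6g})"
                )
            step = 1.0 / self.sampling_rate
            if np.any(np.abs(dt - step) > time_tol):
                warnings.warn(
                    f"walk {self.subject_id}/{self.walk_id}: sampling step deviates "
                    f"from {step} s",
                    TotalsMismatchWarning,
                    stacklevel=2,
                )
        if self.forces.shape[1] == N_CHANNELS and self.channel_names == CHANNEL_NAMES:
            left = self.forces[:, 0:8].sum(axis=1)
            right = self.forces[:, 8:16].sum(axis=1)
            err_l = np.max(np.abs(left - self.forces[:, 16])) if t.size else 0.0
            err_r = np.max(np.abs(right - self.forces[:, 17])) if t.size else 0.0
            if max(err_l, err_r) > totals_tol:
                warnings.warn(
                    f"walk {self.subject_id}/{self.walk_id}: total-force column differs "
                    f"from sensor sum by up to {max(err_l, err_r):.3g} N "
                    f"(tolerance {totals_tol} N)",
                    TotalsMismatchWarning,
                    stacklevel=2,
                )


def read_walk_file(
    path,
    *,
    subject_id: str | None = None,
    study: str = "Ga",
    walk_id: str | None = None,
    walk_type: str = "normal",
    subject: SubjectInfo | None = None,
    totals_tol: float = 1.0,
    validate: bool = True,
) -> WalkRecord:
    """Read one 19-column walk file into a :class:`WalkRecord`.

    The time column is kept for validation only; downstream indexing is
    sample-based.  Totals inconsistency warns; non-monotone time raises.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty-file chatter; we raise below
            data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:  # np names the offending line in its message
        raise ParseError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise ParseError(f"{path}: empty walk file")
    if data.shape[1] != N_CHANNELS + 1:
        raise ParseError(
            f"{path}: expected {N_CHANNELS + 1} columns, found {data.shape[1]}"
        )
    if subject is not None:
        subject_id = subject.subject_id
        study = subject.study
    rec = WalkRecord(
        subject_id=subject_id or path.stem,
        time=data[:, 0].copy(),
        forces=data[:, 1:].copy(),
        study=study,
        walk_id=walk_id or path.stem,
        walk_type=walk_type,
        group=None if subject is None else subject.group,
        severity_class=None if subject is None else subject.severity_class,
    )
    if validate:
        rec.validate(totals_tol=totals_tol)
    return rec


def write_walk_file(record: WalkRecord, path, fmt: str = "%.6f") -> None:
    """Write a record back in the 19-column text dialect."""
    out = np.column_stack([record.time, record.forces])
    np.savetxt(path, out, fmt=fmt, delimiter=" ")


_REQUIRED_DEMO_COLS = ("subject_id", "group", "hoehn_yahr")


def read_demographics(path) -> list[SubjectInfo]:
    """Read a demographics CSV/TSV into :class:`SubjectInfo` rows.

    Requires columns ``subject_id``, ``group``, ``hoehn_yahr``; recognises
    optional ``study``, ``age``, ``sex``, ``height``, ``weight``.  Stages
    outside {healthy, 2, 2.5, 3} load fine but are flagged
    ``severity_known=False`` and excluded from the 4-class task downstream.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_DEMO_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: demographics table missing column(s) {missing}")
    subjects = []
    for _, row in df.iterrows():
        subjects.append(
            SubjectInfo(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                hoehn_yahr=str(row["hoehn_yahr"]),
                study=str(row.get("study", "Ga")),
                age=float(row["age"]) if "age" in df.columns and pd.notna(row["age"]) else None,
                sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row["sex"]) else None,
                height=float(row["height"])
                if "height" in df.columns and pd.notna(row["height"])
                else None,
                weight=float(row["weight"])
                if "weight" in df.columns and pd.notna(row["weight"])
                else None,
            )
        )
    n_unknown = sum(not s.severity_known for s in subjects)
    if n_unknown:
        log.info("%d subject(s) carry stages outside the 4-class task", n_unknown)
    return subjects


def write_demographics(subjects: Iterable[SubjectInfo], path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "study": s.study,
            "group": s.group,
            "hoehn_yahr": s.hoehn_yahr,
            "age": s.age,
            "sex": s.sex,
            "height": s.height,
            "weight": s.weight,
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class GaitDataset:
    """A loaded cohort: walk records plus one SubjectInfo per subject."""

    walks: list[WalkRecord]
    subjects: dict[str, SubjectInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.walks:
            if w.subject_id not in self.subjects:
                raise ValidationError(
                    f"walk {w.walk_id} references unknown subject {w.subject_id}"
                )
            s = self.subjects[w.subject_id]
            if w.group is None:
                w.group = s.group
            if w.severity_class is None:
                w.severity_class = s.severity_class
            elif w.severity_class != s.severity_class:
                raise ValidationError(
                    f"walk {w.walk_id}: class {w.severity_class} disagrees with "
                    f"subject {w.subject_id} ({s.severity_class})"
                )

    @property
    def subject_list(self) -> list[SubjectInfo]:
        return list(self.subjects.values())

    def labelled(self) -> "GaitDataset":
        """Restrict to subjects whose stage is inside the 4-class task."""
        keep = {sid: s for sid, s in self.subjects.items() if s.severity_known}
        walks = [w for w in self.walks if w.subject_id in keep]
        return GaitDataset(walks=walks, subjects=keep)

    def drop_channels(self, names: Sequence[str]) -> "GaitDataset":
        """Return a copy with the named force channels removed (sensor ablation)."""
        base = self.walks[0].channel_names if self.walks else CHANNEL_NAMES
        unknown = [n for n in names if n not in base]
        if unknown:
            raise ValueError(f"unknown channel(s) {unknown}; known: {list(base)}")
        keep_idx = [i for i, n in enumerate(base) if n not in names]
        kept_names = tuple(base[i] for i in keep_idx)
        walks = [
            replace(w, forces=w.forces[:, keep_idx].copy(), channel_names=kept_names)
            for w in self.walks
        ]
        return GaitDataset(walks=walks, subjects=dict(self.subjects))

    def walks_of(self, subject_ids: Iterable[str]) -> list[WalkRecord]:
        ids = set(subject_ids)
        return [w for w in self.walks if w.subject_id in ids]


def save_dataset(dataset: GaitDataset, out_dir, fmt: str = "%.2f") -> Path:
    """Write a cohort as walk files + demographics CSV + YAML manifest.

    Returns the manifest path.  The synthetic and real paths share this
    layout, so one loader serves both.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_demographics(dataset.subject_list, out_dir / "demographics.csv")
    entries = []
    for w in dataset.walks:
        fname = f"{w.subject_id}_{w.walk_id}.txt"
        write_walk_file(w, out_dir / fname, fmt=fmt)
        entries.append(
            {
                "path": fname,
                "subject_id": w.subject_id,
                "walk_id": w.walk_id,
                "study": w.study,
                "walk_type": w.walk_type,
            }
        )
    manifest = {"demographics": "demographics.csv", "walks": entries}
    mpath = out_dir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


def load_dataset(manifest_path, totals_tol: float = 1.0) -> GaitDataset:
    """Load a cohort from a YAML/JSON manifest produced by :func:`save_dataset`."""
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    manifest: Mapping = (
        json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    )
    root = manifest_path.parent
    subjects = {s.subject_id: s for s in read_demographics(root / manifest["demographics"])}
    walks = []
    for entry in manifest["walks"]:
        sid = str(entry["subject_id"])
        if sid not in subjects:
            raise ValidationError(f"manifest walk {entry['path']} has unknown subject {sid}")
        walks.append(
            read_walk_file(
                root / entry["path"],
                subject=subjects[sid],
                walk_id=str(entry.get("walk_id", Path(entry["path"]).stem)),
                walk_type=str(entry.get("walk_type", "normal")),
                totals_tol=totals_tol,
            )
        )
    return GaitDataset(walks=walks, subjects=subjects)
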