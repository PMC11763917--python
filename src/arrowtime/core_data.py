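"""Domain types and I/O for subject time-course matrices and cohorts.

A subject is a ``T x N`` real matrix: ``T`` time points (rows) by ``N``
components (columns), e.g. ICA time courses extracted from resting-state
fMRI. Cohorts are exchanged on disk as one delimited-text matrix per
subject (one row per time point, no header) plus a JSON manifest declaring
the shared shape, subject IDs and optional binary labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SubjectTimeSeries",
    "Cohort",
    "LabeledSequence",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]


class CohortValidationError(ValueError):
    """A cohort or subject violates a structural invariant."""


def _check_matrix(values: np.ndarray, who: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise CohortValidationError(f"{who}: expected a 2-D matrix, got ndim={values.ndim}")
    if values.shape[0] < 2:
        raise CohortValidationError(f"{who}: need at least 2 time points, got {values.shape[0]}")
    if values.shape[1] < 1:
        raise CohortValidationError(f"{who}: need at least 1 component")
    if not np.all(np.isfinite(values)):
        raise CohortValidationError(f"{who}: matrix contains NaN or Inf entries")
    return values


@dataclass
class SubjectTimeSeries:
    """One subject's multivariate time course.

    Attributes
    ----------
    subject_id : str
        Unique identifier within a cohort.
    values : ndarray of shape (T, N)
        Rows are time points, columns are components; finite entries.
    label : int or None
        Optional binary class label (e.g. 1 = patient, 0 = control).
    """

    subject_id: str
    values: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = _check_matrix(self.values, f"subject {self.subject_id!r}")
        if self.label is not None:
            if self.label not in (0, 1):
                raise CohortValidationError(
                    f"subject {self.subject_id!r}: label must be 0 or 1, got {self.label!r}"
                )
            self.label = int(self.label)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass
class Cohort:
    """An ordered collection of subjects sharing one matrix shape."""

    name: str
    subjects: list[SubjectTimeSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dup}")
        shapes = {s.values.shape for s in self.subjects}
        if len(shapes) > 1:
            raise CohortValidationError(f"inconsistent subject shapes: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_timepoints(self) -> int:
        if not self.subjects:
            return 0
        return self.subjects[0].n_timepoints

    @property
    def n_components(self) -> int:
        if not self.subjects:
            return 0
        return self.subjects[0].n_components

    @property
    def labels(self) -> Optional[np.ndarray]:
        """Label vector, or None if any subject is unlabeled."""
        if any(s.label is None for s in self.subjects) or not self.subjects:
            return None
        return np.array([s.label for s in self.subjects], dtype=int)


@dataclass
class LabeledSequence:
    """A (matrix, binary label) training example with provenance."""

    values: np.ndarray
    y: int
    origin_id: str

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise CohortValidationError(f"label must be 0 or 1, got {self.y!r}")
        self.y = int(self.y)
        self.values = np.asarray(self.values, dtype=float)


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a JSON manifest and its delimited matrix files.

    The manifest declares ``{name, n_timepoints, n_components,
    subjects: [{id, file, label?}]}``; matrix file paths are resolved
    relative to the manifest's directory. Row order is time order.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    for key in ("name", "n_timepoints", "n_components", "subjects"):
        if key not in manifest:
            raise CohortValidationError(f"manifest missing field {key!r}")
    base = manifest_path.parent
    T, N = int(manifest["n_timepoints"]), int(manifest["n_components"])
    subjects = []
    for entry in manifest["subjects"]:
        sid = str(entry["id"])
        fpath = base / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"matrix file for subject {sid!r} not found: {fpath}")
        values = np.loadtxt(fpath, delimiter=",", ndmin=2)
        if values.shape != (T, N):
            raise CohortValidationError(
                f"subject {sid!r}: matrix shape {values.shape} does not match "
                f"manifest declaration ({T}, {N})"
            )
        subjects.append(SubjectTimeSeries(sid, values, entry.get("label")))
    return Cohort(name=str(manifest["name"]), subjects=subjects)


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort as CSV matrices plus a JSON manifest; returns the manifest path.

    Values are written with 17 significant digits so that
    ``read_cohort(write_cohort(c))`` reproduces every float bit-for-bit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in cohort.subjects:
        fname = f"{s.subject_id}.csv"
        np.savetxt(directory / fname, s.values, delimiter=",", fmt="%.17g")
        entry: dict = {"id": s.subject_id, "file": fname}
        if s.label is not None:
            entry["label"] = s.label
        entries.append(entry)
    manifest = {
        "name": cohort.name,
        "n_timepoints": cohort.n_timepoints,
        "n_components": cohort.n_components,
        "subjects": entries,
    }
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def split_subjects(
    cohort: Cohort, test_fraction: float, seed: int, stratify: bool = True
) -> tuple[list[SubjectTimeSeries], list[SubjectTimeSeries]]:
    """Deterministic (train, test) split of a cohort's subjects.

    Stratifies by label when labels are present and ``stratify`` is True.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    labels = cohort.labels
    if stratify and labels is not None:
        test_idx: list[int] = []
        for cls in np.unique(labels):
            cls_idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(cls_idx)
            k = max(1, int(round(test_fraction * len(cls_idx))))
            test_idx.extend(perm[:k].tolist())
        test_set = set(test_idx)
    else:
        perm = rng.permutation(n)
        k = max(1, int(round(test_fraction * n)))
        test_set = set(perm[:k].tolist())
    train = [s for i, s in enumerate(cohort.subjects) if i not in test_set]
    test = [s for i, s in enumerate(cohort.subjects) if i in test_set]
    return train, test
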