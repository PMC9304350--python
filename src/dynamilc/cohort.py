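"""Cohort data model: per-subject component time courses, windowing and I/O.

A cohort is a list of :class:`TimecourseRecord`, one per subject, each holding
a components × time matrix of ICA time-course activations plus an optional
binary diagnosis label (0 = control, 1 = patient).  Records can be stored as a
directory of per-subject CSV matrices with a ``labels.csv`` sidecar, or as a
single HDF5 container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TimecourseRecord",
    "SlidingWindowSpec",
    "WindowTensor",
    "CohortError",
    "load_cohort",
    "save_cohort",
    "normalize_timecourses",
    "make_windows",
]


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class TimecourseRecord:
    """One subject's components × time matrix with an optional binary label."""

    subject_id: str
    data: np.ndarray  # shape (C, T)
    label: Optional[int] = None
    cohort_tag: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise CohortError(f"{self.subject_id}: data must be 2-D (components × time)")
        if self.data.shape[0] < 2:
            raise CohortError(f"{self.subject_id}: need at least 2 components")
        if not np.all(np.isfinite(self.data)):
            raise CohortError(f"{self.subject_id}: non-finite values in time courses")
        if self.label is not None:
            self.label = int(self.label)
            if self.label not in (0, 1):
                raise CohortError(f"{self.subject_id}: label must be 0 or 1")

    @property
    def n_components(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SlidingWindowSpec:
    """Sliding-window geometry: 20-step windows, stride 10 for pretraining
    and stride 1 for downstream classification."""

    window_length: int = 20
    stride: int = 10

    def __post_init__(self):
        if self.window_length < 1 or self.stride < 1:
            raise ValueError("window_length and stride must be positive")

    def n_windows(self, n_timepoints: int) -> int:
        if n_timepoints < self.window_length:
            raise ValueError(
                f"series length {n_timepoints} shorter than window {self.window_length}"
            )
        return (n_timepoints - self.window_length) // self.stride + 1


@dataclass
class WindowTensor:
    """Stacked contiguous windows of one record, windows × C × window_length."""

    windows: np.ndarray
    start_indices: np.ndarray  # 0-based starts; window i covers [s_i, s_i + w)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_length(self) -> int:
        return self.windows.shape[2]


def normalize_timecourses(record: TimecourseRecord) -> TimecourseRecord:
    """Z-score each component row to mean 0, unit variance (population ddof=0).

    Constant rows cannot be scaled; they map to all-zero rows with a warning.
    """
    data = record.data
    mean = data.mean(axis=1, keepdims=True)
    std = data.std(axis=1, keepdims=True)
    constant = std[:, 0] == 0
    if np.any(constant):
        warnings.warn(
            f"{record.subject_id}: {int(constant.sum())} constant component row(s) "
            "zeroed during normalization",
            stacklevel=2,
        )
    safe_std = np.where(std == 0, 1.0, std)
    out = (data - mean) / safe_std
    out[constant] = 0.0
    return replace(record, data=out)


def make_windows(record: TimecourseRecord, spec: SlidingWindowSpec) -> WindowTensor:
    """Extract contiguous sliding windows; trailing partial windows are dropped."""
    C, T = record.data.shape
    n = spec.n_windows(T)
    starts = np.arange(n) * spec.stride
    windows = np.stack([record.data[:, s : s + spec.window_length] for s in starts])
    return WindowTensor(windows=windows, start_indices=starts)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _check_consistent(records: Sequence[TimecourseRecord]) -> None:
    if not records:
        raise CohortError("empty cohort")
    C = records[0].n_components
    for r in records:
        if r.n_components != C:
            raise CohortError(
                f"inconsistent component count: {r.subject_id} has {r.n_components}, expected {C}"
            )


def load_cohort(path, format: Optional[str] = None) -> list[TimecourseRecord]:
    """Load a cohort from a CSV directory or an HDF5 container.

    CSV directory: one headerless ``<subject_id>.csv`` matrix per subject
    (rows = components, columns = time points) plus an optional ``labels.csv``
    with columns ``subject_id,label``.  HDF5 layout: ``/subjects/<id>/data``
    datasets and an optional ``/labels/<id>`` scalar per labeled subject.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "hdf5" if path.is_file() else "csv-dir"

    records: list[TimecourseRecord] = []
    if format == "csv-dir":
        labels = {}
        labels_file = path / "labels.csv"
        if labels_file.exists():
            df = pd.read_csv(labels_file, dtype={"subject_id": str})
            labels = dict(zip(df["subject_id"], df["label"].astype(int)))
        for f in sorted(path.glob("*.csv")):
            if f.name == "labels.csv":
                continue
            try:
                data = np.loadtxt(f, delimiter=",", ndmin=2)
            except ValueError as e:
                raise CohortError(f"{f.name}: could not parse numeric matrix: {e}") from e
            sid = f.stem
            records.append(
                TimecourseRecord(sid, data, label=labels.get(sid), cohort_tag=path.name)
            )
    elif format == "hdf5":
        with h5py.File(path, "r") as h5:
            tag = h5.attrs.get("cohort_tag", "")
            label_grp = h5.get("labels")
            for sid in sorted(h5["subjects"]):
                data = h5["subjects"][sid]["data"][()]
                label = None
                if label_grp is not None and sid in label_grp:
                    label = int(label_grp[sid][()])
                records.append(TimecourseRecord(sid, data, label=label, cohort_tag=tag))
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_consistent(records)
    return records


def save_cohort(records: Sequence[TimecourseRecord], path, format: str = "hdf5") -> None:
    """Write a cohort in the layout read by :func:`load_cohort`."""
    _check_consistent(records)
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as h5:
            h5.attrs["cohort_tag"] = records[0].cohort_tag
            subj = h5.create_group("subjects")
            lab = h5.create_group("labels")
            for r in records:
                subj.create_group(r.subject_id).create_dataset("data", data=r.data)
                if r.label is not None:
                    lab.create_dataset(r.subject_id, data=r.label)
    elif format == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for r in records:
            np.savetxt(path / f"{r.subject_id}.csv", r.data, delimiter=",", fmt="%.17g")
            if r.label is not None:
                rows.append({"subject_id": r.subject_id, "label": r.label})
        if rows:
            pd.DataFrame(rows).to_csv(path / "labels.csv", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
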