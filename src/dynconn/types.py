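"""Core containers for parcellated source-space data and trial structure.

The pipeline operates on region-by-sample matrices (one per subject), a table
of trial onsets, and sliding-window bookkeeping objects.  All containers are
plain dataclasses validated on construction; heavy numerics live elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcelTimeseries",
    "TrialEvents",
    "WindowPlan",
    "WindowedData",
]


@dataclass
class ParcelTimeseries:
    """One subject's parcellated source timecourses.

    Parameters
    ----------
    data : ndarray, shape (n_regions, n_samples)
        Source-space data matrix Q: one row per parcellated region.
    sampling_rate : float
        Sampling frequency in Hz.
    region_labels : list of str
        Unique region names, one per row.
    subject_id : str
        Subject identifier.
    """

    data: np.ndarray
    sampling_rate: float
    region_labels: list[str]
    subject_id: str = "s00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_regions, n_samples) matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.region_labels = [str(l) for l in self.region_labels]
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {self.data.shape[0]} regions"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class TrialEvents:
    """Trial-onset table for one or more subjects.

    Backed by a DataFrame with columns ``subject_id``, ``onset_s``,
    ``condition``.  Onsets must be strictly increasing within each subject.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "onset_s", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        self.table["subject_id"] = self.table["subject_id"].astype(str)
        self.table["onset_s"] = self.table["onset_s"].astype(float)
        for sid, grp in self.table.groupby("subject_id"):
            on = grp["onset_s"].to_numpy()
            if not np.all(np.diff(on) > 0):
                raise ValueError(f"onsets not strictly increasing for subject {sid}")

    @classmethod
    def from_onsets(
        cls,
        onsets_by_subject: dict[str, np.ndarray],
        condition: str = "task",
    ) -> "TrialEvents":
        rows = [
            {"subject_id": sid, "onset_s": float(t), "condition": condition}
            for sid, onsets in onsets_by_subject.items()
            for t in np.asarray(onsets)
        ]
        return cls(pd.DataFrame(rows))

    def subjects(self) -> list[str]:
        return sorted(self.table["subject_id"].unique())

    def onsets(self, subject_id: str) -> np.ndarray:
        sel = self.table[self.table["subject_id"] == str(subject_id)]
        return sel["onset_s"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class WindowPlan:
    """Sliding-window layout within a trial epoch.

    ``centres`` are window-centre times in seconds relative to trial onset,
    equally spaced by ``shift``; each window spans ``width`` seconds and
    ``samples_per_window`` samples at the planning sampling rate.
    """

    width: float
    shift: float
    centres: np.ndarray
    samples_per_window: int

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if not (0 < self.shift <= self.width):
            raise ValueError("shift must satisfy 0 < shift <= width")
        if self.centres.size > 1:
            steps = np.diff(self.centres)
            if not np.allclose(steps, self.shift, atol=1e-9):
                raise ValueError("centres must be equally spaced by shift")
        if self.samples_per_window < 1:
            raise ValueError("samples_per_window must be >= 1")

    @property
    def n_windows(self) -> int:
        return self.centres.size


@dataclass
class WindowedData:
    """The windowed data matrices Q_i for one trial of one subject."""

    windows: np.ndarray  # (n_windows, n_regions, samples_per_window)
    plan: WindowPlan
    subject_id: str
    trial_index: int
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n_windows, n_regions, n_samples)")
        if self.windows.shape[0] != self.plan.n_windows:
            raise ValueError("window count does not match plan")
        if self.windows.shape[2] != self.plan.samples_per_window:
            raise ValueError("partial windows are not allowed")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]
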