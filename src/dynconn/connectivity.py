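"""Amplitude envelopes and the sliding-window adjacency tensor.

For each orthogonalised window ``O_i`` the Hilbert amplitude envelope of
every region is computed, and the all-to-all Pearson correlation between
envelopes forms an adjacency matrix ``R_i``.  Stacking the ``R_i`` over
windows, trials and subjects yields the adjacency tensor ``R`` of shape
``(n_regions, n_regions, N * Ns)`` whose third axis is the concatenated
window timeline (subjects outermost, trials next, window-in-trial
innermost).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .leakage import OrthogonalisedWindow
from .types import WindowPlan

__all__ = [
    "WindowIndex",
    "AdjacencyTensor",
    "hilbert_envelope",
    "window_adjacency",
    "build_tensor",
]


@dataclass
class WindowIndex:
    """Mapping slab -> (subject, trial, window-in-trial) for the tensor axis.

    Slabs are ordered canonically: subjects (sorted by id) outermost, trials
    next, windows within trial innermost.  ``centres`` are the within-trial
    window-centre times of the plan.
    """

    subject_ids: np.ndarray  # (n_slabs,) str
    trials: np.ndarray  # (n_slabs,) int
    windows: np.ndarray  # (n_slabs,) int, position within trial
    centres: np.ndarray  # (n_windows_per_trial,) seconds

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=str)
        self.trials = np.asarray(self.trials, dtype=int)
        self.windows = np.asarray(self.windows, dtype=int)
        self.centres = np.asarray(self.centres, dtype=float)
        n = self.subject_ids.size
        if not (self.trials.size == n and self.windows.size == n):
            raise ValueError("index columns must have equal length")

    @property
    def n_slabs(self) -> int:
        return self.subject_ids.size

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for s in self.subject_ids:
            if s not in seen:
                seen.append(str(s))
        return seen

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_windows_per_trial(self) -> int:
        return self.centres.size

    @property
    def n_trials_per_subject(self) -> int:
        sid = self.subject_ids[0]
        return int(self.trials[self.subject_ids == sid].max()) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slab": np.arange(self.n_slabs),
                "subject_id": self.subject_ids,
                "trial": self.trials,
                "window": self.windows,
                "centre_s": self.centres[self.windows],
            }
        )

    def validate_complete(self) -> None:
        """Check every subject has the same trials, each with every window."""
        W = self.n_windows_per_trial
        T = self.n_trials_per_subject
        for sid in self.subjects:
            m = self.subject_ids == sid
            if m.sum() != T * W:
                raise ValueError(f"subject {sid} has {m.sum()} slabs, expected {T * W}")
            got = set(zip(self.trials[m].tolist(), self.windows[m].tolist()))
            want = {(t, w) for t in range(T) for w in range(W)}
            if got != want:
                missing = sorted(want - got)[:5]
                raise ValueError(f"subject {sid} missing (trial, window) slabs: {missing}")


@dataclass
class AdjacencyTensor:
    """Concatenated per-window envelope-correlation matrices.

    ``data[j, k, i]`` is the Pearson correlation between the amplitude
    envelopes of regions j and k in window-slab i.
    """

    data: np.ndarray  # (nn, nn, n_slabs)
    window_index: WindowIndex
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("tensor must be (nn, nn, n_slabs)")
        if self.data.shape[2] != self.window_index.n_slabs:
            raise ValueError("slab count does not match window index")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_slabs(self) -> int:
        return self.data.shape[2]

    @property
    def n_windows_per_subject(self) -> int:
        return self.n_slabs // self.window_index.n_subjects

    @property
    def n_subjects(self) -> int:
        return self.window_index.n_subjects


def hilbert_envelope(O: OrthogonalisedWindow | np.ndarray) -> np.ndarray:
    """Amplitude envelope (analytic-signal magnitude) of each region row.

    Computed on the full window with no trimming: windows are long (seconds)
    relative to the carrier period, so edge effects are negligible.
    """
    data = O.data if isinstance(O, OrthogonalisedWindow) else np.asarray(O, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("window contains non-finite values")
    return np.abs(hilbert(data, axis=-1))


def window_adjacency(E: np.ndarray, region_labels: list[str] | None = None) -> np.ndarray:
    """All-to-all Pearson correlation between the envelope rows of a window.

    Returns a symmetric matrix with unit diagonal; a zero-variance envelope
    row raises, naming the region.
    """
    E = np.asarray(E, dtype=float)
    var = E.var(axis=1)
    dead = np.nonzero(var <= 0)[0]
    if dead.size:
        k = int(dead[0])
        name = region_labels[k] if region_labels else f"index {k}"
        raise ValueError(f"zero-variance envelope for region {name}")
    R = np.corrcoef(E)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def build_tensor(
    per_subject: dict[str, list[np.ndarray]],
    plan: WindowPlan,
    region_labels: list[str],
) -> AdjacencyTensor:
    """Concatenate per-window adjacency matrices over trials and subjects.

    Parameters
    ----------
    per_subject : dict
        ``subject_id -> list over trials of (n_windows, nn, nn) arrays``
        (window-in-trial innermost).  Subjects are sorted by id so the slab
        order is canonical regardless of input order.
    plan : WindowPlan
        The within-trial window plan (for centre times).
    region_labels : list of str
        Shared region labels; all subjects must agree on the region count.
    """
    sids = sorted(per_subject)
    if not sids:
        raise ValueError("no subjects provided")
    nn = len(region_labels)
    slabs: list[np.ndarray] = []
    idx_sub: list[str] = []
    idx_trial: list[int] = []
    idx_win: list[int] = []
    n_per_subject = None
    for sid in sids:
        trials = per_subject[sid]
        count = 0
        for t, stack in enumerate(trials):
            stack = np.asarray(stack, dtype=float)
            if stack.ndim != 3 or stack.shape[1:] != (nn, nn):
                raise ValueError(
                    f"subject {sid} trial {t}: expected (n_windows, {nn}, {nn}) "
                    f"adjacency stack, got {stack.shape}"
                )
            for w in range(stack.shape[0]):
                slabs.append(stack[w])
                idx_sub.append(sid)
                idx_trial.append(t)
                idx_win.append(w)
            count += stack.shape[0]
        if n_per_subject is None:
            n_per_subject = count
        elif count != n_per_subject:
            raise ValueError(
                f"subject {sid} has {count} windows, expected {n_per_subject}"
            )
    data = np.stack(slabs, axis=-1)
    index = WindowIndex(
        subject_ids=np.array(idx_sub),
        trials=np.array(idx_trial),
        windows=np.array(idx_win),
        centres=plan.centres,
    )
    return AdjacencyTensor(data=data, window_index=index, region_labels=list(region_labels))
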