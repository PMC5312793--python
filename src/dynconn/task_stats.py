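"""Task-modulation inference for independent connectivity components.

A component's trial-averaged timecourse is compared against two empirical
null distributions:

* **sign-flip** — half of the subjects (``floor(Ns/2)``) have the sign of
  their contribution inverted before trial averaging.  If a component is
  trial-locked consistently across subjects, flipping destroys it; if not,
  flipping changes nothing.  Exhaustive mode enumerates every subset
  (``C(Ns, floor(Ns/2))`` realisations, e.g. 6435 for 15 subjects).
* **sham-onset** — trials are re-epoched at random sham onsets on each
  subject's concatenated window timeline, destroying onset locking while
  preserving the component's marginal dynamics.

A component is significant if at any within-trial timepoint its trial
average falls outside the two-tailed empirical bounds of *both* nulls at a
Bonferroni-corrected level ``alpha / (2 * n_components * n_dof)``, where the
temporal degrees of freedom count one DOF per accumulated shift exceeding
half the window width (overlapping windows are not independent samples).

The expected null spread of a single window's envelope correlation is
``sigma(r) = 1 / sqrt(Bw * delta)`` with ``eta = Bw * delta`` effective
degrees of freedom — envelope bandwidth, not sample count, limits the
information in a window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .connectivity import WindowIndex
from .network_ica import ComponentSet

__all__ = [
    "TrialAverage",
    "NullDistribution",
    "NoiseEstimate",
    "SignificanceReport",
    "trial_average",
    "count_flip_realisations",
    "signflip_null",
    "shamonset_null",
    "temporal_dof",
    "corrected_threshold",
    "sigma_r",
    "test_components",
]

logger = logging.getLogger(__name__)

EXHAUSTIVE_FLIP_CAP = 200_000


@dataclass
class TrialAverage:
    """Trial-averaged component timecourses X-bar (``n_windows x nic``)."""

    data: np.ndarray
    time_axis: np.ndarray  # window-centre seconds relative to trial onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial average contains non-finite values")
        if self.data.shape[0] != self.time_axis.size:
            raise ValueError("time axis length must match window count")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def nic(self) -> int:
        return self.data.shape[1]


@dataclass
class NullDistribution:
    """Empirical null samples (``n_realisations x n_windows x nic``)."""

    samples: np.ndarray
    kind: str  # "sign_flip" | "sham_onset"
    exhaustive: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValueError("samples must be (n_realisations, n_windows, nic)")
        if self.kind not in ("sign_flip", "sham_onset"):
            raise ValueError(f"unknown null kind {self.kind!r}")

    @property
    def n_realisations(self) -> int:
        return self.samples.shape[0]


@dataclass
class NoiseEstimate:
    """Window correlation-noise figures from carrier bandwidth and width."""

    bandwidth: float  # Bw, Hz
    window_width: float  # delta, seconds
    dof: float  # eta = Bw * delta
    sigma_r: float  # 1 / sqrt(eta)


@dataclass
class SignificanceReport:
    """Per-component task-modulation verdicts at a corrected level."""

    significant: np.ndarray  # (nic,) bool
    significant_timepoints: list[np.ndarray]  # per component, window centres (s)
    threshold_alpha: float
    dof_used: int
    n_components: int
    time_axis: np.ndarray
    null_realisations: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in range(self.n_components):
            pts = self.significant_timepoints[j]
            rows.append(
                {
                    "component": j,
                    "significant": bool(self.significant[j]),
                    "n_significant_timepoints": pts.size,
                    "significant_centres_s": ";".join(f"{t:g}" for t in pts),
                    "threshold_alpha": self.threshold_alpha,
                    "dof_used": self.dof_used,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Task-modulation test (two-tailed, Bonferroni over components x temporal DOF)",
            f"  corrected alpha : {self.threshold_alpha:.3g}",
            f"  temporal DOF    : {self.dof_used}",
            "  null realisations: "
            + ", ".join(f"{k}={v}" for k, v in self.null_realisations.items()),
        ]
        for j in range(self.n_components):
            pts = self.significant_timepoints[j]
            verdict = "SIGNIFICANT" if self.significant[j] else "not significant"
            at = f" at t = {', '.join(f'{t:g} s' for t in pts)}" if pts.size else ""
            lines.append(f"  component {j:2d}: {verdict}{at}")
        return "\n".join(lines)


def _per_subject_blocks(C: ComponentSet, index: WindowIndex) -> np.ndarray:
    """Reshape X into (Ns, T, W, nic) per-subject/trial/window blocks."""
    index.validate_complete()
    W = index.n_windows_per_trial
    T = index.n_trials_per_subject
    subjects = index.subjects
    nic = C.nic
    if C.X.shape[1] != index.n_slabs:
        raise ValueError("component timecourse length does not match window index")
    out = np.empty((len(subjects), T, W, nic))
    for si, sid in enumerate(subjects):
        m = index.subject_ids == sid
        Xs = C.X[:, m]  # (nic, T*W)
        order = np.lexsort((index.windows[m], index.trials[m]))
        out[si] = Xs[:, order].T.reshape(T, W, nic)
    return out


def trial_average(C: ComponentSet, index: WindowIndex) -> TrialAverage:
    """Mean over all trials of all subjects at each within-trial window."""
    blocks = _per_subject_blocks(C, index)
    return TrialAverage(data=blocks.mean(axis=(0, 1)), time_axis=index.centres)


def count_flip_realisations(n_subjects: int) -> int:
    """Number of distinct half-subject sign-flip subsets, C(n, floor(n/2))."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for the sign-flip null")
    return math.comb(n_subjects, n_subjects // 2)


def signflip_null(
    C: ComponentSet,
    index: WindowIndex,
    mode: str = "exhaustive",
    n_realisations: int | None = None,
    seed: int | None = None,
    cap: int = EXHAUSTIVE_FLIP_CAP,
) -> NullDistribution:
    """Sign-flip null: invert half the subjects' contributions, re-average.

    ``mode='exhaustive'`` enumerates every subset of ``floor(Ns/2)``
    subjects (complementary subsets are distinct realisations);
    ``mode='sampled'`` draws ``n_realisations`` random subsets.
    """
    blocks = _per_subject_blocks(C, index)  # (Ns, T, W, nic)
    subj_avg = blocks.mean(axis=1)  # (Ns, W, nic)
    Ns = subj_avg.shape[0]
    k = Ns // 2
    total = count_flip_realisations(Ns)
    if mode == "exhaustive":
        if total > cap:
            raise ValueError(
                f"exhaustive sign-flip would need {total} realisations "
                f"(cap {cap}); use mode='sampled'"
            )
        subsets = combinations(range(Ns), k)
        signs = np.ones((total, Ns))
        for i, sub in enumerate(subsets):
            signs[i, list(sub)] = -1.0
        exhaustive = True
    elif mode == "sampled":
        if not n_realisations or n_realisations < 1:
            raise ValueError("sampled mode requires n_realisations >= 1")
        rng = np.random.default_rng(seed)
        signs = np.ones((n_realisations, Ns))
        for i in range(n_realisations):
            signs[i, rng.choice(Ns, size=k, replace=False)] = -1.0
        exhaustive = False
    else:
        raise ValueError(f"unknown sign-flip mode {mode!r}")
    flat = subj_avg.reshape(Ns, -1)  # (Ns, W*nic)
    samples = (signs @ flat) / Ns
    samples = samples.reshape(signs.shape[0], *subj_avg.shape[1:])
    return NullDistribution(samples=samples, kind="sign_flip", exhaustive=exhaustive, seed=seed)


def shamonset_null(
    C: ComponentSet,
    index: WindowIndex,
    n_realisations: int = 6000,
    seed: int | None = None,
) -> NullDistribution:
    """Sham-onset null: re-epoch component timecourses at random onsets.

    Sham epochs are stretches of ``n_windows_per_trial`` consecutive window
    slabs drawn uniformly (independently per subject and sham trial) from
    each subject's concatenated window timeline; the sham trials are then
    averaged exactly as the genuine trial average.
    """
    if n_realisations < 1:
        raise ValueError("n_realisations must be >= 1")
    blocks = _per_subject_blocks(C, index)  # (Ns, T, W, nic)
    Ns, T, W, nic = blocks.shape
    seq = blocks.reshape(Ns, T * W, nic)  # per-subject window timeline
    n_valid = T * W - W + 1
    if n_valid < 1:
        raise ValueError("window timeline too short to draw sham epochs")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n_valid, size=(n_realisations, Ns, T))
    gather = starts[..., None] + np.arange(W)  # (n_real, Ns, T, W)
    acc = np.zeros((n_realisations, T, W, nic))
    for s in range(Ns):
        acc += seq[s][gather[:, s]]  # fancy-gather (n_real, T, W, nic)
    samples = acc.mean(axis=1) / Ns
    return NullDistribution(samples=samples, kind="sham_onset", seed=seed)


def temporal_dof(n_windows: int, shift: float, width: float) -> int:
    """Temporal degrees of freedom of a sliding-window trial average.

    One DOF accrues each time the accumulated shift exceeds half the window
    width: ``floor(n_windows * shift / (width / 2))``.
    """
    if shift <= 0 or width <= 0:
        raise ValueError("shift and width must be positive")
    return int(np.floor(n_windows * shift / (width / 2.0) + 1e-9))


def corrected_threshold(alpha: float, n_components: int, n_dof: int) -> float:
    """Two-tailed Bonferroni level ``alpha / (2 * n_components * n_dof)``."""
    if alpha <= 0 or n_components < 1 or n_dof < 1:
        raise ValueError("alpha, n_components and n_dof must be positive")
    return alpha / (2.0 * n_components * n_dof)


def sigma_r(Bw: float, delta: float) -> NoiseEstimate:
    """Null spread of a window envelope correlation: 1/sqrt(Bw * delta).

    ``eta = Bw * delta`` is the effective DOF of a windowed envelope — set
    by carrier bandwidth and window width, not by the sample count.
    """
    if Bw <= 0 or delta <= 0:
        raise ValueError("bandwidth and window width must be positive")
    eta = Bw * delta
    return NoiseEstimate(
        bandwidth=float(Bw),
        window_width=float(delta),
        dof=float(eta),
        sigma_r=1.0 / math.sqrt(eta),
    )


def _empirical_bounds(
    samples: np.ndarray, alpha_corrected: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed order-statistic bounds, clamped to sample extremes."""
    n = samples.shape[0]
    tail = alpha_corrected / 2.0
    if tail * n < 1.0:
        logger.warning(
            "requested tail quantile %.3g is finer than 1/%d realisations; "
            "bounds clamped to the sample extremes (min achievable two-tailed "
            "p = %.3g)",
            tail,
            n,
            2.0 / n,
        )
        return samples.min(axis=0), samples.max(axis=0)
    lower = np.quantile(samples, tail, axis=0, method="lower")
    upper = np.quantile(samples, 1.0 - tail, axis=0, method="higher")
    return lower, upper


def test_components(
    xbar: TrialAverage,
    nulls: list[NullDistribution],
    alpha_corrected: float,
    dof_used: int = 1,
) -> SignificanceReport:
    """Flag components whose trial average escapes *all* null envelopes.

    At each (timepoint, component), the trial average must lie strictly
    outside the two-tailed empirical bounds of every supplied null; a
    component is significant if any timepoint qualifies.
    """
    if not nulls:
        raise ValueError("at least one null distribution is required")
    outside = np.ones_like(xbar.data, dtype=bool)
    for null in nulls:
        if null.samples.shape[1:] != xbar.data.shape:
            raise ValueError(
                f"null {null.kind} shape {null.samples.shape[1:]} does not "
                f"match trial average {xbar.data.shape}"
            )
        lower, upper = _empirical_bounds(null.samples, alpha_corrected)
        outside &= (xbar.data > upper) | (xbar.data < lower)
    significant = outside.any(axis=0)
    points = [xbar.time_axis[outside[:, j]] for j in range(xbar.nic)]
    return SignificanceReport(
        significant=significant,
        significant_timepoints=points,
        threshold_alpha=alpha_corrected,
        dof_used=dof_used,
        n_components=xbar.nic,
        time_axis=xbar.time_axis,
        null_realisations={n.kind: n.n_realisations for n in nulls},
    )
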