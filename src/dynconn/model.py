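"""Model/Results surface tying the pipeline stages together.

:class:`DynamicNetworkModel` is built from parcellated timecourses and a
trial-event table; ``fit()`` runs band-pass filtering, sliding-window
segmentation, per-window symmetric orthogonalisation, Hilbert envelopes,
all-to-all envelope correlation, tensor assembly and temporal ICA, and
returns a :class:`DynamicNetworkResults` carrying the component set.  The
results object exposes trial averages, the permutation tests, per-component
network matrices, plots and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import task_stats
from .connectivity import (
    AdjacencyTensor,
    build_tensor,
    hilbert_envelope,
    window_adjacency,
)
from .leakage import symmetric_orthogonalise
from .network_ica import (
    ComponentSet,
    NetworkMatrix,
    component_to_network,
    decompose_timecourses,
    threshold_network,
    vectorise_tensor,
)
from .task_stats import (
    NullDistribution,
    SignificanceReport,
    TrialAverage,
    corrected_threshold,
    shamonset_null,
    signflip_null,
    temporal_dof,
    trial_average,
)
from .types import ParcelTimeseries, TrialEvents
from .windowing import bandpass_filter, plan_windows, segment

__all__ = ["DynamicNetworkModel", "DynamicNetworkResults"]


class DynamicNetworkModel:
    """Dynamic envelope-connectivity network model for a group of subjects.

    Parameters
    ----------
    timeseries : list of ParcelTimeseries
        One region-by-sample matrix per subject (same regions, same rate).
    events : TrialEvents
        Trial onsets per subject.
    band : (float, float)
        Carrier band in Hz (e.g. ``(13, 30)`` for beta).
    window_width, window_shift : float
        Sliding-window width and shift in seconds (defaults 6 and 0.5).
    epoch_start, epoch_end : float
        First and last window-centre times relative to trial onset.
    n_components : int
        Number of independent connectivity components (default 10).
    orth_tol, orth_max_iter
        Convergence controls of the symmetric orthogonalisation.
    """

    def __init__(
        self,
        timeseries: list[ParcelTimeseries],
        events: TrialEvents,
        band: tuple[float, float],
        window_width: float = 6.0,
        window_shift: float = 0.5,
        epoch_start: float = -12.0,
        epoch_end: float = 12.0,
        n_components: int = 10,
        orth_tol: float = 1e-9,
        orth_max_iter: int = 60,
    ) -> None:
        if not timeseries:
            raise ValueError("need at least one subject")
        rates = {ts.sampling_rate for ts in timeseries}
        if len(rates) != 1:
            raise ValueError("all subjects must share one sampling rate")
        labels = timeseries[0].region_labels
        for ts in timeseries:
            if ts.region_labels != labels:
                raise ValueError(
                    f"subject {ts.subject_id} region labels differ from "
                    f"subject {timeseries[0].subject_id}"
                )
        ids = [ts.subject_id for ts in timeseries]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        missing = set(ids) - set(events.subjects())
        if missing:
            raise ValueError(f"no events for subjects: {sorted(missing)}")
        self.timeseries = list(timeseries)
        self.events = events
        self.band = (float(band[0]), float(band[1]))
        self.sampling_rate = timeseries[0].sampling_rate
        self.region_labels = labels
        self.plan = plan_windows(
            epoch_start, epoch_end, window_width, window_shift, self.sampling_rate
        )
        self.n_components = int(n_components)
        self.orth_tol = orth_tol
        self.orth_max_iter = orth_max_iter

    @classmethod
    def from_paths(
        cls,
        timeseries_paths: list[str],
        events_path: str,
        **kwargs,
    ) -> "DynamicNetworkModel":
        from .io import read_events, read_timeseries

        return cls(
            [read_timeseries(p) for p in timeseries_paths],
            read_events(events_path),
            **kwargs,
        )

    # -- pipeline stages -----------------------------------------------------

    def build_adjacency_tensor(self) -> AdjacencyTensor:
        """Filter, segment, orthogonalise, envelope and correlate all windows."""
        per_subject: dict[str, list[np.ndarray]] = {}
        for ts in self.timeseries:
            filtered = bandpass_filter(ts, self.band)
            trials = segment(filtered, self.events, self.plan)
            stacks = []
            for wd in trials:
                mats = []
                for w in range(wd.n_windows):
                    O = symmetric_orthogonalise(
                        wd.windows[w], tol=self.orth_tol, max_iter=self.orth_max_iter
                    )
                    E = hilbert_envelope(O)
                    mats.append(window_adjacency(E, self.region_labels))
                stacks.append(np.stack(mats))
            per_subject[ts.subject_id] = stacks
        return build_tensor(per_subject, self.plan, self.region_labels)

    def fit(self, seed: int = 0) -> "DynamicNetworkResults":
        """Run the full pipeline and decompose into independent networks."""
        tensor = self.build_adjacency_tensor()
        P = vectorise_tensor(tensor)
        components = decompose_timecourses(P, nic=self.n_components, seed=seed)
        return DynamicNetworkResults(model=self, components=components)


@dataclass
class DynamicNetworkResults:
    """Fitted dynamic-network decomposition with inference helpers."""

    model: DynamicNetworkModel
    components: ComponentSet

    def __post_init__(self) -> None:
        self._xbar: TrialAverage | None = None
        self._report: SignificanceReport | None = None
        self._nulls: list[NullDistribution] = []

    # -- accessors -----------------------------------------------------------

    @property
    def mixing(self) -> np.ndarray:
        return self.components.A

    @property
    def nic(self) -> int:
        return self.components.nic

    def trial_average(self) -> TrialAverage:
        if self._xbar is None:
            self._xbar = trial_average(self.components, self.components.window_index)
        return self._xbar

    def network(self, j: int) -> NetworkMatrix:
        return component_to_network(self.components, j)

    def network_edges(self, j: int, fraction: float = 0.7):
        return threshold_network(self.network(j), fraction)

    @property
    def temporal_dof(self) -> int:
        return temporal_dof(self.model.plan.n_windows, self.model.plan.shift, self.model.plan.width)

    # -- inference -----------------------------------------------------------

    def test_task_modulation(
        self,
        alpha: float = 0.05,
        n_onset_realisations: int = 6000,
        flip_mode: str = "exhaustive",
        n_flip_realisations: int | None = None,
        seed: int = 0,
    ) -> SignificanceReport:
        """Sign-flip and sham-onset permutation tests, Bonferroni corrected."""
        index = self.components.window_index
        dof = self.temporal_dof
        alpha_c = corrected_threshold(alpha, self.nic, dof)
        flip = signflip_null(
            self.components,
            index,
            mode=flip_mode,
            n_realisations=n_flip_realisations,
            seed=seed,
        )
        sham = shamonset_null(
            self.components, index, n_realisations=n_onset_realisations, seed=seed
        )
        self._nulls = [flip, sham]
        self._report = task_stats.test_components(
            self.trial_average(), self._nulls, alpha_c, dof_used=dof
        )
        return self._report

    @property
    def nulls(self) -> list[NullDistribution]:
        return self._nulls

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        idx = self.components.window_index
        lines = [
            "Dynamic envelope-connectivity network decomposition",
            "===================================================",
            f"subjects            : {idx.n_subjects}",
            f"trials per subject  : {idx.n_trials_per_subject}",
            f"windows per trial   : {idx.n_windows_per_trial}"
            f" (width {m.plan.width} s, shift {m.plan.shift} s)",
            f"band                : {m.band[0]}-{m.band[1]} Hz",
            f"regions / connections: {len(m.region_labels)} / "
            f"{len(self.components.edge_index)}",
            f"components (nic)    : {self.nic}",
            f"retained variance   : {self.components.whitening.retained_variance:.1%}",
            f"temporal DOF        : {self.temporal_dof}",
        ]
        xbar = self.trial_average()
        peaks = np.abs(xbar.data).max(axis=0)
        order = np.argsort(-peaks)
        lines.append("component |trial-average| peaks:")
        for j in order:
            flag = ""
            if self._report is not None:
                flag = "  *significant*" if self._report.significant[j] else ""
            lines.append(f"  component {j:2d}: peak {peaks[j]:.4f}{flag}")
        if self._report is not None:
            lines.append("")
            lines.append(self._report.summary())
        return "\n".join(lines)

    def plot_component(self, j: int, ax=None):
        """Trial-averaged timecourse of component j with null envelopes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xbar = self.trial_average()
        ax.plot(xbar.time_axis, xbar.data[:, j], "k-", lw=1.5, label="trial average")
        for null, color in zip(self._nulls, ("0.7", "0.85")):
            lo = null.samples[:, :, j].min(axis=0)
            hi = null.samples[:, :, j].max(axis=0)
            ax.fill_between(
                xbar.time_axis, lo, hi, color=color, alpha=0.6, label=f"{null.kind} null"
            )
        ax.axvline(0.0, color="k", ls=":", lw=0.8)
        ax.set_xlabel("time relative to trial onset (s)")
        ax.set_ylabel("component amplitude")
        ax.set_title(f"component {j}")
        ax.legend(loc="best", fontsize="small")
        return ax

    def plot_network_matrix(self, j: int, ax=None):
        """Mixing-coefficient matrix of component j as an image."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        W = self.network(j).weights
        vmax = np.abs(W).max() or 1.0
        im = ax.imshow(W, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xlabel("region")
        ax.set_ylabel("region")
        ax.set_title(f"component {j} mixing coefficients")
        ax.figure.colorbar(im, ax=ax)
        return ax
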