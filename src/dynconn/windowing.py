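"""Band-pass filtering and sliding-window segmentation of parcellated data.

Filtering is zero-phase (forward-backward Butterworth) and applied to the
continuous recording before segmentation, so window contents carry no filter
edge transients.  Windows are planned as centre times relative to trial onset
and realised as half-open sample ranges ``[start, start + f*width)``.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import ParcelTimeseries, TrialEvents, WindowedData, WindowPlan

__all__ = ["bandpass_filter", "plan_windows", "segment"]

_BUTTER_ORDER = 4  # per pass; filtfilt doubles the effective order


def _validate_band(band: tuple[float, float], f: float) -> tuple[float, float]:
    low, high = float(band[0]), float(band[1])
    if not (0 < low < high):
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    if high >= f / 2:
        raise ValueError(
            f"band upper edge {high} Hz is at or above Nyquist ({f / 2} Hz)"
        )
    return low, high


def bandpass_sos(band: tuple[float, float], f: float) -> np.ndarray:
    """Second-order sections of the pipeline's Butterworth band-pass."""
    low, high = _validate_band(band, f)
    return signal.butter(_BUTTER_ORDER, [low, high], btype="bandpass", fs=f, output="sos")


def bandpass_filter(ts: ParcelTimeseries, band: tuple[float, float]) -> ParcelTimeseries:
    """Zero-phase band-pass of every region timecourse.

    Uses an order-4 Butterworth applied forward and backward
    (``sosfiltfilt``), giving zero phase shift so amplitude-envelope timing
    is preserved.
    """
    sos = bandpass_sos(band, ts.sampling_rate)
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return ParcelTimeseries(
        data=filtered,
        sampling_rate=ts.sampling_rate,
        region_labels=list(ts.region_labels),
        subject_id=ts.subject_id,
    )


def plan_windows(
    t_start: float,
    t_end: float,
    width: float,
    shift: float,
    f: float,
) -> WindowPlan:
    """Enumerate window centres ``t_start, t_start+shift, ..., t_end``.

    The count is ``floor((t_end - t_start)/shift) + 1``; a small relative
    guard absorbs floating-point representation of the step.
    """
    if shift <= 0:
        raise ValueError("window shift must be positive")
    if width <= 0:
        raise ValueError("window width must be positive")
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    if f <= 0:
        raise ValueError("sampling rate must be positive")
    n = int(np.floor((t_end - t_start) / shift + 1e-9)) + 1
    centres = t_start + shift * np.arange(n)
    return WindowPlan(
        width=float(width),
        shift=float(shift),
        centres=centres,
        samples_per_window=int(round(f * width)),
    )


def segment(
    ts: ParcelTimeseries,
    events: TrialEvents,
    plan: WindowPlan,
) -> list[WindowedData]:
    """Cut one :class:`WindowedData` per trial out of a continuous recording.

    Window ``i`` of a trial with onset ``o`` spans samples
    ``[round((o + centre_i - width/2) * f), + samples_per_window)``.
    Windows that would overrun the recording raise, naming the trial and
    window — partial windows are never zero-padded.
    """
    f = ts.sampling_rate
    spw = plan.samples_per_window
    onsets = events.onsets(ts.subject_id)
    if onsets.size == 0:
        raise ValueError(f"no events for subject {ts.subject_id}")
    out: list[WindowedData] = []
    for trial, onset in enumerate(onsets):
        starts = np.round((onset + plan.centres - plan.width / 2) * f).astype(int)
        bad = np.nonzero((starts < 0) | (starts + spw > ts.n_samples))[0]
        if bad.size:
            w = int(bad[0])
            raise ValueError(
                f"subject {ts.subject_id} trial {trial} window {w} "
                f"(centre {plan.centres[w]:+.2f} s) overruns the recording "
                f"[0, {ts.duration:.2f}) s"
            )
        windows = np.stack([ts.data[:, s : s + spw] for s in starts])
        out.append(
            WindowedData(
                windows=windows,
                plan=plan,
                subject_id=ts.subject_id,
                trial_index=trial,
                region_labels=list(ts.region_labels),
            )
        )
    return out
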