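"""File formats: delimited-text and HDF5 containers for every pipeline artifact.

Timecourses travel as delimited numeric text (one row per region, with a
small ``# key: value`` header carrying sampling rate, subject id and region
labels) or inside an HDF5 container (lossless round-trip).  Events and
reports are CSV.  The adjacency tensor and component set are HDF5 with
named dimensions and the (subject, trial, window) index table.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .connectivity import AdjacencyTensor, WindowIndex
from .network_ica import ComponentSet, NetworkMatrix, WhiteningRecord, _upper_edges
from .task_stats import SignificanceReport
from .types import ParcelTimeseries, TrialEvents

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_events",
    "write_events",
    "write_tensor",
    "read_tensor",
    "write_components",
    "read_components",
    "write_network_matrix",
    "write_edge_list",
    "write_report",
    "load_config",
]


# -- parcellated timecourses -------------------------------------------------

def write_timeseries(ts: ParcelTimeseries, path: str | Path) -> Path:
    """Write one subject's timecourses; ``.h5`` gives a lossless container,
    anything else delimited text with a metadata header."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as h:
            d = h.create_dataset("data", data=ts.data)
            d.attrs["sampling_rate"] = ts.sampling_rate
            d.attrs["subject_id"] = ts.subject_id
            h.create_dataset(
                "region_labels", data=np.array(ts.region_labels, dtype="S")
            )
    else:
        header = (
            f"# sampling_rate_hz: {ts.sampling_rate!r}\n"
            f"# subject_id: {ts.subject_id}\n"
            f"# region_labels: {','.join(ts.region_labels)}"
        )
        np.savetxt(path, ts.data, delimiter="\t", header=header, comments="")
    return path


def read_timeseries(path: str | Path) -> ParcelTimeseries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as h:
            d = h["data"]
            return ParcelTimeseries(
                data=d[()],
                sampling_rate=float(d.attrs["sampling_rate"]),
                region_labels=[l.decode() for l in h["region_labels"][()]],
                subject_id=str(d.attrs["subject_id"]),
            )
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
                continue
            try:
                rows.append([float(x) for x in line.replace(",", "\t").split()])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric entry on line {lineno}") from exc
    if "sampling_rate_hz" not in meta:
        raise ValueError(f"{path}: missing '# sampling_rate_hz:' metadata header")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise ValueError(f"{path}: ragged row {bad} ({len(rows[bad])} values)")
    data = np.asarray(rows)
    labels = (
        meta["region_labels"].split(",")
        if "region_labels" in meta
        else [f"region{r:02d}" for r in range(data.shape[0])]
    )
    return ParcelTimeseries(
        data=data,
        sampling_rate=float(meta["sampling_rate_hz"].strip("'\"")),
        region_labels=labels,
        subject_id=meta.get("subject_id", "s00"),
    )


# -- events ------------------------------------------------------------------

def write_events(events: TrialEvents, path: str | Path) -> Path:
    path = Path(path)
    events.table.to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> TrialEvents:
    return TrialEvents(pd.read_csv(path))


# -- window index helpers ----------------------------------------------------

def _write_index(h: h5py.File, index: WindowIndex) -> None:
    grp = h.create_group("window_index")
    grp.create_dataset("subject_ids", data=np.array(index.subject_ids, dtype="S"))
    grp.create_dataset("trials", data=index.trials)
    grp.create_dataset("windows", data=index.windows)
    grp.create_dataset("centres_s", data=index.centres)


def _read_index(h: h5py.File) -> WindowIndex:
    grp = h["window_index"]
    return WindowIndex(
        subject_ids=np.array([s.decode() for s in grp["subject_ids"][()]]),
        trials=grp["trials"][()],
        windows=grp["windows"][()],
        centres=grp["centres_s"][()],
    )


# -- adjacency tensor --------------------------------------------------------

def write_tensor(R: AdjacencyTensor, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h:
        d = h.create_dataset("adjacency", data=R.data)
        d.attrs["dims"] = "region,region,window_slab"
        h.create_dataset("region_labels", data=np.array(R.region_labels, dtype="S"))
        _write_index(h, R.window_index)
    return path


def read_tensor(path: str | Path) -> AdjacencyTensor:
    with h5py.File(path, "r") as h:
        return AdjacencyTensor(
            data=h["adjacency"][()],
            window_index=_read_index(h),
            region_labels=[l.decode() for l in h["region_labels"][()]],
        )


def write_slab_text(R: AdjacencyTensor, slab: int, path: str | Path) -> Path:
    """Export a single adjacency matrix as delimited text."""
    path = Path(path)
    np.savetxt(path, R.data[:, :, slab], delimiter="\t")
    return path


# -- component set -----------------------------------------------------------

def write_components(C: ComponentSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h:
        h.create_dataset("X", data=C.X)
        h.create_dataset("A", data=C.A)
        h.attrs["seed"] = C.seed
        h.create_dataset("region_labels", data=np.array(C.region_labels, dtype="S"))
        wg = h.create_group("whitening")
        wg.create_dataset("transform", data=C.whitening.transform)
        wg.create_dataset("back_projection", data=C.whitening.back_projection)
        wg.create_dataset("mean", data=C.whitening.mean)
        wg.create_dataset(
            "explained_variance_ratio", data=C.whitening.explained_variance_ratio
        )
        if C.window_index is not None:
            _write_index(h, C.window_index)
    return path


def read_components(path: str | Path) -> ComponentSet:
    with h5py.File(path, "r") as h:
        labels = [l.decode() for l in h["region_labels"][()]]
        wg = h["whitening"]
        record = WhiteningRecord(
            transform=wg["transform"][()],
            back_projection=wg["back_projection"][()],
            mean=wg["mean"][()],
            explained_variance_ratio=wg["explained_variance_ratio"][()],
        )
        return ComponentSet(
            X=h["X"][()],
            A=h["A"][()],
            edge_index=_upper_edges(len(labels)),
            region_labels=labels,
            whitening=record,
            seed=int(h.attrs["seed"]),
            window_index=_read_index(h) if "window_index" in h else None,
        )


# -- network exports ---------------------------------------------------------

def write_network_matrix(M: NetworkMatrix, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, M.weights, delimiter="\t")
    return path


def write_edge_list(
    edges: list[tuple[int, int, float]],
    region_labels: list[str],
    path: str | Path,
) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "region_a": region_labels[j],
                "region_b": region_labels[k],
                "weight": w,
            }
            for j, k, w in edges
        ],
        columns=["region_a", "region_b", "weight"],
    ).to_csv(path, index=False)
    return path


def write_report(report: SignificanceReport, path: str | Path) -> Path:
    path = Path(path)
    report.to_frame().to_csv(path, index=False)
    path.with_suffix(".txt").write_text(report.summary() + "\n")
    return path


# -- configuration -----------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) pipeline configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
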