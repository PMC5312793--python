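"""Temporal ICA over connection timecourses.

The adjacency tensor is vectorised (strict upper triangle, row-major) into a
matrix P of shape ``(N*Ns, nc)`` whose columns are the timecourses of
individual connections.  P' = P^T is reduced to ``nic`` dimensions by
PCA prewhitening, and deflation-mode FastICA (cubic contrast) extracts
temporally independent connectivity signatures:

    P^T  ~=  A X

where the rows of ``X`` (``nic x N*Ns``) are independent timecourses and
each column of the mixing matrix ``A`` (``nc x nic``) gives the contribution
of every connection to one component — i.e. the spatial signature of a
network of connections that co-modulate in time.

Sign and scale of an ICA decomposition are arbitrary; here each column of A
is normalised to unit length with its largest-magnitude entry made positive,
and X is rescaled so the product A X is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .connectivity import AdjacencyTensor, WindowIndex

__all__ = [
    "ConnectionTimecourses",
    "WhiteningRecord",
    "ComponentSet",
    "NetworkMatrix",
    "vectorise_tensor",
    "unvectorise",
    "prewhiten",
    "fastica_deflation",
    "decompose_timecourses",
    "component_to_network",
    "threshold_network",
]

_SYMMETRY_TOL = 1e-8


@dataclass
class ConnectionTimecourses:
    """Connection-wise correlation timecourses P (``n_slabs x nc``)."""

    data: np.ndarray
    edge_index: list[tuple[int, int]]  # column -> (j, k), j < k, row-major
    region_labels: list[str]
    window_index: WindowIndex | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        nn = len(self.region_labels)
        if self.data.shape[1] != (nn * nn - nn) // 2:
            raise ValueError("column count must be (nn^2 - nn)/2")

    @property
    def nc(self) -> int:
        return self.data.shape[1]

    @property
    def n_slabs(self) -> int:
        return self.data.shape[0]


@dataclass
class WhiteningRecord:
    """PCA prewhitening transform and retained-variance bookkeeping."""

    transform: np.ndarray  # (nic, nc): Z = transform @ (D - mean)
    back_projection: np.ndarray  # (nc, nic): D ~= mean + back_projection @ Z
    mean: np.ndarray  # (nc,) per-connection temporal mean
    explained_variance_ratio: np.ndarray  # (nic,)

    @property
    def retained_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())


@dataclass
class ComponentSet:
    """ICA mixing matrix A and independent connectivity timecourses X."""

    X: np.ndarray  # (nic, n_slabs), rows zero-mean
    A: np.ndarray  # (nc, nic), unit-norm columns
    edge_index: list[tuple[int, int]]
    region_labels: list[str]
    whitening: WhiteningRecord
    seed: int
    window_index: WindowIndex | None = None

    @property
    def nic(self) -> int:
        return self.A.shape[1]

    @property
    def n_slabs(self) -> int:
        return self.X.shape[1]


@dataclass
class NetworkMatrix:
    """Spatial signature of one component as a symmetric region matrix."""

    weights: np.ndarray  # (nn, nn) symmetric, zero diagonal
    component_id: int
    region_labels: list[str] = field(default_factory=list)


def _upper_edges(nn: int) -> list[tuple[int, int]]:
    iu = np.triu_indices(nn, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def vectorise_tensor(R: AdjacencyTensor) -> ConnectionTimecourses:
    """Extract the strict upper triangle of every slab, row-major.

    The diagonal (self-correlation, always 1) and the lower triangle
    (redundant by symmetry) are dropped, leaving ``nc = (nn^2 - nn)/2``
    unique connections per window.
    """
    asym = np.abs(R.data - R.data.transpose(1, 0, 2)).max()
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"tensor slab asymmetric beyond tolerance (max |R - R^T| = {asym:.3g})")
    nn = R.n_regions
    iu = np.triu_indices(nn, k=1)
    data = R.data[iu[0], iu[1], :].T  # (n_slabs, nc)
    return ConnectionTimecourses(
        data=data,
        edge_index=_upper_edges(nn),
        region_labels=list(R.region_labels),
        window_index=R.window_index,
    )


def unvectorise(values: np.ndarray, nn: int) -> np.ndarray:
    """Scatter an nc-vector back to a symmetric matrix with zero diagonal."""
    values = np.asarray(values, dtype=float)
    M = np.zeros((nn, nn))
    iu = np.triu_indices(nn, k=1)
    M[iu] = values
    M += M.T
    return M


def prewhiten(
    P: ConnectionTimecourses | np.ndarray,
    nic: int,
) -> tuple[np.ndarray, WhiteningRecord]:
    """Reduce the connection dimension to ``nic`` whitened channels.

    The connection-by-time matrix ``D = P^T`` is mean-centred per connection
    and decomposed by SVD; the output ``Z`` (``nic x n_slabs``) satisfies
    ``Z Z^T / n_slabs = I``.  The record keeps the transform, its
    back-projection and the explained-variance fractions of the retained
    principal directions.
    """
    data = P.data if isinstance(P, ConnectionTimecourses) else np.asarray(P, dtype=float)
    D = data.T  # (nc, n_slabs)
    nc, n = D.shape
    if not (1 <= nic <= min(nc, n)):
        raise ValueError(f"nic={nic} must be in [1, min(nc={nc}, n={n})]")
    mean = D.mean(axis=1)
    Dc = D - mean[:, None]
    U, s, Vt = np.linalg.svd(Dc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(nc, n) * np.finfo(float).eps)) if s.size else 0
    if nic > rank:
        raise ValueError(f"nic={nic} exceeds the data rank {rank}")
    var = s**2
    record = WhiteningRecord(
        transform=np.sqrt(n) * (U[:, :nic] / s[:nic]).T,
        back_projection=U[:, :nic] * s[:nic] / np.sqrt(n),
        mean=mean,
        explained_variance_ratio=var[:nic] / var.sum(),
    )
    Z = np.sqrt(n) * Vt[:nic]
    return Z, record


def fastica_deflation(
    whitened: np.ndarray,
    record: WhiteningRecord,
    nic: int,
    seed: int = 0,
    *,
    edge_index: list[tuple[int, int]] | None = None,
    region_labels: list[str] | None = None,
    window_index: WindowIndex | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    n_restarts: int = 5,
) -> ComponentSet:
    """Deflation-mode FastICA with the cubic contrast on whitened data.

    Runs are deterministic given ``seed``; on a convergence warning the
    decomposition is restarted (fresh rotation seed) up to ``n_restarts``
    times before raising.
    """
    Z = np.asarray(whitened, dtype=float)
    if Z.shape[0] != nic:
        raise ValueError("whitened data must have nic rows")
    last_warning: str | None = None
    for attempt in range(n_restarts):
        ica = FastICA(
            n_components=nic,
            algorithm="deflation",
            fun="cube",
            whiten=False,
            max_iter=max_iter,
            tol=tol,
            random_state=seed + 1000 * attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(Z.T)  # (n_slabs, nic)
        conv = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
        if not conv:
            break
        last_warning = str(conv[0].message)
    else:
        raise RuntimeError(
            f"FastICA failed to converge after {n_restarts} restarts "
            f"(deflation stage report: {last_warning})"
        )
    W = ica.components_  # (nic, nic) unmixing of the whitened channels
    X = S.T  # (nic, n_slabs), X = W @ Z
    A = record.back_projection @ np.linalg.pinv(W)  # (nc, nic)
    # Fix sign/scale: unit-norm A columns, largest-|entry| positive.
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    signs = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(A.shape[1])])
    signs[signs == 0] = 1.0
    A = A / (norms * signs)
    X = X * (norms * signs)[:, None]
    return ComponentSet(
        X=X,
        A=A,
        edge_index=edge_index if edge_index is not None else [],
        region_labels=region_labels if region_labels is not None else [],
        whitening=record,
        seed=seed,
        window_index=window_index,
    )


def decompose_timecourses(
    P: ConnectionTimecourses,
    nic: int = 10,
    seed: int = 0,
    **ica_kwargs,
) -> ComponentSet:
    """Prewhiten P and run deflation FastICA in one step (group level).

    Whitening is computed once on the full concatenated matrix (all windows,
    trials and subjects), so components are a group-level decomposition.
    """
    Z, record = prewhiten(P, nic)
    return fastica_deflation(
        Z,
        record,
        nic,
        seed=seed,
        edge_index=P.edge_index,
        region_labels=P.region_labels,
        window_index=P.window_index,
        **ica_kwargs,
    )


def component_to_network(C: ComponentSet, j: int) -> NetworkMatrix:
    """Scatter column j of the mixing matrix to a symmetric region matrix."""
    if not (0 <= j < C.nic):
        raise IndexError(f"component index {j} out of range [0, {C.nic})")
    nn = len(C.region_labels)
    return NetworkMatrix(
        weights=unvectorise(C.A[:, j], nn),
        component_id=j,
        region_labels=list(C.region_labels),
    )


def threshold_network(
    M: NetworkMatrix,
    fraction: float = 0.7,
) -> list[tuple[int, int, float]]:
    """Edges with |weight| >= fraction * max |weight|, strongest first.

    Returns ``(region_j, region_k, weight)`` triples over the strict upper
    triangle; an all-zero matrix yields an empty list.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    W = M.weights
    nn = W.shape[0]
    iu = np.triu_indices(nn, k=1)
    vals = W[iu]
    vmax = np.abs(vals).max() if vals.size else 0.0
    if vmax == 0:
        return []
    keep = np.abs(vals) >= fraction * vmax
    edges = [
        (int(j), int(k), float(v))
        for j, k, v in zip(iu[0][keep], iu[1][keep], vals[keep])
    ]
    edges.sort(key=lambda e: -abs(e[2]))
    return edges
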