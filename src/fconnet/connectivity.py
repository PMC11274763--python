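"""Connectivity matrices and proportional-threshold binarization.

A subject's functional connectivity matrix is the Pearson correlation
between every pair of ROI time series, Fisher z-transformed (atanh), with a
zero diagonal. Binary graphs are obtained by proportional (sparsity)
thresholding: at sparsity ``s`` exactly ``round(s * N(N-1)/2)`` of the
strongest edges are kept, so every subject's graph has the identical edge
count at a given sparsity level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import SubjectTimeSeries

#: r values are clipped to +/- (1 - R_CLIP) before atanh so z stays finite.
R_CLIP = 1e-7


class ConnectivityError(ValueError):
    pass


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N Fisher-z correlation matrix with zero diagonal."""

    values: np.ndarray = field(repr=False)
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectivityError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ConnectivityError("connectivity matrix has non-finite entries")
        if not np.allclose(v, v.T):
            raise ConnectivityError("connectivity matrix must be symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ConnectivityError("connectivity matrix diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def mean_connectivity(self) -> float:
        """Mean upper-triangle Fisher-z value (whole-brain average FC)."""
        iu = np.triu_indices(self.n_rois, k=1)
        return float(self.values[iu].mean())


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected binary adjacency at one sparsity level."""

    adjacency: np.ndarray = field(repr=False)
    sparsity: float = 0.0
    subject_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class SparsityGrid:
    """Strictly increasing sparsity thresholds, all in (0, 1)."""

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0:
            raise ConnectivityError("sparsity grid is empty")
        if np.any(t <= 0) or np.any(t >= 1):
            raise ConnectivityError("sparsity thresholds must lie in (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise ConnectivityError("sparsity thresholds must be strictly increasing")

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


def default_sparsity_grid() -> SparsityGrid:
    """The standard grid: 0.10 to 0.50 in steps of 0.05 (9 levels)."""
    return SparsityGrid(tuple(np.round(np.arange(0.10, 0.501, 0.05), 2)))


def pearson_matrix(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Fisher-z Pearson connectivity matrix of one subject's time series.

    Raises
    ------
    ConnectivityError
        If T < 3 or any ROI column is constant (named in the message).
    """
    x = np.asarray(ts.data, dtype=float)
    if x.shape[0] < 3:
        raise ConnectivityError(
            f"subject {ts.subject_id}: need T >= 3 timepoints, got {x.shape[0]}"
        )
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ConnectivityError(
            f"subject {ts.subject_id}: constant time series in ROI column(s) "
            f"{dead.tolist()}"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0 + R_CLIP, 1.0 - R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp asymmetry
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, subject_id=ts.subject_id, group=ts.group)


def edge_order(cm: ConnectivityMatrix, edge_rank: str = "signed") -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge indices sorted strongest-first.

    ``edge_rank='signed'`` ranks by signed Fisher z (strongest positive
    first, the common proportional-thresholding practice);
    ``'absolute'`` ranks by |z|. Ties are broken by lexicographic (i, j)
    order, making nested thresholds exactly nested.
    """
    if edge_rank not in ("signed", "absolute"):
        raise ConnectivityError(f"edge_rank must be 'signed' or 'absolute', got {edge_rank!r}")
    n = cm.n_rois
    iu, ju = np.triu_indices(n, k=1)
    w = cm.values[iu, ju]
    if edge_rank == "absolute":
        w = np.abs(w)
    # primary key: -w (descending); then i, then j ascending
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def binarize_at_sparsity(
    cm: ConnectivityMatrix, s: float, edge_rank: str = "signed"
) -> BinaryGraph:
    """Binary graph keeping the ``round(s * N(N-1)/2)`` strongest edges."""
    if not (0.0 < s < 1.0):
        raise ConnectivityError(f"sparsity must lie in (0, 1), got {s}")
    n = cm.n_rois
    m = int(np.rint(s * n * (n - 1) / 2))
    if m == 0:
        raise ConnectivityError(
            f"sparsity {s} yields 0 edges for {n} nodes; increase s"
        )
    oi, oj = edge_order(cm, edge_rank)
    a = np.zeros((n, n), dtype=np.uint8)
    a[oi[:m], oj[:m]] = 1
    a |= a.T
    return BinaryGraph(a, sparsity=float(s), subject_id=cm.subject_id)


def binarize_over_grid(
    cm: ConnectivityMatrix, grid: SparsityGrid, edge_rank: str = "signed"
) -> list[BinaryGraph]:
    """Binary graphs at every grid level, sharing one edge ordering (so the
    edge sets are exactly nested across levels)."""
    n = cm.n_rois
    oi, oj = edge_order(cm, edge_rank)
    out = []
    for s in grid:
        m = int(np.rint(s * n * (n - 1) / 2))
        if m == 0:
            raise ConnectivityError(f"sparsity {s} yields 0 edges for {n} nodes")
        a = np.zeros((n, n), dtype=np.uint8)
        a[oi[:m], oj[:m]] = 1
        a |= a.T
        out.append(BinaryGraph(a, sparsity=float(s), subject_id=cm.subject_id))
    return out
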