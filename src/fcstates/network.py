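"""Functional-connectome construction from ROI time series.

A subject-session's connectome is built in three steps: pairwise Pearson
correlation of the region-averaged BOLD-like signals, Fisher z
(variance-stabilising arctanh) transform of the off-diagonal entries with
self-connections removed, and binarisation keeping only strictly positive
weights.  Group-level sparsity is summarised by the frequency connection
matrix: the per-edge count of subjects whose binarised network contains
that edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "WeightedConnectome",
    "BinaryConnectome",
    "FrequencyMatrix",
    "compute_fc",
    "fisher_z",
    "binarize_positive",
    "frequency_matrix",
    "count_unconnected_edges",
]


def _default_labels(r: int) -> list[str]:
    return [f"ROI{i + 1:03d}" for i in range(r)]


@dataclass
class RoiTimeSeries:
    """One subject-session's T x R matrix of region-averaged signals."""

    subject_id: str
    group: str  # NC | IBSbs | IBS1st
    session: str  # single | baseline | post
    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D T x R matrix")
        t, r = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 time points, got {t}")
        if r < 2:
            raise ValueError(f"need at least 2 ROIs, got {r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if not self.roi_labels:
            self.roi_labels = _default_labels(r)
        if len(self.roi_labels) != r:
            raise ValueError("roi_labels length does not match column count")
        if len(set(self.roi_labels)) != r:
            raise ValueError("roi_labels must be unique")

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class WeightedConnectome:
    """Symmetric R x R Fisher-z weight matrix with zeroed diagonal."""

    z_weights: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""
    group: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z_weights, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_weights must be square")
        if not np.allclose(z, z.T):
            raise ValueError("z_weights must be symmetric")
        if np.any(np.diag(z) != 0):
            raise ValueError("diagonal must be exactly 0 (self-connections removed)")
        if not np.all(np.isfinite(z)):
            raise ValueError("z_weights must be finite")
        self.z_weights = z

    def edge_weight(self, label_i: str, label_j: str) -> float:
        i = self.roi_labels.index(label_i)
        j = self.roi_labels.index(label_j)
        return float(self.z_weights[i, j])


@dataclass
class BinaryConnectome:
    """Undirected binary adjacency matrix over the atlas ROIs."""

    adjacency: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""
    group: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be 0")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class FrequencyMatrix:
    """Per-edge count of subjects possessing the binarised edge."""

    counts: np.ndarray
    n_subjects: int
    roi_labels: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(c < 0) or np.any(c > self.n_subjects):
            raise ValueError("counts must lie in [0, n_subjects]")
        if np.any(np.diag(c) != 0):
            raise ValueError("diagonal must be 0")
        self.counts = c.astype(int)


def compute_fc(ts: RoiTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlation matrix of the ROI time series.

    Columns with zero variance cannot be correlated; their rows/columns are
    set to 0 (diagonal kept at 1) and a warning is emitted, so downstream
    binarisation stays total.
    """
    x = ts.values
    sd = x.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance ROI column(s); "
            "their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    # guard against floating-point excursions beyond +/-1
    return np.clip(r, -1.0, 1.0)


def fisher_z(r_matrix: np.ndarray, roi_labels: Sequence[str] | None = None,
             **meta: str) -> WeightedConnectome:
    """Fisher z transform (arctanh) of a correlation matrix.

    The diagonal is forced to 0 — self-connections are removed before the
    transform — and an off-diagonal correlation of exactly +/-1 is an error
    rather than an infinite weight.
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) == 1.0):
        raise ValueError("off-diagonal correlation of magnitude 1: Fisher z undefined")
    z = np.arctanh(np.where(off, r, 0.0))
    z = (z + z.T) / 2.0
    labels = list(roi_labels) if roi_labels is not None else _default_labels(r.shape[0])
    return WeightedConnectome(z_weights=z, roi_labels=labels, **meta)


def binarize_positive(w: WeightedConnectome) -> BinaryConnectome:
    """Keep strictly positive weights as edges: a_ij = 1 iff z_ij > 0."""
    a = (w.z_weights > 0).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryConnectome(
        adjacency=a,
        roi_labels=list(w.roi_labels),
        subject_id=w.subject_id,
        group=w.group,
        session=w.session,
    )


def frequency_matrix(nets: Sequence[BinaryConnectome]) -> FrequencyMatrix:
    """Element-wise sum of binarised adjacencies across subjects."""
    if not nets:
        raise ValueError("need at least one network")
    labels = nets[0].roi_labels
    for net in nets[1:]:
        if net.roi_labels != labels:
            raise ValueError("all networks must share the same ROI labels")
    counts = np.sum([net.adjacency.astype(int) for net in nets], axis=0)
    return FrequencyMatrix(counts=counts, n_subjects=len(nets), roi_labels=list(labels))


def count_unconnected_edges(f: FrequencyMatrix,
                            roi_subset: Sequence[str] | None = None) -> int:
    """Number of unordered ROI pairs with zero subjects carrying the edge.

    With ``roi_subset`` the scan is restricted to pairs within that subset
    (e.g. the cerebellar block of the atlas).
    """
    if roi_subset is None:
        idx = np.arange(len(f.roi_labels))
    else:
        missing = set(roi_subset) - set(f.roi_labels)
        if missing:
            raise KeyError(f"unknown ROI label(s): {sorted(missing)}")
        idx = np.array([f.roi_labels.index(l) for l in roi_subset])
    sub = f.counts[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return int(np.sum(sub[iu] == 0))
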