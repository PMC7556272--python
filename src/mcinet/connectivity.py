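"""Functional connectivity matrices and sparsity thresholding.

The FC between two ROIs is the absolute Pearson correlation of their time
series; the N x N matrix of all pairs (diagonal forced to 0) defines a
fully connected weighted undirected network per subject.  Group-level
networks are element-wise means of the individual matrices.  Networks are
sparsified by keeping the K strongest edges, K = round(s * N(N-1)/2) for a
target sparsity s; the analysis grid spans 5-50% in 1% steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class FCMatrix:
    """Symmetric absolute-correlation matrix with zero diagonal."""

    values: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("FC matrix must be square")
        if len(self.roi_names) != n:
            raise ValueError("roi_names length mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("FC diagonal must be 0")
        off = self.values[np.triu_indices(n, 1)]
        if off.size and (off.min() < 0.0 or off.max() > 1.0):
            raise ValueError("FC entries must lie in [0, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class ThresholdedNetwork:
    """Weighted undirected network retained at a given sparsity."""

    adjacency: np.ndarray
    sparsity: float
    retained_edges: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, w) arrays over retained upper-triangle edges, i < j."""
        iu, ju = np.triu_indices(self.n_nodes, 1)
        mask = self.adjacency[iu, ju] > 0
        return iu[mask], ju[mask], self.adjacency[iu, ju][mask]


def compute_fc(timeseries: np.ndarray, roi_names: list[str] | None = None) -> FCMatrix:
    """Absolute Pearson correlation of ROI time series, diagonal zeroed.

    A zero-variance ROI is degenerate, not fatal: its correlations are set
    to 0 with a warning.  NaN input is an error.
    """
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("timeseries must be T x N with T >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("timeseries contains non-finite values")
    sd = x.std(axis=0)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        warnings.warn(f"{flat.size} zero-variance ROI(s); their FC set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    w = np.abs(r)
    w[~np.isfinite(w)] = 0.0
    w[flat, :] = 0.0
    w[:, flat] = 0.0
    np.clip(w, 0.0, 1.0, out=w)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    names = roi_names if roi_names is not None else [f"ROI{i + 1:03d}" for i in range(x.shape[1])]
    return FCMatrix(values=w, roi_names=list(names))


def group_mean_network(fcs: list[FCMatrix]) -> FCMatrix:
    """Element-wise mean of individual FC matrices (connectivity backbone)."""
    if not fcs:
        raise ValueError("empty FC list")
    names = fcs[0].roi_names
    for fc in fcs[1:]:
        if fc.values.shape != fcs[0].values.shape or fc.roi_names != names:
            raise ValueError("FC matrices differ in dimension or ROI names")
    mean = np.mean([fc.values for fc in fcs], axis=0)
    np.fill_diagonal(mean, 0.0)
    return FCMatrix(values=mean, roi_names=list(names))


def edge_count_for_sparsity(n_rois: int, sparsity: float) -> int:
    """K = round(s * n(n-1)/2), half-to-even rounding."""
    if not (0.0 < sparsity <= 1.0):
        raise ValueError("sparsity must lie in (0, 1]")
    return round(sparsity * n_rois * (n_rois - 1) / 2)


def threshold_by_sparsity(fc: FCMatrix, sparsity: float) -> ThresholdedNetwork:
    """Keep the K strongest edges with their original weights.

    Ties at the cutoff are broken by ascending (i, j) lexicographic order,
    which makes edge sets nest monotonically in sparsity.
    """
    n = fc.n_rois
    k = edge_count_for_sparsity(n, sparsity)
    if k == 0:
        raise ValueError(f"sparsity {sparsity} retains no edges for N={n}")
    iu, ju = np.triu_indices(n, 1)
    w = fc.values[iu, ju]
    # primary key: descending weight; ties: ascending i then j
    order = np.lexsort((ju, iu, -w))[:k]
    adj = np.zeros_like(fc.values)
    adj[iu[order], ju[order]] = w[order]
    adj += adj.T
    return ThresholdedNetwork(adjacency=adj, sparsity=float(sparsity), retained_edges=k)


def sparsity_grid() -> np.ndarray:
    """The 46-point analysis grid: 5% to 50% in 1% steps."""
    return np.round(np.arange(5, 51) / 100.0, 2)


def isolated_fraction(net: ThresholdedNetwork) -> float:
    """Fraction of zero-degree (disconnected) nodes."""
    degree = (net.adjacency > 0).sum(axis=1)
    return float((degree == 0).mean())


# --- I/O ------------------------------------------------------------------


def read_timeseries(path: str | Path, sep: str = "\t") -> tuple[np.ndarray, list[str]]:
    """Read a T x N delimited matrix with an ROI-name header row."""
    df = pd.read_csv(path, sep=sep)
    return df.to_numpy(dtype=float), list(df.columns)


def write_matrix_csv(values: np.ndarray, roi_names: list[str], path: str | Path) -> None:
    pd.DataFrame(values, index=roi_names, columns=roi_names).to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def write_matrix_mtx(values: np.ndarray, path: str | Path) -> None:
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(values))


def read_matrix_mtx(path: str | Path) -> np.ndarray:
    return np.asarray(scipy.io.mmread(str(path)).todense(), dtype=float)
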