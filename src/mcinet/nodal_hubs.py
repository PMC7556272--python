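"""Scale-II nodal betweenness centrality and hub detection.

Betweenness is computed on weighted shortest paths (edge length 1/w,
Brandes accumulation, unordered-pair convention with endpoints excluded),
normalized by its network mean (BC_i = bc_i / <bc>), and nodes with
BC > 2.5 are flagged as hubs.  Hub stability is summarized across the
sparsity grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .connectivity import FCMatrix, ThresholdedNetwork, threshold_by_sparsity

HUB_THRESHOLD = 2.5


@dataclass
class NodalCentrality:
    bc: np.ndarray
    BC: np.ndarray
    hub_flags: np.ndarray
    sparsity: float


def betweenness(net: ThresholdedNetwork) -> np.ndarray:
    """Weighted betweenness of every node (raw, unordered-pair counts).

    Equal-length shortest paths are counted with multiplicity via Brandes
    fractional accumulation (delegated to igraph's C implementation).
    """
    i, j, w = net.edge_list()
    g = ig.Graph(n=net.n_nodes, edges=list(zip(i.tolist(), j.tolist())), directed=False)
    if g.ecount() == 0:
        return np.zeros(net.n_nodes)
    return np.asarray(g.betweenness(weights=(1.0 / w).tolist()), dtype=float)


def normalize_bc(bc: np.ndarray) -> np.ndarray:
    """BC = bc / mean(bc); the mean of BC is exactly 1."""
    bc = np.asarray(bc, dtype=float)
    m = bc.mean()
    if m <= 0:
        raise ValueError("all-zero betweenness: no intermediate paths")
    return bc / m


def identify_hubs(BC: np.ndarray, threshold: float = HUB_THRESHOLD) -> np.ndarray:
    """Indices with BC strictly greater than the threshold."""
    return np.flatnonzero(np.asarray(BC) > threshold)


def nodal_centrality(net: ThresholdedNetwork, threshold: float = HUB_THRESHOLD) -> NodalCentrality:
    bc = betweenness(net)
    BC = normalize_bc(bc)
    flags = BC > threshold
    return NodalCentrality(bc=bc, BC=BC, hub_flags=flags, sparsity=net.sparsity)


def hub_stability(
    fc: FCMatrix, grid: np.ndarray, threshold: float = HUB_THRESHOLD
) -> pd.DataFrame:
    """ROI x sparsity boolean hub table over the grid.

    A "stable hub" summary (hub at >= x% of sparsities) is a row mean of
    this table.
    """
    cols = {}
    for s in np.asarray(grid, dtype=float):
        net = threshold_by_sparsity(fc, s)
        try:
            cent = nodal_centrality(net, threshold=threshold)
            flags = cent.hub_flags
        except ValueError:  # no paths at all at this sparsity
            flags = np.zeros(fc.n_rois, dtype=bool)
        cols[float(s)] = flags
    return pd.DataFrame(cols, index=fc.roi_names)


def hub_table_long(stability: pd.DataFrame) -> pd.DataFrame:
    """Long-format (roi, sparsity, hub_flag) view of a stability table."""
    long = stability.rename_axis("roi").reset_index().melt(
        id_vars="roi", var_name="sparsity", value_name="hub_flag"
    )
    return long.sort_values(["roi", "sparsity"]).reset_index(drop=True)
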