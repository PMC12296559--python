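"""Top-fraction voxel selection and DBSCAN source-space clustering.

The strongest voxels of a source map (top 1 % by default) within anatomically
labelled, non-excluded regions are clustered with DBSCAN.  With
``min_points = 2`` DBSCAN reduces to the connected components of the
eps-neighborhood graph, with singletons labelled noise; an eps of 1.5x the
grid spacing connects face-, edge- and corner-diagonal lattice neighbors but
not two-step axial neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .headmodel import SourceGrid
from .source_dics import SourcePowerMap

__all__ = ["ClusterSet", "select_top_voxels", "dbscan_clusters"]

NOISE = -1


@dataclass(frozen=True)
class ClusterSet:
    """DBSCAN partition of selected source voxels.

    ``labels[i]`` is the cluster id of ``voxel_indices[i]`` (-1 = noise).
    """

    voxel_indices: np.ndarray
    points: np.ndarray
    labels: np.ndarray
    eps: float
    min_points: int
    region_labels: np.ndarray | None = None

    @property
    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != NOISE]

    def members(self, cluster_id: int) -> np.ndarray:
        """Grid voxel indices belonging to one cluster."""
        return self.voxel_indices[self.labels == cluster_id]

    def summary(self, values: np.ndarray | None = None) -> pd.DataFrame:
        """Per-cluster size, centroid, dominant region label, mean value."""
        rows = []
        for cid in self.cluster_ids:
            m = self.labels == cid
            row = {
                "cluster": int(cid),
                "n_voxels": int(m.sum()),
                "centroid_x": self.points[m, 0].mean(),
                "centroid_y": self.points[m, 1].mean(),
                "centroid_z": self.points[m, 2].mean(),
            }
            if self.region_labels is not None:
                labs, counts = np.unique(self.region_labels[m], return_counts=True)
                row["dominant_label"] = labs[counts.argmax()]
            if values is not None:
                row["mean_value"] = float(np.mean(values[m]))
            rows.append(row)
        return pd.DataFrame(rows)


def select_top_voxels(
    source_map: SourcePowerMap,
    region_labels: np.ndarray,
    fraction: float = 0.01,
    exclude_labels=(),
    mode: str | None = None,
) -> np.ndarray:
    """Indices of the top-``fraction`` voxels among eligible labelled voxels.

    Voxels whose region label is empty or in ``exclude_labels`` are
    ineligible.  ``mode="signed"`` (default for power maps) ranks by value
    and keeps ceil(fraction * n_eligible) voxels; ``mode="two_sided"``
    (default for ratio maps) ranks by magnitude separately within the
    positive and the negative side, keeping ceil(fraction * side count) per
    side.  Ties break by voxel order, which is deterministic.
    """
    labels = np.asarray(region_labels)
    values = source_map.values
    if labels.shape[0] != values.shape[0]:
        raise ValueError("one region label per voxel required")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if mode is None:
        mode = "two_sided" if source_map.kind == "ratio" else "signed"
    excluded = set(exclude_labels)
    eligible = np.array([bool(l) and l not in excluded for l in labels])
    idx = np.where(eligible)[0]
    if idx.size == 0:
        raise ValueError("no eligible voxels after label exclusion")

    def top_k(candidates, keys, k):
        # stable sort descending by key, ties by voxel order
        order = np.argsort(-keys, kind="stable")
        return candidates[order[:k]]

    if mode == "signed":
        k = int(np.ceil(fraction * idx.size))
        sel = top_k(idx, values[idx], k)
    elif mode == "two_sided":
        parts = []
        for side in (values[idx] > 0, values[idx] < 0):
            cand = idx[side]
            if cand.size:
                k = int(np.ceil(fraction * cand.size))
                parts.append(top_k(cand, np.abs(values[cand]), k))
        if not parts:
            raise ValueError("map is identically zero; nothing to select")
        sel = np.concatenate(parts)
    else:
        raise ValueError("mode must be 'signed' or 'two_sided'")
    return np.sort(sel)


def dbscan_clusters(
    voxel_indices: np.ndarray,
    grid: SourceGrid,
    eps: float | None = None,
    eps_factor: float = 1.5,
    min_points: int = 2,
) -> ClusterSet:
    """Cluster selected voxels with DBSCAN (Euclidean metric).

    ``eps`` defaults to ``eps_factor`` times the grid spacing.
    """
    if eps is None:
        eps = eps_factor * grid.spacing
    if eps <= 0:
        raise ValueError("eps must be positive")
    vox = np.asarray(voxel_indices, dtype=int)
    pts = grid.positions[vox]
    if vox.size == 0:
        labels = np.array([], dtype=int)
    else:
        labels = DBSCAN(eps=eps, min_samples=min_points).fit(pts).labels_
    region = grid.region_labels[vox] if grid.region_labels is not None else None
    return ClusterSet(vox, pts, labels, float(eps), int(min_points), region)
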