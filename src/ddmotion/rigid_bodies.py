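"""Rigid-body identification by hierarchical clustering of helix segments.

Two segments that keep their mutual Cα distances through a conformational
change have a small inter-segment RMSDD; using the hb-DDM as a distance
matrix, average-linkage (UPGMA) clustering therefore groups segments that
move as one rigid body during that transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ddm import HbDDM

__all__ = ["HelixLinkage", "cluster_helices", "flat_clusters"]


@dataclass(frozen=True)
class HelixLinkage:
    """UPGMA merge tree over helix segments.

    ``linkage`` is a scipy-format (k−1)×4 matrix: merged node indices, merge
    height in Å, and resulting cluster size per step.
    """

    segment_labels: tuple[str, ...]
    linkage: np.ndarray
    method: str = "average"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        """Leaf ordering used by dendrograms/clustermaps."""
        order = hierarchy.leaves_list(self.linkage)
        return [self.segment_labels[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (step, int(a), int(b), float(h), int(size))
            for step, (a, b, h, size) in enumerate(self.linkage)
        ]
        return pd.DataFrame(rows, columns=["step", "left", "right", "height", "size"])


def cluster_helices(hbddm: HbDDM, method: str = "average") -> HelixLinkage:
    """Hierarchical clustering of segments with the hb-DDM as distances.

    Diagonal entries (intrasegment flexing) are set to zero first so the
    matrix is a proper dissimilarity; linkage is UPGMA by default.
    """
    values = np.array(hbddm.values, dtype=float)
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("hb-DDM must be symmetric (within 1e-9) for clustering")
    np.fill_diagonal(values, 0.0)
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return HelixLinkage(hbddm.segment_labels, Z, method)


def flat_clusters(linkage: HelixLinkage, cut_height: float) -> dict[str, int]:
    """Cut the merge tree at a height and return segment → cluster label.

    Segments merged at height ≤ ``cut_height`` share a cluster.  Labels are
    renumbered by first appearance in segment order (stable across
    permutations of the input segments).
    """
    if cut_height < 0:
        raise ValueError("cut_height must be ≥ 0")
    raw = hierarchy.fcluster(linkage.linkage, t=cut_height, criterion="distance")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, cluster in zip(linkage.segment_labels, raw):
        if cluster not in remap:
            remap[cluster] = len(remap)
        out[label] = remap[cluster]
    return out
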