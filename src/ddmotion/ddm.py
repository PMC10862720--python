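"""Distance matrices, distance difference matrices (DDMs), and their
helix-restricted and helix-binned summaries.

A DDM compares two conformations of the same protein through their internal
Cα–Cα distances only, so it is independent of any superposition choice.  For
an A→B comparison the entries are ``d_ij(B) − d_ij(A)``: positive where two
residues move apart, negative where they approach.  Binning the DDM per pair
of helix segments into root-mean-squared distance differences (RMSDDs)
yields a fixed-size fingerprint (14×14 for the LeuT-fold core) that can be
compared across distant homologs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .structures import CaTrace, SegmentationScheme

__all__ = [
    "DistanceMatrix",
    "DDM",
    "HbDDM",
    "distance_matrix",
    "compute_ddm",
    "ho_ddm",
    "hb_ddm",
    "intra_vs_inter_summary",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric matrix of Cα–Cα Euclidean distances in Å."""

    residue_numbers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        nums = np.asarray(self.residue_numbers, dtype=int)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(nums), len(nums)):
            raise ValueError("values must be square and match the labels")
        object.__setattr__(self, "residue_numbers", nums)
        object.__setattr__(self, "values", vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.residue_numbers,
                            columns=self.residue_numbers)


@dataclass(frozen=True)
class DDM:
    """Distance difference matrix ``d_ij(B) − d_ij(A)`` for an A→B comparison.

    ``residue_numbers`` are the residues resolved in both structures;
    ``direction`` records the ordered (A, B) structure identifiers.
    """

    residue_numbers: np.ndarray
    values: np.ndarray
    direction: tuple[str, str]
    segment_boundaries: tuple[tuple[str, int, int], ...] = ()
    # (label, first_index, last_index) into residue_numbers, for rendering
    # the black segment-boundary lines on helix-only DDM heatmaps

    def __post_init__(self) -> None:
        nums = np.asarray(self.residue_numbers, dtype=int)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(nums), len(nums)):
            raise ValueError("values must be square and match the labels")
        object.__setattr__(self, "residue_numbers", nums)
        object.__setattr__(self, "values", vals)

    def reversed(self) -> "DDM":
        """The B→A comparison: elementwise negation."""
        return DDM(self.residue_numbers.copy(), -self.values,
                   (self.direction[1], self.direction[0]),
                   self.segment_boundaries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.residue_numbers,
                            columns=self.residue_numbers)


@dataclass(frozen=True)
class HbDDM:
    """Helix-binned DDM: per segment pair, the RMSDD in Å.

    Symmetric and nonnegative; the diagonal holds intrasegment RMSDDs
    (helix flexing) and is *not* forced to zero.
    """

    segment_labels: tuple[str, ...]
    values: np.ndarray
    direction: tuple[str, str]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        k = len(self.segment_labels)
        if vals.shape != (k, k):
            raise ValueError("values must be square and match segment_labels")
        object.__setattr__(self, "segment_labels", tuple(self.segment_labels))
        object.__setattr__(self, "values", vals)

    @property
    def k(self) -> int:
        return len(self.segment_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.segment_labels),
                            columns=list(self.segment_labels))

    def to_long(self, comparison_id: str | None = None) -> pd.DataFrame:
        """Long-format table (comparison, h1, h2, rmsdd), upper triangle incl. diagonal."""
        cid = comparison_id or "{}->{}".format(*self.direction)
        rows = []
        for i, h1 in enumerate(self.segment_labels):
            for j in range(i, self.k):
                rows.append((cid, h1, self.segment_labels[j], self.values[i, j]))
        return pd.DataFrame(rows, columns=["comparison", "h1", "h2", "rmsdd"])


def distance_matrix(trace: CaTrace) -> DistanceMatrix:
    """All pairwise Cα–Cα Euclidean distances of one trace."""
    values = squareform(pdist(trace.coords)) if len(trace) > 1 else np.zeros((1, 1))
    return DistanceMatrix(trace.residue_numbers, values)


def _common_residues(trace_a: CaTrace, trace_b: CaTrace) -> np.ndarray:
    common = np.intersect1d(trace_a.residue_numbers, trace_b.residue_numbers)
    if len(common) < 2:
        raise ValueError(
            "fewer than 2 residues in common: "
            f"{trace_a.structure_id} spans "
            f"{trace_a.residue_numbers[0]}..{trace_a.residue_numbers[-1]}, "
            f"{trace_b.structure_id} spans "
            f"{trace_b.residue_numbers[0]}..{trace_b.residue_numbers[-1]}"
        )
    return common


def compute_ddm(trace_a: CaTrace, trace_b: CaTrace) -> DDM:
    """DDM of an A→B comparison on the residues resolved in both traces.

    Residues are matched by author residue number; both traces must belong
    to the same protein (supply an explicit mapping upstream for orthologs).
    """
    if trace_a.protein_id != trace_b.protein_id:
        raise ValueError(
            f"traces are from different proteins ({trace_a.protein_id!r} vs "
            f"{trace_b.protein_id!r}); DDMs compare conformations of one "
            "protein — remap residue numbers explicitly to compare orthologs"
        )
    common = _common_residues(trace_a, trace_b)
    sub_a = trace_a.subset(common)
    sub_b = trace_b.subset(common)
    dm_a = distance_matrix(sub_a).values
    dm_b = distance_matrix(sub_b).values
    return DDM(common, dm_b - dm_a, (trace_a.structure_id, trace_b.structure_id))


def ho_ddm(ddm: DDM, scheme: SegmentationScheme) -> DDM:
    """Helix-only DDM: drop rows/columns outside every segment.

    Segment boundary positions (index ranges into the retained residues)
    are recorded for drawing boundary lines on heatmaps.
    """
    keep = np.zeros(len(ddm.residue_numbers), dtype=bool)
    for seg in scheme.segments:
        keep |= (ddm.residue_numbers >= seg.start) & (ddm.residue_numbers <= seg.end)
    if not keep.any():
        raise ValueError(
            f"scheme for {scheme.protein_id} covers none of the DDM residues"
        )
    numbers = ddm.residue_numbers[keep]
    values = ddm.values[np.ix_(keep, keep)]
    boundaries = []
    for seg in scheme.segments:
        idx = np.nonzero((numbers >= seg.start) & (numbers <= seg.end))[0]
        if len(idx):
            boundaries.append((seg.label, int(idx[0]), int(idx[-1])))
    return DDM(numbers, values, ddm.direction, tuple(boundaries))


def hb_ddm(ddm: DDM, scheme: SegmentationScheme) -> HbDDM:
    """Helix-binned DDM of segment-pair RMSDDs.

    For segments h1, h2 with N = |h1|·|h2| resolved residue pairs::

        RMSDD(h1, h2) = sqrt( (1/N) · Σ_{i∈h1} Σ_{j∈h2} (d_ij(B) − d_ij(A))² )

    N always counts residues actually present in the DDM, so partially
    resolved helices are averaged over what was compared.
    """
    members: list[np.ndarray] = []
    for seg in scheme.segments:
        idx = np.nonzero(
            (ddm.residue_numbers >= seg.start) & (ddm.residue_numbers <= seg.end)
        )[0]
        if len(idx) == 0:
            raise ValueError(
                f"segment {seg.label} [{seg.start},{seg.end}] has no resolved "
                f"residues in the {ddm.direction[0]}→{ddm.direction[1]} DDM"
            )
        members.append(idx)
    k = len(members)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            block = ddm.values[np.ix_(members[i], members[j])]
            out[i, j] = out[j, i] = float(np.sqrt(np.mean(block ** 2)))
    return HbDDM(scheme.labels, out, ddm.direction)


def intra_vs_inter_summary(hbddms: Iterable[HbDDM], *, ddof: int = 0) -> dict:
    """Pool intrasegment (diagonal) vs intersegment (unique off-diagonal)
    RMSDDs across a set of hb-DDMs and summarize each pool.

    Returns a dict with means and standard deviations (population SD by
    default; ``ddof`` recorded in the output).
    """
    diag: list[float] = []
    off: list[float] = []
    n_matrices = 0
    for m in hbddms:
        n_matrices += 1
        diag.extend(np.diag(m.values))
        iu = np.triu_indices(m.k, k=1)
        off.extend(m.values[iu])
    if n_matrices == 0:
        raise ValueError("need at least one hb-DDM")
    diag_a = np.asarray(diag)
    off_a = np.asarray(off)
    return {
        "intra_mean": float(diag_a.mean()),
        "intra_sd": float(diag_a.std(ddof=ddof)),
        "inter_mean": float(off_a.mean()),
        "inter_sd": float(off_a.std(ddof=ddof)),
        "n_matrices": n_matrices,
        "n_intra": len(diag_a),
        "n_inter": len(off_a),
        "sd_ddof": ddof,
    }
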