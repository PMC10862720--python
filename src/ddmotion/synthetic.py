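"""Ground-truth synthetic inputs for the whole pipeline.

Three generators: ideal α-helical Cα traces arranged into multi-segment toy
proteins; programmed rigid-body motions of chosen segment subsets (so the
"true" rotation angles and rigid bodies are known exactly); and hb-DDM
datasets built as nonnegative mixtures of known sparse components plus
noise (so decomposition recovery can be scored against ground truth).

These fixtures have no physical realism beyond Cα geometry — no side
chains, no packing energetics, no membrane — but they exercise every
downstream operation through its real input path, including minimal PDB
round trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ddm import HbDDM
from .structures import CaTrace, SegmentationScheme

__all__ = [
    "IDEAL_HELIX_RADIUS",
    "IDEAL_HELIX_RISE",
    "IDEAL_HELIX_TWIST_DEG",
    "Move",
    "MotionScript",
    "make_ideal_helix",
    "default_scheme",
    "make_toy_protein",
    "apply_motion",
    "make_sparse_components",
    "make_hbddm_dataset",
]

# Textbook α-helix Cα parameters: ~3.6 residues/turn (100° twist),
# 1.5 Å rise per residue, 2.3 Å helix radius → consecutive Cα ≈ 3.8 Å.
IDEAL_HELIX_RADIUS = 2.3
IDEAL_HELIX_RISE = 1.5
IDEAL_HELIX_TWIST_DEG = 100.0


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if abs(n - 1.0) > 1e-9:
        raise ValueError("rotation axis must have unit norm")
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    t = np.radians(angle_deg)
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _frame_for_axis(axis: np.ndarray) -> np.ndarray:
    """Rotation taking the z axis onto ``axis`` (columns: new x, y, z)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if abs(n - 1.0) > 1e-9:
        raise ValueError("helix axis must have unit norm")
    z = axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(z @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def make_ideal_helix(
    n_residues: int,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    *,
    start_residue: int = 1,
    radius: float = IDEAL_HELIX_RADIUS,
    rise: float = IDEAL_HELIX_RISE,
    twist_deg: float = IDEAL_HELIX_TWIST_DEG,
    phase_deg: float = 0.0,
    protein_id: str = "toy",
    structure_id: str = "SYN1",
    chain_id: str = "A",
) -> CaTrace:
    """Cα trace of an ideal α-helix along ``axis`` starting at ``origin``.

    Residue ``i`` sits at angle ``phase + i·twist`` on a cylinder of the
    given radius, ``i·rise`` along the axis.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be ≥ 1")
    i = np.arange(n_residues)
    angles = np.radians(phase_deg + i * twist_deg)
    local = np.column_stack([
        radius * np.cos(angles),
        radius * np.sin(angles),
        rise * i,
    ])
    frame = _frame_for_axis(np.asarray(axis, dtype=float))
    coords = local @ frame.T + np.asarray(origin, dtype=float)
    return CaTrace(
        protein_id, structure_id, chain_id,
        np.arange(start_residue, start_residue + n_residues),
        coords,
    )


def default_scheme(
    per_segment_length: int = 8,
    labels: Sequence[str] | None = None,
    *,
    gap: int = 4,
    protein_id: str = "toy",
) -> SegmentationScheme:
    """A segmentation scheme with contiguous equal-length segments
    separated by short unmodelled linkers (the 14 LeuT-fold labels by
    default)."""
    from .structures import LEUT_FOLD_SEGMENT_LABELS

    labels = list(labels) if labels is not None else list(LEUT_FOLD_SEGMENT_LABELS)
    ranges = []
    start = 1
    for label in labels:
        ranges.append((label, start, start + per_segment_length - 1))
        start += per_segment_length + gap
    return SegmentationScheme.from_ranges(protein_id, ranges)


def make_toy_protein(
    scheme: SegmentationScheme,
    per_segment_length: int | None = None,
    layout: str = "circle",
    *,
    min_separation: float = 6.0,
    structure_id: str = "SYN1",
    chain_id: str = "A",
) -> CaTrace:
    """One ideal helix per scheme segment, placed so segments do not clash.

    Helices run along z; their axes sit on a circle (or square grid) sized
    so every inter-segment Cα distance is at least ``min_separation`` Å.
    Residue numbers follow the scheme ranges; if ``per_segment_length`` is
    given it must not exceed any segment range.
    """
    k = len(scheme)
    # center-to-center spacing that guarantees the Cα clearance
    spacing = min_separation + 2 * IDEAL_HELIX_RADIUS
    if layout == "circle":
        if k == 1:
            centers = np.zeros((1, 2))
        else:
            R = spacing / (2 * np.sin(np.pi / k))
            ang = 2 * np.pi * np.arange(k) / k
            centers = np.column_stack([R * np.cos(ang), R * np.sin(ang)])
    elif layout == "grid":
        side = int(np.ceil(np.sqrt(k)))
        centers = np.array(
            [[spacing * (i % side), spacing * (i // side)] for i in range(k)],
            dtype=float,
        )
    else:
        raise ValueError(f"unknown layout {layout!r}")

    numbers: list[int] = []
    coords: list[np.ndarray] = []
    for seg, (cx, cy) in zip(scheme.segments, centers):
        n = seg.end - seg.start + 1
        if per_segment_length is not None:
            if per_segment_length > n:
                raise ValueError(
                    f"segment {seg.label} holds only {n} residues; "
                    f"cannot place {per_segment_length}"
                )
            n = per_segment_length
        helix = make_ideal_helix(
            n, origin=(cx, cy, 0.0), start_residue=seg.start,
            protein_id=scheme.protein_id, structure_id=structure_id,
            chain_id=chain_id,
        )
        numbers.extend(helix.residue_numbers)
        coords.append(helix.coords)
    trace = CaTrace(
        scheme.protein_id, structure_id, chain_id,
        np.array(numbers), np.vstack(coords),
    )
    _check_separation(trace, scheme, min_separation)
    return trace


def _check_separation(
    trace: CaTrace, scheme: SegmentationScheme, min_separation: float
) -> None:
    from scipy.spatial.distance import cdist

    seg_coords = []
    for seg in scheme.segments:
        mask = (trace.residue_numbers >= seg.start) & (trace.residue_numbers <= seg.end)
        seg_coords.append(trace.coords[mask])
    for i in range(len(seg_coords)):
        for j in range(i + 1, len(seg_coords)):
            d = cdist(seg_coords[i], seg_coords[j]).min()
            if d < min_separation - 1e-9:
                raise ValueError(
                    f"layout violates clash rule: segments "
                    f"{scheme.segments[i].label} and {scheme.segments[j].label} "
                    f"come within {d:.2f} Å (< {min_separation} Å)"
                )


@dataclass(frozen=True)
class Move:
    """Rigid transform of a segment subset: rotation about an axis through
    a pivot, followed by a translation."""

    segment_labels: tuple[str, ...]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0
    pivot: tuple[float, float, float] | None = None  # None → subset centroid
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("move axis must have unit norm")


@dataclass(frozen=True)
class MotionScript:
    """An ordered list of rigid moves applied to disjoint segment subsets."""

    moves: tuple[Move, ...]

    @classmethod
    def single(cls, labels: Sequence[str], **kwargs) -> "MotionScript":
        return cls((Move(tuple(labels), **kwargs),))


def apply_motion(
    trace: CaTrace,
    scheme: SegmentationScheme,
    script: MotionScript | Move,
    *,
    structure_id: str | None = None,
) -> CaTrace:
    """Apply scripted rigid moves to a trace; unlisted residues untouched."""
    moves = (script,) if isinstance(script, Move) else script.moves
    coords = trace.coords.copy()
    for move in moves:
        mask = np.zeros(len(trace), dtype=bool)
        for label in move.segment_labels:
            seg = scheme.segment(label)
            mask |= (trace.residue_numbers >= seg.start) & (
                trace.residue_numbers <= seg.end
            )
        if not mask.any():
            raise ValueError(
                f"move touches no residues (segments {move.segment_labels})"
            )
        pivot = (coords[mask].mean(axis=0) if move.pivot is None
                 else np.asarray(move.pivot, dtype=float))
        R = _rotation_about_axis(np.asarray(move.axis, dtype=float), move.angle_deg)
        coords[mask] = (coords[mask] - pivot) @ R.T + pivot
        coords[mask] += np.asarray(move.translation, dtype=float)
    return CaTrace(
        trace.protein_id,
        structure_id or trace.structure_id + "m",
        trace.chain_id,
        trace.residue_numbers.copy(),
        coords,
    )


def make_sparse_components(
    k: int,
    supports: Sequence[Sequence[tuple[int, int]]],
    magnitude: float = 2.0,
) -> np.ndarray:
    """Symmetric nonnegative k×k components with the given (i, j) supports.

    Each listed cell and its transpose get the magnitude; everything else
    is zero.  Supports of different components should be disjoint for
    recovery experiments.
    """
    comps = np.zeros((len(supports), k, k))
    for c, cells in enumerate(supports):
        for i, j in cells:
            comps[c, i, j] = magnitude
            comps[c, j, i] = magnitude
    return comps


def make_hbddm_dataset(
    components: np.ndarray,
    weights: np.ndarray,
    noise_sd: float = 0.05,
    seed: int = 0,
    *,
    segment_labels: Sequence[str] | None = None,
) -> list[HbDDM]:
    """hb-DDMs as nonnegative mixtures of known components plus noise.

    ``matrix_i = Σ_j weights[i, j] · components[j] + symmetric N(0, σ²)``,
    clipped at zero to stay in the valid RMSDD domain.  Deterministic for a
    fixed seed.
    """
    comps = np.asarray(components, dtype=float)
    W = np.asarray(weights, dtype=float)
    if comps.ndim != 3 or comps.shape[1] != comps.shape[2]:
        raise ValueError("components must have shape (m, k, k)")
    if W.ndim != 2 or W.shape[1] != comps.shape[0]:
        raise ValueError(
            f"weights shape {W.shape} incompatible with {comps.shape[0]} components"
        )
    if np.any(W < 0):
        raise ValueError("mixture weights must be nonnegative")
    k = comps.shape[1]
    labels = (tuple(segment_labels) if segment_labels is not None
              else tuple(f"s{i}" for i in range(k)))
    rng = np.random.default_rng(seed)
    out: list[HbDDM] = []
    for i in range(W.shape[0]):
        m = np.tensordot(W[i], comps, axes=1)
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, size=(k, k))
            m = m + 0.5 * (noise + noise.T)
        m = np.clip(m, 0.0, None)
        out.append(HbDDM(labels, m, (f"synA{i}", f"synB{i}")))
    return out
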