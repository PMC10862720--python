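"""Rigid superposition and rotation-angle geometry.

Superposition-based measurements complement the superposition-free DDMs:
after identifying rigid bodies, fitting one body and measuring the residual
rotation of another quantifies, e.g., how far a helix bundle rocks relative
to the hash scaffold, or how much a predicted membrane plane tilts between
two conformations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import CaTrace, SegmentationScheme, select_segments

__all__ = [
    "SuperpositionResult",
    "MembranePlane",
    "kabsch",
    "superpose",
    "rotation_angle_deg",
    "rigid_body_rotation_angle",
    "plane_normal",
    "membrane_angle",
    "membrane_rotation_workflow",
    "read_membrane_plane",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid fit of a mobile point set onto a reference.

    ``rotation`` is a proper rotation (det = +1); applying
    ``coords @ rotation.T + translation`` maps mobile coordinates into the
    reference frame.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    selection: tuple[str, ...] = ()

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class MembranePlane:
    """Three non-collinear points (Å) on one membrane leaflet plane."""

    points: np.ndarray  # (3, 3)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (3, 3):
            raise ValueError("a membrane plane needs exactly three 3D points")
        area = 0.5 * np.linalg.norm(
            np.cross(pts[1] - pts[0], pts[2] - pts[0])
        )
        if area <= 1e-6:
            raise ValueError("membrane plane points are (nearly) collinear")
        object.__setattr__(self, "points", pts)

    @property
    def normal(self) -> np.ndarray:
        return plane_normal(self)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with the proper-rotation
    correction applied when the cross-covariance is reflective
    (d = sign(det) on the smallest singular direction).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must share the same (n, 3) shape")
    if len(P) < 3:
        raise ValueError("need at least 3 point pairs for a rigid fit")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # degenerate (e.g. collinear) point set
        raise ValueError("degenerate point configuration; cannot orient fit")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


def superpose(
    mobile: CaTrace,
    reference: CaTrace,
    scheme: SegmentationScheme | None = None,
    selection: Sequence[str] | None = None,
) -> SuperpositionResult:
    """Kabsch fit of ``mobile`` onto ``reference`` over matched residues.

    With a scheme and selection, only residues of the selected segments are
    fitted; residues are matched by author residue number.
    """
    if scheme is not None:
        labels = tuple(selection) if selection is not None else scheme.labels
        mobile_sel = select_segments(mobile, scheme, labels)
        reference_sel = select_segments(reference, scheme, labels)
    else:
        labels = ()
        mobile_sel, reference_sel = mobile, reference
    common = np.intersect1d(mobile_sel.residue_numbers, reference_sel.residue_numbers)
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} matched Cα pairs in selection; need ≥ 3"
        )
    P = mobile_sel.subset(common).coords
    Q = reference_sel.subset(common).coords
    R, t, rmsd = kabsch(P, Q)
    return SuperpositionResult(R, t, rmsd, len(common), labels)


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Rotation angle of a 3×3 rotation matrix, in degrees within [0, 180]."""
    cos_theta = (np.trace(rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))


def rigid_body_rotation_angle(
    trace_a: CaTrace,
    trace_b: CaTrace,
    scheme: SegmentationScheme,
    align_selection: Sequence[str],
    measure_selection: Sequence[str],
) -> float:
    """Rotation (degrees) of one segment set between two conformations,
    in the frame of another segment set.

    The structures are first superposed on ``align_selection`` (e.g. the
    hash helices); the residual rigid transform of ``measure_selection``
    (e.g. TM1a or the bundle) then gives the rotation angle.
    """
    frame_fit = superpose(trace_b, trace_a, scheme, align_selection)
    b_aligned = trace_b.with_coords(frame_fit.transform(trace_b.coords))
    residual = superpose(b_aligned, trace_a, scheme, measure_selection)
    return rotation_angle_deg(residual.rotation)


def plane_normal(plane: MembranePlane) -> np.ndarray:
    """Normal vector v = (p2 − p1) × (p3 − p1) of a membrane plane."""
    p1, p2, p3 = plane.points
    return np.cross(p2 - p1, p3 - p1)


def membrane_angle(v_o: np.ndarray, v_i: np.ndarray) -> float:
    """Angle θ (degrees) between two plane normals, folded into [0°, 90°].

    Folding removes the sign ambiguity of plane normals: antiparallel
    normals describe the same plane, so θ(v, −v) = 0.
    """
    v_o = np.asarray(v_o, dtype=float)
    v_i = np.asarray(v_i, dtype=float)
    n_o = np.linalg.norm(v_o)
    n_i = np.linalg.norm(v_i)
    if n_o == 0 or n_i == 0:
        raise ValueError("plane normals must be nonzero")
    cos_theta = np.clip(np.dot(v_o, v_i) / (n_o * n_i), -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_theta)))
    return min(theta, 180.0 - theta)


def membrane_rotation_workflow(
    trace_o: CaTrace,
    plane_o: MembranePlane,
    trace_i: CaTrace,
    plane_i: MembranePlane,
    scheme: SegmentationScheme,
    selection: Sequence[str],
) -> float:
    """θ between the predicted membrane planes of two conformations after
    superposing structure I onto structure O on the selected segments.

    The fitted rigid transform is applied to I's membrane plane points, so
    θ measures how much the membrane plane rotates when the selection is
    held fixed — large θ means the selection itself rotates relative to the
    membrane during the conformational change.
    """
    fit = superpose(trace_i, trace_o, scheme, selection)
    moved = MembranePlane(fit.transform(plane_i.points))
    return membrane_angle(plane_normal(plane_o), plane_normal(moved))


def read_membrane_plane(path: str | Path, *, leaflet: str = "lower") -> MembranePlane:
    """Read a membrane plane from an OPM/PPM-style PDB file or a 9-number
    text file.

    For PDB input the DUM (dummy) atom records of one leaflet are used:
    ``leaflet="lower"`` (intracellular, z < 0 in OPM convention) or
    ``"upper"``.  Three well-separated dummy atoms are chosen.  For text
    input the file holds nine whitespace-separated numbers (three points).
    """
    path = Path(path)
    text = path.read_text()
    if "DUM" in text:
        pts = []
        for line in text.splitlines():
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            if line[17:20].strip() != "DUM":
                continue
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            pts.append((x, y, z))
        pts_a = np.array(pts)
        if len(pts_a) < 3:
            raise ValueError(f"{path}: fewer than 3 DUM atoms")
        z_mid = pts_a[:, 2].mean()
        mask = pts_a[:, 2] < z_mid if leaflet == "lower" else pts_a[:, 2] >= z_mid
        leaf = pts_a[mask]
        if len(leaf) < 3:
            raise ValueError(f"{path}: fewer than 3 DUM atoms in {leaflet} leaflet")
        # spread the three chosen points: extremes in x and y
        i1 = int(np.argmin(leaf[:, 0]))
        i2 = int(np.argmax(leaf[:, 0]))
        i3 = int(np.argmax(leaf[:, 1]))
        if len({i1, i2, i3}) < 3:
            i3 = int(np.argmin(leaf[:, 1]))
        return MembranePlane(leaf[[i1, i2, i3]])
    numbers = [float(tok) for tok in text.split()]
    if len(numbers) != 9:
        raise ValueError(f"{path}: expected 9 numbers (three 3D points)")
    return MembranePlane(np.array(numbers).reshape(3, 3))
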