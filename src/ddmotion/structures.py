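"""Cα traces, helix segmentation schemes, and structure file I/O.

The whole toolkit works on Cα traces indexed by *author* residue numbers —
the numbering printed in the PDB/mmCIF file, which is also the numbering
used in curated helix-boundary tables. No renumbering is ever performed.
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CaTrace",
    "Segment",
    "SegmentationScheme",
    "LEUT_FOLD_SEGMENT_LABELS",
    "load_ca_trace",
    "select_segment",
    "select_segments",
    "read_segment_table",
    "write_ca_trace_pdb",
    "fetch_structure",
]

#: Canonical segment order for the 10-helix core of LeuT-fold transporters.
#: TM1, TM5, TM6 and TM10 are split into "a" (N-terminal) and "b"
#: (C-terminal) halves at their breaks/kinks, giving 14 segments.
LEUT_FOLD_SEGMENT_LABELS: tuple[str, ...] = (
    "1a", "1b", "2", "3", "4", "5a", "5b", "6a", "6b", "7", "8", "9", "10a", "10b",
)


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα coordinates for one chain of one structure.

    Parameters
    ----------
    protein_id : str
        Name of the protein (e.g. ``"LeuT"``); traces of the same protein
        are comparable residue-by-residue.
    structure_id : str
        Identifier of the structure (typically the PDB ID).
    chain_id : str
        Author chain identifier.
    residue_numbers : ndarray of int, shape (n,)
        Author residue numbers, strictly increasing.
    coords : ndarray of float, shape (n, 3)
        Cα positions in Å.
    """

    protein_id: str
    structure_id: str
    chain_id: str
    residue_numbers: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        nums = np.asarray(self.residue_numbers, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        if nums.ndim != 1 or len(nums) == 0:
            raise ValueError("a CaTrace needs at least one residue")
        if xyz.shape != (len(nums), 3):
            raise ValueError(
                f"coords shape {xyz.shape} does not match {len(nums)} residues"
            )
        if np.any(np.diff(nums) <= 0):
            raise ValueError("residue numbers must be strictly increasing")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "residue_numbers", nums)
        object.__setattr__(self, "coords", xyz)

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def subset(self, residue_numbers: Iterable[int]) -> "CaTrace":
        """Restrict the trace to the given residue numbers (order preserved)."""
        wanted = set(int(r) for r in residue_numbers)
        mask = np.array([int(r) in wanted for r in self.residue_numbers])
        if not mask.any():
            raise ValueError(
                f"selection is empty; trace {self.structure_id}:{self.chain_id} "
                f"spans residues {self.residue_numbers[0]}..{self.residue_numbers[-1]}"
            )
        return CaTrace(
            self.protein_id,
            self.structure_id,
            self.chain_id,
            self.residue_numbers[mask],
            self.coords[mask],
        )

    def with_coords(self, coords: np.ndarray) -> "CaTrace":
        return CaTrace(
            self.protein_id,
            self.structure_id,
            self.chain_id,
            self.residue_numbers.copy(),
            np.asarray(coords, dtype=float),
        )


@dataclass(frozen=True)
class Segment:
    label: str
    start: int  # inclusive, author numbering
    end: int    # inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.label}: start {self.start} > end {self.end}")

    def contains(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.end


@dataclass(frozen=True)
class SegmentationScheme:
    """Named helix segments with inclusive author-numbering residue ranges."""

    protein_id: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("a scheme needs at least one segment")
        seen: list[Segment] = []
        for seg in segs:
            for other in seen:
                if seg.start <= other.end and other.start <= seg.end:
                    raise ValueError(
                        f"segments {other.label} and {seg.label} overlap in "
                        f"scheme for {self.protein_id}"
                    )
            seen.append(seg)
        object.__setattr__(self, "segments", segs)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(
            f"unknown segment {label!r}; scheme for {self.protein_id} has "
            f"{', '.join(self.labels)}"
        )

    def residue_numbers(self, label: str) -> range:
        seg = self.segment(label)
        return range(seg.start, seg.end + 1)

    def all_residue_numbers(self) -> list[int]:
        out: list[int] = []
        for seg in self.segments:
            out.extend(range(seg.start, seg.end + 1))
        return out

    @classmethod
    def from_ranges(
        cls, protein_id: str, ranges: Sequence[tuple[str, int, int]]
    ) -> "SegmentationScheme":
        return cls(protein_id, tuple(Segment(l, s, e) for l, s, e in ranges))


def load_ca_trace(
    path: str | Path,
    chain_id: str,
    *,
    protein_id: str | None = None,
    structure_id: str | None = None,
) -> CaTrace:
    """Read a PDB or mmCIF file and extract the Cα trace of one chain.

    Model 1 is used for multi-model files.  For residues with alternate
    locations the highest-occupancy Cα conformer is kept (ties resolved by
    altloc identifier).  Residues without a Cα atom (waters, ligands,
    backbone-incomplete residues) are excluded.  Residues with insertion
    codes are kept in file order after their base number; ranges elsewhere
    are interpreted on base numbers only, so such residues sort with their
    base number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    if len(structure) == 0:
        raise ValueError(f"{path} contains no models")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(c.name for c in model)
        raise KeyError(f"chain {chain_id!r} not found in {path}; available: {available}")

    numbers: list[int] = []
    coords: list[tuple[float, float, float]] = []
    for residue in chain:
        best: gemmi.Atom | None = None
        if residue.name == "CA":
            continue  # calcium ion, not an alpha carbon
        for atom in residue:
            if atom.name != "CA":
                continue
            if best is None or atom.occ > best.occ or (
                atom.occ == best.occ and atom.altloc < best.altloc
            ):
                best = atom
        if best is None:
            continue
        num = residue.seqid.num
        if numbers and num <= numbers[-1]:
            # insertion-coded residue sharing a base number: keep file order
            if num == numbers[-1] and residue.seqid.icode.strip():
                logger.debug("insertion-coded residue %s%s kept after base",
                             num, residue.seqid.icode)
            else:
                continue  # altloc-duplicated or out-of-order residue record
        numbers.append(num)
        coords.append((best.pos.x, best.pos.y, best.pos.z))

    # collapse duplicated numbers from insertion codes: keep the first
    uniq_numbers: list[int] = []
    uniq_coords: list[tuple[float, float, float]] = []
    for n, c in zip(numbers, coords):
        if uniq_numbers and n == uniq_numbers[-1]:
            continue
        uniq_numbers.append(n)
        uniq_coords.append(c)

    if not uniq_numbers:
        raise ValueError(f"chain {chain_id!r} of {path} has no Cα atoms")
    return CaTrace(
        protein_id=protein_id or structure.name or path.stem,
        structure_id=structure_id or (structure.name or path.stem).upper(),
        chain_id=chain_id,
        residue_numbers=np.array(uniq_numbers, dtype=int),
        coords=np.array(uniq_coords, dtype=float),
    )


def select_segment(trace: CaTrace, scheme: SegmentationScheme, label: str) -> CaTrace:
    """Restrict a trace to one segment's residue range.

    Residues that are unresolved in the structure are silently dropped (and
    logged), so the result may be shorter than ``end - start + 1``.
    """
    seg = scheme.segment(label)
    mask = (trace.residue_numbers >= seg.start) & (trace.residue_numbers <= seg.end)
    n_found = int(mask.sum())
    expected = seg.end - seg.start + 1
    if n_found == 0:
        raise ValueError(
            f"segment {label} [{seg.start},{seg.end}] selects no residues from "
            f"trace {trace.structure_id}:{trace.chain_id} spanning "
            f"{trace.residue_numbers[0]}..{trace.residue_numbers[-1]}"
        )
    if n_found < expected:
        logger.info(
            "segment %s of %s: %d of %d residues resolved",
            label, trace.structure_id, n_found, expected,
        )
    return CaTrace(
        trace.protein_id,
        trace.structure_id,
        trace.chain_id,
        trace.residue_numbers[mask],
        trace.coords[mask],
    )


def select_segments(
    trace: CaTrace, scheme: SegmentationScheme, labels: Sequence[str] | None = None
) -> CaTrace:
    """Restrict a trace to the union of several segments (all by default)."""
    labels = list(labels) if labels is not None else list(scheme.labels)
    wanted: set[int] = set()
    for label in labels:
        seg = scheme.segment(label)
        wanted.update(range(seg.start, seg.end + 1))
    return trace.subset(sorted(wanted))


def read_segment_table(path: str | Path) -> dict[str, SegmentationScheme]:
    """Read a tab-delimited helix-boundary table.

    Expected header: ``protein<TAB>segment<TAB>start<TAB>end`` with 1-based
    inclusive author-numbering ranges.  Returns one scheme per protein, with
    segments in file order.
    """
    path = Path(path)
    rows: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein", "segment", "start", "end"]
        if [h.strip().lower() for h in header] != expected:
            raise ValueError(
                f"{path}: expected header {expected!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            protein, segment, start, end = parts
            rows.setdefault(protein.strip(), []).append(
                (segment.strip(), int(start), int(end))
            )
    return {
        protein: SegmentationScheme.from_ranges(protein, ranges)
        for protein, ranges in rows.items()
    }


def write_ca_trace_pdb(trace: CaTrace, path: str | Path) -> None:
    """Write a trace as a minimal PDB file (CA/ALA records, 3-decimal Å)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, (num, (x, y, z)) in enumerate(
            zip(trace.residue_numbers, trace.coords), start=1
        ):
            fh.write(
                f"ATOM  {i:5d}  CA  ALA {trace.chain_id:>1}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def fetch_structure(
    pdb_id: str, directory: str | Path, *, fmt: str = "cif", timeout: float = 30.0
) -> Path:
    """Download a PDB entry into ``directory`` (skips if already present).

    Requires network access; analysis functions never call this implicitly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pdb_id = pdb_id.lower()
    suffix = {"cif": "cif", "pdb": "pdb"}[fmt]
    target = directory / f"{pdb_id}.{suffix}"
    if target.exists():
        return target
    url = f"https://files.rcsb.org/download/{pdb_id}.{suffix}"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    target.write_bytes(data)
    return target
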