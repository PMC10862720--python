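"""Clustering structures of one protein into conformational states.

With dozens to hundreds of deposited structures per transporter, manual
state assignment does not scale.  The pipeline here: a pairwise Cα-RMSD
matrix (after optimal rigid superposition), k-means on the matrix rows,
propagation of literature-derived anchor labels to cluster members within
an RMSD threshold, and rule-based selection of a representative structure
per conformational state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .geometry import superpose
from .structures import CaTrace

logger = logging.getLogger(__name__)

__all__ = [
    "RmsdMatrix",
    "ConformationLabeling",
    "Candidate",
    "CONFORMATION_LABELS",
    "UNRESOLVED",
    "pairwise_rmsd_matrix",
    "kmeans_conformations",
    "propagate_labels",
    "select_representative",
    "dispersion_scan",
]

#: Conformational states of the alternating-access cycle, in half-cycle order.
CONFORMATION_LABELS: tuple[str, ...] = ("O_op", "O_oc", "I_oc", "I_op")
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class RmsdMatrix:
    structure_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.structure_ids)
        if vals.shape != (n, n):
            raise ValueError("values must be square and match structure_ids")
        object.__setattr__(self, "structure_ids", tuple(self.structure_ids))
        object.__setattr__(self, "values", vals)

    def rmsd(self, id_a: str, id_b: str) -> float:
        i = self.structure_ids.index(id_a)
        j = self.structure_ids.index(id_b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.structure_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass
class ConformationLabeling:
    """Cluster assignment per structure plus per-cluster conformation labels."""

    cluster_of: dict[str, int]
    conformation_of_cluster: dict[int, str] = field(default_factory=dict)
    conformation_of_structure: dict[str, str] = field(default_factory=dict)

    def conformation_of(self, structure_id: str) -> str:
        if structure_id in self.conformation_of_structure:
            return self.conformation_of_structure[structure_id]
        return self.conformation_of_cluster.get(
            self.cluster_of[structure_id], UNRESOLVED
        )

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.cluster_of.items() if c == cluster]

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.cluster_of.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sid, c, self.conformation_of(sid))
            for sid, c in sorted(self.cluster_of.items())
        ]
        return pd.DataFrame(rows, columns=["structure_id", "cluster", "conformation"])


def pairwise_rmsd_matrix(traces: Sequence[CaTrace]) -> RmsdMatrix:
    """Pairwise Cα RMSD after optimal rigid superposition, per structure pair.

    Residues are matched by author residue number; each pair is fitted once
    (the matrix is symmetric by construction).
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 structures")
    ids = tuple(t.structure_id for t in traces)
    if len(set(ids)) != len(ids):
        raise ValueError("structure_ids must be unique")
    n = len(traces)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fit = superpose(traces[j], traces[i])
            values[i, j] = values[j, i] = fit.rmsd
    return RmsdMatrix(ids, values)


def kmeans_conformations(
    matrix: RmsdMatrix, k: int, seed: int = 0, *, n_init: int = 10
) -> ConformationLabeling:
    """k-means on the rows of the RMSD matrix.

    Each structure's feature vector is its row of RMSDs to all structures.
    Cluster indices are renumbered by descending size, ties broken by the
    lexicographically smallest member structure id, so output is stable.
    """
    n = len(matrix.structure_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} structures")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    raw = km.fit_predict(matrix.values)
    centroids = km.cluster_centers_
    dup = any(
        np.allclose(centroids[i], centroids[j], atol=1e-9)
        for i in range(k) for j in range(i + 1, k)
    )
    if len(set(raw)) < k or dup:
        warnings.warn(
            f"k-means clusters are degenerate for k={k} "
            f"({len(set(raw))} distinct clusters, "
            f"{'duplicate' if dup else 'distinct'} centroids); input "
            "structures may be (near-)identical",
            stacklevel=2,
        )
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(matrix.structure_ids, raw):
        groups.setdefault(int(lab), []).append(sid)
    order = sorted(groups, key=lambda g: (-len(groups[g]), min(groups[g])))
    remap = {old: new for new, old in enumerate(order)}
    return ConformationLabeling(
        {sid: remap[int(lab)] for sid, lab in zip(matrix.structure_ids, raw)}
    )


def dispersion_scan(
    matrix: RmsdMatrix, k_values: Sequence[int] = range(1, 7), seed: int = 0
) -> pd.DataFrame:
    """Within-cluster dispersion (k-means inertia) across k, to guide the
    per-protein choice of cluster count."""
    rows = []
    for k in k_values:
        if k > len(matrix.structure_ids):
            break
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        km.fit(matrix.values)
        rows.append((k, float(km.inertia_)))
    return pd.DataFrame(rows, columns=["k", "inertia"])


def propagate_labels(
    labeling: ConformationLabeling,
    anchors: Mapping[str, str],
    matrix: RmsdMatrix,
    threshold: float = 0.5,
) -> ConformationLabeling:
    """Spread anchor conformation labels through clusters.

    A structure inherits its cluster's anchor label only if its RMSD to an
    anchor of that cluster is below ``threshold`` (Å); otherwise it is
    flagged unresolved for manual review.  Clusters whose anchors disagree
    raise an error.
    """
    anchors_by_cluster: dict[int, list[str]] = {}
    for sid, conf in anchors.items():
        if sid not in labeling.cluster_of:
            raise KeyError(f"anchor {sid!r} is not among the clustered structures")
        anchors_by_cluster.setdefault(labeling.cluster_of[sid], []).append(sid)

    cluster_conf: dict[int, str] = {}
    for cluster, sids in anchors_by_cluster.items():
        confs = sorted({anchors[s] for s in sids})
        if len(confs) > 1:
            raise ValueError(
                f"cluster {cluster} has conflicting anchors: "
                + ", ".join(f"{s}={anchors[s]}" for s in sids)
            )
        cluster_conf[cluster] = confs[0]

    per_structure: dict[str, str] = {}
    for sid, cluster in labeling.cluster_of.items():
        anchor_ids = anchors_by_cluster.get(cluster, [])
        if not anchor_ids:
            per_structure[sid] = UNRESOLVED
            continue
        if sid in anchors:
            per_structure[sid] = anchors[sid]
            continue
        closest = min(matrix.rmsd(sid, a) for a in anchor_ids)
        if closest < threshold:
            per_structure[sid] = cluster_conf[cluster]
        else:
            per_structure[sid] = UNRESOLVED
            logger.info(
                "structure %s is %.2f Å from the nearest anchor of its "
                "cluster (threshold %.2f); left unresolved", sid, closest, threshold,
            )
    return ConformationLabeling(
        dict(labeling.cluster_of), dict(cluster_conf), per_structure
    )


@dataclass(frozen=True)
class Candidate:
    structure_id: str
    organism: str
    resolution: float
    conformation: str
    disorder_flag: bool = False


def select_representative(
    candidates: Sequence[Candidate],
    reference_organism: str,
    matrix: RmsdMatrix | None = None,
    *,
    atypical_percentile: float = 90.0,
) -> dict[str, str]:
    """Pick one representative structure per conformation.

    Priorities, applied lexicographically within each conformation:

    1. structures from ``reference_organism``;
    2. structures without an atypical RMSD — operationalized as RMSD to the
       conformation's medoid above its ``atypical_percentile`` (needs
       ``matrix``; skipped otherwise);
    3. highest resolution (smallest Å value);
    4. structures without a disordered core helix.

    Remaining ties break by structure id alphabetically.  Disordered
    structures are replaced by the next-best candidate; if only disordered
    candidates exist the best of them is returned with a warning.
    """
    by_conf: dict[str, list[Candidate]] = {}
    for c in candidates:
        by_conf.setdefault(c.conformation, []).append(c)
    if not by_conf:
        raise ValueError("no candidates supplied")

    chosen: dict[str, str] = {}
    for conf, pool in by_conf.items():
        atypical: set[str] = set()
        if matrix is not None and len(pool) > 2:
            ids = [c.structure_id for c in pool]
            sub = np.array([[matrix.rmsd(a, b) for b in ids] for a in ids])
            medoid = int(np.argmin(sub.sum(axis=1)))
            d_to_medoid = sub[:, medoid]
            cutoff = np.percentile(d_to_medoid, atypical_percentile)
            atypical = {ids[i] for i in range(len(ids)) if d_to_medoid[i] > cutoff}

        ranked = sorted(
            pool,
            key=lambda c: (
                c.organism != reference_organism,
                c.structure_id in atypical,
                c.resolution,
                c.structure_id,
            ),
        )
        winner = next((c for c in ranked if not c.disorder_flag), None)
        if winner is None:
            winner = ranked[0]
            warnings.warn(
                f"conformation {conf}: only candidates with disordered core "
                f"helices are available; returning {winner.structure_id}",
                stacklevel=2,
            )
        logger.info("representative for %s: %s", conf, winner.structure_id)
        chosen[conf] = winner.structure_id
    return chosen
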