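"""Sparse decomposition of hb-DDM sets into "building-block" motions.

A collection of helix-binned RMSDD fingerprints — one per conformational
comparison — is flattened into k²-feature vectors and factored by sparse
PCA (L1-penalized components solved via least-angle-regression lasso).
Because each simple rigid-body motion touches only a few segment pairs, the
sparse components isolate interpretable motions (a single half-helix swing,
a bundle–hash rock), and each comparison is then expressible as a weighted
sum of these building blocks.

The latent-space origin is shifted so the projection of the all-zero matrix
(no motion at all) is the zero weight vector; on datasets of nonnegative
RMSDD fingerprints the rescaled weights then come out nonnegative, so a
weight reads directly as "how much of this motion the transition contains".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import SparsePCA

from .ddm import HbDDM

__all__ = [
    "MotionBasis",
    "flatten",
    "fit_motion_basis",
    "project_weights",
    "reconstruction_error",
    "component_scan",
    "nmf_crosscheck",
]


def flatten(hbddm: HbDDM | np.ndarray) -> np.ndarray:
    """Row-major flattening of a k×k hb-DDM into a k² feature vector.

    Both symmetric copies of each off-diagonal entry and the diagonal are
    kept, so a 14×14 matrix gives 196 features.
    """
    values = hbddm.values if isinstance(hbddm, HbDDM) else np.asarray(hbddm)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square matrix")
    return values.reshape(-1).astype(float)


@dataclass(frozen=True)
class MotionBasis:
    """Fitted sparse motion components over k×k hb-DDM fingerprints.

    ``components`` are k×k symmetric nonnegative matrices (Å), sign-fixed
    so each component's entry sum is ≥ 0.  ``zero_projection`` is the raw
    latent projection of the all-zero matrix; subtracting it rescales
    projections so "no motion" sits at the origin.
    """

    segment_labels: tuple[str, ...]
    components: np.ndarray          # (n_components, k, k)
    feature_means: np.ndarray       # (k*k,)
    zero_projection: np.ndarray     # (n_components,)
    alpha: float
    solver: str = "sparse_pca_lars"
    ridge_alpha: float = 0.01

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def components_flat(self) -> np.ndarray:
        return self.components.reshape(self.n_components, -1)

    def _raw_transform(self, flat: np.ndarray) -> np.ndarray:
        """Ridge regression of centered features on the components (the
        same estimator sparse PCA uses for its transform step)."""
        X = np.atleast_2d(flat) - self.feature_means
        C = self.components_flat()
        gram = C @ C.T + self.ridge_alpha * np.eye(self.n_components)
        return np.linalg.solve(gram, C @ X.T).T

    @classmethod
    def from_components(
        cls,
        segment_labels: Sequence[str],
        components: np.ndarray,
        *,
        feature_means: np.ndarray | None = None,
        ridge_alpha: float = 0.0,
    ) -> "MotionBasis":
        """Build a basis directly from known k×k components.

        Useful for projecting data onto externally defined motions and for
        validating fitted bases against ground truth.  With the default
        ``ridge_alpha=0`` the transform is an exact least-squares
        projection onto the component span.
        """
        comps = np.asarray(components, dtype=float)
        if comps.ndim != 3 or comps.shape[1] != comps.shape[2]:
            raise ValueError("components must have shape (n, k, k)")
        k = comps.shape[1]
        means = (np.zeros(k * k) if feature_means is None
                 else np.asarray(feature_means, dtype=float))
        basis = cls(
            segment_labels=tuple(segment_labels),
            components=comps,
            feature_means=means,
            zero_projection=np.zeros(comps.shape[0]),
            alpha=0.0,
            solver="fixed_components",
            ridge_alpha=float(ridge_alpha),
        )
        zero_proj = basis._raw_transform(np.zeros(k * k))[0]
        return cls(
            basis.segment_labels, basis.components, basis.feature_means,
            zero_proj, basis.alpha, basis.solver, basis.ridge_alpha,
        )

    def components_frame(self) -> dict[int, pd.DataFrame]:
        labels = list(self.segment_labels)
        return {
            i: pd.DataFrame(self.components[i], index=labels, columns=labels)
            for i in range(self.n_components)
        }


def _as_feature_matrix(dataset: Sequence[HbDDM]) -> tuple[np.ndarray, tuple[str, ...]]:
    if not dataset:
        raise ValueError("dataset is empty")
    labels = dataset[0].segment_labels
    for m in dataset:
        if m.segment_labels != labels:
            raise ValueError("all hb-DDMs must share the same segment labels")
    X = np.stack([flatten(m) for m in dataset])
    return X, labels


def fit_motion_basis(
    dataset: Sequence[HbDDM],
    n_components: int = 6,
    alpha: float = 2.0,
    *,
    ridge_alpha: float = 0.01,
    seed: int = 0,
) -> MotionBasis:
    """Fit sparse nonnegative motion components to a set of hb-DDMs.

    Features are centered on the dataset mean; components come from sparse
    PCA with an L1 penalty of ``alpha`` solved by LARS lasso.  Each
    component is sign-fixed to have nonnegative entry sum, clipped at zero
    (solver noise only — fitted components come out one-signed), stored as
    a symmetrized k×k matrix, and ordered by total rescaled weight over the
    training set, descending.
    """
    if alpha < 0:
        raise ValueError("alpha must be ≥ 0")
    X, labels = _as_feature_matrix(dataset)
    if n_components > len(dataset):
        raise ValueError(
            f"n_components={n_components} exceeds dataset size {len(dataset)}"
        )
    model = SparsePCA(
        n_components=n_components,
        alpha=alpha,
        ridge_alpha=ridge_alpha,
        method="lars",
        random_state=seed,
    )
    model.fit(X)
    comps = model.components_.copy()

    # sign fixing: flip components whose entries sum negative
    for i in range(n_components):
        if comps[i].sum() < 0:
            comps[i] = -comps[i]

    k = len(labels)
    mats = comps.reshape(n_components, k, k)
    asym = np.abs(mats - np.transpose(mats, (0, 2, 1))).max() if n_components else 0.0
    if asym > 1e-6:
        warnings.warn(
            f"components deviate from symmetry by up to {asym:.2e} Å before "
            "symmetrization", stacklevel=2,
        )
    mats = 0.5 * (mats + np.transpose(mats, (0, 2, 1)))
    mats = np.clip(mats, 0.0, None)

    basis = MotionBasis(
        segment_labels=labels,
        components=mats,
        feature_means=X.mean(axis=0),
        zero_projection=np.zeros(n_components),
        alpha=float(alpha),
        ridge_alpha=float(ridge_alpha),
    )
    zero_proj = basis._raw_transform(np.zeros(k * k))[0]
    basis = MotionBasis(
        basis.segment_labels, basis.components, basis.feature_means,
        zero_proj, basis.alpha, basis.solver, basis.ridge_alpha,
    )

    # order components by total rescaled weight across the training set
    W = np.stack([project_weights(basis, m) for m in dataset])
    order = np.argsort(-W.sum(axis=0))
    return MotionBasis(
        basis.segment_labels,
        basis.components[order],
        basis.feature_means,
        basis.zero_projection[order],
        basis.alpha,
        basis.solver,
        basis.ridge_alpha,
    )


def project_weights(basis: MotionBasis, hbddm: HbDDM | np.ndarray) -> np.ndarray:
    """Rescaled motion weights of one hb-DDM.

    Raw latent projection minus the projection of the all-zero matrix, so
    an all-zero fingerprint maps exactly to the zero weight vector.  On
    hb-DDM datasets like those this basis is meant for, the rescaled
    weights are empirically nonnegative; a materially negative weight
    (below −1e-6) triggers a warning rather than an error.
    """
    flat = flatten(hbddm)
    if flat.shape[0] != basis.k ** 2:
        raise ValueError(
            f"matrix has {flat.shape[0]} features; basis expects {basis.k ** 2}"
        )
    w = basis._raw_transform(flat)[0] - basis.zero_projection
    if np.any(w < -1e-6):
        warnings.warn(
            f"negative rescaled weight(s) down to {w.min():.3g}; the "
            "fingerprint may lie outside the motion repertoire of the basis",
            stacklevel=2,
        )
    return w


def _reconstruct(basis: MotionBasis, flat: np.ndarray) -> np.ndarray:
    raw = basis._raw_transform(flat)
    return raw @ basis.components_flat() + basis.feature_means


def reconstruction_error(basis: MotionBasis, dataset: Sequence[HbDDM]) -> dict:
    """Reconstruction error of the basis on a dataset.

    Returns both the mean squared error over all matrices and features
    (``mse``, Å²) and its square root (``rmse``, Å); reporting conventions
    differ in the field, so both are labelled explicitly.
    """
    X, labels = _as_feature_matrix(dataset)
    if labels != basis.segment_labels:
        raise ValueError("dataset segment labels do not match the basis")
    recon = _reconstruct(basis, X)
    mse = float(np.mean((X - recon) ** 2))
    return {"mse": mse, "rmse": float(np.sqrt(mse)), "n_matrices": len(dataset)}


def component_scan(
    dataset: Sequence[HbDDM],
    n_values: Sequence[int] = range(1, 9),
    alpha: float = 2.0,
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Reconstruction error as a function of the number of components.

    Used to choose the component count by locating where the improvement
    levels off (an elbow).
    """
    rows = []
    for n in n_values:
        if n > len(dataset):
            break
        basis = fit_motion_basis(dataset, n_components=n, alpha=alpha, seed=seed)
        err = reconstruction_error(basis, dataset)
        rows.append((n, err["mse"], err["rmse"]))
    return pd.DataFrame(rows, columns=["n_components", "mse", "rmse"])


def nmf_crosscheck(basis: MotionBasis, dataset: Sequence[HbDDM]) -> dict:
    """Express each matrix as a purely nonnegative sum of the fixed
    components (nonnegative least squares with the component matrix held
    fixed) and compare with the rescaled projections.

    Returns the nonnegative weights and, per comparison, the cosine
    similarity between the NNLS weights and ``project_weights`` output.
    """
    X, labels = _as_feature_matrix(dataset)
    if labels != basis.segment_labels:
        raise ValueError("dataset segment labels do not match the basis")
    C = basis.components_flat()
    nn_weights = np.zeros((len(dataset), basis.n_components))
    for i, x in enumerate(X):
        nn_weights[i], _ = nnls(C.T, x)
    pca_weights = np.stack([project_weights(basis, m) for m in dataset])
    cosines = np.full(len(dataset), np.nan)
    for i in range(len(dataset)):
        na = np.linalg.norm(nn_weights[i])
        nb = np.linalg.norm(pca_weights[i])
        if na > 0 and nb > 0:
            cosines[i] = float(nn_weights[i] @ pca_weights[i] / (na * nb))
        elif na == 0 and nb == 0:
            cosines[i] = 1.0
    return {
        "nmf_weights": nn_weights,
        "pca_weights": pca_weights,
        "cosine_similarity": cosines,
        "mean_cosine_similarity": float(np.nanmean(cosines)),
    }
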