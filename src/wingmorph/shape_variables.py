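"""Thin-plate-spline shape variables: partial warps and relative warps.

Tangent-space residuals from a GPA are re-expressed on an orthonormal basis
built from the thin-plate-spline principal warps of the consensus (the
non-uniform, bending part of shape change) plus the two-dimensional uniform
(affine) component estimated in the orthogonal complement of the bending
space within the tangent plane.  No bending-energy weighting is applied
(warp weight exponent alpha = 0), so the full partial-warp score space is an
isometric rotation of tangent space: Euclidean distances among specimens are
identical in either representation, and discriminant results do not depend
on the basis choice.  Relative warps are the principal components of the
partial-warp scores (covariance PCA, unweighted).

Scores are always relative to the consensus of one particular GPA.  Adding
or removing a specimen changes the consensus and therefore every score;
score matrices from different consensuses must never be mixed, and the API
refuses to concatenate them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConsensusMismatchError, RankError, SingularGeometryError
from .landmark_io import LandmarkConfiguration
from .superimposition import SuperimpositionResult, tangent_coordinates

__all__ = [
    "BendingEnergyBasis",
    "ShapeVariables",
    "bending_energy",
    "partial_warps",
    "relative_warps",
    "consensus_hash",
]


def consensus_hash(consensus: np.ndarray) -> str:
    """Stable identity of a consensus configuration (for mix-up detection)."""
    rounded = np.round(np.asarray(consensus, dtype=float), 12)
    return hashlib.sha1(rounded.tobytes()).hexdigest()[:16]


@dataclass
class BendingEnergyBasis:
    """Thin-plate-spline bending-energy decomposition of a reference shape.

    ``bending_matrix`` is the upper k x k block of the inverse bordered TPS
    system; it is symmetric positive-semidefinite with exactly three zero
    eigenvalues (the affine null space) for any non-collinear reference.
    ``principal_warps`` holds the k-3 eigenvectors with positive eigenvalue,
    ordered by increasing bending energy.
    """

    bending_matrix: np.ndarray  # (k, k)
    principal_warps: np.ndarray  # (k, k-3)
    eigenvalues: np.ndarray  # (k-3,) positive, increasing
    zero_space_dim: int = 3


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log(r^2), with U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    out[r2 == 0.0] = 0.0
    return out


def bending_energy(reference: LandmarkConfiguration | np.ndarray) -> BendingEnergyBasis:
    """Bending-energy matrix and principal warps of a reference configuration.

    Assembles the bordered system L = [[K, Q], [Q', 0]] with kernel
    K_ij = U(r_ij), affine border Q = [1 | x | y], and takes the upper k x k
    block of its inverse.  Collinear references make L singular and raise.
    """
    xy = reference.coords if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, float)
    k = xy.shape[0]
    if k < 3:
        raise ValueError("bending energy needs k >= 3 landmarks")
    centered = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(np.linalg.norm(centered), 1e-30)) < 2:
        raise SingularGeometryError(
            "reference landmarks are collinear: the thin-plate spline system is singular"
        )
    diff = xy[:, None, :] - xy[None, :, :]
    r2 = (diff**2).sum(axis=-1)
    K = _tps_kernel(r2)
    Q = np.column_stack([np.ones(k), xy])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise SingularGeometryError(f"TPS system is singular: {exc}") from None
    B = Linv[:k, :k]
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    # three smallest eigenvalues are the affine null space
    scale = max(float(eigval[-1]), 1e-30)
    order = np.argsort(eigval)
    positive = order[3:]
    eigval_pos = np.clip(eigval[positive], 0.0, None)
    return BendingEnergyBasis(
        bending_matrix=B,
        principal_warps=eigvec[:, positive],
        eigenvalues=eigval_pos,
        zero_space_dim=3,
    )


@dataclass
class ShapeVariables:
    """Per-specimen shape-variable scores with the basis that produced them.

    ``scores`` is n x m; ``basis`` maps flattened tangent coordinates (2k) to
    scores, with orthonormal rows for partial warps.  ``reference_consensus``
    records the GPA consensus the scores are relative to; operations that
    would mix scores from different consensuses raise ConsensusMismatchError.
    """

    scores: np.ndarray
    basis: np.ndarray  # (m, 2k)
    eigenvalues: np.ndarray
    reference_consensus: np.ndarray  # (k, 2)
    kind: str  # "partial_warps" | "relative_warps"
    specimen_ids: list[str]
    column_names: list[str]
    labels: list | None = None  # optional per-row species labels
    extra: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    @property
    def consensus_id(self) -> str:
        return consensus_hash(self.reference_consensus)

    def require_same_consensus(self, other: "ShapeVariables") -> None:
        if self.consensus_id != other.consensus_id:
            raise ConsensusMismatchError(
                "shape variables were computed relative to different consensuses and "
                "cannot be combined; recompute them from a joint superimposition"
            )

    def concat(self, other: "ShapeVariables") -> "ShapeVariables":
        """Row-wise concatenation, allowed only for a shared consensus."""
        self.require_same_consensus(other)
        if self.kind != other.kind or self.column_names != other.column_names:
            raise ConsensusMismatchError("shape-variable bases differ; cannot concatenate")
        return ShapeVariables(
            scores=np.vstack([self.scores, other.scores]),
            basis=self.basis,
            eigenvalues=self.eigenvalues,
            reference_consensus=self.reference_consensus,
            kind=self.kind,
            specimen_ids=self.specimen_ids + other.specimen_ids,
            column_names=self.column_names,
            labels=(self.labels or []) + (other.labels or []) if (self.labels or other.labels) else None,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.specimen_ids, columns=self.column_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.12g")


def _interleave(vec_x: np.ndarray, vec_y: np.ndarray) -> np.ndarray:
    """k-vectors for x and y components -> flattened 2k vector (row-major k,2)."""
    out = np.empty(2 * vec_x.shape[0])
    out[0::2] = vec_x
    out[1::2] = vec_y
    return out


def partial_warps(
    result: SuperimpositionResult, include_uniform: bool = True
) -> ShapeVariables:
    """Partial-warp scores of every specimen of a GPA result.

    Each principal warp e_j contributes an (x, y) score pair: the projection
    of a specimen's tangent residual onto e_j in each coordinate direction.
    The uniform (affine) component contributes two further scores spanning
    the orthogonal complement of the bending space within the tangent plane,
    giving m = 2k - 4 variables in total.  The basis is orthonormal, so
    pairwise Euclidean distances among score rows equal tangent-space
    distances exactly.
    """
    k = result.k
    if k < 4:
        if not include_uniform:
            raise RankError("k < 4 leaves no non-uniform warp space and uniform was excluded")
    basis_vectors: list[np.ndarray] = []
    names: list[str] = []
    eigs: list[float] = []

    if k >= 4:
        beb = bending_energy(result.consensus)
        for j in range(beb.principal_warps.shape[1]):
            e = beb.principal_warps[:, j]
            basis_vectors.append(_interleave(e, np.zeros(k)))
            basis_vectors.append(_interleave(np.zeros(k), e))
            names += [f"pw{j + 1}x", f"pw{j + 1}y"]
            eigs += [float(beb.eigenvalues[j])] * 2

    if include_uniform:
        uniform = _uniform_basis(result.consensus, basis_vectors)
        for i in range(uniform.shape[0]):
            basis_vectors.append(uniform[i])
        names += ["uniX", "uniY"][: uniform.shape[0]]
        eigs += [0.0] * uniform.shape[0]

    B = np.array(basis_vectors)  # (m, 2k)
    T = tangent_coordinates(result)
    scores = T @ B.T
    labels = (
        [c.species for c in result.dataset.configurations] if result.dataset is not None else None
    )
    return ShapeVariables(
        scores=scores,
        basis=B,
        eigenvalues=np.array(eigs),
        reference_consensus=result.consensus.copy(),
        kind="partial_warps",
        specimen_ids=list(result.specimen_ids),
        column_names=names,
        labels=labels,
    )


def _uniform_basis(consensus: np.ndarray, nonuniform: list[np.ndarray]) -> np.ndarray:
    """Orthonormal basis of the uniform subspace: affine deformations of the
    consensus orthogonal to similarity transforms.

    Generated deterministically from the two non-similarity affine generators
    applied to the consensus — pure stretch diag(1, -1) and pure shear
    [[0, 1], [1, 0]] — then Gram-Schmidted against the scale and rotation
    directions.  Both generators are centered (the consensus is) and, having
    zero bending energy, are exactly orthogonal to every principal-warp
    direction, so the result spans the orthogonal complement of the
    non-uniform space within the tangent plane.  Unlike a generic null-space
    computation, this basis is a continuous function of the consensus, so
    uniform scores are reproducible across equivalent superimpositions.
    """
    x, y = consensus[:, 0], consensus[:, 1]
    c = consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    c_rot = _interleave(-y, x)
    c_rot /= np.linalg.norm(c_rot)
    w1 = _interleave(x, -y)  # stretch
    w2 = _interleave(y, x)  # shear
    basis = []
    for w in (w1, w2):
        v = w - (w @ c) * c - (w @ c_rot) * c_rot
        for prev in basis:
            v = v - (v @ prev) * prev
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            basis.append(v / norm)
    return np.array(basis) if basis else np.empty((0, c.shape[0]))


def relative_warps(pw: ShapeVariables, retain: int | float | None = None) -> ShapeVariables:
    """Relative warps: principal components of partial-warp scores.

    Covariance-style PCA (no standardization, no eigenvalue weighting),
    taken about the tangent-space origin — the consensus — rather than the
    sample mean, so the consensus always maps to zero scores; after GPA the
    two centers coincide to high order anyway.  ``retain`` is either an axis
    count, a variance fraction in (0, 1), or None for all axes up to the
    score-matrix rank.  Axes are ordered by decreasing variance.
    """
    if pw.kind != "partial_warps":
        raise ValueError("relative_warps expects partial-warp scores as input")
    X = pw.scores
    Xc = X
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    var = s**2 / max(n - 1, 1)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())

    if retain is None:
        q = rank
    elif isinstance(retain, float) and 0 < retain < 1:
        frac = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
        q = int(np.searchsorted(frac, retain - 1e-12) + 1)
        q = min(q, rank)
    else:
        q = int(retain)
        if q > rank:
            raise RankError(f"retain={q} exceeds the score-matrix rank {rank}")
    if q < 1:
        raise RankError("must retain at least one relative warp")

    scores = Xc @ Vt[:q].T
    return ShapeVariables(
        scores=scores,
        basis=Vt[:q] @ pw.basis,
        eigenvalues=var[:q],
        reference_consensus=pw.reference_consensus,
        kind="relative_warps",
        specimen_ids=list(pw.specimen_ids),
        column_names=[f"rw{i + 1}" for i in range(q)],
        labels=list(pw.labels) if pw.labels is not None else None,
        extra={
            "explained_variance_fraction": float(var[:q].sum() / var.sum()) if var.sum() else 1.0,
            "total_rank": rank,
        },
    )
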