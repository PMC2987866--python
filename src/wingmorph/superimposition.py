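"""Procrustes superimposition: centroid size, OPA, GPA, tangent space, distances.

Two-dimensional configurations are handled in complex form: a k-landmark
configuration is a complex k-vector, rotation by an angle theta is
multiplication by exp(i*theta), and the optimal rotation aligning one
centered configuration onto another has the closed form
``angle(<z_moving, z_target>)``.  Reflections are never used to fit
(rotation determinant is always +1): all specimens are assumed digitized on
the same side, and allowing reflections would mask left/right digitization
mistakes.

The GPA scaling convention fixes every specimen at unit centroid size
("partial Procrustes" fitting); full-Procrustes scaling is available via
``scale="full"``.  The consensus orientation is made canonical (principal
axis along x with a deterministic sign rule), which makes the GPA result
invariant both to the input order and to arbitrary similarity transforms of
any input specimen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateConfigurationError, ShapeMismatchError
from .landmark_io import LandmarkConfiguration, LandmarkDataset

__all__ = [
    "centroid_size",
    "preshape",
    "opa",
    "gpa",
    "tangent_coordinates",
    "procrustes_distance",
    "distance_matrix",
    "OpaResult",
    "SuperimpositionResult",
    "DistanceMatrix",
]

_DISTANCE_VARIANTS = ("partial", "full", "geodesic")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def _coords_of(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    The standard geometric size measure: scaling all coordinates by c scales
    CS by c, and it is translation-invariant.  A degenerate configuration
    (all landmarks coincident) yields CS = 0 with a warning, not an error.
    """
    xy = _coords_of(config)
    centered = xy - xy.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: centroid size is 0", stacklevel=2)
    return cs


def _to_complex(xy: np.ndarray) -> np.ndarray:
    return xy[:, 0] + 1j * xy[:, 1]


def _to_real(z: np.ndarray) -> np.ndarray:
    return np.column_stack([z.real, z.imag])


def _unit_preshape_z(xy: np.ndarray) -> np.ndarray:
    """Centered, unit-norm complex representation; raises on CS == 0."""
    z = _to_complex(np.asarray(xy, dtype=float))
    z = z - z.mean()
    norm = np.linalg.norm(z)
    if norm == 0.0:
        raise DegenerateConfigurationError("cannot preshape a zero-size configuration")
    return z / norm


def preshape(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Center at the origin and scale to unit centroid size (shape unchanged)."""
    z = _unit_preshape_z(_coords_of(config))
    if isinstance(config, LandmarkConfiguration):
        return config.with_coords(_to_real(z))
    return _to_real(z)


@dataclass
class OpaResult:
    """Ordinary (pairwise) Procrustes fit of one configuration onto another."""

    rotation: np.ndarray  # 2x2, orthogonal, det +1
    scale: float
    translation: np.ndarray  # 2-vector
    aligned: LandmarkConfiguration
    distance: float  # partial Procrustes distance between the preshapes

    @property
    def rotation_angle(self) -> float:
        return float(np.arctan2(self.rotation[1, 0], self.rotation[0, 0]))


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def opa(
    target: LandmarkConfiguration,
    moving: LandmarkConfiguration,
    allow_scaling: bool = True,
) -> OpaResult:
    """Least-squares similarity fit (rotation+translation, optional scaling,
    reflections excluded) mapping ``moving`` onto ``target``.

    The reported ``distance`` is the partial Procrustes distance between the
    two unit-size preshapes and does not depend on ``allow_scaling``.
    """
    xt, xm = _coords_of(target), _coords_of(moving)
    if xt.shape != xm.shape:
        raise ShapeMismatchError(f"landmark counts differ: {xt.shape[0]} vs {xm.shape[0]}")
    zt = _to_complex(xt)
    zm = _to_complex(xm)
    ct, cm = zt.mean(), zm.mean()
    zt_c, zm_c = zt - ct, zm - cm
    nt, nm = np.linalg.norm(zt_c), np.linalg.norm(zm_c)
    if nt == 0.0 or nm == 0.0:
        raise DegenerateConfigurationError("OPA requires non-degenerate configurations")

    # inner product <moving, target> in complex form: sum(conj(zm) * zt)
    w = np.vdot(zm_c, zt_c)
    theta = float(np.angle(w))
    beta = float(np.abs(w) / nm**2) if allow_scaling else 1.0

    rot = _rotation_matrix(theta)
    aligned_z = beta * np.exp(1j * theta) * zm_c + ct
    translation = np.array([aligned_z.mean().real, aligned_z.mean().imag]) - (
        beta * (_rotation_matrix(theta) @ np.array([cm.real, cm.imag]))
    )
    aligned = (
        moving.with_coords(_to_real(aligned_z))
        if isinstance(moving, LandmarkConfiguration)
        else _to_real(aligned_z)
    )

    cos_rho = min(float(np.abs(w) / (nt * nm)), 1.0)
    distance = float(np.sqrt(max(2.0 - 2.0 * cos_rho, 0.0)))
    return OpaResult(rotation=rot, scale=beta, translation=translation, aligned=aligned, distance=distance)


# ---------------------------------------------------------------------------
# Generalized Procrustes Analysis
# ---------------------------------------------------------------------------


@dataclass
class SuperimpositionResult:
    """GPA output: aligned unit-size configurations and their consensus.

    ``aligned`` is (n, k, 2); every aligned specimen is centered with unit
    centroid size (partial-Procrustes convention, or full-Procrustes scales
    when fitted with ``scale='full'``).  ``centroid_sizes`` are the original
    pre-scaling sizes.  ``objective_trace`` records the sum of squared
    deviations from the consensus after each iteration and is nonincreasing.
    """

    aligned: np.ndarray
    consensus: np.ndarray  # (k, 2), centered, unit CS
    centroid_sizes: np.ndarray
    iterations: int
    objective_trace: np.ndarray
    converged: bool
    specimen_ids: list[str]
    dataset: LandmarkDataset | None = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def consensus_configuration(self) -> LandmarkConfiguration:
        return LandmarkConfiguration(specimen_id="<consensus>", coords=self.consensus.copy())


def _canonical_orientation(z: np.ndarray) -> complex:
    """Phase factor rotating a centered complex shape to canonical orientation.

    The orientation aligns the shape's principal axis (from the second
    complex moment sum(z^2)) with the x-axis; the residual two-fold ambiguity
    is resolved by making the first landmark with non-negligible projection
    onto the axis point in the +x direction.  Intrinsic to the shape, hence
    invariant to how the input was rotated.
    """
    m2 = np.sum(z**2)
    if np.abs(m2) > 1e-12 * np.vdot(z, z).real:
        phase = np.exp(-0.5j * np.angle(m2))
    else:
        phase = 1.0 + 0.0j  # (near-)circular shape: principal axis undefined
    zr = z * phase
    for val in zr:
        if abs(val.real) > 1e-9 * np.linalg.norm(zr):
            if val.real < 0:
                phase = -phase
            break
    return complex(phase)


def _stack_preshapes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n,k,2) coords -> (unit complex preshapes (n,k), centroid sizes (n,))."""
    Z = coords[..., 0] + 1j * coords[..., 1]
    Z = Z - Z.mean(axis=1, keepdims=True)
    sizes = np.linalg.norm(Z, axis=1)
    if np.any(sizes == 0.0):
        raise DegenerateConfigurationError("GPA input contains a degenerate configuration")
    return Z / sizes[:, None], sizes


def gpa(
    dataset: LandmarkDataset,
    tol: float = 1e-10,
    max_iter: int = 100,
    scale: str = "unit",
) -> SuperimpositionResult:
    """Generalized Procrustes Analysis.

    Iterates: rotate every unit preshape to the current consensus, recompute
    the consensus as the renormalized coordinate-wise mean, until the
    Frobenius change of the consensus falls below ``tol`` or ``max_iter`` is
    reached (the result is then flagged ``converged=False`` rather than
    raising).  With ``scale="full"`` each specimen additionally receives the
    least-squares optimal scale toward the consensus at the final step.
    """
    if len(dataset) < 2:
        raise ValueError("GPA requires at least 2 configurations")
    if scale not in ("unit", "full"):
        raise ValueError(f"unknown scaling convention {scale!r}")
    coords = dataset.coords_array()
    Z, sizes = _stack_preshapes(coords)
    n = Z.shape[0]

    # Permutation-invariant initialization: canonically orient each preshape,
    # then take the renormalized mean.
    Z0 = np.array([z * _canonical_orientation(z) for z in Z])
    c = Z0.mean(axis=0)
    c /= np.linalg.norm(c)

    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        w = Z @ np.conj(c)  # <z_i, c>
        phases = np.where(np.abs(w) > 0, np.conj(w) / np.maximum(np.abs(w), 1e-300), 1.0)
        Za = Z * phases[:, None]
        m = Za.mean(axis=0)
        c_new = m / np.linalg.norm(m)
        # objective after this full cycle: sum ||rot_i(z_i) - c_new||^2
        obj = float(2.0 * n - 2.0 * np.sum(np.abs(Z @ np.conj(c_new))))
        trace.append(obj)
        delta = float(np.linalg.norm(c_new - c))
        c = c_new
        if delta < tol:
            converged = True
            break

    phase_c = _canonical_orientation(c)
    c = c * phase_c
    w = Z @ np.conj(c)
    phases = np.where(np.abs(w) > 0, np.conj(w) / np.maximum(np.abs(w), 1e-300), 1.0)
    Za = Z * phases[:, None]
    if scale == "full":
        Za = Za * np.abs(w)[:, None]  # optimal least-squares scale toward consensus

    return SuperimpositionResult(
        aligned=np.stack([_to_real(z) for z in Za]),
        consensus=_to_real(c),
        centroid_sizes=sizes,
        iterations=iterations,
        objective_trace=np.array(trace),
        converged=converged,
        specimen_ids=dataset.specimen_ids,
        dataset=dataset,
    )


def tangent_coordinates(result: SuperimpositionResult) -> np.ndarray:
    """Project aligned preshapes onto the tangent plane at the consensus.

    Orthogonal projection ``v_i = x_i - (x_i . c) c`` of each flattened
    aligned configuration, with the consensus as the unit pole vector.  Rows
    are centered, orthogonal to the pole and (because each specimen is
    optimally rotated) to the rotation direction at the pole, so the matrix
    rank is at most 2k - 4.
    """
    X = result.aligned.reshape(result.n, -1)
    c = result.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    return X - np.outer(X @ c, c)


# ---------------------------------------------------------------------------
# Procrustes distances
# ---------------------------------------------------------------------------


def _cos_rho(za: np.ndarray, zb: np.ndarray) -> float:
    return min(float(np.abs(np.vdot(za, zb))), 1.0)


# cosines this close to 1 are rounding residue of identical preshapes; without
# snapping, sqrt(2 - 2*cos) would amplify 1e-16 of noise into ~1e-8 of distance
_COS_SNAP = 1.0 - 1e-15


def procrustes_distance(a, b, variant: str = "partial") -> float:
    """Shape distance between two configurations after optimal superimposition.

    partial  — minimized norm between unit-CS preshapes over rotations,
               equal to 2*sin(rho/2);
    full     — additionally minimized over the scaling of one preshape,
               equal to sin(rho);
    geodesic — the great-circle (Kendall shape space) distance rho itself.
    All variants are symmetric, zero on identical shapes, and invariant to
    similarity transforms of either argument.
    """
    if variant not in _DISTANCE_VARIANTS:
        raise ValueError(f"unknown distance variant {variant!r}")
    xa, xb = _coords_of(a), _coords_of(b)
    if xa.shape != xb.shape:
        raise ShapeMismatchError(f"landmark counts differ: {xa.shape[0]} vs {xb.shape[0]}")
    cos_rho = _cos_rho(_unit_preshape_z(xa), _unit_preshape_z(xb))
    return float(_distance_from_cos(cos_rho, variant))


def _distance_from_cos(cos_rho, variant: str):
    cos_rho = np.clip(cos_rho, 0.0, 1.0)
    cos_rho = np.where(cos_rho > _COS_SNAP, 1.0, cos_rho)
    if variant == "partial":
        return np.sqrt(np.maximum(2.0 - 2.0 * cos_rho, 0.0))
    if variant == "full":
        return np.sqrt(np.maximum(1.0 - cos_rho**2, 0.0))
    return np.arccos(cos_rho)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Procrustes distance matrix with specimen ids."""

    ids: list[str]
    values: np.ndarray
    variant: str

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.12g")

    def to_phylip(self, path) -> None:
        lines = [str(len(self.ids))]
        for sid, row in zip(self.ids, self.values):
            lines.append(sid + "  " + " ".join(f"{v:.10f}" for v in row))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def distance_matrix(dataset: LandmarkDataset, variant: str = "partial") -> DistanceMatrix:
    """All pairwise Procrustes distances of a dataset (vectorized)."""
    if variant not in _DISTANCE_VARIANTS:
        raise ValueError(f"unknown distance variant {variant!r}")
    if len(dataset) < 2:
        raise ValueError("distance matrix requires at least 2 configurations")
    Z, _ = _stack_preshapes(dataset.coords_array())
    G = np.abs(np.conj(Z) @ Z.T)  # |<z_i, z_j>|
    D = _distance_from_cos(G, variant)
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(ids=dataset.specimen_ids, values=D, variant=variant)
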