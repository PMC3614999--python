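"""Generalized Procrustes analysis and thin-plate-spline shape variables.

The shape pipeline mirrors standard landmark-based geometric morphometrics:
configurations of k 2-D landmarks are translated to a common centroid,
scaled to unit centroid size and rotated to minimise summed squared
landmark distances to an iteratively refined consensus (partial Procrustes
fitting: no secondary scaling during rotation, reflections disallowed).
Residuals from the consensus are then re-expressed as partial-warp scores:
projections onto the eigenvectors of the thin-plate-spline bending-energy
matrix of the consensus, plus a two-dimensional uniform (affine) component
estimated as the orthogonal complement of the non-uniform space within the
affine subspace (Rohlf–Bookstein complement method).  With the orthonormal
(alpha = 0) basis used here the resulting W' score matrix is an isometric
rotation of Procrustes residual space, so downstream ordinations are
unaffected by the change of basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class DegenerateConfigurationError(ValueError):
    pass


class ShapeMismatchError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg, residual):
        super().__init__(msg)
        self.residual = residual


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmark set."""

    specimen_id: str
    coords: np.ndarray  # (k, 2)
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (k, 2)")
        if self.coords.shape[0] < 3:
            raise ValueError("need at least 3 landmarks")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


def centroid_size(config) -> float:
    """Square root of summed squared landmark distances from their centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs <= 0:
        raise DegenerateConfigurationError("all landmarks coincide; centroid size is zero")
    return cs


def _normalize(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    return centred / centroid_size(centred)


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||a - b R||_F (applied as b @ R).

    Reflections are never returned (all specimens are same-side lateral
    views), so det(R) is forced to +1.
    """
    h = b.T @ a
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return u @ s @ vt


@dataclass
class AlignedShapes:
    """GPA output: aligned specimen coordinates, consensus, original sizes."""

    specimen_ids: list
    taxa: list
    coords: np.ndarray  # (n, k, 2) aligned, unit centroid size, centred
    consensus: np.ndarray  # (k, 2) unit centroid size, centred
    centroid_sizes: np.ndarray  # (n,) original sizes
    n_iterations: int = 0

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def residuals(self) -> np.ndarray:
        """Per-specimen deviations from the consensus, shape (n, k, 2)."""
        return self.coords - self.consensus[None]

    def to_dict(self) -> dict:
        return {
            "specimen_ids": self.specimen_ids,
            "taxa": self.taxa,
            "coords": self.coords,
            "consensus": self.consensus,
            "centroid_sizes": self.centroid_sizes,
            "n_iterations": self.n_iterations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlignedShapes":
        return cls(
            specimen_ids=list(d["specimen_ids"]),
            taxa=list(d["taxa"]),
            coords=np.asarray(d["coords"], float),
            consensus=np.asarray(d["consensus"], float),
            centroid_sizes=np.asarray(d["centroid_sizes"], float),
            n_iterations=int(d.get("n_iterations", 0)),
        )


def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Rotation aligning the consensus major axis with x, with fixed signs.

    GPA solutions are unique only up to a global rotation; fixing the
    orientation makes the output invariant to input order.  The sign of the
    major axis is chosen so the landmark with the largest |x| has x > 0;
    the minor axis sign then follows from det = +1.
    """
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    rot = evecs[:, ::-1]  # columns: major, minor axis
    if np.linalg.det(rot) < 0:
        rot[:, 1] = -rot[:, 1]
    x = consensus @ rot[:, 0]
    if x[np.argmax(np.abs(x))] < 0:
        rot = rot @ np.diag([-1.0, -1.0])  # keeps det = +1
    return rot


def gpa_align(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapes:
    """Iterative generalized Procrustes superimposition.

    Each configuration is centred, scaled to unit centroid size and rotated
    onto the current consensus by the least-squares rotation; the consensus
    is the coordinate-wise mean re-normalised to unit centroid size.
    Iteration stops when the consensus moves by less than ``tol`` (root
    summed squared coordinate change).
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ShapeMismatchError(f"mixed landmark counts: {sorted(ks)}")
    sizes = np.array([centroid_size(c) for c in configs])
    shapes = np.stack([_normalize(c.coords) for c in configs])
    consensus = shapes[0].copy()
    n_it = 0
    for n_it in range(1, max_iter + 1):
        rotated = np.stack([s @ optimal_rotation(consensus, s) for s in shapes])
        new_consensus = _normalize(rotated.mean(axis=0))
        # consensus is defined up to rotation; compare after aligning old onto new
        old_aligned = consensus @ optimal_rotation(new_consensus, consensus)
        change = np.sqrt(((new_consensus - old_aligned) ** 2).sum())
        shapes = rotated
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})",
            residual=change,
        )
    rot = _canonical_orientation(consensus)
    consensus = consensus @ rot
    shapes = np.stack([(s @ rot) @ optimal_rotation(consensus, s @ rot) for s in shapes])
    return AlignedShapes(
        specimen_ids=[c.specimen_id for c in configs],
        taxa=[c.taxon for c in configs],
        coords=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        n_iterations=n_it,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two centred unit-size shapes.

    Square root of summed squared coordinate differences after optimally
    rotating ``b`` onto ``a``; symmetric in its arguments.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"landmark counts differ: {a.shape} vs {b.shape}")
    b_rot = b @ optimal_rotation(a, b)
    return float(np.sqrt(((a - b_rot) ** 2).sum()))


# ---------------------------------------------------------------------------
# Thin-plate spline machinery


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2 with U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


def tps_kernel_matrix(points: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    return _tps_kernel(d2)


def bending_energy_matrix(consensus: np.ndarray) -> np.ndarray:
    """The k x k bending-energy matrix: upper-left block of L^-1.

    L = [[K, Q], [Q^T, 0]] with K the TPS kernel matrix over the consensus
    landmarks and Q = [1 | x | y].  Its upper-left k x k block penalises
    non-affine deformation; the affine subspace spans its null space.
    """
    consensus = np.asarray(consensus, float)
    k = consensus.shape[0]
    d2 = ((consensus[:, None, :] - consensus[None, :, :]) ** 2).sum(axis=2)
    off = d2 + np.eye(k)  # guard the log on the diagonal
    if np.min(off) <= 0:
        raise DegenerateConfigurationError("coincident landmarks make the TPS kernel singular")
    kmat = tps_kernel_matrix(consensus)
    q = np.hstack([np.ones((k, 1)), consensus])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    try:
        linv = np.linalg.inv(lmat)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError("singular TPS system") from exc
    be = linv[:k, :k]
    return (be + be.T) / 2.0


@dataclass
class BendingEnergyBasis:
    """Eigenstructure of the consensus bending-energy matrix.

    ``principal_warps`` holds all k eigenvectors (columns) sorted by
    ascending eigenvalue; the first three eigenvalues are zero (the affine
    null space for 2-D data).  ``uniform_basis`` holds two orthonormal
    2k-vectors spanning the uniform shape directions: the part of the
    affine subspace orthogonal to translation, rotation and scaling at the
    consensus.
    """

    consensus: np.ndarray
    principal_warps: np.ndarray  # (k, k) columns ascending by eigenvalue
    bending_eigenvalues: np.ndarray  # (k,)
    uniform_basis: np.ndarray  # (2k, 2)

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    def nonuniform_warps(self) -> np.ndarray:
        """The k-3 eigenvectors with positive bending energy, (k, k-3)."""
        return self.principal_warps[:, 3:]


def _uniform_complement(consensus: np.ndarray) -> np.ndarray:
    """Two orthonormal uniform directions in the 2k coordinate space.

    Within the 6-dimensional affine subspace span{1, x, y} (x) {e_x, e_y},
    remove the two translations, the scaling direction (the consensus
    itself) and the rotation direction (consensus rotated 90 degrees); the
    orthonormal basis of what remains is the uniform component.
    """
    k = consensus.shape[0]
    ones = np.ones(k)
    x, y = consensus[:, 0], consensus[:, 1]
    zeros = np.zeros(k)

    def flat(xpart, ypart):
        return np.stack([xpart, ypart], axis=1).reshape(-1)

    affine = np.stack(
        [
            flat(ones, zeros),
            flat(zeros, ones),
            flat(x, zeros),
            flat(y, zeros),
            flat(zeros, x),
            flat(zeros, y),
        ],
        axis=1,
    )  # (2k, 6)
    remove = np.stack(
        [
            flat(ones, zeros),
            flat(zeros, ones),
            flat(x, y),  # scaling
            flat(-y, x),  # rotation
        ],
        axis=1,
    )
    qa, _ = np.linalg.qr(affine)
    qr_, _ = np.linalg.qr(remove)
    proj = qa - qr_ @ (qr_.T @ qa)  # affine basis with removed directions projected out
    u, s, _ = np.linalg.svd(proj, full_matrices=False)
    keep = s > 1e-9
    basis = u[:, keep]
    if basis.shape[1] != 2:
        raise DegenerateConfigurationError(
            f"uniform complement has dimension {basis.shape[1]}, expected 2"
        )
    return basis


def bending_energy_basis(consensus: np.ndarray) -> BendingEnergyBasis:
    """Eigen-decompose the bending-energy matrix of a consensus shape."""
    consensus = np.asarray(consensus, float)
    be = bending_energy_matrix(consensus)
    evals, evecs = np.linalg.eigh(be)
    order = np.argsort(evals)
    evals = evals[order]
    evecs = evecs[:, order]
    evals[np.abs(evals) < 1e-9] = 0.0
    return BendingEnergyBasis(
        consensus=consensus,
        principal_warps=evecs,
        bending_eigenvalues=evals,
        uniform_basis=_uniform_complement(consensus),
    )


@dataclass
class PartialWarpMatrix:
    """The W' shape-variable block: partial-warp + uniform scores."""

    specimen_ids: list
    taxa: list
    scores: np.ndarray  # (n, 2k-4) with uniform, (n, 2k-6) without
    column_labels: list
    include_uniform: bool = True

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def to_dict(self) -> dict:
        return {
            "specimen_ids": self.specimen_ids,
            "taxa": self.taxa,
            "scores": self.scores,
            "column_labels": self.column_labels,
            "include_uniform": self.include_uniform,
        }


def _score_basis(basis: BendingEnergyBasis, include_uniform: bool) -> tuple:
    """Orthonormal 2k-space basis columns and their labels."""
    k = basis.k
    warps = basis.nonuniform_warps()  # (k, k-3)
    cols = []
    labels = []
    for j in range(warps.shape[1]):
        e = warps[:, j]
        ex = np.stack([e, np.zeros(k)], axis=1).reshape(-1)
        ey = np.stack([np.zeros(k), e], axis=1).reshape(-1)
        cols.extend([ex, ey])
        labels.extend([f"pw{j + 1}x", f"pw{j + 1}y"])
    if include_uniform:
        cols.extend([basis.uniform_basis[:, 0], basis.uniform_basis[:, 1]])
        labels.extend(["uniform1", "uniform2"])
    return np.stack(cols, axis=1), labels


def partial_warp_scores(
    aligned: AlignedShapes,
    basis: Optional[BendingEnergyBasis] = None,
    include_uniform: bool = True,
) -> PartialWarpMatrix:
    """Project Procrustes residuals onto the partial-warp + uniform basis.

    With the orthonormal basis convention the per-specimen sum of squared
    scores equals the squared Procrustes residual norm (up to the tiny
    out-of-tangent component of the residual).
    """
    if basis is None:
        basis = bending_energy_basis(aligned.consensus)
    if basis.consensus.shape != aligned.consensus.shape or not np.allclose(
        basis.consensus, aligned.consensus, atol=1e-9
    ):
        raise ValueError("basis was built from a different consensus")
    bmat, labels = _score_basis(basis, include_uniform)
    resid = aligned.residuals().reshape(aligned.n, -1)  # (n, 2k)
    scores = resid @ bmat
    return PartialWarpMatrix(
        specimen_ids=list(aligned.specimen_ids),
        taxa=list(aligned.taxa),
        scores=scores,
        column_labels=labels,
        include_uniform=include_uniform,
    )


def reconstruct_residuals(warps: PartialWarpMatrix, basis: BendingEnergyBasis) -> np.ndarray:
    """Invert :func:`partial_warp_scores`: scores back to (n, k, 2) residuals."""
    bmat, _ = _score_basis(basis, warps.include_uniform)
    flat = warps.scores @ bmat.T
    return flat.reshape(warps.n, basis.k, 2)


def tps_warp_grid(
    consensus: np.ndarray,
    target: np.ndarray,
    grid_shape: tuple = (20, 20),
    padding: float = 0.1,
) -> tuple:
    """Apply the consensus-to-target TPS interpolant to a rectangular grid.

    Returns ``(grid, warped)``: the (nx*ny, 2) source grid covering the
    consensus bounding box expanded by ``padding`` (fraction of the range),
    and its image under the fitted deformation.  The interpolant is exact
    at the consensus landmarks.
    """
    consensus = np.asarray(consensus, float)
    target = np.asarray(target, float)
    if consensus.shape != target.shape:
        raise ShapeMismatchError("consensus and target must share landmark count")
    k = consensus.shape[0]
    kmat = tps_kernel_matrix(consensus)
    q = np.hstack([np.ones((k, 1)), consensus])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        sol = np.linalg.solve(lmat, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError("singular TPS system") from exc
    w, a = sol[:k], sol[k:]
    lo = consensus.min(axis=0)
    hi = consensus.max(axis=0)
    span = hi - lo
    lo = lo - padding * span
    hi = hi + padding * span
    nx, ny = grid_shape
    gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], nx), np.linspace(lo[1], hi[1], ny))
    grid = np.stack([gx.reshape(-1), gy.reshape(-1)], axis=1)
    d2 = ((grid[:, None, :] - consensus[None, :, :]) ** 2).sum(axis=2)
    u = _tps_kernel(d2)
    warped = np.hstack([np.ones((grid.shape[0], 1)), grid]) @ a + u @ w
    return grid, warped
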