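"""Three-dimensional thin-plate-spline fitting, evaluation and bending energy.

The interpolant ``h: R^3 -> R^3`` decomposes into a radial non-affine part and
an affine part,

    h(p) = Psi(p) K + [p, 1] Gamma,

where ``Psi_w(p) = ||p - source_w||`` is the 3D TPS kernel (U(r) = r, not the
2D r^2 log r), ``K`` holds the non-affine warping coefficients and ``Gamma``
is a homogeneous affine transform.  Coefficients come from the bordered
linear system

    [ Psi - beta*I   P ] [ K     ]   [ D ]
    [ P^T            0 ] [ Gamma ] = [ 0 ],

with ``P`` the (M, 4) homogeneous source matrix and ``D`` the destinations.
At ``beta = 0`` the map interpolates exactly; ``beta > 0`` trades exactness
for smoothness.  The bending energy (the integral of squared second
derivatives that the spline minimizes) is evaluated in closed form as a
quadratic form in the non-affine coefficients — with the kernel r this form
is negative semidefinite on the constrained subspace, so the energy is its
negation.  It is zero exactly for affine maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

DUPLICATE_TOL = 1e-9


class TPSFitError(ValueError):
    """Raised for singular or rank-deficient TPS systems."""


def kernel_vector(query: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Euclidean distances from one query point to each control point."""
    query = np.asarray(query, float).reshape(3)
    return np.linalg.norm(np.asarray(controls, float) - query, axis=1)


def kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise-distance kernel block Psi with Psi_wl = ||a_w - b_l||."""
    return cdist(np.asarray(a, float), np.asarray(b, float))


def _homogeneous(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, float)
    return np.hstack([points, np.ones((len(points), 1))])


@dataclass
class TPSModel:
    """A fitted 3D thin-plate spline from ``source_points`` to ``destination_points``.

    ``nonaffine_K`` is (M, 4) and ``affine_gamma`` (4, 4), both acting on
    homogeneous coordinates; the 4th output column is identically the
    homogeneous 1 so the affine block's last column is (0, 0, 0, 1).
    """

    source_points: np.ndarray
    destination_points: np.ndarray
    nonaffine_K: np.ndarray
    affine_gamma: np.ndarray
    beta: float = 0.0
    bending_energy: float = field(default=0.0)


def fit_tps(source: np.ndarray, destination: np.ndarray, beta: float = 0.0) -> TPSModel:
    """Fit the spline mapping ``source`` onto ``destination``.

    Requires M >= 5 pairwise-distinct, non-coplanar source points so the
    affine part has full rank.  ``beta >= 0`` adds smoothing regularization
    on the kernel diagonal; at 0 the interpolation conditions hold exactly.
    """
    source = np.asarray(source, float)
    destination = np.asarray(destination, float)
    if source.shape != destination.shape or source.ndim != 2 or source.shape[1] != 3:
        raise TPSFitError("source and destination must both be (M, 3)")
    m = len(source)
    if m < 5:
        raise TPSFitError(f"need at least 5 control points, got {m}")
    if beta < 0:
        raise TPSFitError("beta must be >= 0")

    psi = kernel_matrix(source, source)
    off_diag = psi.copy()
    np.fill_diagonal(off_diag, np.inf)
    if off_diag.min() < DUPLICATE_TOL:
        w, l = np.unravel_index(np.argmin(off_diag), psi.shape)
        raise TPSFitError(f"duplicate source points {w} and {l} (within {DUPLICATE_TOL} mm)")

    p = _homogeneous(source)
    if np.linalg.matrix_rank(p, tol=1e-9 * max(1.0, np.abs(source).max())) < 4:
        raise TPSFitError("source points are coplanar: affine part rank-deficient")

    sys_mat = np.zeros((m + 4, m + 4))
    # smoothing enters as -beta*I: the distance kernel is conditionally
    # *negative* definite, so the energy penalty is the negated quadratic form
    sys_mat[:m, :m] = psi - beta * np.eye(m)
    sys_mat[:m, m:] = p
    sys_mat[m:, :m] = p.T
    rhs = np.zeros((m + 4, 4))
    rhs[:m] = _homogeneous(destination)
    try:
        sol = np.linalg.solve(sys_mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise TPSFitError(f"singular TPS system: {exc}") from exc

    k = sol[:m]
    gamma = sol[m:]
    model = TPSModel(source, destination, k, gamma, beta=beta)
    model.bending_energy = bending_energy(model)
    return model


def warp_points(model: TPSModel, queries: np.ndarray) -> np.ndarray:
    """Evaluate the fitted map at arbitrary query points."""
    queries = np.asarray(queries, float)
    single = queries.ndim == 1
    queries = np.atleast_2d(queries)
    psi = kernel_matrix(queries, model.source_points)
    out = psi @ model.nonaffine_K + _homogeneous(queries) @ model.affine_gamma
    result = out[:, :3]
    return result[0] if single else result


def bending_energy(model: TPSModel) -> float:
    """Closed-form bending energy: -trace(K_xyz^T Psi K_xyz), clipped at 0.

    The kernel U(r) = r is conditionally negative definite, so the quadratic
    form is non-positive on the subspace the bordered system confines K to;
    its negation is the non-negative energy, zero iff the map is affine.
    """
    psi = kernel_matrix(model.source_points, model.source_points)
    kxyz = model.nonaffine_K[:, :3]
    return max(0.0, -float(np.trace(kxyz.T @ psi @ kxyz)))


def bending_energy_matrix(control_points: np.ndarray) -> np.ndarray:
    """Positive-semidefinite bending-energy matrix B of a control configuration.

    B is the negated upper-left (M, M) block of the inverse bordered system
    matrix; the energy of a spline mapping the controls onto targets ``Y``
    is ``sum_d Y[:, d]^T B Y[:, d]``.  Used as the metric that semi-landmark
    sliding minimizes.
    """
    control_points = np.asarray(control_points, float)
    m = len(control_points)
    psi = kernel_matrix(control_points, control_points)
    p = _homogeneous(control_points)
    sys_mat = np.zeros((m + 4, m + 4))
    sys_mat[:m, :m] = psi
    sys_mat[:m, m:] = p
    sys_mat[m:, :m] = p.T
    try:
        inv = np.linalg.inv(sys_mat)
    except np.linalg.LinAlgError as exc:
        raise TPSFitError(f"singular bending-energy system: {exc}") from exc
    b = -inv[:m, :m]
    return (b + b.T) / 2.0
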