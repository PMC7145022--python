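"""Template construction and transfer of sliding surface semi-landmarks.

A craniofacial template carries 20 fixed anatomical anchor landmarks plus a
cloud of surface semi-landmarks grown outward from the pronasale (nose tip).
For each target head the template is warped onto the target through a
thin-plate spline fitted on the anchor pairs, the semi-landmarks are
projected onto the target surface, and then slid along local tangent planes
in the direction that minimizes the TPS bending energy relative to the
template, re-projecting after every cycle.  Six cycles with a geometrically
decaying step (100% down to 5%) give geometrically homologous landmarks that
downstream analyses treat exactly like anatomical landmarks.  Anchors never
slide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist

from .geometry_io import LandmarkConfiguration, SurfaceMesh
from .tps import bending_energy_matrix, fit_tps, warp_points

log = logging.getLogger(__name__)

SURFACE_TOL = 1e-6  # mm; "on the surface" means within this distance


class TemplateError(ValueError):
    """Template construction failed (capacity, off-surface anchors, ...)."""


class SlidingError(RuntimeError):
    """Semi-landmark sliding hit a degenerate configuration."""


@dataclass
class TemplateModel:
    """Template mesh with its 20 anchors + surface semi-landmarks."""

    mesh: SurfaceMesh
    landmarks: LandmarkConfiguration
    seed_anchor: str = "pr"
    spacing_radius: float = 1.5


@dataclass
class SlidingTrace:
    """Per-cycle bookkeeping of one sliding run.

    ``energies`` holds the bending energy relative to the template after each
    cycle; ``initial_energy`` the energy right after transfer (E_i), so the
    final entry is E_f.  ``step_fractions`` is the decay schedule actually
    applied.
    """

    initial_energy: float
    energies: list[float] = field(default_factory=list)
    step_fractions: list[float] = field(default_factory=list)
    final_landmarks: LandmarkConfiguration | None = None

    @property
    def final_energy(self) -> float:
        return self.energies[-1] if self.energies else self.initial_energy


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _mesh_query_cache(mesh: SurfaceMesh):
    """KD-tree over triangle centroids + geometry arrays, cached on the mesh."""
    cached = mesh.__dict__.get("_closest_cache")
    if cached is None:
        tris = mesh.vertices[mesh.triangles]  # (T, 3, 3)
        centroids = tris.mean(axis=1)
        radius = np.linalg.norm(tris - centroids[:, None, :], axis=2).max()
        cached = (cKDTree(centroids), tris, float(radius))
        mesh.__dict__["_closest_cache"] = cached
    return cached


def _closest_among(tris: np.ndarray, cand: np.ndarray, queries: np.ndarray):
    """Best point-to-triangle hit per query over per-query candidate triangles."""
    nq, k = cand.shape
    flat_tris = tris[cand.ravel()]
    flat_q = np.repeat(queries, k, axis=0)
    pts = trimesh.triangles.closest_point(flat_tris, flat_q)
    d = np.linalg.norm(pts - flat_q, axis=1).reshape(nq, k)
    best = np.argmin(d, axis=1)
    rows = np.arange(nq)
    return (pts.reshape(nq, k, 3)[rows, best],
            d[rows, best],
            cand[rows, best])


def closest_point_on_mesh(query, mesh: SurfaceMesh):
    """Nearest point on the triangulated surface.

    Returns ``(point, distance, triangle_index)`` minimizing the Euclidean
    distance over all triangles (point-to-triangle with barycentric clamping).
    A KD-tree over triangle centroids prefilters candidates; a widened second
    pass guarantees the true minimizer cannot hide beyond the candidate set.
    """
    query = np.asarray(query, float)
    single = query.ndim == 1
    queries = np.atleast_2d(query)
    tree, tris, radius = _mesh_query_cache(mesh)
    n_tri = len(tris)
    k = min(32, n_tri)
    d_cent, cand = tree.query(queries, k=k)
    cand = cand.reshape(len(queries), k)
    pts, dists, tids = _closest_among(tris, cand, queries)
    # a triangle whose centroid is farther than d* + radius cannot beat d*
    unsafe = dists + radius > d_cent[:, -1] if k < n_tri else np.zeros(len(queries), bool)
    for i in np.where(unsafe)[0]:
        ball = tree.query_ball_point(queries[i], dists[i] + radius + 1e-9)
        if len(ball) > k:
            p, d, t = _closest_among(tris, np.asarray(ball)[None, :], queries[i:i + 1])
            pts[i], dists[i], tids[i] = p[0], d[0], t[0]
    if single:
        return pts[0], float(dists[0]), int(tids[0])
    return pts, dists, tids


def _vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    # area-weighted vertex normals (trimesh weights incident faces by area)
    return np.asarray(mesh.as_trimesh().vertex_normals, float)


def surface_normal(mesh: SurfaceMesh, point, triangle_index: int | None = None) -> np.ndarray:
    """Smoothly varying surface normal at an on-surface point.

    Barycentric interpolation of area-weighted vertex normals over the
    triangle containing the point.
    """
    point = np.asarray(point, float)
    if triangle_index is None:
        _, dist, triangle_index = closest_point_on_mesh(point, mesh)
        if dist > 100 * SURFACE_TOL:
            raise TemplateError(f"point {point} is {dist:.3g} mm off the surface")
    tri = mesh.triangles[triangle_index]
    corners = mesh.vertices[tri]
    bary = trimesh.triangles.points_to_barycentric(corners[None], point[None])[0]
    normal = (bary[:, None] * _vertex_normals(mesh)[tri]).sum(axis=0)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise TemplateError(f"degenerate surface normal at {point}")
    return normal / norm


def tangent_frame(mesh: SurfaceMesh, point, triangle_index: int | None = None):
    """Two orthonormal tangent vectors at an on-surface point."""
    n = surface_normal(mesh, point, triangle_index)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


def _batch_tangent_frames(mesh: SurfaceMesh, points: np.ndarray, tids: np.ndarray) -> np.ndarray:
    """Tangent frames for many on-surface points; returns (n, 2, 3)."""
    vn = _vertex_normals(mesh)
    tris = mesh.triangles[tids]
    corners = mesh.vertices[tris]
    bary = trimesh.triangles.points_to_barycentric(corners, points)
    normals = np.einsum("ik,ikd->id", bary, vn[tris])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise SlidingError("degenerate surface normal during sliding")
    normals /= norms
    helper = np.where(np.abs(normals[:, :1]) < 0.9,
                      np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
    t1 = np.cross(normals, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)
    return np.stack([t1, t2], axis=1)


# ---------------------------------------------------------------------------
# Template generation
# ---------------------------------------------------------------------------

def generate_template_semilandmarks(
    mesh: SurfaceMesh,
    anchors: LandmarkConfiguration,
    n: int = 480,
    radius: float = 1.5,
    seed: int | np.random.Generator = 0,
    seed_anchor: str = "pr",
    relax_iters: int = 3,
) -> TemplateModel:
    """Spread ``n`` semi-landmarks over the mesh surface from the seed anchor.

    Random surface candidates are drawn first, then uniformized: growth by
    farthest-point selection starting at the seed anchor (the pronasale),
    followed by tangent-plane repulsion relaxation with re-projection.  The
    result keeps every point on the surface and pairwise spacing at least
    ``0.5 * radius``.  Deterministic for a given seed.
    """
    if n < 1:
        raise TemplateError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mesh.validate()
    seed_idx = anchors.anchor_index(seed_anchor)
    seed_point, seed_dist, _ = closest_point_on_mesh(anchors.points[seed_idx], mesh)
    if seed_dist > 1e-3:
        raise TemplateError(f"seed anchor {seed_anchor!r} lies {seed_dist:.3g} mm off the mesh")

    min_spacing = 0.5 * radius
    total_area = mesh.triangle_areas().sum()
    # each point excludes a disc of radius min_spacing/2; refuse impossible requests
    if n * np.pi * (min_spacing / 2.0) ** 2 > total_area:
        raise TemplateError(
            f"surface area {total_area:.1f} mm^2 cannot hold {n} points at spacing {min_spacing} mm"
        )

    n_candidates = max(20 * n, 2000)
    candidates, _ = trimesh.sample.sample_surface(
        mesh.as_trimesh(), n_candidates, seed=int(rng.integers(2**31 - 1))
    )
    candidates = np.vstack([seed_point, candidates])

    # farthest-point growth from the seed
    chosen = [0]
    dist_to_set = np.linalg.norm(candidates - candidates[0], axis=1)
    while len(chosen) < n:
        nxt = int(np.argmax(dist_to_set))
        if dist_to_set[nxt] < min_spacing:
            raise TemplateError(
                f"only {len(chosen)} of {n} semi-landmarks placeable at spacing {min_spacing} mm"
            )
        chosen.append(nxt)
        dist_to_set = np.minimum(dist_to_set, np.linalg.norm(candidates - candidates[nxt], axis=1))
    points = candidates[chosen]

    if n > 1:
        # the seed point starts exactly on the pronasale anchor; nudge it along
        # the surface so the combined 500-point TPS system stays non-singular
        t1, _ = tangent_frame(mesh, points[0])
        points[0], _, _ = closest_point_on_mesh(points[0] + min_spacing * t1, mesh)

    # tangent repulsion relaxation, re-projected each sweep
    for _ in range(relax_iters if n > 2 else 0):
        tree = cKDTree(points)
        k = min(7, n)
        dists, idx = tree.query(points, k=k)
        moved = points.copy()
        for i in range(n):
            neigh = idx[i, 1:]
            d = dists[i, 1:]
            valid = d > 1e-12
            if not valid.any():
                continue
            rep = ((points[i] - points[neigh[valid]]) / d[valid, None] ** 2).sum(axis=0)
            step = 0.15 * d[valid].min()
            norm = np.linalg.norm(rep)
            if norm > 1e-12:
                moved[i] = points[i] + rep / norm * step
        proj, _, _ = closest_point_on_mesh(moved, mesh)
        # accept the sweep only if it keeps the spacing contract
        if len(proj) < 2 or pdist(proj).min() >= min_spacing:
            points = proj

    if n > 1 and pdist(points).min() < min_spacing:
        raise TemplateError("relaxation failed to maintain the minimum spacing")

    # projection can land a semi-landmark exactly on an anchor vertex; nudge it
    # along the surface so the combined configuration stays pairwise distinct
    if n > 1:
        d_anchor = cdist(points, anchors.points)
        for i in np.where(d_anchor.min(axis=1) < 1e-6)[0]:
            t1, _ = tangent_frame(mesh, points[i])
            points[i], _, _ = closest_point_on_mesh(points[i] + min_spacing * t1, mesh)
        all_points = np.vstack([anchors.points, points])
        if pdist(all_points).min() < 1e-9:
            raise TemplateError("a semi-landmark coincides with an anchor landmark")
    all_points = np.vstack([anchors.points, points])
    landmarks = LandmarkConfiguration(all_points, anchor_count=len(anchors.points),
                                      labels=list(anchors.labels))
    return TemplateModel(mesh=mesh, landmarks=landmarks, seed_anchor=seed_anchor,
                         spacing_radius=radius)


# ---------------------------------------------------------------------------
# Transfer and sliding
# ---------------------------------------------------------------------------

def step_schedule(cycles: int = 6, start: float = 1.0, end: float = 0.05) -> np.ndarray:
    """Geometric decay of the sliding step fraction from ``start`` to ``end``."""
    if cycles == 1:
        return np.array([start])
    ratio = (end / start) ** (1.0 / (cycles - 1))
    return start * ratio ** np.arange(cycles)


def _check_anchor_labels(template: TemplateModel, target_anchors: LandmarkConfiguration) -> None:
    if list(target_anchors.labels) != list(template.landmarks.labels):
        raise ValueError(
            "target anchor labels do not match template anchors: "
            f"{target_anchors.labels} vs {template.landmarks.labels}"
        )


def transfer_template(
    template: TemplateModel,
    target_mesh: SurfaceMesh,
    target_anchors: LandmarkConfiguration,
) -> LandmarkConfiguration:
    """Warp template semi-landmarks to a target through its anchor TPS.

    The spline is fitted on the 20 anchor pairs (the anchors establish the
    warping field), semi-landmarks are pushed through it and projected onto
    the target surface by closest-point search.
    """
    _check_anchor_labels(template, target_anchors)
    model = fit_tps(template.landmarks.anchors, target_anchors.anchors, beta=0.0)
    warped = warp_points(model, template.landmarks.semilandmarks)
    projected, dists, _ = closest_point_on_mesh(warped, target_mesh)
    limit = 10.0 * template.spacing_radius
    far = np.where(dists > limit)[0]
    if far.size:
        log.warning("projection moved %d semi-landmarks farther than %.1f mm: ids %s",
                    far.size, limit, far.tolist())
    points = np.vstack([target_anchors.anchors, projected])
    return LandmarkConfiguration(points, anchor_count=target_anchors.anchor_count,
                                 labels=list(target_anchors.labels))


def _config_energy(bmat: np.ndarray, config: np.ndarray) -> float:
    return max(0.0, float(np.einsum("id,ij,jd->", config, bmat, config)))


def slide_semilandmarks(
    template: TemplateModel,
    target_mesh: SurfaceMesh,
    target_anchors: LandmarkConfiguration,
    cycles: int = 6,
    step_start: float = 1.0,
    step_end: float = 0.05,
) -> SlidingTrace:
    """Relax transferred semi-landmarks by bending-energy-minimizing sliding.

    Each cycle: tangent frames at the current semi-landmarks; one dense
    symmetric solve for the tangent displacements minimizing the template
    bending-energy quadratic form; displacements scaled by the decaying step
    fraction; re-projection onto the target surface.  Anchors never move.
    """
    current = transfer_template(template, target_mesh, target_anchors)
    na = current.anchor_count
    x = template.landmarks.points  # reference configuration
    bmat = bending_energy_matrix(x)

    schedule = step_schedule(cycles, step_start, step_end)
    trace = SlidingTrace(initial_energy=_config_energy(bmat, current.points))

    y = current.points.copy()
    for frac in schedule:
        if len(y) > 1 and pdist(y).min() < 1e-9:
            d = np.linalg.norm(y[:, None] - y[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise SlidingError(f"semi-landmarks {i} and {j} collided during sliding")
        _, _, tids = closest_point_on_mesh(y[na:], target_mesh)
        frames = _batch_tangent_frames(target_mesh, y[na:], tids)  # (ks, 2, 3)

        grad = bmat @ y  # (k, 3); gradient/2 of the energy wrt coordinates
        rhs = -np.einsum("iad,id->ia", frames, grad[na:]).ravel()
        b_ss = bmat[na:, na:]
        gram = np.einsum("iad,jbd->iajb", frames, frames)
        hess = (gram * b_ss[:, None, :, None]).reshape(rhs.size, rhs.size)
        hess[np.diag_indices_from(hess)] += 1e-10 * max(1.0, np.trace(hess) / rhs.size)
        try:
            t = np.linalg.solve(hess, rhs)
        except np.linalg.LinAlgError as exc:
            raise SlidingError(f"singular sliding system: {exc}") from exc
        disp = np.einsum("ia,iad->id", t.reshape(-1, 2), frames)
        # the tangent step is optimal in the tangent planes, but re-projection
        # can raise the energy; backtrack the step until the cycle is
        # non-increasing (keeping the previous configuration as a last resort)
        prev_energy = trace.energies[-1] if trace.energies else trace.initial_energy
        f_try = float(frac)
        accepted, accepted_energy = y, prev_energy
        for _ in range(4):
            cand = y.copy()
            cand[na:] += f_try * disp
            cand[na:], _, _ = closest_point_on_mesh(cand[na:], target_mesh)
            e = _config_energy(bmat, cand)
            if e <= prev_energy * (1 + 1e-12):
                accepted, accepted_energy = cand, e
                break
            f_try *= 0.5
        y = accepted

        trace.step_fractions.append(float(frac))
        trace.energies.append(accepted_energy)

    trace.final_landmarks = LandmarkConfiguration(y, anchor_count=na,
                                                  labels=list(target_anchors.labels))
    return trace
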