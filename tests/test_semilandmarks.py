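"""Template spreading, closest-point projection, tangent frames, sliding."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import morphohead as mh
from conftest import random_rotation
from morphohead.semilandmarks import TemplateError, step_schedule, surface_normal
from morphohead.synthetic import HeadParams


def brute_force_closest(query, mesh):
    """Independent oracle: exhaustive point-to-triangle minimization."""
    best_d, best_p = np.inf, None
    for tri in mesh.triangles:
        a, b, c = mesh.vertices[tri]
        # Ericson-style closest point on triangle
        ab, ac, ap = b - a, c - a, query - a
        d1, d2 = ab @ ap, ac @ ap
        if d1 <= 0 and d2 <= 0:
            p = a
        else:
            bp = query - b
            d3, d4 = ab @ bp, ac @ bp
            if d3 >= 0 and d4 <= d3:
                p = b
            else:
                vc = d1 * d4 - d3 * d2
                if vc <= 0 and d1 >= 0 and d3 <= 0:
                    p = a + ab * (d1 / (d1 - d3))
                else:
                    cp = query - c
                    d5, d6 = ab @ cp, ac @ cp
                    if d6 >= 0 and d5 <= d6:
                        p = c
                    else:
                        vb = d5 * d2 - d1 * d6
                        if vb <= 0 and d2 >= 0 and d6 <= 0:
                            p = a + ac * (d2 / (d2 - d6))
                        else:
                            va = d3 * d6 - d5 * d4
                            if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
                                p = b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
                            else:
                                denom = va + vb + vc
                                v, w = vb / denom, vc / denom
                                p = a + ab * v + ac * w
        d = np.linalg.norm(query - p)
        if d < best_d:
            best_d, best_p = d, p
    return best_p, best_d


def test_closest_point_on_vertex_and_above_triangle(small_head):
    mesh, anchors = small_head
    p, d, _ = mh.closest_point_on_mesh(mesh.vertices[10], mesh)
    assert d < 1e-12
    np.testing.assert_allclose(p, mesh.vertices[10], atol=1e-12)
    # 1 mm along the normal above a triangle interior -> foot of perpendicular
    tri = mesh.triangles[0]
    a, b, c = mesh.vertices[tri]
    center = (a + b + c) / 3
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n)
    q = center + 1.0 * n
    p, d, tid = mh.closest_point_on_mesh(q, mesh)
    assert abs(d - 1.0) < 1e-9
    np.testing.assert_allclose(p, center, atol=1e-9)


def test_closest_point_matches_brute_force(small_head):
    """KD-tree-accelerated search equals exhaustive per-triangle minimization."""
    mesh, _ = small_head
    rng = np.random.default_rng(3)
    queries = rng.normal(scale=130, size=(60, 3))
    pts, dists, _ = mh.closest_point_on_mesh(queries, mesh)
    for q, p, d in zip(queries, pts, dists):
        bp, bd = brute_force_closest(q, mesh)
        assert abs(d - bd) < 1e-9
        np.testing.assert_allclose(p, bp, atol=1e-6)


def test_tangent_frame_orthonormal(small_head):
    mesh, _ = small_head
    rng = np.random.default_rng(1)
    import trimesh
    samples, _ = trimesh.sample.sample_surface(mesh.as_trimesh(), 40, seed=7)
    for p in samples:
        t1, t2 = mh.tangent_frame(mesh, p)
        n = surface_normal(mesh, p)
        assert abs(np.linalg.norm(t1) - 1) < 1e-10
        assert abs(np.linalg.norm(t2) - 1) < 1e-10
        assert abs(t1 @ t2) < 1e-10
        assert abs(t1 @ n) < 1e-10 and abs(t2 @ n) < 1e-10


def test_tangent_frame_planar_patch():
    """On a flat plate with normal +z the tangents span the xy-plane."""
    v = np.array([[0.0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0], [5, 5, 1e-9]])
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 1, 4]])
    mesh = mh.SurfaceMesh(v, f)
    t1, t2 = mh.tangent_frame(mesh, np.array([6.0, 3.0, 0.0]), triangle_index=1)
    assert abs(t1[2]) < 1e-6 and abs(t2[2]) < 1e-6


def test_normals_vary_continuously(head):
    """Interpolated normals of neighboring surface points differ by < 10 deg."""
    mesh, _ = head
    import trimesh
    samples, _ = trimesh.sample.sample_surface(mesh.as_trimesh(), 25, seed=5)
    for p in samples:
        n0 = surface_normal(mesh, p)
        for delta in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
            q, _, tid = mh.closest_point_on_mesh(p + delta, mesh)
            n1 = surface_normal(mesh, q, tid)
            ang = np.degrees(np.arccos(np.clip(n0 @ n1, -1, 1)))
            assert ang < 10.0


class TestTemplateGeneration:
    def test_single_point_is_seed_anchor(self, small_head):
        mesh, anchors = small_head
        tpl = mh.generate_template_semilandmarks(mesh, anchors, n=1, radius=1.5, seed=0)
        pr = anchors.points[anchors.anchor_index("pr")]
        np.testing.assert_allclose(tpl.landmarks.semilandmarks[0], pr, atol=1e-9)

    def test_full_template_contract(self, head):
        mesh, anchors = head
        tpl = mh.generate_template_semilandmarks(mesh, anchors, n=480, radius=1.5, seed=2)
        semis = tpl.landmarks.semilandmarks
        assert len(semis) == 480
        assert pdist(semis).min() >= 0.75
        _, d, _ = mh.closest_point_on_mesh(semis, mesh)
        assert d.max() < 1e-6

    def test_determinism_and_seed_sensitivity(self, small_head):
        mesh, anchors = small_head
        a = mh.generate_template_semilandmarks(mesh, anchors, n=50, radius=1.5, seed=4)
        b = mh.generate_template_semilandmarks(mesh, anchors, n=50, radius=1.5, seed=4)
        c = mh.generate_template_semilandmarks(mesh, anchors, n=50, radius=1.5, seed=5)
        np.testing.assert_array_equal(a.landmarks.points, b.landmarks.points)
        assert len(c.landmarks.points) == len(a.landmarks.points)
        assert not np.array_equal(a.landmarks.semilandmarks, c.landmarks.semilandmarks)

    def test_capacity_error(self):
        v = np.array([[0.0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0], [1, 1, 0.3]])
        f = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
        tiny = mh.SurfaceMesh(v, f)
        anchors = mh.LandmarkConfiguration(
            np.array([[1.0, 1.0, 0.3]]), anchor_count=1, labels=["pr"])
        with pytest.raises(TemplateError):
            mh.generate_template_semilandmarks(tiny, anchors, n=400, radius=1.5, seed=0)


class TestTransferAndSliding:
    def test_step_schedule_geometric(self):
        sched = step_schedule(6, 1.0, 0.05)
        expected = [1.0, 0.549, 0.302, 0.166, 0.091, 0.05]
        np.testing.assert_allclose(sched, expected, atol=5e-4)
        ratios = sched[1:] / sched[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_identity_transfer(self, template, small_head):
        mesh, anchors = small_head
        out = mh.transfer_template(template, mesh, anchors)
        assert np.abs(out.points - template.landmarks.points).max() < 1e-6

    def test_rigid_motion_transfer_exact(self, template, small_head, rng):
        mesh, anchors = small_head
        r = random_rotation(rng)
        t = np.array([12.0, -5.0, 30.0])
        mesh_r = mh.SurfaceMesh(mesh.vertices @ r.T + t, mesh.triangles)
        anch_r = mh.LandmarkConfiguration(anchors.points @ r.T + t, anchors.anchor_count,
                                          labels=list(anchors.labels))
        out = mh.transfer_template(template, mesh_r, anch_r)
        expected = template.landmarks.points @ r.T + t
        assert np.abs(out.points - expected).max() < 1e-6

    def test_transfer_lands_on_target_surface(self, template):
        target, t_anchors = mh.make_head_mesh(
            HeadParams(nose_mm=18, chin_mm=14, brow_mm=3, subdivisions=3))
        out = mh.transfer_template(template, target, t_anchors)
        _, d, _ = mh.closest_point_on_mesh(out.semilandmarks, target)
        assert d.max() < 1e-6

    def test_anchor_label_mismatch(self, template, small_head):
        mesh, anchors = small_head
        bad = mh.LandmarkConfiguration(anchors.points, anchors.anchor_count,
                                       labels=list(reversed(anchors.labels)))
        with pytest.raises(ValueError, match="labels"):
            mh.transfer_template(template, mesh, bad)

    def test_sliding_identity_leaves_landmarks(self, template, small_head):
        mesh, anchors = small_head
        tr = mh.slide_semilandmarks(template, mesh, anchors, cycles=6)
        assert np.abs(tr.final_landmarks.points - template.landmarks.points).max() < 1e-6
        assert tr.initial_energy < 1e-8
        assert all(e < 1e-8 for e in tr.energies)

    def test_sliding_rigid_homology(self, template, small_head, rng):
        """Procrustes distance to the template < 1e-6 for a rotated copy."""
        mesh, anchors = small_head
        r = random_rotation(rng)
        t = np.array([-8.0, 14.0, 3.0])
        mesh_r = mh.SurfaceMesh(mesh.vertices @ r.T + t, mesh.triangles)
        anch_r = mh.LandmarkConfiguration(anchors.points @ r.T + t, anchors.anchor_count,
                                          labels=list(anchors.labels))
        tr = mh.slide_semilandmarks(template, mesh_r, anch_r, cycles=6)
        assert mh.procrustes_distance(tr.final_landmarks.points,
                                      template.landmarks.points) < 1e-6

    def test_sliding_energy_descent_and_containment(self, template):
        target, t_anchors = mh.make_head_mesh(
            HeadParams(nose_mm=18, chin_mm=14, brow_mm=3, subdivisions=3))
        tr = mh.slide_semilandmarks(template, target, t_anchors, cycles=6)
        assert tr.final_energy <= tr.initial_energy
        assert tr.energies[-1] <= tr.energies[0] * (1 + 1e-9)
        _, d, _ = mh.closest_point_on_mesh(tr.final_landmarks.semilandmarks, target)
        assert d.max() < 1e-6
        # anchors immobile
        np.testing.assert_array_equal(tr.final_landmarks.anchors, t_anchors.anchors)
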