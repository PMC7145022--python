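"""Generalized Procrustes analysis, centroid size and shape-space distances.

Full Procrustes superimposition: every configuration is translated to the
origin, scaled to unit centroid size (CS), and rotated — rotations only,
never reflections, so anatomical left/right cannot flip — to a consensus
that is re-estimated until it stops moving.  Downstream linear statistics
operate on tangent-space coordinates obtained by orthogonal projection at
the consensus.

Group mean-shape differences are tested with permutation tests on the
Procrustes distance, using the add-one p-value convention so p is never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class AlignmentError(ValueError):
    """Degenerate configuration or mismatched landmark counts."""


def centroid_size(config: np.ndarray) -> float:
    """Root summed squared distances of the points from their centroid (mm)."""
    config = np.asarray(config, float)
    if config.ndim != 2 or len(config) < 2:
        raise AlignmentError("configuration must be (K>=2, 3)")
    dev = config - config.mean(axis=0)
    cs = float(np.sqrt((dev**2).sum()))
    if cs <= 0.0:
        raise AlignmentError("all landmarks coincide: centroid size is zero")
    return cs


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||a @ R - b||_F for centered configs."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    return u @ flip @ vt


@dataclass
class ShapeSpace:
    """GPA-aligned sample: (N, K, 3) unit-size shapes + consensus + sizes."""

    aligned: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def tangent_coordinates(self) -> np.ndarray:
        """(N, 3K) coordinates projected orthogonally to the consensus at the pole."""
        flat = self.aligned.reshape(self.n_specimens, -1)
        m = self.mean_shape.ravel()
        m = m / np.linalg.norm(m)
        return flat - np.outer(flat @ m, m)

    def subset(self, mask) -> "ShapeSpace":
        mask = np.asarray(mask)
        ids = [sid for sid, keep in zip(self.specimen_ids, mask) if keep]
        return ShapeSpace(self.aligned[mask], self.mean_shape,
                          self.centroid_sizes[mask], ids)


def _center_scale(config: np.ndarray) -> np.ndarray:
    dev = config - config.mean(axis=0)
    return dev / np.sqrt((dev**2).sum())


def gpa(configs: np.ndarray, specimen_ids: list[str] | None = None,
        tol: float = 1e-10, max_iter: int = 100) -> ShapeSpace:
    """Generalized Procrustes analysis of an (N, K, 3) landmark sample."""
    configs = np.asarray(configs, float)
    if configs.ndim != 3 or configs.shape[0] < 2 or configs.shape[1] < 3:
        raise AlignmentError("need at least 2 configurations of >= 3 landmarks")
    n = configs.shape[0]
    if specimen_ids is None:
        specimen_ids = [f"spec{i:04d}" for i in range(n)]

    sizes = np.empty(n)
    aligned = np.empty_like(configs)
    for i, cfg in enumerate(configs):
        if not np.isfinite(cfg).all():
            raise AlignmentError(f"non-finite coordinates in specimen {specimen_ids[i]}")
        try:
            sizes[i] = centroid_size(cfg)
        except AlignmentError as exc:
            raise AlignmentError(f"degenerate specimen {specimen_ids[i]}: {exc}") from exc
        aligned[i] = _center_scale(cfg)

    # initialize the consensus from the raw mean so GPA is a strict fixed
    # point on already-aligned input; fall back to the first specimen when
    # random orientations cancel the mean out
    raw_mean = aligned.mean(axis=0)
    mean = _center_scale(raw_mean) if np.linalg.norm(raw_mean) > 1e-3 else _center_scale(aligned[0])
    for _ in range(max_iter):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], mean)
        new_mean = _center_scale(aligned.mean(axis=0))
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    # final pass so every specimen is optimally rotated to the converged mean
    for i in range(n):
        aligned[i] = aligned[i] @ optimal_rotation(aligned[i], mean)
    mean = aligned.mean(axis=0)

    return ShapeSpace(aligned=aligned, mean_shape=mean, centroid_sizes=sizes,
                      specimen_ids=list(specimen_ids))


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance: unit-size, optimally rotated root-sum-square."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise AlignmentError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    a = _center_scale(a)
    b = _center_scale(b)
    a = a @ optimal_rotation(a, b)
    return float(np.linalg.norm(a - b))


def permutation_test_group_distance(
    shape_space: ShapeSpace,
    labels,
    group_pair: tuple,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation test of the Procrustes distance between two group means.

    Returns ``(observed_distance, p)`` with the add-one estimator
    ``p = (#{permuted >= observed} + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    if labels.shape[0] != shape_space.n_specimens:
        raise ValueError("one label per specimen required")
    g1, g2 = group_pair
    mask = (labels == g1) | (labels == g2)
    if (labels == g1).sum() == 0 or (labels == g2).sum() == 0:
        raise ValueError(f"empty group in pair {group_pair}")
    import warnings
    if (labels == g1).sum() < 2 or (labels == g2).sum() < 2:
        warnings.warn(f"a group in {group_pair} has fewer than 2 members", stacklevel=2)

    sub = shape_space.aligned[mask]
    sub_labels = labels[mask]
    is_g1 = sub_labels == g1

    def group_dist(flags: np.ndarray) -> float:
        return procrustes_distance(sub[flags].mean(axis=0), sub[~flags].mean(axis=0))

    observed = group_dist(is_g1)
    rng = np.random.default_rng(seed)
    count = 0
    flags = is_g1.copy()
    for _ in range(n_perm):
        rng.shuffle(flags)
        if group_dist(flags) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return observed, p
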