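"""Synthetic head-like meshes and populations with known shape structure.

Real craniofacial scan collections are license-restricted, so every stage of
the pipeline is exercised on generated data instead: star-shaped head meshes
built from a radially deformed icosphere-ellipsoid with parameterized nose,
mouth, chin and brow features, carrying ground-truth positions for the 20
anchor anatomical landmarks (placed by construction on mesh vertices).

A population adds, per specimen, its demographic cell's smooth effect
fields (ethnicity -> cranial width, sex -> nose and mouth scale, age -> chin
and forehead protrusion), an individual random low-frequency radial
deformation (spatially correlated, not per-landmark white noise), an
allometric shape component coupled to log centroid size, a random rigid
pose, and — on the landmarks only — digitization noise.  A subset of
specimens is "re-digitized": duplicated with fresh landmark noise, giving
the error stratum of the Procrustes ANOVA.  Everything is deterministic per
seed (numpy Generator / PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .geometry_io import AGE_CLASSES, ANCHOR_LABELS, LandmarkConfiguration, SpecimenRecord, SurfaceMesh


class GenerationError(ValueError):
    """Parameters produced an invalid (collapsed or self-intersecting) head."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


#: outward directions of the 20 anchors on the unit head sphere
#: (x anterior, y left, z superior)
_ANCHOR_DIRECTIONS = {
    "enl": (0.92, 0.20, 0.04), "exl": (0.78, 0.44, 0.04),
    "exr": (0.78, -0.44, 0.04), "enr": (0.92, -0.20, 0.04),
    "me": (0.92, 0.0, 0.42), "g": (1.0, 0.0, 0.22),
    "n": (1.0, 0.0, 0.04), "pr": (1.0, 0.0, -0.14),
    "all": (0.93, 0.22, -0.20), "alr": (0.93, -0.22, -0.20),
    "chl": (0.83, 0.36, -0.36), "chr": (0.83, -0.36, -0.36),
    "ls": (0.97, 0.0, -0.30), "li": (0.92, 0.0, -0.46),
    "pg": (0.85, 0.0, -0.62), "gn": (0.74, 0.0, -0.78),
    "tl": (0.05, 1.0, -0.05), "tr": (0.05, -1.0, -0.05),
    "op": (-1.0, 0.0, 0.06), "ve": (0.0, 0.0, 1.0),
}


@dataclass
class HeadParams:
    """Base-shape parameters of one synthetic head (mm)."""

    depth_mm: float = 95.0      # anterior-posterior semi-axis
    width_mm: float = 75.0      # lateral semi-axis
    height_mm: float = 110.0    # vertical semi-axis
    nose_mm: float = 14.0
    mouth_mm: float = 4.0
    chin_mm: float = 10.0
    brow_mm: float = 6.0
    width_scale: float = 1.0
    subdivisions: int = 4


def _gaussian_on_sphere(dirs: np.ndarray, center, sigma: float) -> np.ndarray:
    """exp(-angle^2 / 2 sigma^2) between unit directions and a center direction."""
    c = _unit(center)
    cosang = np.clip(dirs @ c, -1.0, 1.0)
    ang = np.arccos(cosang)
    return np.exp(-(ang**2) / (2.0 * sigma**2))


def _base_radius(dirs: np.ndarray, p: HeadParams) -> np.ndarray:
    a, b, c = p.depth_mm, p.width_mm * p.width_scale, p.height_mm
    r = 1.0 / np.sqrt((dirs[:, 0] / a) ** 2 + (dirs[:, 1] / b) ** 2 + (dirs[:, 2] / c) ** 2)
    r += p.nose_mm * _gaussian_on_sphere(dirs, _ANCHOR_DIRECTIONS["pr"], 0.13)
    r += p.mouth_mm * _gaussian_on_sphere(dirs, (0.98, 0.0, -0.31), 0.12)
    r += p.chin_mm * _gaussian_on_sphere(dirs, _ANCHOR_DIRECTIONS["gn"], 0.20)
    r += p.brow_mm * _gaussian_on_sphere(dirs, _ANCHOR_DIRECTIONS["g"], 0.22)
    return r


def _sphere_and_anchors(subdivisions: int):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(ico.vertices, float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    anchor_idx = []
    for lab in ANCHOR_LABELS:
        d = _unit(_ANCHOR_DIRECTIONS[lab])
        anchor_idx.append(int(np.argmax(dirs @ d)))
    if len(set(anchor_idx)) != len(anchor_idx):
        raise GenerationError("mesh resolution too coarse: anchors collide on one vertex")
    return dirs, np.asarray(ico.faces, np.int64), np.asarray(anchor_idx)


def make_head_mesh(params: HeadParams | None = None, seed: int = 0,
                   name: str = "head") -> tuple[SurfaceMesh, LandmarkConfiguration]:
    """Build one head mesh; anchors are returned at exact surface vertices."""
    params = params or HeadParams()
    dirs, faces, anchor_idx = _sphere_and_anchors(params.subdivisions)
    r = _base_radius(dirs, params)
    if r.min() <= 5.0:
        raise GenerationError("radius field collapsed (<= 5 mm): parameters out of range")
    vertices = dirs * r[:, None]
    mesh = SurfaceMesh(vertices, faces, name=name).validate()
    anchors = LandmarkConfiguration(vertices[anchor_idx], anchor_count=len(anchor_idx),
                                    labels=list(ANCHOR_LABELS))
    return mesh, anchors


# ---------------------------------------------------------------------------
# Population structure
# ---------------------------------------------------------------------------

#: demographic cell counts of the emulated study sample
#: (ethnicity x sex x the five age classes), total 292
_CELL_COUNTS_292 = {
    ("british", "M"): [21, 13, 26, 21, 21],
    ("british", "F"): [24, 11, 32, 33, 32],
    ("irish", "M"): [1, 0, 6, 14, 6],
    ("irish", "F"): [1, 3, 7, 12, 8],
}

ETHNICITIES = ["british", "irish"]
SEXES = ["M", "F"]


def cell_counts(total: int = 120) -> dict:
    """Cell counts mirroring the study's demographic margins, rescaled to ``total``
    by largest-remainder rounding."""
    flat = [(k, a, c) for k, counts in _CELL_COUNTS_292.items()
            for a, c in zip(AGE_CLASSES, counts)]
    raw = np.array([c for _, _, c in flat], float) * total / 292.0
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    out: dict = {}
    for (key, age, _), c in zip(flat, base):
        out.setdefault(key, {})[age] = int(c)
    return out


@dataclass
class PopulationSpec:
    """Study conditions for one synthetic population.

    Effect amplitudes are peak radial displacements in mm between extreme
    factor levels; ``individual_sd`` is the per-surface-point SD of the
    smooth individual deformation field; ``digitization_sd`` the white-noise
    SD added to digitized landmark coordinates; ``allometric_slope_mm`` the
    peak shape displacement per unit change in log centroid size.
    """

    n_total: int = 120
    counts: dict | None = None           # overrides n_total when given
    ethnicity_mm: float = 2.0
    sex_mm: float = 6.0
    age_mm: float = 3.0
    individual_sd: float = 1.0
    digitization_sd: float = 0.1
    allometric_slope_mm: float = 12.0
    log_size_sd: float = 0.05
    n_redigitized: int = 30
    n_individual_bumps: int = 10
    subdivisions: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("individual_sd", "digitization_sd", "log_size_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ethnicity_mm", "sex_mm", "age_mm", "allometric_slope_mm"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def resolved_counts(self) -> dict:
        counts = self.counts or cell_counts(self.n_total)
        if sum(sum(v.values()) for v in counts.values()) <= 0:
            raise ValueError("population spec resolves to zero specimens")
        return counts


@dataclass
class SyntheticPopulation:
    """Specimens + meshes + the constructive ground truth behind them."""

    spec: PopulationSpec
    records: list[SpecimenRecord]
    meshes: dict
    truth: pd.DataFrame                 # per observation: factors, log size, amplitudes
    true_anchors: dict = field(default_factory=dict)        # pre-pose, pre-noise configs
    true_anchors_noallo: dict = field(default_factory=dict)  # same without the allometric term


def _normalized_field(raw: np.ndarray) -> np.ndarray:
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def _effect_fields(dirs: np.ndarray) -> dict:
    """Fixed unit-peak effect fields per factor (where on the head each acts)."""
    eth = dirs[:, 1] ** 2  # lateral cranial widening / roundness
    sex = (_gaussian_on_sphere(dirs, _ANCHOR_DIRECTIONS["pr"], 0.25)
           + _gaussian_on_sphere(dirs, (0.95, 0.0, -0.32), 0.25))
    age = (_gaussian_on_sphere(dirs, _ANCHOR_DIRECTIONS["gn"], 0.30)
           + _gaussian_on_sphere(dirs, _ANCHOR_DIRECTIONS["me"], 0.30))
    allo = (_gaussian_on_sphere(dirs, _ANCHOR_DIRECTIONS["gn"], 0.35)
            + _gaussian_on_sphere(dirs, _ANCHOR_DIRECTIONS["g"], 0.35)
            + 0.5 * dirs[:, 1] ** 2)
    return {k: v / np.abs(v).max() for k, v in
            {"ethnicity": eth, "sex": sex, "age": age, "allometry": allo}.items()}


#: mean log centroid size offset per age class (children smaller, growth to adult)
_AGE_LOG_SIZE = {"<13": -0.08, "13-19": -0.02, "20-29": 0.01, "30-49": 0.03, "50>": 0.03}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def sample_population(spec: PopulationSpec) -> SyntheticPopulation:
    """Draw a full population (with re-digitized replicates) from a spec."""
    rng = np.random.default_rng(spec.seed)
    counts = spec.resolved_counts()
    dirs, faces, anchor_idx = _sphere_and_anchors(spec.subdivisions)
    base = HeadParams(subdivisions=spec.subdivisions)
    base_r = _base_radius(dirs, base)
    fields = _effect_fields(dirs)

    records: list[SpecimenRecord] = []
    meshes: dict = {}
    true_anchors: dict = {}
    true_anchors_noallo: dict = {}
    posed_anchors: dict = {}
    truth_rows = []

    def digitize(points: np.ndarray) -> np.ndarray:
        if spec.digitization_sd > 0:
            return points + rng.normal(0.0, spec.digitization_sd, size=points.shape)
        return points.copy()

    i = 0
    for (eth, sex), by_age in counts.items():
        eth_sign = 0.5 if eth == ETHNICITIES[0] else -0.5
        sex_sign = 0.5 if sex == SEXES[0] else -0.5
        for age, n_cell in by_age.items():
            age_coef = (AGE_CLASSES.index(age) - 2) / 2.0
            for _ in range(n_cell):
                sid = f"spec{i:04d}"
                i += 1
                log_size = _AGE_LOG_SIZE[age] + rng.normal(0.0, spec.log_size_sd)
                size = float(np.exp(log_size))

                indiv_raw = np.zeros(len(dirs))
                for _b in range(spec.n_individual_bumps):
                    center = _unit(rng.normal(size=3))
                    indiv_raw += rng.normal() * _gaussian_on_sphere(dirs, center, 0.35)
                indiv = _normalized_field(indiv_raw) * spec.individual_sd

                effect = (eth_sign * spec.ethnicity_mm * fields["ethnicity"]
                          + sex_sign * spec.sex_mm * fields["sex"]
                          + age_coef * spec.age_mm * fields["age"])
                allo = spec.allometric_slope_mm * log_size * fields["allometry"]

                r = base_r + effect + indiv + allo
                if r.min() <= 5.0:
                    raise GenerationError(f"specimen {sid}: radius field collapsed")
                verts = dirs * (r * size)[:, None]
                anchors_clean = verts[anchor_idx]
                noallo = (dirs * ((r - allo) * size)[:, None])[anchor_idx]

                rot = _random_rotation(rng)
                trans = rng.normal(0.0, 20.0, size=3)
                verts_posed = verts @ rot.T + trans
                mesh = SurfaceMesh(verts_posed, faces, name=sid)
                meshes[sid] = mesh
                true_anchors[sid] = anchors_clean
                true_anchors_noallo[sid] = noallo
                posed_anchors[sid] = anchors_clean @ rot.T + trans

                lm = LandmarkConfiguration(digitize(posed_anchors[sid]),
                                           anchor_count=len(anchor_idx),
                                           labels=list(ANCHOR_LABELS))
                records.append(SpecimenRecord(sid, eth, sex, age, None, lm))
                truth_rows.append({
                    "id": sid, "ethnicity": eth, "sex": sex, "age_class": age,
                    "replicate_of": "", "log_size": log_size,
                    "ethnicity_effect_mm": eth_sign * spec.ethnicity_mm,
                    "sex_effect_mm": sex_sign * spec.sex_mm,
                    "age_effect_mm": age_coef * spec.age_mm,
                    "allometric_slope_mm": spec.allometric_slope_mm,
                })

    n_redig = min(spec.n_redigitized, len(records))
    redig_pick = rng.choice(len(records), size=n_redig, replace=False) if n_redig else []
    for j in sorted(redig_pick):
        orig = records[j]
        sid = orig.id
        # re-digitization: the same posed head, fresh landmark noise
        rep_lm = LandmarkConfiguration(digitize(posed_anchors[sid]),
                                       anchor_count=orig.landmarks.anchor_count,
                                       labels=list(ANCHOR_LABELS))
        rep_id = f"{sid}_r"
        records.append(SpecimenRecord(rep_id, orig.ethnicity, orig.sex, orig.age_class,
                                      sid, rep_lm))
        row = dict(truth_rows[j])
        row.update({"id": rep_id, "replicate_of": sid})
        truth_rows.append(row)

    return SyntheticPopulation(spec=spec, records=records, meshes=meshes,
                               truth=pd.DataFrame(truth_rows),
                               true_anchors=true_anchors,
                               true_anchors_noallo=true_anchors_noallo)


def ground_truth(population: SyntheticPopulation) -> tuple[pd.DataFrame, dict]:
    """Per-observation truth table + constructive summary statistics.

    ``allometry_percent_expected`` is the percent of shape variance that
    centroid size predicts in the *noise-free, un-posed* configurations —
    the population-level target of a shape-on-size regression.  It includes
    every size-coupled mechanism the generator builds in (the explicit
    allometric field, the age size trajectory interacting with age shape
    effects, and the size/shape coupling of individual deformation), which
    is precisely what a regression on real data would face.
    ``allometric_component_percent`` isolates the explicit allometric term
    alone (shape-space difference between configurations generated with and
    without it).
    """
    spec = population.spec
    ids = [r.id for r in population.records if r.replicate_of is None]
    configs = np.stack([population.true_anchors[s] for s in ids])
    noallo = np.stack([population.true_anchors_noallo[s] for s in ids])

    def to_shape(c):  # center + unit centroid size, as superimposition does
        c = c - c.mean(axis=1, keepdims=True)
        return c / np.sqrt((c**2).sum(axis=(1, 2)))[:, None, None]

    norm = to_shape(configs)
    dev = (norm - norm.mean(axis=0)).reshape(len(ids), -1)
    ss_total = float((dev**2).sum())

    # size-predictable percent: regression of clean shape on clean CS
    cent = configs - configs.mean(axis=1, keepdims=True)
    cs = np.sqrt((cent**2).sum(axis=(1, 2)))
    xc = cs - cs.mean()
    beta = (xc @ dev) / float(xc @ xc)
    ss_pred = float((beta**2).sum() * (xc @ xc))

    # explicit allometric term alone, as a shape-space component
    allo_comp = (norm - to_shape(noallo)).reshape(len(ids), -1)
    allo_c = allo_comp - allo_comp.mean(axis=0)
    ss_allo = float((allo_c**2).sum())

    summary = {
        "allometry_percent_expected": 100.0 * ss_pred / ss_total if ss_total else 0.0,
        "allometric_component_percent": 100.0 * ss_allo / ss_total if ss_total else 0.0,
        "ethnicity_mm": spec.ethnicity_mm,
        "sex_mm": spec.sex_mm,
        "age_mm": spec.age_mm,
        "individual_sd": spec.individual_sd,
        "digitization_sd": spec.digitization_sd,
    }
    return population.truth.copy(), summary
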