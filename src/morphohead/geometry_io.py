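"""Reading, writing and validation of meshes, landmark sets and specimen metadata.

All coordinates are millimetres throughout the package; no unit conversion
happens on I/O.  Meshes are triangular surfaces (Wavefront OBJ or PLY);
landmark files are plain CSV with a ``label,x,y,z`` header.  The coordinate
system is right-handed and no canonical head orientation is enforced — every
downstream analysis is invariant to superimposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

log = logging.getLogger(__name__)

MESH_EXTENSIONS = (".obj", ".ply")

#: Notations of the 20 anchor anatomical landmarks (facial landmark standards):
#: canthi, metopion, glabella, nasion, pronasale, alare, cheilion, labiale
#: superius/inferius, pogonion, gnathion, tragion, opisthocranion, vertex.
ANCHOR_LABELS = [
    "enl", "exl", "exr", "enr", "me", "g", "n", "pr", "all", "alr",
    "chl", "chr", "ls", "li", "pg", "gn", "tl", "tr", "op", "ve",
]


class MeshValidationError(ValueError):
    """A mesh violates a geometric invariant (bad indices, NaN, degenerate faces)."""


class LandmarkFormatError(ValueError):
    """A landmark CSV could not be parsed or fails its row-count contract."""


@dataclass
class SurfaceMesh:
    """A triangulated surface: one head scan or one synthetic head.

    ``vertices`` is (V, 3) float64 in mm; ``triangles`` is (T, 3) int indices.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)

    # -- validation ---------------------------------------------------------
    def validate(self) -> "SurfaceMesh":
        v, t = self.vertices, self.triangles
        if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
            raise MeshValidationError(f"mesh {self.name!r}: vertex array must be non-empty (V, 3)")
        if t.ndim != 2 or t.shape[1] != 3 or len(t) == 0:
            raise MeshValidationError(f"mesh {self.name!r}: triangle array must be non-empty (T, 3)")
        if not np.isfinite(v).all():
            raise MeshValidationError(f"mesh {self.name!r}: non-finite vertex coordinates")
        if t.min() < 0 or t.max() >= len(v):
            raise MeshValidationError(
                f"mesh {self.name!r}: triangle index out of range (max {t.max()}, {len(v)} vertices)"
            )
        areas = self.triangle_areas()
        if np.any(areas <= 0.0):
            bad = int(np.argmin(areas))
            raise MeshValidationError(f"mesh {self.name!r}: degenerate zero-area triangle {bad}")
        return self

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def as_trimesh(self) -> trimesh.Trimesh:
        cached = self.__dict__.get("_trimesh_cache")
        if cached is None:
            cached = trimesh.Trimesh(vertices=self.vertices, faces=self.triangles, process=False)
            self.__dict__["_trimesh_cache"] = cached
        return cached


@dataclass
class LandmarkConfiguration:
    """Ordered 3D landmark set: an anchor block followed by semi-landmarks.

    The first ``anchor_count`` points are anatomical anchor landmarks with
    ``labels``; the remaining ``semilandmark_count`` points are surface
    semi-landmarks with generated labels ``s0001…``.
    """

    points: np.ndarray
    anchor_count: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("landmark points must be (N, 3)")
        if not np.isfinite(self.points).all():
            raise ValueError("non-finite landmark coordinates")
        if not 0 <= self.anchor_count <= len(self.points):
            raise ValueError("anchor_count outside [0, point count]")
        if not self.labels:
            self.labels = [f"p{i:04d}" for i in range(self.anchor_count)]
        if len(self.labels) != self.anchor_count:
            raise ValueError("one label per anchor required")

    @property
    def semilandmark_count(self) -> int:
        return len(self.points) - self.anchor_count

    @property
    def anchors(self) -> np.ndarray:
        return self.points[: self.anchor_count]

    @property
    def semilandmarks(self) -> np.ndarray:
        return self.points[self.anchor_count:]

    def all_labels(self) -> list[str]:
        return list(self.labels) + [f"s{i + 1:04d}" for i in range(self.semilandmark_count)]

    def anchor_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown anchor label {label!r}; known: {', '.join(self.labels)}") from None


@dataclass
class SpecimenRecord:
    """Metadata + landmarks for one digitization of one specimen."""

    id: str
    ethnicity: str
    sex: str
    age_class: str
    replicate_of: str | None = None
    landmarks: LandmarkConfiguration | None = None


AGE_CLASSES = ["<13", "13-19", "20-29", "30-49", "50>"]


# ---------------------------------------------------------------------------
# Mesh I/O.  Reading goes through trimesh; writing is done directly so that
# coordinates are stored in full double precision (ASCII PLY with `double`
# properties), which the 1e-6 mm round-trip contract requires.
# ---------------------------------------------------------------------------

def read_mesh(path) -> SurfaceMesh:
    """Read an OBJ or PLY triangular mesh and validate it."""
    path = str(path)
    if not path.lower().endswith(MESH_EXTENSIONS):
        raise MeshValidationError(f"unsupported mesh extension: {path}")
    try:
        tm = trimesh.load(path, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - surface the parser's message
        raise MeshValidationError(f"unreadable mesh file {path}: {exc}") from exc
    if not hasattr(tm, "vertices") or len(tm.vertices) == 0:
        raise MeshValidationError(f"empty mesh: {path}")
    mesh = SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64),
                       name=path.rsplit("/", 1)[-1]).validate()
    log.info("read %s: %d vertices, %d triangles", path, len(mesh.vertices), len(mesh.triangles))
    return mesh


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a validated mesh as OBJ (v/f records) or ASCII PLY (double precision)."""
    mesh.validate()
    path = str(path)
    if path.lower().endswith(".obj"):
        lines = [f"v {x:.12g} {y:.12g} {z:.12g}" for x, y, z in mesh.vertices]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.triangles]
        text = "\n".join(lines) + "\n"
    elif path.lower().endswith(".ply"):
        header = [
            "ply", "format ascii 1.0",
            f"element vertex {len(mesh.vertices)}",
            "property double x", "property double y", "property double z",
            f"element face {len(mesh.triangles)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        body = [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
        body += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
        text = "\n".join(header + body) + "\n"
    else:
        raise MeshValidationError(f"unsupported mesh extension: {path}")
    with open(path, "w") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# Landmark and metadata CSV
# ---------------------------------------------------------------------------

def read_landmarks(path, anchor_count: int) -> LandmarkConfiguration:
    """Read a ``label,x,y,z`` CSV; the first ``anchor_count`` rows are anchors."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise LandmarkFormatError(f"unreadable landmark file {path}: {exc}") from exc
    required = ["label", "x", "y", "z"]
    if list(df.columns[:4]) != required:
        raise LandmarkFormatError(f"{path}: expected header {required}, got {list(df.columns)}")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.where(~np.isfinite(coords).all(axis=1))[0]
    if bad.size:
        raise LandmarkFormatError(f"{path}: non-numeric coordinate at data row {bad[0] + 1}")
    if len(df) < anchor_count:
        raise LandmarkFormatError(f"{path}: {len(df)} rows < anchor_count {anchor_count}")
    labels = [str(v) for v in df["label"].iloc[:anchor_count]]
    return LandmarkConfiguration(coords, anchor_count=anchor_count, labels=labels)


def write_landmarks(config: LandmarkConfiguration, path) -> None:
    df = pd.DataFrame(config.points, columns=["x", "y", "z"])
    df.insert(0, "label", config.all_labels())
    df.to_csv(path, index=False, float_format="%.12g")


def read_metadata(path) -> list[SpecimenRecord]:
    """Read specimen metadata CSV (`id,ethnicity,sex,age_class,replicate_of`)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    records = []
    ids = set(df["id"])
    for _, row in df.iterrows():
        rep = row.get("replicate_of", "") or None
        if rep is not None and rep not in ids:
            raise ValueError(f"replicate_of {rep!r} does not name an existing specimen id")
        if row["age_class"] not in AGE_CLASSES:
            raise ValueError(f"unknown age class {row['age_class']!r}; expected one of {AGE_CLASSES}")
        records.append(SpecimenRecord(row["id"], row["ethnicity"], row["sex"],
                                      row["age_class"], rep))
    return records


def write_metadata(records: list[SpecimenRecord], path) -> None:
    df = pd.DataFrame(
        [(r.id, r.ethnicity, r.sex, r.age_class, r.replicate_of or "") for r in records],
        columns=["id", "ethnicity", "sex", "age_class", "replicate_of"],
    )
    df.to_csv(path, index=False)
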