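"""Domain types and file I/O for the facial-morphology pipeline.

The pipeline works in millimetres throughout.  Meshes travel as OBJ/PLY,
landmarks as ``name,x,y,z[,replicate]`` CSV, phenotype matrices as TSV with a
sidecar metadata table (phenotype id, category, units).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh
import yaml

__all__ = [
    "FormatError",
    "SurfaceMesh",
    "LandmarkDictionary",
    "LandmarkSet",
    "PhenotypeMatrix",
    "StudyConfig",
    "PHENOTYPE_CATEGORIES",
    "default_landmark_dictionary",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_phenotypes",
    "write_phenotypes",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected dialect."""


#: The 15 phenotype categories used to tag every column of a PhenotypeMatrix.
PHENOTYPE_CATEGORIES = (
    "Point",
    "Curvature",
    "Euclidean",
    "Manhattan",
    "Geodesic",
    "Index",
    "Angle",
    "Triangle_area",
    "Volume",
    "Surface_area",
    "Module_PCs",
    "Module_surf_area",
    "Module_mor_z",
    "Module_mor_mea",
    "Module_mor_gau",
)


# ---------------------------------------------------------------------------
# SurfaceMesh
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A triangulated facial surface with vertices in mm.

    Faces are triples of 0-based vertex indices.  Optional named per-vertex
    scalar fields ride along in ``vertex_attributes``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("faces must be an (m, 3) array of vertex triples")
        self.validate()

    def validate(self) -> None:
        n = len(self.vertices)
        if not np.isfinite(self.vertices).all():
            raise FormatError("non-finite vertex coordinate")
        if self.faces.size:
            bad = (self.faces < 0) | (self.faces >= n)
            if bad.any():
                f, c = np.argwhere(bad)[0]
                raise FormatError(
                    f"face {f} references vertex {self.faces[f, c]} "
                    f"but the mesh has only {n} vertices"
                )
            rep = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if rep.any():
                raise FormatError(f"face {int(np.argmax(rep))} has a repeated vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices, float), np.asarray(mesh.faces, np.int64))

    def face_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def surface_area(self) -> float:
        return float(self.face_areas().sum())


def _check_obj_indices(path: Path) -> None:
    # trimesh silently drops/wraps some malformed OBJ faces; scan face lines
    # so dangling 1-based indices fail loudly with the offending element.
    n_v = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "v":
            n_v += 1
        elif tok[0] == "f":
            refs = tok[1:]
            if len(refs) != 3:
                raise FormatError(
                    f"{path}:{lineno}: non-triangular face with {len(refs)} vertices"
                )
            for r in refs:
                idx = int(r.split("/")[0])
                if idx < 0:
                    idx = n_v + 1 + idx
                if not (1 <= idx <= n_v):
                    raise FormatError(
                        f"{path}:{lineno}: face references vertex {r.split('/')[0]} "
                        f"but only {n_v} vertices are defined so far"
                    )


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read an OBJ or PLY triangle mesh.

    On-disk 1-based OBJ indices become 0-based internally.  Non-triangular or
    dangling faces raise :class:`FormatError` naming the offending element.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".obj":
        _check_obj_indices(path)
    try:
        m = trimesh.load_mesh(path, process=False)
    except Exception as exc:  # pragma: no cover - format specific
        raise FormatError(f"cannot read mesh {path}: {exc}") from exc
    if isinstance(m, trimesh.Scene):
        geoms = list(m.geometry.values())
        if len(geoms) != 1:
            raise FormatError(f"{path}: expected a single mesh, found {len(geoms)}")
        m = geoms[0]
    faces = np.asarray(m.faces)
    if faces.size and faces.shape[1] != 3:
        raise FormatError(f"{path}: non-triangular faces")
    return SurfaceMesh(np.asarray(m.vertices, float), faces.astype(np.int64))


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    mesh.to_trimesh().export(path)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkDictionary:
    """Ordered list of named soft-tissue landmarks with left/right pairing.

    ``pairs`` maps the name of a paired landmark to its mirror partner;
    midline landmarks are absent from the map.
    """

    names: tuple[str, ...]
    definitions: Mapping[str, str]
    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("landmark names must be unique")
        for a, b in self.pairs.items():
            if self.pairs.get(b) != a:
                raise ValueError(f"pairing of {a!r}/{b!r} is not symmetric")
            if a not in self.names or b not in self.names:
                raise ValueError(f"paired landmark {a!r} or {b!r} not in dictionary")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


_DEFAULT_LANDMARKS: list[tuple[str, str, str | None]] = [
    # (name, anatomical definition, mirror partner or None)
    ("glabella", "most prominent midline point between the eyebrows", None),
    ("nasion", "deepest midline point of the nasal root", None),
    ("pronasale", "most protruded point of the nasal tip", None),
    ("subnasale", "midline junction of the columella and upper lip", None),
    ("labiale_superius", "midline point of the upper vermilion border", None),
    ("stomion", "midline point of the closed lips", None),
    ("labiale_inferius", "midline point of the lower vermilion border", None),
    ("sublabiale", "midline depth of the labiomental groove", None),
    ("pogonion", "most anterior midline point of the chin", None),
    ("gnathion", "lowest midline point of the chin", None),
    ("endocanthion_l", "inner corner of the left eye fissure", "endocanthion_r"),
    ("endocanthion_r", "inner corner of the right eye fissure", "endocanthion_l"),
    ("exocanthion_l", "outer corner of the left eye fissure", "exocanthion_r"),
    ("exocanthion_r", "outer corner of the right eye fissure", "exocanthion_l"),
    ("zygion_l", "most lateral point of the left cheekbone", "zygion_r"),
    ("zygion_r", "most lateral point of the right cheekbone", "zygion_l"),
    ("alare_l", "most lateral point of the left nasal ala", "alare_r"),
    ("alare_r", "most lateral point of the right nasal ala", "alare_l"),
    ("subalare_l", "lower attachment of the left nasal ala", "subalare_r"),
    ("subalare_r", "lower attachment of the right nasal ala", "subalare_l"),
    ("cheilion_l", "left corner of the mouth", "cheilion_r"),
    ("cheilion_r", "right corner of the mouth", "cheilion_l"),
    ("gonion_l", "most lateral point of the left mandibular angle", "gonion_r"),
    ("gonion_r", "most lateral point of the right mandibular angle", "gonion_l"),
    ("tragion_l", "notch above the tragus of the left ear", "tragion_r"),
    ("tragion_r", "notch above the tragus of the right ear", "tragion_l"),
]


def default_landmark_dictionary() -> LandmarkDictionary:
    """The default 26-landmark Farkas-style dictionary.

    A conventional anthropometric set (midline points plus eight bilateral
    pairs).  Any supplementary study-specific set can be substituted; the
    pipeline only requires 26 named points with pairing flags.
    """
    names = tuple(n for n, _, _ in _DEFAULT_LANDMARKS)
    defs = {n: d for n, d, _ in _DEFAULT_LANDMARKS}
    pairs = {n: p for n, _, p in _DEFAULT_LANDMARKS if p is not None}
    return LandmarkDictionary(names, defs, pairs)


@dataclass
class LandmarkSet:
    """26 named 3D points (mm) for one individual and one landmarking replicate."""

    coords: np.ndarray
    dictionary: LandmarkDictionary
    individual_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.dictionary), 3):
            raise ValueError(
                f"expected {(len(self.dictionary), 3)} coordinates, "
                f"got {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite landmark coordinate")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coords[self.dictionary.index(name)]

    def with_coords(self, coords: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(coords, self.dictionary, self.individual_id, self.replicate_id)


def read_landmarks(
    path: str | Path,
    dictionary: LandmarkDictionary | None = None,
    individual_id: str | None = None,
    replicate_id: str | None = None,
) -> LandmarkSet:
    """Read a ``name,x,y,z[,replicate]`` CSV and reorder to dictionary order.

    The replicate id is taken from the ``replicate`` column if present,
    otherwise from a trailing ``_rep<k>`` in the file name.
    """
    path = Path(path)
    dictionary = dictionary or default_landmark_dictionary()
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns name,x,y,z, got {list(df.columns)}")
    names = df["name"].tolist()
    dup = {n for n in names if names.count(n) > 1}
    if dup:
        raise FormatError(f"{path}: duplicate landmark rows: {sorted(dup)}")
    missing = [n for n in dictionary.names if n not in names]
    unknown = [n for n in names if n not in dictionary.names]
    if missing or unknown:
        raise FormatError(
            f"{path}: missing landmarks {missing or 'none'}, unknown {unknown or 'none'}"
        )
    df = df.set_index("name").loc[list(dictionary.names)]
    try:
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric coordinate ({exc})") from exc
    if replicate_id is None:
        if "replicate" in df.columns:
            reps = set(df["replicate"].astype(str))
            if len(reps) != 1:
                raise FormatError(f"{path}: mixed replicate ids {sorted(reps)}")
            replicate_id = reps.pop()
        else:
            stem = path.stem
            replicate_id = stem.rsplit("_rep", 1)[1] if "_rep" in stem else ""
    if individual_id is None:
        individual_id = path.stem.rsplit("_rep", 1)[0]
    return LandmarkSet(coords, dictionary, individual_id, replicate_id)


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": lms.dictionary.names,
            "x": lms.coords[:, 0],
            "y": lms.coords[:, 1],
            "z": lms.coords[:, 2],
        }
    )
    if lms.replicate_id:
        df["replicate"] = lms.replicate_id
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PhenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeMatrix:
    """Individuals x phenotypes table with a category tag and units per column.

    ``values`` is a DataFrame indexed by individual id; ``metadata`` is indexed
    by phenotype id with columns ``category`` and ``units``.  Missing values are
    NaN in memory and a literal ``NA`` token on disk.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.metadata.index):
            raise ValueError("metadata rows must match value columns in order")
        bad = set(self.metadata["category"]) - set(PHENOTYPE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown phenotype categories: {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.values)

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def categories(self) -> pd.Series:
        return self.metadata["category"]

    def select(self, categories: Iterable[str]) -> "PhenotypeMatrix":
        cats = set(categories)
        keep = [c for c in self.values.columns if self.metadata.loc[c, "category"] in cats]
        return PhenotypeMatrix(self.values[keep], self.metadata.loc[keep])

    @staticmethod
    def concat(parts: Sequence["PhenotypeMatrix"]) -> "PhenotypeMatrix":
        values = pd.concat([p.values for p in parts], axis=1)
        meta = pd.concat([p.metadata for p in parts], axis=0)
        return PhenotypeMatrix(values, meta)

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        individual_ids: Sequence[str],
        phenotype_ids: Sequence[str],
        category: str,
        units: str,
    ) -> "PhenotypeMatrix":
        vals = pd.DataFrame(values, index=list(individual_ids), columns=list(phenotype_ids))
        meta = pd.DataFrame(
            {"category": category, "units": units}, index=list(phenotype_ids)
        )
        return cls(vals, meta)


def write_phenotypes(matrix: PhenotypeMatrix, path: str | Path) -> None:
    """Write the value table as TSV plus a ``<stem>.meta.tsv`` sidecar."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="individual")
    meta_path = path.with_suffix(".meta.tsv")
    matrix.metadata.to_csv(meta_path, sep="\t", index_label="phenotype")


def read_phenotypes(path: str | Path) -> PhenotypeMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="individual", na_values=["NA"])
    values.index = values.index.astype(str)
    values.index.name = None
    meta = pd.read_csv(path.with_suffix(".meta.tsv"), sep="\t", index_col="phenotype")
    meta.index.name = None
    return PhenotypeMatrix(values, meta)


# ---------------------------------------------------------------------------
# StudyConfig
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Pipeline-wide settings: statistics, segmentation depth, seeds.

    Only scalars live here; the landmark dictionary, proportion-index battery
    and region definitions have their own module-level defaults that can be
    overridden programmatically.
    """

    alpha: float = 0.05
    n_permutations: int = 999
    segmentation_levels: int = 7
    segment_min_size: int = 10
    parallel_analysis_permutations: int = 100
    curvature_radius_mm: float = 10.0
    geodesic_snap_tolerance_mm: float = 2.0
    warp_bandwidth_mm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.segmentation_levels < 1:
            raise ValueError("segmentation depth must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
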