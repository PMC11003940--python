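"""Landmark- and mesh-based facial phenotypes.

From 26 landmarks (optionally with the individual's surface mesh) this module
derives the measurement families of the phenotype library:

* point coordinates (78 values),
* principal curvatures at each landmark -> mean curvature MC = (k_max+k_min)/2
  and Gaussian curvature GC = k_max*k_min (52 values),
* all C(26,2) = 325 Euclidean, Manhattan and on-surface geodesic distances,
* Farkas-style proportion indices (smaller/larger x 100; default battery of 32),
* all 3*C(26,3) = 7800 vertex angles of landmark triples,
* all C(26,3) = 2600 Heron triangle areas,
* convex-hull volumes and surface areas of named landmark regions (10 each).

Euclidean distances, angles, areas, hulls, geodesics and curvatures are
invariant to rigid motion; Manhattan distances are axis-dependent and are
meant to be computed in the GPA consensus frame.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist

from ._fast_marching import MeshGeodesics
from .core_io import (
    LandmarkDictionary,
    LandmarkSet,
    PhenotypeMatrix,
    SurfaceMesh,
    default_landmark_dictionary,
)

__all__ = [
    "CurvatureProfile",
    "RegionDefinition",
    "ProportionIndex",
    "default_proportion_battery",
    "default_regions",
    "euclidean_distances",
    "manhattan_distances",
    "geodesic_distances",
    "landmark_curvatures",
    "vertex_curvatures",
    "proportion_indices",
    "angles",
    "triangle_areas",
    "region_volume_surface",
    "pair_names",
    "extract_phenotypes",
]


def pair_names(dictionary: LandmarkDictionary) -> list[str]:
    """Names of the 325 unordered landmark pairs, in combination order."""
    return [f"{a}|{b}" for a, b in itertools.combinations(dictionary.names, 2)]


def triple_indices(n: int = 26) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), 3)), dtype=np.int64)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def euclidean_distances(lms: LandmarkSet) -> np.ndarray:
    """All 325 pairwise straight-line distances (mm)."""
    return pdist(lms.coords, metric="euclidean")


def manhattan_distances(lms: LandmarkSet) -> np.ndarray:
    """All 325 pairwise city-block distances (mm); axis-dependent, so the
    input should be in the GPA consensus frame."""
    return pdist(lms.coords, metric="cityblock")


def geodesic_distances(
    mesh: SurfaceMesh,
    lms: LandmarkSet,
    snap_tolerance_mm: float = 2.0,
    solver: MeshGeodesics | None = None,
) -> np.ndarray:
    """All 325 pairwise on-surface geodesic distances by fast marching.

    Each landmark is snapped to its nearest mesh vertex; a landmark farther
    than ``snap_tolerance_mm`` from the surface, or a pair on disconnected
    components, is an error.  Every geodesic is >= its Euclidean chord.
    """
    tree = cKDTree(mesh.vertices)
    dist, vid = tree.query(lms.coords)
    too_far = dist > snap_tolerance_mm
    if too_far.any():
        bad = [lms.dictionary.names[i] for i in np.where(too_far)[0]]
        raise ValueError(
            f"landmarks farther than {snap_tolerance_mm} mm from the surface: {bad}"
        )
    solver = solver or MeshGeodesics(mesh.vertices, mesh.faces)
    p = len(lms.dictionary)
    out = np.zeros((p, p))
    for i in range(p - 1):
        field = solver.distance_field(int(vid[i]))
        out[i, i + 1 :] = field[vid[i + 1 :]]
    if not np.isfinite(out).all():
        i, j = np.argwhere(~np.isfinite(out))[0]
        raise ValueError(
            f"no surface path between {lms.dictionary.names[i]} and "
            f"{lms.dictionary.names[j]} (disconnected mesh)"
        )
    iu = np.triu_indices(p, k=1)
    return out[iu]


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurvatureProfile:
    """Principal curvatures at a point, ordered by magnitude."""

    k_max: float  # 1/mm, larger |.|
    k_min: float  # 1/mm
    mean_curvature: float  # (k_max + k_min) / 2, 1/mm
    gaussian_curvature: float  # k_max * k_min, 1/mm^2

    @classmethod
    def from_principal(cls, k1: float, k2: float) -> "CurvatureProfile":
        k_max, k_min = (k1, k2) if abs(k1) >= abs(k2) else (k2, k1)
        return cls(k_max, k_min, 0.5 * (k_max + k_min), k_max * k_min)


def _principal_curvatures_at(
    point: np.ndarray, neighborhood: np.ndarray, outward_ref: np.ndarray
) -> tuple[float, float]:
    """Quadric (Monge patch) fit of a neighborhood; returns (k1, k2) with the
    convention that convex-toward-``outward_ref`` surfaces are positive."""
    centered = neighborhood - point
    # tangent frame from the local covariance; smallest axis ~ normal
    _, _, vt = np.linalg.svd(centered - centered.mean(axis=0), full_matrices=False)
    normal = vt[2]
    if normal @ (point - outward_ref) < 0:
        normal = -normal
    e1, e2 = vt[0], vt[1]
    xy = centered @ np.column_stack([e1, e2])
    h = centered @ normal
    x, y = xy[:, 0], xy[:, 1]
    design = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, h, rcond=None)
    a, b, c, d, e, _ = coef
    w = np.sqrt(1.0 + d * d + e * e)
    first = np.array([[1 + d * d, d * e], [d * e, 1 + e * e]])
    second = np.array([[2 * a, b], [b, 2 * c]]) / w
    shape_op = np.linalg.solve(first, second)
    k = np.linalg.eigvals(shape_op).real
    # h measured along the outward normal: a convex bump has negative a, c
    return -float(k[0]), -float(k[1])


def vertex_curvatures(
    mesh: SurfaceMesh, radius_mm: float = 10.0, min_neighbors: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex mean and Gaussian curvature by local quadric fits."""
    tree = cKDTree(mesh.vertices)
    ref = mesh.vertices.mean(axis=0)
    neighbor_lists = tree.query_ball_point(mesh.vertices, radius_mm)
    mc = np.full(mesh.n_vertices, np.nan)
    gc = np.full(mesh.n_vertices, np.nan)
    for i, nbrs in enumerate(neighbor_lists):
        if len(nbrs) < min_neighbors:
            continue
        k1, k2 = _principal_curvatures_at(mesh.vertices[i], mesh.vertices[nbrs], ref)
        prof = CurvatureProfile.from_principal(k1, k2)
        mc[i] = prof.mean_curvature
        gc[i] = prof.gaussian_curvature
    return mc, gc


def landmark_curvatures(
    mesh: SurfaceMesh,
    lms: LandmarkSet,
    radius_mm: float = 10.0,
    min_neighbors: int = 6,
) -> list[CurvatureProfile]:
    """Curvature profile at each of the 26 landmarks.

    Principal curvatures come from a quadric fit over the mesh vertices within
    ``radius_mm`` of the landmark, with normals oriented away from the mesh
    centroid (convex regions such as pronasale get positive mean curvature).
    """
    tree = cKDTree(mesh.vertices)
    ref = mesh.vertices.mean(axis=0)
    profiles = []
    for i, name in enumerate(lms.dictionary.names):
        nbrs = tree.query_ball_point(lms.coords[i], radius_mm)
        if len(nbrs) < min_neighbors:
            raise ValueError(
                f"landmark {name}: only {len(nbrs)} mesh vertices within "
                f"{radius_mm} mm (need >= {min_neighbors})"
            )
        k1, k2 = _principal_curvatures_at(lms.coords[i], mesh.vertices[nbrs], ref)
        profiles.append(CurvatureProfile.from_principal(k1, k2))
    return profiles


# ---------------------------------------------------------------------------
# Proportion indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionIndex:
    name: str
    numerator: tuple[str, str]
    denominator: tuple[str, str]


_DEFAULT_BATTERY: list[tuple[str, tuple[str, str], tuple[str, str]]] = [
    ("facial_index", ("nasion", "gnathion"), ("zygion_l", "zygion_r")),
    ("mandibular_width_index", ("gonion_l", "gonion_r"), ("zygion_l", "zygion_r")),
    ("upper_face_index", ("nasion", "stomion"), ("zygion_l", "zygion_r")),
    ("nasal_index", ("alare_l", "alare_r"), ("nasion", "subnasale")),
    ("nose_face_width_index", ("alare_l", "alare_r"), ("zygion_l", "zygion_r")),
    ("nasal_tip_index", ("subnasale", "pronasale"), ("alare_l", "alare_r")),
    ("nasal_protrusion_height_index", ("subnasale", "pronasale"), ("nasion", "subnasale")),
    ("intercanthal_index", ("endocanthion_l", "endocanthion_r"), ("exocanthion_l", "exocanthion_r")),
    ("orbital_width_index_l", ("exocanthion_l", "endocanthion_l"), ("endocanthion_l", "endocanthion_r")),
    ("orbital_width_index_r", ("exocanthion_r", "endocanthion_r"), ("endocanthion_l", "endocanthion_r")),
    ("biocular_face_index", ("exocanthion_l", "exocanthion_r"), ("zygion_l", "zygion_r")),
    ("mouth_face_width_index", ("cheilion_l", "cheilion_r"), ("zygion_l", "zygion_r")),
    ("nose_mouth_width_index", ("alare_l", "alare_r"), ("cheilion_l", "cheilion_r")),
    ("upper_lip_index", ("subnasale", "stomion"), ("cheilion_l", "cheilion_r")),
    ("lower_lip_index", ("stomion", "sublabiale"), ("cheilion_l", "cheilion_r")),
    ("vermilion_height_index", ("labiale_superius", "labiale_inferius"), ("cheilion_l", "cheilion_r")),
    ("chin_width_index", ("sublabiale", "gnathion"), ("gonion_l", "gonion_r")),
    ("lower_face_height_index", ("subnasale", "gnathion"), ("nasion", "gnathion")),
    ("upper_face_height_index", ("nasion", "subnasale"), ("nasion", "gnathion")),
    ("forehead_nose_index", ("glabella", "nasion"), ("nasion", "subnasale")),
    ("face_depth_index_l", ("tragion_l", "gnathion"), ("tragion_l", "nasion")),
    ("face_depth_index_r", ("tragion_r", "gnathion"), ("tragion_r", "nasion")),
    ("bitragal_face_index", ("tragion_l", "tragion_r"), ("zygion_l", "zygion_r")),
    ("bigonial_bitragal_index", ("gonion_l", "gonion_r"), ("tragion_l", "tragion_r")),
    ("nasal_root_index", ("endocanthion_l", "endocanthion_r"), ("alare_l", "alare_r")),
    ("philtrum_mouth_index", ("subnasale", "labiale_superius"), ("cheilion_l", "cheilion_r")),
    ("chin_height_index", ("sublabiale", "gnathion"), ("subnasale", "gnathion")),
    ("mouth_chin_index", ("stomion", "gnathion"), ("subnasale", "gnathion")),
    ("nose_lower_face_index", ("nasion", "subnasale"), ("subnasale", "gnathion")),
    ("ala_length_index_l", ("alare_l", "pronasale"), ("alare_l", "alare_r")),
    ("ala_length_index_r", ("alare_r", "pronasale"), ("alare_l", "alare_r")),
    ("lip_height_ratio", ("labiale_superius", "stomion"), ("stomion", "labiale_inferius")),
]


def default_proportion_battery() -> list[ProportionIndex]:
    """The default battery of 32 Farkas-style proportion indices.

    Stand-ins for a study-specific supplementary list; any battery of
    (numerator pair, denominator pair) definitions can be substituted.
    """
    return [ProportionIndex(n, a, b) for n, a, b in _DEFAULT_BATTERY]


def proportion_indices(
    lms: LandmarkSet, battery: list[ProportionIndex] | None = None
) -> dict[str, float]:
    """Each index is the smaller distance as a percentage of the larger,
    so every value lies in (0, 100]."""
    battery = battery or default_proportion_battery()
    out = {}
    for idx in battery:
        num = float(np.linalg.norm(lms[idx.numerator[0]] - lms[idx.numerator[1]]))
        den = float(np.linalg.norm(lms[idx.denominator[0]] - lms[idx.denominator[1]]))
        lo, hi = sorted((num, den))
        if hi == 0.0:
            raise ValueError(f"proportion index {idx.name}: zero distance")
        out[idx.name] = 100.0 * lo / hi
    return out


# ---------------------------------------------------------------------------
# Angles and areas
# ---------------------------------------------------------------------------

def angles(lms: LandmarkSet) -> tuple[np.ndarray, list[str]]:
    """The three vertex angles (degrees) of every unordered landmark triple.

    3 * C(26,3) = 7800 values; within a triple the three angles are emitted in
    vertex landmark-index order and sum to 180 degrees.  A triple containing
    coincident landmarks yields NaN for its three angles.
    """
    coords = lms.coords
    trips = triple_indices(len(lms.dictionary))
    p1, p2, p3 = coords[trips[:, 0]], coords[trips[:, 1]], coords[trips[:, 2]]
    vals = np.empty((len(trips), 3))
    for col, (v, a, b) in enumerate(((p1, p2, p3), (p2, p1, p3), (p3, p1, p2))):
        u1, u2 = a - v, b - v
        n1 = np.linalg.norm(u1, axis=1)
        n2 = np.linalg.norm(u2, axis=1)
        denom = n1 * n2
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.where(denom > 0, (u1 * u2).sum(1) / denom, np.nan)
        vals[:, col] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    degenerate = ~np.isfinite(vals).all(axis=1)
    vals[degenerate] = np.nan
    names = lms.dictionary.names
    labels = [
        f"{names[t[col]]}@{names[t[0]]}|{names[t[1]]}|{names[t[2]]}"
        for t in trips
        for col in range(3)
    ]
    return vals.reshape(-1), labels


def triangle_areas(lms: LandmarkSet) -> tuple[np.ndarray, list[str]]:
    """Heron's-formula area (mm^2) of every landmark triple (2600 values).

    A = sqrt(s(s-a)(s-b)(s-c)) with s the semiperimeter; a negative radicand
    from rounding on collinear triples clamps to zero.
    """
    coords = lms.coords
    trips = triple_indices(len(lms.dictionary))
    p1, p2, p3 = coords[trips[:, 0]], coords[trips[:, 1]], coords[trips[:, 2]]
    a = np.linalg.norm(p2 - p3, axis=1)
    b = np.linalg.norm(p1 - p3, axis=1)
    c = np.linalg.norm(p1 - p2, axis=1)
    s = 0.5 * (a + b + c)
    rad = s * (s - a) * (s - b) * (s - c)
    areas = np.sqrt(np.clip(rad, 0.0, None))
    names = lms.dictionary.names
    labels = [f"{names[i]}|{names[j]}|{names[k]}" for i, j, k in trips]
    return areas, labels


# ---------------------------------------------------------------------------
# Region hulls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionDefinition:
    name: str
    landmarks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.landmarks)) != len(self.landmarks):
            raise ValueError(f"region {self.name}: duplicate landmarks")


_DEFAULT_REGIONS: list[tuple[str, tuple[str, ...]]] = [
    ("nose", ("nasion", "pronasale", "subnasale", "alare_l", "alare_r", "subalare_l", "subalare_r")),
    ("cheek_l", ("zygion_l", "exocanthion_l", "alare_l", "cheilion_l", "gonion_l", "tragion_l")),
    ("cheek_r", ("zygion_r", "exocanthion_r", "alare_r", "cheilion_r", "gonion_r", "tragion_r")),
    ("chin", ("sublabiale", "pogonion", "gnathion", "gonion_l", "gonion_r")),
    ("mouth", ("cheilion_l", "cheilion_r", "labiale_superius", "labiale_inferius", "stomion", "sublabiale")),
    ("upper_lip", ("subnasale", "labiale_superius", "stomion", "cheilion_l", "cheilion_r")),
    ("lower_lip", ("stomion", "labiale_inferius", "sublabiale", "cheilion_l", "cheilion_r")),
    ("eye_span", ("endocanthion_l", "endocanthion_r", "exocanthion_l", "exocanthion_r", "glabella", "nasion")),
    ("jaw", ("gonion_l", "gonion_r", "gnathion", "pogonion", "tragion_l", "tragion_r")),
    ("midface", ("nasion", "zygion_l", "zygion_r", "subnasale", "pronasale")),
]


def default_regions() -> list[RegionDefinition]:
    """Ten default facial regions for hull volumes and surface areas."""
    return [RegionDefinition(n, lm) for n, lm in _DEFAULT_REGIONS]


def region_volume_surface(
    lms: LandmarkSet, regions: list[RegionDefinition] | None = None
) -> dict[str, tuple[float, float]]:
    """Convex-hull volume (mm^3) and surface area (mm^2) per region.

    Coplanar point sets get volume 0 (with a warning) and the area of the
    planar hull polygon.
    """
    regions = regions or default_regions()
    out: dict[str, tuple[float, float]] = {}
    for region in regions:
        pts = np.stack([lms[name] for name in region.landmarks])
        if len(pts) < 3:
            raise ValueError(f"region {region.name}: needs >= 3 landmarks")
        try:
            hull = ConvexHull(pts)
            out[region.name] = (float(hull.volume), float(hull.area))
        except QhullError:
            warnings.warn(f"region {region.name}: coplanar landmarks, volume set to 0")
            centered = pts - pts.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            xy = centered @ vt[:2].T
            try:
                area = float(ConvexHull(xy).volume)  # 2D hull "volume" is area
            except QhullError:
                area = 0.0
            out[region.name] = (0.0, area)
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

ALL_FAMILIES = (
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
)


def extract_phenotypes(
    landmark_sets: list[LandmarkSet],
    meshes: list[SurfaceMesh] | None = None,
    families: tuple[str, ...] = ALL_FAMILIES,
    battery: list[ProportionIndex] | None = None,
    regions: list[RegionDefinition] | None = None,
    curvature_radius_mm: float = 10.0,
    geodesic_snap_tolerance_mm: float = 2.0,
) -> PhenotypeMatrix:
    """Assemble the phenotype matrix for a set of individuals.

    ``landmark_sets`` should already be replicate-averaged and GPA-aligned
    (the Manhattan family assumes a common frame).  The Curvature and Geodesic
    families require one mesh per individual, in the same frame as its
    landmarks.
    """
    mesh_families = {"Curvature", "Geodesic"}
    if mesh_families & set(families):
        if meshes is None or len(meshes) != len(landmark_sets):
            raise ValueError("Curvature/Geodesic families need one mesh per individual")
    dictionary = landmark_sets[0].dictionary
    ids = [s.individual_id for s in landmark_sets]
    names = dictionary.names
    parts: list[PhenotypeMatrix] = []

    def block(family: str, columns: list[str], rows: list[np.ndarray], units: str):
        labelled = [f"{family}:{c}" for c in columns]
        parts.append(
            PhenotypeMatrix.from_array(np.stack(rows), ids, labelled, family, units)
        )

    if "Point" in families:
        cols = [f"{n}.{ax}" for n in names for ax in ("x", "y", "z")]
        block("Point", cols, [s.coords.reshape(-1) for s in landmark_sets], "mm")
    if "Curvature" in families:
        rows = []
        for s, m in zip(landmark_sets, meshes):
            profs = landmark_curvatures(m, s, curvature_radius_mm)
            rows.append(
                np.array(
                    [p.mean_curvature for p in profs] + [p.gaussian_curvature for p in profs]
                )
            )
        cols = [f"MC.{n}" for n in names] + [f"GC.{n}" for n in names]
        block("Curvature", cols, rows, "1/mm;1/mm^2")
    pairs = pair_names(dictionary)
    if "Euclidean" in families:
        block("Euclidean", pairs, [euclidean_distances(s) for s in landmark_sets], "mm")
    if "Manhattan" in families:
        block("Manhattan", pairs, [manhattan_distances(s) for s in landmark_sets], "mm")
    if "Geodesic" in families:
        rows = [
            geodesic_distances(m, s, geodesic_snap_tolerance_mm)
            for s, m in zip(landmark_sets, meshes)
        ]
        block("Geodesic", pairs, rows, "mm")
    if "Index" in families:
        vals = [proportion_indices(s, battery) for s in landmark_sets]
        cols = list(vals[0].keys())
        block("Index", cols, [np.array([v[c] for c in cols]) for v in vals], "%")
    if "Angle" in families:
        rows, labels = [], None
        for s in landmark_sets:
            v, labels = angles(s)
            rows.append(v)
        block("Angle", labels, rows, "deg")
    if "Triangle_area" in families:
        rows, labels = [], None
        for s in landmark_sets:
            v, labels = triangle_areas(s)
            rows.append(v)
        block("Triangle_area", labels, rows, "mm^2")
    if "Volume" in families or "Surface_area" in families:
        per_ind = [region_volume_surface(s, regions) for s in landmark_sets]
        region_names = list(per_ind[0].keys())
        if "Volume" in families:
            block(
                "Volume",
                region_names,
                [np.array([v[r][0] for r in region_names]) for v in per_ind],
                "mm^3",
            )
        if "Surface_area" in families:
            block(
                "Surface_area",
                region_names,
                [np.array([v[r][1] for r in region_names]) for v in per_ind],
                "mm^2",
            )
    return PhenotypeMatrix.concat(parts)
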