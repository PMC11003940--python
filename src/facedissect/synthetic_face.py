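"""Synthetic face-like populations with known regional structure.

The study data this pipeline targets (3D facial scans with manual landmark
replicates) is not publicly deposited, so every downstream stage is exercised
on procedurally generated faces: a parametric face-like surface patch (domed
ellipsoid with nose ridge, eye depressions and a mouth groove), 26 template
landmarks at the named features, and a population model with

* per-region mean landmark displacements (optionally graded monotonically
  north -> central -> south),
* individual Gaussian shape variation (``sigma_individual``),
* two landmarking replicates with per-landmark measurement noise
  (``sigma_measurement``), mimicking two manual landmarking sessions,
* small linear age/sex drifts so covariate adjustment has signal to remove,
* a Gaussian radial-basis warp tying each individual's mesh to its landmarks.

Everything is reproducible bit-for-bit from (model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    LandmarkDictionary,
    LandmarkSet,
    SurfaceMesh,
    default_landmark_dictionary,
)

__all__ = [
    "FaceTemplate",
    "PopulationModel",
    "Individual",
    "PopulationSample",
    "build_template",
    "warp_mesh",
    "simulate_population",
]

# Half-axes of the elliptical face domain and dome height, mm.
_FACE_HALF_WIDTH = 85.0
_FACE_HALF_HEIGHT = 100.0
_DOME_HEIGHT = 55.0
_DOMAIN_MARGIN = 0.94  # keep (x/a)^2 + (y/b)^2 below this to avoid the steep rim

# (x, y) feature positions of the 26 default landmarks on the template, mm.
_LANDMARK_XY: dict[str, tuple[float, float]] = {
    "glabella": (0.0, 45.0),
    "nasion": (0.0, 32.0),
    "pronasale": (0.0, -8.0),
    "subnasale": (0.0, -22.0),
    "labiale_superius": (0.0, -38.0),
    "stomion": (0.0, -45.0),
    "labiale_inferius": (0.0, -52.0),
    "sublabiale": (0.0, -62.0),
    "pogonion": (0.0, -72.0),
    "gnathion": (0.0, -84.0),
    "endocanthion_l": (14.0, 28.0),
    "endocanthion_r": (-14.0, 28.0),
    "exocanthion_l": (42.0, 28.0),
    "exocanthion_r": (-42.0, 28.0),
    "zygion_l": (62.0, 8.0),
    "zygion_r": (-62.0, 8.0),
    "alare_l": (16.0, -14.0),
    "alare_r": (-16.0, -14.0),
    "subalare_l": (11.0, -20.0),
    "subalare_r": (-11.0, -20.0),
    "cheilion_l": (24.0, -45.0),
    "cheilion_r": (-24.0, -45.0),
    "gonion_l": (52.0, -55.0),
    "gonion_r": (-52.0, -55.0),
    "tragion_l": (72.0, 25.0),
    "tragion_r": (-72.0, 25.0),
}


def _face_height(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """z(x, y) of the template: dome plus facial features (mm)."""
    r2 = (x / _FACE_HALF_WIDTH) ** 2 + (y / _FACE_HALF_HEIGHT) ** 2
    z = _DOME_HEIGHT * np.sqrt(np.clip(1.0 - r2, 0.0, None))
    # nose ridge running down the midline, plus a tip bump at pronasale
    z = z + 10.0 * np.exp(-(x**2) / (2 * 8.0**2) - ((y + 5.0) ** 2) / (2 * 16.0**2))
    z = z + 6.0 * np.exp(-(x**2 + (y + 8.0) ** 2) / (2 * 6.0**2))
    # eye depressions
    for sx in (+1.0, -1.0):
        z = z - 5.0 * np.exp(-((x - sx * 30.0) ** 2 + (y - 28.0) ** 2) / (2 * 11.0**2))
    # mouth groove (shallow, wide in x)
    z = z - 3.0 * np.exp(-(x**2) / (2 * 18.0**2) - ((y + 45.0) ** 2) / (2 * 4.0**2))
    return z


@dataclass
class FaceTemplate:
    """Procedural face surface plus the vertex ids of its 26 landmarks."""

    mesh: SurfaceMesh
    landmark_vertex_ids: np.ndarray
    dictionary: LandmarkDictionary
    resolution: int

    @property
    def landmarks(self) -> LandmarkSet:
        coords = self.mesh.vertices[self.landmark_vertex_ids]
        return LandmarkSet(coords, self.dictionary, individual_id="template")


def build_template(resolution: int = 81) -> FaceTemplate:
    """Build the parametric face patch on a ``resolution x resolution`` grid.

    ``resolution`` is the grid sampling per axis; the default yields roughly
    5000 vertices, echoing the vertex-count scale of a decimated facial scan.
    Raises if the grid is too coarse to give 26 distinct landmark vertices.
    """
    if resolution < 3:
        raise ValueError("resolution must be >= 3")
    u = np.linspace(-1.0, 1.0, resolution)
    xx, yy = np.meshgrid(u * _FACE_HALF_WIDTH, u * _FACE_HALF_HEIGHT, indexing="ij")
    inside = (xx / _FACE_HALF_WIDTH) ** 2 + (yy / _FACE_HALF_HEIGHT) ** 2 <= _DOMAIN_MARGIN
    index = -np.ones(xx.shape, dtype=np.int64)
    index[inside] = np.arange(int(inside.sum()))
    xs, ys = xx[inside], yy[inside]
    zs = _face_height(xs, ys)
    vertices = np.column_stack([xs, ys, zs])

    faces = []
    for i in range(resolution - 1):
        for j in range(resolution - 1):
            a, b = index[i, j], index[i + 1, j]
            c, d = index[i + 1, j + 1], index[i, j + 1]
            if a >= 0 and b >= 0 and c >= 0:
                faces.append((a, b, c))
            if a >= 0 and c >= 0 and d >= 0:
                faces.append((a, c, d))
    mesh = SurfaceMesh(vertices, np.asarray(faces, dtype=np.int64))

    dictionary = default_landmark_dictionary()
    ids = []
    for name in dictionary.names:
        px, py = _LANDMARK_XY[name]
        d2 = (xs - px) ** 2 + (ys - py) ** 2
        ids.append(int(np.argmin(d2)))
    ids = np.asarray(ids, dtype=np.int64)
    if len(set(ids.tolist())) != len(ids):
        raise ValueError(
            f"resolution {resolution} too coarse: landmark vertices are not distinct"
        )
    return FaceTemplate(mesh, ids, dictionary, resolution)


# ---------------------------------------------------------------------------
# Population model
# ---------------------------------------------------------------------------

def _default_gradient_effects() -> dict[tuple[str, int], tuple[float, ...]]:
    # (landmark, axis) -> per-region mean offsets in mm, north -> south.
    # Monotone gradients on nose projection, nose width, face width and chin
    # height; magnitudes are free parameters of the generator (the study
    # reports significance, not effect sizes).
    return {
        ("pronasale", 2): (1.5, 0.0, -1.5),
        ("alare_l", 0): (-1.0, 0.0, 1.0),
        ("alare_r", 0): (1.0, 0.0, -1.0),
        ("zygion_l", 0): (1.2, 0.3, -1.2),
        ("zygion_r", 0): (-1.2, -0.3, 1.2),
        ("gnathion", 1): (-1.5, 0.0, 1.5),
    }


@dataclass
class PopulationModel:
    """Generative model for a three-region face population.

    ``gradient_effects`` maps (landmark name, axis 0/1/2) to one mean offset
    per region in ``regions`` order; by default the per-trait means are
    strictly monotone from north to south.  ``measurement_sd_per_landmark``
    optionally replaces the isotropic landmarking noise with per-landmark
    values (some landmarks, e.g. zygion, are far noisier in practice).
    """

    regions: tuple[str, ...] = ("north", "central", "south")
    gradient_effects: dict[tuple[str, int], tuple[float, ...]] = field(
        default_factory=_default_gradient_effects
    )
    sigma_individual: float = 1.0
    sigma_measurement: float = 0.5
    measurement_sd_per_landmark: np.ndarray | None = None
    age_effect_mm_per_year: dict[tuple[str, int], float] = field(
        default_factory=lambda: {("gnathion", 1): -0.03, ("pronasale", 2): -0.02}
    )
    sex_effect_mm: dict[tuple[str, int], float] = field(
        default_factory=lambda: {("zygion_l", 0): 0.6, ("zygion_r", 0): -0.6}
    )
    age_mean: float = 49.0
    age_sd: float = 12.7
    warp_bandwidth_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.sigma_individual < 0 or self.sigma_measurement < 0:
            raise ValueError("noise SDs must be >= 0")
        for key, vals in self.gradient_effects.items():
            if len(vals) != len(self.regions):
                raise ValueError(f"effect {key} needs one value per region")
            diffs = np.diff(vals)
            if not ((diffs > 0).all() or (diffs < 0).all() or (diffs == 0).all()):
                raise ValueError(f"gradient effect {key} is not monotone across regions")

    @classmethod
    def null(cls, **kwargs) -> "PopulationModel":
        """A model with no region, age or sex structure (pure noise)."""
        return cls(
            gradient_effects={},
            age_effect_mm_per_year={},
            sex_effect_mm={},
            **kwargs,
        )

    def region_displacements(self, dictionary: LandmarkDictionary) -> np.ndarray:
        """(n_regions, 26, 3) mean landmark offsets."""
        out = np.zeros((len(self.regions), len(dictionary), 3))
        for (name, axis), vals in self.gradient_effects.items():
            out[:, dictionary.index(name), axis] += np.asarray(vals)
        return out

    def _effect_field(
        self, effects: Mapping[tuple[str, int], float], dictionary: LandmarkDictionary
    ) -> np.ndarray:
        out = np.zeros((len(dictionary), 3))
        for (name, axis), v in effects.items():
            out[dictionary.index(name), axis] += v
        return out


@dataclass
class Individual:
    """One simulated participant: labels, true shape, mesh, two replicates."""

    individual_id: str
    region: str
    sex: str
    age: float
    true_landmarks: LandmarkSet
    replicates: tuple[LandmarkSet, LandmarkSet]
    mesh: SurfaceMesh | None = None


@dataclass
class PopulationSample:
    template: FaceTemplate
    model: PopulationModel
    individuals: list[Individual]
    seed: int

    def __len__(self) -> int:
        return len(self.individuals)

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": [i.individual_id for i in self.individuals],
                "region": [i.region for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "age": [i.age for i in self.individuals],
            }
        ).set_index("individual")

    def averaged_landmarks(self) -> list[LandmarkSet]:
        from .align import average_replicates

        return [average_replicates(*ind.replicates) for ind in self.individuals]


def _wendland_c2(r: np.ndarray, support: float) -> np.ndarray:
    """Wendland C2 compactly supported RBF: (1 - s)^4 (4s + 1), s = r/support."""
    s = np.clip(r / support, 0.0, 1.0)
    return (1.0 - s) ** 4 * (4.0 * s + 1.0)


def warp_mesh(
    template: FaceTemplate,
    target_landmarks: LandmarkSet,
    bandwidth_mm: float = 30.0,
) -> SurfaceMesh:
    """Deform the template so its landmark vertices land on the targets.

    Radial-basis interpolation of the 26 landmark displacements with a
    Wendland C2 kernel of support ``2.5 * bandwidth_mm``: exact at every
    landmark, smooth, strictly local (identically zero beyond the support),
    and well conditioned even for closely spaced landmarks — an exact
    interpolant with a globally supported kernel at this bandwidth is
    near-singular and rings far from the moved landmarks.
    """
    src = template.mesh.vertices[template.landmark_vertex_ids]
    dst = np.asarray(target_landmarks.coords, dtype=float)
    if not np.isfinite(dst).all():
        raise ValueError("target landmarks must be finite")
    d = src[:, None, :] - src[None, :, :]
    pair = np.sqrt((d**2).sum(-1))
    np.fill_diagonal(pair, np.inf)
    if pair.min() < 1e-9:
        raise ValueError("degenerate template: coincident landmark vertices")
    dd = dst[:, None, :] - dst[None, :, :]
    pair_t = np.sqrt((dd**2).sum(-1))
    np.fill_diagonal(pair_t, np.inf)
    if pair_t.min() < 1e-9:
        raise ValueError("degenerate target: coincident landmarks")
    disp = dst - src
    if np.allclose(disp, 0.0):
        return SurfaceMesh(template.mesh.vertices.copy(), template.mesh.faces.copy())
    support = 2.5 * bandwidth_mm
    np.fill_diagonal(pair, 0.0)
    kernel = _wendland_c2(pair, support)
    coeffs = np.linalg.solve(kernel, disp)
    r_eval = np.linalg.norm(
        template.mesh.vertices[:, None, :] - src[None, :, :], axis=-1
    )
    new_vertices = template.mesh.vertices + _wendland_c2(r_eval, support) @ coeffs
    return SurfaceMesh(new_vertices, template.mesh.faces.copy())


def simulate_population(
    template: FaceTemplate,
    model: PopulationModel,
    n_per_region: int,
    seed: int,
    generate_meshes: bool = True,
) -> PopulationSample:
    """Draw a population of ``n_per_region`` individuals per region.

    Per individual: true landmarks = template + region offset + covariate
    drift + N(0, sigma_individual^2) per coordinate; each of the two replicates
    adds independent N(0, sigma_measurement^2) landmarking noise; the mesh is
    the template RBF-warped onto the true landmarks.
    """
    if n_per_region < 1:
        raise ValueError("n_per_region must be >= 1")
    rng = np.random.default_rng(seed)
    dictionary = template.dictionary
    base = template.mesh.vertices[template.landmark_vertex_ids]
    region_disp = model.region_displacements(dictionary)
    age_field = model._effect_field(model.age_effect_mm_per_year, dictionary)
    sex_field = model._effect_field(model.sex_effect_mm, dictionary)
    if model.measurement_sd_per_landmark is not None:
        meas_sd = np.asarray(model.measurement_sd_per_landmark, float)[:, None]
        if meas_sd.shape[0] != len(dictionary):
            raise ValueError("per-landmark SD table must have 26 entries")
    else:
        meas_sd = np.full((len(dictionary), 1), model.sigma_measurement)

    individuals: list[Individual] = []
    for r_idx, region in enumerate(model.regions):
        for k in range(n_per_region):
            ind_id = f"{region}_{k:04d}"
            age = float(np.clip(rng.normal(model.age_mean, model.age_sd), 17.0, 83.0))
            sex = "M" if rng.random() < 0.5 else "F"
            true = (
                base
                + region_disp[r_idx]
                + (age - model.age_mean) * age_field
                + (1.0 if sex == "M" else 0.0) * sex_field
                + rng.normal(0.0, model.sigma_individual, size=base.shape)
            )
            true_lms = LandmarkSet(true, dictionary, ind_id, "true")
            reps = tuple(
                LandmarkSet(
                    true + rng.normal(0.0, 1.0, size=base.shape) * meas_sd,
                    dictionary,
                    ind_id,
                    f"{j + 1}",
                )
                for j in range(2)
            )
            mesh = (
                warp_mesh(template, true_lms, model.warp_bandwidth_mm)
                if generate_meshes
                else None
            )
            individuals.append(Individual(ind_id, region, sex, age, true_lms, reps, mesh))
    return PopulationSample(template, model, individuals, seed)
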