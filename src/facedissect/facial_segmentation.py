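"""Global-to-local facial segmentation and per-segment phenotypes.

The facial surface is partitioned by recursive two-way spectral clustering of
template vertices, using as affinity the RV coefficient between the vertices'
3D displacement patterns across the sample (vertices that co-vary strongly
end up in the same module).  Run to 7 levels this yields 2^7 - 1 = 127 nested
segments, the whole face included.  Per segment the module then derives:

* shape principal components, with the retained count set by Horn's parallel
  analysis against column-permuted null data,
* surface area on an individual's mesh,
* Moran's I spatial autocorrelation of the z coordinate, mean curvature or
  Gaussian curvature over the segment's vertices, with k-nearest-neighbour
  weights built from the (x, y) vertex locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.linalg import ArpackNoConvergence, eigsh
from scipy.spatial import cKDTree

from .align import gpa, kabsch_rotation
from .core_io import PhenotypeMatrix, SurfaceMesh
from .synthetic_face import FaceTemplate, PopulationSample

__all__ = [
    "Segment",
    "SegmentHierarchy",
    "SegmentShapeModel",
    "SpatialWeightMatrix",
    "displacement_field",
    "vertex_similarity",
    "hierarchical_segmentation",
    "segment_pca",
    "segment_surface_area",
    "knn_weights",
    "morans_i",
    "segment_moran",
    "extract_segment_phenotypes",
]


# ---------------------------------------------------------------------------
# Dense correspondence
# ---------------------------------------------------------------------------

def displacement_field(
    sample: PopulationSample,
    template: FaceTemplate | None = None,
    align: bool = True,
) -> np.ndarray:
    """Per-individual, per-template-vertex 3D displacements, (n, V, 3).

    Meshes must be in template correspondence (same vertex count and order) —
    true by construction for synthetic samples; externally registered data
    must arrive the same way.  With ``align=True`` each individual's mesh is
    first carried into the template frame by the rigid (rotation+translation)
    transform fitted on its true landmarks.
    """
    template = template or sample.template
    tv = template.mesh.vertices
    fields = np.empty((len(sample), len(tv), 3))
    t_lms = tv[template.landmark_vertex_ids]
    t_cent = t_lms.mean(axis=0)
    for i, ind in enumerate(sample.individuals):
        if ind.mesh is None:
            raise ValueError(f"individual {ind.individual_id} has no mesh")
        if ind.mesh.n_vertices != len(tv):
            raise ValueError(
                f"individual {ind.individual_id}: {ind.mesh.n_vertices} vertices vs "
                f"template {len(tv)}; register meshes to the template externally first"
            )
        verts = ind.mesh.vertices
        if align:
            lms = ind.true_landmarks.coords
            c = lms.mean(axis=0)
            r = kabsch_rotation(lms - c, t_lms - t_cent)
            verts = (verts - c) @ r.T + t_cent
        fields[i] = verts - tv
    return fields


# ---------------------------------------------------------------------------
# RV similarity
# ---------------------------------------------------------------------------

def vertex_similarity(fields: np.ndarray) -> np.ndarray:
    """Pairwise RV coefficient between template vertices' displacement blocks.

    For vertices i, j with centered n x 3 displacement matrices X_i, X_j the
    similarity is  RV(i,j) = tr(C_ij C_ji) / sqrt(tr(C_ii^2) tr(C_jj^2))  with
    C_ij = X_i^T X_j; values lie in [0, 1].  Vertices with zero displacement
    variance get similarity 0 (with a warning).
    """
    fields = np.asarray(fields, float)
    n, v, _ = fields.shape
    if n < 10:
        raise ValueError("vertex similarity needs >= 10 individuals")
    x = fields - fields.mean(axis=0, keepdims=True)
    # numerator[i, j] = sum_{a,b} (X_a^T X_b)_{ij}^2 over the 3 coordinate axes
    num = np.zeros((v, v))
    for a in range(3):
        for b in range(3):
            g = x[:, :, a].T @ x[:, :, b]
            num += g * g
    diag = np.sqrt(np.diag(num))
    zero = diag <= 1e-12
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance vertices; similarity set to 0")
    denom = np.outer(diag, diag)
    with np.errstate(invalid="ignore", divide="ignore"):
        rv = np.where(denom > 0, num / denom, 0.0)
    np.clip(rv, 0.0, 1.0, out=rv)
    rv[zero, :] = 0.0
    rv[:, zero] = 0.0
    return rv


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    segment_id: int  # heap numbering: root 1, children 2k and 2k+1
    level: int  # 1-based; root is level 1
    parent_id: int | None
    vertex_ids: np.ndarray


@dataclass
class SegmentHierarchy:
    segments: dict[int, Segment]
    levels: int
    n_vertices: int

    def __len__(self) -> int:
        return len(self.segments)

    def at_level(self, level: int) -> list[Segment]:
        return [s for s in self.segments.values() if s.level == level]

    def children(self, segment_id: int) -> list[Segment]:
        return [s for s in (self.segments.get(2 * segment_id),
                            self.segments.get(2 * segment_id + 1)) if s is not None]

    def membership_table(self) -> pd.DataFrame:
        rows = []
        for seg in sorted(self.segments.values(), key=lambda s: s.segment_id):
            for vid in seg.vertex_ids:
                rows.append((int(vid), seg.segment_id, seg.level))
        return pd.DataFrame(rows, columns=["vertex", "segment", "level"])


def _fiedler_split(w: np.ndarray) -> np.ndarray:
    """Boolean mask of the positive side of the normalized-Laplacian Fiedler
    vector; ties (zeros) go to the smaller side."""
    m = len(w)
    d = w.sum(axis=1)
    d = np.where(d <= 1e-12, 1e-12, d)
    inv_sqrt = 1.0 / np.sqrt(d)
    a = w * np.outer(inv_sqrt, inv_sqrt)  # D^-1/2 W D^-1/2
    a = 0.5 * (a + a.T)
    if m <= 200:
        vals, vecs = np.linalg.eigh(a)
        fiedler = vecs[:, -2]  # second-largest of the affinity = Fiedler of L_sym
    else:
        try:
            vals, vecs = eigsh(a, k=2, which="LA")
            fiedler = vecs[:, np.argsort(vals)[0]]
        except ArpackNoConvergence:
            vals, vecs = np.linalg.eigh(a)
            fiedler = vecs[:, -2]
    pos = fiedler > 0
    if pos.sum() == 0 or pos.sum() == m:
        # degenerate eigenvector: split at the median instead
        pos = fiedler >= np.median(fiedler)
        if pos.sum() in (0, m):
            pos = np.zeros(m, bool)
            pos[: m // 2] = True
            return pos
    if pos.sum() > m - pos.sum():
        # zero entries (if any) belong to the smaller side
        pos = pos & (fiedler != 0)
    return pos


def hierarchical_segmentation(
    similarity: np.ndarray,
    levels: int = 7,
    min_size: int = 10,
) -> SegmentHierarchy:
    """Recursive two-way spectral partition of the vertex similarity matrix.

    Splits ``levels - 1`` times; all 2^levels - 1 segments, ancestors
    included, are returned.  A branch whose split would produce a segment
    smaller than ``min_size`` stops subdividing (with a warning), in which
    case the total count falls short of 2^levels - 1.
    """
    similarity = np.asarray(similarity, float)
    if similarity.ndim != 2 or similarity.shape[0] != similarity.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(similarity, similarity.T, atol=1e-8):
        raise ValueError("similarity must be symmetric")
    if (similarity < -1e-12).any():
        raise ValueError("similarity must be nonnegative")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n = similarity.shape[0]
    root = Segment(1, 1, None, np.arange(n))
    segments = {1: root}
    frontier = [root]
    for level in range(2, levels + 1):
        next_frontier = []
        for seg in frontier:
            idx = seg.vertex_ids
            if len(idx) < 2:
                warnings.warn(
                    f"segment {seg.segment_id} has {len(idx)} vertices; branch stops"
                )
                continue
            sub = similarity[np.ix_(idx, idx)]
            mask = _fiedler_split(sub)
            left, right = idx[mask], idx[~mask]
            if min(len(left), len(right)) < min_size:
                warnings.warn(
                    f"split of segment {seg.segment_id} would give a segment of "
                    f"{min(len(left), len(right))} < {min_size} vertices; branch stops"
                )
                continue
            for child_idx, vid in ((2 * seg.segment_id, left), (2 * seg.segment_id + 1, right)):
                child = Segment(child_idx, level, seg.segment_id, np.sort(vid))
                segments[child_idx] = child
                next_frontier.append(child)
        frontier = next_frontier
    return SegmentHierarchy(segments, levels, n)


# ---------------------------------------------------------------------------
# Segment PCA with parallel analysis
# ---------------------------------------------------------------------------

@dataclass
class SegmentShapeModel:
    segment_id: int
    n_retained: int
    scores: np.ndarray  # (n_individuals, n_retained)
    explained_variance_ratio: np.ndarray
    null_thresholds: np.ndarray


def segment_pca(
    fields: np.ndarray,
    segment: Segment | np.ndarray,
    n_null: int = 100,
    seed: int = 0,
    percentile: float = 95.0,
) -> SegmentShapeModel:
    """PCA of a segment's displacement data with Horn's parallel analysis.

    The individuals x (3 * segment vertices) matrix is column-centered and
    decomposed; a component is retained while its eigenvalue exceeds the
    ``percentile`` of the matching-rank eigenvalues from ``n_null``
    column-permuted datasets.  Score signs follow the convention that each
    component's largest-magnitude loading is positive.
    """
    if n_null < 20:
        raise ValueError("n_null must be >= 20 for a usable null")
    vid = segment.vertex_ids if isinstance(segment, Segment) else np.asarray(segment)
    if len(vid) < 3:
        raise ValueError("segment must have >= 3 vertices")
    n = fields.shape[0]
    if n < 10:
        raise ValueError("segment PCA needs >= 10 individuals")
    x = fields[:, vid, :].reshape(n, -1)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()

    rng = np.random.default_rng(seed)
    k = len(eig)
    null_eigs = np.empty((n_null, k))
    for b in range(n_null):
        xp = rng.permuted(x, axis=0)  # each column shuffled independently
        xp -= xp.mean(axis=0, keepdims=True)
        if xp.shape[0] <= xp.shape[1]:
            ev = np.linalg.eigvalsh(xp @ xp.T)[::-1] / (n - 1)
        else:
            ev = np.linalg.eigvalsh(xp.T @ xp)[::-1] / (n - 1)
        null_eigs[b] = np.clip(ev[:k], 0.0, None)
    thresholds = np.percentile(null_eigs, percentile, axis=0)

    n_retained = 0
    for j in range(k):
        if eig[j] > thresholds[j]:
            n_retained += 1
        else:
            break
    # sign convention: largest-|loading| entry of each retained component positive
    scores = u[:, :n_retained] * s[:n_retained]
    for j in range(n_retained):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    seg_id = segment.segment_id if isinstance(segment, Segment) else -1
    evr = eig / total if total > 0 else eig
    return SegmentShapeModel(seg_id, n_retained, scores, evr, thresholds)


# ---------------------------------------------------------------------------
# Segment surface area
# ---------------------------------------------------------------------------

def segment_surface_area(mesh: SurfaceMesh, segment: Segment | np.ndarray) -> float:
    """Total area (mm^2) of faces assigned to the segment.

    A face belongs to the segment when the majority (>= 2) of its vertices do,
    so per level the segment areas sum to (almost exactly) the whole-mesh area.
    """
    vid = segment.vertex_ids if isinstance(segment, Segment) else np.asarray(segment)
    member = np.zeros(mesh.n_vertices, bool)
    member[vid] = True
    counts = member[mesh.faces].sum(axis=1)
    return float(mesh.face_areas()[counts >= 2].sum())


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeightMatrix:
    weights: np.ndarray
    k: int
    row_standardized: bool = True


def knn_weights(locations: np.ndarray, k: int = 8, row_standardize: bool = True) -> SpatialWeightMatrix:
    """Symmetrized k-nearest-neighbour weights over 2D locations.

    Binary kNN adjacency, symmetrized by the maximum, zero diagonal, then
    (optionally) row-standardized to sum 1.
    """
    locations = np.asarray(locations, float)
    n = len(locations)
    if n < 2:
        raise ValueError("need >= 2 locations")
    k = min(k, n - 1)
    tree = cKDTree(locations)
    _, idx = tree.query(locations, k=k + 1)
    w = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    w[rows, idx[:, 1:].reshape(-1)] = 1.0
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    return SpatialWeightMatrix(w, k, row_standardize)


def morans_i(values: np.ndarray, weights: SpatialWeightMatrix | np.ndarray) -> float:
    """Global Moran's I of ``values`` under the given proximity weights.

        I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with S0 the total weight.  Null expectation under random permutation is
    -1/(n-1); a constant attribute is an error (zero denominator).
    """
    w = weights.weights if isinstance(weights, SpatialWeightMatrix) else np.asarray(weights)
    x = np.asarray(values, float)
    n = len(x)
    if n < 5:
        raise ValueError("Moran's I needs >= 5 observations")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom <= 0:
        raise ValueError("constant attribute: Moran's I undefined")
    s0 = w.sum()
    return float(n / s0 * (z @ w @ z) / denom)


def segment_moran(
    template: FaceTemplate | SurfaceMesh,
    segment: Segment | np.ndarray,
    attribute: np.ndarray,
    k: int = 8,
) -> float:
    """Moran's I of a per-vertex attribute (z, mean or Gaussian curvature)
    over a segment's vertices, with kNN weights from their (x, y) locations."""
    mesh = template.mesh if isinstance(template, FaceTemplate) else template
    vid = segment.vertex_ids if isinstance(segment, Segment) else np.asarray(segment)
    locs = mesh.vertices[vid][:, :2]
    return morans_i(np.asarray(attribute)[vid], knn_weights(locs, k=k))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def moran_attribute_fields(
    sample: PopulationSample,
    fields: np.ndarray,
    which: tuple[str, ...] = ("Module_mor_z",),
    curvature_radius_mm: float = 10.0,
) -> dict[str, np.ndarray]:
    """Per-individual per-vertex attribute arrays (n, V) for segment Moran's I.

    ``Module_mor_z`` is the z coordinate in the template frame (template plus
    displacement) and is cheap; ``Module_mor_mea`` / ``Module_mor_gau`` run a
    quadric curvature fit over every vertex of every individual's mesh, which
    dominates runtime for large samples.
    """
    from .landmark_phenotypes import vertex_curvatures

    tv = sample.template.mesh.vertices
    out: dict[str, np.ndarray] = {}
    if "Module_mor_z" in which:
        out["Module_mor_z"] = tv[None, :, 2] + fields[:, :, 2]
    if {"Module_mor_mea", "Module_mor_gau"} & set(which):
        mc_rows, gc_rows = [], []
        for i in range(fields.shape[0]):
            mesh_i = SurfaceMesh(tv + fields[i], sample.template.mesh.faces)
            mc, gc = vertex_curvatures(mesh_i, radius_mm=curvature_radius_mm)
            mc_rows.append(mc)
            gc_rows.append(gc)
        if "Module_mor_mea" in which:
            out["Module_mor_mea"] = np.stack(mc_rows)
        if "Module_mor_gau" in which:
            out["Module_mor_gau"] = np.stack(gc_rows)
    return out


def extract_segment_phenotypes(
    sample: PopulationSample,
    hierarchy: SegmentHierarchy,
    fields: np.ndarray,
    n_null: int = 100,
    seed: int = 0,
    moran_attributes: dict[str, np.ndarray] | None = None,
    moran_k: int = 8,
) -> PhenotypeMatrix:
    """Per-segment phenotype block: PCs, surface areas, and Moran's I columns.

    ``moran_attributes`` maps category tags (Module_mor_z, Module_mor_mea,
    Module_mor_gau) to per-individual, per-template-vertex attribute arrays of
    shape (n, V), as built by :func:`moran_attribute_fields`.
    """
    ids = [ind.individual_id for ind in sample.individuals]
    parts: list[PhenotypeMatrix] = []
    seg_ids = sorted(hierarchy.segments)

    pc_cols, pc_rows = [], []
    rng = np.random.default_rng(seed)
    for sid in seg_ids:
        seg = hierarchy.segments[sid]
        if len(seg.vertex_ids) < 3:  # too small for a shape model
            continue
        model = segment_pca(fields, seg, n_null=n_null, seed=int(rng.integers(2**31)))
        for j in range(model.n_retained):
            pc_cols.append(f"Module_PCs:seg{sid}_pc{j + 1}")
            pc_rows.append(model.scores[:, j])
    if pc_cols:
        parts.append(
            PhenotypeMatrix.from_array(
                np.column_stack(pc_rows), ids, pc_cols, "Module_PCs", "mm"
            )
        )

    areas = np.empty((len(ids), len(seg_ids)))
    for i, ind in enumerate(sample.individuals):
        for j, sid in enumerate(seg_ids):
            areas[i, j] = segment_surface_area(ind.mesh, hierarchy.segments[sid])
    parts.append(
        PhenotypeMatrix.from_array(
            areas, ids, [f"Module_surf_area:seg{s}" for s in seg_ids],
            "Module_surf_area", "mm^2",
        )
    )

    if moran_attributes:
        for category, attr in moran_attributes.items():
            attr = np.asarray(attr, float)
            if attr.shape != (len(ids), hierarchy.n_vertices):
                raise ValueError(
                    f"{category}: expected an (n_individuals, n_vertices) attribute array"
                )
            vals = np.empty((len(ids), len(seg_ids)))
            for j, sid in enumerate(seg_ids):
                seg = hierarchy.segments[sid]
                if len(seg.vertex_ids) < 5:  # Moran's I needs a neighbourhood
                    vals[:, j] = np.nan
                    continue
                w = knn_weights(
                    sample.template.mesh.vertices[seg.vertex_ids][:, :2], k=moran_k
                )
                for i in range(len(ids)):
                    a = attr[i, seg.vertex_ids]
                    ok = np.isfinite(a)
                    if ok.sum() < 5 or np.ptp(a[ok]) == 0:
                        vals[i, j] = np.nan
                    elif ok.all():
                        vals[i, j] = morans_i(a, w)
                    else:
                        sub = knn_weights(
                            sample.template.mesh.vertices[seg.vertex_ids[ok]][:, :2],
                            k=moran_k,
                        )
                        vals[i, j] = morans_i(a[ok], sub)
            parts.append(
                PhenotypeMatrix.from_array(
                    vals, ids, [f"{category}:seg{s}" for s in seg_ids], category, "1"
                )
            )
    return PhenotypeMatrix.concat(parts)
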