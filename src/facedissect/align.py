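"""Replicate handling, landmarking reliability, and generalized Procrustes
alignment (GPA) without scaling.

The alignment deliberately removes only translation and rotation, preserving
centroid size, so that absolute facial dimensions (mm) survive into the
phenotype battery.  Reliability of the two manual landmarking sessions is
summarised two ways: per-coordinate SDs of the signed replicate difference
(raw scanner frame, before any alignment), and two-way mixed-effects
intraclass correlation of the consistency form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import LandmarkSet
from .synthetic_face import PopulationSample

__all__ = [
    "AlignedSample",
    "average_replicates",
    "reproducibility",
    "icc_consistency",
    "kabsch_rotation",
    "gpa",
]

AXES = ("x", "y", "z")


def average_replicates(rep1: LandmarkSet, rep2: LandmarkSet) -> LandmarkSet:
    """Coordinate-wise midpoint of two landmarking replicates."""
    if rep1.individual_id != rep2.individual_id:
        raise ValueError(
            f"replicates belong to different individuals: "
            f"{rep1.individual_id!r} vs {rep2.individual_id!r}"
        )
    if rep1.dictionary is not rep2.dictionary and (
        rep1.dictionary.names != rep2.dictionary.names
    ):
        raise ValueError("replicates use different landmark dictionaries")
    mid = 0.5 * (rep1.coords + rep2.coords)
    return LandmarkSet(mid, rep1.dictionary, rep1.individual_id, "avg")


def reproducibility(sample: PopulationSample, sd_threshold_mm: float = 1.0) -> pd.DataFrame:
    """Per landmark x axis SD of the signed between-session difference.

    Returns a 78-row table (26 landmarks x 3 axes) with the SD over
    individuals of (replicate 1 - replicate 2) and a reproducibility class:
    ``"moderate_or_high"`` when SD <= ``sd_threshold_mm`` (1 mm by default),
    else ``"low"``.  Computed in the raw pre-alignment frame, matching when
    the landmarking itself happens.
    """
    if len(sample) < 2:
        raise ValueError("reproducibility needs >= 2 individuals (SD undefined otherwise)")
    diffs = np.stack(
        [ind.replicates[0].coords - ind.replicates[1].coords for ind in sample.individuals]
    )  # (n, 26, 3)
    sds = diffs.std(axis=0, ddof=1)
    names = sample.template.dictionary.names
    rows = [
        {
            "landmark": name,
            "axis": AXES[a],
            "sd_mm": sds[i, a],
            "reproducibility": "moderate_or_high" if sds[i, a] <= sd_threshold_mm else "low",
        }
        for i, name in enumerate(names)
        for a in range(3)
    ]
    return pd.DataFrame(rows)


def icc_consistency(ratings: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Two-way mixed-effects consistency ICC for an n-subjects x k-raters table.

    Returns ICC(3,1) (single measures) and ICC(3,k) (average measures) with
    their exact F-based confidence intervals:

        ICC(3,1) = (MS_S - MS_E) / (MS_S + (k-1) MS_E)
        ICC(3,k) = (MS_S - MS_E) / MS_S

    where MS_S and MS_E are the subject and residual mean squares of the
    two-way (subject x rater) ANOVA.  Consistency ignores systematic rater
    offsets by design.
    """
    x = np.asarray(ratings, float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be n x k with n >= 3 subjects, k >= 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("ratings contain non-finite values")
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    if np.allclose(x, x[0, 0]):
        raise ValueError("constant ratings: ICC undefined")
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_rater
    df_subj, df_err = n - 1, (n - 1) * (k - 1)
    ms_subj = ss_subj / df_subj
    ms_err = ss_err / df_err
    if ms_err == 0.0 and ms_subj == 0.0:
        raise ValueError("zero variance everywhere: ICC undefined")

    icc1 = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
    icck = (ms_subj - ms_err) / ms_subj if ms_subj > 0 else np.nan

    if ms_err > 0:
        f_obs = ms_subj / ms_err
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df_subj, df_err)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df_err, df_subj)
        ci1 = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        cik = (1 - 1 / fl, 1 - 1 / fu)
    else:  # perfect agreement
        ci1 = (1.0, 1.0)
        cik = (1.0, 1.0)
    return pd.DataFrame(
        {
            "measure": ["ICC(3,1)", f"ICC(3,{k})"],
            "estimate": [icc1, icck],
            "ci_lower": [ci1[0], cik[0]],
            "ci_upper": [ci1[1], cik[1]],
        }
    )


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def kabsch_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det = +1) taking centered ``source`` onto
    centered ``target`` in the least-squares sense."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


@dataclass
class AlignedSample:
    """GPA output: aligned configurations, consensus, convergence trace."""

    aligned: np.ndarray  # (n, p, 3)
    consensus: np.ndarray  # (p, 3)
    objective_trace: list[float]
    n_iterations: int
    converged: bool


def _centroid_size(x: np.ndarray) -> float:
    c = x - x.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def gpa(
    sets: list[LandmarkSet] | np.ndarray,
    scale: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedSample:
    """Generalized Procrustes alignment of landmark configurations.

    Iteratively centers every configuration, rotates each onto the current
    consensus (proper rotations only — faces never mirror), and updates the
    consensus to the coordinate-wise mean, until the consensus RMS change
    drops below ``tol`` mm.  ``scale=False`` (the default) preserves centroid
    size.  The summed squared distance to the consensus is non-increasing.
    """
    if isinstance(sets, np.ndarray):
        configs = np.asarray(sets, float).copy()
    else:
        configs = np.stack([s.coords for s in sets]).astype(float)
    if configs.ndim != 3 or configs.shape[0] < 2:
        raise ValueError("GPA needs >= 2 landmark configurations")
    n, p, _ = configs.shape
    configs -= configs.mean(axis=1, keepdims=True)
    for i, c in enumerate(configs):
        if np.linalg.matrix_rank(c, tol=1e-9) < 2:
            raise ValueError(f"configuration {i} is degenerate (collinear points)")
    if scale:
        configs /= np.array([_centroid_size(c) for c in configs])[:, None, None]

    consensus = configs[0].copy()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            r = kabsch_rotation(configs[i], consensus)
            configs[i] = configs[i] @ r.T
        new_consensus = configs.mean(axis=0)
        trace.append(float(((configs - new_consensus) ** 2).sum()))
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last objective {trace[-1]:.6g}, trace {trace[-3:]})"
        )
    return AlignedSample(configs, consensus, trace, it, converged)


def align_landmark_sets(sets: list[LandmarkSet], **kwargs) -> tuple[list[LandmarkSet], AlignedSample]:
    """GPA over LandmarkSets, returning aligned sets alongside the raw result."""
    result = gpa(sets, **kwargs)
    aligned = [s.with_coords(result.aligned[i]) for i, s in enumerate(sets)]
    return aligned, result
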