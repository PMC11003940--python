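"""Population-stratification statistics for the phenotype library.

The screening layer correlates every phenotype with the ordinal geographic
region (north < central < south) by Spearman's rho, Bonferroni-corrects over
the battery, and labels phenotypes *heterogeneous* (significantly different
across regions) or *homogeneous*.  Multivariate structure is assessed by
PLS-DA with VIP variable selection and by PERMANOVA on a distance matrix;
design balance by Pearson's chi-square; and a linear age adjustment removes
covariate drift before screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PhenotypeMatrix

__all__ = [
    "ScreenResult",
    "PlsdaModel",
    "PermanovaResult",
    "bonferroni_threshold",
    "region_screen",
    "chi2_balance",
    "plsda",
    "vip_scores",
    "permanova",
    "age_adjust",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Region screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Per-phenotype Spearman screen with Bonferroni control."""

    table: pd.DataFrame  # columns: rho, p, significant, label
    alpha: float
    threshold: float
    n_tests: int

    @property
    def heterogeneous(self) -> list[str]:
        return self.table.index[self.table["label"] == "heterogeneous"].tolist()

    @property
    def homogeneous(self) -> list[str]:
        return self.table.index[self.table["label"] == "homogeneous"].tolist()


def _spearman_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho of each column of x against y, with the two-sided
    t-approximation p-value (average ranks for ties)."""
    n = len(y)
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rx.T @ ry / denom, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), np.nan, np.where(np.abs(rho) >= 1.0, 0.0, p))
    return rho, p


def region_screen(
    matrix: PhenotypeMatrix | pd.DataFrame,
    regions: pd.Series | np.ndarray,
    alpha: float = 0.05,
    region_order: tuple[str, ...] = ("north", "central", "south"),
    method: str = "spearman",
) -> ScreenResult:
    """Screen every phenotype for regional differences.

    Regions are coded ordinally in ``region_order`` (a latitude gradient);
    ``method="spearman"`` correlates each phenotype with that code,
    ``method="kruskal"`` runs a Kruskal-Wallis test treating regions as
    unordered groups.  Significance uses the Bonferroni threshold
    alpha / (number of phenotypes); significant phenotypes are labelled
    heterogeneous, the rest homogeneous.  Constant phenotypes screen as NA.
    """
    values = matrix.values if isinstance(matrix, PhenotypeMatrix) else matrix
    x = values.to_numpy(dtype=float)
    regions = pd.Series(np.asarray(regions), index=values.index)
    levels = [r for r in region_order if r in set(regions)]
    if len(levels) < 2:
        raise ValueError("need >= 2 region levels")
    code = regions.map({r: i + 1 for i, r in enumerate(levels)}).to_numpy(float)

    n_tests = x.shape[1]
    threshold = bonferroni_threshold(alpha, n_tests)
    if method == "spearman":
        rho, p = _spearman_columns(x, code)
    elif method == "kruskal":
        rho = np.full(n_tests, np.nan)
        p = np.empty(n_tests)
        groups_idx = [np.where(code == i + 1)[0] for i in range(len(levels))]
        for j in range(n_tests):
            col = x[:, j]
            try:
                _, p[j] = stats.kruskal(*[col[g] for g in groups_idx])
            except ValueError:  # all values identical
                p[j] = np.nan
    else:
        raise ValueError(f"unknown screen method {method!r}")

    const = np.nanstd(x, axis=0) == 0
    rho[const] = np.nan
    p = np.asarray(p)
    p[const] = np.nan
    significant = p < threshold
    label = np.where(
        np.isnan(p), "NA", np.where(significant, "heterogeneous", "homogeneous")
    )
    table = pd.DataFrame(
        {"rho": rho, "p": p, "significant": significant, "label": label},
        index=values.columns,
    )
    return ScreenResult(table, alpha, threshold, n_tests)


# ---------------------------------------------------------------------------
# Chi-square design balance
# ---------------------------------------------------------------------------

def chi2_balance(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction (it applies only to 2x2 tables, which this
    design-balance check typically is not).  Returns (statistic, df, p).
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected count <= 0")
    return float(stat), int(dof), float(p)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    """NIPALS PLS2 discriminant model on autoscaled X and one-hot labels."""

    n_components: int
    x_weights: np.ndarray  # (p, A)
    x_loadings: np.ndarray  # (p, A)
    x_scores: np.ndarray  # (n, A)
    y_loadings: np.ndarray  # (g, A)
    vip: pd.Series
    r2x: float
    r2y: float
    q2: float
    classes: tuple[str, ...]
    feature_names: tuple[str, ...] = ()

    @property
    def selected(self) -> list[str]:
        """Variables with VIP > 1.0 (the conventional selection rule)."""
        return self.vip.index[self.vip > 1.0].tolist()


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    classes = tuple(sorted(set(labels)))
    y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        y[np.asarray(labels) == c, j] = 1.0
    return y, classes


def _nipals_pls2(
    x: np.ndarray, y: np.ndarray, n_components: int, tol: float = 1e-10, max_iter: int = 500
):
    """Core NIPALS PLS2: returns weights W, x-loadings P, scores T, y-loadings Q."""
    n, p = x.shape
    xa, ya = x.copy(), y.copy()
    ws, ps, ts, qs = [], [], [], []
    for _ in range(n_components):
        u = ya[:, np.argmax(ya.var(axis=0))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = xa.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0:
                break
            w_new /= nw
            t = xa @ w_new
            q = ya.T @ t / (t @ t)
            u_new = ya @ q / (q @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = xa @ w
        tt = t @ t
        if tt <= 1e-12:
            break
        p_load = xa.T @ t / tt
        q = ya.T @ t / tt
        xa = xa - np.outer(t, p_load)
        ya = ya - np.outer(t, q)
        ws.append(w)
        ps.append(p_load)
        ts.append(t)
        qs.append(q)
    if not ws:
        raise ValueError("PLS-DA: X has no variance")
    return (np.column_stack(ws), np.column_stack(ps), np.column_stack(ts), np.column_stack(qs))


def vip_scores(w: np.ndarray, t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Variable importance in projection.

        VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

    where SSY_a = sum of squares of Y explained by component a.  The squared
    VIPs always average to 1 (sum to the number of variables).
    """
    p = w.shape[0]
    ssy = (t**2).sum(axis=0) * (q**2).sum(axis=0)  # per-component explained Y SS
    wnorm2 = (w**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (w**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


def _autoscale(x: np.ndarray, center_only: bool = False):
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    xs = (x - mu) if center_only else (x - mu) / sd_safe
    return xs, mu, sd_safe


def plsda(
    matrix: PhenotypeMatrix | pd.DataFrame | np.ndarray,
    labels: np.ndarray | pd.Series,
    max_components: int = 10,
    cv_folds: int = 7,
    seed: int = 0,
    q2_gain_tol: float = 0.01,
    scale: bool = True,
) -> PlsdaModel:
    """PLS-DA with cross-validated component selection and VIP scores.

    X is autoscaled (mean 0, unit variance; ``scale=False`` centers only) and
    Y is the centered one-hot label matrix.  Components accrue while the
    cross-validated Q2 improves by at least ``q2_gain_tol``.  R2X/R2Y are the
    cumulative fractions of X/Y variance captured; Q2 = 1 - PRESS/SSY from
    ``cv_folds``-fold CV with a seeded shuffle.
    """
    if isinstance(matrix, PhenotypeMatrix):
        x_raw = matrix.values.to_numpy(float)
        feat = tuple(matrix.values.columns)
    elif isinstance(matrix, pd.DataFrame):
        x_raw = matrix.to_numpy(float)
        feat = tuple(matrix.columns)
    else:
        x_raw = np.asarray(matrix, float)
        feat = tuple(f"x{j}" for j in range(x_raw.shape[1]))
    labels = np.asarray(labels)
    y_raw, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs >= 2 groups")
    counts = y_raw.sum(axis=0)
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")

    n = len(x_raw)
    x, _, _ = _autoscale(x_raw, center_only=not scale)
    y = y_raw - y_raw.mean(axis=0)
    ssx = (x**2).sum()
    ssy = (y**2).sum()

    max_a = int(min(max_components, x.shape[1], n - 1))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, min(cv_folds, n))

    press = np.zeros(max_a)
    for fold in folds:
        mask = np.ones(n, bool)
        mask[fold] = False
        xt, _, _ = _autoscale(x_raw[mask], center_only=not scale)
        yt = y_raw[mask] - y_raw[mask].mean(axis=0)
        mu = x_raw[mask].mean(axis=0)
        sd = x_raw[mask].std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        xv = (x_raw[fold] - mu) if not scale else (x_raw[fold] - mu) / sd
        yv = y_raw[fold] - y_raw[mask].mean(axis=0)
        a_fit = min(max_a, int(mask.sum()) - 1)
        w, pl, t, q = _nipals_pls2(xt, yt, a_fit)
        xa = xv.copy()
        pred = np.zeros_like(yv)
        for a in range(max_a):
            if a < w.shape[1]:
                ta = xa @ w[:, a]
                pred = pred + np.outer(ta, q[:, a])
                xa = xa - np.outer(ta, pl[:, a])
            press[a] += ((yv - pred) ** 2).sum()
    q2_cum = 1.0 - press / ssy

    n_comp = 1
    for a in range(1, max_a):
        if q2_cum[a] - q2_cum[a - 1] >= q2_gain_tol:
            n_comp = a + 1
        else:
            break

    w, pl, t, q = _nipals_pls2(x, y, n_comp)
    n_comp = w.shape[1]
    r2x = float(((t**2).sum(axis=0) * (pl**2).sum(axis=0)).sum() / ssx)
    r2y = float(((t**2).sum(axis=0) * (q**2).sum(axis=0)).sum() / ssy)
    q2 = float(q2_cum[n_comp - 1])
    vip = pd.Series(vip_scores(w, t, q), index=list(feat), name="VIP")
    return PlsdaModel(n_comp, w, pl, t, q, vip, r2x, r2y, q2, classes, feat)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    seed: int
    df_between: int
    df_within: int


def _permanova_ss(d2: np.ndarray, groups: list[np.ndarray], n: int):
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        if len(g) > 1:
            sub = d2[np.ix_(g, g)]
            ss_within += sub[np.triu_indices(len(g), 1)].sum() / len(g)
    return ss_total, ss_total - ss_within, ss_within


def permanova(
    data: np.ndarray | pd.DataFrame | PhenotypeMatrix,
    labels: np.ndarray | pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
    distance: str = "euclidean",
    standardize: bool = True,
    is_distance_matrix: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA (Adonis) on a data matrix or distance matrix.

    Sums of squares are partitioned from pairwise distances; the pseudo-F is
    (SS_between/df_b) / (SS_within/df_w) and the p-value is the permutation
    tail probability (1 + #{F_perm >= F_obs}) / (1 + n_permutations).  With a
    Euclidean distance on a univariate column this reduces exactly to one-way
    ANOVA's R^2.
    """
    if n_permutations < 99:
        raise ValueError("use >= 99 permutations")
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if isinstance(data, PhenotypeMatrix):
        data = data.values.to_numpy(float)
    elif isinstance(data, pd.DataFrame):
        data = data.to_numpy(float)
    data = np.asarray(data, float)
    if is_distance_matrix:
        d2 = data**2
        n = data.shape[0]
    else:
        x = data
        if standardize:
            sd = x.std(axis=0, ddof=1)
            x = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        from scipy.spatial.distance import pdist, squareform

        d2 = squareform(pdist(x, metric=distance)) ** 2
        n = len(x)
    groups = [np.where(labels == c)[0] for c in classes]
    df_b, df_w = len(classes) - 1, n - len(classes)
    ss_total, ss_between, ss_within = _permanova_ss(d2, groups, n)
    f_obs = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pgroups = [perm[g] for g in groups]
        _, ssb, ssw = _permanova_ss(d2, pgroups, n)
        f_perm = (ssb / df_b) / (ssw / df_w)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations, seed, df_b, df_w)


# ---------------------------------------------------------------------------
# Age adjustment
# ---------------------------------------------------------------------------

def age_adjust(
    matrix: PhenotypeMatrix | pd.DataFrame, age: np.ndarray | pd.Series
) -> PhenotypeMatrix | pd.DataFrame:
    """Residualize every phenotype on age (least squares), keeping the mean.

    The output is orthogonal to age and the operation is idempotent.
    """
    values = matrix.values if isinstance(matrix, PhenotypeMatrix) else matrix
    age = np.asarray(age, float)
    if not np.isfinite(age).all():
        raise ValueError("age must be finite")
    if np.ptp(age) == 0:
        raise ValueError("age is constant; adjustment undefined")
    a = age - age.mean()
    x = values.to_numpy(float)
    mu = np.nanmean(x, axis=0)
    xc = x - mu
    xc_f = np.where(np.isnan(xc), 0.0, xc)
    a_mask = ~np.isnan(x)
    denom = (a[:, None] ** 2 * a_mask).sum(axis=0)
    beta = (a[:, None] * xc_f).sum(axis=0) / np.where(denom == 0, 1.0, denom)
    resid = xc - np.outer(a, beta) + mu
    out = pd.DataFrame(resid, index=values.index, columns=values.columns)
    if isinstance(matrix, PhenotypeMatrix):
        return PhenotypeMatrix(out, matrix.metadata)
    return out
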