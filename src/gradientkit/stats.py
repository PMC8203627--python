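"""Parcel-wise multivariate association models and null machinery.

The central model regresses each parcel's aligned manifold coordinates
(E1..Ek jointly) on subject covariates,

    Y = b0 + b1 * age + b2 * sex + b3 * bmi  (+ optional confounds),

and tests the BMI term across the k coordinates with Hotelling's T^2,
converted to an exact F with (k, n - p - k + 1) degrees of freedom.
Parcel-wise p-values are corrected with Benjamini-Hochberg FDR.
Supporting machinery: subject-permutation tests for partial
correlations (Freedman-Lane residual scheme, add-one p-values), spin
permutation nulls that rotate a parcel map over the sphere to preserve
spatial autocorrelation, an overweight-vs-healthy-weight group contrast
using the same Hotelling machinery, stratified (per-module /
per-hierarchy) summaries, and split-half reproducibility over random
subject partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from statsmodels.stats.multitest import multipletests

from .synthetic import ParcelAtlas

__all__ = [
    "DesignMatrix",
    "StatMap",
    "design_matrix",
    "hotelling_glm",
    "fdr_bh",
    "partial_correlation_permutation",
    "rotate_parcel_map",
    "spin_nulls",
    "group_hotelling",
    "stratify_map",
    "split_half_reproducibility",
]


@dataclass
class DesignMatrix:
    """Named covariate columns with an intercept, full column rank."""

    data: pd.DataFrame

    def __post_init__(self):
        if "intercept" not in self.data.columns:
            raise ValueError("design matrix must contain an 'intercept' column")
        X = self.data.to_numpy(float)
        if np.isnan(X).any():
            raise ValueError("design matrix contains NaN")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient (columns: {list(self.data.columns)})"
            )

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)


@dataclass
class StatMap:
    """Per-parcel statistic with raw p, BH q and a significance mask."""

    statistic: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    significant: np.ndarray
    name: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": np.arange(len(self.statistic)),
                "statistic": self.statistic,
                "p": self.p_value,
                "q": self.q_value,
                "significant": self.significant.astype(int),
            }
        )


def design_matrix(
    covariates: pd.DataFrame, columns=("age", "sex", "bmi")
) -> DesignMatrix:
    """Assemble an intercept-plus-covariates design from a subject table."""
    data = pd.DataFrame({"intercept": np.ones(len(covariates))})
    for c in columns:
        data[c] = covariates[c].to_numpy(float)
    return DesignMatrix(data=data)


def _hotelling_term(Y: np.ndarray, X: np.ndarray, j: int, XtX_inv, pinvX):
    """T^2 / exact-F test that coefficient row j is zero across responses."""
    n, p = X.shape
    k = Y.shape[1]
    B = pinvX @ Y
    E = Y - X @ B
    # exact fit: the tested coefficient is determined with zero error, so
    # a (numerically garbage) ratio of round-off terms must not leak out
    if np.abs(E).max() <= 1e-10 * max(1.0, np.abs(Y).max()):
        return 0.0, 1.0
    S = (E.T @ E) / (n - p)
    b = B[j]
    c = XtX_inv[j, j]
    try:
        T2 = float(b @ np.linalg.solve(S, b)) / c
    except np.linalg.LinAlgError:
        T2 = float(b @ np.linalg.pinv(S) @ b) / c
    df2 = n - p - k + 1
    F = T2 * df2 / (k * (n - p))
    pval = scipy.stats.f.sf(F, k, df2)
    return F, pval


def hotelling_glm(
    Y: np.ndarray, X: DesignMatrix, term: str, q: float = 0.05
) -> StatMap:
    """Parcel-wise Hotelling T^2 test of one design term.

    Y is subjects x parcels x k (or subjects x k for one parcel). For
    each parcel, the k responses are regressed on the full design and
    the single-row hypothesis b_term = 0 is tested with T^2 converted
    to an exact F on (k, n - p - k + 1) df. q-values are BH across
    parcels. For k = 1, F is exactly the squared t-statistic of the
    univariate test.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 2:
        Y = Y[:, None, :]
    n, n_parcels, k = Y.shape
    Xv = X.values
    p = Xv.shape[1]
    if term not in X.columns:
        raise ValueError(f"unknown term {term!r}; have {X.columns}")
    if n - p - k + 1 <= 0:
        raise ValueError(
            f"too few subjects (n={n}) for p={p} covariates and k={k} responses"
        )
    j = X.columns.index(term)
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    pinvX = XtX_inv @ Xv.T
    stat = np.empty(n_parcels)
    pval = np.empty(n_parcels)
    for i in range(n_parcels):
        stat[i], pval[i] = _hotelling_term(Y[:, i, :], Xv, j, XtX_inv, pinvX)
    qv, rej = fdr_bh(pval, q)
    return StatMap(statistic=stat, p_value=pval, q_value=qv, significant=rej,
                   name=f"hotelling[{term}]")


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q_values, reject mask)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    rej, qv, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qv, rej


def _residualize(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation_permutation(
    x, y, covars: DesignMatrix | None = None, n_perm: int = 5000, seed: int = 0
):
    """Permutation test of the partial Pearson correlation of x and y.

    Both variables are residualized on the covariates (Freedman-Lane);
    the null permutes y's residuals across subjects. Two-tailed add-one
    p: (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covars is not None:
        X = covars.values
        x = _residualize(x, X)
        y = _residualize(y, X)
    else:
        x = x - x.mean()
        y = y - y.mean()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant residuals: correlation undefined")
    xs = x / np.linalg.norm(x)
    ys = y / np.linalg.norm(y)
    r_obs = float(xs @ ys)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(ys)) for _ in range(n_perm)])
    r_null = ys[perms] @ xs
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (n_perm + 1.0)
    return r_obs, p


def rotate_parcel_map(parcel_map, atlas: ParcelAtlas, rotation) -> np.ndarray:
    """Reassign parcel values after rotating the atlas sphere.

    Each parcel takes the value of the parcel whose rotated centroid is
    nearest to it (duplicates allowed). The identity rotation returns
    the map unchanged.
    """
    vals = np.asarray(parcel_map, float)
    rotated = rotation.apply(atlas.centroids)
    _, nearest = cKDTree(rotated).query(atlas.centroids, k=1)
    return vals[nearest]


def spin_nulls(
    parcel_map, atlas: ParcelAtlas, n_rotations: int = 100, seed: int = 0
) -> np.ndarray:
    """Spatial null maps from random sphere rotations of the atlas.

    For each uniformly random 3-D rotation, every parcel is reassigned
    the value of the parcel whose rotated centroid lies nearest
    (duplicates allowed). Returns an (n_rotations, n_parcels) array.
    The rotated maps preserve the spatial autocorrelation family of the
    input while breaking its alignment with other maps.
    """
    vals = np.asarray(parcel_map, float)
    if atlas.n_parcels < 2:
        raise ValueError("spin test needs at least 2 parcels")
    if vals.shape != (atlas.n_parcels,):
        raise ValueError("map length does not match atlas")
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_rotations, random_state=rng)
    out = np.empty((n_rotations, atlas.n_parcels))
    for i in range(n_rotations):
        out[i] = rotate_parcel_map(vals, atlas, rots[i])
    return out


def group_hotelling(
    Y: np.ndarray,
    groups,
    covars: pd.DataFrame | None = None,
    covar_columns=("age", "sex"),
    q: float = 0.05,
) -> StatMap:
    """Hotelling contrast of manifold coordinates between two groups.

    ``groups`` is a binary indicator (e.g. overweight = 1 vs healthy
    weight = 0); the indicator enters the design as the tested term
    alongside the covariates, so this is hotelling_glm with a 0/1
    regressor.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("groups must be a binary label")
    g = (groups == uniq[1]).astype(float)
    Ya = np.asarray(Y, float)
    k = 1 if Ya.ndim == 2 else Ya.shape[2]
    for lvl in (0, 1):
        if (g == lvl).sum() < k + 2:
            raise ValueError(f"group {uniq[lvl]!r} too small for k={k} responses")
    data = pd.DataFrame({"intercept": np.ones(len(g))})
    if covars is not None:
        for c in covar_columns:
            data[c] = covars[c].to_numpy(float)
    data["group"] = g
    sm = hotelling_glm(Y, DesignMatrix(data=data), term="group", q=q)
    sm.name = "group_hotelling"
    return sm


def stratify_map(stat_map: StatMap, atlas: ParcelAtlas, by: str = "module_label"):
    """Mean statistic per module or hierarchy class (spider-plot values)."""
    if by == "module_label":
        labels = atlas.module_labels
    elif by == "hierarchy_label":
        labels = atlas.hierarchy_labels
    else:
        raise ValueError("by must be 'module_label' or 'hierarchy_label'")
    df = pd.DataFrame({"label": labels, "stat": stat_map.statistic})
    out = df.groupby("label", sort=True)["stat"].mean()
    out.name = "mean_statistic"
    return out


def split_half_reproducibility(
    embeddings: np.ndarray,
    covariates: pd.DataFrame,
    n_train: int,
    n_rep: int = 100,
    term: str = "bmi",
    covar_columns=("age", "sex", "bmi"),
    q: float = 0.05,
    seed: int = 0,
):
    """Detection frequency of each parcel over random subject splits.

    For each replicate, subjects are split into a train set of size
    ``n_train`` and its complement; hotelling_glm is fitted on both and
    per-parcel FDR significance is recorded. Returns a dict with
    per-parcel detection frequencies for the train and complement
    splits.
    """
    Y = np.asarray(embeddings, float)
    n, n_parcels, k = Y.shape
    if n_train >= n:
        raise ValueError("n_train must be smaller than the cohort")
    n_test = n - n_train
    p = len(covar_columns) + 1
    if n_test - p - k + 1 <= 0:
        raise ValueError("complement split too small for the model")
    rng = np.random.default_rng(seed)
    freq_train = np.zeros(n_parcels)
    freq_test = np.zeros(n_parcels)
    for _ in range(n_rep):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        for idx, freq in ((tr, freq_train), (te, freq_test)):
            X = design_matrix(covariates.iloc[idx], columns=covar_columns)
            sm = hotelling_glm(Y[idx], X, term=term, q=q)
            freq += sm.significant
    return {"train": freq_train / n_rep, "test": freq_test / n_rep}
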