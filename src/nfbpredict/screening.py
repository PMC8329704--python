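"""Screening of learning-index correlates across modalities.

Three screening routes, matched to the data they serve:

* **EEG cells** — Spearman rank correlation of each ROI x band x condition
  relative-power cell with the learning index, Benjamini–Hochberg FDR
  across the whole family.
* **Voxel maps** (morphometry, ALFF) — mass-univariate multiple regression
  of voxel intensity on LI with age and sex as covariates, with
  nonparametric inference: the null distribution of the LI t-statistic is
  built by Freedman–Lane permutation of reduced-model residuals; surviving
  voxels (p below the voxel threshold) are grouped into 26-connected
  clusters and small clusters discarded.
* **Connectome edges** — partial Spearman correlation of each Fisher-z edge
  with LI, controlling age and sex, thresholded at an uncorrected p.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenResult",
    "StatMap",
    "Cluster",
    "fdr_bh",
    "spearman_screen",
    "permutation_glm_map",
    "edge_screen",
]


@dataclass
class ScreenResult:
    """One screened feature: its statistic, inference and selection flag."""

    feature: object
    rho: float
    p: float
    q: float | None = None
    selected: bool = False

    @property
    def sign(self) -> int:
        return int(np.sign(self.rho))


@dataclass
class Cluster:
    """A suprathreshold cluster of a statistic map."""

    label: int
    sign: int
    size: int
    peak_ijk: tuple[int, int, int]
    peak_t: float
    voxels: np.ndarray  # (size, 3) voxel indices


@dataclass
class StatMap:
    """Voxelwise permutation-GLM output for one contrast variable."""

    t_map: np.ndarray
    p_map: np.ndarray
    cluster_labels: np.ndarray
    clusters: list[Cluster] = field(default_factory=list)

    @property
    def n_significant_voxels(self) -> int:
        return int(sum(c.size for c in self.clusters))


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR.

    Returns ``(qvals, selected)`` with q monotone in p and ``selected``
    the boolean rejection set at level ``alpha``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    selected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, selected


def _rank(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, axis, np.asarray(x, dtype=float))


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of vector ``y`` with every column of ``x``."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    num = xc.T @ yc
    den = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def _t_pvalue(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1.0 - r ** 2))
    return 2.0 * stats.t.sf(np.abs(t), df)


def spearman_screen(feature_table: pd.DataFrame, li: np.ndarray,
                    alpha: float = 0.05) -> list[ScreenResult]:
    """Spearman correlation of every feature column with LI, BH-FDR corrected.

    The FDR family is all columns of ``feature_table`` jointly.  Constant
    columns have undefined rank correlation: they are reported with
    ``rho = nan``, excluded from the FDR family, and a warning is emitted.

    Ties are handled by midranks; two-sided p-values use the t
    approximation (n >= 4 required).
    """
    x = feature_table.to_numpy(dtype=float)
    li = np.asarray(li, dtype=float)
    n = li.size
    if n < 4:
        raise ValueError("need at least 4 participants")
    if x.shape[0] != n:
        raise ValueError("feature table rows must match LI length")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    const = x.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant feature(s) excluded from FDR family",
                      RuntimeWarning, stacklevel=2)
    rx = _rank(x[:, ~const], axis=0) if (~const).any() else np.empty((n, 0))
    rho_ok = _pearson_columns(rx, stats.rankdata(li))
    p_ok = _t_pvalue(rho_ok, n - 2)
    q_ok, sel_ok = fdr_bh(p_ok, alpha)
    results: list[ScreenResult] = []
    it = iter(range(rho_ok.size))
    for j, col in enumerate(feature_table.columns):
        if const[j]:
            results.append(ScreenResult(feature=col, rho=np.nan, p=np.nan,
                                        q=None, selected=False))
        else:
            k = next(it)
            results.append(ScreenResult(feature=col, rho=float(rho_ok[k]),
                                        p=float(p_ok[k]), q=float(q_ok[k]),
                                        selected=bool(sel_ok[k])))
    return results


def _sex_to_numeric(sex: np.ndarray) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "OU":
        cats = {v: i for i, v in enumerate(sorted(set(s)))}
        return np.array([cats[v] for v in s], dtype=float)
    return s.astype(float)


def _design(li: np.ndarray, covariates: pd.DataFrame | None) -> tuple[np.ndarray, np.ndarray, int]:
    """Full design [1, li, covars], reduced design [1, covars], LI column index."""
    n = li.size
    cols = [np.ones(n), np.asarray(li, dtype=float)]
    if covariates is not None:
        for c in covariates.columns:
            v = covariates[c].to_numpy()
            cols.append(_sex_to_numeric(v) if v.dtype.kind in "OU" else v.astype(float))
    x_full = np.column_stack(cols)
    x_red = np.delete(x_full, 1, axis=1)
    return x_full, x_red, 1


def _glm_t(x: np.ndarray, y: np.ndarray, col: int,
           variance_fwhm_vox: float | None = None,
           shape: tuple[int, ...] | None = None,
           mask_idx: np.ndarray | None = None) -> np.ndarray:
    """t-statistic of regressor ``col`` for every column of Y (n x V).

    With ``variance_fwhm_vox`` set, the residual variance is spatially
    smoothed before forming the statistic (a pseudo-t).
    """
    n, p = x.shape
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    if variance_fwhm_vox is not None and shape is not None and mask_idx is not None:
        from scipy.ndimage import gaussian_filter
        vol = np.zeros(shape)
        vol[tuple(mask_idx.T)] = sigma2
        sig = variance_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        vol = gaussian_filter(vol, sigma=sig, mode="reflect")
        norm = np.zeros(shape)
        norm[tuple(mask_idx.T)] = 1.0
        norm = gaussian_filter(norm, sigma=sig, mode="reflect")
        with np.errstate(invalid="ignore", divide="ignore"):
            vol = np.where(norm > 0, vol / np.where(norm > 0, norm, 1.0), 0.0)
        sigma2 = vol[tuple(mask_idx.T)]
    c = np.linalg.inv(x.T @ x)[col, col]
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 * c)
        t = np.where(se > 0, beta[col] / np.where(se > 0, se, 1.0), 0.0)
    return t


def permutation_glm_map(maps: np.ndarray, li: np.ndarray,
                        covariates: pd.DataFrame | None = None,
                        mask: np.ndarray | None = None,
                        n_perm: int = 10000, voxel_p: float = 0.005,
                        min_cluster: int = 50,
                        variance_fwhm_vox: float | None = None,
                        seed: int | np.random.Generator | None = 0,
                        ) -> tuple[StatMap, StatMap]:
    """Voxelwise permutation GLM of maps on LI with nuisance covariates.

    Per voxel, intensity is regressed on ``[1, LI, covariates]`` and the
    t-statistic of the LI coefficient is referred to a Freedman–Lane
    permutation null: residuals of the reduced (covariates-only) model are
    permuted across participants, added back to the reduced fit, and the
    full model refit.  The two-sided voxel p-value is
    ``(1 + #{|t*| >= |t|}) / (n_perm + 1)``.

    Suprathreshold voxels (p < ``voxel_p``) are labelled into 26-connected
    clusters separately for positive and negative t; clusters smaller than
    ``min_cluster`` voxels are dropped.

    Parameters
    ----------
    maps : array, shape (n_participants, *grid)
        One spatial map per participant (any spatial dimensionality).
    li, covariates : LI vector and nuisance table (e.g. age, sex).
    mask : boolean array over the grid; default all voxels.
    variance_fwhm_vox : float, optional
        FWHM (voxels) of variance smoothing for a pseudo-t statistic;
        ``None`` (default) uses the plain t.

    Returns
    -------
    (StatMap, StatMap)
        Positive- and negative-contrast maps sharing t and p grids.
    """
    maps = np.asarray(maps, dtype=float)
    li = np.asarray(li, dtype=float)
    n = li.size
    if maps.shape[0] != n:
        raise ValueError("maps first axis must match LI length")
    grid_shape = maps.shape[1:]
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    mask_idx = np.argwhere(mask)
    y = maps.reshape(n, -1)[:, mask.reshape(-1)]
    x_full, x_red, li_col = _design(li, covariates)
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if n <= x_full.shape[1]:
        raise ValueError("need more participants than regressors")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t_obs = _glm_t(x_full, y, li_col, variance_fwhm_vox, grid_shape, mask_idx)

    # Freedman-Lane: permute reduced-model residuals
    pinv_red = np.linalg.pinv(x_red)
    fitted_red = x_red @ (pinv_red @ y)
    resid_red = y - fitted_red
    exceed = np.zeros(y.shape[1])
    # tiny slack so floating-point ties count as exceedances regardless of
    # participant ordering (conservative)
    abs_obs = np.abs(t_obs) * (1.0 - 1e-10) - 1e-12
    n_fact = float(math.factorial(n)) if n <= 20 else np.inf
    if n_fact <= n_perm:
        # exhaustive enumeration over all n! orderings (identity included)
        count = 0
        for perm in itertools.permutations(range(n)):
            y_star = fitted_red + resid_red[list(perm)]
            t_star = _glm_t(x_full, y_star, li_col, variance_fwhm_vox,
                            grid_shape, mask_idx)
            exceed += np.abs(t_star) >= abs_obs
            count += 1
        p = exceed / count
    else:
        for _ in range(n_perm):
            perm = rng.permutation(n)
            y_star = fitted_red + resid_red[perm]
            t_star = _glm_t(x_full, y_star, li_col, variance_fwhm_vox,
                            grid_shape, mask_idx)
            exceed += np.abs(t_star) >= abs_obs
        p = (1.0 + exceed) / (n_perm + 1.0)

    t_map = np.zeros(grid_shape)
    p_map = np.ones(grid_shape)
    t_map[mask] = t_obs
    p_map[mask] = p

    structure = np.ones((3,) * len(grid_shape), dtype=bool)  # 26-connectivity in 3D

    def _clusters(sign: int) -> StatMap:
        supra = mask & (p_map < voxel_p) & (np.sign(t_map) == sign)
        labels, n_lab = ndimage.label(supra, structure=structure)
        clusters = []
        keep_labels = np.zeros_like(labels)
        for lab in range(1, n_lab + 1):
            vox = np.argwhere(labels == lab)
            if vox.shape[0] < min_cluster:
                continue
            tvals = t_map[tuple(vox.T)]
            peak = vox[np.argmax(np.abs(tvals))]
            clusters.append(Cluster(label=lab, sign=sign, size=vox.shape[0],
                                    peak_ijk=tuple(int(v) for v in peak),
                                    peak_t=float(tvals[np.argmax(np.abs(tvals))]),
                                    voxels=vox))
            keep_labels[labels == lab] = lab
        return StatMap(t_map=t_map, p_map=p_map, cluster_labels=keep_labels,
                       clusters=clusters)

    return _clusters(+1), _clusters(-1)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of (columns of) y on the design x (with intercept)."""
    beta = np.linalg.pinv(x) @ y
    return y - x @ beta


def edge_screen(connectomes: np.ndarray, li: np.ndarray,
                covariates: pd.DataFrame | None = None,
                p_thresh: float = 0.005,
                edge_names: list[tuple] | None = None) -> list[ScreenResult]:
    """Partial Spearman screening of connectome edges against LI.

    ``connectomes`` is (n_participants, n_roi, n_roi) of Fisher-z values;
    each upper-triangle edge is rank-transformed together with LI and the
    covariates, residualized on the covariates, and the residual Pearson
    correlation is tested two-sided (t approximation, df = n - 2 - k).
    Edges are selected at ``p < p_thresh`` with no multiplicity correction.
    Constant edges are excluded with a warning.
    """
    c = np.asarray(connectomes, dtype=float)
    li = np.asarray(li, dtype=float)
    n = li.size
    if c.ndim != 3 or c.shape[0] != n or c.shape[1] != c.shape[2]:
        raise ValueError("connectomes must be (n_participants, n_roi, n_roi)")
    iu = np.triu_indices(c.shape[1], k=1)
    edges = c[:, iu[0], iu[1]]  # n x E
    if edge_names is None:
        edge_names = list(zip(iu[0].tolist(), iu[1].tolist()))
    const = edges.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant edge(s) excluded", RuntimeWarning,
                      stacklevel=2)
    k = 0
    x_cov = np.ones((n, 1))
    if covariates is not None:
        k = covariates.shape[1]
        cov_cols = []
        for col in covariates.columns:
            v = covariates[col].to_numpy()
            v = _sex_to_numeric(v) if v.dtype.kind in "OU" else v.astype(float)
            cov_cols.append(stats.rankdata(v))
        x_cov = np.column_stack([np.ones(n)] + cov_cols)
    li_r = _residualize(stats.rankdata(li), x_cov)
    e_rank = _rank(edges[:, ~const], axis=0) if (~const).any() else np.empty((n, 0))
    e_res = _residualize(e_rank, x_cov)
    rho = _pearson_columns(e_res, li_r)
    df = n - 2 - k
    if df < 1:
        raise ValueError("not enough participants for the covariate-adjusted test")
    p = _t_pvalue(rho, df)
    results: list[ScreenResult] = []
    it = iter(range(rho.size))
    for j, name in enumerate(edge_names):
        if const[j]:
            results.append(ScreenResult(feature=name, rho=np.nan, p=np.nan,
                                        selected=False))
        else:
            m = next(it)
            results.append(ScreenResult(feature=name, rho=float(rho[m]),
                                        p=float(p[m]),
                                        selected=bool(p[m] < p_thresh)))
    return results
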