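"""Mass-univariate group comparison with Monte-Carlo cluster-extent control.

The group model is a per-voxel OLS fit of the standardized maps on an
intercept, a patient/control indicator, and the age/sex/education nuisance
covariates; the reported statistic is the t on the group coefficient with
df = n_subjects - n_columns.

Cluster-extent correction follows the AlphaSim recipe: simulate smooth
Gaussian null fields inside the analysis mask, threshold them two-sided at
the voxel p, record the largest connected component per iteration, and take
the smallest extent k whose exceedance fraction is <= alpha. Suprathreshold
clusters of the real t-map are labeled separately per sign (the contrast has
both increases and decreases) under 6-, 18-, or 26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .errors import DataError, DesignError, ParameterError
from .preprocess import smooth_gaussian

DESIGN_COLUMNS = ("intercept", "group", "age", "sex", "education")

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def build_design_matrix(manifest: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + group (patient=1) + age + sex (M=1) + education.

    Row order follows the manifest; callers must order their map stack the
    same way.
    """
    n = len(manifest)
    group = (manifest["group"] == "patient").astype(float).to_numpy()
    sex = (manifest["sex"] == "M").astype(float).to_numpy()
    x = np.column_stack(
        [
            np.ones(n),
            group,
            manifest["age"].to_numpy(dtype=float),
            sex,
            manifest["education"].to_numpy(dtype=float),
        ]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("group design matrix is rank deficient")
    return x, list(DESIGN_COLUMNS)


@dataclass
class StatMap:
    """Voxel-wise t and two-sided p for the group contrast."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    mask: np.ndarray


def fit_group_glm(
    maps: np.ndarray,
    design: np.ndarray,
    mask: np.ndarray,
    group_col: int = 1,
) -> StatMap:
    """Per-voxel OLS of the stacked maps (n_subjects, x, y, z) on ``design``.

    t is the group coefficient over its standard error; p is two-sided
    Student-t with df = n - n_columns.
    """
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(design, dtype=float)
    n, p_cols = x.shape
    if maps.shape[0] != n:
        raise DataError(f"{maps.shape[0]} maps for {n} design rows")
    if maps.shape[1:] != mask.shape:
        raise DataError("map grid does not match the mask")
    if n < p_cols + 3:
        raise DataError("need at least 3 more subjects than design columns")
    if np.linalg.matrix_rank(x) < p_cols:
        raise DesignError("design matrix is rank deficient")
    df = n - p_cols
    y = maps.reshape(n, -1)[:, mask.ravel()]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    # a numerically perfect fit (e.g. identical maps in both groups) gives
    # sigma2 at rounding-noise level; report t = 0 there, not noise ratios
    y_power = (y**2).mean(axis=0)
    degenerate = sigma2 <= 1e-20 * np.maximum(y_power, np.finfo(float).tiny)
    se = np.sqrt(sigma2 * xtx_inv[group_col, group_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((se > 0) & ~degenerate, beta[group_col] / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    t_grid = np.zeros(mask.shape)
    p_grid = np.ones(mask.shape)
    t_grid[mask] = t
    p_grid[mask] = p
    return StatMap(t_grid, p_grid, df=df, mask=mask)


@dataclass(frozen=True)
class McParams:
    """AlphaSim-style Monte-Carlo parameters."""

    voxel_p: float = 0.01
    alpha: float = 0.05
    n_iter: int = 1000
    fwhm_mm: float = 6.0
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.voxel_p < 1:
            raise ParameterError("voxel_p must lie in (0, 1)")
        if self.n_iter < 100:
            raise ParameterError("n_iter must be >= 100")
        if self.connectivity not in _STRUCTURES:
            raise ParameterError("connectivity must be 6, 18 or 26")


@dataclass
class McResult:
    k_min: int
    null_max_sizes: np.ndarray
    params: McParams


def _max_component(binary: np.ndarray, structure) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def mc_cluster_extent(
    mask: np.ndarray,
    mc: McParams,
    voxel_size_mm: float = 3.0,
) -> McResult:
    """Estimate the cluster-extent threshold controlling FWE at ``alpha``.

    Each iteration fills the mask's bounding grid with white Gaussian noise,
    smooths it to the stated FWHM, re-standardizes inside the mask,
    thresholds two-sided at ``voxel_p`` and records the largest
    suprathreshold component (per sign). k_min is the smallest extent whose
    null exceedance fraction is <= alpha.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DataError("empty mask")
    if mc.alpha < 1.0 / mc.n_iter:
        raise ParameterError(
            f"alpha={mc.alpha} cannot be resolved with n_iter={mc.n_iter}"
        )
    rng = np.random.default_rng(mc.seed)
    z_crit = sps.norm.ppf(1.0 - mc.voxel_p / 2.0)
    structure = _STRUCTURES[mc.connectivity]
    max_sizes = np.zeros(mc.n_iter, dtype=np.int64)
    for it in range(mc.n_iter):
        noise = rng.standard_normal(mask.shape)
        if mc.fwhm_mm > 0:
            noise = smooth_gaussian(noise, mc.fwhm_mm, voxel_size_mm)
        vals = noise[mask]
        vals = (vals - vals.mean()) / vals.std()
        field = np.zeros(mask.shape)
        field[mask] = vals
        pos = _max_component((field > z_crit) & mask, structure)
        neg = _max_component((field < -z_crit) & mask, structure)
        max_sizes[it] = max(pos, neg)
    # smallest k with P(max cluster >= k) <= alpha
    ks = np.arange(1, max_sizes.max() + 2)
    exceed = (max_sizes[None, :] >= ks[:, None]).mean(axis=1)
    k_min = int(ks[np.argmax(exceed <= mc.alpha)])
    return McResult(k_min=k_min, null_max_sizes=max_sizes, params=mc)


@dataclass
class ClusterTable:
    """Suprathreshold clusters: a tidy table plus the label image.

    ``table`` columns: cluster_id, sign, label, peak_x_mm, peak_y_mm,
    peak_z_mm, peak_t, extent_voxels. ``labels`` maps each voxel to its
    cluster_id (0 = background), for downstream ROI extraction.
    """

    table: pd.DataFrame
    labels: np.ndarray

    def cluster_mask(self, cluster_id: int) -> np.ndarray:
        return self.labels == cluster_id


def extract_clusters(
    stat: StatMap,
    voxel_p: float = 0.01,
    min_extent: int = 50,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
    atlas_labels=None,
) -> ClusterTable:
    """Group suprathreshold voxels into sign-separated connected components.

    Components smaller than ``min_extent`` are dropped (the filter is
    extent >= min_extent). Peak coordinates are world mm via the affine;
    ``atlas_labels`` may supply an optional {cluster peak voxel -> text}
    callable for anatomical annotation.
    """
    if not 0 < voxel_p < 1:
        raise ParameterError("voxel_p must lie in (0, 1)")
    if connectivity not in _STRUCTURES:
        raise ParameterError("connectivity must be 6, 18 or 26")
    if not stat.mask.any():
        raise DataError("empty mask")
    if affine is None:
        affine = np.eye(4)
    structure = _STRUCTURES[connectivity]
    supra = (stat.p_values < voxel_p) & stat.mask
    rows = []
    labels_out = np.zeros(stat.mask.shape, dtype=np.int32)
    next_id = 1
    for sign, sel in (("positive", stat.t_values > 0), ("negative", stat.t_values < 0)):
        comp, n = ndimage.label(supra & sel, structure=structure)
        for c in range(1, n + 1):
            vox = comp == c
            extent = int(vox.sum())
            if extent < min_extent:
                continue
            tvals = np.where(vox, stat.t_values, 0.0)
            flat_peak = np.abs(tvals).argmax()
            peak_idx = np.unravel_index(flat_peak, stat.mask.shape)
            peak_mm = (affine @ np.array([*peak_idx, 1.0]))[:3]
            label_txt = ""
            if atlas_labels is not None:
                label_txt = atlas_labels(peak_idx)
            rows.append(
                {
                    "sign": sign,
                    "label": label_txt,
                    "peak_x_mm": peak_mm[0],
                    "peak_y_mm": peak_mm[1],
                    "peak_z_mm": peak_mm[2],
                    "peak_t": float(stat.t_values[peak_idx]),
                    "extent_voxels": extent,
                    "_vox": vox,
                }
            )
    rows.sort(key=lambda r: (r["sign"] != "positive", -r["extent_voxels"]))
    for r in rows:
        labels_out[r.pop("_vox")] = next_id
        r["cluster_id"] = next_id
        next_id += 1
    cols = [
        "cluster_id",
        "sign",
        "label",
        "peak_x_mm",
        "peak_y_mm",
        "peak_z_mm",
        "peak_t",
        "extent_voxels",
    ]
    table = pd.DataFrame(rows, columns=cols)
    return ClusterTable(table=table, labels=labels_out)
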