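"""ROI-level association statistics and structural measures.

Cluster/ROI means of standardized maps are regressed against clinical scores
(EDSS, MFIS-5, PASAT) or diffusion measures (MD, FA) with simple (single
predictor) OLS, Bonferroni correction over the declared test family, and a
leave-one-out cross-validated prediction whose accuracy is the correlation
between held-out predictions and observations.

In simple regression the standardized slope equals the Pearson correlation,
so |beta_std| = sqrt(R^2) holds identically; that identity is asserted on
every fit.

Structural measures: brain parenchymal fraction BPF = (GM + WM) / (GM + WM +
CSF) and normalized lesion volume in ml from a binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError


def roi_mean(map_values: np.ndarray, roi_mask: np.ndarray, with_count: bool = False):
    """Mean of the map over the ROI voxels, ignoring flagged-undefined (NaN)
    voxels; optionally also return (n_used, n_undefined)."""
    values = np.asarray(map_values, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if values.shape != mask.shape:
        raise DataError("map/ROI shape mismatch")
    if not mask.any():
        raise DataError("empty ROI mask")
    vox = values[mask]
    good = np.isfinite(vox)
    if not good.any():
        raise DataError("all ROI voxels are flagged undefined")
    mean = float(vox[good].mean())
    if with_count:
        return mean, int(good.sum()), int((~good).sum())
    return mean


@dataclass(frozen=True)
class RegressionResult:
    r_squared: float
    beta_std: float  # standardized slope == Pearson r in simple regression
    p_value: float
    n: int
    slope: float
    intercept: float


def simple_regression(x, y) -> RegressionResult:
    """OLS of y on [1, x]; beta_std is the (signed) Pearson correlation."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DataError("x and y lengths differ")
    n = x.size
    if n < 3:
        raise DataError("simple regression needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DataError("zero-variance input to simple regression")
    fit = sps.linregress(x, y)
    r = float(fit.rvalue)
    return RegressionResult(
        r_squared=r * r,
        beta_std=r,
        p_value=float(fit.pvalue),
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


@dataclass(frozen=True)
class BonferroniResult:
    significant: tuple[bool, ...]
    threshold: float
    k: int
    family: str


def bonferroni_adjust(p_values, alpha: float = 0.05, family: str = "") -> BonferroniResult:
    """Flag p_i < alpha / k where k is the size of the declared family."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    k = p.size
    threshold = alpha / k
    return BonferroniResult(
        significant=tuple(bool(v) for v in (p < threshold)),
        threshold=threshold,
        k=k,
        family=family or f"{k} tests in one invocation",
    )


@dataclass(frozen=True)
class LoocvResult:
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    r_squared: float
    p_value: float


def loocv_predict(x, y) -> LoocvResult:
    """Leave-one-out cross-validated simple-regression prediction.

    For each subject i the model is fit on the other n-1 subjects and y_i is
    predicted from x_i; accuracy is the Pearson correlation between the
    held-out predictions and the observations, with a two-sided t test on
    n-2 df.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DataError("x and y lengths differ")
    n = x.size
    if n < 4:
        raise DataError("LOOCV needs n >= 4")
    pred = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        xt, yt = x[keep], y[keep]
        if xt.std() == 0:
            raise DataError(f"zero variance in training fold {i}")
        slope, intercept = np.polyfit(xt, yt, 1)
        pred[i] = intercept + slope * x[i]
    if pred.std() == 0 or y.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return LoocvResult(
        predicted=pred, observed=y.copy(), r=r, r_squared=r * r, p_value=p
    )


def brain_parenchymal_fraction(gm, wm, csf, voxel_size_mm: float | None = None) -> float:
    """BPF = (GM + WM) / (GM + WM + CSF).

    Accepts scalar volumes, or probability maps plus a voxel size, in which
    case each tissue volume is the sum of probabilities times the voxel
    volume.
    """
    def _vol(v):
        a = np.asarray(v, dtype=float)
        if a.ndim == 0:
            return float(a)
        if voxel_size_mm is None:
            raise ParameterError("voxel_size_mm required for probability maps")
        return float(a.sum() * voxel_size_mm**3)

    g, w, c = _vol(gm), _vol(wm), _vol(csf)
    if g < 0 or w < 0 or c < 0:
        raise DataError("tissue volumes must be non-negative")
    total = g + w + c
    if total == 0:
        raise DataError("all tissue volumes are zero")
    return (g + w) / total


def lesion_volume_ml(lesion_mask, voxel_size_mm: float) -> float:
    """Lesion volume in ml: voxel count x voxel volume (mm^3) / 1000."""
    mask = np.asarray(lesion_mask)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise DataError("lesion mask must be binary (0/1)")
    return float(mask.sum() * voxel_size_mm**3 / 1000.0)


def association_table(
    roi_means: pd.DataFrame,
    measures: pd.DataFrame,
    rois=None,
    measure_names=None,
    alpha: float = 0.05,
    run_loocv: bool = True,
) -> pd.DataFrame:
    """Tidy (ROI x measure) regression table with a Bonferroni flag.

    ``roi_means``: one row per subject, one column per ROI. ``measures``:
    one row per subject (same order), one column per clinical/structural
    measure. The Bonferroni family is all tests run in this invocation; its
    size is recorded in the output.
    """
    rois = list(rois if rois is not None else roi_means.columns)
    measure_names = list(
        measure_names if measure_names is not None else measures.columns
    )
    rows = []
    for roi in rois:
        for meas in measure_names:
            res = simple_regression(roi_means[roi], measures[meas])
            row = {
                "roi": roi,
                "measure": meas,
                "n": res.n,
                "r_squared": res.r_squared,
                "beta_std": res.beta_std,
                "p": res.p_value,
            }
            if run_loocv:
                cv = loocv_predict(roi_means[roi], measures[meas])
                row["loocv_r_squared"] = cv.r_squared
                row["loocv_p"] = cv.p_value
            rows.append(row)
    table = pd.DataFrame(rows)
    bonf = bonferroni_adjust(
        table["p"], alpha=alpha, family=f"{len(rows)} ROI-by-measure tests"
    )
    table["p_bonferroni_flag"] = list(bonf.significant)
    table.attrs["bonferroni_k"] = bonf.k
    table.attrs["bonferroni_threshold"] = bonf.threshold
    return table
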