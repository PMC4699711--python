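"""Temporal and spatial preprocessing of 4D BOLD series.

The pipeline assumes spatially aligned inputs on a common grid and covers the
standard resting-state denoising chain: discarding initial volumes (signal
equilibration), isotropic Gaussian smoothing, linear detrending, band-pass
filtering to the low-frequency band, nuisance regression (6 motion parameters
plus mean white-matter and CSF signals), and motion-based subject exclusion.

Steps carry an append-only provenance list on the series and the canonical
order discard -> smooth -> detrend -> bandpass -> nuisance is enforced: a step
may be skipped but never applied after a step that canonically follows it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import (
    DataError,
    DesignError,
    ParameterError,
    PipelineOrderError,
)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: canonical order of the temporal/spatial preprocessing chain
STEP_ORDER = ("discard", "smooth", "detrend", "bandpass", "nuisance")


@dataclass
class BoldSeries:
    """A 4D BOLD acquisition: ``data[x, y, z, t]`` plus voxel geometry.

    ``provenance`` is an ordered, append-only record of the preprocessing
    steps already applied; operations consult it to enforce step order.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    tr_s: float
    affine: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise DataError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise DataError("BOLD series needs at least 2 timepoints")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float).reshape(3)
        if np.any(self.voxel_size_mm <= 0):
            raise DataError("voxel sizes must be positive")
        if self.tr_s <= 0:
            raise DataError("TR must be positive")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def _with(self, data: np.ndarray, step: str) -> "BoldSeries":
        return replace(self, data=data, provenance=self.provenance + [step])


def _check_order(series: BoldSeries, step: str) -> None:
    name = step.split("(")[0]
    rank = STEP_ORDER.index(name)
    for done in series.provenance:
        done_name = done.split("(")[0]
        if done_name in STEP_ORDER and STEP_ORDER.index(done_name) > rank:
            raise PipelineOrderError(
                f"step '{name}' cannot follow already-applied step '{done_name}'"
            )


def _check_finite(series: BoldSeries) -> None:
    if not np.all(np.isfinite(series.data)):
        raise DataError("BOLD data contains non-finite values")


def discard_initial_volumes(series: BoldSeries, k: int) -> BoldSeries:
    """Drop the first ``k`` volumes (scanner equilibration period)."""
    if not 0 <= k < series.n_timepoints:
        raise ParameterError(
            f"cannot discard {k} of {series.n_timepoints} volumes"
        )
    _check_order(series, "discard")
    return series._with(series.data[..., k:].copy(), f"discard(k={k})")


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Remove, per voxel, the OLS fit on an intercept and a linear ramp."""
    if series.n_timepoints < 3:
        raise ParameterError("detrending needs at least 3 timepoints")
    _check_finite(series)
    _check_order(series, "detrend")
    t = series.n_timepoints
    ramp = np.arange(t, dtype=float)
    ramp_c = ramp - ramp.mean()
    flat = series.data.reshape(-1, t)
    mean = flat.mean(axis=1, keepdims=True)
    slope = (flat @ ramp_c) / (ramp_c @ ramp_c)
    resid = flat - mean - slope[:, None] * ramp_c[None, :]
    return series._with(resid.reshape(series.data.shape), "detrend")


def bandpass_filter(series: BoldSeries, f_lo: float, f_hi: float) -> BoldSeries:
    """Ideal (brick-wall) band-pass in the DFT domain.

    Bins with frequency strictly below ``f_lo`` or strictly above ``f_hi``
    are zeroed; the DC bin is always removed when ``f_lo > 0``. This is the
    REST/DPARSF-style filter, not a rolled-off IIR design.
    """
    if not (0 <= f_lo < f_hi):
        raise ParameterError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi > series.nyquist_hz + 1e-12:
        raise ParameterError(
            f"f_hi={f_hi} Hz exceeds the Nyquist frequency {series.nyquist_hz} Hz"
        )
    _check_finite(series)
    _check_order(series, "bandpass")
    t = series.n_timepoints
    freqs = np.fft.rfftfreq(t, d=series.tr_s)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    if f_lo > 0:
        keep[0] = False
    flat = series.data.reshape(-1, t)
    spec = np.fft.rfft(flat, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=1)
    return series._with(
        out.reshape(series.data.shape), f"bandpass(f_lo={f_lo},f_hi={f_hi})"
    )


@dataclass
class NuisanceSet:
    """Nuisance regressors: 6 motion parameters, mean WM and CSF signals."""

    motion: np.ndarray
    wm_signal: np.ndarray
    csf_signal: np.ndarray

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=float)
        self.wm_signal = np.asarray(self.wm_signal, dtype=float).ravel()
        self.csf_signal = np.asarray(self.csf_signal, dtype=float).ravel()
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise DataError(
                f"motion must be (t, 6), got shape {self.motion.shape}"
            )
        t = self.motion.shape[0]
        if self.wm_signal.shape[0] != t or self.csf_signal.shape[0] != t:
            raise DataError("nuisance regressor lengths disagree")

    def design(self) -> tuple[np.ndarray, list[str]]:
        """Intercept + 8 nuisance columns, with column names."""
        t = self.motion.shape[0]
        cols = [np.ones(t)] + [self.motion[:, j] for j in range(6)]
        cols += [self.wm_signal, self.csf_signal]
        names = (
            ["intercept"]
            + [f"motion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
            + ["wm", "csf"]
        )
        return np.column_stack(cols), names


def _rank_check(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns from the pivoted-QR diagonal
        _, r = np.linalg.qr(design)
        scale = max(np.abs(np.diag(r)).max(), 1.0)
        bad = [
            names[j]
            for j in range(design.shape[1])
            if abs(r[j, j]) < 1e-10 * scale
        ]
        raise DesignError(
            "nuisance design is rank deficient; collinear columns: "
            + ", ".join(bad or ["<unidentified>"])
        )


def regress_nuisance(series: BoldSeries, nuisance: NuisanceSet) -> BoldSeries:
    """Per-voxel OLS residual after regressing on intercept + 8 nuisances."""
    x, names = nuisance.design()
    if x.shape[0] != series.n_timepoints:
        raise DataError(
            f"regressor length {x.shape[0]} != series length {series.n_timepoints}"
        )
    _check_finite(series)
    _rank_check(x, names)
    _check_order(series, "nuisance")
    flat = series.data.reshape(-1, series.n_timepoints)
    beta = np.linalg.pinv(x) @ flat.T
    resid = flat.T - x @ beta
    return series._with(resid.T.reshape(series.data.shape), "nuisance")


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for an isotropic FWHM in mm."""
    voxel = np.asarray(voxel_size_mm, dtype=float).reshape(-1)
    return fwhm_mm * FWHM_TO_SIGMA / voxel


def smooth_gaussian(data, fwhm_mm: float, voxel_size_mm=None):
    """Isotropic Gaussian smoothing of a 3D volume, a 4D series (volume by
    volume), or a :class:`BoldSeries`.

    Reflective boundaries keep the total image sum invariant; the kernel is
    truncated at 6 sigma so the discrete kernel mass is 1 to well below 1e-6.
    """
    if fwhm_mm < 0:
        raise ParameterError("FWHM must be non-negative")
    if isinstance(data, BoldSeries):
        _check_order(data, "smooth")
        out = smooth_gaussian(data.data, fwhm_mm, data.voxel_size_mm)
        return data._with(out, f"smooth(fwhm={fwhm_mm})")
    arr = np.asarray(data, dtype=float)
    if voxel_size_mm is None:
        raise ParameterError("voxel_size_mm required for array input")
    if fwhm_mm == 0:
        return arr.copy()
    sigma = fwhm_to_sigma_vox(fwhm_mm, np.broadcast_to(np.atleast_1d(voxel_size_mm), (3,)))
    if arr.ndim == 3:
        return ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect", truncate=6.0)
    if arr.ndim == 4:
        return ndimage.gaussian_filter(
            arr, sigma=(*sigma, 0.0), mode="reflect", truncate=6.0
        )
    raise DataError(f"expected 3D or 4D array, got shape {arr.shape}")


@dataclass(frozen=True)
class QcRule:
    """Motion-exclusion thresholds on mean absolute realignment parameters."""

    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.max_translation_mm <= 0 or self.max_rotation_deg <= 0:
            raise ParameterError("QC thresholds must be positive")


@dataclass(frozen=True)
class QcDecision:
    keep: bool
    reasons: tuple[str, ...]


_AXES = ("x", "y", "z")


def qc_motion_exclude(motion_params, rule: QcRule = QcRule()) -> QcDecision:
    """Apply the mean-head-motion exclusion rule.

    ``motion_params`` is a (t, 6) table: translations in mm (x, y, z) then
    rotations in degrees. A subject is excluded when the time-mean absolute
    value exceeds the threshold on any translation axis or any rotation axis.
    """
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DataError(f"motion table must be (t, 6), got {motion.shape}")
    mean_abs = np.abs(motion).mean(axis=0)
    reasons = []
    for j in range(3):
        if mean_abs[j] > rule.max_translation_mm:
            reasons.append(f"{_AXES[j]}-translation")
    for j in range(3):
        if mean_abs[3 + j] > rule.max_rotation_deg:
            reasons.append(f"{_AXES[j]}-rotation")
    return QcDecision(keep=not reasons, reasons=tuple(reasons))


def extract_tissue_signal(
    series: BoldSeries,
    prob_map: np.ndarray,
    threshold: float = 0.9,
    erode_voxels: int = 1,
) -> np.ndarray:
    """Mean time course within a thresholded, eroded tissue-probability mask.

    The default (probability > 0.9, one-voxel erosion) is the common choice
    for WM/CSF nuisance extraction when no subject-specific anatomy is used.
    """
    mask = np.asarray(prob_map, dtype=float) > threshold
    if erode_voxels > 0:
        eroded = ndimage.binary_erosion(mask, iterations=erode_voxels)
        # thin compartments can vanish under erosion; fall back to the
        # uneroded mask rather than failing
        if eroded.any():
            mask = eroded
    if not mask.any():
        raise DataError("tissue mask is empty after thresholding")
    return series.data[mask].mean(axis=0)
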