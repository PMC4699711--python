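"""Voxel-wise brain entropy (Sample Entropy) and ALFF mapping.

Sample Entropy of a series x[0..N-1] with template length m and tolerance
r = r_frac * SD(x):

    B = # ordered pairs (i, j), i != j, i, j in 0..N-m-1, with
        max_{k < m} |x[i+k] - x[j+k]| < r           (Chebyshev distance)
    A = the same count for (m+1)-length templates over the same index range
    SampEn = -ln(A / B)

Restricting both counts to templates 0..N-m-1 guarantees every m-template has
an (m+1)-point extension; self-matches are excluded. This is the standard
pair-count (Richman-Moorman) form. A second normalization,
``paper_literal``, divides B by (N-m)(N-m+1) and A by (N-m)(N-m-1) before the
log; these denominators are mutually inconsistent (an all-matching series
comes out with negative entropy, -ln[(N-m+1)/(N-m-1)]) and the mode exists
only to reproduce that published variant.

ALFF (amplitude of low-frequency fluctuations) is the square root of the
summed squared DFT magnitudes over the positive-frequency bins inside the
analysis band (default 0.01-0.08 Hz), using the unnormalized forward DFT
convention; in-mask standardization removes the resulting scale before any
group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .errors import DataError, DomainError, ParameterError
from .preprocess import BoldSeries, smooth_gaussian

VALID_NORMALIZATIONS = ("standard", "paper_literal")


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters.

    m : template (window) length, default 3.
    r_frac : match tolerance as a fraction of the series SD, default 0.6.
    normalization : ``standard`` pair-count form or ``paper_literal``.
    distance : only ``chebyshev`` is defined for SampEn.
    """

    m: int = 3
    r_frac: float = 0.6
    normalization: str = "standard"
    distance: str = "chebyshev"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if not self.r_frac > 0:
            raise ParameterError("r_frac must be > 0")
        if self.normalization not in VALID_NORMALIZATIONS:
            raise ParameterError(
                f"normalization must be one of {VALID_NORMALIZATIONS}"
            )
        if self.distance != "chebyshev":
            raise ParameterError("only the Chebyshev distance is supported")


@njit(cache=True)
def _sampen_counts(x, m, r):  # pragma: no cover - exercised via wrappers
    """Ordered-pair match counts (B, A) for template lengths m and m+1.

    Box-assisted enumeration: templates are sorted by their first sample, so
    pairs whose first coordinates already differ by >= r are skipped without
    being visited; the counts are identical to the naive double loop.
    """
    n_templates = x.shape[0] - m
    order = np.argsort(x[:n_templates])
    b = 0
    a = 0
    for p in range(n_templates - 1):
        i = order[p]
        xi = x[i]
        for q in range(p + 1, n_templates):
            j = order[q]
            if x[j] - xi >= r:
                break
            match = True
            for k in range(1, m):
                if abs(x[i + k] - x[j + k]) >= r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    return 2 * b, 2 * a


@njit(cache=True)
def _sampen_batch(series_matrix, m, r_per_row, out_b, out_a):  # pragma: no cover
    for v in range(series_matrix.shape[0]):
        b, a = _sampen_counts(series_matrix[v], m, r_per_row[v])
        out_b[v] = b
        out_a[v] = a


@njit(cache=True)
def _sampen_batch_m3(series_matrix, r_per_row, out_b, out_a):  # pragma: no cover
    """m=3 fast path: sorted structure-of-arrays templates, a two-pointer
    window on the first coordinate, and a branchless inner accumulation.
    Counts are identical to the generic kernel."""
    nvox, n = series_matrix.shape
    nt = n - 3
    t0 = np.empty(nt)
    t1 = np.empty(nt)
    t2 = np.empty(nt)
    t3 = np.empty(nt)
    for v in range(nvox):
        x = series_matrix[v]
        r = r_per_row[v]
        order = np.argsort(x[:nt])
        for p in range(nt):
            i = order[p]
            t0[p] = x[i]
            t1[p] = x[i + 1]
            t2[p] = x[i + 2]
            t3[p] = x[i + 3]
        b = 0
        a = 0
        hi = 0
        for p in range(nt - 1):
            x0 = t0[p]
            x1 = t1[p]
            x2 = t2[p]
            x3 = t3[p]
            if hi < p + 1:
                hi = p + 1
            while hi < nt and t0[hi] - x0 < r:
                hi += 1
            for q in range(p + 1, hi):
                c = (abs(t1[q] - x1) < r) * (abs(t2[q] - x2) < r)
                b += c
                a += c * (abs(t3[q] - x3) < r)
        out_b[v] = 2 * b
        out_a[v] = 2 * a


def sample_entropy_counts(x, params: SampEnParams) -> tuple[int, int, float]:
    """Return (B, A, r) — the ordered-pair match counts and the tolerance."""
    x = np.ascontiguousarray(x, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < params.m + 2:
        raise ParameterError(
            f"series length {n} too short for m={params.m} (need N >= m+2)"
        )
    sd = float(x.std())
    if sd == 0.0:
        raise DataError("constant series: tolerance r is zero")
    r = params.r_frac * sd
    b, a = _sampen_counts(x, params.m, r)
    return int(b), int(a), r


def sample_entropy(x, params: SampEnParams = SampEnParams()) -> float:
    """Sample Entropy of a 1D series; NaN flags an undefined result.

    The result is undefined (NaN, never unflagged +/-inf) when the series is
    constant (r = 0) or when either match count is zero.
    """
    x = np.ascontiguousarray(x, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < params.m + 2:
        raise ParameterError(
            f"series length {n} too short for m={params.m} (need N >= m+2)"
        )
    sd = float(x.std())
    if sd == 0.0:
        return float("nan")
    b, a = _sampen_counts(x, params.m, params.r_frac * sd)
    return _sampen_from_counts(b, a, n, params)


def _sampen_from_counts(b: int, a: int, n: int, params: SampEnParams) -> float:
    if a == 0 or b == 0:
        return float("nan")
    ratio = a / b
    if params.normalization == "paper_literal":
        nm = n - params.m
        ratio *= (nm + 1) / (nm - 1)
    return -math.log(ratio)


@dataclass
class BenMap:
    """A 3D brain-entropy map over a mask.

    ``values`` holds NaN at in-mask voxels where SampEn is undefined and 0
    outside the mask; ``defined`` flags the valid in-mask voxels. ``qc``
    records the undefined-voxel count and the parameters used.
    """

    values: np.ndarray
    mask: np.ndarray
    params: SampEnParams
    standardized: bool = False
    defined: np.ndarray | None = None
    qc: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise DataError("map/mask shape mismatch")
        if self.defined is None:
            self.defined = self.mask & np.isfinite(self.values)


@dataclass
class AlffMap:
    """A 3D ALFF map over a mask; non-negative before standardization."""

    values: np.ndarray
    mask: np.ndarray
    band: tuple[float, float]
    standardized: bool = False
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise DataError("map/mask shape mismatch")
        if self.defined is None:
            self.defined = self.mask & np.isfinite(self.values)


def ben_map(
    series: BoldSeries,
    mask: np.ndarray,
    params: SampEnParams = SampEnParams(),
) -> BenMap:
    """Voxel-wise Sample Entropy over the in-mask voxels of a 4D series.

    Each voxel's tolerance is r_frac times that voxel's own series SD, so the
    measure is scale-free per voxel. Out-of-mask voxels are 0; voxels with an
    undefined SampEn (constant series or zero match count) are NaN and
    counted in the QC record.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.data.shape[:3]:
        raise DataError(
            f"mask shape {mask.shape} != series grid {series.data.shape[:3]}"
        )
    n = series.n_timepoints
    if n < params.m + 2:
        raise ParameterError("series too short for the requested m")
    flat = np.ascontiguousarray(series.data[mask], dtype=np.float64)
    sd = flat.std(axis=1)
    r = params.r_frac * sd
    n_vox = flat.shape[0]
    b = np.zeros(n_vox, dtype=np.int64)
    a = np.zeros(n_vox, dtype=np.int64)
    ok = sd > 0
    if ok.any():
        b_ok = np.zeros(int(ok.sum()), dtype=np.int64)
        a_ok = np.zeros(int(ok.sum()), dtype=np.int64)
        x_ok = np.ascontiguousarray(flat[ok])
        r_ok = np.ascontiguousarray(r[ok])
        if params.m == 3:
            _sampen_batch_m3(x_ok, r_ok, b_ok, a_ok)
        else:
            _sampen_batch(x_ok, params.m, r_ok, b_ok, a_ok)
        b[ok] = b_ok
        a[ok] = a_ok
    vals = np.full(n_vox, np.nan)
    defined = ok & (a > 0) & (b > 0)
    ratio = np.empty(n_vox)
    ratio.fill(np.nan)
    ratio[defined] = a[defined] / b[defined]
    if params.normalization == "paper_literal":
        nm = n - params.m
        ratio[defined] *= (nm + 1) / (nm - 1)
    vals[defined] = -np.log(ratio[defined])
    values = np.zeros(mask.shape)
    values[mask] = vals
    defined_grid = np.zeros(mask.shape, dtype=bool)
    defined_grid[mask] = defined
    qc = {
        "n_in_mask": int(mask.sum()),
        "n_undefined": int(mask.sum() - defined.sum()),
        "m": params.m,
        "r_frac": params.r_frac,
        "normalization": params.normalization,
    }
    return BenMap(values, mask, params, standardized=False, defined=defined_grid, qc=qc)


def _masked_smooth(values, weight_mask, fwhm_mm, voxel_size_mm):
    """Mask-normalized Gaussian smoothing; undefined/out-of-mask voxels carry
    zero weight so they neither leak in nor bleed out."""
    w = weight_mask.astype(float)
    filled = np.where(weight_mask, values, 0.0)
    num = smooth_gaussian(filled, fwhm_mm, voxel_size_mm)
    den = smooth_gaussian(w, fwhm_mm, voxel_size_mm)
    out = np.full(values.shape, np.nan)
    good = weight_mask & (den > 0)
    out[good] = num[good] / den[good]
    return out


def smooth_and_standardize_ben(
    benmap,
    fwhm_mm: float = 6.0,
    voxel_size_mm=3.0,
    mode: str = "zscore",
):
    """Smooth a BEN (or ALFF) map within its mask, then standardize.

    ``zscore`` subtracts the in-mask mean and divides by the in-mask SD; the
    ``artanh`` alternative (an inverse hyperbolic tangent, i.e. Fisher's
    r-to-z) is only defined when every in-mask value lies in (-1, 1) —
    raw SampEn regularly exceeds 1, so zscore is the default.
    """
    if benmap.standardized:
        raise ParameterError("map is already standardized")
    if mode not in ("zscore", "artanh"):
        raise ParameterError("mode must be 'zscore' or 'artanh'")
    defined = benmap.defined
    if fwhm_mm > 0:
        sm = _masked_smooth(benmap.values, defined, fwhm_mm, voxel_size_mm)
    else:
        sm = np.where(defined, benmap.values, np.nan)
    inside = sm[defined]
    if inside.size == 0:
        raise DataError("no defined voxels to standardize")
    if mode == "artanh":
        if np.any(np.abs(inside) >= 1):
            raise DomainError(
                "artanh standardization requires all in-mask values in (-1, 1); "
                f"max |value| = {np.abs(inside).max():.4g}"
            )
        out_vals = np.where(defined, np.arctanh(np.where(defined, sm, 0.0)), np.nan)
    else:
        mu = inside.mean()
        sd = inside.std()
        if sd == 0:
            raise DataError("zero variance inside mask; cannot z-score")
        out_vals = np.where(defined, (sm - mu) / sd, np.nan)
    out_vals = np.where(benmap.mask, out_vals, 0.0)
    return replace(benmap, values=out_vals, standardized=True, defined=defined)


def alff_map(
    series: BoldSeries,
    mask: np.ndarray,
    band: tuple[float, float] = (0.01, 0.08),
) -> AlffMap:
    """ALFF: sqrt of the summed squared spectral magnitude within ``band``.

    The input should be the detrended, nuisance-corrected series that has NOT
    been band-pass filtered (band selection happens here). Uses the
    unnormalized forward DFT, so a unit sine on an in-band bin gives N/2.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.data.shape[:3]:
        raise DataError("mask/series shape mismatch")
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi):
        raise ParameterError("need 0 <= f_lo < f_hi")
    if f_hi > series.nyquist_hz + 1e-12:
        raise ParameterError("band exceeds the Nyquist frequency")
    n = series.n_timepoints
    freqs = np.fft.rfftfreq(n, d=series.tr_s)
    sel = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    if not sel.any():
        raise ParameterError(
            f"no positive-frequency DFT bins inside band {band} at N={n}, "
            f"TR={series.tr_s}s"
        )
    flat = series.data[mask]
    spec = np.fft.rfft(flat, axis=1)
    power = np.abs(spec[:, sel]) ** 2
    vals = np.sqrt(power.sum(axis=1))
    values = np.zeros(mask.shape)
    values[mask] = vals
    return AlffMap(values, mask, band=(f_lo, f_hi), standardized=False)
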