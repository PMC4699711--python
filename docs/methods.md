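# Methods

## Pipeline

The analysis chain, in execution order:

1. **Volume discard** — the first `discard_k` (default 10) volumes are
   dropped to let the signal reach steady state.
2. **Spatial smoothing** — isotropic Gaussian, default FWHM 6 mm
   (`sigma = FWHM / (2 sqrt(2 ln 2))` per axis in voxel units), reflective
   boundaries, kernel truncated at 6 sigma so the discrete kernel mass is 1
   to well below 1e-6. Smoothing before temporal filtering follows the
   DPARSF-style step order; the order is enforced via the series'
   provenance record.
3. **Linear detrend** — per-voxel OLS on an intercept and linear ramp.
4. **Band-pass** — ideal (brick-wall) DFT filter, default 0.01–0.08 Hz,
   the REST/DPARSF convention; bins strictly outside the band are zeroed
   and DC is always removed.
5. **Nuisance regression** — per-voxel OLS residual on an intercept, the 6
   realignment parameters, and mean WM and CSF signals (probability > 0.9,
   one-voxel erosion, falling back to the uneroded mask when erosion
   empties a thin compartment). The tissue signals are extracted from the
   *same* series being cleaned: the BEN branch regresses band-passed data
   on band-pass-extracted tissue signals, the ALFF branch regresses the
   unfiltered (detrended) data on broadband tissue signals. Regressing
   broadband tissue courses out of a band-limited series would leak
   out-of-band signal back into the residuals.
6. **Motion QC** — a subject is excluded when the time-mean absolute
   realignment parameter exceeds 2 mm on any translation axis or 2 degrees
   on any rotation axis. "Mean absolute parameter" is the simplest reading
   of mean head motion; motion files use the SPM `rp_*.txt` dialect
   (radians) with a flag for degree-native files.

## Sample entropy

`SampEn(m, r, N, x) = -ln(A/B)` with ordered-pair match counts over
templates `i, j in 0..N-m-1` (every m-template has an (m+1)-point
extension), Chebyshev distance, strict `< r` matching, self-matches
excluded, and `r = r_frac * SD(x)` recomputed per voxel from the fully
preprocessed series (ddof = 0, the convention of the reference SampEn
implementations). Defaults `m = 3`, `r_frac = 0.6`.

An alternative normalization (`paper_literal`) divides B by
`(N-m)(N-m+1)` and A by `(N-m)(N-m-1)` before the log. These denominators
are mutually inconsistent — an all-matching series yields
`-ln[(N-m+1)/(N-m-1)] < 0` — so the standard pair-count form is the
default and the literal form exists for comparability only.

Undefined results (constant series, zero match count) are flagged NaN,
carried through smoothing and standardization as zero-weight voxels, and
counted in a QC sidecar — never silently zeroed and never ±inf.

The production kernel sorts templates by first coordinate and enumerates
only pairs whose first coordinates are within `r` (box-assisted counting,
numba-compiled, with a branchless m = 3 fast path); its counts are
bit-identical to the naive double loop, which the test suite verifies
against an independent brute-force oracle.

"Fisher's z" standardization of BEN maps is implemented as in-mask
z-scoring (subtract in-mask mean, divide by in-mask SD, after
mask-normalized Gaussian smoothing). The literal inverse hyperbolic
tangent is available as `mode="artanh"` but raises a domain error whenever
any in-mask value is >= 1 — which raw SampEn values regularly are — so
z-scoring is the only reading that runs in general; the ambiguity is
documented rather than resolved.

## ALFF

`ALFF = sqrt( sum_{f_lo <= f <= f_hi} |X(f)|^2 )` over positive-frequency
bins of the unnormalized forward DFT (a unit-amplitude sine on an in-band
bin gives N/2). The input is the detrended, nuisance-corrected but *not*
band-passed series — band selection happens in the ALFF sum itself, and
band-passing first would make out-of-band content trivially zero. The
scale set by the DFT convention is removed by in-mask z-scoring before any
group statistics.

## Group statistics

Per-voxel OLS of standardized maps on intercept + group (patient = 1) +
age + sex (M = 1) + education; `t` is the group coefficient over its
standard error, `df = n - 5`, two-sided p. A numerically perfect fit
(zero residual variance) reports t = 0.

Cluster-extent correction is AlphaSim-style Monte Carlo: each iteration
fills the mask grid with white Gaussian noise, smooths to the map FWHM
(the known applied smoothness by default — on synthetic data the truth is
known; residual-based smoothness estimation adds variance), re-standardizes
in-mask, thresholds two-sided at the voxel p, and records the largest
connected component per sign. `k_min` is the smallest extent whose null
exceedance fraction is <= alpha. Defaults: voxel p 0.01, alpha 0.05, 1000
iterations, 26-connectivity (the most inclusive neighborhood and the
common DPARSF setting; 6 and 18 available). Clusters of the real t-map are
labeled separately per sign (both increases and decreases are reported),
filtered at extent >= max(min_extent, k_min) with min_extent = 50, sorted
by sign then extent, with peaks reported in world mm via the image affine
(voxel indices stay 0-based and internal).

## Associations

Cluster/ROI means (undefined voxels excluded and counted) are regressed
one predictor at a time; `beta_std` is reported as the signed Pearson
correlation, so `beta_std^2 = R^2` holds identically — the
internal-consistency relation any printed (R², β) pair from such an
analysis must satisfy. The Bonferroni family is the set of (ROI × measure)
tests run in one invocation and its size is recorded in the output table
rather than guessed. LOOCV refits the simple regression n times, each
omitting one subject; accuracy is the Pearson correlation between held-out
predictions and observations with a t-test on n − 2 df. Regressions run
within the patient group by default. Diffusion (MD/FA) couplings use the
identical regression code path. BPF = (GM + WM) / (GM + WM + CSF) with
volumes as probability-map sums times voxel volume; lesion load is binary
voxel count × voxel volume / 1000 (ml).

## Synthetic cohort

Each voxel's course is `x = (1 - w)·s + w·e`: `s` a stationary
unit-variance AR(1), `e` unit white noise. SampEn is monotone
non-decreasing in `w`, making `w` the entropy dial. Two design choices
matter and were fixed by spectral analysis of the band, not by tuning on
outcomes:

- **AR coefficient phi = 0.8.** At TR = 2 s the AR(1) half-power point is
  roughly `(1 - phi)/(2 pi TR)` Hz. phi = 0.8 places it near 0.016 Hz,
  inside the 0.01–0.08 Hz analysis band, so the contrast carried by `w`
  survives band-pass filtering; with phi near 1 the AR power sits below
  0.01 Hz and the filter removes exactly the structure that distinguishes
  `w`.
- **All group weights inside [0.25, 0.7]**, where post-filter SampEn is
  steepest in `w`: WM core 0.30, GM shell 0.60 (the GM/WM entropy contrast
  of real maps, direction fixed by construction), CSF rim 0.45; planted
  regions 0.65 (patients) vs 0.35 (controls) and the reverse.

Anatomy is a centered ellipsoid (~60% of the grid) with concentric
WM/GM/CSF compartments; planted regions are ~5×5×5 boxes (125 voxels)
labeled GM in the tissue maps so the WM/CSF nuisance masks never overlap
them (regressing a region's own mean signal out of itself would erase the
planted effect). Each subject gets a per-region Gaussian entropy offset
(SD 0.15); clinical scores are linear in these offsets — EDSS on the
entropy-increased region (intercept 3, slope 8, noise SD 1.85, clipped to
[0, 10]), MFIS-5 on the entropy-decreased region (11, 15, 3.44, [0, 20]),
PASAT with slope 0 (the groups differ in PASAT but no entropy association
is planted) — giving an implied in-sample R² near 0.3. Controls draw from
separate null distributions (EDSS 0, MFIS-5 in {0, 1}, PASAT ~ N(97.8,
8)). MD maps are a 0.8e-3 mm²/s baseline plus `md_coupling` × offset in
coupled regions plus voxel noise. Demographics: ages uniform 20–58,
13 M : 21 F per group, education uniform 8–18 years. Motion parameters are
small random walks; a configurable fraction of subjects is pushed past the
QC threshold (default 0). A shared AR(0.5) confound (amplitude 0.3) is
added to all in-mask voxels to exercise nuisance regression. Everything
planted is stored in a ground-truth record; fixed seed means byte-identical
outputs (per-subject streams spawned from one seed sequence, images
written as uncompressed NIfTI-1).

What the generator does **not** emulate: scanner physics, slice timing,
susceptibility artifacts, motion in image space, spatial autocorrelation of
the underlying neural signal (voxels are independent before smoothing),
non-Gaussian BOLD amplitude distributions, or realistic anatomy. Passing
tests therefore demonstrate that the chain recovers effects of the planted
kind under the planted noise model — not that it would detect comparable
effects in real data.

## Numerical choices and degenerate inputs

- Strict inequalities throughout SampEn matching and thresholding
  (`< r`, `p < voxel_p`, extent `>= min_extent`).
- SD uses ddof = 0 everywhere (SampEn tolerance, map z-scoring).
- Gaussian smoothing: reflect boundaries, truncate 6 sigma (mass
  preservation to < 1e-6).
- Band-pass keeps bins with `f_lo <= f <= f_hi` inclusive; empty bands are
  a parameter error.
- Rank-deficient nuisance or group designs raise errors naming the
  collinear columns; zero-variance regression inputs and empty ROI masks
  are data errors, not NaNs.
- Series shorter than `m + 2` are rejected; constant series are flagged
  undefined.

## Problem sizes in the test suite

Unit and property tests run on reduced cohorts: a 14×14×10 grid with 8+8
subjects, keeping the full 240 timepoints. The temporal dimension is
deliberately not reduced: with ~half the volumes the band-limited series
retains so few spectral degrees of freedom (~15 in-band bins) that
regressing six motion regressors materially distorts the signal — a real
phenomenon worth knowing about when planning short acquisitions. The
full-pipeline recovery check runs the complete default cohort (34+34,
24×24×16×240) over 20 seeds with the extent threshold computed once (the
mask, smoothness and seed are shared). Family-wise-error calibration uses
200 simulated no-effect datasets of 12 smoothed-noise maps on the reduced
grid; LOOCV calibration uses 200 null replicates at n = 34. The
acceptance script uses 6 cohorts for the recovery rate to keep its
runtime in minutes.

## Known limitations

- The Monte-Carlo null assumes stationary Gaussian fields of known
  smoothness; residual-based smoothness estimation is not implemented
  beyond the planned option surface, and non-stationary smoothness is not
  modeled.
- The brick-wall filter has infinite impulse response in time; edge
  ringing is not windowed.
- ALFF normalization conventions differ across packages; only in-mask
  z-scored maps are comparable across this package's versions.
- The LOOCV accuracy index (Pearson r between held-out predictions and
  observations, two-sided t on n − 2 df) mirrors common practice but is
  not null-calibrated: each held-out prediction contains −y_i/(n − 1)
  through the training mean, so under a true null the predicted-observed
  correlation is biased strongly negative (mean r ≈ −0.34 at n = 34,
  two-sided rejection rate ≈ 0.49, verified against an independent
  leave-one-out implementation). Claims of *positive* predictive accuracy
  are correspondingly conservative (null rate ≈ 0.008). Interpret the
  two-sided p accordingly, or prefer a permutation test when the sign of
  the accuracy matters.
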