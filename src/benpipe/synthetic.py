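"""Synthetic two-group resting-state cohort with planted entropy effects.

The generator emulates the statistical structure the downstream analysis
assumes, not scanner physics. Each voxel's time course is a mixture

    x = (1 - w) * s + w * e

of a unit-variance AR(1) process s (coefficient phi) and unit-variance white
noise e. Sample Entropy is monotone non-decreasing in the white-noise weight
w, so w is the entropy control knob: planting a group difference in w inside
a region plants a BEN difference of known sign there.

The anatomy is a centered ellipsoidal "brain" (~60% of the grid) split into
concentric compartments — a WM-like core, a GM-like shell, and a CSF-like rim
— each with its own baseline w. Regions of interest override w per group and
receive a per-subject, per-region Gaussian offset delta; that offset is the
subject's "entropy offset", the quantity clinical scores and MD maps are
coupled to, and everything planted is stored in a ground-truth record.

Default cohort: 34 patients + 34 controls, 24 x 24 x 16 grid of 3 mm voxels,
240 timepoints at TR = 2 s, ages uniform 20-58, 13 M / 21 F per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import ConfigurationError, DataError, ParameterError

DEFAULT_GRID = (24, 24, 16)

# AR(1) coefficient of the smooth component. At TR = 2 s the AR(1) spectral
# half-power point is roughly (1 - phi) / (2 pi TR) Hz; phi = 0.8 puts it
# near 0.016 Hz, inside the 0.01-0.08 Hz analysis band, so the entropy
# contrast carried by w survives band-pass filtering (with phi close to 1
# the AR power sits below 0.01 Hz and the filter removes the contrast).
DEFAULT_PHI = 0.8

# compartment baselines for the white-noise weight w: the GM shell is set
# more irregular than the WM core (mirrors the empirical GM/WM BEN contrast
# in real maps, with the direction here fixed by construction). Values sit
# inside [0.25, 0.7], where post-filter Sample Entropy is steepest in w.
DEFAULT_W_WM = 0.30
DEFAULT_W_GM = 0.60
DEFAULT_W_CSF = 0.45


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiSpec:
    """A planted region: voxel set plus per-group white-noise weights.

    ``md_coupling`` is the slope (in MD units, mm^2/s, per unit w-offset)
    linking a subject's entropy offset in this region to their MD map there.
    """

    name: str
    voxels: tuple[tuple[int, int, int], ...]
    w_patient: float
    w_control: float
    md_coupling: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.w_patient <= 1 and 0 <= self.w_control <= 1):
            raise ParameterError("ROI mix weights must lie in [0, 1]")
        if len(self.voxels) == 0:
            raise ParameterError(f"ROI '{self.name}' has no voxels")

    def index_array(self) -> np.ndarray:
        return np.asarray(self.voxels, dtype=int)


@dataclass(frozen=True)
class ScoreLink:
    """Linear link from ROI entropy offsets to one clinical score."""

    intercept: float
    slopes: tuple[tuple[str, float], ...]  # (roi_name, slope) pairs
    noise_sd: float
    clip: tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LinkParams:
    """Per-score linear links plus the control-group null distributions."""

    scores: tuple[tuple[str, ScoreLink], ...]

    def as_dict(self) -> dict[str, ScoreLink]:
        return dict(self.scores)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    education: float
    edss: float
    mfis5: float
    pasat: float
    motion_params: np.ndarray  # (t, 6): translations mm, rotations deg

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ParameterError(f"bad group {self.group!r}")


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 34
    n_controls: int = 34
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size_mm: float = 3.0
    n_timepoints: int = 240
    tr_s: float = 2.0
    roi_specs: tuple[RoiSpec, ...] | None = None  # None -> defaults for grid
    clinical_link: LinkParams | None = None  # None -> default links
    seed: int = 0
    phi: float = DEFAULT_PHI
    w_wm: float = DEFAULT_W_WM
    w_gm: float = DEFAULT_W_GM
    w_csf: float = DEFAULT_W_CSF
    subject_w_sd: float = 0.15  # SD of the per-subject, per-ROI entropy offset
    confound_amplitude: float = 0.3  # shared physiological-like confound
    motion_walk_sd: float = 0.02  # per-frame random-walk step, mm / deg
    motion_exceed_fraction: float = 0.0  # fraction of subjects pushed past QC
    md_baseline: float = 0.8e-3  # mm^2/s
    md_noise_sd: float = 0.02e-3

    def __post_init__(self) -> None:
        if self.n_timepoints < 20:
            raise ConfigurationError("n_timepoints must be >= 20")
        if any(d < 8 for d in self.grid_shape):
            raise ConfigurationError("all grid dimensions must be >= 8")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be > 0")
        if not abs(self.phi) < 1:
            raise ConfigurationError("|phi| must be < 1")


# ---------------------------------------------------------------------------
# geometry: ellipsoidal brain, concentric tissue shells, default ROIs
# ---------------------------------------------------------------------------

def _ellipsoid_radius(grid_shape) -> np.ndarray:
    """Normalized ellipsoidal radius u (u <= 1 inside the brain)."""
    nx, ny, nz = grid_shape
    center = (np.array(grid_shape) - 1) / 2.0
    semi = 0.525 * np.array(grid_shape)  # slightly beyond the half-width
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    u = np.sqrt(
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    return u


def make_brain_geometry(grid_shape):
    """Brain mask (centered ellipsoid, ~60% of the grid) and 0/1 tissue maps.

    Compartments are concentric: WM core (u < 0.55), GM shell
    (0.55 <= u < 0.85), CSF rim (0.85 <= u <= 1).
    """
    u = _ellipsoid_radius(grid_shape)
    mask = u <= 1.0
    wm = (u < 0.55) & mask
    gm = (u >= 0.55) & (u < 0.85) & mask
    csf = (u >= 0.85) & mask
    return mask, {"gm": gm.astype(float), "wm": wm.astype(float), "csf": csf.astype(float)}


def _box_voxels(center, half, grid_shape, mask):
    c = np.asarray(center)
    lo = np.maximum(c - half, 0)
    hi = np.minimum(c + half + 1, grid_shape)
    vox = [
        (i, j, k)
        for i in range(lo[0], hi[0])
        for j in range(lo[1], hi[1])
        for k in range(lo[2], hi[2])
        if mask[i, j, k]
    ]
    return tuple(vox)


def default_roi_specs(grid_shape=DEFAULT_GRID) -> tuple[RoiSpec, ...]:
    """Two planted regions: one with higher entropy in patients (a
    supplementary-motor-area analog, superior), one with lower entropy in
    patients (a parahippocampal analog, inferior). Each is a ~4-voxel box
    (>= 50 voxels at the default grid) with an MD coupling on the first."""
    mask, _ = make_brain_geometry(grid_shape)
    cx, cy, cz = (np.array(grid_shape) - 1) // 2
    up_center = (cx, cy, min(cz + grid_shape[2] // 4, grid_shape[2] - 3))
    down_center = (cx, cy, max(cz - grid_shape[2] // 4, 2))
    up = _box_voxels(np.array(up_center), 2, grid_shape, mask)  # 5x5x5 box
    down = _box_voxels(np.array(down_center), 2, grid_shape, mask)
    return (
        RoiSpec("sma_analog", up, w_patient=0.65, w_control=0.35, md_coupling=2.0e-3),
        RoiSpec("phipp_analog", down, w_patient=0.35, w_control=0.65, md_coupling=0.0),
    )


def default_link_params() -> LinkParams:
    """Default clinical couplings.

    EDSS rises with the entropy offset in the entropy-increased region and
    MFIS-5 with the offset in the entropy-decreased region (higher regional
    entropy <-> more disability / fatigue); with offset SD 0.15 the implied
    in-sample R^2 is ~0.3 for both. PASAT is linked with slope 0: the groups
    differ in PASAT but no entropy association is planted.
    """
    return LinkParams(
        scores=(
            ("edss", ScoreLink(3.0, (("sma_analog", 8.0),), 1.85, (0.0, 10.0))),
            ("mfis5", ScoreLink(11.0, (("phipp_analog", 15.0),), 3.44, (0.0, 20.0))),
            ("pasat", ScoreLink(84.0, (("sma_analog", 0.0),), 9.0, (0.0, 120.0))),
        )
    )


CONTROL_SCORE_NULLS = {
    # control scores are drawn from separate null distributions
    "edss": ("constant", 0.0),
    "mfis5": ("uniform_int", 0, 1),
    "pasat": ("normal", 97.8, 8.0),
}


# ---------------------------------------------------------------------------
# signal model
# ---------------------------------------------------------------------------

def _ar1_unit_variance(eps: np.ndarray, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) driven by standard-normal draws.

    eps has shape (..., n); the first draw seeds the stationary state and the
    rest are innovations scaled to sqrt(1 - phi^2).
    """
    scaled = eps * np.sqrt(1.0 - phi**2)
    scaled[..., 0] = eps[..., 0]
    return _signal.lfilter([1.0], [1.0, -phi], scaled, axis=-1)


def synth_voxel_signal(w: float, phi: float, n: int, seed) -> np.ndarray:
    """One entropy-tunable voxel time course: (1-w)*AR(1) + w*white noise."""
    if not 0 <= w <= 1:
        raise ParameterError("w must lie in [0, 1]")
    if not abs(phi) < 1:
        raise ParameterError("|phi| must be < 1")
    if n < 20:
        raise ParameterError("n must be >= 20")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = _ar1_unit_variance(rng.standard_normal(n), phi)
    e = rng.standard_normal(n)
    return (1.0 - w) * s + w * e


def _subject_bold(w_map_flat, phi, n_t, confound, confound_amp, rng):
    """All in-mask voxel signals for one subject, shape (V, T)."""
    v = w_map_flat.shape[0]
    s = _ar1_unit_variance(rng.standard_normal((v, n_t)), phi)
    e = rng.standard_normal((v, n_t))
    w = w_map_flat[:, None]
    x = (1.0 - w) * s + w * e
    return x + confound_amp * confound[None, :]


def _random_walk_motion(n_t, step_sd, rng, scale=1.0):
    steps = rng.standard_normal((n_t, 6)) * step_sd
    walk = np.cumsum(steps, axis=0)
    return walk * scale


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory synthetic cohort plus its complete ground-truth record."""

    config: CohortConfig
    brain_mask: np.ndarray
    tissue_probs: dict[str, np.ndarray]
    roi_masks: dict[str, np.ndarray]
    manifest: pd.DataFrame
    subjects: list[SubjectRecord]
    bold: dict[str, np.ndarray]  # subject_id -> (x, y, z, t)
    md_maps: dict[str, np.ndarray]
    fa_maps: dict[str, np.ndarray]
    ground_truth: dict

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.config.voxel_size_mm] * 3 + [1.0])
        # RAS, centered origin
        aff[:3, 3] = -(np.array(self.config.grid_shape) - 1) / 2.0 * self.config.voxel_size_mm
        return aff


def _resolve_specs(cfg: CohortConfig):
    rois = cfg.roi_specs if cfg.roi_specs is not None else default_roi_specs(cfg.grid_shape)
    link = cfg.clinical_link if cfg.clinical_link is not None else default_link_params()
    return tuple(rois), link


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate the full cohort: images, masks, manifest, MD/FA maps, truth.

    Deterministic given ``cfg.seed``: per-subject random streams are spawned
    from a single seed sequence, so the same config yields identical arrays.
    """
    rois, link = _resolve_specs(cfg)
    mask, tissues = make_brain_geometry(cfg.grid_shape)
    for roi in rois:
        idx = roi.index_array()
        if (idx < 0).any() or (idx >= np.array(cfg.grid_shape)).any():
            raise ConfigurationError(f"ROI '{roi.name}' extends outside the grid")
        if not mask[idx[:, 0], idx[:, 1], idx[:, 2]].all():
            raise ConfigurationError(f"ROI '{roi.name}' has voxels outside the brain mask")

    # planted regions are labeled gray matter in the tissue maps: real
    # findings live in GM, and the WM/CSF nuisance masks must not overlap a
    # planted region (regressing a region's own mean signal out of itself
    # would erase the planted effect)
    for roi in rois:
        idx = roi.index_array()
        for name in ("wm", "csf"):
            tissues[name][idx[:, 0], idx[:, 1], idx[:, 2]] = 0.0
        tissues["gm"][idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0

    root_ss = np.random.SeedSequence(cfg.seed)
    demo_rng = np.random.default_rng(root_ss.spawn(1)[0])

    n_total = cfg.n_patients + cfg.n_controls
    groups = ["patient"] * cfg.n_patients + ["control"] * cfg.n_controls
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_total)]
    subject_seeds = root_ss.spawn(n_total)

    # baseline w per voxel from the tissue compartments
    w_base = np.zeros(cfg.grid_shape)
    w_base[tissues["wm"] > 0] = cfg.w_wm
    w_base[tissues["gm"] > 0] = cfg.w_gm
    w_base[tissues["csf"] > 0] = cfg.w_csf

    roi_masks = {}
    for roi in rois:
        m = np.zeros(cfg.grid_shape, dtype=bool)
        idx = roi.index_array()
        m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        roi_masks[roi.name] = m

    # demographics: ages uniform 20-58, 13M/21F-proportioned sex per group,
    # education uniform 8-18 years
    records: list[SubjectRecord] = []
    truth_subjects: dict[str, dict] = {}
    bold: dict[str, np.ndarray] = {}
    md_maps: dict[str, np.ndarray] = {}
    fa_maps: dict[str, np.ndarray] = {}

    def _sexes(n, rng):
        n_m = int(round(n * 13 / 34))
        sexes = ["M"] * n_m + ["F"] * (n - n_m)
        rng.shuffle(sexes)
        return sexes

    sex_by_group = {
        "patient": _sexes(cfg.n_patients, demo_rng),
        "control": _sexes(cfg.n_controls, demo_rng),
    }
    sex_counters = {"patient": 0, "control": 0}

    n_exceed = int(round(cfg.motion_exceed_fraction * n_total))
    exceed_ids = set(
        demo_rng.choice(n_total, size=n_exceed, replace=False).tolist()
        if n_exceed
        else []
    )

    flat_mask = mask.ravel()
    roi_flat = {
        name: m.ravel()[flat_mask] for name, m in roi_masks.items()
    }

    for i, (sid, group, seed_i) in enumerate(zip(subject_ids, groups, subject_seeds)):
        rng = np.random.default_rng(seed_i)
        age = float(rng.uniform(20, 58))
        education = float(rng.uniform(8, 18))
        sex = sex_by_group[group][sex_counters[group]]
        sex_counters[group] += 1

        # per-subject, per-ROI entropy offsets; realized w clipped to [0, 1]
        w_map = w_base.copy()
        offsets: dict[str, float] = {}
        realized: dict[str, float] = {}
        for roi in rois:
            delta = float(rng.normal(0.0, cfg.subject_w_sd))
            group_w = roi.w_patient if group == "patient" else roi.w_control
            w_roi = float(np.clip(group_w + delta, 0.0, 1.0))
            w_map[roi_masks[roi.name]] = w_roi
            offsets[roi.name] = delta
            realized[roi.name] = w_roi

        confound = _ar1_unit_variance(rng.standard_normal(cfg.n_timepoints), 0.5)
        sig = _subject_bold(
            w_map.ravel()[flat_mask],
            cfg.phi,
            cfg.n_timepoints,
            confound,
            cfg.confound_amplitude,
            rng,
        )
        img = np.zeros(cfg.grid_shape + (cfg.n_timepoints,), dtype=np.float32)
        img.reshape(-1, cfg.n_timepoints)[flat_mask] = 100.0 + sig
        bold[sid] = img

        motion = _random_walk_motion(cfg.n_timepoints, cfg.motion_walk_sd, rng)
        if i in exceed_ids:
            motion[:, 2] += 3.0  # push the z-translation mean past 2 mm

        # MD map: baseline + coupling * entropy offset inside coupled ROIs
        md = np.full(cfg.grid_shape, cfg.md_baseline)
        md += rng.normal(0.0, cfg.md_noise_sd, size=cfg.grid_shape)
        for roi in rois:
            if roi.md_coupling != 0.0:
                md[roi_masks[roi.name]] += roi.md_coupling * offsets[roi.name]
        md[~mask] = 0.0
        md_maps[sid] = md
        fa = np.clip(
            0.40 + rng.normal(0.0, 0.03, size=cfg.grid_shape), 0.0, 1.0
        )
        fa[~mask] = 0.0
        fa_maps[sid] = fa

        records.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                age=age,
                sex=sex,
                education=education,
                edss=float("nan"),
                mfis5=float("nan"),
                pasat=float("nan"),
                motion_params=motion,
            )
        )
        truth_subjects[sid] = {
            "group": group,
            "entropy_offsets": offsets,
            "realized_w": realized,
        }

    manifest = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": groups,
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "education": [r.education for r in records],
            "edss": np.nan,
            "mfis5": np.nan,
            "pasat": np.nan,
        }
    )

    ground_truth = {
        "seed": cfg.seed,
        "phi": cfg.phi,
        "baseline_w": {"wm": cfg.w_wm, "gm": cfg.w_gm, "csf": cfg.w_csf},
        "subject_w_sd": cfg.subject_w_sd,
        "rois": {
            roi.name: {
                "w_patient": roi.w_patient,
                "w_control": roi.w_control,
                "md_coupling": roi.md_coupling,
                "n_voxels": int(roi_masks[roi.name].sum()),
            }
            for roi in rois
        },
        "clinical_link": {
            score: {
                "intercept": lk.intercept,
                "slopes": dict(lk.slopes),
                "noise_sd": lk.noise_sd,
                "clip": list(lk.clip),
            }
            for score, lk in link.as_dict().items()
        },
        "md_baseline": cfg.md_baseline,
        "subjects": truth_subjects,
    }

    cohort = Cohort(
        config=cfg,
        brain_mask=mask,
        tissue_probs=tissues,
        roi_masks=roi_masks,
        manifest=manifest,
        subjects=records,
        bold=bold,
        md_maps=md_maps,
        fa_maps=fa_maps,
        ground_truth=ground_truth,
    )
    entropy_means = {
        sid: dict(truth_subjects[sid]["entropy_offsets"]) for sid in subject_ids
    }
    assign_clinical_scores(cohort, entropy_means, link, root_ss.spawn(1)[0])
    return cohort


def assign_clinical_scores(cohort_or_manifest, entropy_means, link: LinkParams, seed):
    """Fill clinical scores from the linear link on per-subject ROI offsets.

    Patients: score = intercept + sum_roi slope * offset + N(0, noise_sd),
    clipped to the score's plausible range. Controls are drawn from separate
    null distributions (EDSS 0, MFIS-5 in {0, 1}, PASAT ~ N(97.8, 8)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(cohort_or_manifest, Cohort):
        manifest = cohort_or_manifest.manifest
        records = {r.subject_id: r for r in cohort_or_manifest.subjects}
    else:
        manifest = cohort_or_manifest
        records = {}
    links = link.as_dict()
    for idx, row in manifest.iterrows():
        sid, group = row["subject_id"], row["group"]
        for score, lk in links.items():
            if group == "patient":
                if sid not in entropy_means:
                    raise DataError(f"no entropy means for subject {sid}")
                means = entropy_means[sid]
                total = lk.intercept
                for roi_name, slope in lk.slopes:
                    if roi_name not in means:
                        raise DataError(
                            f"missing ROI mean '{roi_name}' for subject {sid}"
                        )
                    total += slope * means[roi_name]
                total += rng.normal(0.0, lk.noise_sd) if lk.noise_sd > 0 else 0.0
                value = float(np.clip(total, lk.clip[0], lk.clip[1]))
            else:
                kind, *p = CONTROL_SCORE_NULLS.get(score, ("constant", 0.0))
                if kind == "constant":
                    value = float(p[0])
                elif kind == "uniform_int":
                    value = float(rng.integers(p[0], p[1] + 1))
                else:
                    value = float(np.clip(rng.normal(p[0], p[1]), 0.0, np.inf))
            manifest.loc[idx, score] = value
            if sid in records:
                setattr(records[sid], score, value)
    return manifest


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write the cohort to disk: per-subject 4D NIfTI + motion text files,
    3D masks/tissue/MD/FA NIfTIs, a TSV manifest, and a YAML ground truth.

    Motion files use the SPM ``rp_*.txt`` dialect (translations in mm,
    rotations in radians). Images are uncompressed NIfTI-1 so that repeated
    writes of the same cohort are byte-identical.
    """
    import nibabel as nib
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = cohort.affine
    tr = cohort.config.tr_s

    def _save(arr, path, four_d=False):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), aff)
        if four_d:
            img.header.set_zooms(
                tuple([cohort.config.voxel_size_mm] * 3 + [tr])
            )
            img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))

    _save(cohort.brain_mask.astype(np.float32), out / "brain_mask.nii")
    for name, prob in cohort.tissue_probs.items():
        _save(prob, out / f"tissue_{name}.nii")
    for name, m in cohort.roi_masks.items():
        _save(m.astype(np.float32), out / f"roi_{name}_mask.nii")

    rows = []
    for rec in cohort.subjects:
        sid = rec.subject_id
        bold_path = out / f"{sid}_bold.nii"
        motion_path = out / f"{sid}_motion.txt"
        _save(cohort.bold[sid], bold_path, four_d=True)
        motion = rec.motion_params.copy()
        motion[:, 3:] = np.deg2rad(motion[:, 3:])  # SPM dialect: radians
        np.savetxt(motion_path, motion, fmt="%.10e")
        _save(cohort.md_maps[sid], out / f"{sid}_md.nii")
        _save(cohort.fa_maps[sid], out / f"{sid}_fa.nii")
        rows.append(
            {
                "subject_id": sid,
                "group": rec.group,
                "age": rec.age,
                "sex": rec.sex,
                "education": rec.education,
                "edss": rec.edss,
                "mfis5": rec.mfis5,
                "pasat": rec.pasat,
                "bold_path": bold_path.name,
                "motion_path": motion_path.name,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(cohort.ground_truth, fh, sort_keys=True)
    return out
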