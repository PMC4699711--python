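"""End-to-end orchestration: simulate -> preprocess -> BEN/ALFF -> group
statistics -> ROI associations, with a single-file configuration and
reproducible, seed-stamped outputs.

The no-flag defaults are the analysis defaults throughout the package:
discard 10 volumes, 6 mm FWHM smoothing, 0.01-0.08 Hz band, SampEn m=3 /
r_frac=0.6, voxel p<0.01, extent >= 50, alpha=0.05 with 1000 Monte-Carlo
iterations, 26-connectivity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import entropy as ent
from . import preprocess as pre
from . import stats as grp
from . import synthetic as syn
from .errors import ConfigurationError, DataError
from .io import load_bold, load_manifest, load_map, load_motion, save_map

log = logging.getLogger("benpipe")


@dataclass
class RunConfig:
    """Every stage parameter of a pipeline run, serializable to YAML."""

    # inputs / outputs
    data_dir: str = ""
    out_dir: str = "benpipe_run"
    simulate: bool = True  # generate a synthetic cohort into data_dir first
    seed: int = 0
    log_level: str = "INFO"
    # synthetic cohort
    n_patients: int = 34
    n_controls: int = 34
    grid_shape: tuple[int, int, int] = syn.DEFAULT_GRID
    n_timepoints: int = 240
    tr_s: float = 2.0
    voxel_size_mm: float = 3.0
    # preprocessing
    discard_k: int = 10
    fwhm_mm: float = 6.0
    band: tuple[float, float] = (0.01, 0.08)
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    # entropy / ALFF
    sampen_m: int = 3
    sampen_r_frac: float = 0.6
    sampen_normalization: str = "standard"
    standardize_mode: str = "zscore"
    # group statistics
    voxel_p: float = 0.01
    min_extent: int = 50
    alpha: float = 0.05
    n_iter: int = 1000
    connectivity: int = 26
    # associations
    clinical_measures: tuple[str, ...] = ("edss", "mfis5")
    association_group: str = "patient"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "band", "clinical_measures"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded)."""
        data = dataclasses.asdict(self)
        for key in ("data_dir", "out_dir", "log_level"):
            data.pop(key, None)
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def preprocess_subject(
    series: pre.BoldSeries,
    motion_deg: np.ndarray,
    wm_prob: np.ndarray,
    csf_prob: np.ndarray,
    cfg: RunConfig,
) -> tuple[pre.BoldSeries, pre.BoldSeries]:
    """Run the preprocessing chain on one subject.

    Returns (fully preprocessed series, ALFF input series). The ALFF input
    is detrended and nuisance-corrected but not band-pass filtered — band
    selection happens inside the ALFF spectrum sum.
    """
    s = pre.discard_initial_volumes(series, cfg.discard_k)
    s = pre.smooth_gaussian(s, cfg.fwhm_mm)
    s = pre.detrend_linear(s)
    motion_cut = motion_deg[cfg.discard_k :]
    filtered = pre.bandpass_filter(s, *cfg.band)
    # tissue signals are extracted from the series being cleaned: regressing
    # broadband WM/CSF time courses out of a band-limited series would leak
    # out-of-band signal back into the residuals
    nuis_filtered = pre.NuisanceSet(
        motion=motion_cut,
        wm_signal=pre.extract_tissue_signal(filtered, wm_prob),
        csf_signal=pre.extract_tissue_signal(filtered, csf_prob),
    )
    nuis_broadband = pre.NuisanceSet(
        motion=motion_cut,
        wm_signal=pre.extract_tissue_signal(s, wm_prob),
        csf_signal=pre.extract_tissue_signal(s, csf_prob),
    )
    ben_input = pre.regress_nuisance(filtered, nuis_filtered)
    alff_input = pre.regress_nuisance(s, nuis_broadband)
    return ben_input, alff_input


def _series_from_array(arr, cfg: RunConfig, affine) -> pre.BoldSeries:
    return pre.BoldSeries(
        data=np.asarray(arr, dtype=np.float64),
        voxel_size_mm=np.full(3, cfg.voxel_size_mm),
        tr_s=cfg.tr_s,
        affine=affine,
    )


def analyze_cohort(cohort: syn.Cohort, cfg: RunConfig, mc_result=None) -> dict:
    """Run the full analysis on an in-memory cohort; returns a result dict.

    Stages: motion QC -> preprocessing -> BEN and ALFF maps -> group GLM ->
    Monte-Carlo cluster threshold -> cluster table -> ROI means -> clinical
    regressions with Bonferroni and LOOCV.
    """
    rule = pre.QcRule(cfg.max_translation_mm, cfg.max_rotation_deg)
    kept, excluded = [], {}
    for rec in cohort.subjects:
        decision = pre.qc_motion_exclude(rec.motion_params, rule)
        if decision.keep:
            kept.append(rec.subject_id)
        else:
            excluded[rec.subject_id] = list(decision.reasons)
    if not kept:
        raise DataError("no subjects remain after motion QC")

    manifest = cohort.manifest[cohort.manifest["subject_id"].isin(kept)].reset_index(
        drop=True
    )
    mask = cohort.brain_mask
    params = ent.SampEnParams(
        m=cfg.sampen_m,
        r_frac=cfg.sampen_r_frac,
        normalization=cfg.sampen_normalization,
    )
    ben_stack, alff_stack = [], []
    qc_reports = {}
    for sid in manifest["subject_id"]:
        series = _series_from_array(cohort.bold[sid], cfg, cohort.affine)
        rec = next(r for r in cohort.subjects if r.subject_id == sid)
        ben_in, alff_in = preprocess_subject(
            series,
            rec.motion_params,
            cohort.tissue_probs["wm"],
            cohort.tissue_probs["csf"],
            cfg,
        )
        bmap = ent.ben_map(ben_in, mask, params)
        qc_reports[sid] = bmap.qc
        bmap = ent.smooth_and_standardize_ben(
            bmap, cfg.fwhm_mm, cfg.voxel_size_mm, cfg.standardize_mode
        )
        amap = ent.alff_map(alff_in, mask, cfg.band)
        amap = ent.smooth_and_standardize_ben(
            amap, 0.0, cfg.voxel_size_mm, cfg.standardize_mode
        )
        ben_stack.append(np.where(bmap.defined, bmap.values, 0.0))
        alff_stack.append(np.where(amap.defined, amap.values, 0.0))
        log.info("subject %s: BEN/ALFF mapped (%d undefined voxels)",
                 sid, bmap.qc["n_undefined"])

    ben_stack = np.stack(ben_stack)
    alff_stack = np.stack(alff_stack)
    design, columns = grp.build_design_matrix(manifest)
    stat = grp.fit_group_glm(ben_stack, design, mask)
    stat_alff = grp.fit_group_glm(alff_stack, design, mask)

    if mc_result is None:
        mc = grp.McParams(
            voxel_p=cfg.voxel_p,
            alpha=cfg.alpha,
            n_iter=cfg.n_iter,
            fwhm_mm=cfg.fwhm_mm,
            connectivity=cfg.connectivity,
            seed=cfg.seed,
        )
        mc_result = grp.mc_cluster_extent(mask, mc, cfg.voxel_size_mm)
    min_extent = max(cfg.min_extent, mc_result.k_min)
    clusters = grp.extract_clusters(
        stat, cfg.voxel_p, min_extent, cfg.connectivity, cohort.affine
    )
    clusters_alff = grp.extract_clusters(
        stat_alff, cfg.voxel_p, min_extent, cfg.connectivity, cohort.affine
    )

    # ROI associations within the patient group, on cluster means
    pat = manifest[manifest["group"] == cfg.association_group].reset_index(drop=True)
    pat_rows = manifest.index[manifest["group"] == cfg.association_group].to_numpy()
    associations = None
    loocv_predictions = None
    if len(pat) >= 4 and len(clusters.table) > 0:
        roi_means = pd.DataFrame(
            {
                f"cluster_{cid}": [
                    assoc.roi_mean(ben_stack[i], clusters.cluster_mask(cid))
                    for i in pat_rows
                ]
                for cid in clusters.table["cluster_id"]
            }
        )
        measures = pat[list(cfg.clinical_measures)]
        associations = assoc.association_table(roi_means, measures, alpha=cfg.alpha)
        pred_rows = []
        for roi in roi_means.columns:
            for meas in measures.columns:
                cv = assoc.loocv_predict(roi_means[roi], measures[meas])
                for sid, obs, predicted in zip(
                    pat["subject_id"], cv.observed, cv.predicted
                ):
                    pred_rows.append(
                        {
                            "roi": roi,
                            "measure": meas,
                            "subject_id": sid,
                            "observed": obs,
                            "predicted": predicted,
                        }
                    )
        loocv_predictions = pd.DataFrame(pred_rows)

    return {
        "manifest": manifest,
        "excluded": excluded,
        "qc_reports": qc_reports,
        "ben_stack": ben_stack,
        "alff_stack": alff_stack,
        "design_columns": columns,
        "stat_ben": stat,
        "stat_alff": stat_alff,
        "mc_result": mc_result,
        "min_extent": min_extent,
        "clusters_ben": clusters,
        "clusters_alff": clusters_alff,
        "associations": associations,
        "loocv_predictions": loocv_predictions,
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute a full run from a config; writes all products to out_dir."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {"config_digest": cfg.digest(), "seed": cfg.seed}
    cfg.to_yaml(out / "config.yaml")

    if cfg.simulate:
        ccfg = syn.CohortConfig(
            n_patients=cfg.n_patients,
            n_controls=cfg.n_controls,
            grid_shape=tuple(cfg.grid_shape),
            voxel_size_mm=cfg.voxel_size_mm,
            n_timepoints=cfg.n_timepoints,
            tr_s=cfg.tr_s,
            seed=cfg.seed,
        )
        cohort = syn.generate_cohort(ccfg)
        if cfg.data_dir:
            syn.write_cohort(cohort, cfg.data_dir)
    else:
        cohort = _load_cohort_from_dir(cfg)

    results = analyze_cohort(cohort, cfg)

    aff = cohort.affine
    save_map(results["stat_ben"].t_values, aff, out / "ben_tmap.nii")
    save_map(results["stat_ben"].p_values, aff, out / "ben_pmap.nii")
    save_map(results["stat_alff"].t_values, aff, out / "alff_tmap.nii")
    results["clusters_ben"].table.to_csv(out / "ben_clusters.tsv", sep="\t", index=False)
    results["clusters_alff"].table.to_csv(
        out / "alff_clusters.tsv", sep="\t", index=False
    )
    pd.DataFrame({"max_cluster_size": results["mc_result"].null_max_sizes}).to_csv(
        out / "mc_null_distribution.tsv", sep="\t", index=False
    )
    if results["associations"] is not None:
        results["associations"].to_csv(out / "associations.tsv", sep="\t", index=False)
        results["loocv_predictions"].to_csv(
            out / "loocv_predictions.tsv", sep="\t", index=False
        )
    results["manifest"].to_csv(out / "manifest_used.tsv", sep="\t", index=False)

    summary = {
        **sidecar,
        "n_subjects_used": len(results["manifest"]),
        "excluded_subjects": results["excluded"],
        "k_min": int(results["mc_result"].k_min),
        "min_extent_applied": int(results["min_extent"]),
        "n_ben_clusters": int(len(results["clusters_ben"].table)),
        "n_alff_clusters": int(len(results["clusters_alff"].table)),
        "glm_df": int(results["stat_ben"].df),
    }
    if cfg.simulate:
        summary["planted_roi_detection"] = planted_roi_detection(
            cohort, results["stat_ben"], results["clusters_ben"]
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out


def planted_roi_detection(cohort: syn.Cohort, stat, clusters) -> dict:
    """Compare surviving clusters against the planted ground truth.

    For each planted ROI: the expected sign (from w_patient vs w_control),
    whether a surviving cluster of that sign overlaps it, and whether the
    global |t| peak falls inside any planted ROI.
    """
    truth = cohort.ground_truth["rois"]
    flat_peak = np.abs(np.where(stat.mask, stat.t_values, 0.0)).argmax()
    peak_idx = np.unravel_index(flat_peak, stat.mask.shape)
    peak_in_planted = any(
        bool(m[peak_idx]) for m in cohort.roi_masks.values()
    )
    per_roi = {}
    for name, m in cohort.roi_masks.items():
        expected = np.sign(truth[name]["w_patient"] - truth[name]["w_control"])
        expected_sign = "positive" if expected > 0 else "negative"
        detected = False
        for _, row in clusters.table.iterrows():
            overlap = (clusters.labels == row["cluster_id"]) & m
            if overlap.any() and row["sign"] == expected_sign:
                detected = True
                break
        per_roi[name] = {
            "expected_sign": expected_sign,
            "detected_with_expected_sign": detected,
        }
    return {"peak_in_planted_roi": bool(peak_in_planted), "rois": per_roi}


def _load_cohort_from_dir(cfg: RunConfig) -> syn.Cohort:
    """Rehydrate a written cohort directory into the in-memory form."""
    root = Path(cfg.data_dir)
    if not root.exists():
        raise ConfigurationError(f"data_dir {root} does not exist")
    manifest = load_manifest(root / "manifest.tsv", root)
    mask, _ = load_map(root / "brain_mask.nii")
    mask = mask > 0.5
    tissues = {
        name: load_map(root / f"tissue_{name}.nii")[0] for name in ("gm", "wm", "csf")
    }
    roi_masks = {
        p.name[len("roi_") : -len("_mask.nii")]: load_map(p)[0] > 0.5
        for p in sorted(root.glob("roi_*_mask.nii"))
    }
    ccfg = syn.CohortConfig(
        n_patients=int((manifest["group"] == "patient").sum()),
        n_controls=int((manifest["group"] == "control").sum()),
        grid_shape=tuple(mask.shape),
        voxel_size_mm=cfg.voxel_size_mm,
        n_timepoints=cfg.n_timepoints,
        tr_s=cfg.tr_s,
        seed=cfg.seed,
    )
    subjects, bold, md_maps, fa_maps = [], {}, {}, {}
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        series = load_bold(root / row["bold_path"], tr_fallback_s=cfg.tr_s)
        bold[sid] = series.data
        motion = load_motion(root / row["motion_path"])
        md_path = root / f"{sid}_md.nii"
        if md_path.exists():
            md_maps[sid] = load_map(md_path)[0]
        fa_path = root / f"{sid}_fa.nii"
        if fa_path.exists():
            fa_maps[sid] = load_map(fa_path)[0]
        subjects.append(
            syn.SubjectRecord(
                subject_id=sid,
                group=row["group"],
                age=float(row["age"]),
                sex=row["sex"],
                education=float(row["education"]),
                edss=float(row["edss"]),
                mfis5=float(row["mfis5"]),
                pasat=float(row["pasat"]),
                motion_params=motion,
            )
        )
    truth_path = root / "ground_truth.yaml"
    ground_truth = {}
    if truth_path.exists():
        with open(truth_path) as fh:
            ground_truth = yaml.safe_load(fh)
    return syn.Cohort(
        config=ccfg,
        brain_mask=mask,
        tissue_probs=tissues,
        roi_masks=roi_masks,
        manifest=manifest[list
            (("subject_id", "group", "age", "sex", "education", "edss", "mfis5", "pasat"))
        ].copy(),
        subjects=subjects,
        bold=bold,
        md_maps=md_maps,
        fa_maps=fa_maps,
        ground_truth=ground_truth,
    )
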