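"""End-to-end pipeline driver.

Stage order mirrors the mirrored analysis: preprocess (drop / detrend /
nuisance / band-pass) -> degree centrality on the *unsmoothed* series ->
gray-matter z-scoring -> spatial smoothing of the DC z-map -> voxel-wise
group GLM with cluster-level permutation FDR -> significant DC clusters
become seeds for smoothed seed-based FC -> FC group statistics ->
patient-group clinical correlations -> linear-SVM MVPA on the DC z-maps.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import connectome, groupstats, io as ndio, mvpa as mvpa_mod, preproc
from .config import PipelineConfig
from .errors import InputError
from .images import BoldSeries, VolumeMap
from .synthgen import Cohort

log = logging.getLogger("netdc")


def subject_dc_zmap(series: BoldSeries, nuisance, gray_mask, cfg: PipelineConfig) -> VolumeMap:
    """One subject's smoothed DC z-map from the raw series.

    DC is computed on the unsmoothed preprocessed series; the z-map is
    smoothed afterwards (binary-DC convention).
    """
    clean = preproc.preprocess(series, n_drop=cfg.n_drop, nuisance=nuisance,
                               band=(cfg.band_low_hz, cfg.band_high_hz), fwhm_mm=0.0)
    dc = connectome.degree_centrality(clean, gray_mask, cfg.r_threshold,
                                      use_absolute=cfg.use_absolute_r,
                                      weighted=cfg.weighted_dc)
    dcz = connectome.zscore_map(dc, gray_mask)
    smoothed = preproc.smooth_gaussian(np.nan_to_num(dcz.data, nan=0.0),
                                       cfg.fwhm_mm, dcz.affine)
    out = np.full(dcz.grid_shape, np.nan)
    out[gray_mask] = smoothed[gray_mask]
    return VolumeMap(data=out, affine=dcz.affine, kind="dc_z")


def cohort_dc_zmaps(cohort: Cohort, cfg: PipelineConfig) -> list:
    return [subject_dc_zmap(s, n, cohort.gray_mask, cfg)
            for s, n in zip(cohort.series, cohort.nuisance)]


def dc_group_analysis(dcz_maps, table: pd.DataFrame, cfg: PipelineConfig, rng=None):
    """Voxel-wise GLM + cluster-level permutation FDR on DC z-maps."""
    design = groupstats.make_design(table)
    return groupstats.cluster_fdr(
        dcz_maps, design, voxel_p=cfg.voxel_p, q=cfg.cluster_q,
        connectivity=cfg.connectivity, n_permutations=cfg.n_permutations,
        rng=rng if rng is not None else cfg.rng_seed)


def seeds_from_report(labels: np.ndarray, report: groupstats.ClusterReport) -> list:
    """Significant clusters as FC seeds (``dc_cluster_<id>`` labels)."""
    seeds = []
    for c in report.significant:
        mask = labels == c["id"]
        seeds.append(connectome.SeedSpec(mask=mask, label=f"dc_cluster_{c['id']}",
                                         source=f"cluster_id:{c['id']}"))
    return seeds


def run_on_cohort(cohort: Cohort, cfg: PipelineConfig, out_dir=None, rng=None) -> dict:
    """Run the whole chain on an in-memory cohort; optionally write outputs.

    Returns a result bundle dict; see keys in the implementation.  With
    ``out_dir`` set, every declared output (maps, cluster reports, ROI and
    correlation tables, MVPA artifacts, provenance) is written to disk.
    """
    t0 = time.time()
    rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for key, val in sorted(cfg.to_dict().items()):   # no silent defaults
        log.info("config %s = %r", key, val)

    # --- preprocessing + DC ---------------------------------------------
    stage = time.time()
    dcz = cohort_dc_zmaps(cohort, cfg)
    log.info("stage dc_maps done in %.1fs", time.time() - stage)
    if out is not None:
        for sid, m in zip(cohort.table["subject_id"], dcz):
            ndio.write_map(out / f"{sid}_dcz.nii.gz", m)

    # --- DC group statistics --------------------------------------------
    stage = time.time()
    t_map, labels, report = dc_group_analysis(dcz, cohort.table, cfg,
                                              rng=rng.integers(2**31))
    log.info("stage dc_groupstats done in %.1fs (%d clusters, %d significant)",
             time.time() - stage, len(report.clusters), len(report.significant))
    if out is not None:
        ndio.write_map(out / "dc_tmap.nii.gz", t_map)
        ndio.write_volume(out / "dc_clusters.nii.gz", labels.astype(float), t_map.affine)
        report.to_frame().to_csv(out / "dc_clusters.tsv", sep="\t", index=False)
        (out / "dc_clusters.json").write_text(
            json.dumps({"df": report.df, "forming_threshold": report.forming_threshold,
                        "connectivity": report.connectivity,
                        "n_permutations": report.n_permutations,
                        "clusters": [{k: v for k, v in c.items()} for c in report.clusters]},
                       indent=2, default=str) + "\n")

    # --- seed-based FC on significant DC clusters -----------------------
    seeds = seeds_from_report(labels, report)
    fc_results = {}
    if not seeds:
        log.info("stage seed_fc skipped: no significant DC clusters")
    for seed in seeds:
        stage = time.time()
        fc_maps = []
        for series, nuis in zip(cohort.series, cohort.nuisance):
            clean = preproc.preprocess(series, n_drop=cfg.n_drop, nuisance=nuis,
                                       band=(cfg.band_low_hz, cfg.band_high_hz),
                                       fwhm_mm=cfg.fwhm_mm)  # FC inputs are smoothed
            fc_maps.append(connectome.seed_fc_map(clean, seed, cohort.gray_mask))
        fc_t, fc_labels, fc_report = dc_group_analysis(fc_maps, cohort.table, cfg,
                                                       rng=rng.integers(2**31))
        fc_results[seed.label] = {"maps": fc_maps, "t_map": fc_t,
                                  "labels": fc_labels, "report": fc_report}
        log.info("stage seed_fc[%s] done in %.1fs", seed.label, time.time() - stage)
        if out is not None:
            for sid, m in zip(cohort.table["subject_id"], fc_maps):
                ndio.write_map(out / f"{sid}_{seed.label}_fcz.nii.gz", m)
            ndio.write_map(out / f"fc_{seed.label}_tmap.nii.gz", fc_t)
            fc_report.to_frame().to_csv(out / f"fc_{seed.label}_clusters.tsv",
                                        sep="\t", index=False)

    # --- clinical correlations ------------------------------------------
    corr_table = None
    if report.clusters:
        roi = assoc_mod.extract_cluster_means(dcz, labels, table=cohort.table)
        corr_table = assoc_mod.correlate_clusters(
            roi, patient_only=cfg.patient_only_correlations,
            bh_correction=cfg.assoc_bh_correction)
        if out is not None:
            roi.to_csv(out / "dc_cluster_means.tsv", sep="\t", index=False)
            corr_table.to_csv(out / "dc_clinical_correlations.tsv", sep="\t", index=False)

    # --- MVPA ------------------------------------------------------------
    stage = time.time()
    features = mvpa_mod.build_feature_matrix(
        dcz, cohort.gray_mask, cohort.table["group"],
        subject_ids=cohort.table["subject_id"])
    cv = mvpa_mod.loocv_classify(features, cfg.svm_C, pair_folds=cfg.pair_folds,
                                 standardize=cfg.standardize_features)
    perm = mvpa_mod.permutation_test(features, cfg.n_permutations,
                                     rng=rng.integers(2**31), svm_c=cfg.svm_C,
                                     pair_folds=cfg.pair_folds, observed=cv)
    wmap = mvpa_mod.weight_map(features, cfg.top_fraction, cfg.svm_C)
    log.info("stage mvpa done in %.1fs (accuracy %.2f%%)", time.time() - stage, cv.accuracy)
    if out is not None:
        metrics = {**cv.metrics(), "p": perm["p"], "n_permutations": cfg.n_permutations,
                   "n_folds": cv.n_folds}
        (out / "mvpa_metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
        pd.DataFrame({"subject_id": cohort.table["subject_id"],
                      "true": cv.true_labels, "predicted": cv.predictions,
                      "decision_value": cv.decision_values}).to_csv(
            out / "mvpa_predictions.tsv", sep="\t", index=False)
        _write_roc_points(out / "mvpa_roc.tsv", cv.decision_values, cv.true_labels)
        ndio.write_map(out / "mvpa_weights.nii.gz", wmap.to_volume())
        ndio.write_volume(out / "mvpa_top_mask.nii.gz",
                          wmap.top_mask().astype(float), t_map.affine)

    # --- provenance -------------------------------------------------------
    if out is not None:
        ndio.write_provenance(out / "provenance.json", stage="run",
                              config_dict=cfg.to_dict(), seed=cfg.rng_seed,
                              extra={"n_subjects": len(cohort.series),
                                     "elapsed_seconds": round(time.time() - t0, 2)})

    return {"dcz_maps": dcz, "t_map": t_map, "labels": labels, "report": report,
            "fc": fc_results, "correlations": corr_table, "cv": cv,
            "permutation": perm, "weight_map": wmap,
            "elapsed_seconds": time.time() - t0}


def _write_roc_points(path, decision_values, labels) -> None:
    order = np.argsort(-np.asarray(decision_values))
    y = np.asarray(labels)[order]
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    tpr = np.concatenate([[0], np.cumsum(y == 1) / n_pos])
    fpr = np.concatenate([[0], np.cumsum(y == 0) / n_neg])
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(path, sep="\t", index=False)


def load_cohort_from_manifest(phenotype_path, gray_mask_path, tr: float) -> Cohort:
    """Rebuild a Cohort bundle from on-disk files (CLI entry path)."""
    table = ndio.read_phenotype_table(phenotype_path)
    if "image_path" not in table.columns:
        raise InputError("phenotype table needs an image_path column")
    gray, affine = ndio.read_mask(gray_mask_path)
    series, nuisance = [], []
    base = Path(phenotype_path).parent
    for _, row in table.iterrows():
        p = Path(row["image_path"])
        if not p.is_absolute():
            p = base / p
        series.append(ndio.read_bold(p, tr))
        if "nuisance_path" in table.columns and isinstance(row["nuisance_path"], str):
            np_path = Path(row["nuisance_path"])
            if not np_path.is_absolute():
                np_path = base / np_path
            nuisance.append(ndio.read_nuisance(np_path))
        else:
            nuisance.append(None)
    hub = np.zeros(gray.shape, dtype=bool)
    from .synthgen import CohortSpec
    spec = CohortSpec(n_per_group=max(1, int((table["group"] == "patient").sum())),
                      grid_shape=gray.shape, n_timepoints=series[0].n_timepoints,
                      tr=tr)
    return Cohort(series=series, nuisance=nuisance, table=table, gray_mask=gray,
                  hub_mask=hub, affine=affine, spec=spec)
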