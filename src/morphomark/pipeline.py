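"""End-to-end orchestration: simulate -> mask -> GLM -> searchlight ->
region evaluation -> biomarker selection -> severity correlation.

One global seed deterministically derives a per-stage seed (hash of
stage name + seed), so any stage can be rerun in isolation and
reproduce its artifacts exactly.  Every stage parameter is serialized
into the report for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from ._utils import derive_seed
from .exceptions import PipelineConfigError
from .glm import fit_voxelwise_glm, label_clusters_with_atlas, threshold_stat_map
from .regioneval import (SearchSpace, extract_region_features, multisite_evaluate,
                         nested_cv_evaluate, permutation_test, select_biomarkers)
from .searchlight import (SphereSpec, clusters_to_region_features,
                          searchlight_accuracy_map, threshold_accuracy_map)
from .severity import correlate_region_scores
from .simulate import (AtlasParcellation, CohortDesign, make_atlas, read_atlas,
                       simulate_cohort, simulate_scores, write_atlas)
from .volio import (BrainMask, Cohort, build_group_mask, read_cohort,
                    write_cohort, write_mask)

log = logging.getLogger("morphomark")

ALL_STAGES = ("simulate", "mask", "vbm", "searchlight", "evaluate",
              "select", "correlate")


@dataclass
class PipelineConfig:
    out_dir: str = "morphomark_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulate (ignored when volumes/phenotype paths are given)
    simulate_params: dict = field(default_factory=dict)
    n_atlas_regions: int = 10
    score_target_r: float = -0.4
    score_name: str = "ados_comm"
    # existing-data inputs
    volumes_dir: str | None = None
    phenotype_path: str | None = None
    atlas_path: str | None = None
    atlas_labels_path: str | None = None
    # mask / glm
    abs_threshold: float = 0.1
    covariates: tuple[str, ...] = ("age", "sex", "tiv")
    p_crit: float = 0.001
    glm_extent: int = 50
    connectivity: int = 26
    # searchlight
    sphere_radius_vox: float = 3.0
    n_folds: int = 5
    n_repeats_map: int = 5
    variance_frac: float = 0.8
    svm_C: float = 1.0
    acc_threshold: float = 0.70
    min_cluster: int = 50
    min_region_overlap: int = 10
    # region evaluation
    families: tuple[str, ...] = ("pca_ridge", "pca_svm", "bagging")
    outer_folds: int = 5
    n_repeats_cv: int = 10
    budget: int = 30
    n_perm: int = 5000
    gap_threshold: float = 20.0
    alpha: float = 0.05
    train_site: str | None = None   # enables multisite evaluation

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise PipelineConfigError(f"unknown stages: {sorted(bad)}")
        if "simulate" not in self.stages:
            for name in ("volumes_dir", "phenotype_path", "atlas_path",
                         "atlas_labels_path"):
                if getattr(self, name) is None:
                    raise PipelineConfigError(
                        f"simulation disabled but {name} is not set")

    def provenance(self) -> dict:
        out = dataclasses.asdict(self)
        for k, v in out.items():
            if isinstance(v, tuple):
                out[k] = list(v)
        return out


def _setup_logging(out_dir: Path) -> None:
    if log.handlers:
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(out_dir / "pipeline.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the report dict.

    The report (also written to ``<out_dir>/report.json``) aggregates
    cluster tables, evaluation tables, biomarker decisions, severity
    correlations, per-stage seeds and wall-clock times.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)

    report: dict[str, Any] = {"config": config.provenance(), "stages": {}}
    seeds = {stage: derive_seed(config.seed, "stage", stage) for stage in ALL_STAGES}
    report["stage_seeds"] = seeds

    cohort: Cohort | None = None
    atlas: AtlasParcellation | None = None
    mask: BrainMask | None = None
    region_set = None
    eval_results: list = []
    perm_results: list = []
    decisions: list = []

    def stage(name: str):
        return name in config.stages

    def record(name: str, started: float, **payload) -> None:
        report["stages"][name] = {"seed": seeds[name],
                                  "elapsed_s": round(time.time() - started, 3),
                                  **payload}
        log.info("stage %s done in %.1fs", name, time.time() - started)

    # --- simulate or load -------------------------------------------------
    t0 = time.time()
    if stage("simulate"):
        params = dict(config.simulate_params)
        params.setdefault("seed", seeds["simulate"])
        design = CohortDesign(**params)
        atlas = make_atlas(design.grid_shape, config.n_atlas_regions,
                           seed=derive_seed(seeds["simulate"], "atlas"),
                           voxel_size_mm=design.voxel_size_mm)
        cohort = simulate_cohort(design, atlas)
        score_region = (design.effect_regions[0] if design.effect_regions
                        else atlas.label_values[0])
        cohort = simulate_scores(cohort, score_region, atlas,
                                 config.score_target_r, config.score_name,
                                 seed=derive_seed(seeds["simulate"], "scores"))
        write_cohort(cohort, out_dir / "cohort", round_scores=True)
        write_atlas(atlas, out_dir / "atlas.nii.gz", out_dir / "atlas_labels.tsv")
        record("simulate", t0, n_subjects=cohort.n_subjects,
               grid_shape=list(cohort.grid_shape),
               effect_regions=list(design.effect_regions))
    else:
        cohort = read_cohort(config.volumes_dir, config.phenotype_path)
        atlas = read_atlas(config.atlas_path, config.atlas_labels_path)
        record("simulate", t0, loaded=True, n_subjects=cohort.n_subjects)

    # --- mask -------------------------------------------------------------
    if stage("mask"):
        t0 = time.time()
        mask = build_group_mask(cohort, config.abs_threshold)
        write_mask(mask, cohort.affine, out_dir / "mask.nii.gz")
        record("mask", t0, n_voxels=mask.n_voxels)
    else:
        mask = build_group_mask(cohort, config.abs_threshold)

    # --- vbm glm ----------------------------------------------------------
    if stage("vbm"):
        t0 = time.time()
        diff_map = fit_voxelwise_glm(cohort, config.covariates, mask)
        glm_clusters = threshold_stat_map(diff_map, config.p_crit,
                                          config.glm_extent, config.connectivity)
        table = label_clusters_with_atlas(glm_clusters, atlas, cohort.affine)
        table.to_csv(out_dir / "vbm_clusters.tsv", sep="\t", index=False)
        record("vbm", t0, df=diff_map.df, n_clusters=len(glm_clusters),
               total_voxels=glm_clusters.total_voxels())

    # --- searchlight ------------------------------------------------------
    if stage("searchlight"):
        t0 = time.time()
        amap = searchlight_accuracy_map(
            cohort, mask, SphereSpec(config.sphere_radius_vox),
            n_folds=config.n_folds, n_repeats=config.n_repeats_map,
            variance_frac=config.variance_frac, C=config.svm_C,
            seed=seeds["searchlight"], keep_fold_details=False)
        sl_clusters = threshold_accuracy_map(amap, config.acc_threshold,
                                             config.min_cluster,
                                             config.connectivity)
        region_set = clusters_to_region_features(sl_clusters, atlas,
                                                 config.min_region_overlap)
        region_set.to_json(out_dir / "regions.json")
        table = label_clusters_with_atlas(sl_clusters, atlas, cohort.affine)
        table.to_csv(out_dir / "searchlight_clusters.tsv", sep="\t", index=False)
        record("searchlight", t0, n_clusters=len(sl_clusters),
               n_regions=len(region_set.regions),
               mean_accuracy=float(amap.accuracy[mask.include].mean()))

    # --- region evaluation ------------------------------------------------
    if stage("evaluate") and region_set is not None and region_set.regions:
        t0 = time.time()
        space = SearchSpace()
        sites = cohort.phenotype["site"].unique().tolist()
        train_site = config.train_site
        multisite = train_site is not None and len(sites) > 1
        if multisite:
            train_cohort = cohort.subset(
                (cohort.phenotype["site"] == train_site).to_numpy())
            test_cohorts = [cohort.subset((cohort.phenotype["site"] == s).to_numpy())
                            for s in sites if s != train_site]
        else:
            train_cohort, test_cohorts = cohort, []

        rows = []
        for region in sorted(region_set.regions):
            X, y = extract_region_features(train_cohort, region_set, region)
            for family in config.families:
                ev = nested_cv_evaluate(
                    X, y, family, space, outer_folds=config.outer_folds,
                    n_repeats=config.n_repeats_cv, budget=config.budget,
                    seed=derive_seed(seeds["evaluate"], region, family),
                    region=region)
                eval_results.append(ev)
                config_for_perm = ev.chosen_configs[0]
                perm = permutation_test(
                    X, y, family, config_for_perm, n_perm=config.n_perm,
                    cv_folds=config.n_folds,
                    seed=derive_seed(seeds["evaluate"], "perm", region, family),
                    region=region)
                perm_results.append(perm)
                rows.append({"region": region, "family": family,
                             "setting": "nested_cv", "acc": ev.acc,
                             "sen": ev.sen, "spe": ev.spe, "auc": ev.auc,
                             "p_perm": perm.p})
                if multisite:
                    mev = multisite_evaluate(
                        train_cohort, test_cohorts, region_set, region, family,
                        space, budget=config.budget,
                        seed=derive_seed(seeds["evaluate"], "ms", region, family))
                    eval_results.append(mev)
                    rows.append({"region": region, "family": family,
                                 "setting": "multisite", "acc": mev.acc,
                                 "sen": mev.sen, "spe": mev.spe,
                                 "auc": mev.auc, "p_perm": perm.p})
        import pandas as pd
        pd.DataFrame(rows).to_csv(out_dir / "evaluation.tsv", sep="\t", index=False)
        record("evaluate", t0, n_regions=len(region_set.regions),
               table=rows)

    # --- biomarker selection ----------------------------------------------
    if stage("select") and eval_results:
        t0 = time.time()
        decisions = select_biomarkers(eval_results, perm_results,
                                      config.gap_threshold, config.alpha)
        payload = [dataclasses.asdict(d) for d in decisions]
        (out_dir / "biomarkers.json").write_text(json.dumps(payload, indent=2))
        record("select", t0, decisions=payload)

    # --- severity correlation ----------------------------------------------
    if stage("correlate") and region_set is not None:
        t0 = time.time()
        corr_rows = []
        score_cols = [c for c in cohort.phenotype.columns
                      if c not in ("subject_id", "site", "group", "age", "sex", "tiv")]
        included = {d.region for d in decisions if d.included} or set(region_set.regions)
        for region in sorted(included):
            for score in score_cols:
                try:
                    res = correlate_region_scores(
                        cohort, region_set.regions[region], score, region=region)
                except Exception as exc:
                    log.warning("correlation %s/%s skipped: %s", region, score, exc)
                    continue
                corr_rows.append(dataclasses.asdict(res))
        import pandas as pd
        pd.DataFrame(corr_rows).to_csv(out_dir / "correlations.tsv",
                                       sep="\t", index=False)
        record("correlate", t0, correlations=corr_rows)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
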