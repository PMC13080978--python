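"""End-to-end orchestration of the post-docking analysis pipeline.

Stages: ingest and bookkeeping validation -> conformational-ensemble
curation per site (eRMSD QT clustering + diverse-centroid retention) ->
pose clustering per site (symmetry-corrected scaffold RMSD, QT at 5 Å,
population-coverage selection) -> interaction fingerprints -> per-site PCA
refit on the retained poses -> per-cluster affinity regression and cluster
ranking.  Stages communicate through files in the output directory so any
stage can be rerun or swapped; a full run is deterministic for a fixed
configuration and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering as cl
from . import io_formats as iof
from . import pose_geometry as pg
from . import rna_metrics as rm
from . import synthetic_data as sd
from . import trends as tr
from .interactions import FingerprintConfig, fingerprint_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    rna_path: str
    poses_path: str
    affinities_path: str
    manifest_path: str
    scaffold_path: str
    site_residues: dict[str, list[int]]
    out_dir: str
    ensemble_qt_threshold: float = 0.7
    retain_cutoff: float = 0.7
    pose_qt_threshold: float = 5.0
    coverage: float = 0.5
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    regression_scale: str = "log10_cd50"
    include_out_of_range: bool = False
    min_poses: int = 3
    reference_model: int = 0

    def __post_init__(self) -> None:
        if min(self.ensemble_qt_threshold, self.pose_qt_threshold,
               self.retain_cutoff) <= 0:
            raise ValueError("thresholds must be positive")
        if not self.site_residues:
            raise ValueError("at least one site residue list required")


@dataclass
class RunReport:
    n_models: int = 0
    n_poses: int = 0
    ensemble: dict = field(default_factory=dict)     # per site
    pose_clusters: dict = field(default_factory=dict)
    trends: list = field(default_factory=list)       # ranked dicts
    validation_warnings: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    @property
    def top_trend(self) -> dict | None:
        return self.trends[0] if self.trends else None


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _curate_site(models, site, threshold, retain_cutoff):
    mat = rm.ermsd_matrix(models, residue_selection=site)
    dm = cl.DistanceMatrix(mat, metric_tag="ermsd")
    clustering = cl.qt_cluster(dm, threshold)
    cents = cl.extract_centroids(clustering, dm)
    retained = cl.select_diverse_centroids(cents, dm, retain_cutoff)
    return dm, clustering, retained


def curate_ensemble(
    model_set: iof.RnaModelSet,
    site_residues: Mapping[str, Sequence[int]],
    qt_threshold: float = 0.7,
    retain_cutoff: float = 0.7,
) -> dict:
    """Site-wise eRMSD QT clustering + diverse-centroid retention.

    Returns per site: the eRMSD matrix, the clustering, the centroid set
    and the retained model indices (the curated docking ensemble).
    """
    out = {}
    for site_tag, site in site_residues.items():
        dm, clustering, retained = _curate_site(
            model_set.models, site, qt_threshold, retain_cutoff)
        out[site_tag] = {
            "ermsd_matrix": dm,
            "clustering": clustering,
            "centroids": retained,
            "retained_models": retained.retained_indices(),
        }
    return out


def analyze_poses(
    poses: Sequence[iof.LigandPose],
    rna_for_pose,
    affinities: iof.AffinityTable,
    pose_qt_threshold: float = 5.0,
    coverage: float = 0.5,
    fingerprint_config: FingerprintConfig | None = None,
    regression_scale: str = "log10_cd50",
    include_out_of_range: bool = False,
    min_poses: int = 3,
) -> dict:
    """Pose clustering, fingerprints and affinity trends for the poses of
    ONE site (assumes all poses share the site tag and scaffold layout).

    Returns the clustering, the retained cluster ids, the fingerprint rows,
    the refit PCA model, per-cluster trend results and the pose bookkeeping
    needed to join everything downstream.
    """
    if not poses:
        raise ValueError("no poses")
    if fingerprint_config is None:
        fingerprint_config = FingerprintConfig()
    group = pg.scaffold_automorphisms(poses[0].scaffold_bonds(),
                                      poses[0].scaffold_elements())
    pdm = pg.pose_distance_matrix(poses, group)
    clustering = cl.qt_cluster(pdm.matrix, pose_qt_threshold)
    retained_ids = cl.select_top_clusters(clustering, coverage)
    retained_set = set(retained_ids)
    retained_mask = np.array([clustering.labels[i] in retained_set
                              for i in range(len(poses))])
    coverage_frac = float(retained_mask.mean())

    fp_rows = fingerprint_matrix(poses, rna_for_pose, fingerprint_config)
    sub = fp_rows[retained_mask]
    pca = tr.fit_pca(sub.astype(float), n_components=min(10, sub.shape[0] - 1))
    sub_labels = [int(clustering.labels[i]) for i in range(len(poses))
                  if retained_mask[i]]
    sub_ligands = [poses[i].ligand_id for i in range(len(poses))
                   if retained_mask[i]]
    means = tr.cluster_mean_pc(pca.scores, sub_labels, sub_ligands,
                               min_poses=min_poses)
    site_tag = poses[0].site_tag
    results = []
    for cid in retained_ids:
        if cid not in means:
            continue
        try:
            results.append(tr.affinity_regression(
                means[cid], affinities, scale=regression_scale,
                include_out_of_range=include_out_of_range,
                cluster_id=cid, site_tag=site_tag))
        except ValueError as exc:
            logger.warning("site %s cluster %d: regression skipped (%s)",
                           site_tag, cid, exc)
    return {
        "symmetry_group": group,
        "distance_matrix": pdm,
        "clustering": clustering,
        "retained_clusters": retained_ids,
        "retained_mask": retained_mask,
        "coverage_fraction": coverage_frac,
        "fingerprints": fp_rows,
        "pca": pca,
        "cluster_ligand_means": means,
        "trend_results": results,
    }


def run_pipeline_objects(
    model_set: iof.RnaModelSet,
    poses: Sequence[iof.LigandPose],
    affinities: iof.AffinityTable,
    manifest: iof.DockingManifest | None,
    site_residues: Mapping[str, Sequence[int]],
    config: PipelineConfig | None = None,
    **overrides,
) -> tuple[RunReport, dict]:
    """The full pipeline on in-memory objects (the file-based
    :func:`run_pipeline` wraps this).  Returns (report, stage outputs)."""
    params = dict(
        ensemble_qt_threshold=0.7, retain_cutoff=0.7, pose_qt_threshold=5.0,
        coverage=0.5, fingerprint=FingerprintConfig(),
        regression_scale="log10_cd50", include_out_of_range=False,
        min_poses=3, reference_model=0)
    if config is not None:
        for k in params:
            params[k] = getattr(config, k)
    params.update(overrides)

    report = RunReport(n_models=len(model_set), n_poses=len(poses))
    if manifest is not None:
        report.validation_warnings = iof.validate_pose_counts(poses, manifest)

    try:
        curated = curate_ensemble(model_set, site_residues,
                                  params["ensemble_qt_threshold"],
                                  params["retain_cutoff"])
    except Exception as exc:
        raise StageError("ensemble_curation", str(exc)) from exc
    for site_tag, res in curated.items():
        report.ensemble[site_tag] = {
            "n_clusters": len(res["clustering"].clusters),
            "cluster_sizes": res["clustering"].sizes,
            "n_retained_centroids": len(res["retained_models"]),
            "retained_models": res["retained_models"],
        }

    reference = model_set[params["reference_model"]]
    by_site: dict[str, list[iof.LigandPose]] = {}
    for p in poses:
        by_site.setdefault(p.site_tag, []).append(p)
    if not by_site:
        raise StageError("pose_clustering", "no poses ingested")

    outputs = {"curated": curated, "sites": {}}
    all_results = []
    for site_tag, site_poses in sorted(by_site.items()):
        try:
            res = analyze_poses(
                site_poses, reference, affinities,
                pose_qt_threshold=params["pose_qt_threshold"],
                coverage=params["coverage"],
                fingerprint_config=params["fingerprint"],
                regression_scale=params["regression_scale"],
                include_out_of_range=params["include_out_of_range"],
                min_poses=params["min_poses"])
        except Exception as exc:
            raise StageError(f"pose_analysis[{site_tag}]", str(exc)) from exc
        outputs["sites"][site_tag] = res
        report.pose_clusters[site_tag] = {
            "n_poses": len(site_poses),
            "n_clusters": len(res["clustering"].clusters),
            "cluster_sizes": res["clustering"].sizes,
            "retained_clusters": res["retained_clusters"],
            "coverage_fraction": res["coverage_fraction"],
            "pc_variance_retained": res["pca"].explained_variance_ratio[:2].tolist(),
        }
        all_results.extend(res["trend_results"])

    if all_results:
        ranked = tr.rank_clusters(all_results)
        report.trends = [
            {"site_tag": r.site_tag, "cluster_id": r.cluster_id,
             "r_squared": r.r_squared, "slope": r.slope,
             "intercept": r.intercept, "n_ligands": r.n_ligands,
             "affinity_scale": r.affinity_scale}
            for r in ranked]
    return report, outputs


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline from files, persisting all intermediates.

    Aborts with :class:`StageError` naming the failing stage.  Rerunning
    with identical config and inputs reproduces identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        model_set = iof.read_rna_models(config.rna_path)
        scaffold = iof.read_scaffold_map(config.scaffold_path)
        poses = iof.read_ligand_poses(config.poses_path, scaffold)
        affinities = iof.read_affinities(config.affinities_path)
        manifest = iof.read_manifest(config.manifest_path)
    except Exception as exc:
        raise StageError("ingest", str(exc)) from exc

    report, outputs = run_pipeline_objects(
        model_set, poses, affinities, manifest, config.site_residues, config)
    report.config = {
        k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
        for k, v in dataclasses.asdict(config).items()}

    # persist intermediates
    for site_tag, res in outputs["curated"].items():
        np.savetxt(out_dir / f"ermsd_matrix_{site_tag}.csv",
                   res["ermsd_matrix"].values, delimiter=",")
        rows = []
        for cid, members in enumerate(res["clustering"].clusters):
            med = res["centroids"].medoids[cid]
            rows.append({"cluster_id": cid, "size": len(members),
                         "medoid_model": med,
                         "retained": res["centroids"].retained[cid]})
        pd.DataFrame(rows).to_csv(
            out_dir / f"ensemble_clusters_{site_tag}.csv", index=False)
        retained_models = [model_set[i] for i in res["retained_models"]]
        if retained_models:
            iof.write_rna_models(iof.RnaModelSet(retained_models),
                                 out_dir / f"ensemble_{site_tag}.pdb")
    for site_tag, res in outputs["sites"].items():
        site_poses = [p for p in poses if p.site_tag == site_tag]
        pd.DataFrame({
            "pose_id": [p.pose_id for p in site_poses],
            "ligand_id": [p.ligand_id for p in site_poses],
            "cluster": res["clustering"].labels,
            "retained": res["retained_mask"],
        }).to_csv(out_dir / f"pose_clusters_{site_tag}.csv", index=False)
        np.savetxt(out_dir / f"fingerprints_{site_tag}.csv",
                   res["fingerprints"], delimiter=",", fmt="%d")
    if report.trends:
        pd.DataFrame(report.trends).to_csv(out_dir / "trend_table.csv",
                                           index=False)
    (out_dir / "report.json").write_text(report.to_json())
    return report


def validate_counts(report: RunReport, manifest: iof.DockingManifest) -> dict:
    """Compare the report's ingested pose counts with the docking design."""
    expected = iof.expected_pose_counts(manifest)
    per_ligand_expected = {lig: expected[lig] for lig in manifest.ligand_ids}
    total_expected = sum(per_ligand_expected.values())
    return {
        "expected_per_ligand": per_ligand_expected,
        "expected_total": total_expected,
        "ingested_total": report.n_poses,
        "discrepancy": report.n_poses - total_expected,
        "warnings": list(report.validation_warnings),
    }


# ---------------------------------------------------------------------------
# Synthetic workspace
# ---------------------------------------------------------------------------

def generate_scenario_workspace(
    out_dir: str | Path,
    scenario: sd.PlantedScenario | None = None,
    ensemble_spec: sd.EnsembleSpec | None = None,
) -> PipelineConfig:
    """Write a complete synthetic input set (models.pdb, poses.sdf,
    cd50.csv, scaffold.yaml, manifest.yaml, sites.yaml, truth.json) and
    return a ready-to-run :class:`PipelineConfig`."""
    if scenario is None:
        scenario = sd.PlantedScenario()
    if ensemble_spec is None:
        ensemble_spec = sd.EnsembleSpec(seed=scenario.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    helix = sd.make_idealized_helix(ensemble_spec.n_residues,
                                    seed=ensemble_spec.seed)
    ref = helix[0]
    ensemble = sd.perturb_ensemble(ref, dataclasses.replace(
        ensemble_spec, n_models=ensemble_spec.n_models - 1))
    models = iof.RnaModelSet(
        [ref] + [iof.RnaModel(m.model_id + 1, m.residues)
                 for m in ensemble.models])
    series, scaffold_map = sd.make_congeneric_series(
        scenario.n_ligands, seed=scenario.seed)
    poses, affinities, truth = sd.plant_pose_set(ref, series, scenario)
    manifest = sd.scenario_manifest(scenario, [t.ligand_id for t in series])

    iof.write_rna_models(models, out / "models.pdb")
    iof.write_ligand_poses(poses, out / "poses.sdf")
    iof.write_affinities(affinities, out / "cd50.csv")
    iof.write_scaffold_map(scaffold_map, out / "scaffold.yaml")
    iof.write_manifest(manifest, out / "manifest.yaml")
    (out / "truth.json").write_text(json.dumps(truth, indent=1))

    n_res = ensemble_spec.n_residues
    site = list(range(max(1, n_res // 3), min(n_res, 2 * n_res // 3) + 1))
    (out / "sites.yaml").write_text(yaml.safe_dump({"S1": site}))

    return PipelineConfig(
        rna_path=str(out / "models.pdb"),
        poses_path=str(out / "poses.sdf"),
        affinities_path=str(out / "cd50.csv"),
        manifest_path=str(out / "manifest.yaml"),
        scaffold_path=str(out / "scaffold.yaml"),
        site_residues={"S1": site},
        out_dir=str(out / "work"),
    )
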