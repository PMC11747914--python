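"""Stage orchestration: simulate -> harmonize -> graphs -> similarity ->
fuse -> embed/cluster -> post-hoc, with cached stage outputs, resume support
and a run manifest recording configuration, seeds and output checksums."""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .assoc import KernelParams, build_participant_graphs, graphs_to_long
from .config import CohortConfig, PipelineConfig
from .embed import cluster_sweep, feature_matrix, labels_frame
from .fusion import snf_fuse
from .harmonize import harmonize_table
from .similarity import scaled_exponential_kernel, spectral_distance_matrix
from .stats import agreement_scores, edgewise_comparison, phenotype_battery
from .synthetic import generate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "harmonize", "graphs", "similarity", "fuse", "cluster", "posthoc")


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


class PipelineRun:
    """Filesystem-backed pipeline state for one output directory."""

    def __init__(self, outdir, cohort: CohortConfig | None = None, pipeline: PipelineConfig | None = None):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.cohort = cohort or CohortConfig()
        self.pipeline = pipeline or PipelineConfig()
        self.manifest: dict = {
            "cohort_config": self.cohort.to_dict(),
            "pipeline_config": self.pipeline.to_dict(),
            "version": _version(),
            "stages": {},
        }

    # --- stage output inventories -------------------------------------
    def _stage_outputs(self, stage: str) -> list[Path]:
        measures = list(self.cohort.regions_per_measure)
        out = self.outdir
        if stage == "simulate":
            return [out / f"{m}.csv" for m in measures] + [
                out / "covariates.csv", out / "phenotypes.csv", out / "truth.csv"]
        if stage == "harmonize":
            return [out / f"harmonized_{m}.csv" for m in measures]
        if stage == "graphs":
            return [out / f"graphs_{m}.csv" for m in measures]
        if stage == "similarity":
            return [out / f"distance_{m}.csv" for m in measures] + [
                out / f"similarity_{m}.csv" for m in measures]
        if stage == "fuse":
            return [out / "fused.csv"]
        if stage == "cluster":
            return [out / "labels.csv", out / "consensus.csv", out / "quality.csv"]
        if stage == "posthoc":
            return [out / "agreement.json", out / "phenotype_comparisons.csv"] + [
                out / f"edgewise_{m}.csv" for m in measures]
        raise ValueError(f"unknown stage {stage!r}")

    def _done(self, stage: str) -> bool:
        return all(p.exists() for p in self._stage_outputs(stage))

    def _record(self, stage: str) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {p.name: _checksum(p) for p in self._stage_outputs(stage)}
        }
        mio.write_json(self.outdir / "manifest.json", self.manifest)

    # --- stages --------------------------------------------------------
    def simulate(self) -> None:
        tables, covariates, phenotypes, truth = generate_cohort(self.cohort)
        write_cohort(self.outdir, tables, covariates, phenotypes, truth)

    def harmonize(self) -> None:
        cov = mio.read_covariates(self.outdir / "covariates.csv")
        for measure in self.cohort.regions_per_measure:
            table = mio.read_measure_table(self.outdir / f"{measure}.csv")
            corrected, _, _ = harmonize_table(
                table, cov["batch"].to_numpy(), cov["sex"].to_numpy(), cov["age"].to_numpy(),
                n_folds=self.pipeline.cv_folds, seed=self.pipeline.cv_seed,
            )
            mio.write_measure_table(self.outdir / f"harmonized_{measure}.csv", corrected)

    def graphs(self) -> None:
        sigmas = {}
        for measure in self.cohort.regions_per_measure:
            table = mio.read_measure_table(self.outdir / f"harmonized_{measure}.csv")
            params = None
            if self.pipeline.sigma_fixed is not None:
                params = KernelParams(sigma=self.pipeline.sigma_fixed, rule="fixed")
            stack, params = build_participant_graphs(table, params)
            sigmas[measure] = params.sigma
            mio.write_graphs(self.outdir / f"graphs_{measure}.csv",
                             graphs_to_long(stack, table.index, table.columns, measure))
        self.manifest["kernel_sigma"] = sigmas

    def similarity(self) -> None:
        for measure in self.cohort.regions_per_measure:
            stack, ids, _ = mio.long_to_stack(mio.read_graphs(self.outdir / f"graphs_{measure}.csv"))
            dist = spectral_distance_matrix(stack)
            mio.write_similarity_matrix(self.outdir / f"distance_{measure}.csv", dist, ids)
            K = min(self.pipeline.n_neighbors, len(ids) - 1)
            sim = scaled_exponential_kernel(dist, self.pipeline.mu, K)
            mio.write_similarity_matrix(self.outdir / f"similarity_{measure}.csv", sim, ids)

    def fuse(self) -> None:
        mats, ids = [], None
        for measure in self.cohort.regions_per_measure:
            m, ids = mio.read_similarity_matrix(self.outdir / f"similarity_{measure}.csv")
            mats.append(m)
        K = min(self.pipeline.n_neighbors, len(ids) - 1)
        fused = snf_fuse(mats, K=K, t_max=self.pipeline.snf_iterations)
        mio.write_similarity_matrix(self.outdir / "fused.csv", fused, ids)

    def cluster(self) -> None:
        distances, ids = [], None
        for measure in self.cohort.regions_per_measure:
            d, ids = mio.read_similarity_matrix(self.outdir / f"distance_{measure}.csv")
            distances.append(d)
        tables = {m: mio.read_measure_table(self.outdir / f"harmonized_{m}.csv")
                  for m in self.cohort.regions_per_measure}
        features, _ = feature_matrix(tables)
        pc = self.pipeline
        solutions, profile, selected, _ = cluster_sweep(
            distances, features,
            k_range=pc.k_range, budget_per_k=pc.consensus_budget,
            mu_grid=pc.mu_grid, k_neighbor_grid=pc.k_neighbor_grid,
            seeds=pc.consensus_seeds, epochs=pc.epochs,
            embed_dim=pc.embed_dim, hidden=pc.hidden_dim,
            snf_iterations=pc.snf_iterations, kmeans_n_init=pc.kmeans_n_init,
        )
        final = solutions[selected]
        labels_frame(ids, final.labels).to_csv(self.outdir / "labels.csv", index=False)
        mio.write_similarity_matrix(self.outdir / "consensus.csv", final.consensus, ids)
        pd.DataFrame({
            "k": profile.ks,
            "davies_bouldin": profile.davies_bouldin,
            "silhouette": profile.silhouette,
            "calinski_harabasz": profile.calinski_harabasz,
        }).to_csv(self.outdir / "quality.csv", index=False)
        self.manifest["selected_k"] = selected

    def posthoc(self) -> None:
        labels = pd.read_csv(self.outdir / "labels.csv")["cluster"].to_numpy()
        cov = mio.read_covariates(self.outdir / "covariates.csv")
        phen = pd.read_csv(self.outdir / "phenotypes.csv", index_col="participant_id")
        scores = {}
        if "diagnosis" in cov.columns:
            scores["vs_diagnosis"] = agreement_scores(cov["diagnosis"].to_numpy(), labels).to_dict()
        truth_path = self.outdir / "truth.csv"
        if truth_path.exists():
            truth = pd.read_csv(truth_path)
            scores["vs_truth"] = agreement_scores(truth["true_label"].to_numpy(), labels).to_dict()
        mio.write_json(self.outdir / "agreement.json", scores)
        phenotype_battery(phen, labels, q=self.pipeline.fdr_q).to_csv(
            self.outdir / "phenotype_comparisons.csv", index=False)
        if np.unique(labels).size >= 2:
            for measure in self.cohort.regions_per_measure:
                stack, _, regions = mio.long_to_stack(mio.read_graphs(self.outdir / f"graphs_{measure}.csv"))
                edgewise_comparison(stack, labels, regions, q=self.pipeline.fdr_q).to_csv(
                    self.outdir / f"edgewise_{measure}.csv", index=False)

    # --- driver ---------------------------------------------------------
    def run(self, stages=STAGES, resume: bool = True) -> dict:
        for stage in stages:
            if resume and self._done(stage):
                logger.info("stage %s: outputs present, skipping", stage)
                self._record(stage)
                continue
            logger.info("stage %s: running", stage)
            try:
                getattr(self, stage)()
            except Exception:
                mio.write_json(self.outdir / "manifest.json", self.manifest)
                logger.exception("stage %s failed", stage)
                raise
            self._record(stage)
        return self.manifest


def run_pipeline(cohort: CohortConfig | None = None, pipeline: PipelineConfig | None = None,
                 outdir="morphotype_run", stages=STAGES, resume: bool = True) -> dict:
    """Execute the pipeline stages in order, resuming from cached outputs."""
    return PipelineRun(outdir, cohort, pipeline).run(stages=stages, resume=resume)


def _version() -> str:
    from . import __version__

    return __version__
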