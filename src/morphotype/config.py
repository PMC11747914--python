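"""Configuration objects for the synthetic cohort and the analysis pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: Region counts of the atlases used at full scale: three cortical measures on
#: 76 AAL regions of interest and subcortical volumes on 95 MAGeT regions.
DEFAULT_REGIONS: Mapping[str, int] = {
    "cortical_thickness": 76,
    "surface_area": 76,
    "cortical_volume": 76,
    "subcortical_volume": 95,
}

MEASURES = tuple(DEFAULT_REGIONS)

DIAGNOSES = ("ASD", "ADHD", "TD")


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic structural-MRI cohort.

    The generator plants ``n_clusters_true`` subgroups that differ in regional
    means (``mean_shift``, in within-region SD units, on a fraction of
    regions) and in inter-regional correlation (``edge_effect`` added to a
    fraction of region-pair correlations), then layers scanner-batch
    location/scale effects, a polynomial age trend, and a linear sex effect on
    top — the nuisance structure the harmonization stage is supposed to
    remove.
    """

    n_participants: int = 565
    regions_per_measure: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    n_clusters_true: int = 2
    mean_shift: float = 1.0
    edge_effect: float = 0.2
    affected_region_fraction: float = 0.5
    affected_edge_fraction: float = 0.1
    n_batches: int = 4
    batch_additive_sd: float = 0.2
    batch_multiplicative_sd: float = 0.1
    age_range: tuple = (6.0, 18.0)
    age_poly_degree: int = 2
    age_effect_sd: float = 0.5
    sex_effect_sd: float = 0.5
    phenotype_effect: float = 1.0
    diagnosis_mode: str = "independent"
    diagnosis_mixing: float = 0.7
    base_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_clusters_true < 2:
            raise ValueError("n_clusters_true must be >= 2")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        for name, count in self.regions_per_measure.items():
            if count < 2:
                raise ValueError(f"regions_per_measure[{name!r}] must be >= 2")
        for name in ("affected_region_fraction", "affected_edge_fraction"):
            frac = getattr(self, name)
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.mean_shift < 0:
            raise ValueError("mean_shift must be >= 0")
        if not (0.0 <= self.edge_effect < 1.0):
            raise ValueError("edge_effect must lie in [0, 1)")
        if self.age_poly_degree not in (1, 2, 3):
            raise ValueError("age_poly_degree must be 1, 2 or 3")
        if not (0.0 < self.base_corr < 1.0):
            raise ValueError("base_corr must lie in (0, 1)")
        if self.diagnosis_mode not in ("independent", "enriched"):
            raise ValueError("diagnosis_mode must be 'independent' or 'enriched'")
        if not (0.0 <= self.diagnosis_mixing <= 1.0):
            raise ValueError("diagnosis_mixing must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class PipelineConfig:
    """Parameters of the analysis stages, with one explicit seed per stochastic stage."""

    # participant-similarity kernel (SNF-style locally scaled exponential)
    mu: float = 0.5
    n_neighbors: int = 20
    # SNF fusion
    snf_iterations: int = 20
    # graph-convolutional autoencoder
    embed_dim: int = 32
    hidden_dim: int = 64
    epochs: int = 150
    embed_seed: int = 0
    # consensus clustering
    k_range: tuple = (2, 3, 4, 5, 6)
    mu_grid: tuple = (0.3, 0.5, 0.8)
    k_neighbor_grid: tuple = (10, 20, 30)
    consensus_seeds: tuple = (0, 1, 2, 3)
    consensus_budget: int = 100
    kmeans_n_init: int = 10
    # bandwidth rule for the association-graph Gaussian kernel
    sigma_rule: str = "median"
    sigma_fixed: float | None = None
    # harmonization
    cv_folds: int = 5
    cv_seed: int = 0
    # post-hoc
    fdr_q: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("k_range", "mu_grid", "k_neighbor_grid", "consensus_seeds"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        for key in ("k_range", "mu_grid", "k_neighbor_grid", "consensus_seeds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path) -> tuple[CohortConfig, PipelineConfig]:
    """Read a YAML document with optional ``cohort:`` and ``pipeline:`` sections."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cohort = CohortConfig.from_dict(doc.get("cohort", {}))
    pipeline = PipelineConfig.from_dict(doc.get("pipeline", {}))
    return cohort, pipeline


def save_config(path, cohort: CohortConfig, pipeline: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"cohort": cohort.to_dict(), "pipeline": pipeline.to_dict()}, fh)
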