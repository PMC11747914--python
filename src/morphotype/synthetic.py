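"""Synthetic structural-MRI cohorts with known subgroup structure.

Every downstream stage of the pipeline is validated against cohorts produced
here, because the ground truth — which participants belong together, which
regions and region-pair correlations carry the subgroup signal, which scanner
batch each participant came from — is known exactly.  The tables mimic the
shape of morphometric feature tables (participants x regions, one table per
measure) without any attempt to mimic image-processing artefacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DIAGNOSES, CohortConfig

#: Plausible per-region location/scale per measure (mm, mm^2, mm^3).
_MEASURE_SCALES = {
    "cortical_thickness": (2.5, 0.2),
    "surface_area": (2500.0, 300.0),
    "cortical_volume": (6000.0, 800.0),
    "subcortical_volume": (1500.0, 250.0),
}
_DEFAULT_SCALE = (100.0, 15.0)

#: Phenotype instruments: (mean, SD, lower, upper, integer?, direction of the
#: planted shift in cluster 1).  Positive direction = higher in cluster 1.
_PHENOTYPES = {
    "SWAN_inattention": (8.0, 4.0, 0, 21, True, +1),
    "SWAN_hyperactivity": (7.0, 4.0, 0, 21, True, +1),
    "SCQ": (10.0, 6.0, 0, 39, True, 0),
    "ABAS": (85.0, 15.0, 40, 120, True, -1),
    "CBCL_internalizing": (58.0, 10.0, 30, 100, True, 0),
    "CBCL_externalizing": (56.0, 10.0, 30, 100, True, 0),
    "IQ": (100.0, 15.0, 40, 160, True, -1),
    "SSRT": (280.0, 50.0, 100.0, 600.0, False, 0),
}


@dataclass
class TrueStructure:
    """Ground truth of a generated cohort."""

    true_labels: np.ndarray
    affected_regions: dict
    affected_edges: dict
    batch_assignment: np.ndarray
    generating_parameters: CohortConfig
    age: np.ndarray = None
    sex: np.ndarray = None

    def to_frame(self, participant_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": participant_ids,
                "true_label": self.true_labels,
                "batch": self.batch_assignment,
            }
        )


def _nearest_pd_correlation(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() > eps:
        return mat
    vals = np.clip(vals, eps, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2


def make_covariance(
    n_regions: int,
    base_corr: float,
    edge_set=(),
    perturbation: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Uniform-correlation matrix with selected entries perturbed, repaired to PD.

    ``edge_set`` is an iterable of (i, j) index pairs whose correlation is set
    to ``base_corr + perturbation``; the result is symmetrized and, if the
    perturbation breaks positive definiteness, projected to the nearest
    positive-definite correlation matrix.  ``seed`` is accepted for interface
    uniformity; the construction is deterministic.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not (0.0 < base_corr < 1.0):
        raise ValueError("base_corr must lie in (0, 1)")
    target = base_corr + perturbation
    if not (-1.0 < target < 1.0):
        raise ValueError("perturbation drives correlations outside (-1, 1)")
    corr = np.full((n_regions, n_regions), base_corr)
    np.fill_diagonal(corr, 1.0)
    for i, j in edge_set:
        if i == j:
            raise ValueError("edge_set must contain off-diagonal pairs")
        corr[i, j] = corr[j, i] = target
    return _nearest_pd_correlation(corr)


def _sample_edges(n_regions: int, fraction: float, rng: np.random.Generator):
    pairs = [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]
    n_pick = max(1, int(round(fraction * len(pairs))))
    idx = rng.choice(len(pairs), size=n_pick, replace=False)
    return [pairs[i] for i in sorted(idx)]


def _cluster_shift_multipliers(k: int) -> np.ndarray:
    # evenly spaced so adjacent clusters differ by one mean_shift unit
    return np.arange(k, dtype=float) - (k - 1) / 2.0


def generate_measures(config: CohortConfig):
    """Draw the four regional measure tables plus the cohort's ground truth.

    Per cluster the regional values are multivariate normal with
    cluster-specific means and correlation; the scanner batch then rescales
    the residual noise (multiplicative delta) and shifts the location
    (additive gamma), and polynomial-age and linear-sex terms are added —
    i.e. exactly the location/scale model the harmonizer assumes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    k = config.n_clusters_true

    labels = rng.permutation(np.arange(n) % k)
    batches = rng.permutation(np.arange(n) % config.n_batches)
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    sex = rng.integers(0, 2, size=n)
    age_std = (age - age.mean()) / (np.ptp(age) / 2 + 1e-12)

    shift_mult = _cluster_shift_multipliers(k)
    tables: dict[str, pd.DataFrame] = {}
    affected_regions: dict[str, list] = {}
    affected_edges: dict[str, list] = {}
    ids = [f"P{i:04d}" for i in range(n)]

    for measure, n_regions in config.regions_per_measure.items():
        base_mean, base_sd = _MEASURE_SCALES.get(measure, _DEFAULT_SCALE)
        mu_r = base_mean + rng.normal(0.0, 0.1 * base_mean, size=n_regions)
        sd_r = base_sd * rng.uniform(0.8, 1.2, size=n_regions)

        n_affected = max(1, int(round(config.affected_region_fraction * n_regions)))
        regions_hit = sorted(rng.choice(n_regions, size=n_affected, replace=False).tolist())
        edges_hit = _sample_edges(n_regions, config.affected_edge_fraction, rng)
        affected_regions[measure] = regions_hit
        affected_edges[measure] = edges_hit

        # cluster-specific correlation: alternate the sign of the edge
        # perturbation across non-reference clusters so clusters differ
        corrs = []
        for c in range(k):
            if c == 0 or config.edge_effect == 0.0:
                corrs.append(make_covariance(n_regions, config.base_corr))
            else:
                sign = 1.0 if c % 2 == 1 else -1.0
                pert = sign * min(config.edge_effect, 0.99 - config.base_corr)
                corrs.append(make_covariance(n_regions, config.base_corr, edges_hit, pert))

        det = np.tile(mu_r, (n, 1))
        # per-region shift direction: subgroups differ in regional *profile*
        # (some regions up, some down), not in a global scaling — shifts along
        # the shared correlation direction would be invisible to the
        # association graphs
        direction = rng.choice([-1.0, 1.0], size=len(regions_hit))
        for c in range(k):
            shift = shift_mult[c] * config.mean_shift
            det[np.ix_(labels == c, regions_hit)] += shift * direction * sd_r[regions_hit]

        # age: shared polynomial basis, region-specific coefficients
        deg = config.age_poly_degree
        coeffs = rng.normal(0.0, config.age_effect_sd, size=(deg, n_regions)) * sd_r
        basis = np.vstack([age_std**j for j in range(1, deg + 1)])  # deg x n
        det += basis.T @ coeffs

        sex_coef = rng.normal(0.0, config.sex_effect_sd, size=n_regions) * sd_r
        det += np.outer(sex, sex_coef)

        # correlated noise per cluster
        eps = np.zeros((n, n_regions))
        for c in range(k):
            members = np.flatnonzero(labels == c)
            chol = np.linalg.cholesky(corrs[c])
            z = rng.standard_normal((members.size, n_regions))
            eps[members] = (z @ chol.T) * sd_r

        # batch location/scale effects on the residual noise
        gamma = rng.normal(0.0, config.batch_additive_sd, size=(config.n_batches, n_regions))
        delta = np.clip(
            rng.normal(1.0, config.batch_multiplicative_sd, size=(config.n_batches, n_regions)),
            0.2,
            None,
        )
        values = det + eps * delta[batches] + gamma[batches] * sd_r

        tables[measure] = pd.DataFrame(values, index=pd.Index(ids, name="participant_id"),
                                       columns=[f"{measure}_R{r:03d}" for r in range(n_regions)])

    truth = TrueStructure(
        true_labels=labels,
        affected_regions=affected_regions,
        affected_edges=affected_edges,
        batch_assignment=batches,
        generating_parameters=config,
        age=age,
        sex=sex,
    )
    return tables, truth


def generate_phenotypes(true_labels: np.ndarray, config: CohortConfig, seed: int | None = None):
    """Phenotype table plus diagnosis labels.

    Cluster 1 is planted as the "ADHD-trait-enriched" subgroup: its SWAN
    medians shift up and its adaptive-functioning (ABAS) and IQ medians shift
    down by ``phenotype_effect`` SD units.  In ``independent`` mode the
    diagnosis label carries no information about the planted clusters; in
    ``enriched`` mode a participant's diagnosis follows a cluster-specific
    preferred label with probability ``diagnosis_mixing``.
    """
    true_labels = np.asarray(true_labels)
    n = true_labels.size
    rng = np.random.default_rng(config.seed + 101 if seed is None else seed)

    data = {}
    in_cluster1 = (true_labels == 1).astype(float)
    for name, (mean, sd, lo, hi, integer, direction) in _PHENOTYPES.items():
        vals = rng.normal(mean, sd, size=n)
        vals += direction * config.phenotype_effect * sd * in_cluster1
        vals = np.clip(vals, lo, hi)
        data[name] = np.round(vals).astype(int) if integer else vals
    phenotypes = pd.DataFrame(data, index=pd.Index([f"P{i:04d}" for i in range(n)], name="participant_id"))

    # cohort diagnosis mix follows the ASD/ADHD/TD proportions of the study design
    probs = np.array([262.0, 171.0, 132.0])
    probs /= probs.sum()
    random_dx = rng.choice(len(DIAGNOSES), size=n, p=probs)
    if config.diagnosis_mode == "independent":
        dx_idx = random_dx
    else:
        preferred = true_labels % len(DIAGNOSES)
        take_pref = rng.random(n) < config.diagnosis_mixing
        dx_idx = np.where(take_pref, preferred, random_dx)
    diagnosis = np.array([DIAGNOSES[i] for i in dx_idx])
    return phenotypes, diagnosis


def generate_cohort(config: CohortConfig):
    """Full synthetic cohort: measure tables, covariates, phenotypes, truth."""
    tables, truth = generate_measures(config)
    phenotypes, diagnosis = generate_phenotypes(truth.true_labels, config)
    ids = tables[next(iter(tables))].index
    covariates = pd.DataFrame(
        {
            "age": truth.age,
            "sex": truth.sex,
            "batch": truth.batch_assignment,
            "diagnosis": diagnosis,
        },
        index=ids,
    )
    return tables, covariates, phenotypes, truth


def write_cohort(outdir, tables, covariates, phenotypes, truth) -> None:
    """Write the cohort as the delimited-text files the readers expect."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for measure, table in tables.items():
        table.to_csv(outdir / f"{measure}.csv")
    covariates.to_csv(outdir / "covariates.csv")
    phenotypes.to_csv(outdir / "phenotypes.csv")
    truth.to_frame(covariates.index).to_csv(outdir / "truth.csv", index=False)
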