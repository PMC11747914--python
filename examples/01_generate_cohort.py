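"""Generate a synthetic structural-MRI cohort with planted subgroups.

The generator draws four regional measure tables (cortical thickness,
surface area, cortical volume, subcortical volume) for a cohort with two
planted subgroups that differ in regional means and in inter-regional
correlation, then layers scanner-batch, age and sex effects on top.
"""

import numpy as np

from morphotype import CohortConfig, generate_cohort

config = CohortConfig(
    n_participants=200,
    regions_per_measure={
        "cortical_thickness": 15,
        "surface_area": 15,
        "cortical_volume": 15,
        "subcortical_volume": 15,
    },
    n_clusters_true=2,
    mean_shift=2.0,      # subgroup mean separation, in within-region SD units
    edge_effect=0.25,    # correlation perturbation on affected region pairs
    n_batches=2,
    seed=1,
)

tables, covariates, phenotypes, truth = generate_cohort(config)

print("measure tables:")
for name, table in tables.items():
    print(f"  {name}: {table.shape[0]} participants x {table.shape[1]} regions")
print("covariates:", ", ".join(covariates.columns))
print("phenotypes:", ", ".join(phenotypes.columns))

sizes = np.bincount(truth.true_labels)
print(f"planted subgroup sizes: {sizes.tolist()}")
print(f"affected thickness regions: {truth.affected_regions['cortical_thickness']}")
print(f"first affected thickness edges: {truth.affected_edges['cortical_thickness'][:3]}")
print(covariates.head())
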