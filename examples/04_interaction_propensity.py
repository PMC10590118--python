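"""Cell-cell interaction propensity between macrophage conditions and
partner immune cells.

For each channel (soluble cytokine->receptor, physical membrane PPI) the
score for (condition, partner cell type) is the sum over curated edges of
the product of z-standardized expression on the two sides; deltas against
untreated macrophages are radar-chart-ready, and the per-gene driver
decomposition is exact.
"""
from quiescentome import SimConfig, simulate
from quiescentome.interactome import (
    condition_profile,
    interaction_drivers,
    interaction_propensity,
    relative_to_reference,
    standardize,
)

study = simulate(SimConfig(seed=17))
macro_z = standardize(condition_profile(study.expression))
cell_z = standardize(study.cell_profiles)

scores, coverage = interaction_propensity(macro_z, cell_z, study.edges,
                                          "soluble")
deltas = relative_to_reference(scores, reference="uM")
print(f"soluble coverage: {coverage['used']} used / "
      f"{coverage['skipped']} skipped edges")
pivot = deltas.pivot(index="condition", columns="cell_type",
                     values="delta_vs_ref").round(2)
print(pivot)

drivers = interaction_drivers(macro_z, cell_z, study.edges, "soluble",
                              cond_a="hlf_LPS", cond_b="uM_LPS",
                              cell_profiles=study.cell_profiles)
print(drivers.head(5).to_string(index=False))

# Positive deltas mean a condition is more interaction-prone toward that
# cell type than untreated macrophages (arbitrary units). Drivers are the
# macrophage-side genes whose expression difference between the two LPS
# conditions contributes most, ordered by the number of partner cell types
# they reach ("interaction count") then by |contribution|.
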