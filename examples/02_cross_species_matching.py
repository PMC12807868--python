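"""Cross-species tumor matching on an ortholog CpG panel.

Simulates a labeled "human" reference cohort and "mouse" query samples drawn
from the same class profiles through a 20% ortholog map, then matches each
query model by iterated UMAP embedding and by the class-balanced random
forest, with binomial significance per model.
"""

from murimeth.crossmap import (
    balanced_forest_match,
    build_cross_species_panel,
    consensus_match,
    iterated_embedding_match,
    match_significance,
    per_sample_consensus,
)
from murimeth.simulate import SimCohortSpec, gen_cross_species_cohort

fx = gen_cross_species_cohort(
    SimCohortSpec(n_classes=5, samples_per_class=4, n_probes=6000,
                  signature_sites_per_class=120, seed=7),
    ortholog_fraction=0.2, query_samples_per_class=2,
)

panel = build_cross_species_panel(
    fx.reference, fx.reference_labels, fx.query, fx.orthologs,
    human_top_sites=1000,
)
print(f"ortholog panel: {len(panel.pairs)} CpGs shared by both arrays")

votes = iterated_embedding_match(panel, n_iter=5, seed=1)
embedding = consensus_match(per_sample_consensus(votes), fx.query_sheet.table["model"])
forest_pred, _ = balanced_forest_match(panel, n_trees=300, seed=2)
forest = consensus_match(forest_pred, fx.query_sheet.table["model"])

expected = fx.query_sheet.table.groupby("model")["entity"].first()
print("\nmodel consensus (embedding arm / forest arm / expected):")
for model in embedding.index:
    print(f"  {model}: {embedding[model]} / {forest[model]} / {expected[model]}")

pvals = match_significance(
    per_sample_consensus(votes), fx.query_sheet.table["model"], expected,
    panel.reference_labels,
)
print("\nbinomial matching significance (BH adjusted):")
print(pvals[["n_matched", "n_samples", "p0", "adj_p"]].round(4))
# p0 is the chance of hitting the expected class by reference-frequency alone;
# small adj_p means the model matches its human counterpart beyond chance
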