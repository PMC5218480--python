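"""Combinatorial expression-response classification and enrichment.

Simulates a four-arm log2 expression experiment (vehicle, drug A, drug
B, combination; 3 arrays each) with genes planted into the eight
combination-response categories, classifies every gene, and tests a
planted gene set for enrichment in the combination-vs-drug-A ranking.
"""

from synergykit import (GeneSet, PipelineConfig, SimulationConfig,
                        run_expression, simulate_expression_experiment)

config = SimulationConfig(seed=11, n_genes=4000, expression_sigma_log2=0.1)
matrix, truth = simulate_expression_experiment(config)

g_genes = truth.index[truth["category"] == "G"]
sets = [GeneSet("PLANTED_CATEGORY_G", frozenset(g_genes),
                "genes up-regulated by both agents and amplified by the combination")]

report = run_expression(matrix, gene_sets=sets,
                        config=PipelineConfig(seed=11, n_perm=500))

print("genes per category:",
      ", ".join(f"{c}={report.category_counts.get(c, 0)}" for c in "ABCDEFGH"))
print("three-set Venn of the >= 2-fold lists:", report.venn)
print(report.enrichment.to_string(index=False))
print("Category G holds genes pushed up by both single agents and further "
      "amplified by the combination; ranking genes by combination-vs-drug-A "
      "difference of means finds that planted set strongly enriched "
      "(NES >> 1, FDR ~ 0).")
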