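"""Profile metabolic pathways, CAZymes and PUL markers across genomes.

Plants per-pathway completeness into two groups of genomes, scores presence
with the >= 80%-of-genes rule, tests for modules enriched in one group,
applies the dual-evidence CAZyme consensus and compares marker counts
between groups.
"""

import numpy as np
import pandas as pd

from magtaxa import (HitEvidence, cazyme_consensus, compare_groups,
                     enriched_modules, load_pathway_definitions,
                     pathway_presence, simulate_annotations)

defs = load_pathway_definitions()
pathway_ids = sorted(defs)
gene_lists = {p: sorted(defs[p].genes) for p in pathway_ids}

# group 1 (20 genomes) carries the urease pathway, group 2 (20) does not
n = 40
completeness = np.full((n, len(pathway_ids)), 1.0)
urease_col = pathway_ids.index("urease")
completeness[20:, urease_col] = 0.3
genome_genes, _ = simulate_annotations(n, gene_lists, completeness, seed=9)

pm = pathway_presence(genome_genes, defs, threshold=0.8)
groups = {g: ("order_A" if i < 20 else "order_B")
          for i, g in enumerate(sorted(genome_genes))}
enriched = enriched_modules(pm, groups, q_max=0.01)
print("modules enriched between the two orders (q < 0.01):")
print(enriched[enriched["enriched"]][["prevalence_order_A",
                                      "prevalence_order_B", "q_value"]])

evidence = [
    HitEvidence("cds1", "GH5", a_pident=52.0, a_coverage=0.8,
                b_evalue=1e-25, b_coverage=0.5),      # both pass -> accepted
    HitEvidence("cds2", "GH13", a_pident=55.0, a_coverage=0.9),  # A only
    HitEvidence("cds3", "PL1", a_pident=38.0, a_coverage=0.8,
                b_evalue=1e-30, b_coverage=0.6),      # A fails identity
]
print("\naccepted CAZyme assignments (evidence from both strategies):",
      cazyme_consensus(evidence))

rng = np.random.default_rng(4)
counts = {f"g{i:02d}": float(rng.poisson(30 if i < 20 else 55))
          for i in range(40)}
result = compare_groups(counts, {g: ("order_A" if int(g[1:]) < 20
                                     else "order_B") for g in counts})
print(f"\nCAZyme-count comparison: Kruskal-Wallis H = "
      f"{result.statistic:.1f}, p = {result.p_value:.2e}")
print(result.pairwise.to_string(index=False))
print("\nThe planted urease gap and the count shift are both detected;"
      "\ngroups with 16 or fewer genomes would be excluded from the tests.")
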