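"""Delineate genera from paired trees plus a 16S identity matrix.

Simulates a clade with 5 planted genera, computes the all-pairs identity
matrix, calls genera (clades shared by the NJ and ML trees with minimum
pairwise identity above 94.5%) and tests coarser ranks at the conventional
16S thresholds (family 86.5%, order 82.0%).
"""

from magtaxa import (assign_rank, call_genera, pairwise_identity,
                     simulate_sequences)

records, taxonomy, (tree_nj, tree_ml) = simulate_sequences(
    n_genera=5, members_per_genus=4, seq_length=1200,
    within_id=97.0, between_id=88.0, seed=3)

idm = pairwise_identity(records)
calls = call_genera(tree_nj, tree_ml, idm, genus_threshold=94.5)

print(f"{len(calls)} genera delineated (planted: 5):")
for call in calls:
    print(f"  genus {call.index}: {len(call.members)} members, "
          f"min pairwise identity {call.min_identity:.1f}%")

everyone = [r.id for r in records]
for rank in ("family", "order"):
    decision = assign_rank(everyone, idm, rank)
    verdict = "assigned" if decision.assigned else \
        f"refused (pair {decision.violating_pair})"
    print(f"all {len(everyone)} sequences at rank {rank} "
          f"(threshold {decision.threshold}%): {verdict} "
          f"[min identity {decision.min_identity:.1f}%]")

print("\nEach genus is a clade in both trees with within-genus identity"
      "\nabove 94.5%; the whole clade coheres at the order threshold but the"
      "\nfamily call depends on the between-genus divergence planted here.")
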