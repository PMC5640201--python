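"""Hypergeometric enrichment of motif-containing proteins between groups.

Generates a synthetic cohort in which a 500-protein subset is 3-fold
enriched for LIR-motif-containing proteins (LIRCPs) over a 10% baseline,
then recovers the fold and its upper-tail hypergeometric p-value.  This is
the statistic used to contrast, e.g., viruses infecting eukaryotes against
bacteriophages, or viruses against their hosts.
"""

import pandas as pd

import lirscan

table, realised = lirscan.generate_enrichment_cohort(
    n_universe=3000, n_subset=500, baseline_rate=0.1, fold=3.0, seed=42
)
flags = pd.Series(table["is_lircp"].to_numpy(), index=table["protein_id"].to_numpy())
result = lirscan.compare_groups(table, flags).set_index("group")

for group in ("subset", "rest"):
    row = result.loc[group]
    print(f"{group:>7}: k={row['k']:>4} of n={row['n']:>4}  "
          f"fold={row['fold']:.3f}  p={row['p_value']:.3g}")

print("\nfold is (k/n)/(K/N): the group's LIRCP rate relative to the whole")
print("universe; p is the exact upper-tail probability of drawing at least")
print("k LIRCPs by chance. The subset recovers the planted 3-fold signal.")
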