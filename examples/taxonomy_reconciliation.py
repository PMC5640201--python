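"""Reconcile noisy species names against an ICTV-style list.

Generates 20 synthetic virus species, introduces single-character typos
into half the query names, and matches each query back by Levenshtein edit
distance (threshold 2).  The same machinery maps semicolon-delimited
lineage strings to Baltimore genome-type groups.
"""

import lirscan
from lirscan.taxonomy import IctvRecord

ictv_df, queries, truth = lirscan.generate_taxa(
    n_species=20, typo_rate=0.5, max_typo_distance=1, seed=7
)
records = [
    IctvRecord(species=s, genus=g, family=f)
    for s, g, f in zip(ictv_df["species"], ictv_df["genus"], ictv_df["family"])
]

correct = 0
for q in queries[:8]:
    a = lirscan.match_species(q, records, max_distance=2)
    ok = a.matched.species == truth[q]
    correct += ok
    print(f"{q:<28} -> {a.matched.species:<28} d={a.edit_distance} [{a.method}]")

all_correct = sum(
    lirscan.match_species(q, records, max_distance=2).matched.species == truth[q]
    for q in queries
)
print(f"\nrecovered {all_correct}/{len(queries)} queries correctly")

for lineage in (
    "Viruses; dsDNA viruses, no RNA stage; Herpesvirales",
    "Viruses; Retro-transcribing viruses; Retroviridae",
):
    print(f"Baltimore({lineage.split(';')[1].strip()}) = "
          f"{lirscan.assign_baltimore(lineage)}")

print("\nEach query is assigned its closest ICTV species (d = edit distance,")
print("method exact/approximate/unmatched); lineage keywords give the")
print("Baltimore genome-type group.")
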