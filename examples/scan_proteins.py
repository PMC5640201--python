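"""Scan two small proteins for LIR motifs and print the hit table.

Builds an HIV-1 Nef-like fixture (xLIR motif EGWQTI at position 11) and an
HSV-1 ICP34.5-like fixture (WxxL motif RQWLHV at position 64), scans both,
and prints one row per detected motif.  Coordinates are 1-based inclusive;
the PSSM score is the summed log-odds of the window under the matrix built
from the bundled training set (higher = more LIR-like).
"""

import lirscan

records = [
    lirscan.ProteinRecord(
        id="NEF_like", sequence="P" * 10 + "EGWQTI" + "P" * 10,
        description="Nef-like fixture", organism="HIV-1 (synthetic)",
    ),
    lirscan.ProteinRecord(
        id="ICP34.5_like", sequence="P" * 63 + "RQWLHV" + "P" * 51,
        description="ICP34.5-like fixture", organism="HSV-1 (synthetic)",
    ),
]

matrix = lirscan.build_pssm(lirscan.load_training_set())
disorder = {"ICP34.5_like": [(50, 100)]}

print(f"{'accession':<14}{'span':<10}{'motif':<8}{'class':<6}"
      f"{'subtype':<8}{'score':>6}  disorder")
for rec in records:
    for h in lirscan.scan_sequence(rec, pssm=matrix,
                                   disorder=disorder.get(rec.id)):
        print(f"{h.protein_id:<14}{f'{h.start}-{h.end}':<10}{h.window:<8}"
              f"{h.pattern_class:<6}{h.subtype:<8}"
              f"{lirscan.display_score(h.pssm_score):>6}  {h.in_disorder}")

print("\nEach row is one candidate LC3-interacting region: the 6-mer window,")
print("its consensus class (xLIR is the stricter pattern), the aromatic")
print("subtype, the integer display PSSM score, and whether the window lies")
print("fully inside a supplied disordered region.")
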