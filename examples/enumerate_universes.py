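"""How many amino-acid pairs and triplets can encode an Nrd1/Nab3 motif.

The 4-5 bp consensus motifs span two codons (any motif) or three codons
(5-mers whose centre pins the middle codon). This enumerates both
universes and counts the members able to host a motif on the coding
strand (sense), on the opposite strand (antisense), or both.
"""

from codonmask import enumeration_summary, spanning_middle_codons
from codonmask.codon import SYM_OF_CODON

summary = enumeration_summary()
for key, value in summary.items():
    print(f"{key:24s} {value}")

for direction in ("sense", "antisense"):
    mids = sorted(spanning_middle_codons(direction))
    aas = [SYM_OF_CODON[c] for c in mids]
    print(f"middle codons ({direction}): {mids} -> residues {aas}")

print()
print("Of 440 ordered pairs (20 amino acids + STOP, at most one STOP),")
print(f"{summary['pairs_sense_only']} encode a motif only in sense, "
      f"{summary['pairs_antisense_only']} only in antisense and "
      f"{summary['pairs_both']} in both; of the 1760 triplets, "
      f"{summary['triplets_sense']} host a sense and "
      f"{summary['triplets_antisense']} an antisense three-codon-spanning "
      "5-mer. Antisense capacity exceeds sense capacity: the genetic code "
      "leaves more room to write degradation signals on the reverse strand.")
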