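"""Classify ORFs by antisense ncRNA overlap and profile site densities.

Generates a small ground-truthed dataset, recovers the ORF classes from
the annotation alone, and compares antisense site counts in the last
400 bp of the coding region across classes (the region where unstable
antisense transcripts make the difference).
"""

import numpy as np

from codonmask import (
    GeneratorConfig, classify_orfs, compare_site_counts, count_window,
    density_profile, filter_min_length, intergenic_regions,
    intergenic_window_counts, make_dataset,
)

ds = make_dataset(GeneratorConfig(seed=42, n_clear=60, n_cut=30, n_sut=30))
transcripts = filter_min_length(ds.transcripts, min_len=200)
classes = classify_orfs(transcripts, min_overlap=100)

labels = [c.label for c in classes.values()]
for label in ("ORF_CLEAR", "ORF_CUT", "ORF_SUT"):
    print(f"{label:10s} {labels.count(label):3d} ORFs")

counts = {}
for label in ("ORF_CLEAR", "ORF_CUT", "ORF_SUT"):
    members = [t for t in transcripts if t.ttype == "ORF"
               and classes[t.id].label == label and t.cds_length >= 400]
    counts[label] = [count_window(t, ds.genome, "stop_codon", "antisense",
                                  span=400) for t in members]
    print(f"{label}: mean antisense sites in last 400 bp of CDS = "
          f"{np.mean(counts[label]):.2f}")

p = compare_site_counts(counts["ORF_CUT"], counts["ORF_SUT"])
print(f"rank-sum p, CUT-class vs SUT-class antisense counts: {p:.2e}")
print("CUT-overlapped genes carry more antisense degradation signals than")
print("SUT-overlapped genes of identical amino-acid composition.\n")

regions = intergenic_regions(ds.genome, transcripts, window=400)
ctrl = intergenic_window_counts(regions, ds.genome)
print(f"{len(regions)} intergenic 400 bp control windows, "
      f"mean pooled sites {np.mean(ctrl):.2f}")

orfs = [t for t in transcripts if t.ttype == "ORF"
        and classes[t.id].label == "ORF_CUT"]
prof = density_profile(orfs, ds.genome, "stop_codon", "antisense")
body = prof.values[prof.bin_starts < 0].mean()
flank = prof.values[prof.bin_starts >= 0].mean()
print(f"CUT-class antisense density: {body:.3f}/bin inside the CDS vs "
      f"{flank:.3f}/bin downstream of the stop codon")
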