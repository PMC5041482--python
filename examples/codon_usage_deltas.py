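"""Quantify how synonymous codon choice tunes antisense motif content.

Fits class-level codon-usage models, computes each gene's expected motif
count under its own class usage and under the background (clear-class)
usage, and reports the distribution of the differences: positive means
the class's codon choices create antisense sites, negative means they
avoid them. Sense distributions stay centred because the classes encode
the same proteins with sense-equivalent codon swaps.
"""

import numpy as np

from codonmask import (
    GeneratorConfig, cai, classify_orfs, delta_expected, filter_min_length,
    fit_usage, load_cai_weights, make_dataset, residual_normality,
    class_residuals,
)

ds = make_dataset(GeneratorConfig(seed=7, n_clear=150, n_cut=75, n_sut=75))
transcripts = filter_min_length(ds.transcripts)
classes = classify_orfs(transcripts)
orfs = {label: [t for t in transcripts if t.ttype == "ORF"
                and classes[t.id].label == label]
        for label in ("ORF_CLEAR", "ORF_CUT", "ORF_SUT")}
usages = {label: fit_usage(members, ds.genome, label)
          for label, members in orfs.items()}
pooled = usages["ORF_CLEAR"].merged_with(usages["ORF_CUT"], usages["ORF_SUT"])

print("expected-site deltas (own-class usage minus clear-class usage):")
for label in ("ORF_CUT", "ORF_SUT"):
    for direction in ("sense", "antisense"):
        d = [delta_expected(t, usages[label], usages["ORF_CLEAR"], direction,
                            ds.genome, pooled) for t in orfs[label]]
        print(f"  {label:8s} {direction:9s} mean {np.mean(d):+6.2f} "
              f"sd {np.std(d, ddof=1):5.2f}")
print("Antisense deltas separate the classes (CUT-like > 0 > SUT-like),")
print("while sense deltas are an order of magnitude smaller: the designed")
print("bias lives on the reverse strand.\n")

res = class_residuals(orfs["ORF_CLEAR"], usages["ORF_CLEAR"], "antisense",
                      ds.genome, pooled)
stat, p = residual_normality(res["residual"])
print(f"clear-class observed-minus-expected residuals: mean "
      f"{res['residual'].mean():+.3f}, A^2* = {stat:.2f} (p = {p:.2f})")
print("Near-normal, mean-zero residuals: class-average codon usage models")
print("the per-gene motif counts well.\n")

weights = load_cai_weights()
for label, members in orfs.items():
    med = np.median([cai(t.cds_sequence(ds.genome), weights)
                     for t in members])
    print(f"median CAI {label:10s} {med:.3f}")
print("Overlapping codon-adaptation medians: the antisense bias is not a")
print("by-product of expression-driven codon optimality.")
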