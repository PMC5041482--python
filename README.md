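# codonmask

Antisense Nrd1/Nab3 degradation-signal encoding in yeast protein-coding
sequences: motif scanning, ORF/ncRNA overlap classification, codon-usage
expectation models, metagene density and PAR-CLIP occupancy profiles,
and a fully ground-truthed synthetic-data generator.

## The science

In *S. cerevisiae*, the Nrd1–Nab3 pathway terminates and degrades RNA
that carries many copies of short consensus motifs — UGUA, GUAG, UGUAG
(Nrd1) and UCUU, CUUG, UCUUG (Nab3). Cryptic unstable transcripts (CUTs)
are loaded with these signals and destroyed; stable unannotated
transcripts (SUTs) largely escape. Many of these ncRNAs run antisense to
protein-coding genes, so one DNA segment encodes a protein on one strand
and the fate of antisense RNA on the other.

The key observation this package operationalises: a 4–5 bp motif inside
a coding region is carried by two adjacent codons (or three, when a
5-mer spans a whole middle codon — possible only when that codon is GTA
or CTT in sense, TAC or AAG in antisense). Of the 440 ordered
amino-acid/STOP pairs, 71 can host a motif only in sense, 82 only in
antisense and 10 in both; of the 1760 admissible triplets, 150 host a
sense and 210 an antisense spanning 5-mer. Because most amino-acid pairs
can realise a motif with some synonymous codon choices and avoid it with
others, genes with identical protein sequences can tune their antisense
motif content. The pipeline quantifies this with a class-conditional
codon-usage model: for ORF class *c*, direction *d* and amino-acid key
*k*, let `p_c(motif | k, d)` be the usage-weighted fraction of
motif-bearing codon combinations. The expected motif content of an ORF
is

    E_c(orf, d) = Σ_pairs p_c(motif | k_i, d) + Σ_triplets p_c(motif | k_i, d)

and the per-ORF **delta** `E_own − E_clear` measures whether a class's
codon choices create (positive) or avoid (negative) motifs relative to
genes with no antisense transcript.

## Worked example

Everything is importable (`import codonmask`); `examples/` holds one
short script per capability, and the same steps are available as a thin
CLI (`codonmask enumerate|simulate|classify|scan|profile|codon-model|parclip|report`).

`python examples/codon_usage_deltas.py` simulates 300 genes in three
classes sharing one protein distribution but differing in synonymous
codon choice, recovers the classes from the annotation, fits the usage
models and prints:

```
expected-site deltas (own-class usage minus clear-class usage):
  ORF_CUT  sense     mean  +0.44 sd  0.85
  ORF_CUT  antisense mean  +4.17 sd  1.98
  ORF_SUT  sense     mean  +0.63 sd  0.79
  ORF_SUT  antisense mean  -5.46 sd  2.47
...
clear-class observed-minus-expected residuals: mean +0.000, A^2* = 0.29 (p = 0.63)
```

Reading: genes overlapped by an unstable antisense transcript (CUT-like
class) choose codons that create ~4 extra antisense binding sites per
gene relative to background usage, genes under a stable antisense
transcript avoid ~5, and the sense direction shows no comparable
separation — the degradation signal is written on the reverse strand
without touching the protein. The mean-zero, near-normal residuals say
the class-average usage model fits the per-gene counts.

`python examples/parclip_occupancy.py` couples simulated crosslinking
reads to expression × local motif content and shows that
expression-normalised occupancy recovers the site-density profile
(Pearson r ≈ 0.91 at ~50k reads):

```
antisense site density: 0.292/bin in the CDS vs 0.140/bin downstream
occupancy (reads per expression unit): 0.417 vs 0.260
Pearson r between profiles: 0.912
```

## Layout

- `src/codonmask/catalog.py` — genome/annotation loading, filters,
  antisense-overlap classification, intergenic controls
- `src/codonmask/motifs.py` — longest-match motif scanning, window
  counts, metagene density profiles, rank-sum comparison
- `src/codonmask/codon.py` — pair/triplet universes, usage models,
  expected counts, deltas, single-codon comparator, CAI,
  residual-normality test
- `src/codonmask/occupancy.py` — read midpoints, expression tracks,
  expression-normalised occupancy profiles
- `src/codonmask/simulate.py` — ground-truthed synthetic datasets
- `src/codonmask/cli.py` — subcommand front end
- `docs/methods.md` — model, conventions, generator design, limitations
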