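# Methods

## The problem

In *Saccharomyces cerevisiae*, the RNA-binding proteins Nrd1 and Nab3
recognise short consensus sequences in nascent RNA (UGUA, GUAG and UGUAG
for Nrd1; UCUU, CUUG and UCUUG for Nab3), terminate RNA polymerase II and
hand the transcript to the nuclear exosome for degradation. Cryptic
unstable transcripts (CUTs) carry many of these signals and are destroyed
rapidly; stable unannotated transcripts (SUTs) carry fewer and persist.
Many CUTs and SUTs are transcribed antisense to protein-coding genes, so
the same stretch of DNA must simultaneously encode a protein on one
strand and the appropriate density of degradation signals on the other.
`codonmask` implements the analysis of how synonymous codon choice
resolves this dual constraint.

## Motif scanning

Motifs are searched as DNA (TGTA/GTAG/TGTAG, TCTT/CTTG/TCTTG) on both
strands. Because each 4-mer is a substring of its protein's 5-mer, the
scanner applies a longest-match rule: every 5-mer occurrence is reported,
and a 4-mer occurrence is suppressed exactly when its span lies inside a
reported 5-mer occurrence. Partially overlapping occurrences (e.g. TGTAG
and GTAG in TGTAGTAG) are distinct sites. N never matches. A site is
assigned to windows and bins by its 5'-most base on the scanned strand,
which makes window counts additive over any partition of a sequence.

## Transcript catalogue and ORF classes

Coordinates are 0-based half-open throughout; a 1-based inclusive table
can be read with `dialect="one-based"`. Transcripts shorter than 200 bp
are removed. An ORF is classed by its antisense ncRNA overlap, computed
on transcript intervals (UTRs included): ORF_CUT if some single antisense
CUT overlaps it by ≥ 100 bp and no SUT does, ORF_SUT symmetrically,
EXCLUDED if both types reach the threshold, ORF_CLEAR otherwise
(sub-threshold antisense overlaps included). When several antisense
ncRNAs of one type overlap an ORF the recorded overlap is the maximum
single-transcript overlap, not the union, because classification asks
whether *an* overlapping antisense transcript exists. Codon-level and
occupancy analyses additionally require the annotated CDS to begin with
ATG, to be a multiple of three, to contain no internal stop, and the ORF
to overlap no other ORF by more than 10 bp. Intergenic control regions
take, from every maximal transcript-free gap of at least 400 bp, the
centred 400 bp window — one per gap; the construction of the original
control set is not fully specified anywhere we know of, so this explicit
rule is our declared choice.

## Metagene profiles

Densities are binned in 10 bp windows spanning ±400 bp of the start or
stop codon, in transcript orientation (offset 0 is the first CDS base at
the start anchor, and the first base after the CDS at the stop anchor).
A bin's value is the summed site count over contributing ORFs divided by
the number of ORFs whose coding region extends over the whole bin; bins
on the flank side use genomic sequence and every in-bounds ORF
contributes. The denominator is therefore non-increasing into the gene
body. Box-plot style window counts (first/last 400 bp) exclude regions
shorter than the window rather than truncating them.

## Codon-usage expectation model

The symbol alphabet is the 20 amino acids plus a STOP symbol; ordered
pairs with at most one STOP give 440 keys (400 amino-acid pairs + 40
with a stop — STOP is allowed in either slot; this combinatorial reading
is what yields 440). A 4 bp motif, or a 5 bp motif straddling one codon
boundary, lies inside the 6-mer of an adjacent codon pair; a 5 bp motif
can instead span three codons, which forces the middle codon to be the
motif centre — GTA (Val) or CTT (Leu) in sense, TAC (Tyr) or AAG (Lys)
in antisense — giving 4 × 440 = 1760 triplet keys. Exhaustive
enumeration over all synonymous combinations finds 71 pairs encoding a
motif only in sense, 82 only in antisense and 10 in both (81/92
inclusive), and 150/210 motif-encoding triplets (disjoint sets). The
published pair counts are the exclusive partition; both forms are
reported.

For each ORF class we count, over all CDSs, how often each codon
combination realises each pair key (and each eligible-middle triplet
key). The motif probability of a key is the usage-weighted fraction of
its motif-bearing combinations, and the expected motif content of an ORF
is the sum of those probabilities over its pairs and eligible triplets.
A key never realised in a class falls back to a model pooling all
classes, and finally to a uniform prior over the key's combinations.

**Counting convention for residuals.** A three-codon-spanning 5-mer
necessarily leaves 4-mer fragments inside both flanking 6-mers, so
binary per-pair events plus the triplet term would over-count scanner
sites. Residual and delta analyses therefore use a frame-consistent
observable: the number of adjacent codon pairs whose 6-mer contains a
motif plus the number of eligible triplets whose core is a spanning
5-mer (`observed_sites(method="frame")`). Its expectation is exactly the
model expectation, so observed-minus-expected residuals are mean-zero by
construction when the model fits; they are close to normal on
model-matched data (Anderson–Darling A²* with Stephens' p-value
approximation). Scanner-site counting (`method="scan"`) remains the
convention for window counts and profiles; the two differ only where
spanning 5-mers occur.

The per-ORF *delta* is the expected count under the ORF's own class
usage minus under the clear-class (background) usage: positive values
mean the class's synonymous choices actively create motifs. A
single-codon comparator computes the same expectations from per-symbol
marginal codon frequencies, ignoring within-pair coupling; it is kept
only for the model comparison by sum of squared residuals.

**CAI.** The codon adaptation index is the geometric mean of relative
adaptiveness weights over a CDS, excluding stop codons and the
single-codon families ATG/TGG (no synonymous choice), matching the
reference R implementation. The weights ship as a versioned TSV of the
Sharp & Li (1987) *S. cerevisiae* values; the code never hardcodes them
and rejects non-positive weights.

## PAR-CLIP occupancy

The module consumes already-mapped alignments (BAM/SAM or BED); adapter
trimming, quality filtering, duplicate collapsing and unique mapping
belong to the upstream alignment pipeline. Each alignment contributes
its midpoint ⌊(start+end)/2⌋. Midpoints are binned in the metagene
layout above, each ORF's binned counts are divided by that ORF's
strand-appropriate expression (mean of 5 bp-window track values over the
transcript), and bins are averaged over contributing ORFs. ORF-strand
combinations with expression below a floor (default 1e-6 on the track's
scale) are skipped rather than producing unbounded ratios. Intergenic
occupancy pools both strands for reads and expression. The profile is
exactly invariant under joint scaling of reads and expression.

## Synthetic data generator

The generator emits a genome FASTA, transcript TSV, 5 bp expression
track, midpoint BED and a truth table from a single seed (byte-identical
re-runs). Each ORF occupies its own cassette (pad, 5'UTR, CDS, 3'UTR,
pad); CUT-like and SUT-like ORFs receive one antisense ncRNA overlapping
the transcript 3' end by at least the classification threshold and
extending into the pad, so intended labels are recovered exactly and no
ORF–ORF overlaps occur.

Proteins are i.i.d. draws from a yeast-like amino-acid distribution
shipped as a codon-usage table; every class shares it, so amino-acid
pair spectra are identical across classes by construction. Classes
differ only through **antisense dials**: five synonymous swaps
(TAC/TAT, AAG/AAA, CAA/CAG, AGA/AGG, ACA/ACG) whose members were
verified to be interchangeable for sense-motif creation in every
non-stop pair context, while the first member can seed antisense motif
cores (TACA, AAGA, CAAG, CTAC on the coding strand). The dial factor
multiplies the odds of the first member against its partner (defaults:
clear 1.0, CUT-like 2.5, SUT-like 0.35), chosen to give a clear
antisense separation at realistic motif densities. An optional
first-order pair coupling (`pair_boost`) multiplies codon probabilities
conditional on the previous codon, used to demonstrate when the
pairwise model outperforms the single-codon model.

Default study conditions: 300/150/150 clear/CUT-like/SUT-like ORFs,
CDS lengths lognormal (median 300 codons, σ = 0.4, clipped to 60–1200),
UTRs 20–200 bp (5') and 40–300 bp (3'), intergenic GC 0.38, expression
lognormal around 8 (mRNA) and 4 (ncRNA) track units with σ = 0.6 over a
floor of 0.2. Reads are Poisson per 10 bp bin and strand at rate
`read_rate × expression × (1 + site count within a 100 bp coupling
window)`; the coupling window reflects that protein occupancy integrates
motif content over a binding footprint rather than a single 10 bp bin.

**Occupancy validation conditions.** Verifying that expression
normalisation recovers relative site density requires the known signal
to stand above Poisson counting noise at a realistic depth (~50k reads).
`occupancy_validation_config()` therefore uses one CUT-like class
(n = 1000) with a strong dial (8.0), GC-balanced flanks, ncRNAs long
enough that their uniform expression domain covers the whole profiled
window, constant expression levels, and depth calibrated once to ~50k
reads. This configuration validates the normalisation arithmetic; it is
deliberately not a model of yeast.

**What the generator does not emulate:** introns, nucleosome positioning
and NFR structure, realistic read-length/error/mismatch models,
background array noise in the expression track, codon-usage/expression
correlations, and chromosome-scale heterogeneity. Passing recovery tests
therefore demonstrates correctness of the pipeline's arithmetic and its
ability to detect designed biases, not that real yeast data would yield
any particular effect size.

## Statistical notes and limitations

- Site-count comparisons use the two-sided Wilcoxon rank-sum
  (Mann–Whitney) test; an all-tied input returns p = 1 with a warning.
- With class usage fitted in-sample, the sum of expected counts equals
  the sum of observed frame counts identically, so a class's mean delta
  equals its realised excess of motif frames over the background model.
  For classes of ~150 ORFs this mean carries an irreducible sampling
  fluctuation of order √(Ē(1/n₁+1/n₂)) ≈ 0.3 frames in the sense
  direction — small against the antisense separation (~±5) but not
  against zero. Sense deltas should therefore be read relative to the
  antisense effect, not as exact nulls.
- The Anderson–Darling p-value uses Stephens' case-3 approximation for
  the composite normal hypothesis; samples must have n ≥ 8 and be
  non-constant.
- Expectations use class-level average usage; per-ORF usage is not
  implemented as a separate mode because with the frame-consistent
  observable it reproduces the observation identically (the in-sample
  identity above, at class size one).
- The GAUG spelling of the second Nrd1 4-mer that circulates in parts of
  the literature is available as an alternative motif set; GUAG is the
  canonical default.
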