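"""Nrd1/Nab3 binding-site prediction on both strands, with the longest-match rule.

Nrd1 recognises UGUA/GUAG (UGUAG at full length), Nab3 UCUU/CUUG (UCUUG);
on DNA we search for the transcribed motifs TGTA/GTAG/TGTAG and
TCTT/CTTG/TCTTG. Because each 4-mer is a substring of its set's 5-mer, a
4-mer occurrence is suppressed when its span lies inside a reported 5-mer
occurrence; partially overlapping occurrences are counted separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .catalog import Genome, Transcript, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifSet:
    """One protein's consensus motifs, as DNA on the transcribed (sense) strand."""

    protein: str
    motifs: tuple[str, ...]

    def __post_init__(self):
        if not self.motifs:
            raise ValueError("empty motif set")
        fives = [m for m in self.motifs if len(m) == 5]
        for m in self.motifs:
            if any(len(m) not in (4, 5) for m in self.motifs):
                raise ValueError("motifs must be 4 or 5 bp")
            if len(m) == 4 and not any(m in f for f in fives):
                # longest-match suppression never fires for such a 4-mer
                warnings.warn(f"4-mer {m} is not a substring of any 5-mer in the set")


NRD1 = MotifSet("Nrd1", ("TGTA", "GTAG", "TGTAG"))
NAB3 = MotifSet("Nab3", ("TCTT", "CTTG", "TCTTG"))
DEFAULT_MOTIF_SETS: tuple[MotifSet, ...] = (NRD1, NAB3)
ALL_MOTIFS: tuple[str, ...] = NRD1.motifs + NAB3.motifs

# The older literature occasionally lists GAUG in place of GUAG; selectable
# as an alternative set, but GUAG is canonical here.
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    NRD1_GATG_VARIANT = MotifSet("Nrd1", ("TGTA", "GATG", "TGTAG"))


@dataclass(frozen=True)
class MotifSite:
    """One matched occurrence. ``offset`` is the leftmost base in the scanned frame."""

    seqid: str
    offset: int
    length: int
    strand: str
    protein: str
    motif: str

    @property
    def five_prime(self) -> int:
        """Position of the 5'-most base in the strand of the scan."""
        return self.offset if self.strand == "+" else self.offset + self.length - 1


def _find_all(seq: str, motif: str) -> list[int]:
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def scan(seq: str, mset: MotifSet, seqid: str = "seq") -> list[MotifSite]:
    """All predicted sites of one protein on the given (+) strand of ``seq``.

    Every 5-mer occurrence is reported; a 4-mer occurrence is reported
    unless its span is contained within a reported 5-mer occurrence.
    N never matches.
    """
    if not isinstance(mset, MotifSet):
        raise TypeError("mset must be a MotifSet")
    seq = seq.upper()
    five_spans: list[tuple[int, int]] = []
    sites: list[MotifSite] = []
    for motif in mset.motifs:
        if len(motif) == 5:
            for i in _find_all(seq, motif):
                five_spans.append((i, i + 5))
                sites.append(MotifSite(seqid, i, 5, "+", mset.protein, motif))
    five_starts = {s for s, _ in five_spans}
    for motif in mset.motifs:
        if len(motif) == 4:
            for i in _find_all(seq, motif):
                contained = i in five_starts or (i - 1) in five_starts
                if not contained:
                    sites.append(MotifSite(seqid, i, 4, "+", mset.protein, motif))
    sites.sort(key=lambda s: (s.offset, -s.length))
    return sites


def scan_antisense(seq: str, mset: MotifSet, seqid: str = "seq") -> list[MotifSite]:
    """Sites on the reverse strand, with coordinates mapped to the input frame."""
    n = len(seq)
    sites = [
        MotifSite(seqid, n - s.offset - s.length, s.length, "-", s.protein, s.motif)
        for s in scan(reverse_complement(seq.upper()), mset, seqid)
    ]
    sites.sort(key=lambda s: (s.offset, -s.length))
    return sites


def scan_both(seq: str, msets: Sequence[MotifSet] = DEFAULT_MOTIF_SETS,
              seqid: str = "seq") -> list[MotifSite]:
    """Pooled Nrd1+Nab3 sites on both strands."""
    sites: list[MotifSite] = []
    for mset in msets:
        sites += scan(seq, mset, seqid)
        sites += scan_antisense(seq, mset, seqid)
    sites.sort(key=lambda s: (s.offset, s.strand, -s.length))
    return sites


def _anchor_position(t: Transcript, anchor: str) -> int:
    """Genomic anchor base: offset 0 sits on the first CDS base (start_codon)
    or one past the last CDS base (stop_codon), in transcript orientation."""
    if anchor == "tss":
        return t.start if t.strand == "+" else t.end
    if t.cds_start is None:
        raise ValueError(f"{t.id}: anchor {anchor!r} needs a CDS ({t.ttype} has none)")
    if anchor == "start_codon":
        return t.cds_start if t.strand == "+" else t.cds_end
    if anchor == "stop_codon":
        return t.cds_end if t.strand == "+" else t.cds_start
    raise ValueError(f"unknown anchor {anchor!r}")


def _relative_sites(t: Transcript, genome: Genome, anchor: str, flank: int,
                    msets: Sequence[MotifSet]) -> tuple[list[int], list[int]]:
    """5'-base offsets of sense and antisense sites within ±flank of the anchor.

    Offsets are in transcript orientation: for anchor=start_codon the CDS
    occupies [0, cds_len); for stop_codon it occupies [-cds_len, 0).
    """
    pos = _anchor_position(t, anchor)
    length = genome.lengths[t.chrom]
    lo_c, hi_c = max(0, pos - flank), min(length, pos + flank)
    window = genome.fetch(t.chrom, lo_c, hi_c, t.strand)
    # window is in transcript orientation; index 0 is at genomic lo_c (+) or hi_c (-)
    if t.strand == "+":
        frame_offset = lo_c - pos
    else:
        frame_offset = pos - hi_c
    sense, antisense = [], []
    for mset in msets:
        for s in scan(window, mset):
            sense.append(s.five_prime + frame_offset)
        for s in scan_antisense(window, mset):
            antisense.append(s.five_prime + frame_offset)
    return sense, antisense


def count_window(t: Transcript, genome: Genome, anchor: str, direction: str,
                 span: int = 400, msets: Sequence[MotifSet] = DEFAULT_MOTIF_SETS,
                 truncate: bool = False) -> int:
    """Pooled predicted sites in one ``span``-bp window of a transcript.

    The window runs downstream (into the transcript body) from ``tss`` or
    ``start_codon`` anchors and upstream (back into the CDS) from
    ``stop_codon``. A site belongs to the window when its 5'-most base in
    the scanned strand lies inside it; ``direction`` is relative to the
    transcript ('sense' = its own strand). Regions shorter than ``span``
    raise unless ``truncate`` is set (boxplot-style counts exclude them).
    """
    if direction not in ("sense", "antisense"):
        raise ValueError(f"unknown direction {direction!r}")
    body = t.cds_length if anchor in ("start_codon", "stop_codon") else t.length
    if body < span and not truncate:
        raise ValueError(f"{t.id}: region ({body} bp) shorter than window ({span} bp)")
    if anchor == "stop_codon":
        lo, hi = -min(span, body), 0
    else:
        lo, hi = 0, min(span, body)
    sense, antisense = _relative_sites(t, genome, anchor, span, msets)
    offsets = sense if direction == "sense" else antisense
    return sum(lo <= o < hi for o in offsets)


@dataclass
class DensityProfile:
    """Binned mean predicted-site counts around an anchor.

    ``values[i]`` is the mean number of sites per contributing transcript
    whose 5' base falls in ``[bin_starts[i], bin_starts[i] + bin_size)``
    (offsets relative to the anchor, transcript orientation);
    ``denominators[i]`` counts the transcripts long enough to contribute.
    """

    anchor: str
    direction: str
    flank: int
    bin_size: int
    bin_starts: np.ndarray
    values: np.ndarray
    denominators: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "bin_start": self.bin_starts,
            "bin_end": self.bin_starts + self.bin_size,
            "value": self.values,
            "denominator": self.denominators,
        })


def _contributing_bins(t: Transcript, genome: Genome, anchor: str,
                       bin_starts: np.ndarray, bin_size: int) -> np.ndarray:
    """Mask of bins this transcript contributes to.

    Bins on the transcript-body side require the coding region to extend
    over the whole bin; bins on the flank side use genomic sequence and
    require only that the window stays within the chromosome.
    """
    pos = _anchor_position(t, anchor)
    length = genome.lengths[t.chrom]
    body = t.cds_length if anchor in ("start_codon", "stop_codon") else t.length
    ends = bin_starts + bin_size
    if anchor == "stop_codon":
        interior = bin_starts < 0          # body occupies [-body, 0)
        long_enough = -bin_starts <= body
    else:
        interior = bin_starts >= 0         # body occupies [0, body)
        long_enough = ends <= body
    ok = np.where(interior, long_enough, True)
    # chromosome bounds for the genomic window
    if t.strand == "+":
        g_lo, g_hi = pos + bin_starts, pos + ends
    else:
        g_lo, g_hi = pos - ends, pos - bin_starts
    ok &= (g_lo >= 0) & (g_hi <= length)
    return ok


def density_profile(orfs: Iterable[Transcript], genome: Genome, anchor: str,
                    direction: str, flank: int = 400, bin_size: int = 10,
                    msets: Sequence[MotifSet] = DEFAULT_MOTIF_SETS) -> DensityProfile:
    """Metagene density of predicted sites for one ORF class.

    Per bin: (sum of sites over contributing ORFs) / (number of ORFs whose
    coding region extends to the bin); flank bins outside the transcript
    use the genomic flank and all in-bounds ORFs contribute.
    """
    orfs = list(orfs)
    if not orfs:
        raise ValueError("empty transcript class")
    if direction not in ("sense", "antisense"):
        raise ValueError(f"unknown direction {direction!r}")
    bin_starts = np.arange(-flank, flank, bin_size)
    counts = np.zeros(len(bin_starts))
    denom = np.zeros(len(bin_starts), dtype=int)
    for t in orfs:
        mask = _contributing_bins(t, genome, anchor, bin_starts, bin_size)
        denom += mask
        sense, antisense = _relative_sites(t, genome, anchor, flank, msets)
        offsets = sense if direction == "sense" else antisense
        for o in offsets:
            idx = (o + flank) // bin_size
            if 0 <= idx < len(bin_starts) and mask[idx]:
                counts[idx] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, counts / np.maximum(denom, 1), 0.0)
    return DensityProfile(anchor, direction, flank, bin_size, bin_starts, values, denom)


def intergenic_window_counts(regions: Sequence[tuple[str, int, int]], genome: Genome,
                             msets: Sequence[MotifSet] = DEFAULT_MOTIF_SETS) -> list[int]:
    """Pooled both-strand site counts in each intergenic control window."""
    counts = []
    for chrom, start, end in regions:
        seq = genome.fetch(chrom, start, end)
        counts.append(len(scan_both(seq, msets)))
    return counts


def compare_site_counts(counts_a: Sequence[float], counts_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two site-count samples."""
    a, b = np.asarray(counts_a, float), np.asarray(counts_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; rank-sum test is degenerate (p = 1)")
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def sites_to_bed(sites: Iterable[MotifSite], path) -> None:
    """Write sites as BED6 (name = protein:motif, score = motif length)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.seqid}\t{s.offset}\t{s.offset + s.length}\t"
                     f"{s.protein}:{s.motif}\t{s.length}\t{s.strand}\n")
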