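"""Genome and transcript catalogue: loading, filtering and antisense-overlap classification.

Transcripts are typed genomic intervals (ORF, CUT or SUT) on a strand;
ORFs additionally carry a CDS sub-interval. Protein-coding genes are
classified by the kind of non-coding transcript that overlaps them in
antisense: an overlap of at least ``min_overlap`` bp with a CUT makes an
ORF_CUT, with a SUT an ORF_SUT, with both the ORF is excluded, and
everything else (including sub-threshold antisense overlaps) is ORF_CLEAR.

All coordinates are 0-based half-open internally (BED convention); a
1-based inclusive table can be read by passing ``dialect="one-based"``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ALPHABET = set("ACGTN")
TRANSCRIPT_TYPES = ("ORF", "CUT", "SUT")

ORF_CLEAR = "ORF_CLEAR"
ORF_CUT = "ORF_CUT"
ORF_SUT = "ORF_SUT"
EXCLUDED = "EXCLUDED"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """In-memory genome: chromosome name -> upper-case sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = str(seq).upper()
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains illegal characters {sorted(bad)}"
                )
            self._seqs[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the given strand (reverse-complemented for '-')."""
        if not (0 <= start <= end <= len(self._seqs[chrom])):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        seq = self._seqs[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq


@dataclass(frozen=True)
class Transcript:
    """A typed, stranded genomic interval; ORFs carry a CDS sub-interval."""

    id: str
    ttype: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.ttype not in TRANSCRIPT_TYPES:
            raise ValueError(f"{self.id}: unknown transcript type {self.ttype!r}")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        if self.end - self.start < 1:
            raise ValueError(f"{self.id}: empty interval")
        if self.ttype == "ORF":
            if self.cds_start is None or self.cds_end is None:
                raise ValueError(f"{self.id}: ORF requires CDS coordinates")
            if not (self.start <= self.cds_start < self.cds_end <= self.end):
                raise ValueError(f"{self.id}: CDS not contained in transcript interval")
        elif self.cds_start is not None or self.cds_end is not None:
            raise ValueError(f"{self.id}: CDS coordinates only allowed on ORFs")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        if self.cds_start is None:
            raise ValueError(f"{self.id}: no CDS")
        return self.cds_end - self.cds_start

    def cds_sequence(self, genome: Genome) -> str:
        """CDS in transcript orientation (starts with the start codon if well-formed)."""
        return genome.fetch(self.chrom, self.cds_start, self.cds_end, self.strand)

    def overlap_bp(self, other: "Transcript") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class OrfClass:
    """Antisense-overlap class of one ORF plus the overlap length that produced it."""

    label: str
    antisense_overlap_bp: int


def load_genome(path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences upper-cased)."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA record {record.id!r}")
        try:
            seqs[record.id] = str(record.seq)
        except Exception as exc:  # pragma: no cover - SeqIO rarely fails here
            raise ValueError(f"malformed FASTA record {record.id!r}: {exc}") from exc
    genome = Genome(seqs)
    logger.info("loaded genome: %d chromosomes, %d bp total",
                len(genome.chroms), sum(genome.lengths.values()))
    return genome


def load_transcripts(path, genome: Genome | None = None,
                     dialect: str = "bed") -> list[Transcript]:
    """Read the transcript catalogue from a header-bearing TSV.

    Expected columns: ``chrom start end id ttype strand`` plus optional
    ``cds_start cds_end`` (required for ORFs; empty for ncRNAs). ORFs whose
    CDS length is not a multiple of three are excluded with a logged reason;
    duplicate ids and out-of-bounds intervals are errors. ``dialect`` is
    ``"bed"`` (0-based half-open, the native format) or ``"one-based"``
    (1-based inclusive, converted on load).
    """
    if dialect not in ("bed", "one-based"):
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    off = 1 if dialect == "one-based" else 0
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "id", "ttype", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript table missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate transcript ids: {dups}")

    transcripts: list[Transcript] = []
    n_bad_frame = 0
    for row in df.itertuples(index=False):
        cds_start = cds_end = None
        if row.ttype == "ORF":
            if "cds_start" not in df.columns or "cds_end" not in df.columns:
                raise ValueError(f"{row.id}: ORF rows require cds_start/cds_end columns")
            if pd.isna(row.cds_start) or pd.isna(row.cds_end):
                raise ValueError(f"{row.id}: ORF without CDS coordinates")
            cds_start = int(row.cds_start) - off
            cds_end = int(row.cds_end)
            if (cds_end - cds_start) % 3 != 0:
                logger.warning("%s: CDS length %d not divisible by 3; excluded",
                               row.id, cds_end - cds_start)
                n_bad_frame += 1
                continue
        t = Transcript(str(row.id), str(row.ttype), str(row.chrom),
                       int(row.start) - off, int(row.end),
                       str(row.strand), cds_start, cds_end)
        if genome is not None:
            if t.chrom not in genome:
                raise ValueError(f"{t.id}: unknown chromosome {t.chrom!r}")
            if t.end > genome.lengths[t.chrom]:
                raise ValueError(f"{t.id}: interval extends past end of {t.chrom}")
        transcripts.append(t)
    if n_bad_frame:
        logger.info("excluded %d ORFs with out-of-frame CDS", n_bad_frame)
    return transcripts


def filter_min_length(transcripts: Iterable[Transcript],
                      min_len: int = 200) -> list[Transcript]:
    """Drop transcripts shorter than ``min_len`` bp (paper-scale default 200)."""
    kept, removed = [], defaultdict(int)
    for t in transcripts:
        if t.length >= min_len:
            kept.append(t)
        else:
            removed[t.ttype] += 1
    if removed:
        logger.info("length filter (< %d bp) removed: %s", min_len, dict(removed))
    return kept


def _max_antisense_overlap(orf: Transcript, others: Sequence[Transcript]) -> int:
    """Largest single-transcript antisense overlap of `orf` with `others`."""
    best = 0
    for t in others:
        if t.strand != orf.strand:
            best = max(best, orf.overlap_bp(t))
    return best


def classify_orfs(transcripts: Iterable[Transcript],
                  min_overlap: int = 100) -> dict[str, OrfClass]:
    """Classify every ORF by its antisense CUT/SUT overlap.

    An ORF is ORF_CUT when some single antisense CUT overlaps it by at
    least ``min_overlap`` bp and no SUT does; ORF_SUT symmetrically; an ORF
    with both is EXCLUDED; everything else is ORF_CLEAR. The recorded
    overlap is the maximum single-transcript antisense overlap over both
    ncRNA types. Classification is a pure function of the intervals, so it
    is deterministic and order-independent.
    """
    ts = list(transcripts)
    by_chrom: dict[str, dict[str, list[Transcript]]] = defaultdict(
        lambda: {"ORF": [], "CUT": [], "SUT": []})
    for t in ts:
        by_chrom[t.chrom][t.ttype].append(t)

    classes: dict[str, OrfClass] = {}
    for chrom, groups in by_chrom.items():
        for orf in groups["ORF"]:
            cut_ov = _max_antisense_overlap(orf, groups["CUT"])
            sut_ov = _max_antisense_overlap(orf, groups["SUT"])
            if cut_ov >= min_overlap and sut_ov >= min_overlap:
                label = EXCLUDED
            elif cut_ov >= min_overlap:
                label = ORF_CUT
            elif sut_ov >= min_overlap:
                label = ORF_SUT
            else:
                label = ORF_CLEAR
            classes[orf.id] = OrfClass(label, max(cut_ov, sut_ov))
    return dict(sorted(classes.items()))


def analysis_orfs(transcripts: Iterable[Transcript], genome: Genome,
                  orf_orf_max: int = 10) -> list[Transcript]:
    """ORFs eligible for codon-usage and occupancy analyses.

    Drops ORFs whose CDS does not begin with ATG (in transcript
    orientation), whose CDS is out of frame, or which overlap another ORF
    by more than ``orf_orf_max`` bp. Interval-level analyses keep using the
    full catalogue.
    """
    orfs = [t for t in transcripts if t.ttype == "ORF"]
    by_chrom: dict[str, list[Transcript]] = defaultdict(list)
    for t in orfs:
        by_chrom[t.chrom].append(t)

    kept = []
    for orf in orfs:
        if orf.cds_length % 3 != 0:
            logger.warning("%s: out-of-frame CDS; excluded from codon analyses", orf.id)
            continue
        if not orf.cds_sequence(genome).startswith("ATG"):
            logger.warning("%s: CDS does not begin with ATG; excluded from codon analyses",
                           orf.id)
            continue
        clash = max((orf.overlap_bp(o) for o in by_chrom[orf.chrom] if o.id != orf.id),
                    default=0)
        if clash > orf_orf_max:
            logger.warning("%s: overlaps another ORF by %d bp (> %d); excluded",
                           orf.id, clash, orf_orf_max)
            continue
        kept.append(orf)
    return kept


def neighbor_orientation(transcripts: Iterable[Transcript]) -> dict[tuple[str, str], str]:
    """Orientation of each non-overlapping adjacent ORF pair along a chromosome.

    Pairs on the same strand are *tandem*; a ``-`` gene followed by a ``+``
    gene (5' ends facing) is *divergent*; ``+`` then ``-`` (3' ends facing)
    is *convergent*. Keys are (left id, right id) in genomic order.
    """
    orfs_by_chrom: dict[str, list[Transcript]] = defaultdict(list)
    for t in transcripts:
        if t.ttype == "ORF":
            orfs_by_chrom[t.chrom].append(t)

    orientations: dict[tuple[str, str], str] = {}
    for chrom, orfs in orfs_by_chrom.items():
        orfs.sort(key=lambda t: (t.start, t.end))
        for left, right in zip(orfs, orfs[1:]):
            if left.overlap_bp(right) > 0:
                continue
            if left.strand == right.strand:
                label = "tandem"
            elif (left.strand, right.strand) == ("-", "+"):
                label = "divergent"
            else:
                label = "convergent"
            orientations[(left.id, right.id)] = label
    return orientations


def intergenic_regions(genome: Genome, transcripts: Iterable[Transcript],
                       window: int = 400) -> list[tuple[str, int, int]]:
    """Control windows from transcript-free gaps.

    From every maximal region covered by no transcript on either strand and
    at least ``window`` bp long, take the centred ``window`` bp — one
    control region per gap.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for t in transcripts:
        by_chrom[t.chrom].append((t.start, t.end))

    regions: list[tuple[str, int, int]] = []
    for chrom, length in genome.lengths.items():
        merged: list[list[int]] = []
        for start, end in sorted(by_chrom.get(chrom, [])):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        gaps = []
        prev = 0
        for start, end in merged:
            if start > prev:
                gaps.append((prev, start))
            prev = max(prev, end)
        if prev < length:
            gaps.append((prev, length))
        for gs, ge in gaps:
            if ge - gs >= window:
                mid = (gs + ge) // 2
                regions.append((chrom, mid - window // 2, mid - window // 2 + window))
    return regions


def write_classification(classes: Mapping[str, OrfClass], path) -> None:
    """Write the per-ORF classification as TSV `orf_id label antisense_overlap_bp`."""
    df = pd.DataFrame(
        [(oid, c.label, c.antisense_overlap_bp) for oid, c in classes.items()],
        columns=["orf_id", "label", "antisense_overlap_bp"],
    )
    df.to_csv(path, sep="\t", index=False)
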