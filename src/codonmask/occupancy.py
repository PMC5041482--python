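"""Expression-normalised PAR-CLIP occupancy around start and stop codons.

Consumes already-mapped alignments (upstream trimming, quality filtering
and unique mapping are assumed done by the aligner pipeline): each
alignment contributes its midpoint, midpoints are binned in 10 bp windows
around the codon anchors, each ORF's binned counts are divided by that
ORF's strand-appropriate expression level (a 5 bp-window track), and bins
are averaged over the ORFs long enough to contribute — the same metagene
convention as the motif density profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import Genome, Transcript
from .motifs import DensityProfile, _anchor_position, _contributing_bins

logger = logging.getLogger(__name__)


def load_midpoints(path, min_mapq: int | None = None) -> pd.DataFrame:
    """Read midpoints (floor((start+end)/2)) from a BAM or a BED6 text file.

    Returns a DataFrame with columns ``chrom``, ``pos``, ``strand``.
    Unmapped BAM records are skipped with a logged count; ``min_mapq``
    optionally re-applies a mapping-quality floor.
    """
    path = str(path)
    rows: list[tuple[str, int, str]] = []
    if path.endswith((".bam", ".sam", ".cram")):
        import pysam

        n_unmapped = 0
        mode = "rb" if path.endswith(".bam") else "r"
        with pysam.AlignmentFile(path, mode) as bam:
            for aln in bam.fetch(until_eof=True):
                if aln.is_unmapped:
                    n_unmapped += 1
                    continue
                if min_mapq is not None and aln.mapping_quality < min_mapq:
                    continue
                mid = (aln.reference_start + aln.reference_end) // 2
                rows.append((aln.reference_name, mid,
                             "-" if aln.is_reverse else "+"))
        if n_unmapped:
            logger.info("skipped %d unmapped records", n_unmapped)
    else:
        bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2, 5],
                          names=["chrom", "start", "end", "strand"])
        for row in bed.itertuples(index=False):
            rows.append((row.chrom, (int(row.start) + int(row.end)) // 2, row.strand))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


class ExpressionTrack:
    """Strand-resolved expression values on a fixed 5 bp window grid."""

    def __init__(self, window: int = 5):
        self.window = window
        self._data: dict[tuple[str, str], np.ndarray] = {}

    @classmethod
    def from_arrays(cls, arrays: dict[tuple[str, str], np.ndarray],
                    window: int = 5) -> "ExpressionTrack":
        track = cls(window)
        for key, values in arrays.items():
            values = np.asarray(values, float)
            if np.any(values < 0):
                raise ValueError(f"negative expression values on {key}")
            track._data[key] = values
        return track

    @classmethod
    def from_tsv(cls, path, window: int = 5) -> "ExpressionTrack":
        """Read a bedGraph-like TSV with columns chrom, start, strand, value."""
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"chrom", "start", "strand", "value"}
        if missing := required - set(df.columns):
            raise ValueError(f"expression track missing columns {sorted(missing)}")
        arrays: dict[tuple[str, str], np.ndarray] = {}
        for (chrom, strand), grp in df.groupby(["chrom", "strand"]):
            idx = (grp["start"] // window).to_numpy()
            values = np.zeros(idx.max() + 1)
            values[idx] = grp["value"].to_numpy()
            arrays[(chrom, strand)] = values
        return cls.from_arrays(arrays, window)

    def to_tsv(self, path) -> None:
        rows = []
        for (chrom, strand), values in sorted(self._data.items()):
            for i, v in enumerate(values):
                rows.append((chrom, i * self.window, strand, v))
        pd.DataFrame(rows, columns=["chrom", "start", "strand", "value"]).to_csv(
            path, sep="\t", index=False)

    def mean_over(self, chrom: str, start: int, end: int, strand: str) -> float:
        """Mean of the 5 bp-window values overlapping [start, end) on a strand."""
        values = self._data.get((chrom, strand))
        if values is None:
            raise KeyError(f"no expression data for {chrom} strand {strand}")
        lo = start // self.window
        hi = (end - 1) // self.window + 1
        if lo >= len(values):
            raise ValueError(f"no expression coverage for {chrom}:{start}-{end}")
        return float(values[lo:min(hi, len(values))].mean())


def orf_expression(orf: Transcript, track: ExpressionTrack) -> tuple[float, float]:
    """(sense, antisense) expression of an ORF: mean of overlapping 5 bp windows."""
    other = "-" if orf.strand == "+" else "+"
    try:
        sense = track.mean_over(orf.chrom, orf.start, orf.end, orf.strand)
        antisense = track.mean_over(orf.chrom, orf.start, orf.end, other)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"no expression coverage for ORF {orf.id}: {exc}") from exc
    return sense, antisense


@dataclass
class OccupancyProfile(DensityProfile):
    """Expression-normalised mean read midpoints per bin (metagene layout
    identical to :class:`DensityProfile`)."""


def occupancy_profile(orfs: Iterable[Transcript], midpoints: pd.DataFrame,
                      track: ExpressionTrack, genome: Genome, anchor: str,
                      direction: str, flank: int = 400, bin_size: int = 10,
                      expression_floor: float = 1e-6) -> OccupancyProfile:
    """Metagene PAR-CLIP occupancy for one ORF class.

    Per ORF, midpoints on the requested relative strand are binned around
    the anchor and divided by the ORF's expression on that strand; per
    bin, normalised counts are averaged over contributing ORFs. ORFs whose
    relevant expression falls below ``expression_floor`` are skipped for
    that strand (unbounded ratios), with a logged reason.
    """
    orfs = list(orfs)
    if not orfs:
        raise ValueError("empty transcript class")
    if direction not in ("sense", "antisense"):
        raise ValueError(f"unknown direction {direction!r}")
    bin_starts = np.arange(-flank, flank, bin_size)
    total = np.zeros(len(bin_starts))
    denom = np.zeros(len(bin_starts), dtype=int)
    by_chrom_strand = {key: grp["pos"].to_numpy()
                       for key, grp in midpoints.groupby(["chrom", "strand"])}
    for t in orfs:
        read_strand = t.strand if direction == "sense" else ("-" if t.strand == "+" else "+")
        sense_lv, anti_lv = orf_expression(t, track)
        level = sense_lv if direction == "sense" else anti_lv
        if level < expression_floor:
            logger.warning("%s: %s expression %.3g below floor; skipped",
                           t.id, direction, level)
            continue
        mask = _contributing_bins(t, genome, anchor, bin_starts, bin_size)
        denom += mask
        pos = by_chrom_strand.get((t.chrom, read_strand))
        if pos is None or pos.size == 0:
            continue
        anchor_pos = _anchor_position(t, anchor)
        rel = pos - anchor_pos if t.strand == "+" else anchor_pos - 1 - pos
        idx = (rel + flank) // bin_size
        ok = (idx >= 0) & (idx < len(bin_starts))
        idx = idx[ok]
        keep = mask[idx]
        np.add.at(total, idx[keep], 1.0 / level)
    values = np.where(denom > 0, total / np.maximum(denom, 1), 0.0)
    return OccupancyProfile(anchor, direction, flank, bin_size,
                            bin_starts, values, denom)


def intergenic_occupancy(regions: Sequence[tuple[str, int, int]],
                         midpoints: pd.DataFrame, track: ExpressionTrack,
                         expression_floor: float = 1e-6) -> float:
    """Mean strand-pooled, expression-normalised midpoint count over control regions.

    Midpoints from both strands are pooled per region and divided by the
    region's strand-pooled (summed) expression; regions below the floor
    are skipped.
    """
    if midpoints.empty:
        return 0.0
    values = []
    by_chrom = {chrom: grp["pos"].to_numpy()
                for chrom, grp in midpoints.groupby("chrom")}
    for chrom, start, end in regions:
        pos = by_chrom.get(chrom)
        n = int(((pos >= start) & (pos < end)).sum()) if pos is not None else 0
        level = 0.0
        for strand in "+-":
            try:
                level += track.mean_over(chrom, start, end, strand)
            except (KeyError, ValueError):
                pass
        if level < expression_floor:
            logger.warning("intergenic region %s:%d-%d below expression floor; skipped",
                           chrom, start, end)
            continue
        values.append(n / level)
    return float(np.mean(values)) if values else 0.0
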