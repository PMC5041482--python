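"""Motif scanning (longest-match rule), window counts and density profiles."""

import numpy as np
import pytest

from codonmask import (
    DEFAULT_MOTIF_SETS, Genome, MotifSet, NAB3, NRD1, Transcript,
    compare_site_counts, count_window, density_profile, reverse_complement,
    scan, scan_antisense,
)


def naive_scan(seq, mset):
    """Oracle: every occurrence of every motif, then suppress any 4-mer
    whose span lies inside a reported 5-mer occurrence's span."""
    seq = seq.upper()
    occ = []
    for m in mset.motifs:
        for i in range(len(seq) - len(m) + 1):
            if seq[i:i + len(m)] == m:
                occ.append((i, len(m)))
    fives = [(i, i + 5) for i, L in occ if L == 5]
    out = []
    for i, L in occ:
        if L == 4 and any(s <= i and i + 4 <= e for s, e in fives):
            continue
        out.append((i, L))
    return sorted(out)


def random_dna(rng, n, p=(0.31, 0.19, 0.19, 0.31)):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


class TestScan:
    def test_five_mer_suppresses_contained_four_mers(self):
        sites = scan("TGTAG", NRD1)
        assert [(s.offset, s.length) for s in sites] == [(0, 5)]

    def test_partial_overlaps_counted_separately(self):
        sites = scan("TGTAGTAG", NRD1)
        assert [(s.offset, s.length, s.motif) for s in sites] == [
            (0, 5, "TGTAG"), (4, 4, "GTAG")]

    def test_no_occurrence(self):
        assert scan("AAAAAA", NRD1) == [] and scan("AAAAAA", NAB3) == []

    def test_n_never_matches(self):
        assert scan("TGTNG", NRD1) == []
        assert scan_antisense("CTNCA", NRD1) == []

    def test_empty_motif_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MotifSet("x", ())

    def test_antisense_example_and_symmetry(self, rng):
        sites = scan_antisense("CTACA", NRD1)
        assert [(s.offset, s.length, s.strand) for s in sites] == [(0, 5, "-")]
        assert scan_antisense("TGTAG", NRD1) == []
        for _ in range(20):
            seq = random_dna(rng, 300)
            for mset in DEFAULT_MOTIF_SETS:
                assert len(scan_antisense(seq, mset)) == \
                    len(scan(reverse_complement(seq), mset))

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        for _ in range(50):
            seq = random_dna(rng, 2000)
            for mset in DEFAULT_MOTIF_SETS:
                got = sorted((s.offset, s.length) for s in scan(seq, mset))
                assert got == naive_scan(seq, mset)

    def test_site_start_additivity_over_window_partition(self, rng):
        seq = random_dna(rng, 3000)
        for mset in DEFAULT_MOTIF_SETS:
            whole = [(s.offset, s.length) for s in scan(seq, mset)]
            # partitioning counts by site start must preserve the total
            edges = [0, 700, 1500, 2200, 3000]
            total = sum(
                sum(1 for o, _ in whole if lo <= o < hi)
                for lo, hi in zip(edges, edges[1:]))
            assert total == len(whole)


def make_orf(seq_parts, utr5=50, utr3=50, strand="+"):
    """Genome with one ORF whose CDS is seq_parts joined, plus flanks."""
    cds = "".join(seq_parts)
    assert len(cds) % 3 == 0
    flank = "A" * 500
    tx = "C" * utr5 + cds + "C" * utr3
    if strand == "+":
        chrom = flank + tx + flank
        cds_start = len(flank) + utr5
    else:
        chrom = flank + reverse_complement(tx) + flank
        cds_start = len(flank) + utr3
    genome = Genome({"c": chrom})
    t = Transcript("o", "ORF", "c", len(flank), len(flank) + len(tx), strand,
                   cds_start, cds_start + len(cds))
    return genome, t


class TestCountWindow:
    def test_known_motifs_counted(self):
        cds = "ATG" + "TGTAG" + "C" + "TCTTG" + "C" * 85 + "TAA"
        genome, t = make_orf([cds])
        assert count_window(t, genome, "start_codon", "sense", span=102,
                            truncate=True) == 2

    def test_all_a_window_is_zero(self):
        genome, t = make_orf(["ATG" + "AAA" * 40 + "TAA"])
        assert count_window(t, genome, "start_codon", "sense", span=120,
                            truncate=True) == 0

    def test_codon_anchor_requires_cds(self):
        genome, _ = make_orf(["ATG" + "AAA" * 40 + "TAA"])
        cut = Transcript("cut", "CUT", "c", 0, 300, "+")
        with pytest.raises(ValueError, match="CDS"):
            count_window(cut, genome, "start_codon", "sense")

    def test_short_region_rejected_unless_truncated(self):
        genome, t = make_orf(["ATG" + "AAA" * 20 + "TAA"])
        with pytest.raises(ValueError, match="shorter"):
            count_window(t, genome, "start_codon", "sense", span=400)
        assert count_window(t, genome, "start_codon", "sense", span=400,
                            truncate=True) == 0

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_stop_anchor_window_and_strands(self, strand):
        # one antisense site (CTACA on coding strand) in the last 30 bp of CDS
        cds = "ATG" + "CCC" * 20 + "CTACAC" + "CCC" * 3 + "TAA"
        genome, t = make_orf([cds], strand=strand)
        assert count_window(t, genome, "stop_codon", "antisense", span=30,
                            truncate=True) == 1
        assert count_window(t, genome, "stop_codon", "sense", span=30,
                            truncate=True) == 0


class TestDensityProfile:
    def test_single_site_single_bin(self):
        cds = "ATG" + "CCC" * 11 + "TGTAG" + "C" + "CCC" * 10 + "TAA"
        genome, t = make_orf([cds])
        prof = density_profile([t], genome, "start_codon", "sense",
                               flank=100, bin_size=10)
        # site 5' base at CDS offset 36 -> bin [30, 40)
        idx = list(prof.bin_starts).index(30)
        assert prof.values[idx] == 1.0
        assert prof.values.sum() == 1.0

    def test_denominator_counts_only_long_enough_orfs(self):
        long_cds = "ATG" + "CCC" * 40 + "TGTAG" + "C" + "CCC" * 8 + "TAA"
        short_cds = "ATG" + "CCC" * 20 + "TAA"
        g1, t1 = make_orf([long_cds])
        g2, t2 = make_orf([short_cds])
        chrom = g1["c"] + g2["c"]
        genome = Genome({"c": chrom})
        off = len(g1["c"])
        t2 = Transcript("o2", "ORF", "c", t2.start + off, t2.end + off, "+",
                        t2.cds_start + off, t2.cds_end + off)
        prof = density_profile([t1, t2], genome, "start_codon", "sense",
                               flank=200, bin_size=10)
        idx = list(prof.bin_starts).index(120)  # site at CDS offset 123
        assert prof.denominators[idx] == 1     # only the long ORF reaches it
        assert prof.values[idx] == 1.0
        # denominator non-increasing into the gene body
        body = prof.denominators[prof.bin_starts >= 0]
        assert (np.diff(body) <= 0).all()

    def test_profile_recovers_implant_rate(self, rng):
        # implant one TGTAG per bin with probability p in an A background
        p, n_orfs, flank = 0.25, 120, 200
        transcripts, chrom_parts, cursor = [], [], 0
        for i in range(n_orfs):
            body = []
            for _ in range(60):  # 600 bp CDS in 10 bp bins
                if rng.random() < p:
                    off = rng.integers(0, 6)
                    body.append("A" * off + "TGTAG" + "A" * (5 - off))
                else:
                    body.append("A" * 10)
            cds = "ATG" + "".join(body)[:-6] + "TAA"  # keep frame, length 600
            pad = "C" * 300
            chrom_parts += [pad, cds]
            start = cursor + len(pad)
            transcripts.append(Transcript(f"o{i}", "ORF", "c", start,
                                          start + len(cds), "+",
                                          start, start + len(cds)))
            cursor += len(pad) + len(cds)
        chrom_parts.append("C" * 300)
        genome = Genome({"c": "".join(chrom_parts)})
        prof = density_profile(transcripts, genome, "start_codon", "sense",
                               flank=flank, bin_size=10)
        body_vals = prof.values[prof.bin_starts >= 0]
        assert abs(body_vals.mean() - p) < 0.02
        se = np.sqrt(p * (1 - p) / n_orfs)
        assert (np.abs(body_vals - p) < 4 * se).all()

    def test_strand_symmetry_under_genome_reversal(self, small_dataset):
        ds = small_dataset
        genome = ds.genome
        L = genome.lengths[ds.config.chrom_name]
        mirrored_genome = Genome(
            {ds.config.chrom_name: reverse_complement(genome[ds.config.chrom_name])})
        orfs = [t for t in ds.transcripts if t.ttype == "ORF"][:12]
        mirrored = [
            Transcript(t.id, t.ttype, t.chrom, L - t.end, L - t.start,
                       "-" if t.strand == "+" else "+",
                       L - t.cds_end, L - t.cds_start)
            for t in orfs
        ]
        for direction, mirrored_direction in (("sense", "sense"),
                                              ("antisense", "antisense")):
            a = density_profile(orfs, genome, "stop_codon", direction)
            b = density_profile(mirrored, mirrored_genome, "stop_codon",
                                mirrored_direction)
            np.testing.assert_array_equal(a.values, b.values)
            np.testing.assert_array_equal(a.denominators, b.denominators)


class TestCompareSiteCounts:
    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            assert compare_site_counts([3, 3, 3], [3, 3, 3]) == 1.0

    def test_separated_samples_significant(self):
        p = compare_site_counts(list(range(1, 21)), list(range(101, 121)))
        assert p < 0.001

    def test_type_one_error_calibrated(self, rng):
        n_rej = 0
        reps = 600
        for _ in range(reps):
            a, b = rng.normal(size=20), rng.normal(size=20)
            if compare_site_counts(a, b) < 0.05:
                n_rej += 1
        assert 0.03 < n_rej / reps < 0.07

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_site_counts([], [1.0])
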