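"""Genome/transcript loading, filtering and antisense-overlap classification."""

import numpy as np
import pandas as pd
import pytest

from codonmask import (
    EXCLUDED, ORF_CLEAR, ORF_CUT, ORF_SUT,
    Genome, Transcript, analysis_orfs, classify_orfs, filter_min_length,
    intergenic_regions, load_genome, load_transcripts, neighbor_orientation,
    reverse_complement,
)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def write_transcripts(path, rows):
    cols = ["chrom", "start", "end", "id", "ttype", "strand",
            "cds_start", "cds_end"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


class TestLoadGenome:
    def test_single_record_read_back(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, {"c1": "ACGT"})
        g = load_genome(p)
        assert g.lengths == {"c1": 4}
        assert g["c1"] == "ACGT"

    def test_lower_case_normalised(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, {"c1": "acgtn"})
        assert load_genome(p)["c1"] == "ACGTN"

    def test_illegal_character_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, {"c1": "ACXGT"})
        with pytest.raises(ValueError, match="c1"):
            load_genome(p)

    def test_fetch_respects_strand_and_bounds(self):
        g = Genome({"c": "ACGTACGT"})
        assert g.fetch("c", 0, 4) == "ACGT"
        assert g.fetch("c", 0, 4, "-") == reverse_complement("ACGT")
        with pytest.raises(ValueError):
            g.fetch("c", 4, 100)


class TestLoadTranscripts:
    def test_three_rows_read_back(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_transcripts(p, [
            ("c1", 0, 300, "orf1", "ORF", "+", 50, 251),
            ("c1", 400, 700, "cut1", "CUT", "-", "", ""),
            ("c1", 800, 1100, "sut1", "SUT", "+", "", ""),
        ])
        ts = load_transcripts(p)
        assert {t.id for t in ts} == {"orf1", "cut1", "sut1"}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_transcripts(p, [
            ("c1", 0, 300, "x", "ORF", "+", 50, 251),
            ("c1", 400, 700, "x", "CUT", "-", "", ""),
        ])
        with pytest.raises(ValueError, match="duplicate"):
            load_transcripts(p)

    def test_orf_without_cds_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_transcripts(p, [("c1", 0, 300, "orf1", "ORF", "+", "", "")])
        with pytest.raises(ValueError, match="CDS"):
            load_transcripts(p)

    def test_out_of_frame_cds_excluded_with_log(self, tmp_path, caplog):
        p = tmp_path / "t.tsv"
        write_transcripts(p, [
            ("c1", 0, 300, "bad", "ORF", "+", 50, 250),   # 200 bp CDS
            ("c1", 400, 700, "good", "ORF", "+", 450, 651),
        ])
        with caplog.at_level("WARNING"):
            ts = load_transcripts(p)
        assert [t.id for t in ts] == ["good"]
        assert any("divisible by 3" in r.message for r in caplog.records)

    def test_one_based_dialect_converted(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_transcripts(p, [("c1", 1, 300, "orf1", "ORF", "+", 51, 251)])
        t = load_transcripts(p, dialect="one-based")[0]
        assert (t.start, t.end, t.cds_start, t.cds_end) == (0, 300, 50, 251)

    def test_non_atg_orf_kept_for_intervals_dropped_for_codon_work(self):
        seq = ("T" * 40 + "ATG" + "GGC" * 6 + "TAA"          # well-formed CDS
               + "T" * 40 + "CCC" + "GGC" * 6 + "TAA"        # CDS not starting ATG
               + "T" * 40)
        genome = Genome({"c1": seq})
        orf_atg = Transcript("atg", "ORF", "c1", 20, 70, "+", 40, 64)
        orf_bad = Transcript("bad", "ORF", "c1", 100, 184, "+", 104, 128)
        kept = analysis_orfs([orf_atg, orf_bad], genome)
        assert [t.id for t in kept] == ["atg"]
        # both remain available for interval-level work
        assert len(filter_min_length([orf_atg, orf_bad], min_len=1)) == 2


class TestFilters:
    @pytest.mark.parametrize("length,kept", [(199, False), (200, True)])
    def test_min_length_boundary(self, length, kept):
        t = Transcript("t", "CUT", "c", 0, length, "+")
        assert (len(filter_min_length([t])) == 1) is kept


def orf(oid, start, end, strand="+", cds=None, chrom="c"):
    cds = cds or (start, end)
    return Transcript(oid, "ORF", chrom, start, end, strand, cds[0], cds[1])


def nc(tid, ttype, start, end, strand="-", chrom="c"):
    return Transcript(tid, ttype, chrom, start, end, strand)


class TestClassifyOrfs:
    def test_antisense_cut_overlap_rule(self):
        ts = [orf("o", 0, 600, "+", (0, 600)), nc("c", "CUT", 450, 800)]
        c = classify_orfs(ts)
        assert c["o"].label == ORF_CUT
        assert c["o"].antisense_overlap_bp == 150

    def test_sub_threshold_overlap_is_clear(self):
        ts = [orf("o", 0, 600), nc("s", "SUT", 501, 900)]
        assert classify_orfs(ts)["o"].label == ORF_CLEAR

    def test_both_types_excluded(self):
        ts = [orf("o", 0, 600), nc("c", "CUT", 400, 800),
              nc("s", "SUT", 0, 150)]
        assert classify_orfs(ts)["o"].label == EXCLUDED

    def test_sense_overlap_ignored(self):
        ts = [orf("o", 0, 600), nc("c", "CUT", 100, 500, strand="+")]
        assert classify_orfs(ts)["o"].label == ORF_CLEAR

    def test_max_single_overlap_not_union(self):
        # two CUTs overlapping 60 bp each: union 120 >= 100 but max 60 < 100
        ts = [orf("o", 0, 600), nc("c1", "CUT", 0, 60), nc("c2", "CUT", 300, 360)]
        c = classify_orfs(ts)
        assert c["o"].label == ORF_CLEAR
        assert c["o"].antisense_overlap_bp == 60

    def test_order_independent_and_partition(self, rng):
        ts = [orf(f"o{i}", i * 1000, i * 1000 + 600) for i in range(8)]
        ts += [nc(f"c{i}", "CUT", i * 1000 + 400, i * 1000 + 900)
               for i in range(0, 8, 2)]
        ts += [nc(f"s{i}", "SUT", i * 1000 + 300, i * 1000 + 800)
               for i in range(1, 8, 3)]
        base = classify_orfs(ts)
        assert set(base) == {f"o{i}" for i in range(8)}
        for _ in range(5):
            shuffled = list(ts)
            rng.shuffle(shuffled)
            assert classify_orfs(shuffled) == base
        labels = {ORF_CLEAR, ORF_CUT, ORF_SUT, EXCLUDED}
        assert all(c.label in labels for c in base.values())

    def test_overlap_matches_per_base_oracle(self, rng):
        # random intervals; recorded overlap equals brute-force base intersection
        ts = []
        for i in range(30):
            s = int(rng.integers(0, 5000))
            ts.append(orf(f"o{i}", s, s + int(rng.integers(50, 400)),
                          strand=rng.choice(["+", "-"])))
        for i in range(30):
            s = int(rng.integers(0, 5000))
            ts.append(nc(f"n{i}", rng.choice(["CUT", "SUT"]), s,
                         s + int(rng.integers(50, 400)),
                         strand=rng.choice(["+", "-"])))
        classes = classify_orfs(ts)
        for o in ts:
            if o.ttype != "ORF":
                continue
            best = 0
            for t in ts:
                if t.ttype in ("CUT", "SUT") and t.strand != o.strand:
                    bases = set(range(o.start, o.end)) & set(range(t.start, t.end))
                    best = max(best, len(bases))
            assert classes[o.id].antisense_overlap_bp == best


class TestNeighborOrientation:
    def test_three_orientations(self):
        ts = [orf("a", 0, 100, "+"), orf("b", 200, 300, "+"),
              orf("c", 400, 500, "-"), orf("d", 600, 700, "+")]
        ori = neighbor_orientation(ts)
        assert ori[("a", "b")] == "tandem"
        assert ori[("b", "c")] == "convergent"   # + then - : 3' ends face
        assert ori[("c", "d")] == "divergent"    # - then + : 5' ends face

    def test_overlapping_pairs_skipped(self):
        ts = [orf("a", 0, 100, "+"), orf("b", 50, 200, "-")]
        assert neighbor_orientation(ts) == {}


class TestIntergenicRegions:
    def test_gap_boundaries(self):
        g = Genome({"c": "A" * 1000})
        below = [nc("x", "CUT", 0, 300, "+"), nc("y", "CUT", 699, 1000, "+")]
        at = [nc("x", "CUT", 0, 300, "+"), nc("y", "CUT", 700, 1000, "+")]
        assert intergenic_regions(g, below) == []
        assert intergenic_regions(g, at) == [("c", 300, 700)]

    def test_region_count_matches_interval_subtraction_oracle(self, rng):
        length = 20000
        g = Genome({"c": "A" * length})
        ts = []
        for i in range(12):
            s = int(rng.integers(0, length - 500))
            ts.append(nc(f"t{i}", "SUT", s, s + int(rng.integers(100, 500)),
                         strand=rng.choice(["+", "-"])))
        covered = np.zeros(length, bool)
        for t in ts:
            covered[t.start:t.end] = True
        # count maximal uncovered runs >= 400
        runs, run = [], 0
        for c in covered:
            if not c:
                run += 1
            else:
                runs.append(run)
                run = 0
        runs.append(run)
        expected = sum(1 for r in runs if r >= 400)
        regions = intergenic_regions(g, ts, window=400)
        assert len(regions) == expected
        for chrom, s, e in regions:
            assert e - s == 400
            assert not covered[s:e].any()
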