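"""Pileup counting: read filters, clip masking, strand-aware tallies."""

from __future__ import annotations

import pysam
import pytest

from nanopsi.counts import (build_count_table, filter_alignment,
                            mask_clip_adjacent, merge_replicates,
                            CountTable, SiteCounts)

from conftest import write_fasta, write_sam


_HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 1000}]})


def _segment(flag=0, mapq=60, cigar="10M", seq="A" * 10, pos=0):
    a = pysam.AlignedSegment(_HEADER)
    a.query_name = "r"
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigarstring = cigar
    a.query_sequence = seq
    return a


@pytest.mark.parametrize("flag,mapq,expected", [
    (0, 19, False),      # MAPQ just below the threshold
    (0, 20, True),       # boundary is inclusive
    (256, 60, False),    # secondary alignment never passes
    (2048, 60, False),   # supplementary alignment never passes
    (4, 60, False),      # unmapped
    (0, 60, True),
])
def test_filter_alignment(flag, mapq, expected):
    assert filter_alignment(_segment(flag=flag, mapq=mapq)) is expected


def test_mask_left_softclip_masks_first_aligned_bases():
    read = _segment(cigar="5S10M", seq="A" * 15, pos=100)
    assert mask_clip_adjacent(read, 3) == {100, 101, 102}


def test_mask_right_softclip_masks_last_aligned_bases():
    read = _segment(cigar="10M2S", seq="A" * 12, pos=100)
    assert mask_clip_adjacent(read, 3) == {107, 108, 109}


def test_mask_no_clip_is_empty():
    assert mask_clip_adjacent(_segment(cigar="10M", seq="A" * 10)) == set()


def test_mask_truncates_on_short_reads():
    # 2 aligned bases, mask depth 3: both masked, nothing else
    read = _segment(cigar="2S2M", seq="AAAA", pos=50)
    assert mask_clip_adjacent(read, 3) == {50, 51}


def test_hard_clips_trigger_mask_like_soft_clips():
    read = _segment(cigar="4H6M", seq="A" * 6, pos=10)
    assert mask_clip_adjacent(read, 2) == {10, 11}


class TestBuildCountTable:
    REF = {"c1": "AAGTTCAAAA"}  # T at 3, 4; A elsewhere

    def test_plus_strand_tally(self, tmp_path):
        # 10 reads over position 3 (ref T): 4 call C, 6 call T
        reads = []
        for i in range(10):
            base = "C" if i < 4 else "T"
            reads.append({"name": f"r{i}", "contig": "c1", "pos": 2,
                          "cigar": "5M", "seq": "G" + base + "TCA"})
        ref = write_fasta(tmp_path / "r.fa", self.REF)
        sam = write_sam(tmp_path / "a.sam", self.REF, reads)
        table = build_count_table(sam, ref)
        site = table.get(("c1", 3, "+"))
        assert site.depth == 10
        assert site.count_C == 4
        assert site.mismatch_frac == pytest.approx(0.4)

    def test_minus_strand_complement_tally(self, tmp_path):
        # reverse reads over a plus-strand A at position 2: read-space C
        # appears as plus-strand G
        contigs = {"c1": "GGAGGGGG"}
        reads = []
        for i in range(8):
            plus_base = "G" if i < 2 else "A"  # 2 transcript-space C calls
            reads.append({"name": f"m{i}", "contig": "c1", "pos": 0,
                          "flag": 16, "cigar": "5M",
                          "seq": "GG" + plus_base + "GG"})
        ref = write_fasta(tmp_path / "r.fa", contigs)
        sam = write_sam(tmp_path / "a.sam", contigs, reads)
        table = build_count_table(sam, ref)
        site = table.get(("c1", 2, "-"))
        assert site.depth == 8
        assert site.count_C == 2
        assert site.mismatch_frac == pytest.approx(0.25)
        # no plus-strand site exists at a reference A
        assert table.get(("c1", 2, "+")) is None

    def test_deletion_counts_toward_depth_not_c(self, tmp_path):
        contigs = {"c1": "AATAAA"}
        reads = [
            {"name": "d1", "contig": "c1", "pos": 0, "cigar": "2M1D3M",
             "seq": "AAAAA"},
            {"name": "d2", "contig": "c1", "pos": 0, "cigar": "6M",
             "seq": "AACAAA"},
        ]
        ref = write_fasta(tmp_path / "r.fa", contigs)
        sam = write_sam(tmp_path / "a.sam", contigs, reads)
        site = build_count_table(sam, ref).get(("c1", 2, "+"))
        assert site.depth == 2
        assert site.count_del == 1
        assert site.count_C == 1

    def test_read_n_calls_are_ignored(self, tmp_path):
        contigs = {"c1": "AATAAA"}
        reads = [{"name": "n1", "contig": "c1", "pos": 0, "cigar": "6M",
                  "seq": "AANAAA"}]
        ref = write_fasta(tmp_path / "r.fa", contigs)
        sam = write_sam(tmp_path / "a.sam", contigs, reads)
        assert build_count_table(sam, ref).get(("c1", 2, "+")) is None

    def test_contig_mismatch_raises(self, tmp_path):
        ref = write_fasta(tmp_path / "r.fa", {"other": "AAAA"})
        sam = write_sam(tmp_path / "a.sam", {"c1": "AAAA"},
                        [{"name": "x", "contig": "c1", "pos": 0,
                          "cigar": "4M", "seq": "AAAA"}])
        with pytest.raises(ValueError, match="c1"):
            build_count_table(sam, ref)


def _brute_force_tally(sam_path, ref_path, min_mapq=20, n_mask=3):
    """Independent oracle: per-read walk over aligned_pairs."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    ref = pysam.FastaFile(ref_path)
    tally = {}
    with pysam.AlignmentFile(sam_path) as aln:
        for read in aln.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.mapping_quality < min_mapq):
                continue
            strand = "-" if read.is_reverse else "+"
            pairs = read.get_aligned_pairs()
            aligned_ref = [r for q, r in pairs
                           if q is not None and r is not None]
            masked = set()
            cig = read.cigartuples
            if cig[0][0] in (4, 5):
                masked |= set(aligned_ref[:n_mask])
            if cig[-1][0] in (4, 5):
                masked |= set(aligned_ref[-n_mask:])
            for q, r in pairs:
                if r is None or r in masked:
                    continue
                refbase = ref.fetch(read.reference_name, r, r + 1).upper()
                if (strand == "+" and refbase != "T") or \
                        (strand == "-" and refbase != "A"):
                    continue
                key = (read.reference_name, r, strand)
                counts = tally.setdefault(key, {"U": 0, "C": 0, "A": 0,
                                                "G": 0, "del": 0})
                if q is None:
                    counts["del"] += 1
                    continue
                b = read.query_sequence[q].upper()
                if b == "N":
                    continue
                if strand == "-":
                    b = comp[b]
                b = "U" if b == "T" else b
                if b in counts:
                    counts[b] += 1
    ref.close()
    return tally


def _mixed_fixture(tmp_path):
    """~20 reads exercising strands, clips, deletions and MAPQ boundary."""
    contigs = {"g1": "ACGTTCAGGATTACAGCTAGTTCAGACGTACGTAACGTAG",
               "g2": "TTTACGTACGATAGCATTTACGGATC"}
    ref_seq = contigs["g1"]
    reads = []
    for i in range(8):
        seq = list(ref_seq[2:22])
        if i < 3:
            seq[2] = "C"  # mismatch at ref pos 4 (T)
        reads.append({"name": f"f{i}", "contig": "g1", "pos": 2,
                      "cigar": "20M", "seq": "".join(seq)})
    # soft-clipped read: first 3 aligned bases masked
    reads.append({"name": "clip", "contig": "g1", "pos": 3,
                  "cigar": "4S15M", "seq": "AAAA" + ref_seq[3:18]})
    # deletion spanning T at pos 10-11
    reads.append({"name": "del", "contig": "g1", "pos": 8,
                  "cigar": "2M2D8M", "seq": ref_seq[8:10] + ref_seq[12:20]})
    # reverse reads on g1 (minus-strand sites at plus-strand A)
    for i in range(5):
        seq = list(ref_seq[25:40])
        if i < 2:
            seq[9] = "G"  # plus-strand G = transcript C at A site 34
        reads.append({"name": f"r{i}", "contig": "g1", "pos": 25,
                      "flag": 16, "cigar": "15M", "seq": "".join(seq)})
    # MAPQ boundary pair
    reads.append({"name": "q19", "contig": "g2", "pos": 0, "mapq": 19,
                  "cigar": "10M", "seq": contigs["g2"][:10]})
    reads.append({"name": "q20", "contig": "g2", "pos": 0, "mapq": 20,
                  "cigar": "10M", "seq": contigs["g2"][:10]})
    # secondary alignment: ignored entirely
    reads.append({"name": "sec", "contig": "g2", "pos": 0, "flag": 256,
                  "cigar": "10M", "seq": contigs["g2"][:10]})
    ref = write_fasta(tmp_path / "mix.fa", contigs)
    sam = write_sam(tmp_path / "mix.sam", contigs, reads)
    return sam, ref


def test_count_table_matches_brute_force_oracle(tmp_path):
    sam, ref = _mixed_fixture(tmp_path)
    table = build_count_table(sam, ref)
    oracle = _brute_force_tally(sam, ref)
    assert set(table.sites) == set(oracle)
    for key, counts in oracle.items():
        site = table.sites[key]
        assert (site.count_U, site.count_C, site.count_A, site.count_G,
                site.count_del) == (counts["U"], counts["C"], counts["A"],
                                    counts["G"], counts["del"]), key


def test_count_conservation_and_filter_monotonicity(tmp_path):
    sam, ref = _mixed_fixture(tmp_path)
    base = build_count_table(sam, ref, min_mapq=20, n_mask=3)
    for site in base.sites.values():
        assert (site.count_U + site.count_C + site.count_A + site.count_G
                + site.count_del) == site.depth
    stricter_mapq = build_count_table(sam, ref, min_mapq=30, n_mask=3)
    wider_mask = build_count_table(sam, ref, min_mapq=20, n_mask=6)
    for key, site in base.sites.items():
        for other in (stricter_mapq, wider_mask):
            s = other.get(key)
            assert (0 if s is None else s.depth) <= site.depth


def test_merge_replicates_pools_counts():
    s1 = SiteCounts("c1", 5, "+", count_U=6, count_C=4)
    s2 = SiteCounts("c1", 5, "+", count_U=27, count_C=3)
    t1 = CountTable("direct", "rep1", {s1.key: s1})
    t2 = CountTable("direct", "rep2", {s2.key: s2})
    merged = merge_replicates([t1, t2])
    site = merged.get(("c1", 5, "+"))
    assert site.depth == 40
    assert site.count_C == 7
    assert site.mismatch_frac == pytest.approx(0.175)  # pooled, not mean


def test_merge_single_table_is_identity():
    s1 = SiteCounts("c1", 5, "+", count_U=6, count_C=4)
    t1 = CountTable("direct", "rep1", {s1.key: s1})
    merged = merge_replicates([t1])
    assert merged.get(s1.key).count_C == 4
    merged.get(s1.key).count_C = 99  # deep copy: original untouched
    assert t1.get(s1.key).count_C == 4


def test_merge_mixed_labels_raises():
    t1 = CountTable("direct", "rep1", {})
    t2 = CountTable("ivt", "rep1", {})
    with pytest.raises(ValueError, match="mixed"):
        merge_replicates([t1, t2])


def test_pooled_fraction_bounded_by_replicate_fractions(tmp_path):
    from nanopsi.simulate import SimulationConfig, make_reference, \
        simulate_library
    cfg = SimulationConfig(seed=3, n_transcripts=2, coverage=15)
    ref = make_reference(cfg, str(tmp_path))
    tables = []
    for r in range(3):
        sam = simulate_library(cfg, ref, "direct", r,
                               str(tmp_path / f"d{r}.sam"))
        tables.append(build_count_table(sam, ref.fasta_path, label="direct",
                                        replicate_id=f"rep{r}"))
    merged = merge_replicates(tables)
    for key, site in merged.sites.items():
        fracs = [t.get(key).mismatch_frac for t in tables
                 if t.get(key) is not None]
        assert min(fracs) - 1e-12 <= site.mismatch_frac <= max(fracs) + 1e-12
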