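"""Strand-aware per-site base-call tallies at reference uridine positions.

Direct RNA nanopore reads align on the transcribed strand, so the alignment
strand of a read is the strand of the transcript it came from.  A site is a
(contig, 0-based position, strand) triple whose transcript-space reference
base is U: a plus-strand T, or a minus-strand A, on the reference.  Counts
are recorded in transcript space — a read-space C over a minus-strand site
appears as a G on the reference plus strand.

Read-level filters follow the method's defaults: primary alignments only,
MAPQ >= 20, and the first/last 3 aligned bases adjacent to a clipped read
end masked (clip-adjacent bases carry degraded base quality).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import pysam

from .sequence import extract_kmer

SiteKey = tuple[str, int, str]

#: CIGAR operation codes treated as clips (soft and hard alike: the clipped
#: sequence is absent from the alignment either way).
_CLIP_OPS = (4, 5)


@dataclass
class SiteCounts:
    """Base-call tally of one replicate at one uridine site."""

    contig: str
    position: int          # 0-based, reference plus strand
    strand: str            # '+' or '-': the transcribed strand
    count_U: int = 0
    count_C: int = 0
    count_A: int = 0
    count_G: int = 0
    count_del: int = 0

    @property
    def depth(self) -> int:
        return (self.count_U + self.count_C + self.count_A + self.count_G
                + self.count_del)

    @property
    def mismatch_frac(self) -> float:
        """U-to-C mismatch fraction: count_C / depth."""
        d = self.depth
        return self.count_C / d if d else 0.0

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.position, self.strand)


@dataclass
class CountTable:
    """All uridine-site tallies of one library replicate."""

    library_label: str     # 'direct' or 'ivt'
    replicate_id: str
    sites: dict[SiteKey, SiteCounts] = field(default_factory=dict)

    def get(self, key: SiteKey) -> SiteCounts | None:
        return self.sites.get(key)

    def sorted_keys(self) -> list[SiteKey]:
        return sorted(self.sites)


def clip_lengths(read: pysam.AlignedSegment) -> tuple[int, int]:
    """(left, right) clipped lengths, counting soft and hard clips."""
    cig = read.cigartuples or []
    i = 0
    left = 0
    while i < len(cig) and cig[i][0] in _CLIP_OPS:
        left += cig[i][1]
        i += 1
    right = 0
    j = len(cig)
    while j > i and cig[j - 1][0] in _CLIP_OPS:
        right += cig[j - 1][1]
        j -= 1
    return left, right


def filter_alignment(read: pysam.AlignedSegment, min_mapq: int = 20) -> bool:
    """True iff the read is a primary alignment with MAPQ >= ``min_mapq``.

    Unmapped, secondary and supplementary records never pass.
    """
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    return read.mapping_quality >= min_mapq


def mask_clip_adjacent(read: pysam.AlignedSegment, n_mask: int = 3) -> set[int]:
    """Reference positions of the first/last ``n_mask`` aligned bases next
    to a clipped read end.

    An end with no clip contributes nothing.  A read shorter than ``n_mask``
    aligned bases is masked entirely on the clipped side.
    """
    left, right = clip_lengths(read)
    if not left and not right:
        return set()
    aligned = [rpos for qpos, rpos in read.get_aligned_pairs()
               if qpos is not None and rpos is not None]
    masked: set[int] = set()
    if left:
        masked.update(aligned[:n_mask])
    if right:
        masked.update(aligned[-n_mask:] if n_mask else [])
    return masked


def _check_contigs(aln: pysam.AlignmentFile, ref: pysam.FastaFile) -> None:
    missing = [c for c in aln.references if c not in ref.references]
    if missing:
        raise ValueError(
            "contigs present in alignment but absent from reference FASTA: "
            + ", ".join(missing))


def build_count_table(alignment_path: str, reference_fasta: str,
                      min_mapq: int = 20, n_mask: int = 3,
                      label: str = "direct",
                      replicate_id: str = "rep1") -> CountTable:
    """Tally base calls at every covered uridine site of one SAM/BAM file.

    Reads contribute only at sites on their own alignment strand.  Deletions
    spanning a site increment ``count_del`` (they count toward depth but are
    not evidence of C); insertions and read-space N calls are ignored;
    reference N positions are skipped, lowercase (soft-masked) reference is
    treated as valid sequence.
    """
    tallies: dict[SiteKey, SiteCounts] = {}
    with pysam.FastaFile(reference_fasta) as ref, \
            pysam.AlignmentFile(alignment_path, check_sq=False) as aln:
        _check_contigs(aln, ref)
        ref_cache: dict[str, str] = {}
        for read in aln.fetch(until_eof=True):
            if not filter_alignment(read, min_mapq):
                continue
            strand = "-" if read.is_reverse else "+"
            want = "A" if strand == "-" else "T"
            contig = read.reference_name
            if contig not in ref_cache:
                ref_cache[contig] = ref.fetch(contig).upper()
            refseq = ref_cache[contig]
            masked = mask_clip_adjacent(read, n_mask)
            qseq = read.query_sequence
            for qpos, rpos, op in read.get_aligned_pairs(with_cigar=True):
                if rpos is None:          # insertion in the read
                    continue
                if op == 3:               # N: spliced intron, not sequenced
                    continue
                if refseq[rpos] != want:  # not a U site on this strand (or N)
                    continue
                if rpos in masked:
                    continue
                key = (contig, rpos, strand)
                site = tallies.get(key)
                if site is None:
                    site = tallies[key] = SiteCounts(contig, rpos, strand)
                if qpos is None:          # deletion over the site
                    site.count_del += 1
                    continue
                base = qseq[qpos].upper()
                if base == "N":
                    continue
                # transcript-space call: complement read-space base on '-'
                if strand == "-":
                    base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
                if base == "T":
                    site.count_U += 1
                elif base == "C":
                    site.count_C += 1
                elif base == "A":
                    site.count_A += 1
                elif base == "G":
                    site.count_G += 1
    return CountTable(label, replicate_id,
                      {k: tallies[k] for k in sorted(tallies)
                       if tallies[k].depth > 0})


def merge_replicates(tables: list[CountTable]) -> CountTable:
    """Element-wise sum of per-site counts across replicates of one library.

    The pooled mismatch fraction is recomputed from pooled counts (not a
    mean of per-replicate fractions).
    """
    if not tables:
        raise ValueError("no tables to merge")
    labels = {t.library_label for t in tables}
    if len(labels) > 1:
        raise ValueError(f"cannot merge mixed library labels: {sorted(labels)}")
    if len(tables) == 1:
        t = tables[0]
        return CountTable(t.library_label, t.replicate_id,
                          {k: replace(s) for k, s in t.sites.items()})
    merged: dict[SiteKey, SiteCounts] = {}
    for t in tables:
        for key, s in t.sites.items():
            m = merged.get(key)
            if m is None:
                merged[key] = replace(s)
            else:
                m.count_U += s.count_U
                m.count_C += s.count_C
                m.count_A += s.count_A
                m.count_G += s.count_G
                m.count_del += s.count_del
    rep_id = "+".join(t.replicate_id for t in tables)
    return CountTable(tables[0].library_label, rep_id,
                      {k: merged[k] for k in sorted(merged)})


_TSV_COLUMNS = ["contig", "pos0", "pos1", "strand", "kmer", "depth",
                "nU", "nC", "nA", "nG", "nDel", "mismatch_frac"]


def write_count_table(table: CountTable, path: str,
                      reference_fasta: str | None = None) -> None:
    """Serialize a CountTable as TSV (pos0 0-based, pos1 1-based)."""
    ref = pysam.FastaFile(reference_fasta) if reference_fasta else None
    try:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["#library", table.library_label,
                        "replicate", table.replicate_id])
            w.writerow(_TSV_COLUMNS)
            for key in table.sorted_keys():
                s = table.sites[key]
                kmer = ""
                if ref is not None:
                    kmer = extract_kmer(ref, s.contig, s.position, s.strand) or ""
                w.writerow([s.contig, s.position, s.position + 1, s.strand,
                            kmer, s.depth, s.count_U, s.count_C, s.count_A,
                            s.count_G, s.count_del,
                            f"{s.mismatch_frac:.6g}"])
    finally:
        if ref is not None:
            ref.close()


def read_count_table(path: str) -> CountTable:
    """Load a CountTable written by :func:`write_count_table`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or rows[0][0] != "#library":
        raise ValueError(f"{path}: not a count-table TSV")
    label, rep = rows[0][1], rows[0][3]
    sites: dict[SiteKey, SiteCounts] = {}
    for row in rows[2:]:
        rec = dict(zip(_TSV_COLUMNS, row))
        s = SiteCounts(rec["contig"], int(rec["pos0"]), rec["strand"],
                       count_U=int(rec["nU"]), count_C=int(rec["nC"]),
                       count_A=int(rec["nA"]), count_G=int(rec["nG"]),
                       count_del=int(rec["nDel"]))
        sites[s.key] = s
    return CountTable(label, rep, sites)
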