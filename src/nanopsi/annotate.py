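"""Transcript anatomy, synthase motifs and hypermodification classes.

Type I hypermodification is a per-site property: a called site whose merged
direct U-to-C mismatch exceeds 40%.  Because the basecaller systematically
under-calls pseudouridine (synthetic 100%-occupancy controls read back at
roughly 30-70% mismatch depending on context), >40% mismatch conservatively
captures sites where at least every other transcript copy is modified.
Type II is a per-transcript property: two or more highly significant
(p <= 0.001) modified positions on the same mRNA.

Sites are placed on transcript anatomy (5'UTR / CDS / 3'UTR) through a
dominant-isoform rule: among annotated isoforms overlapping the site, the
one compatible with the most reads covering it wins.  Splice distances are
measured in spliced (transcript) coordinates, since UTR/CDS lengths are
spliced quantities.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pysam

from .counts import filter_alignment
from .detection import SiteCall
from .sequence import revcomp, to_rna

BASE_ORDER = "ACGU"

PUS7_MOTIF = "UGUAG"
TRUB1_PREFIX = "GUUC"


@dataclass
class TranscriptModel:
    """Exon chain and CDS bounds of one annotated isoform."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]          # 0-based half-open, genomic, sorted
    cds_start: int | None = None          # genomic, half-open [cds_start, cds_end)
    cds_end: int | None = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def contains(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.exons)

    def to_transcript_coord(self, position: int) -> int:
        """Genomic 0-based position -> 0-based offset from the 5' end."""
        offset = 0
        for s, e in self.exons:
            if s <= position < e:
                offset += position - s
                break
            offset += e - s
        else:
            raise ValueError(
                f"position {self.contig}:{position} is not exonic in "
                f"{self.transcript_id}")
        if self.strand == "-":
            return self.length - 1 - offset
        return offset

    def junction_coords(self) -> list[int]:
        """Transcript coordinates of exon-exon junctions (first base of the
        downstream exon)."""
        if len(self.exons) <= 1:
            return []
        sizes = [e - s for s, e in self.exons]
        if self.strand == "-":
            sizes = sizes[::-1]
        return [int(c) for c in np.cumsum(sizes[:-1])]


@dataclass
class AnnotatedSite:
    call: SiteCall
    transcript_id: str
    gene_id: str
    region: str                # 5UTR | CDS | 3UTR | noncoding
    splice_distance: int | None
    motif: str                 # PUS7 | TRUB1 | other
    type1: bool


@dataclass
class TranscriptSummary:
    transcript_id: str
    gene_id: str
    sites: list[AnnotatedSite] = field(default_factory=list)

    @property
    def n_high_sites(self) -> int:
        return len({s.call.position for s in self.sites
                    if s.call.tier == "highly_significant"})

    @property
    def type2(self) -> bool:
        return self.n_high_sites >= 2


def load_transcript_models(gtf_path: str) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into transcript models (sorted by id)."""
    db = gffutils.create_db(gtf_path, ":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    models = []
    for tx in db.features_of_type("transcript"):
        exons = sorted((f.start - 1, f.end)
                       for f in db.children(tx, featuretype="exon"))
        cds = sorted((f.start - 1, f.end)
                     for f in db.children(tx, featuretype="CDS"))
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        models.append(TranscriptModel(
            transcript_id=tx.attributes["transcript_id"][0],
            gene_id=tx.attributes["gene_id"][0],
            contig=tx.seqid, strand=tx.strand, exons=exons,
            cds_start=cds_start, cds_end=cds_end))
    return sorted(models, key=lambda m: m.transcript_id)


def classify_type1(call: SiteCall, cutoff: float = 0.40) -> bool:
    """Type I hypermodification: merged mismatch strictly above ``cutoff``."""
    return call.merged_mismatch > cutoff


def motif_tag(kmer: str) -> str:
    """Synthase recognition motif of a centered 5-mer: PUS7, TRUB1 or other."""
    if len(kmer) != 5 or kmer[2] != "U":
        raise ValueError(f"not a center-U 5-mer: {kmer!r}")
    if kmer == PUS7_MOTIF:
        return "PUS7"
    if kmer.startswith(TRUB1_PREFIX) and kmer[4] in "AUCG":
        return "TRUB1"
    return "other"


def assign_region(position: int, model: TranscriptModel
                  ) -> tuple[str, int | None]:
    """(region, splice_distance) of a genomic site on one transcript model.

    Region is 5UTR/CDS/3UTR by comparison with the CDS bounds in transcript
    orientation, or ``noncoding`` for transcripts without a CDS.  Splice
    distance is the minimum nt, in transcript coordinates, to the nearest
    exon-exon junction; None for single-exon transcripts.  Intronic sites
    raise — direct RNA reads are spliced, so this flags a model mismatch.
    """
    if not model.contains(position):
        raise ValueError(
            f"site {model.contig}:{position} is intronic or outside "
            f"{model.transcript_id}")
    t = model.to_transcript_coord(position)
    junctions = model.junction_coords()
    splice = min(abs(t - j) for j in junctions) if junctions else None
    if not model.is_coding:
        return "noncoding", splice
    t_cds_lo = model.to_transcript_coord(
        model.cds_start if model.strand == "+" else model.cds_end - 1)
    t_cds_hi = model.to_transcript_coord(
        model.cds_end - 1 if model.strand == "+" else model.cds_start)
    if t < t_cds_lo:
        return "5UTR", splice
    if t > t_cds_hi:
        return "3UTR", splice
    return "CDS", splice


def read_compatible(read: pysam.AlignedSegment, model: TranscriptModel) -> bool:
    """A read is compatible with an isoform when every aligned reference
    base lies within the isoform's exons."""
    blocks = read.get_blocks()
    for bs, be in blocks:
        covered = False
        for es, ee in model.exons:
            if bs >= es and be <= ee:
                covered = True
                break
        if not covered:
            return False
    return True


def dominant_isoform(position: int, strand: str,
                     models: list[TranscriptModel],
                     alignment_path: str, min_mapq: int = 20
                     ) -> TranscriptModel | None:
    """The overlapping isoform compatible with the most reads covering the
    site; ties broken by longest transcript, then lexicographic id.

    Returns None when no annotated transcript overlaps the site.
    """
    overlapping = [m for m in models
                   if m.strand == strand and m.contains(position)]
    if not overlapping:
        return None
    support = {m.transcript_id: 0 for m in overlapping}
    with pysam.AlignmentFile(alignment_path, check_sq=False) as aln:
        for read in aln.fetch(until_eof=True):
            if not filter_alignment(read, min_mapq):
                continue
            if ("-" if read.is_reverse else "+") != strand:
                continue
            if not (read.reference_start <= position < read.reference_end):
                continue
            for m in overlapping:
                if read_compatible(read, m):
                    support[m.transcript_id] += 1
    return sorted(overlapping,
                  key=lambda m: (-support[m.transcript_id], -m.length,
                                 m.transcript_id))[0]


def annotate_calls(calls: list[SiteCall], models: list[TranscriptModel],
                   alignment_path: str, type1_cutoff: float = 0.40,
                   min_mapq: int = 20) -> list[AnnotatedSite]:
    """Attach dominant isoform, region, splice distance, motif and type I
    status to every consensus call.  Calls with no overlapping annotated
    transcript are reported with transcript_id ``unassigned``."""
    annotated = []
    for call in calls:
        if not call.consensus:
            continue
        motif = motif_tag(call.kmer) if call.kmer else "other"
        model = dominant_isoform(call.position, call.strand,
                                 [m for m in models if m.contig == call.contig],
                                 alignment_path, min_mapq)
        if model is None:
            annotated.append(AnnotatedSite(
                call, "unassigned", "unassigned", "noncoding", None, motif,
                classify_type1(call, type1_cutoff)))
            continue
        region, splice = assign_region(call.position, model)
        annotated.append(AnnotatedSite(
            call, model.transcript_id, model.gene_id, region, splice, motif,
            classify_type1(call, type1_cutoff)))
    return annotated


def classify_type2(annotated: list[AnnotatedSite]) -> list[TranscriptSummary]:
    """Group annotated sites by transcript and mark type II transcripts
    (>= 2 unique highly significant positions)."""
    groups: dict[str, TranscriptSummary] = {}
    for site in annotated:
        if site.transcript_id == "unassigned":
            continue
        summ = groups.get(site.transcript_id)
        if summ is None:
            summ = groups[site.transcript_id] = TranscriptSummary(
                site.transcript_id, site.gene_id)
        summ.sites.append(site)
    return [groups[t] for t in sorted(groups)]


def type2_histogram(summaries: list[TranscriptSummary]) -> dict[int, int]:
    """Transcripts binned by number of unique highly significant sites
    (bins with >= 2 sites are the type II transcripts)."""
    hist = collections.Counter(s.n_high_sites for s in summaries
                               if s.n_high_sites >= 1)
    return dict(sorted(hist.items()))


def kmer_frequency(calls: list[SiteCall], tier_filter: str | None = None
                   ) -> list[tuple[str, int, float]]:
    """(kmer, count, fraction) among selected calls, sorted by descending
    count then k-mer.  ``tier_filter`` of 'highly_significant' restricts to
    that tier; None keeps every consensus call."""
    selected = [c.kmer for c in calls if c.consensus and c.kmer
                and (tier_filter is None or c.tier == tier_filter)]
    counts = collections.Counter(selected)
    total = sum(counts.values())
    return [(k, n, n / total)
            for k, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def position_frequency_matrix(calls: list[SiteCall], reference_fasta: str,
                              flank: int = 6) -> np.ndarray:
    """Base counts (rows A,C,G,U) per offset around called sites.

    Columns span offsets -flank..+flank in transcript orientation; the
    center column is all U by construction.  Calls without full flanks on
    the reference are skipped, so every column sums to the same number of
    contributing calls.
    """
    pfm = np.zeros((4, 2 * flank + 1), dtype=int)
    index = {b: i for i, b in enumerate(BASE_ORDER)}
    with pysam.FastaFile(reference_fasta) as ref:
        for call in calls:
            if not call.consensus:
                continue
            length = ref.get_reference_length(call.contig)
            lo, hi = call.position - flank, call.position + flank + 1
            if lo < 0 or hi > length:
                continue
            window = ref.fetch(call.contig, lo, hi).upper()
            if "N" in window:
                continue
            if call.strand == "-":
                window = revcomp(window)
            for col, base in enumerate(to_rna(window)):
                pfm[index[base], col] += 1
    return pfm


def write_annotation(annotated: list[AnnotatedSite],
                     summaries: list[TranscriptSummary],
                     pfm: np.ndarray,
                     kmer_freq: list[tuple[str, int, float]],
                     out_prefix: str) -> None:
    with open(out_prefix + ".annotated.tsv", "w") as fh:
        fh.write("contig\tpos0\tpos1\tstrand\tkmer\ttier\tmerged_mismatch\t"
                 "transcript_id\tgene_id\tregion\tsplice_distance\tmotif\t"
                 "type1\n")
        for a in annotated:
            c = a.call
            splice = "." if a.splice_distance is None else a.splice_distance
            fh.write("\t".join(map(str, [
                c.contig, c.position, c.position + 1, c.strand, c.kmer,
                c.tier, f"{c.merged_mismatch:.6g}", a.transcript_id,
                a.gene_id, a.region, splice, a.motif, int(a.type1)])) + "\n")
    with open(out_prefix + ".transcripts.tsv", "w") as fh:
        fh.write("transcript_id\tgene_id\tn_sites\tn_high_sites\ttype2\n")
        for s in summaries:
            fh.write(f"{s.transcript_id}\t{s.gene_id}\t{len(s.sites)}\t"
                     f"{s.n_high_sites}\t{int(s.type2)}\n")
    hist = type2_histogram(summaries)
    with open(out_prefix + ".type2_histogram.tsv", "w") as fh:
        fh.write("n_high_sites\tn_transcripts\n")
        for n, count in hist.items():
            fh.write(f"{n}\t{count}\n")
    flank = (pfm.shape[1] - 1) // 2
    with open(out_prefix + ".pfm.tsv", "w") as fh:
        fh.write("base\t" + "\t".join(str(o) for o in
                                      range(-flank, flank + 1)) + "\n")
        for i, base in enumerate(BASE_ORDER):
            fh.write(base + "\t" + "\t".join(map(str, pfm[i])) + "\n")
    with open(out_prefix + ".kmer_freq.tsv", "w") as fh:
        fh.write("kmer\tcount\tfraction\n")
        for kmer, n, frac in kmer_freq:
            fh.write(f"{kmer}\t{n}\t{frac:.6g}\n")
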