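"""Truth-labeled synthetic direct/IVT nanopore libraries.

The generator emulates the study conditions of a paired direct / IVT
nanopore run at the basecall level: transcripts with log-normal lengths
(median ~670 nt, length-weighted median ~850 nt, the scale of a poly(A)
nanopore run), 3 direct and 2 IVT replicates, a per-5-mer background U-to-C
error defaulting to the 2.64% transcriptome average with optional k-mer
overrides (e.g. CUUUG ~10%, AAUCU ~0.4%), and truth sites parameterised by
occupancy (fraction of transcript copies modified) and basecaller
efficiency (probability a modified U is miscalled C; measured between ~0.30
and ~0.70 on 100%-occupancy synthetic controls).  A read covering a truth
site calls C with probability

    occupancy * efficiency + (1 - occupancy * efficiency) * background(kmer)

modelled per molecule, so multi-site co-modification statistics are exact.
IVT libraries use the same reference with occupancy forced to zero.

Output is plain SAM plus FASTA/GTF and a truth TSV; every stream is seeded
through per-component substreams, so the whole run is deterministic and
adding replicates does not perturb earlier draws.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pysam

from .annotate import TranscriptModel
from .sequence import revcomp, to_rna

_BASES = np.array(list("ACGT"))

# rng substream tags: keep every component on its own child stream
_STREAM_REFERENCE = 101
_STREAM_DIRECT = 7
_STREAM_IVT = 11


@dataclass
class TruthSite:
    """A planted modification: position in transcript coordinates (None to
    auto-place on a uridine), plus occupancy and miscall efficiency."""

    transcript_id: str
    tpos: int | None = None
    occupancy: float = 1.0
    efficiency: float = 0.7
    kmer: str | None = None     # force this transcript-space 5-mer context


@dataclass
class TruthRecord:
    transcript_id: str
    tpos: int
    contig: str
    position: int               # genomic, 0-based
    strand: str
    kmer: str
    occupancy: float
    efficiency: float
    background: float
    expected_mismatch: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 20
    length_median: float = 670.0
    length_sigma: float = 0.49          # gives length-weighted median ~850
    min_length: int = 200
    max_length: int = 4000
    coverage: int = 50                  # full-length reads per transcript
    n_direct_reps: int = 3
    n_ivt_reps: int = 2
    background_error: float = 0.0264    # transcriptome-average U-to-C error
    kmer_error_profile: dict[str, float] = field(default_factory=dict)
    non_u_mismatch: float = 0.002
    softclip_prob: float = 0.3
    softclip_max: int = 5
    mapq: int = 60
    low_mapq_frac: float = 0.02         # reads demoted below the MAPQ filter
    frac_minus_strand: float = 0.3
    frac_coding: float = 0.8
    exon_count_range: tuple[int, int] = (1, 5)
    coverage_decay_5p: float = 0.0      # prob. a read is 5'-truncated
    plant_kmers: dict[str, int] = field(default_factory=dict)
    truth_sites: list[TruthSite] = field(default_factory=list)

    def validate(self) -> None:
        rates = [self.background_error, self.non_u_mismatch,
                 self.softclip_prob, self.low_mapq_frac,
                 self.frac_minus_strand, self.frac_coding,
                 self.coverage_decay_5p, *self.kmer_error_profile.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        for ts in self.truth_sites:
            if not (0.0 <= ts.occupancy <= 1.0 and 0.0 <= ts.efficiency <= 1.0):
                raise ValueError("occupancy and efficiency must lie in [0, 1]")


@dataclass
class SimulatedReference:
    fasta_path: str
    gtf_path: str
    models: list[TranscriptModel]
    tx_seqs: dict[str, str]             # transcript-space DNA (T for U)
    contig_seqs: dict[str, str]
    truth: list[TruthRecord]

    def model(self, transcript_id: str) -> TranscriptModel:
        for m in self.models:
            if m.transcript_id == transcript_id:
                return m
        raise KeyError(transcript_id)


def _kmer_rate(seq: str, t: int, config: SimulationConfig) -> float:
    if t < 2 or t + 3 > len(seq):
        return config.background_error
    kmer = to_rna(seq[t - 2:t + 3])
    return config.kmer_error_profile.get(kmer, config.background_error)


def _transcript_lengths(config: SimulationConfig, rng) -> np.ndarray:
    raw = rng.lognormal(math.log(config.length_median), config.length_sigma,
                        size=config.n_transcripts)
    return np.clip(raw.astype(int), config.min_length, config.max_length)


def _chain_offset_to_genomic(model: TranscriptModel, lo: int, hi: int
                             ) -> list[tuple[int, int]]:
    """Map a half-open offset interval along the ascending exon chain to
    genomic blocks."""
    blocks = []
    consumed = 0
    for es, ee in model.exons:
        size = ee - es
        s = max(lo, consumed)
        e = min(hi, consumed + size)
        if s < e:
            blocks.append((es + (s - consumed), es + (e - consumed)))
        consumed += size
    return blocks


def transcript_to_genomic(model: TranscriptModel, t: int) -> int:
    """Transcript coordinate -> genomic coordinate (inverse of
    ``TranscriptModel.to_transcript_coord``)."""
    offset = t if model.strand == "+" else model.length - 1 - t
    blocks = _chain_offset_to_genomic(model, offset, offset + 1)
    return blocks[0][0]


def make_reference(config: SimulationConfig, out_dir: str
                   ) -> SimulatedReference:
    """Build the synthetic genome: FASTA (+ .fai) and GTF, one transcript
    per contig with 1-5 exons, CDS annotated for a fraction of transcripts,
    planted k-mer occurrences and truth sites placed clear of exon
    boundaries so genomic and transcript 5-mer contexts agree."""
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_REFERENCE])
    os.makedirs(out_dir, exist_ok=True)
    lengths = _transcript_lengths(config, rng)
    tx_ids = [f"TX{i:04d}" for i in range(config.n_transcripts)]

    # queue of k-mer occurrences, interleaved so each transcript receives a
    # mix; spread across transcripts greedily, overflowing to later ones
    lanes = [[kmer] * n for kmer, n in sorted(config.plant_kmers.items())]
    plant_queue: list[str] = []
    while any(lanes):
        for lane in lanes:
            if lane:
                plant_queue.append(lane.pop())

    truth_by_tx: dict[str, list[TruthSite]] = {}
    for ts in config.truth_sites:
        truth_by_tx.setdefault(ts.transcript_id, []).append(ts)

    models: list[TranscriptModel] = []
    tx_seqs: dict[str, str] = {}
    contig_seqs: dict[str, str] = {}
    truth_records: list[TruthRecord] = []

    for i, tx_id in enumerate(tx_ids):
        L = int(lengths[i])
        contig = f"chrS{i:04d}"
        gene_id = f"GENE{i:04d}"
        strand = "-" if rng.random() < config.frac_minus_strand else "+"

        # exon structure first, so planted features avoid the junctions
        lo, hi = config.exon_count_range
        n_exons = int(rng.integers(lo, hi + 1))
        n_exons = max(1, min(n_exons, L // 80))
        cuts = sorted(rng.choice(np.arange(60, L - 60), size=n_exons - 1,
                                 replace=False).tolist()) if n_exons > 1 else []
        forbidden = set()
        for c in cuts:
            forbidden.update(range(c - 6, c + 6))
        forbidden.update(range(0, 8))
        forbidden.update(range(L - 8, L))

        seq = rng.choice(_BASES, size=L)

        # reserve evenly spaced 5-mer slots for planting, 8 nt apart
        slots = [p for p in range(10, L - 10, 8)
                 if not any(q in forbidden for q in range(p - 2, p + 7))]
        used: set[int] = set()
        remaining_tx = config.n_transcripts - i
        share = math.ceil(len(plant_queue) / remaining_tx)
        n_plant = min(share, len(slots), len(plant_queue))
        for _ in range(n_plant):
            kmer = plant_queue.pop(0)
            p = slots.pop(0)
            seq[p:p + 5] = list(kmer.replace("U", "T"))
            used.update(range(p - 2, p + 7))

        # truth sites: honour requested positions, else auto-place on a U
        placed: list[tuple[TruthSite, int]] = []
        for ts in truth_by_tx.get(tx_id, []):
            if ts.tpos is not None:
                t = ts.tpos
                if not 2 <= t < L - 2:
                    raise ValueError(
                        f"truth site {tx_id}:{t} lacks full 5-mer flanks")
                if ts.kmer is None and seq[t] != "T":
                    raise ValueError(
                        f"truth site {tx_id}:{t} is not on a uridine")
            else:
                candidates = [p for p in range(8, L - 8)
                              if seq[p] == "T" and p not in forbidden
                              and not any(q in used
                                          for q in range(p - 2, p + 3))]
                if not candidates:
                    raise ValueError(f"no placeable uridine left in {tx_id}")
                t = int(rng.choice(candidates))
            if ts.kmer is not None:
                if len(ts.kmer) != 5 or ts.kmer[2] != "U":
                    raise ValueError(f"truth k-mer must be center-U: {ts.kmer}")
                seq[t - 2:t + 3] = list(ts.kmer.replace("U", "T"))
            used.update(range(t - 2, t + 3))
            placed.append((ts, t))
        tx_seq = "".join(seq)
        tx_seqs[tx_id] = tx_seq

        # assemble the genomic contig: pad + exons with random introns
        bounds = [0, *cuts, L]
        chunks = [tx_seq[bounds[j]:bounds[j + 1]] for j in range(n_exons)]
        if strand == "-":
            genomic_chunks = [revcomp(c) for c in reversed(chunks)]
        else:
            genomic_chunks = chunks
        pad = 50
        pieces = ["".join(rng.choice(_BASES, size=pad))]
        exon_intervals: list[tuple[int, int]] = []
        gpos = pad
        for j, chunk in enumerate(genomic_chunks):
            if j > 0:
                intron = int(rng.integers(80, 300))
                pieces.append("".join(rng.choice(_BASES, size=intron)))
                gpos += intron
            pieces.append(chunk)
            exon_intervals.append((gpos, gpos + len(chunk)))
            gpos += len(chunk)
        pieces.append("".join(rng.choice(_BASES, size=pad)))
        contig_seqs[contig] = "".join(pieces)

        model = TranscriptModel(tx_id, gene_id, contig, strand,
                                exon_intervals)
        # CDS: a central transcript interval mapped to genomic coordinates
        if rng.random() < config.frac_coding and L >= 120:
            t_lo, t_hi = int(0.15 * L), int(0.70 * L)
            g_a = transcript_to_genomic(model, t_lo)
            g_b = transcript_to_genomic(model, t_hi - 1)
            model.cds_start, model.cds_end = min(g_a, g_b), max(g_a, g_b) + 1
        models.append(model)

        for ts, t in placed:
            bg = _kmer_rate(tx_seq, t, config)
            eff_occ = ts.occupancy * ts.efficiency
            truth_records.append(TruthRecord(
                transcript_id=tx_id, tpos=t, contig=contig,
                position=transcript_to_genomic(model, t), strand=strand,
                kmer=to_rna(tx_seq[t - 2:t + 3]), occupancy=ts.occupancy,
                efficiency=ts.efficiency, background=bg,
                expected_mismatch=eff_occ + (1 - eff_occ) * bg))

    if plant_queue:
        raise ValueError(
            f"could not place {len(plant_queue)} requested k-mer occurrences; "
            "increase n_transcripts or transcript lengths")

    fasta_path = os.path.join(out_dir, "reference.fa")
    with open(fasta_path, "w") as fh:
        for contig in sorted(contig_seqs):
            fh.write(f">{contig}\n")
            s = contig_seqs[contig]
            for j in range(0, len(s), 60):
                fh.write(s[j:j + 60] + "\n")
    if os.path.exists(fasta_path + ".fai"):
        os.remove(fasta_path + ".fai")
    if contig_seqs:  # faidx rejects an empty FASTA
        pysam.faidx(fasta_path)

    gtf_path = os.path.join(out_dir, "annotation.gtf")
    _write_gtf(models, gtf_path)
    return SimulatedReference(fasta_path, gtf_path, models, tx_seqs,
                              contig_seqs, truth_records)


def _write_gtf(models: list[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            start = min(s for s, _ in m.exons) + 1
            end = max(e for _, e in m.exons)
            fh.write("\t".join(map(str, [
                m.contig, "nanopsi_sim", "transcript", start, end, ".",
                m.strand, ".", attrs])) + "\n")
            for es, ee in m.exons:
                fh.write("\t".join(map(str, [
                    m.contig, "nanopsi_sim", "exon", es + 1, ee, ".",
                    m.strand, ".", attrs])) + "\n")
            if m.is_coding:
                for es, ee in m.exons:
                    s, e = max(es, m.cds_start), min(ee, m.cds_end)
                    if s < e:
                        fh.write("\t".join(map(str, [
                            m.contig, "nanopsi_sim", "CDS", s + 1, e, ".",
                            m.strand, "0", attrs])) + "\n")


def write_truth_table(ref: SimulatedReference, path: str) -> None:
    cols = ["transcript_id", "tpos", "contig", "pos0", "pos1", "strand",
            "kmer", "occupancy", "efficiency", "background",
            "expected_mismatch"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in sorted(ref.truth, key=lambda r: (r.contig, r.position)):
            fh.write("\t".join(map(str, [
                r.transcript_id, r.tpos, r.contig, r.position, r.position + 1,
                r.strand, r.kmer, f"{r.occupancy:g}", f"{r.efficiency:g}",
                f"{r.background:g}", f"{r.expected_mismatch:.6g}"])) + "\n")


def simulate_library(config: SimulationConfig, ref: SimulatedReference,
                     label: str, rep_index: int, out_sam: str,
                     occupancy_override: dict[str, float] | None = None
                     ) -> str:
    """Write one replicate's reads as SAM.  ``label`` is 'direct' or 'ivt';
    IVT libraries force occupancy to zero everywhere (the control is
    re-transcribed from canonical nucleotides), and a nonzero occupancy
    override on an IVT library is an error."""
    if label not in ("direct", "ivt"):
        raise ValueError(f"label must be 'direct' or 'ivt', got {label!r}")
    if label == "ivt" and occupancy_override and any(
            v > 0 for v in occupancy_override.values()):
        raise ValueError("IVT libraries are unmodified; nonzero occupancy "
                         "override is not allowed")
    stream = _STREAM_DIRECT if label == "direct" else _STREAM_IVT
    rng = np.random.default_rng([config.seed, stream, rep_index])

    truth_by_tx: dict[str, list[TruthRecord]] = {}
    for r in ref.truth:
        truth_by_tx.setdefault(r.transcript_id, []).append(r)

    contigs = sorted(ref.contig_seqs)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": len(ref.contig_seqs[c])}
                     for c in contigs]}
    with pysam.AlignmentFile(out_sam, "w", header=header) as out:
        for model in sorted(ref.models, key=lambda m: m.transcript_id):
            _simulate_transcript(config, ref, model, label, rep_index, rng,
                                 truth_by_tx.get(model.transcript_id, []),
                                 occupancy_override, out)
    return out_sam


def _simulate_transcript(config, ref, model, label, rep_index, rng, truth,
                         occupancy_override, out) -> None:
    tx_id = model.transcript_id
    seq = ref.tx_seqs[tx_id]
    L = len(seq)
    u_positions = np.array([t for t, b in enumerate(seq) if b == "T"],
                           dtype=int)
    u_rates = np.array([_kmer_rate(seq, int(t), config)
                        for t in u_positions])
    truth_tpos = {r.tpos: r for r in truth}
    non_u = np.array([t for t in range(L) if seq[t] != "T"], dtype=int)
    tid = out.get_tid(model.contig)

    for n in range(config.coverage):
        start = 0
        if config.coverage_decay_5p and rng.random() < config.coverage_decay_5p:
            start = int(rng.integers(1, max(2, L // 3)))
        end = L
        read_seq = list(seq[start:end])

        # background U-to-C miscalls, k-mer conditioned
        in_read = (u_positions >= start) & (u_positions < end)
        miscall = rng.random(in_read.sum()) < u_rates[in_read]
        for t, m in zip(u_positions[in_read], miscall):
            if m:
                read_seq[t - start] = "C"

        # truth sites: per-molecule modification state, then miscall
        for t, rec in truth_tpos.items():
            if not start <= t < end:
                continue
            occ = rec.occupancy if label == "direct" else 0.0
            if occupancy_override and tx_id in occupancy_override:
                occ = occupancy_override[tx_id] if label == "direct" else 0.0
            modified = rng.random() < occ
            if modified:
                read_seq[t - start] = ("C" if rng.random() < rec.efficiency
                                       else "T")
            else:
                read_seq[t - start] = ("C" if rng.random() < rec.background
                                       else "T")

        # sparse non-U substitution errors
        in_nu = non_u[(non_u >= start) & (non_u < end)]
        n_err = rng.binomial(len(in_nu), config.non_u_mismatch)
        if n_err:
            for t in rng.choice(in_nu, size=n_err, replace=False):
                current = seq[t]
                others = [b for b in "ACGT" if b != current]
                read_seq[t - start] = others[int(rng.integers(3))]

        # orient to the reference plus strand and map to genomic blocks
        tseq = "".join(read_seq)
        if model.strand == "-":
            fwd = revcomp(tseq)
            off_lo, off_hi = L - end, L - start
        else:
            fwd = tseq
            off_lo, off_hi = start, end
        blocks = _chain_offset_to_genomic(model, off_lo, off_hi)

        left_clip = (int(rng.integers(1, config.softclip_max + 1))
                     if rng.random() < config.softclip_prob else 0)
        right_clip = (int(rng.integers(1, config.softclip_max + 1))
                      if rng.random() < config.softclip_prob else 0)
        clip_left_seq = "".join(rng.choice(_BASES, size=left_clip))
        clip_right_seq = "".join(rng.choice(_BASES, size=right_clip))

        cigar = []
        if left_clip:
            cigar.append((4, left_clip))
        for j, (bs, be) in enumerate(blocks):
            if j > 0:
                cigar.append((3, bs - blocks[j - 1][1]))
            cigar.append((0, be - bs))
        if right_clip:
            cigar.append((4, right_clip))

        a = pysam.AlignedSegment()
        a.query_name = f"{label}{rep_index}_{tx_id}_{n}"
        a.query_sequence = clip_left_seq + fwd + clip_right_seq
        a.flag = 16 if model.strand == "-" else 0
        a.reference_id = tid
        a.reference_start = blocks[0][0]
        mapq = config.mapq
        if config.low_mapq_frac and rng.random() < config.low_mapq_frac:
            mapq = 10
        a.mapping_quality = mapq
        a.cigartuples = cigar
        a.query_qualities = pysam.qualitystring_to_array(
            "I" * len(a.query_sequence))
        out.write(a)


def simulate_run(config: SimulationConfig, out_dir: str
                 ) -> tuple[dict, SimulatedReference]:
    """Reference + all replicates + truth table; returns the file layout
    and the in-memory reference (with truth records)."""
    ref = make_reference(config, out_dir)
    layout = {"reference": ref.fasta_path, "annotation": ref.gtf_path,
              "direct": [], "ivt": [],
              "truth": os.path.join(out_dir, "truth.tsv"),
              "config": os.path.join(out_dir, "config.json")}
    for r in range(config.n_direct_reps):
        path = os.path.join(out_dir, f"direct_rep{r + 1}.sam")
        simulate_library(config, ref, "direct", r, path)
        layout["direct"].append(path)
    for r in range(config.n_ivt_reps):
        path = os.path.join(out_dir, f"ivt_rep{r + 1}.sam")
        simulate_library(config, ref, "ivt", r, path)
        layout["ivt"].append(path)
    write_truth_table(ref, layout["truth"])
    with open(layout["config"], "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return layout, ref


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["exon_count_range"] = list(d["exon_count_range"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "exon_count_range" in d:
        d["exon_count_range"] = tuple(d["exon_count_range"])
    if "truth_sites" in d:
        d["truth_sites"] = [TruthSite(**ts) for ts in d["truth_sites"]]
    return SimulationConfig(**d)


def end_to_end_recovery(config: SimulationConfig, workdir: str) -> dict:
    """Run the full pipeline on a simulated dataset and score it against
    the planted truth.

    Reports the null consensus rate (specificity complement) over eligible
    unplanted U sites, sensitivity of the highly-significant tier at truth
    sites, background-rate recovery per planted k-mer, and type I / type II
    classification of the planted configuration.
    """
    from .annotate import (annotate_calls, classify_type2,
                           load_transcript_models)
    from .background import build_kmer_table
    from .counts import build_count_table, merge_replicates
    from .detection import DetectionParams, detect_transcriptome

    layout, ref = simulate_run(config, workdir)
    direct_tables = [
        build_count_table(p, layout["reference"], label="direct",
                          replicate_id=f"rep{i + 1}")
        for i, p in enumerate(layout["direct"])]
    ivt_tables = [
        build_count_table(p, layout["reference"], label="ivt",
                          replicate_id=f"rep{i + 1}")
        for i, p in enumerate(layout["ivt"])]
    params = DetectionParams()
    calls, manifest = detect_transcriptome(direct_tables, ivt_tables,
                                           layout["reference"], params)
    truth_keys = {(r.contig, r.position, r.strand): r for r in ref.truth}
    tested = [c for c in calls if c.p_values]
    null_tested = [c for c in tested if c.key not in truth_keys]
    truth_calls = {c.key: c for c in calls if c.key in truth_keys}

    n_null_consensus = sum(c.consensus for c in null_tested)
    n_truth = len(truth_keys)
    n_truth_high = sum(c.tier == "highly_significant"
                       for c in truth_calls.values())
    n_truth_consensus = sum(c.consensus for c in truth_calls.values())

    ivt_merged = merge_replicates(ivt_tables)
    kmer_table = build_kmer_table(ivt_merged, layout["reference"],
                                  min_site_depth=params.min_depth)
    background_recovery = {}
    for kmer in sorted(config.plant_kmers):
        st = kmer_table.entries.get(kmer)
        truth_rate = config.kmer_error_profile.get(kmer,
                                                   config.background_error)
        if st is None or st.n_reads == 0:
            background_recovery[kmer] = {"truth": truth_rate,
                                         "estimate": None}
            continue
        se = math.sqrt(truth_rate * (1 - truth_rate) / st.n_reads)
        background_recovery[kmer] = {
            "truth": truth_rate, "estimate": st.pooled_error,
            "n_reads": st.n_reads, "n_sites": st.n_sites,
            "z": (st.pooled_error - truth_rate) / se if se else 0.0}

    models = load_transcript_models(layout["annotation"])
    annotated = annotate_calls(calls, models, layout["direct"][0])
    summaries = classify_type2(annotated)
    type1_truth = {k for k, r in truth_keys.items()
                   if r.expected_mismatch > 0.40}
    type1_called = {a.call.key for a in annotated if a.type1}
    type2_truth_tx = {tx for tx in {r.transcript_id for r in ref.truth}
                      if sum(1 for r in ref.truth
                             if r.transcript_id == tx
                             and r.expected_mismatch > 0.1) >= 2}
    type2_called_tx = {s.transcript_id for s in summaries if s.type2}

    return {
        "manifest": manifest,
        "n_null_tested": len(null_tested),
        "n_null_consensus": n_null_consensus,
        "null_consensus_rate": (n_null_consensus / len(null_tested)
                                if null_tested else 0.0),
        "n_truth_sites": n_truth,
        "truth_consensus_rate": n_truth_consensus / n_truth if n_truth else 0.0,
        "truth_high_rate": n_truth_high / n_truth if n_truth else 0.0,
        "background_recovery": background_recovery,
        "type1_truth": sorted(type1_truth),
        "type1_recall": (len(type1_truth & type1_called) / len(type1_truth)
                         if type1_truth else None),
        "type2_truth_transcripts": sorted(type2_truth_tx),
        "type2_recall": (len(type2_truth_tx & type2_called_tx)
                         / len(type2_truth_tx) if type2_truth_tx else None),
        "calls": calls,
        "annotated": annotated,
        "summaries": summaries,
        "layout": layout,
    }
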