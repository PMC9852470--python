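"""Binomial significance of U-to-C mismatch and replicate-consensus calling.

At a site with depth N and N_mm reads calling C, the probability of seeing
at least that much mismatch by basecalling error alone is the binomial upper
tail

    p(N, N_mm, p0) = sum_{k=N_mm}^{N} C(N, k) p0^k (1 - p0)^(N - k)

with p0 the site's expected unmodified error from the IVT control.  A site
is called modified when a quorum of direct replicates (2 of 3 by default)
individually reach p <= 0.01; the highly-significant tier additionally
requires the quorum at p <= 0.001.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

from scipy.stats import binom

from .background import (ExpectedError, KmerErrorTable, build_kmer_table,
                         expected_error, flag_snp)
from .counts import CountTable, SiteCounts, SiteKey, merge_replicates
from .sequence import extract_kmer

import pysam


def binomial_pvalue(N: int, Nmm: int, p0: float) -> float:
    """Upper-tail binomial probability P[X >= Nmm], X ~ Binomial(N, p0).

    Evaluated through the regularized-incomplete-beta survival function, so
    it stays accurate for depths up to ~1e6 (rRNA-scale coverage) and tail
    probabilities far below float underflow of naive term products.
    """
    if not 0 <= Nmm <= N:
        raise ValueError(f"require 0 <= Nmm <= N, got N={N}, Nmm={Nmm}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if Nmm == 0:
        return 1.0
    return float(binom.sf(Nmm - 1, N, p0))


@dataclass
class SiteCall:
    """Per-site verdict across direct replicates."""

    contig: str
    position: int
    strand: str
    kmer: str
    p_values: dict[str, float] = field(default_factory=dict)  # replicate -> p
    consensus: bool = False
    tier: str = "not_significant"   # | 'significant' | 'highly_significant'
    merged_mismatch: float = 0.0
    merged_depth: int = 0
    p0: float = 0.0
    p0_source: str = ""
    snp_flagged: bool = False
    reason: str = ""                # 'low_coverage' when ineligible

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.position, self.strand)


@dataclass
class DetectionParams:
    min_depth: int = 7            # per direct replicate and merged IVT
    p_sig: float = 0.01
    p_high: float = 0.001
    consensus_frac: float = 2 / 3
    snp_min_ivt: float = 0.20
    snp_alpha: float = 0.05

    def required_replicates(self, n_reps: int) -> int:
        return max(1, math.ceil(self.consensus_frac * n_reps))


def call_site(replicate_sites: dict[str, SiteCounts | None],
              exp_err: ExpectedError, params: DetectionParams,
              snp_flagged: bool = False) -> SiteCall:
    """Score one site across direct replicates and apply the consensus rule.

    ``replicate_sites`` maps replicate id to that replicate's SiteCounts
    (None if uncovered).  Eligibility requires depth >= ``params.min_depth``
    in every replicate; the merged-IVT depth requirement is enforced by the
    caller through ``exp_err.ivt_site_depth``.  The tier comes from the
    k-th smallest replicate p-value where k is the consensus quorum, so the
    highly-significant tier needs the full quorum at p <= p_high.
    """
    if not replicate_sites:
        raise ValueError("no direct replicates supplied")
    sites = list(replicate_sites.values())
    some = next(s for s in sites if s is not None)
    call = SiteCall(some.contig, some.position, some.strand, exp_err.kmer,
                    p0=exp_err.p0, p0_source=exp_err.source,
                    snp_flagged=snp_flagged)
    covered = [s for s in sites if s is not None]
    call.merged_depth = sum(s.depth for s in covered)
    if call.merged_depth:
        call.merged_mismatch = (sum(s.count_C for s in covered)
                                / call.merged_depth)
    if any(s is None or s.depth < params.min_depth for s in sites):
        call.reason = "low_coverage"
        return call
    call.p_values = {rep: binomial_pvalue(s.depth, s.count_C, exp_err.p0)
                     for rep, s in replicate_sites.items()}
    k = params.required_replicates(len(replicate_sites))
    ordered = sorted(call.p_values.values())
    kth = ordered[k - 1]
    if snp_flagged:
        call.reason = "snp"
        return call
    call.consensus = kth <= params.p_sig
    if call.consensus:
        call.tier = ("highly_significant" if kth <= params.p_high
                     else "significant")
    return call


def detect_transcriptome(direct_tables: list[CountTable],
                         ivt_tables: list[CountTable],
                         reference_fasta: str,
                         params: DetectionParams | None = None,
                         kmer_table: KmerErrorTable | None = None,
                         ) -> tuple[list[SiteCall], dict]:
    """Score every candidate uridine site and return calls plus a manifest.

    IVT replicates are merged before the background model is built.
    Candidate sites are those covered in at least one direct replicate;
    sites failing the coverage rule (depth >= min_depth in every direct
    replicate and in the merged IVT) are reported with reason
    ``low_coverage``.  Deterministic: calls are ordered by site key.
    """
    if not direct_tables or not ivt_tables:
        raise ValueError("need at least one direct and one IVT count table")
    params = params or DetectionParams()
    ivt_merged = merge_replicates(ivt_tables)
    if kmer_table is None:
        kmer_table = build_kmer_table(ivt_merged, reference_fasta,
                                      min_site_depth=params.min_depth)
    candidates: set[SiteKey] = set()
    for t in direct_tables:
        candidates.update(t.sites)
    calls: list[SiteCall] = []
    with pysam.FastaFile(reference_fasta) as ref:
        for key in sorted(candidates):
            contig, pos, strand = key
            kmer = extract_kmer(ref, contig, pos, strand)
            if kmer is None:
                continue  # no k-mer context (contig edge / ambiguous base)
            ivt_site = ivt_merged.get(key)
            exp = expected_error(kmer, ivt_site, kmer_table,
                                 min_ivt_depth=params.min_depth)
            rep_sites = {t.replicate_id: t.get(key) for t in direct_tables}
            if exp.ivt_site_depth < params.min_depth:
                call = call_site(rep_sites, exp, params)
                call.consensus = False
                call.tier = "not_significant"
                call.p_values = {}
                call.reason = "low_coverage"
            else:
                merged_direct = _merged_site(rep_sites)
                snp = (ivt_site is not None and merged_direct is not None
                       and merged_direct.depth >= params.min_depth
                       and flag_snp(merged_direct, ivt_site,
                                    params.snp_min_ivt, params.snp_alpha))
                call = call_site(rep_sites, exp, params, snp_flagged=snp)
            calls.append(call)
    manifest = _manifest(direct_tables, ivt_tables, params, kmer_table, calls)
    return calls, manifest


def _merged_site(rep_sites: dict[str, SiteCounts | None]) -> SiteCounts | None:
    covered = [s for s in rep_sites.values() if s is not None]
    if not covered:
        return None
    first = covered[0]
    merged = SiteCounts(first.contig, first.position, first.strand)
    for s in covered:
        merged.count_U += s.count_U
        merged.count_C += s.count_C
        merged.count_A += s.count_A
        merged.count_G += s.count_G
        merged.count_del += s.count_del
    return merged


def _table_hash(table: CountTable) -> str:
    h = hashlib.sha256()
    for key in table.sorted_keys():
        s = table.sites[key]
        h.update(repr((key, s.count_U, s.count_C, s.count_A, s.count_G,
                       s.count_del)).encode())
    return h.hexdigest()[:16]


def _manifest(direct_tables, ivt_tables, params, kmer_table, calls) -> dict:
    tested = [c for c in calls if c.p_values]
    return {
        "params": {"min_depth": params.min_depth, "p_sig": params.p_sig,
                   "p_high": params.p_high,
                   "consensus_frac": params.consensus_frac,
                   "snp_min_ivt": params.snp_min_ivt,
                   "snp_alpha": params.snp_alpha},
        "inputs": {
            "direct": [{"replicate": t.replicate_id, "n_sites": len(t.sites),
                        "sha256_16": _table_hash(t)} for t in direct_tables],
            "ivt": [{"replicate": t.replicate_id, "n_sites": len(t.sites),
                     "sha256_16": _table_hash(t)} for t in ivt_tables]},
        "background": {"global_error": kmer_table.global_error,
                       "n_kmers": len(kmer_table.entries),
                       "total_sites": kmer_table.total_sites},
        "n_candidate_sites": len(calls),
        "n_tested_sites": len(tested),
        "n_snp_flagged": sum(c.snp_flagged for c in calls),
        "n_consensus": sum(c.consensus for c in calls),
        "n_significant": sum(c.tier == "significant" for c in calls),
        "n_highly_significant": sum(c.tier == "highly_significant"
                                    for c in calls),
    }


_CALL_COLUMNS = ["contig", "pos0", "pos1", "strand", "kmer", "merged_depth",
                 "merged_mismatch", "p0", "p0_source", "p_values",
                 "consensus", "tier", "snp_flagged", "reason"]


def write_calls(calls: list[SiteCall], out_prefix: str,
                manifest: dict | None = None) -> None:
    """Write calls TSV, SNP TSV, consensus BED and JSON manifest."""
    with open(out_prefix + ".calls.tsv", "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            pv = ";".join(f"{rep}={p:.4g}"
                          for rep, p in sorted(c.p_values.items()))
            fh.write("\t".join(map(str, [
                c.contig, c.position, c.position + 1, c.strand, c.kmer,
                c.merged_depth, f"{c.merged_mismatch:.6g}", f"{c.p0:.6g}",
                c.p0_source, pv or ".", int(c.consensus), c.tier,
                int(c.snp_flagged), c.reason or "."])) + "\n")
    with open(out_prefix + ".snp.tsv", "w") as fh:
        fh.write("contig\tpos0\tpos1\tstrand\tmerged_mismatch\tp0\n")
        for c in calls:
            if c.snp_flagged:
                fh.write(f"{c.contig}\t{c.position}\t{c.position + 1}\t"
                         f"{c.strand}\t{c.merged_mismatch:.6g}\t{c.p0:.6g}\n")
    with open(out_prefix + ".consensus.bed", "w") as fh:
        for c in calls:
            if c.consensus:
                fh.write(f"{c.contig}\t{c.position}\t{c.position + 1}\t"
                         f"{c.kmer}\t{c.merged_mismatch:.4g}\t{c.strand}\n")
    if manifest is not None:
        with open(out_prefix + ".manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
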