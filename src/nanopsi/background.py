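"""Expected unmodified U-to-C error (p0) from the IVT control.

The IVT library is re-transcribed from cDNA with canonical nucleotides, so
any U-to-C mismatch it shows is basecalling error, not modification.  That
error is strongly k-mer dependent (e.g. ~10% in CUUUG, <0.4% in AAUCU), so
the null rate for a site is conditioned on the 5-mer centered on it.  When a
specific position is noisier in IVT than its k-mer average — a local context
or alignment artifact — the site's own IVT error takes precedence:

    p0 = max(k-mer pooled IVT error, site-specific IVT error, floor)

Sites with equivalently high mismatch in IVT and direct libraries are
SNP-like (the base genuinely differs from the reference) and are flagged out
of modification calling.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

import pysam

from .counts import CountTable, SiteCounts
from .sequence import extract_kmer


@dataclass
class KmerStats:
    n_sites: int = 0
    n_reads: int = 0
    n_mismatch: int = 0

    @property
    def pooled_error(self) -> float:
        """Read-weighted error: sum(count_C) / sum(depth) over sites."""
        return self.n_mismatch / self.n_reads if self.n_reads else 0.0


@dataclass
class KmerErrorTable:
    """Per-center-U-5-mer pooled IVT error, with a global pooled fallback."""

    entries: dict[str, KmerStats] = field(default_factory=dict)
    total_sites: int = 0
    total_reads: int = 0
    total_mismatch: int = 0
    min_site_depth: int = 7
    min_kmer_sites: int = 10

    @property
    def global_error(self) -> float:
        return self.total_mismatch / self.total_reads if self.total_reads else 0.0


@dataclass
class ExpectedError:
    """The null mismatch probability p0 for one site and where it came from."""

    p0: float
    source: str                 # 'kmer_avg' | 'site_ivt' | 'global_fallback'
    kmer: str
    ivt_site_error: float = 0.0
    ivt_site_depth: int = 0


def build_kmer_table(ivt_table: CountTable, reference_fasta: str,
                     min_site_depth: int = 7,
                     min_kmer_sites: int = 10) -> KmerErrorTable:
    """Pool IVT counts per centered 5-mer over sites with enough coverage.

    ``ivt_table`` should be the merged IVT replicates.  Sites below
    ``min_site_depth`` reads, near contig ends, or with N in the window are
    excluded.  K-mers backed by fewer than ``min_kmer_sites`` sites remain in
    the table but are bypassed in favour of the global pooled error when a
    p0 is requested.
    """
    if ivt_table.library_label != "ivt":
        raise ValueError(
            f"k-mer table must be built from an IVT library, got "
            f"{ivt_table.library_label!r}")
    if not ivt_table.sites:
        raise ValueError("empty IVT count table")
    table = KmerErrorTable(min_site_depth=min_site_depth,
                           min_kmer_sites=min_kmer_sites)
    with pysam.FastaFile(reference_fasta) as ref:
        for key in ivt_table.sorted_keys():
            s = ivt_table.sites[key]
            if s.depth < min_site_depth:
                continue
            kmer = extract_kmer(ref, s.contig, s.position, s.strand)
            if kmer is None:
                continue
            st = table.entries.setdefault(kmer, KmerStats())
            st.n_sites += 1
            st.n_reads += s.depth
            st.n_mismatch += s.count_C
            table.total_sites += 1
            table.total_reads += s.depth
            table.total_mismatch += s.count_C
    return table


def expected_error(kmer: str, ivt_site: SiteCounts | None,
                   kmer_table: KmerErrorTable,
                   min_ivt_depth: int = 7) -> ExpectedError:
    """p0 for a site: max of the k-mer average and the site's own IVT error.

    A small floor 1/(n_reads + 2) (an add-one-style guard on the pooled
    denominator) keeps p0 strictly positive, so the binomial tail is never
    degenerate when a k-mer happened to show zero mismatches in IVT.
    """
    st = kmer_table.entries.get(kmer)
    if st is not None and st.n_sites >= kmer_table.min_kmer_sites:
        base, floor, source = st.pooled_error, 1.0 / (st.n_reads + 2), "kmer_avg"
    else:
        base = kmer_table.global_error
        floor = 1.0 / (kmer_table.total_reads + 2)
        source = "global_fallback"
    p0 = max(base, floor)
    ivt_err, ivt_depth = 0.0, 0
    if ivt_site is not None:
        ivt_err, ivt_depth = ivt_site.mismatch_frac, ivt_site.depth
        if ivt_depth >= min_ivt_depth and ivt_err > p0:
            p0, source = ivt_err, "site_ivt"
    return ExpectedError(p0=p0, source=source, kmer=kmer,
                         ivt_site_error=ivt_err, ivt_site_depth=ivt_depth)


def flag_snp(direct_site: SiteCounts, ivt_site: SiteCounts,
             snp_min_ivt: float = 0.20, alpha: float = 0.05) -> bool:
    """SNP-like site: high IVT mismatch not distinguishable from direct.

    A genuine reference mismatch (SNP) shows an equivalent U-to-C fraction
    in both libraries, while a modification elevates only the direct one.
    Flag iff the IVT fraction is >= ``snp_min_ivt`` and a two-sided
    two-proportion z-test of direct vs IVT mismatch is non-significant at
    ``alpha``.  Flagged sites are excluded from modification calling.
    """
    if ivt_site.mismatch_frac < snp_min_ivt:
        return False
    count = np.array([direct_site.count_C, ivt_site.count_C])
    nobs = np.array([direct_site.depth, ivt_site.depth])
    if nobs.min() == 0:
        return False
    if count[0] == count[1] and nobs[0] == nobs[1]:
        return True  # identical proportions: z = 0 by construction
    _, pvalue = proportions_ztest(count, nobs)
    if np.isnan(pvalue):  # degenerate pooled proportion (0 or 1 everywhere)
        return True
    return bool(pvalue >= alpha)


_KMER_COLUMNS = ["kmer", "n_sites", "n_reads", "n_mismatch", "pooled_error"]


def write_kmer_table(table: KmerErrorTable, path: str) -> None:
    """TSV with one row per 5-mer; parameters and global error in a JSON header."""
    header = {"global_error": table.global_error,
              "total_sites": table.total_sites,
              "total_reads": table.total_reads,
              "total_mismatch": table.total_mismatch,
              "min_site_depth": table.min_site_depth,
              "min_kmer_sites": table.min_kmer_sites}
    with open(path, "w", newline="") as fh:
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_KMER_COLUMNS)
        for kmer in sorted(table.entries):
            st = table.entries[kmer]
            w.writerow([kmer, st.n_sites, st.n_reads, st.n_mismatch,
                        f"{st.pooled_error:.6g}"])


def read_kmer_table(path: str) -> KmerErrorTable:
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing k-mer table JSON header")
        header = json.loads(first[1:])
        rows = list(csv.reader(fh, delimiter="\t"))
    table = KmerErrorTable(
        total_sites=header["total_sites"], total_reads=header["total_reads"],
        total_mismatch=header["total_mismatch"],
        min_site_depth=header["min_site_depth"],
        min_kmer_sites=header["min_kmer_sites"])
    for row in rows[1:]:
        table.entries[row[0]] = KmerStats(
            n_sites=int(row[1]), n_reads=int(row[2]), n_mismatch=int(row[3]))
    return table
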