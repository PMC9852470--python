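"""Single-molecule co-modification of multi-site transcripts.

Long direct RNA reads span multiple called sites of the same transcript, so
the per-read base calls at each site form a read x site matrix from which
co-modification on the same molecule can be quantified: the fraction of
reads covering two sites that call C at both.  For independently modified
sites this converges to the product of the marginal C fractions among
co-covering reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam
from scipy.stats import linregress

from .counts import SiteKey, filter_alignment, mask_clip_adjacent


@dataclass
class ReadSiteMatrix:
    """Per-read call (C / U / other / uncovered) at each site of one
    transcript.  Reads covering no site are excluded."""

    transcript_id: str
    sites: list[SiteKey]
    reads: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def column_counts(self, site_index: int) -> dict[str, int]:
        counts = {"C": 0, "U": 0, "other": 0, "uncovered": 0}
        for _, calls in self.reads:
            counts[calls[site_index]] += 1
        return counts


def build_matrix(alignment_path: str, sites: list[SiteKey],
                 transcript_id: str = "", min_mapq: int = 20,
                 n_mask: int = 3) -> ReadSiteMatrix:
    """Per-read calls at the given sites, under the same read filters as
    the pileup counts (primary, MAPQ, clip-adjacent mask).

    A site is ``uncovered`` for a read whose alignment does not span it or
    where it falls in the clip-adjacent mask; a deletion or an A/G call is
    ``other``.  All sites must share one strand (one transcript).
    """
    if len(sites) < 2:
        raise ValueError("need at least two sites for a read-site matrix")
    strands = {s for _, _, s in sites}
    if len(strands) > 1:
        raise ValueError(f"sites on mixed strands: {sorted(strands)}")
    strand = strands.pop()
    contigs = {c for c, _, _ in sites}
    positions = {(c, p) for c, p, _ in sites}
    matrix = ReadSiteMatrix(transcript_id, list(sites))
    with pysam.AlignmentFile(alignment_path, check_sq=False) as aln:
        for read in aln.fetch(until_eof=True):
            if not filter_alignment(read, min_mapq):
                continue
            if ("-" if read.is_reverse else "+") != strand:
                continue
            if read.reference_name not in contigs:
                continue
            masked = mask_clip_adjacent(read, n_mask)
            observed: dict[tuple[str, int], str] = {}
            qseq = read.query_sequence
            for qpos, rpos, op in read.get_aligned_pairs(with_cigar=True):
                if rpos is None or op == 3:   # insertion / spliced intron
                    continue
                key = (read.reference_name, rpos)
                if key not in positions or rpos in masked:
                    continue
                if qpos is None:
                    observed[key] = "other"  # deletion over the site
                    continue
                base = qseq[qpos].upper()
                if strand == "-":
                    base = {"A": "T", "C": "G", "G": "C",
                            "T": "A", "N": "N"}[base]
                observed[key] = {"T": "U", "C": "C"}.get(base, "other")
            calls = tuple(observed.get((c, p), "uncovered")
                          for c, p, _ in sites)
            if all(call == "uncovered" for call in calls):
                continue
            matrix.reads.append((read.query_name, calls))
    return matrix


def comod_fraction(matrix: ReadSiteMatrix, site_i: int, site_j: int
                   ) -> dict | None:
    """Joint and marginal C fractions among reads covering both sites.

    Denominators count every co-covering read regardless of call, matching
    the pileup mismatch_frac convention.  Returns None when no read covers
    both sites.
    """
    both_c = 0
    c_i = c_j = 0
    n = 0
    for _, calls in matrix.reads:
        if calls[site_i] == "uncovered" or calls[site_j] == "uncovered":
            continue
        n += 1
        ci = calls[site_i] == "C"
        cj = calls[site_j] == "C"
        c_i += ci
        c_j += cj
        both_c += ci and cj
    if n == 0:
        return None
    return {"n_cocover": n, "comod_fraction": both_c / n,
            "marginal_i": c_i / n, "marginal_j": c_j / n,
            "n_both_c": both_c}


def pairwise_mismatch_correlation(pairs: list[tuple[float, float]]
                                  ) -> float | None:
    """R^2 of ordinary least squares between position-1 (5'-most) and
    position-2 merged mismatch fractions across two-site transcripts.

    Returns None for fewer than 3 transcripts or degenerate (zero-variance)
    input.
    """
    if len(pairs) < 3:
        return None
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return None
    result = linregress(x, y)
    return float(result.rvalue ** 2)


def write_pair_stats(rows: list[dict], path: str) -> None:
    """Pair-statistics TSV: one row per site pair of a type II transcript."""
    cols = ["transcript_id", "site_i", "site_j", "n_cocover", "marginal_i",
            "marginal_j", "comod_fraction"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_matrix(matrix: ReadSiteMatrix, path: str) -> None:
    with open(path, "w") as fh:
        header = ["read_id"] + [f"{c}:{p + 1}:{s}" for c, p, s in matrix.sites]
        fh.write("\t".join(header) + "\n")
        for read_id, calls in matrix.reads:
            fh.write(read_id + "\t" + "\t".join(calls) + "\n")
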