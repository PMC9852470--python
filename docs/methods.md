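# Methods

## The detection model

Direct RNA nanopore reads retain base modifications, and the basecaller
translates ψ (and some other uridine modifications) into a U-to-C mismatch
against the reference. The caller treats each reference uridine site —
identified strand-aware, a plus-strand T or minus-strand A, with all counts
recorded in transcript space — as an independent binomial experiment:
given depth `N`, mismatch count `N_mm` and a null error rate `p0`, the
site's p-value is the exact binomial upper tail `P[X >= N_mm]`,
`X ~ Binomial(N, p0)`, evaluated through the regularized incomplete beta
(scipy's survival function) so it is stable for depths up to ~10^6 and
p-values far into the underflow region. The test suite pins this against
exact rational enumeration at 1e-12 relative tolerance for all depths up
to 200.

`p0` comes from the IVT control, which contains only canonical
nucleotides, so its U-to-C mismatch is pure basecalling error. Because
that error is strongly context dependent, IVT sites with at least 7 reads
are pooled by the 5-mer centered on the uridine (read-weighted:
`sum(C) / sum(depth)`, which matches the per-read binomial interpretation
and is robust at low-coverage sites). The null for a site is then

    p0 = max(k-mer pooled error, site-specific IVT error, floor)

The site-specific term guards against locally noisy positions that are
noisier than their k-mer average; the max rule means a site must beat the
worst applicable null. K-mers backed by fewer than `min_kmer_sites = 10`
sites fall back to the global pooled error. The floor, `1/(n_reads + 2)`
on the pooled denominator (an add-one-style guard), keeps `p0 > 0` so a
k-mer that happened to show zero IVT mismatches cannot produce p = 0
artifacts.

### Replicate consensus and tiers

Each direct replicate is scored separately; a site is called when at least
`ceil(2/3 * R)` replicates reach `p <= 0.01` (2 of 3 for the default three
replicates, 2 of 2, 1 of 1). The tier is derived from the k-th smallest
replicate p-value where k is the quorum size — so "highly significant"
(`p <= 0.001`) requires the full quorum at the stricter threshold, keeping
tiers monotone with the consensus rule. Whether the stricter tier should
require all replicates or only the quorum is genuinely open; the quorum
rule is this package's declared choice. Thresholds are inclusive (`<=`).
No multiple-testing correction is applied — the cutoffs are reported raw,
and the manifest records the number of tested sites so users can correct
downstream.

### Eligibility, filters and SNP handling

Only primary alignments with MAPQ >= 20 contribute. The first/last three
aligned bases adjacent to a soft- or hard-clipped read end are masked
(clip-adjacent bases carry degraded base quality); hard clips trigger the
same mask because the clipped sequence is equally absent. A site is
eligible when every direct replicate and the merged IVT have depth >= 7.
Deletions count toward depth but never toward the mismatch (a deleted base
is evidence of sequencing, not of C); insertions and read-space N calls
are ignored; reference N positions are skipped while soft-masked lowercase
is treated as valid sequence. Base quality is not used as a per-base
filter.

SNP-like sites — a genuine reference mismatch shows the same elevated
C fraction in both libraries — are flagged when the IVT fraction is
>= 0.20 and a two-sided two-proportion z-test of direct vs IVT mismatch is
non-significant at alpha = 0.05, and are excluded from calling. The
threshold-plus-z-test form is this package's concrete rule for the
"equivalent mismatch in both libraries" principle; with the max-rule p0,
SNP sites are additionally self-suppressed.

## Classification and annotation

- **Type I hypermodification**: merged direct mismatch strictly above
  0.40. The cutoff reflects measured under-calling: synthetic
  100%-occupancy controls read back at roughly 30–70% mismatch depending
  on context, so >40% conservatively captures >= 50% occupancy. For the
  same reason the caller is semi-quantitative and deliberately does not
  estimate absolute occupancy.
- **Type II hypermodification**: a transcript with >= 2 unique highly
  significant positions, counted per dominant isoform (grouping records
  both transcript and gene ids).
- **Motifs**: UGUAG tags PUS7, GUUCN tags TRUB1, everything else "other".
- **Regions**: sites are placed on 5'UTR/CDS/3'UTR by comparing transcript
  coordinates with the CDS bounds of the dominant isoform; non-coding
  transcripts report "noncoding". Splice distance is the minimum distance
  in spliced (transcript) coordinates to an exon–exon junction — UTR and
  CDS lengths are spliced quantities, so genomic distance would be the
  wrong ruler — and is absent for single-exon transcripts. Intronic
  assignments raise an error, since direct RNA reads are spliced.
- **Dominant isoform**: among annotated isoforms overlapping a site, the
  one compatible (every aligned block inside its exons) with the most
  site-covering reads wins; ties break to the longest transcript, then
  lexicographic id. This is a deliberate simplification of full isoform
  inference; externally computed read-to-isoform assignments can be
  supplied instead by restricting the models passed in.
- The position-frequency matrix (4 x 13 by default, offsets -6..+6 in
  transcript orientation) is the motif deliverable; no logo rendering.

## Single-molecule co-modification

For multi-site transcripts, reads passing the same filters as the pileup
are tabulated per site as C / U / other / uncovered. The co-modification
fraction of a site pair is `#reads C at both / #reads covering both`; the
denominator counts all co-covering reads regardless of call, matching the
pileup mismatch convention. Position 1 is the 5'-most site. Across
two-site transcripts, the R² between position-1 and position-2 merged
mismatch comes from ordinary least squares; fewer than 3 transcripts or
zero variance report it as absent.

## The synthetic-data generator

The generator writes plain SAM/FASTA/GTF plus a truth table and emulates,
at the basecall level, the features the method is sensitive to:

- **Transcripts**: log-normal lengths (median 670 nt, sigma 0.49, chosen
  so the length-weighted median is ~850 nt, the scale of a poly(A)
  nanopore run), 1–5 exons with random introns, 80% coding, 30% on the
  minus strand, one transcript per synthetic contig.
- **Background error**: each unmodified U is miscalled C with a rate
  looked up by its centered 5-mer; default 0.0264 everywhere, with
  per-k-mer overrides (the tests use 0.004 / 0.0264 / 0.10, spanning the
  observed best-to-worst k-mer range). Non-U positions get a small 0.002
  substitution rate.
- **Truth sites**: a read covering a planted site represents a modified
  molecule with probability `occupancy`; a modified U is miscalled C with
  probability `efficiency` (default 0.7, within the measured 0.30–0.70
  under-calling range). Expected mismatch is therefore
  `occ*eff + (1 - occ*eff) * background`, and the per-molecule simulation
  makes multi-site co-modification exact.
- **Read artefacts**: random soft clips (30% per end, 1–5 nt), a small
  fraction of low-MAPQ reads, optional 5'-truncation to mimic 5' coverage
  decay. Reads are otherwise full length, which makes per-site depth equal
  the configured coverage and keeps power/type-I analyses analytic.
- **Determinism**: every stream derives from `(seed, component, replicate)`
  substreams, so outputs are byte-identical under a fixed seed and adding
  replicates does not perturb earlier ones.

Not emulated: signal-space behaviour, homopolymer-specific error,
realistic quality strings, inter-site interference from densely clustered
modifications (the effect that makes rRNA a poor benchmark), alignment
errors, and library-size imbalance. Passing tests therefore demonstrate
the statistical machinery — background recovery, error control, power,
classification, co-modification laws — under the stated error model, not
basecaller-specific biases on real signal.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: ~5–14 transcripts
(200–900 nt) per scenario, coverage 50 (2000 for co-modification
convergence), 3 direct + 2 IVT replicates — enough for >= 500 null sites,
>= 200 sites per planted k-mer and tight binomial standard errors, while
keeping the whole suite under a minute of simulation time. Acceptance
checks are property-based (error control <= 0.02 at the nominal 0.01
threshold, power >= 0.95, estimates within 3 binomial SEs, R² < 0.05)
rather than pinned to any particular sequencing run.

Coordinates are 0-based half-open internally; TSVs add a 1-based column.
Ties at the p thresholds are inclusive. Degenerate inputs (empty overlap,
zero co-covering reads, zero-variance regression) return empty/absent
results rather than raising.
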