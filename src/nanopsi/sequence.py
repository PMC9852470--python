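"""Small sequence helpers shared across modules.

All internal sequence handling is in DNA letters (T, not U); k-mers exposed
to users are printed in transcript space (RNA letters, U for T), read 5'->3'
on the transcribed strand.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet (T becomes U), uppercased."""
    return seq.upper().replace("T", "U")


def extract_kmer(reference, contig: str, position: int, strand: str,
                 flank: int = 2) -> str | None:
    """Centered (2*flank+1)-mer around a uridine site, in transcript space.

    ``reference`` is a :class:`pysam.FastaFile`.  ``position`` is 0-based on
    the plus strand.  For a minus-strand site the window is reverse
    complemented so the k-mer reads 5'->3' along the transcript.  Returns
    ``None`` when the site sits within ``flank`` nt of a contig end or any
    window base is N — such sites cannot be conditioned on their k-mer and
    are skipped upstream.

    Raises ``ValueError`` if the centered base is not U in transcript space
    (a T on the plus strand for ``strand == '+'``, an A for ``'-'``):
    callers are expected to pass uridine sites only.
    """
    length = reference.get_reference_length(contig)
    if position < flank or position + flank + 1 > length:
        return None
    window = reference.fetch(contig, position - flank, position + flank + 1)
    window = window.upper()
    if "N" in window:
        return None
    center = window[flank]
    if strand == "+":
        if center != "T":
            raise ValueError(
                f"{contig}:{position}(+) reference base {center!r} is not T")
        return to_rna(window)
    if center != "A":
        raise ValueError(
            f"{contig}:{position}(-) reference base {center!r} is not A")
    return to_rna(revcomp(window))
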