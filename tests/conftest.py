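"""Shared fixtures: tiny hand-written references and SAM files, built
programmatically so the repository carries no binary data."""

from __future__ import annotations

import pysam
import pytest


def write_fasta(path, contigs: dict[str, str]) -> str:
    path = str(path)
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    pysam.faidx(path)
    return path


def write_sam(path, contigs: dict[str, str], reads: list[dict]) -> str:
    """Reads: dicts with name, flag, contig, pos (0-based), mapq, cigar
    (string), seq."""
    path = str(path)
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": n, "LN": len(s)} for n, s in contigs.items()]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r["name"]
            a.flag = r.get("flag", 0)
            a.reference_id = list(contigs).index(r["contig"])
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = r["cigar"]
            a.query_sequence = r["seq"]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
            out.write(a)
    return path


@pytest.fixture()
def toy_contig() -> dict[str, str]:
    #            0         1         2         3
    #            0123456789012345678901234567890123456789
    return {"c1": "ACGTTCAGGATTACAGCTAGTTCAGACGTACGTAACGTAG"}


@pytest.fixture()
def toy_reference(tmp_path, toy_contig):
    return write_fasta(tmp_path / "ref.fa", toy_contig)
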