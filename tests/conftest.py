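"""Shared test helpers: small fragment libraries and a SAM text fixture."""

from __future__ import annotations

import numpy as np
import pytest

from cffrag.io import FragmentRecord, SampleLibrary


def make_lib(intervals, sample_id="s", group="", **record_kwargs) -> SampleLibrary:
    """Build a SampleLibrary from (chrom, start, end[, strand]) tuples."""
    records = []
    for iv in intervals:
        if len(iv) == 4:
            chrom, start, end, strand = iv
            records.append(
                FragmentRecord(chrom, start, end, strand=strand, **record_kwargs)
            )
        else:
            chrom, start, end = iv
            records.append(FragmentRecord(chrom, start, end, **record_kwargs))
    return SampleLibrary(sample_id=sample_id, group=group, records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SAM_HEADER = (
    "@HD\tVN:1.6\tSO:coordinate\n"
    "@SQ\tSN:chr1\tLN:100000\n"
    "@SQ\tSN:chrM\tLN:16000\n"
    "@SQ\tSN:chrX\tLN:100000\n"
)


def sam_pair(qname, chrom, pos, mate_pos, tlen, mapq=60, flag_extra=0, cigar=None):
    """Two SAM lines for a properly-paired fragment (1-based pos)."""
    n = abs(tlen) - abs(mate_pos - pos) if cigar is None else None
    read_len = 50
    cigar = cigar or f"{read_len}M"
    f1 = 0x1 | 0x2 | 0x20 | 0x40 | flag_extra  # paired, proper, mate rev, first
    f2 = 0x1 | 0x2 | 0x10 | 0x80 | flag_extra  # paired, proper, rev, second
    seq = "A" * read_len
    qual = "I" * read_len
    line1 = (
        f"{qname}\t{f1}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t=\t{mate_pos}\t{tlen}\t{seq}\t{qual}"
    )
    line2 = (
        f"{qname}\t{f2}\t{chrom}\t{mate_pos}\t{mapq}\t{cigar}\t=\t{pos}\t{-tlen}\t{seq}\t{qual}"
    )
    return line1 + "\n" + line2 + "\n"


@pytest.fixture
def sam_text():
    """A small SAM file body: one clean pair, one chrM pair, one MAPQ-0 pair,
    one duplicate pair, one soft-clipped pair."""
    body = SAM_HEADER
    body += sam_pair("clean", "chr1", 101, 221, 170)
    body += sam_pair("mito", "chrM", 11, 101, 140)
    body += sam_pair("mapq0", "chr1", 501, 601, 150, mapq=0)
    body += sam_pair("dup", "chr1", 901, 1001, 150, flag_extra=0x400)
    body += sam_pair("clipped", "chr1", 2001, 2101, 150, cigar="30S20M")
    return body
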