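"""Reading, filtering, downsampling and masking of cfDNA fragment libraries.

A fragment is a genomic interval (0-based half-open, BED dialect) obtained
from a sequenced cfDNA molecule. Libraries are read either from a BED3+ file
(chrom, start, end, name, mapq, strand, duplicate-flag[, clipped_bases]) or
from a coordinate-sorted paired-end BAM/SAM, where a properly paired mate
pair collapses to one fragment interval (leftmost start to rightmost end).

The standard processing applied to plasma cfDNA libraries before any
downstream statistic: drop mitochondrial and sex-chromosome fragments, drop
MAPQ-0 alignments, drop PCR/optical duplicates, keep soft-clipped fragments
only when the aligned span is long enough to be informative, and optionally
downsample every sample to a common depth so per-bin counts are comparable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FragmentRecord",
    "SampleLibrary",
    "read_fragments",
    "write_fragments",
    "filter_fragments",
    "downsample",
    "mask_fragments",
    "MITO_NAMES",
    "SEX_NAMES",
]

MITO_NAMES = frozenset({"chrM", "MT", "M"})
SEX_NAMES = frozenset({"chrX", "X", "chrY", "Y"})


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced cfDNA fragment as a genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    mapq: int = 60
    strand: str = "+"
    duplicate: bool = False
    clipped_bases: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"fragment end must exceed start: {self}")
        if self.mapq < 0 or self.clipped_bases < 0:
            raise ValueError("mapq and clipped_bases must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SampleLibrary:
    """An ordered fragment collection for one sample."""

    sample_id: str
    group: str = ""
    records: list[FragmentRecord] = field(default_factory=list)
    warnings: int = 0  # records rejected while parsing

    @property
    def library_size(self) -> int:
        return len(self.records)

    def starts(self) -> np.ndarray:
        return np.fromiter((r.start for r in self.records), dtype=np.int64)

    def ends(self) -> np.ndarray:
        return np.fromiter((r.end for r in self.records), dtype=np.int64)

    def midpoints(self) -> np.ndarray:
        return np.fromiter((r.midpoint for r in self.records), dtype=np.int64)


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_bed_line(line: str, lineno: int) -> FragmentRecord | None:
    fields = line.split()
    if len(fields) < 3:
        raise ValueError(f"malformed BED line {lineno}: expected >=3 fields")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"malformed BED line {lineno}: {exc}") from exc
    name = fields[3] if len(fields) > 3 else "."
    mapq = int(fields[4]) if len(fields) > 4 else 60
    strand = fields[5] if len(fields) > 5 else "+"
    dup = bool(int(fields[6])) if len(fields) > 6 else False
    clipped = int(fields[7]) if len(fields) > 7 else 0
    if end <= start:
        return None
    return FragmentRecord(fields[0], start, end, name, mapq, strand, dup, clipped)


def read_fragments(
    path: str | Path, fmt: str | None = None, sample_id: str | None = None
) -> SampleLibrary:
    """Read a fragment library from BED3+ (optionally gzipped) or BAM/SAM.

    Records with ``end <= start`` are rejected and counted in
    ``SampleLibrary.warnings``; structurally malformed lines raise with the
    line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.name.lower()
        fmt = "bam" if suffix.endswith((".bam", ".sam", ".cram")) else "bed"
    sample_id = sample_id or path.stem.replace(".bed", "")
    lib = SampleLibrary(sample_id=sample_id)
    if fmt == "bed":
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                rec = _parse_bed_line(line, lineno)
                if rec is None:
                    lib.warnings += 1
                else:
                    lib.records.append(rec)
    elif fmt == "bam":
        lib = _read_bam(path, sample_id)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    return lib


def _read_bam(path: Path, sample_id: str) -> SampleLibrary:
    import pysam

    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    lib = SampleLibrary(sample_id=sample_id)
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam.fetch(until_eof=True):
            # collapse each properly paired template to one fragment,
            # emitted once from the leftmost mate
            if (
                read.is_unmapped
                or not read.is_proper_pair
                or read.is_supplementary
                or read.is_secondary
                or read.template_length <= 0
            ):
                continue
            start = read.reference_start
            end = start + read.template_length
            if end <= start:
                lib.warnings += 1
                continue
            clipped = sum(
                n for op, n in (read.cigartuples or []) if op in (4, 5)
            )
            lib.records.append(
                FragmentRecord(
                    chrom=read.reference_name,
                    start=start,
                    end=end,
                    name=read.query_name or ".",
                    mapq=read.mapping_quality,
                    strand="-" if read.is_reverse else "+",
                    duplicate=read.is_duplicate,
                    clipped_bases=clipped,
                )
            )
    return lib


def write_fragments(lib: SampleLibrary, path: str | Path) -> None:
    """Write a library as BED3+ with name/mapq/strand/dup/clipped columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in lib.records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.mapq}\t"
                f"{r.strand}\t{int(r.duplicate)}\t{r.clipped_bases}\n"
            )


def deduplicate_coordinates(lib: SampleLibrary) -> SampleLibrary:
    """Collapse records sharing (chrom, start, end, strand) to one record.

    Used for BED input that carries no duplicate flags; mirrors
    coordinate-based duplicate marking of aligned libraries.
    """
    seen: set[tuple] = set()
    kept = []
    for r in lib.records:
        key = (r.chrom, r.start, r.end, r.strand)
        if key in seen:
            continue
        seen.add(key)
        kept.append(r)
    return replace_records(lib, kept)


def replace_records(
    lib: SampleLibrary, records: list[FragmentRecord]
) -> SampleLibrary:
    return SampleLibrary(
        sample_id=lib.sample_id, group=lib.group, records=records, warnings=lib.warnings
    )


def filter_fragments(lib: SampleLibrary, min_aligned: int = 75) -> SampleLibrary:
    """Apply the standard cfDNA read filters.

    Removes fragments on mitochondrial and sex chromosomes, MAPQ-0 and
    duplicate-flagged fragments; soft-clipped fragments are retained only when
    their aligned span is at least ``min_aligned`` bp.
    """
    kept = []
    for r in lib.records:
        if r.chrom in MITO_NAMES or r.chrom in SEX_NAMES:
            continue
        if r.mapq == 0 or r.duplicate:
            continue
        if r.clipped_bases > 0 and r.length < min_aligned:
            continue
        kept.append(r)
    return replace_records(lib, kept)


def downsample(lib: SampleLibrary, n: int, seed: int = 0) -> SampleLibrary:
    """Uniform sampling of exactly ``n`` fragments without replacement,
    preserving the original record order."""
    if n < 0 or n > lib.library_size:
        raise ValueError(
            f"cannot downsample {lib.library_size} fragments to {n}"
        )
    if n == lib.library_size:
        return replace_records(lib, list(lib.records))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(lib.library_size, size=n, replace=False))
    return replace_records(lib, [lib.records[i] for i in idx])


def mask_fragments(
    lib: SampleLibrary, intervals: list[tuple[str, int, int]]
) -> SampleLibrary:
    """Remove fragments whose midpoint falls inside any half-open interval.

    Typical use: masking ±1,500 bp around every TSS and TTS before re-running
    a genome-wide bin analysis, to show promoter/terminator-local losses do
    not drive compartment-level signal shifts.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out: list[list[int]] = []
        for s, e in ivals:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (
            np.array([s for s, _ in out], dtype=np.int64),
            np.array([e for _, e in out], dtype=np.int64),
        )
    kept = []
    for r in lib.records:
        ms = merged.get(r.chrom)
        if ms is None:
            kept.append(r)
            continue
        starts, ends = ms
        i = int(np.searchsorted(starts, r.midpoint, side="right")) - 1
        if i >= 0 and r.midpoint < ends[i]:
            continue  # midpoint inside a masked interval
        kept.append(r)
    return replace_records(lib, kept)

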