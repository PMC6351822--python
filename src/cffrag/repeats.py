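"""Coverage of cfDNA fragments on repeat-element consensus sequences.

Young retrotransposon subfamilies (L1HS, AluY) exist as many near-identical
genomic copies; coverage is therefore accumulated in *consensus* coordinates.
Uniquely mapped fragments are projected from each genomic copy onto the
consensus and averaged over the copies that reach each consensus position;
multi-mapped fragments, which arrive already expressed in consensus
coordinates with a set of candidate subfamilies, contribute fractionally
(1/k for k candidate subfamilies). The combined profile is the sum of the
two components scaled to fragments-per-million library size, which makes the
5' promoter region of L1HS (first ~668 bp) and dimeric AluY copies
(280–320 bp) directly comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SampleLibrary

__all__ = [
    "RepeatElement",
    "MultiMapRecord",
    "ConsensusProfile",
    "project_to_consensus",
    "unique_profile",
    "multimap_profile",
    "combine_normalize",
    "dimeric_alu_filter",
    "region_mean",
    "mean_profiles",
    "read_repeat_bed",
    "write_repeat_bed",
]


@dataclass(frozen=True, slots=True)
class RepeatElement:
    """One genomic copy of a repeat family, aligned to its consensus."""

    family: str
    chrom: str
    start: int
    end: int
    strand: str
    consensus_offset: int = 0
    consensus_length: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("element end must exceed start")
        if self.consensus_offset < 0:
            raise ValueError("consensus_offset must be >= 0")
        if self.end - self.start > self.consensus_length - self.consensus_offset:
            raise ValueError(
                "element longer than remaining consensus "
                f"({self.family} {self.chrom}:{self.start}-{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MultiMapRecord:
    """A fragment interval already placed on a consensus, with the set of
    candidate subfamilies it aligned to (k >= 1)."""

    start: int
    end: int
    families: frozenset[str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("record end must exceed start")
        if len(self.families) < 1:
            raise ValueError("multi-map record needs >= 1 candidate subfamily")

    @property
    def k(self) -> int:
        return len(self.families)


@dataclass
class ConsensusProfile:
    """Per-position consensus coverage: unique, multi-mapped and combined."""

    family: str
    unique: np.ndarray
    multi: np.ndarray
    combined: np.ndarray  # (unique + multi) * 1e6 / library_size
    library_size: int

    def __len__(self) -> int:
        return self.combined.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(self.combined.size),
                "unique": self.unique,
                "multi": self.multi,
                "combined": self.combined,
            }
        )


def project_to_consensus(
    interval: tuple[int, int], element: RepeatElement
) -> tuple[int, int] | None:
    """Map a genomic interval onto consensus coordinates of ``element``.

    Plus strand: consensus = offset + (g - start); minus strand: the element
    is reverse-complemented relative to the consensus, so consensus =
    offset + (end - 1 - g). Returns the half-open consensus interval of the
    overlap, or None when the interval misses the element.
    """
    g_lo = max(interval[0], element.start)
    g_hi = min(interval[1], element.end)
    if g_hi <= g_lo:
        return None
    off = element.consensus_offset
    if element.strand == "-":
        lo = off + (element.end - g_hi)
        hi = off + (element.end - g_lo)
    else:
        lo = off + (g_lo - element.start)
        hi = off + (g_hi - element.start)
    return lo, hi


def _consensus_length(elements: list[RepeatElement]) -> int:
    lengths = {e.consensus_length for e in elements}
    if len(lengths) != 1:
        raise ValueError("elements disagree on consensus length")
    return lengths.pop()


def unique_profile(lib: SampleLibrary, elements: list[RepeatElement]) -> np.ndarray:
    """Average per-position consensus coverage from uniquely mapped fragments.

    Every fragment increments each consensus position it projects onto; the
    per-position total is divided by the number of element copies whose
    projection reaches that position (so 5'-truncated copies do not dilute
    positions they lack).
    """
    if not elements:
        raise ValueError("need at least one element")
    clen = _consensus_length(elements)
    cov = np.zeros(clen + 1)
    denom = np.zeros(clen + 1)
    by_chrom: dict[str, list[RepeatElement]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el)
        denom[el.consensus_offset] += 1
        denom[el.consensus_offset + el.length] -= 1
    for rec in lib.records:
        for el in by_chrom.get(rec.chrom, ()):  # few copies per family
            proj = project_to_consensus((rec.start, rec.end), el)
            if proj is not None:
                cov[proj[0]] += 1
                cov[proj[1]] -= 1
    cov = np.cumsum(cov[:-1])
    denom = np.cumsum(denom[:-1])
    out = np.zeros(clen)
    np.divide(cov, denom, out=out, where=denom > 0)
    return out


def multimap_profile(records: list[MultiMapRecord], clen: int) -> np.ndarray:
    """Fractionally weighted consensus coverage from multi-mapped fragments.

    Each record deposits 1/k over the consensus positions it covers, where k
    is its number of candidate subfamilies; there is a single consensus, so
    the copy-averaging denominator is 1.
    """
    cov = np.zeros(clen + 1)
    for rec in records:
        if rec.end > clen:
            raise ValueError(f"record beyond consensus length {clen}: {rec}")
        w = 1.0 / rec.k
        cov[rec.start] += w
        cov[rec.end] -= w
    return np.cumsum(cov[:-1])


def combine_normalize(
    unique: np.ndarray,
    multi: np.ndarray,
    library_size: int,
    family: str = "",
) -> ConsensusProfile:
    """Sum the unique and multi-mapped components and scale to counts per
    million library fragments."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    unique = np.asarray(unique, dtype=float)
    multi = np.asarray(multi, dtype=float)
    if unique.shape != multi.shape:
        raise ValueError("unique/multi profiles differ in length")
    combined = (unique + multi) * 1.0e6 / library_size
    return ConsensusProfile(
        family=family,
        unique=unique,
        multi=multi,
        combined=combined,
        library_size=library_size,
    )


def dimeric_alu_filter(
    elements: list[RepeatElement], lo: int = 280, hi: int = 320
) -> list[RepeatElement]:
    """Keep full-length (dimeric) Alu copies: element length in [lo, hi] bp,
    bounds inclusive."""
    return [e for e in elements if lo <= e.length <= hi]


def region_mean(profile: ConsensusProfile | np.ndarray, start: int, end: int) -> float:
    """Mean combined signal over consensus positions [start, end)."""
    values = profile.combined if isinstance(profile, ConsensusProfile) else np.asarray(profile)
    if not (0 <= start < end <= values.size):
        raise ValueError(f"region [{start},{end}) outside consensus of {values.size} bp")
    return float(values[start:end].mean())


def mean_profiles(profiles: list[ConsensusProfile]) -> np.ndarray:
    """Group curve: arithmetic mean of per-library normalized profiles."""
    if not profiles:
        raise ValueError("need at least one profile")
    return np.mean([p.combined for p in profiles], axis=0)


# ---------------------------------------------------------------------------
# BED6+2 interchange (consensus_offset, consensus_length as extra columns)
# ---------------------------------------------------------------------------


def write_repeat_bed(elements: list[RepeatElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{e.family}\t0\t{e.strand}\t"
                f"{e.consensus_offset}\t{e.consensus_length}\n"
            )


def read_repeat_bed(path: str | Path) -> list[RepeatElement]:
    elements = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 8:
                raise ValueError(f"repeat BED line {lineno}: expected 8 columns")
            elements.append(
                RepeatElement(
                    family=f[3],
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5],
                    consensus_offset=int(f[6]),
                    consensus_length=int(f[7]),
                )
            )
    return elements
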