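"""Strand-aware average coverage around genomic anchors (TSS/TTS/CTCF).

A metaprofile is the mean per-base fragment coverage as a function of signed
offset from a set of aligned anchors. Minus-strand anchors contribute with
offsets negated, so "downstream" always means transcription direction.
Promoters and terminators show a nucleosome-depleted dip whose ±1,500 bp
window mean is the summary compared across age groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SampleLibrary
from .stats import (
    TestResult,
    coefficient_of_variation,
    dunn_posthoc,
    kruskal_wallis,
)

__all__ = [
    "MetaProfile",
    "coverage_at_anchors",
    "combine_profiles",
    "window_mean",
    "replicate_cv",
    "group_profile_tests",
]


@dataclass
class MetaProfile:
    """Mean coverage per signed offset around a set of anchors."""

    offsets: np.ndarray  # -flank .. +flank inclusive
    values: np.ndarray  # mean per-base coverage over anchors
    n_anchors: int
    n_fragments: int = 0

    def __post_init__(self) -> None:
        if self.offsets.size != self.values.size:
            raise ValueError("offsets/values length mismatch")

    @property
    def flank(self) -> int:
        return int(self.offsets[-1])


def coverage_at_anchors(
    lib: SampleLibrary,
    anchors: list[tuple[str, int, str]],
    flank: int = 2000,
    strand_aware: bool = True,
    mode: str = "coverage",
    chrom_lengths: dict[str, int] | None = None,
) -> MetaProfile:
    """Per-offset mean coverage over ``anchors`` (chrom, position, strand).

    ``mode="coverage"`` counts every base a fragment overlaps (occupancy-like
    signal); ``mode="midpoint"`` counts fragment midpoints only. Anchors must
    keep the full ±flank window inside the chromosome.
    """
    if not anchors:
        raise ValueError("need at least one anchor")
    if mode not in ("coverage", "midpoint"):
        raise ValueError("mode must be 'coverage' or 'midpoint'")
    needed: dict[str, int] = {}
    for chrom, pos, _ in anchors:
        if pos - flank < 0:
            raise ValueError(f"anchor {chrom}:{pos} closer than flank to chrom start")
        if chrom_lengths is not None and pos + flank >= chrom_lengths[chrom]:
            raise ValueError(f"anchor {chrom}:{pos} closer than flank to chrom end")
        needed[chrom] = max(needed.get(chrom, 0), pos + flank + 1)

    cov: dict[str, np.ndarray] = {}
    for rec in lib.records:
        if rec.chrom in needed:
            needed[rec.chrom] = max(needed[rec.chrom], rec.end + 1)
    for chrom, size in needed.items():
        cov[chrom] = np.zeros(size + 1)
    for rec in lib.records:
        arr = cov.get(rec.chrom)
        if arr is None:
            continue
        if mode == "coverage":
            arr[rec.start] += 1
            arr[rec.end] -= 1
        else:
            arr[rec.midpoint] += 1
            arr[rec.midpoint + 1] -= 1
    for chrom in cov:
        cov[chrom] = np.cumsum(cov[chrom][:-1])

    acc = np.zeros(2 * flank + 1)
    for chrom, pos, strand in anchors:
        window = cov[chrom][pos - flank : pos + flank + 1]
        if strand_aware and strand == "-":
            window = window[::-1]
        acc += window
    return MetaProfile(
        offsets=np.arange(-flank, flank + 1),
        values=acc / len(anchors),
        n_anchors=len(anchors),
        n_fragments=lib.library_size,
    )


def combine_profiles(profiles: list[MetaProfile], weights: list[float] | None = None) -> MetaProfile:
    """Fragment-count-weighted mean of profiles; pass explicit weights to
    override (e.g. equal weights to average replicates regardless of depth)."""
    if not profiles:
        raise ValueError("need at least one profile")
    if weights is None:
        weights = [float(p.n_fragments) for p in profiles]
        if sum(weights) == 0:
            weights = [1.0] * len(profiles)
    w = np.asarray(weights, dtype=float)
    values = np.average([p.values for p in profiles], axis=0, weights=w)
    return MetaProfile(
        offsets=profiles[0].offsets.copy(),
        values=values,
        n_anchors=profiles[0].n_anchors,
        n_fragments=int(sum(p.n_fragments for p in profiles)),
    )


def window_mean(profile: MetaProfile, halfwidth: int = 1500) -> float:
    """Mean profile value over offsets [-halfwidth, +halfwidth]."""
    if halfwidth > profile.flank:
        raise ValueError("halfwidth exceeds profile flank")
    sel = np.abs(profile.offsets) <= halfwidth
    return float(profile.values[sel].mean())


def replicate_cv(window_means: list[float]) -> float:
    """Coefficient of variation (percent) of replicate window means."""
    return coefficient_of_variation(np.asarray(window_means))


def group_profile_tests(
    group_profiles: dict[str, MetaProfile], halfwidth: int = 1500
) -> TestResult:
    """Kruskal–Wallis and Dunn post hoc across groups, observations being the
    per-offset group-mean values inside the ±halfwidth window."""
    if len(group_profiles) < 2:
        raise ValueError("need >=2 groups")
    groups, names = [], []
    for name, prof in group_profiles.items():
        if halfwidth > prof.flank:
            raise ValueError("halfwidth exceeds profile flank")
        sel = np.abs(prof.offsets) <= halfwidth
        vals = prof.values[sel]
        if np.ptp(vals) == 0 and vals.size < 2:
            raise ValueError("degenerate window")
        groups.append(vals)
        names.append(name)
    result = kruskal_wallis(groups)
    result.pairwise = dunn_posthoc(groups, names)
    return result
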