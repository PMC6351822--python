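"""Synthetic cfDNA cohort simulator.

Generates multi-sample plasma cfDNA fragment libraries with the statistical
structure the downstream analyses assume, together with a ground-truth record
for parameter-recovery tests:

* chromatosome-length fragment mixtures (truncated-normal lengths with a
  166–175 bp modal mass),
* phased nucleosome arrays (cosine protection component at a configurable
  spacing, 196 bp by default) downstream of TSS and flanking CTCF sites,
  with nucleosome-depleted dips at TSS/TTS/CTCF,
* per-100-kb-bin baseline coverage weighted by Hi-C subcompartment label
  (A1/A2/B1/B2/B3), the handle used to plant compartment-level
  redistribution between age groups,
* reduced protection over repeat-element 5' regions, and
* sample-level tissue mixtures whose phasing amplitude at a gene
  anti-correlates with the mixture-weighted expression of that gene, the
  structure exploited by WPS/FFT tissue-of-origin ranking.

All coordinates are 0-based half-open (BED dialect). Everything is
deterministic given a configuration and a top-level seed; per-sample RNG
streams are derived by hashing (seed, sample index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FragmentRecord, SampleLibrary
from .repeats import RepeatElement

__all__ = [
    "SUBCOMPARTMENTS",
    "Gene",
    "GenomeConfig",
    "GenomeModel",
    "GroupParams",
    "FragmentLengthModel",
    "SampleTruth",
    "CohortTruth",
    "build_genome_model",
    "simulate_tissue_expression",
    "protection_profile",
    "simulate_fragments",
    "simulate_cohort",
    "default_groups",
]

SUBCOMPARTMENTS = ("A1", "A2", "B1", "B2", "B3")


@dataclass(frozen=True, slots=True)
class Gene:
    """A gene anchor pair; tss < tts on '+' and tss > tts on '-'."""

    gene_id: str
    chrom: str
    tss: int
    tts: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: tss must precede tts on '+'")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: tss must follow tts on '-'")


@dataclass(frozen=True)
class GenomeConfig:
    """Settings for the synthetic genome model."""

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 2_000_000), ("chr2", 2_000_000))
    bin_size: int = 100_000
    n_genes: int = 40
    gene_length: int = 12_000
    n_ctcf: int = 30
    n_repeats: int = 20
    # consensus lengths per repeat family; copies alternate between families
    repeat_families: tuple[tuple[str, int], ...] = (("L1HS", 6019), ("AluY", 311))
    seed: int = 0


@dataclass
class GenomeModel:
    """Synthetic genome: chromosome sizes, labelled bins, genes, CTCF sites
    and repeat copies."""

    chromosomes: list[tuple[str, int]]
    bin_size: int
    bin_labels: pd.DataFrame  # columns chrom, start, end, label
    genes: list[Gene]
    ctcf_sites: list[tuple[str, int]]
    repeats: list[RepeatElement]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for name, ln in self.chromosomes:
            if ln <= 0:
                raise ValueError(f"zero-length chromosome {name}")
        for g in self.genes:
            ln = lengths[g.chrom]
            if not (0 <= g.tss < ln and 0 <= g.tts < ln):
                raise ValueError(f"gene {g.gene_id} outside {g.chrom}")
        for chrom, pos in self.ctcf_sites:
            if not 0 <= pos < lengths[chrom]:
                raise ValueError(f"CTCF site outside {chrom}")
        by_strand: dict[tuple[str, str], list[RepeatElement]] = {}
        for el in self.repeats:
            if el.end > lengths[el.chrom]:
                raise ValueError("repeat copy outside chromosome")
            by_strand.setdefault((el.chrom, el.strand), []).append(el)
        for copies in by_strand.values():
            copies = sorted(copies, key=lambda e: e.start)
            for a, b in zip(copies, copies[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping repeat copies on {a.chrom}{a.strand}"
                    )
        if set(self.bin_labels["label"]) - set(SUBCOMPARTMENTS):
            raise ValueError("unknown subcompartment label")


def _bin_frame(
    chromosomes: list[tuple[str, int]], bin_size: int, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for name, length in chromosomes:
        for i in range(length // bin_size):
            rows.append((name, i * bin_size, (i + 1) * bin_size))
    labels = [SUBCOMPARTMENTS[i % len(SUBCOMPARTMENTS)] for i in range(len(rows))]
    labels = list(rng.permutation(labels))
    return pd.DataFrame(
        [(c, s, e, l) for (c, s, e), l in zip(rows, labels)],
        columns=["chrom", "start", "end", "label"],
    )


def build_genome_model(config: GenomeConfig) -> GenomeModel:
    """Deterministically lay out a synthetic genome.

    Genes, CTCF sites and repeat copies are interleaved over an even grid of
    per-chromosome slots (with seeded jitter), which guarantees that features
    never overlap and that each gene keeps a clear 10-kb downstream span for
    window-protection analysis.
    """
    if not config.chromosomes:
        raise ValueError("need at least one chromosome")
    for name, length in config.chromosomes:
        if length <= 0:
            raise ValueError(f"zero-length chromosome {name}")
        if length % config.bin_size and length < config.bin_size:
            raise ValueError(f"chromosome {name} shorter than one bin")
    rng = np.random.default_rng(config.seed)
    bin_labels = _bin_frame(list(config.chromosomes), config.bin_size, rng)

    n_chrom = len(config.chromosomes)
    genes: list[Gene] = []
    ctcf: list[tuple[str, int]] = []
    repeats: list[RepeatElement] = []
    families = list(config.repeat_families)

    # per-chromosome feature counts (round-robin)
    def split(n: int) -> list[int]:
        return [n // n_chrom + (1 if i < n % n_chrom else 0) for i in range(n_chrom)]

    genes_per, ctcf_per, reps_per = (
        split(config.n_genes),
        split(config.n_ctcf),
        split(config.n_repeats),
    )
    gi = ci = ri = 0
    for ci_chrom, (name, length) in enumerate(config.chromosomes):
        kinds = (
            ["gene"] * genes_per[ci_chrom]
            + ["ctcf"] * ctcf_per[ci_chrom]
            + ["repeat"] * reps_per[ci_chrom]
        )
        kinds = list(rng.permutation(kinds))
        if not kinds:
            continue
        margin = 2_000
        span = length - 2 * margin
        slot = span / len(kinds)
        for k, kind in enumerate(kinds):
            slot_start = margin + int(k * slot)
            slot_end = margin + int((k + 1) * slot)
            if kind == "gene":
                need = config.gene_length
            elif kind == "repeat":
                need = families[ri % len(families)][1]  # consensus length bound
                need = min(need, 6100)
            else:
                need = 1
            if slot_end - slot_start < need + 200:
                raise ValueError(
                    f"feature does not fit on {name}: a {kind} of {need} bp "
                    f"exceeds its {slot_end - slot_start} bp slot"
                )
            jitter = int(rng.integers(0, max(1, slot_end - slot_start - need - 100)))
            pos = slot_start + 50 + jitter
            if kind == "gene":
                strand = "+" if gi % 2 == 0 else "-"
                s, e = pos, pos + config.gene_length
                if strand == "+":
                    gene = Gene(f"g{gi:04d}", name, s, e - 1, "+")
                else:
                    gene = Gene(f"g{gi:04d}", name, e - 1, s, "-")
                genes.append(gene)
                gi += 1
            elif kind == "ctcf":
                ctcf.append((name, pos))
                ci += 1
            else:
                fam, clen = families[ri % len(families)]
                if fam == "L1HS" and ri % 4 == 2:
                    # occasional 5'-truncated L1 copy
                    offset = int(rng.integers(500, 2000))
                else:
                    offset = 0
                el_len = clen - offset
                strand = "+" if ri % 2 == 0 else "-"
                repeats.append(
                    RepeatElement(
                        family=fam,
                        chrom=name,
                        start=pos,
                        end=pos + el_len,
                        strand=strand,
                        consensus_offset=offset,
                        consensus_length=clen,
                    )
                )
                ri += 1
    model = GenomeModel(
        chromosomes=list(config.chromosomes),
        bin_size=config.bin_size,
        bin_labels=bin_labels,
        genes=genes,
        ctcf_sites=ctcf,
        repeats=repeats,
    )
    model.validate()
    return model


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one cohort group."""

    name: str
    compartment_weights: dict[str, float]
    ndr_depth: float = 0.7
    phasing_amplitude: float = 0.5
    repeat_5p_weight: float = 1.0
    tissue_mixture: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.compartment_weights.values()):
            raise ValueError("compartment weights must be >= 0")
        if not 0.0 <= self.ndr_depth <= 1.0:
            raise ValueError("ndr_depth must lie in [0, 1]")
        if not 0.0 <= self.phasing_amplitude <= 1.0:
            raise ValueError("phasing_amplitude must lie in [0, 1]")
        if self.repeat_5p_weight < 0:
            raise ValueError("repeat_5p_weight must be >= 0")
        if self.tissue_mixture:
            if any(w < 0 for w in self.tissue_mixture.values()):
                raise ValueError("tissue mixture weights must be >= 0")
            if abs(sum(self.tissue_mixture.values()) - 1.0) > 1e-9:
                raise ValueError("tissue mixture must sum to 1")


@dataclass(frozen=True)
class FragmentLengthModel:
    """Truncated-normal fragment length distribution (bp)."""

    mean: float = 170.0
    sd: float = 10.0
    min_len: int = 100
    max_len: int = 400

    def __post_init__(self) -> None:
        if not self.min_len <= self.mean <= self.max_len:
            raise ValueError("need min <= mean <= max")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = np.rint(rng.normal(self.mean, self.sd, size=n - filled)).astype(
                np.int64
            )
            ok = draw[(draw >= self.min_len) & (draw <= self.max_len)]
            out[filled : filled + ok.size] = ok
            filled += ok.size
        return out


@dataclass
class SampleTruth:
    sample_id: str
    group: str
    seed: int
    depth: int
    tissue_mixture: dict[str, float]


@dataclass
class CohortTruth:
    """Ground truth of an emitted cohort, JSON round-trippable."""

    spacing: float
    samples: list[SampleTruth]
    group_params: dict[str, dict]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "spacing": self.spacing,
            "samples": [asdict(s) for s in self.samples],
            "group_params": self.group_params,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CohortTruth":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            spacing=payload["spacing"],
            samples=[SampleTruth(**s) for s in payload["samples"]],
            group_params=payload["group_params"],
        )


def simulate_tissue_expression(
    n_genes: int,
    n_tissues: int,
    seed: int = 0,
    marker_fraction: float = 0.2,
    marker_boost: float = 12.0,
    base_sigma: float = 0.05,
    gene_ids: list[str] | None = None,
    tissue_names: list[str] | None = None,
) -> pd.DataFrame:
    """Tissue x gene expression table with disjoint marker-gene blocks.

    Baseline expression is log-normal with log-sd ``base_sigma``; each tissue
    receives a disjoint block of ``round(marker_fraction * n_genes)`` marker
    genes whose expression is multiplied by ``marker_boost``. Values are
    non-negative RPKM-like units.
    """
    if n_genes < 1 or n_tissues < 1:
        raise ValueError("need n_genes >= 1 and n_tissues >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = gene_ids or [f"g{i:04d}" for i in range(n_genes)]
    tissue_names = tissue_names or [f"tissue{i}" for i in range(n_tissues)]
    if len(gene_ids) != n_genes or len(tissue_names) != n_tissues:
        raise ValueError("id list lengths must match n_genes/n_tissues")
    base = rng.lognormal(mean=1.0, sigma=base_sigma, size=(n_tissues, n_genes))
    n_markers = int(round(marker_fraction * n_genes))
    if n_markers * n_tissues > n_genes:
        raise ValueError("marker blocks do not fit: reduce marker_fraction")
    for t in range(n_tissues):
        block = slice(t * n_markers, (t + 1) * n_markers)
        base[t, block] *= marker_boost
    return pd.DataFrame(base, index=tissue_names, columns=gene_ids)


def marker_genes(expression: pd.DataFrame, tissue: str) -> list[str]:
    """Genes whose expression in ``tissue`` exceeds 4x the median over the
    other tissues (the simulator's marker blocks satisfy this)."""
    others = expression.drop(index=tissue)
    ratio = expression.loc[tissue] / others.median(axis=0)
    return list(ratio.index[ratio > 4.0])


DEFAULT_SPACING = 196.0
NDR_SIGMA = 150.0
PHASED_SPAN = 10_000
CTCF_FLANK = 2_000
REPEAT_5P_LEN = 668


def _mixture_weighted_expression(
    expression: pd.DataFrame, mixture: dict[str, float], gene_ids: list[str]
) -> np.ndarray:
    missing = [g for g in gene_ids if g not in expression.columns]
    if missing:
        raise ValueError(f"expression table lacks genes: {missing[:5]}")
    if not mixture:
        return np.zeros(len(gene_ids))
    weights = pd.Series(mixture, dtype=float)
    missing_t = [t for t in weights.index if t not in expression.index]
    if missing_t:
        raise ValueError(f"expression table lacks tissues: {missing_t}")
    mix = weights @ expression.loc[weights.index, gene_ids]
    # log scale: expression acts on protection through a saturating response,
    # so a marker gene's effect depends on its mixture weight rather than
    # being dominated by a few extreme expression values; min-max scaling
    # spreads the response over the full [0, 1] amplitude range
    log_mix = np.log2(mix.to_numpy() + 1.0)
    lo, hi = float(log_mix.min()), float(log_mix.max())
    if hi <= lo:
        return np.zeros(len(gene_ids))
    return (log_mix - lo) / (hi - lo)


def protection_profile(
    model: GenomeModel,
    params: GroupParams,
    expression: pd.DataFrame,
    spacing: float = DEFAULT_SPACING,
    ndr_sigma: float = NDR_SIGMA,
    repeat_5p_len: int = REPEAT_5P_LEN,
) -> dict[str, np.ndarray]:
    """Per-base nucleosome-protection track for one group.

    The track is a product of non-negative factors: a per-bin subcompartment
    baseline, Gaussian NDR dips of relative depth ``ndr_depth`` at TSS, TTS
    and CTCF sites, a cosine phasing component of period ``spacing`` over the
    10 kb downstream of each TSS (amplitude ``phasing_amplitude * (1 -
    normalized mixture-weighted expression)``), symmetric phasing flanks at
    CTCF sites, and a ``repeat_5p_weight`` scaling over repeat 5' regions.
    """
    lengths = model.chrom_lengths
    tracks: dict[str, np.ndarray] = {}
    weights = params.compartment_weights
    missing = set(model.bin_labels["label"]) - set(weights)
    if missing:
        raise ValueError(f"compartment_weights lacks labels: {sorted(missing)}")
    mean_w = float(np.mean([weights[l] for l in SUBCOMPARTMENTS if l in weights]))
    for name, length in model.chromosomes:
        track = np.full(length, mean_w)
        sub = model.bin_labels[model.bin_labels["chrom"] == name]
        for _, row in sub.iterrows():
            track[row["start"] : row["end"]] = weights[row["label"]]
        tracks[name] = track

    gene_ids = [g.gene_id for g in model.genes]
    norm_expr = _mixture_weighted_expression(expression, params.tissue_mixture, gene_ids)

    half = int(4 * ndr_sigma)
    dip_x = np.arange(-half, half + 1)
    dip = np.exp(-0.5 * (dip_x / ndr_sigma) ** 2)

    def apply_ndr(track: np.ndarray, pos: int) -> None:
        lo = max(0, pos - half)
        hi = min(track.size, pos + half + 1)
        track[lo:hi] *= 1.0 - params.ndr_depth * dip[lo - (pos - half) : hi - (pos - half)]

    for gene, nexp in zip(model.genes, norm_expr):
        track = tracks[gene.chrom]
        apply_ndr(track, gene.tss)
        apply_ndr(track, gene.tts)
        amp = params.phasing_amplitude * (1.0 - nexp)
        if amp > 0:
            if gene.strand == "+":
                lo = gene.tss
                hi = min(track.size, gene.tss + PHASED_SPAN)
                d = np.arange(0, hi - lo)
                track[lo:hi] *= 1.0 + amp * np.cos(2 * np.pi * d / spacing)
            else:
                hi = gene.tss + 1
                lo = max(0, gene.tss - PHASED_SPAN + 1)
                dist = gene.tss - np.arange(lo, hi)  # downstream distance from TSS
                track[lo:hi] *= 1.0 + amp * np.cos(2 * np.pi * dist / spacing)

    for chrom, pos in model.ctcf_sites:
        track = tracks[chrom]
        apply_ndr(track, pos)
        lo = max(0, pos - CTCF_FLANK)
        hi = min(track.size, pos + CTCF_FLANK + 1)
        d = np.abs(np.arange(lo, hi) - pos)
        track[lo:hi] *= 1.0 + params.phasing_amplitude * np.cos(2 * np.pi * d / spacing)

    if params.repeat_5p_weight != 1.0:
        for el in model.repeats:
            track = tracks[el.chrom]
            span = max(0, min(repeat_5p_len - el.consensus_offset, el.length))
            if span == 0:
                continue
            if el.strand == "+":
                track[el.start : el.start + span] *= params.repeat_5p_weight
            else:
                track[el.end - span : el.end] *= params.repeat_5p_weight

    for name, track in tracks.items():
        np.maximum(track, 0.0, out=track)
    return tracks


def simulate_fragments(
    track: dict[str, np.ndarray] | np.ndarray,
    depth: int,
    flm: FragmentLengthModel | None = None,
    seed: int = 0,
    jitter: int = 10,
    sample_id: str = "sample",
    group: str = "",
) -> SampleLibrary:
    """Draw exactly ``depth`` fragments with dyad positions proportional to
    the protection track, midpoint jitter of +/-``jitter`` bp, and
    truncated-normal lengths."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    flm = flm or FragmentLengthModel()
    if isinstance(track, np.ndarray):
        track = {"chr1": track}
    names = list(track)
    masses = np.array([float(np.sum(track[n])) for n in names])
    total = masses.sum()
    lib = SampleLibrary(sample_id=sample_id, group=group)
    if depth == 0:
        return lib
    if total <= 0:
        raise ValueError("cannot sample fragments from an all-zero track")
    rng = np.random.default_rng(seed)
    chrom_choice = rng.choice(len(names), size=depth, p=masses / total)
    frag_idx = 0
    for i, name in enumerate(names):
        n_here = int(np.sum(chrom_choice == i))
        if n_here == 0:
            continue
        t = np.asarray(track[name], dtype=float)
        cdf = np.cumsum(t)
        draws = rng.random(n_here) * cdf[-1]
        dyads = np.searchsorted(cdf, draws, side="right")
        mids = dyads + rng.integers(-jitter, jitter + 1, size=n_here)
        lens = flm.sample(n_here, rng)
        starts = mids - lens // 2
        ends = starts + lens
        # shift fragments protruding past the chromosome ends back inside
        shift_left = np.minimum(starts, 0)
        starts -= shift_left
        ends -= shift_left
        over = np.maximum(ends - t.size, 0)
        starts -= over
        ends -= over
        starts = np.maximum(starts, 0)
        strands = np.where(rng.random(n_here) < 0.5, "+", "-")
        for s, e, st in zip(starts, ends, strands):
            lib.records.append(
                FragmentRecord(
                    chrom=name,
                    start=int(s),
                    end=int(e),
                    name=f"frag{frag_idx}",
                    mapq=60,
                    strand=str(st),
                )
            )
            frag_idx += 1
    lib.records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return lib


def derive_sample_seed(top_seed: int, index: int) -> int:
    """Independent per-sample stream seed hashed from (top seed, index)."""
    return int(np.random.SeedSequence([top_seed, index]).generate_state(1)[0] % 2**31)


def simulate_cohort(
    groups: list[GroupParams],
    replicates: int,
    model: GenomeModel,
    expression: pd.DataFrame,
    depth: int = 200_000,
    flm: FragmentLengthModel | None = None,
    seed: int = 0,
    spacing: float = DEFAULT_SPACING,
) -> tuple[list[SampleLibrary], CohortTruth]:
    """Simulate ``replicates`` samples per group; returns the libraries and
    the complete ground-truth record."""
    if not groups or replicates < 1:
        raise ValueError("need >=1 group and >=1 replicate")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")
    libs: list[SampleLibrary] = []
    truth_samples: list[SampleTruth] = []
    index = 0
    for params in groups:
        track = protection_profile(model, params, expression, spacing=spacing)
        for rep in range(replicates):
            sid = f"{params.name}_r{rep + 1}"
            s = derive_sample_seed(seed, index)
            lib = simulate_fragments(
                track, depth, flm, seed=s, sample_id=sid, group=params.name
            )
            libs.append(lib)
            truth_samples.append(
                SampleTruth(
                    sample_id=sid,
                    group=params.name,
                    seed=s,
                    depth=depth,
                    tissue_mixture=dict(params.tissue_mixture),
                )
            )
            index += 1
    truth = CohortTruth(
        spacing=spacing,
        samples=truth_samples,
        group_params={
            g.name: {
                "compartment_weights": dict(g.compartment_weights),
                "ndr_depth": g.ndr_depth,
                "phasing_amplitude": g.phasing_amplitude,
                "repeat_5p_weight": g.repeat_5p_weight,
                "tissue_mixture": dict(g.tissue_mixture),
            }
            for g in groups
        },
    )
    return libs, truth


def default_groups(tissues: list[str] | None = None) -> list[GroupParams]:
    """The four default study groups: young, old, and healthy/unhealthy
    centenarians.

    Parameter trends mirror the qualitative structure the analyses probe:
    with age and deteriorating health the heterochromatic B2/B3 baseline
    rises while A1/B1 falls, promoter/terminator NDRs deepen, phasing
    amplitude attenuates, and repeat 5' protection drops; old and unhealthy
    groups double the focal tissue's mixture weight relative to the young
    base profile.
    """
    tissues = tissues or [f"tissue{i}" for i in range(5)]
    n = len(tissues)
    # Base mixture: the focal (last) tissue contributes clearly the least,
    # the rest form an equal-weight pack whose relative order is left to
    # sampling noise. Aged mixture: the focal tissue's weight doubles (then
    # renormalized), making it clearly the strongest contributor. The focal
    # base weight must exceed 1/(2n-1) for doubling to overtake the pack;
    # 0.15 at n=5 leaves comparable margins on both sides (0.0625 below the
    # pack before doubling, 0.076 above it after).
    focal = 0.75 / n
    base = {t: (focal if i == n - 1 else (1.0 - focal) / (n - 1)) for i, t in enumerate(tissues)}
    shifted = {t: (2.0 * w if i == n - 1 else w) for i, (t, w) in enumerate(base.items())}
    z = sum(shifted.values())
    shifted = {t: w / z for t, w in shifted.items()}
    return [
        GroupParams(
            name="young",
            compartment_weights={"A1": 1.20, "A2": 1.10, "B1": 1.40, "B2": 0.80, "B3": 0.60},
            ndr_depth=0.45,
            phasing_amplitude=0.50,
            repeat_5p_weight=1.00,
            tissue_mixture=dict(base),
        ),
        GroupParams(
            name="healthy_cent",
            compartment_weights={"A1": 1.15, "A2": 1.10, "B1": 1.33, "B2": 0.87, "B3": 0.67},
            ndr_depth=0.55,
            phasing_amplitude=0.46,
            repeat_5p_weight=0.85,
            tissue_mixture=dict(base),
        ),
        GroupParams(
            name="old",
            compartment_weights={"A1": 1.08, "A2": 1.05, "B1": 1.28, "B2": 0.93, "B3": 0.73},
            ndr_depth=0.65,
            phasing_amplitude=0.42,
            repeat_5p_weight=0.70,
            tissue_mixture=shifted,
        ),
        GroupParams(
            name="unhealthy_cent",
            compartment_weights={"A1": 1.00, "A2": 1.04, "B1": 1.22, "B2": 0.97, "B3": 0.79},
            ndr_depth=0.75,
            phasing_amplitude=0.38,
            repeat_5p_weight=0.70,
            tissue_mixture=shifted,
        ),
    ]
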