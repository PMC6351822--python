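"""Tissue-of-origin inference from nucleosome phasing periodicity.

At each position the window protection score (WPS) counts fragments that
span an entire w-bp window minus fragments with an endpoint inside it;
phased nucleosome arrays make it oscillate at the inter-nucleosome spacing.
Per gene, the WPS over the 10 kb downstream of the TSS is detrended
(running-median subtraction), Fourier transformed, and summarized by the
mean squared-magnitude intensity in the 193–199 bp period band. Because
actively transcribed genes lose phasing, a gene's band intensity
anti-correlates with its expression in the tissues the cfDNA came from;
correlating per-gene intensities with each tissue's expression profile and
ranking tissues by that correlation orders candidate tissues of origin, and
rank shifts between age groups are tested per tissue (Kruskal–Wallis, Dunn
post hoc, BH across tissues within each group pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleLibrary
from .simulate import Gene
from .stats import bh_fdr, dunn_posthoc, kruskal_wallis, pearson_r

__all__ = [
    "WPSTrack",
    "PeriodSpectrum",
    "TissueCorrelationTable",
    "RankShiftResult",
    "wps",
    "gene_wps_tracks",
    "detrend",
    "period_spectrum",
    "band_intensity",
    "band_intensity_per_gene",
    "tissue_correlations",
    "rank_shift_test",
]

WPS_WINDOW = 120
TRACK_LENGTH = 10_000
BAND = (193, 199)
PERIOD_RANGE = (120, 280)


@dataclass
class WPSTrack:
    """Window protection scores over [TSS, TSS + 10 kb) in transcription
    direction for one gene."""

    gene_id: str
    values: np.ndarray  # integer scores
    w: int = WPS_WINDOW


def wps(
    lib: SampleLibrary | tuple[np.ndarray, np.ndarray],
    interval: tuple[str, int, int] | tuple[int, int],
    w: int = WPS_WINDOW,
) -> np.ndarray:
    """WPS at each position p of a half-open interval.

    Score(p) = #fragments spanning the whole window [p - w/2, p + w/2)
    minus #fragments with an endpoint (start or end-1) inside that window.
    ``lib`` may be a SampleLibrary (with a chrom in ``interval``) or a bare
    (starts, ends) array pair.
    """
    if w % 2 or w <= 0:
        raise ValueError("w must be a positive even integer")
    if isinstance(lib, SampleLibrary):
        chrom, lo, hi = interval  # type: ignore[misc]
        starts = np.array([r.start for r in lib.records if r.chrom == chrom], dtype=np.int64)
        ends = np.array([r.end for r in lib.records if r.chrom == chrom], dtype=np.int64)
    else:
        starts, ends = (np.asarray(a, dtype=np.int64) for a in lib)
        lo, hi = interval  # type: ignore[misc]
    if hi <= lo:
        raise ValueError("empty interval")
    if w >= hi - lo:
        raise ValueError("window must be narrower than the interval")
    w2 = w // 2
    n = hi - lo
    diff = np.zeros(n + 1, dtype=np.int64)

    def add_range(a: np.ndarray, b: np.ndarray, value: int) -> None:
        # add `value` on [a, b) clipped to [lo, hi), in interval coordinates
        a = np.clip(a - lo, 0, n)
        b = np.clip(b - lo, 0, n)
        keep = b > a
        np.add.at(diff, a[keep], value)
        np.add.at(diff, b[keep], -value)

    # spanning: p in [start + w/2, end - w/2]
    add_range(starts + w2, ends - w2 + 1, 1)
    # endpoint x inside window: p in [x - w/2 + 1, x + w/2]
    for x in (starts, ends - 1):
        add_range(x - w2 + 1, x + w2 + 1, -1)
    return np.cumsum(diff[:-1])


def gene_wps_tracks(
    lib: SampleLibrary,
    genes: list[Gene],
    length: int = TRACK_LENGTH,
    w: int = WPS_WINDOW,
) -> dict[str, WPSTrack]:
    """Per-gene WPS over the ``length`` bp downstream of each TSS, oriented
    in transcription direction (minus-strand tracks are reversed)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in genes}:
        starts = np.array(
            [r.start for r in lib.records if r.chrom == chrom], dtype=np.int64
        )
        ends = np.array([r.end for r in lib.records if r.chrom == chrom], dtype=np.int64)
        by_chrom[chrom] = (starts, ends)
    out = {}
    for gene in genes:
        arrays = by_chrom[gene.chrom]
        if gene.strand == "+":
            track = wps(arrays, (gene.tss, gene.tss + length), w=w)
        else:
            track = wps(arrays, (gene.tss - length + 1, gene.tss + 1), w=w)[::-1]
        out[gene.gene_id] = WPSTrack(gene_id=gene.gene_id, values=track, w=w)
    return out


def detrend(track: np.ndarray, median_window: int = 1000) -> np.ndarray:
    """Subtract a centered running median (edge-truncated) and the residual
    mean, leaving a mean-zero oscillatory signal."""
    values = pd.Series(np.asarray(track, dtype=float))
    trend = values.rolling(median_window, center=True, min_periods=1).median()
    resid = (values - trend).to_numpy()
    return resid - resid.mean()


@dataclass
class PeriodSpectrum:
    """Squared-magnitude FFT intensities indexed by spatial period (bp)."""

    n: int  # track length
    periods: np.ndarray  # N/k for retained k, descending period
    intensities: np.ndarray  # |X_k|^2 / N^2 for retained k
    total_intensity: float  # sum over ALL k of |X_k|^2 / N^2 (Parseval)
    period_range: tuple[int, int] = PERIOD_RANGE

    def band_mean(self, lo: float, hi: float) -> float:
        if not lo < hi:
            raise ValueError("need lo < hi")
        if lo < self.period_range[0] or hi > self.period_range[1]:
            raise ValueError("band outside spectrum period range")
        sel = (self.periods >= lo) & (self.periods <= hi)
        if not sel.any():
            raise ValueError(f"no frequency falls in band [{lo},{hi}]")
        return float(self.intensities[sel].mean())

    def binned(self) -> pd.Series:
        """Mean intensity per integer period bin (rounded N/k)."""
        bins = np.rint(self.periods).astype(int)
        return pd.Series(self.intensities).groupby(bins).mean()

    def peak_period(self) -> int:
        """Integer period bin of maximal mean intensity."""
        b = self.binned()
        return int(b.idxmax())


def period_spectrum(
    track: np.ndarray, period_range: tuple[int, int] = PERIOD_RANGE
) -> PeriodSpectrum:
    """FFT of a (detrended) WPS track, indexed by period L = N/k."""
    x = np.asarray(track, dtype=float)
    n = x.size
    if n < 2 * period_range[1]:
        raise ValueError("track shorter than twice the maximum period")
    spectrum = np.fft.fft(x)
    intensity_all = (np.abs(spectrum) ** 2) / n**2
    k = np.arange(1, n // 2 + 1)
    periods = n / k
    sel = (periods >= period_range[0]) & (periods <= period_range[1])
    return PeriodSpectrum(
        n=n,
        periods=periods[sel],
        intensities=intensity_all[1 : n // 2 + 1][sel],
        total_intensity=float(intensity_all.sum()),
        period_range=period_range,
    )


def band_intensity(spectrum: PeriodSpectrum, lo: float = BAND[0], hi: float = BAND[1]) -> float:
    """Mean intensity over the [lo, hi] bp period band."""
    return spectrum.band_mean(lo, hi)


def band_intensity_per_gene(
    lib: SampleLibrary,
    genes: list[Gene],
    w: int = WPS_WINDOW,
    length: int = TRACK_LENGTH,
    median_window: int = 1000,
    band: tuple[float, float] = BAND,
    normalize: bool = True,
) -> pd.Series:
    """Gene -> 193–199 bp band intensity for one sample: WPS, detrend, FFT.

    With ``normalize=True`` the band intensity is divided by the track's
    total spectral power, making the per-gene value a scale-free measure of
    how periodic the protection signal is. WPS amplitude scales with local
    coverage, so the raw band intensity carries a per-gene coverage factor
    (squared) that has nothing to do with nucleosome phasing; normalizing
    cancels it exactly.
    """
    tracks = gene_wps_tracks(lib, genes, length=length, w=w)
    out = {}
    for gid, tr in tracks.items():
        spec = period_spectrum(detrend(tr.values, median_window))
        value = band_intensity(spec, *band)
        if normalize:
            total = spec.total_intensity
            value = value / total if total > 0 else 0.0
        out[gid] = value
    return pd.Series(out, name=lib.sample_id)


@dataclass
class TissueCorrelationTable:
    """Per-tissue correlation between per-gene band intensities and
    log2(expression + 1), with derived ranks."""

    r: pd.Series  # tissue -> Pearson r
    ranks: pd.Series  # tissue -> rank (1 = strongest contributor)
    excluded: list[str] = field(default_factory=list)


def tissue_correlations(
    band: pd.Series,
    expression: pd.DataFrame,
    rank_ascending: bool = True,
) -> TissueCorrelationTable:
    """Correlate per-gene band intensities with each tissue's expression.

    Phasing intensity anti-correlates with expression, so by default tissues
    are ranked by ascending r: the most negative correlation is rank 1, the
    strongest inferred contributor. Tissues with zero expression variance
    over the shared genes are excluded and reported.
    """
    shared = [g for g in band.index if g in expression.columns]
    if len(shared) < 3:
        raise ValueError("need >=3 genes shared with the expression table")
    b = band.loc[shared].to_numpy(dtype=float)
    if np.ptp(b) == 0:
        raise ValueError("band intensities have zero variance")
    rs, excluded = {}, []
    for tissue in expression.index:
        e = np.log2(expression.loc[tissue, shared].to_numpy(dtype=float) + 1.0)
        if np.ptp(e) == 0:
            excluded.append(tissue)
            continue
        rs[tissue] = pearson_r(b, e)
    r = pd.Series(rs, name=getattr(band, "name", None))
    order = r.sort_values(ascending=rank_ascending, kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index).loc[r.index]
    return TissueCorrelationTable(r=r, ranks=ranks, excluded=excluded)


@dataclass
class RankShiftResult:
    """Per-tissue rank-shift tests between groups."""

    kw: pd.DataFrame  # index tissue; columns H, p
    pairwise: pd.DataFrame  # tissue, group_a, group_b, z, p, p_adjusted, median_change

    def significant(self, group_a: str, group_b: str, alpha: float = 0.05) -> pd.DataFrame:
        t = self.pairwise
        sel = (
            ((t["group_a"] == group_a) & (t["group_b"] == group_b))
            | ((t["group_a"] == group_b) & (t["group_b"] == group_a))
        ) & (t["p_adjusted"] < alpha)
        return t[sel]


def rank_shift_test(
    ranks: pd.DataFrame, groups: dict[str, str]
) -> RankShiftResult:
    """Kruskal–Wallis/Dunn on each tissue's per-sample rank across groups.

    ``ranks`` is samples x tissues. BH adjustment is applied across the group
    pairs within each tissue, answering "is this tissue's rank shifted?" with
    the tissue's own family of pairwise contrasts as the multiplicity unit;
    median_change is median(rank in group_b) - median(rank in group_a), so a
    negative value for (a=young, b=old) means the tissue moved toward rank 1
    (a stronger contributor) in old.
    """
    if ranks.isna().any().any():
        raise ValueError("missing tissue rank for some sample")
    group_names = list(dict.fromkeys(groups.values()))
    if len(group_names) < 2:
        raise ValueError("need >=2 groups")
    by_group = {
        g: [s for s in ranks.index if groups[s] == g] for g in group_names
    }
    for g, samples in by_group.items():
        if len(samples) < 2:
            raise ValueError(f"group {g} has <2 samples")
    kw_rows = {}
    pair_rows = []
    for tissue in ranks.columns:
        values = [ranks.loc[by_group[g], tissue].to_numpy(dtype=float) for g in group_names]
        res = kruskal_wallis(values)
        kw_rows[tissue] = (res.statistic, res.p)
        for row in dunn_posthoc(values, group_names):
            med_a = float(np.median(ranks.loc[by_group[row.group_a], tissue]))
            med_b = float(np.median(ranks.loc[by_group[row.group_b], tissue]))
            pair_rows.append(
                {
                    "tissue": tissue,
                    "group_a": row.group_a,
                    "group_b": row.group_b,
                    "z": row.z,
                    "p": row.p,
                    "median_change": med_b - med_a,
                }
            )
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_adjusted"] = np.nan
    for _, idx in pairwise.groupby("tissue").groups.items():
        pairwise.loc[idx, "p_adjusted"] = bh_fdr(pairwise.loc[idx, "p"].to_numpy())
    kw = pd.DataFrame(kw_rows, index=["H", "p"]).T
    return RankShiftResult(kw=kw, pairwise=pairwise)
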