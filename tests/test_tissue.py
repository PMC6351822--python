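"""WPS, period spectra, band intensities and tissue ranking."""

import numpy as np
import pandas as pd
import pytest

from cffrag.simulate import Gene
from cffrag.tissue import (
    band_intensity,
    band_intensity_per_gene,
    detrend,
    gene_wps_tracks,
    period_spectrum,
    rank_shift_test,
    tissue_correlations,
    wps,
)
from conftest import make_lib


def test_wps_single_fragment_hand_values():
    lib = make_lib([("chr1", 100, 267)])
    track = wps(lib, ("chr1", 0, 400), w=120)
    # spanning window [p-60, p+60) requires p in [160, 207]
    assert track[183] == 1
    assert track[160] == 0  # spanning +1 and start-endpoint -1 cancel
    assert track[161] == 1
    # the start endpoint alone lies in the window for p in [41, 159]
    assert track[100] == -1
    assert track[41] == -1
    assert track[40] == 0
    # the end endpoint (266) alone for p in [208, 326]
    assert track[250] == -1
    assert track[350] == 0


def wps_brute_force(frags, lo, hi, w):
    w2 = w // 2
    out = np.zeros(hi - lo, dtype=int)
    for i, p in enumerate(range(lo, hi)):
        win_lo, win_hi = p - w2, p + w2  # half-open window
        for s, e in frags:
            if s <= win_lo and e >= win_hi:
                out[i] += 1
            for x in (s, e - 1):
                if win_lo <= x < win_hi:
                    out[i] -= 1
    return out


def test_wps_matches_brute_force(rng):
    frags = [
        (int(s), int(s + l))
        for s, l in zip(rng.integers(0, 900, size=80), rng.integers(80, 300, size=80))
    ]
    starts = np.array([s for s, _ in frags])
    ends = np.array([e for _, e in frags])
    track = wps((starts, ends), (200, 800), w=120)
    assert np.array_equal(track, wps_brute_force(frags, 200, 800, 120))


def test_wps_input_validation():
    lib = make_lib([("chr1", 0, 200)])
    with pytest.raises(ValueError):
        wps(lib, ("chr1", 0, 400), w=121)  # odd window
    with pytest.raises(ValueError):
        wps(lib, ("chr1", 0, 100), w=120)  # window wider than interval
    with pytest.raises(ValueError):
        wps(lib, ("chr1", 100, 100), w=120)


def test_gene_wps_minus_strand_mirrors_plus():
    # a fragment at offsets [100, 300) downstream of a plus-strand TSS, and
    # its mirror image downstream of a minus-strand TSS (the half-open WPS
    # window makes the mirror image [8700, 8900), not [8701, 8901))
    lib_plus = make_lib([("chr1", 1100, 1300)])
    lib_minus = make_lib([("chr1", 8700, 8900)])
    g_plus = Gene("gp", "chr1", 1000, 2500, "+")
    g_minus = Gene("gm", "chr1", 9000, 7500, "-")
    t_plus = gene_wps_tracks(lib_plus, [g_plus], length=1000)["gp"].values
    t_minus = gene_wps_tracks(lib_minus, [g_minus], length=1000)["gm"].values
    assert np.array_equal(t_plus, t_minus)


def test_detrend_removes_constant_and_ramp():
    assert np.allclose(detrend(np.full(3000, 7.0)), 0.0)
    ramp = np.linspace(0, 100, 3000)
    resid = detrend(ramp)
    # the truncated median window leaves edge artefacts but the interior is flat
    assert np.max(np.abs(resid[700:2300])) < 0.5
    assert np.max(np.abs(resid)) < 10.0
    cosine = 5 * np.cos(2 * np.pi * np.arange(5000) / 196)
    kept = detrend(cosine, median_window=1000)
    assert np.max(kept) == pytest.approx(5.0, rel=0.05)


def test_spectrum_parseval():
    rng = np.random.default_rng(2)
    x = rng.normal(size=4000)
    spec = period_spectrum(x)
    # sum_k |X_k|^2 / N^2 = sum_t x_t^2 / N
    assert spec.total_intensity == pytest.approx(np.sum(x**2) / x.size, rel=1e-6)


def test_spectrum_periods_within_range():
    x = np.cos(2 * np.pi * np.arange(2000) / 196)
    spec = period_spectrum(x)
    assert spec.periods.min() >= 120
    assert spec.periods.max() <= 280
    assert np.all(np.diff(spec.periods) < 0)  # descending period


def test_cosine_peak_period_in_band():
    n = 9800
    x = np.cos(2 * np.pi * np.arange(n) / 196)
    spec = period_spectrum(x)
    assert 193 <= spec.peak_period() <= 199
    # nearly all retained power lives in the band
    assert band_intensity(spec) > 30 * spec.intensities.mean()


def test_band_separates_periodicities():
    n = 9800
    t = np.arange(n)
    in_band = period_spectrum(np.cos(2 * np.pi * t / 196))
    out_band = period_spectrum(np.cos(2 * np.pi * t / 245))
    assert band_intensity(in_band) > 50 * band_intensity(out_band)


def test_band_mean_validation():
    spec = period_spectrum(np.cos(2 * np.pi * np.arange(2000) / 196))
    with pytest.raises(ValueError):
        spec.band_mean(199, 193)
    with pytest.raises(ValueError):
        spec.band_mean(100, 150)  # below the retained period range


def test_band_intensity_per_gene_normalization(rng):
    frags = [
        ("chr1", int(s), int(s + l))
        for s, l in zip(
            rng.integers(1500, 13000, size=2000), rng.integers(120, 220, size=2000)
        )
    ]
    lib = make_lib(frags)
    gene = Gene("g", "chr1", 2000, 13000, "+")
    raw = band_intensity_per_gene(lib, [gene], normalize=False)
    norm = band_intensity_per_gene(lib, [gene], normalize=True)
    track = gene_wps_tracks(lib, [gene])["g"].values
    spec = period_spectrum(detrend(track))
    assert norm["g"] == pytest.approx(raw["g"] / spec.total_intensity)
    assert 0 <= norm["g"] <= 1


def test_tissue_correlations_hand_example():
    band = pd.Series({"g0": 1.0, "g1": 2.0, "g2": 3.0})
    expression = pd.DataFrame(
        {
            "g0": [15.0, 0.0, 4.0],
            "g1": [3.0, 1.0, 4.0],
            "g2": [0.0, 7.0, 4.0],
        },
        index=["liver", "blood", "flat"],
    )
    res = tissue_correlations(band, expression)
    # expression of 'liver' decreases with band intensity -> negative r
    assert res.r["liver"] < -0.9
    assert res.r["blood"] > 0.9
    assert res.excluded == ["flat"]
    assert res.ranks["liver"] == 1
    assert res.ranks["blood"] == 2


def test_tissue_correlations_rank_permutation(rng):
    genes = [f"g{i}" for i in range(20)]
    band = pd.Series(rng.random(20), index=genes)
    expression = pd.DataFrame(
        rng.random((4, 20)) * 10, index=[f"t{i}" for i in range(4)], columns=genes
    )
    res = tissue_correlations(band, expression)
    assert sorted(res.ranks) == [1, 2, 3, 4]
    # ascending r order: rank 1 has the most negative correlation
    assert res.r[res.ranks.idxmin()] == res.r.min()


def test_tissue_correlations_validation():
    expr = pd.DataFrame({"g0": [1.0], "g1": [2.0]}, index=["t"])
    with pytest.raises(ValueError):
        tissue_correlations(pd.Series({"g0": 1.0, "g1": 2.0}), expr)
    expr3 = pd.DataFrame(
        {"g0": [1.0], "g1": [2.0], "g2": [3.0]}, index=["t"]
    )
    with pytest.raises(ValueError):
        tissue_correlations(pd.Series({"g0": 1.0, "g1": 1.0, "g2": 1.0}), expr3)


def test_rank_shift_test_detects_planted_shift():
    samples = [f"y{i}" for i in range(4)] + [f"o{i}" for i in range(4)]
    groups = {s: ("young" if s.startswith("y") else "old") for s in samples}
    ranks = pd.DataFrame(
        {
            "focal": [5, 5, 5, 5, 1, 1, 1, 1],
            "other": [1, 2, 3, 4, 2, 3, 4, 5],
        },
        index=samples,
        dtype=float,
    )
    res = rank_shift_test(ranks, groups)
    sig = res.significant("young", "old")
    assert "focal" in set(sig["tissue"])
    focal = res.pairwise[res.pairwise["tissue"] == "focal"].iloc[0]
    assert focal["median_change"] == -4.0
    # perfect separation with n=4 vs 4 (two tie groups of 4): z = 4 / 1.5119
    assert abs(focal["z"]) == pytest.approx(2.6458, abs=1e-3)
    assert res.kw.loc["focal", "p"] < 0.01


def test_rank_shift_test_validation():
    ranks = pd.DataFrame({"t": [1.0, np.nan]}, index=["a", "b"])
    with pytest.raises(ValueError):
        rank_shift_test(ranks, {"a": "g1", "b": "g2"})
    ok = pd.DataFrame({"t": [1.0, 2.0, 1.0]}, index=["a", "b", "c"])
    with pytest.raises(ValueError):
        rank_shift_test(ok, {"a": "g1", "b": "g1", "c": "g1"})
    with pytest.raises(ValueError):
        rank_shift_test(ok, {"a": "g1", "b": "g1", "c": "g2"})  # group of 1
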