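"""Rank-based and Bayesian statistical kernels shared by all pipeline stages.

The statistics themselves (Kruskal–Wallis with tie correction, Dunn's post hoc
z with tie correction, Brown–Forsythe/Levene, Benjamini–Hochberg step-up,
coefficient of variation, and a Gibbs sampler for the normal random-intercept
model) are implemented here; only tail probabilities of the chi-square, F and
normal reference distributions come from :mod:`scipy.stats`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "PairwiseRow",
    "midranks",
    "kruskal_wallis",
    "dunn_posthoc",
    "levene_bf",
    "bh_fdr",
    "pearson_r",
    "coefficient_of_variation",
    "GibbsSettings",
    "GibbsDraws",
    "gibbs_random_intercept",
]


@dataclass(frozen=True)
class PairwiseRow:
    """One row of a post hoc pairwise comparison table."""

    group_a: str
    group_b: str
    z: float
    p: float
    p_adjusted: float


@dataclass
class TestResult:
    """Omnibus test outcome with an optional post hoc table.

    ``statistic`` is H for Kruskal–Wallis and W (the ANOVA-on-deviations F)
    for the Brown–Forsythe test.
    """

    statistic: float
    p: float
    pairwise: list[PairwiseRow] = field(default_factory=list)

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.group_a, r.group_b, r.z, r.p, r.p_adjusted) for r in self.pairwise],
            columns=["group_a", "group_b", "z", "p", "p_adjusted"],
        )


def midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties assigned the mean of the ranks they span."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _check_groups(groups: list[np.ndarray], min_size: int = 1) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = []
    for g in groups:
        arr = np.asarray(g, dtype=float).ravel()
        if arr.size < min_size:
            raise ValueError(f"group with fewer than {min_size} values")
        out.append(arr)
    return out


def _tie_sum(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal–Wallis H test with tie correction.

    H = [12/(N(N+1)) * sum n_i * Rbar_i^2 - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N)),
    referred to a chi-square distribution with k-1 degrees of freedom.
    """
    groups = _check_groups(groups, min_size=1)
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = midranks(pooled)
    h = 0.0
    offset = 0
    for g in groups:
        r = ranks[offset : offset + g.size]
        h += g.size * (r.mean() ** 2)
        offset += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    tie = _tie_sum(pooled)
    denom = 1.0 - tie / (n_total**3 - n_total)
    if denom <= 0:  # all observations identical
        return TestResult(statistic=0.0, p=1.0)
    h /= denom
    p = float(_sps.chi2.sf(h, df=len(groups) - 1))
    return TestResult(statistic=float(h), p=p)


def dunn_posthoc(
    groups: list[np.ndarray], names: list[str] | None = None, alpha: float = 0.05
) -> list[PairwiseRow]:
    """Dunn's post hoc pairwise z tests on the joint mid-ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N-1)); two-sided normal p values and
    Benjamini–Hochberg adjustment across the pairs.
    """
    groups = _check_groups(groups, min_size=1)
    if names is None:
        names = [f"group{i}" for i in range(len(groups))]
    if len(names) != len(groups):
        raise ValueError("names/groups length mismatch")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = midranks(pooled)
    mean_ranks, sizes = [], []
    offset = 0
    for g in groups:
        mean_ranks.append(ranks[offset : offset + g.size].mean())
        sizes.append(g.size)
        offset += g.size
    tie_term = _tie_sum(pooled) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        denom = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p = float(2.0 * _sps.norm.sf(abs(z)))
        rows.append((names[i], names[j], float(z), min(p, 1.0)))
    adj = bh_fdr(np.array([r[3] for r in rows]))
    return [
        PairwiseRow(a, b, z, p, float(q)) for (a, b, z, p), q in zip(rows, adj)
    ]


def levene_bf(groups: list[np.ndarray], center: str = "median") -> TestResult:
    """Levene's test for equality of spread; default median centering
    (Brown–Forsythe variant). One-way ANOVA F on absolute deviations."""
    groups = _check_groups(groups, min_size=2)
    if center == "median":
        devs = [np.abs(g - np.median(g)) for g in groups]
    elif center == "mean":
        devs = [np.abs(g - g.mean()) for g in groups]
    else:
        raise ValueError("center must be 'median' or 'mean'")
    k = len(devs)
    n_total = sum(d.size for d in devs)
    grand = np.concatenate(devs).mean()
    ss_between = sum(d.size * (d.mean() - grand) ** 2 for d in devs)
    ss_within = sum(float(np.sum((d - d.mean()) ** 2)) for d in devs)
    df1, df2 = k - 1, n_total - k
    if ss_between == 0.0:
        return TestResult(statistic=0.0, p=1.0)
    if ss_within == 0.0:
        return TestResult(statistic=float("inf"), p=0.0)
    w = (ss_between / df1) / (ss_within / df2)
    p = float(_sps.f.sf(w, df1, df2))
    return TestResult(statistic=float(w), p=p)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of >=3 values")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(np.dot(xc, xc)))
    sy = math.sqrt(float(np.dot(yc, yc)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance input")
    return float(np.dot(xc, yc) / (sx * sy))


def coefficient_of_variation(values: np.ndarray) -> float:
    """100 * sample SD (ddof=1) / mean, in percent."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two replicates")
    mean = v.mean()
    if mean == 0.0:
        raise ValueError("mean is zero; CV undefined")
    return float(100.0 * v.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Gibbs sampler for the normal random-intercept model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GibbsSettings:
    """MCMC settings for the random-intercept sampler.

    Defaults (13,000 sweeps, 3,000 burn-in, thinning 10) mirror common
    animal-model MCMC defaults and yield 1,000 retained draws.
    """

    n_iter: int = 13_000
    burn_in: int = 3_000
    thin: int = 10
    prior_shape: float = 0.001
    prior_rate: float = 0.001
    effect_prior_var: float = 1.0e6

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in or self.thin < 1:
            raise ValueError("invalid MCMC settings")


@dataclass
class GibbsDraws:
    """Thinned posterior draws: per-group intercepts and the two variances."""

    group_names: list[str]
    beta: np.ndarray  # draws x groups
    sigma2_u: np.ndarray
    sigma2_e: np.ndarray

    def difference(self, group_a: str, group_b: str) -> np.ndarray:
        ia = self.group_names.index(group_a)
        ib = self.group_names.index(group_b)
        return self.beta[:, ia] - self.beta[:, ib]

    def rhat(self) -> float:
        """Split-chain potential scale reduction on the first group contrast
        (falls back to sigma2_e when only one group chain is informative)."""
        x = self.beta[:, 0] - self.beta[:, -1]
        if np.allclose(x.std(), 0):
            x = self.sigma2_e
        half = x.size // 2
        chains = np.stack([x[:half], x[half : 2 * half]])
        w = chains.var(axis=1, ddof=1).mean()
        b = half * chains.mean(axis=1).var(ddof=1)
        if w == 0:
            return 1.0
        return float(math.sqrt((w * (half - 1) / half + b / half) / w))


def gibbs_random_intercept(
    y: np.ndarray,
    groups: list[str],
    settings: GibbsSettings | None = None,
    seed: int = 0,
) -> GibbsDraws:
    """Gibbs sampler for y_{b,s} = beta_{g(s)} + u_b + eps.

    ``y`` is a bins x samples matrix, ``groups`` labels each sample column.
    u_b ~ N(0, sigma_u^2), eps ~ N(0, sigma_e^2); per-group intercepts carry a
    vague normal prior, both variances inverse-gamma(shape, rate) priors, so
    every full conditional is conjugate. Group contrasts beta_i - beta_j are
    the quantities of interest and are invariant to the flat-intercept
    parameterization.
    """
    settings = settings or GibbsSettings()
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be a bins x samples matrix")
    n_bins, n_samples = y.shape
    if n_bins < 2 or n_samples < 2:
        raise ValueError("need at least 2 bins and 2 samples")
    if len(groups) != n_samples:
        raise ValueError("one group label per sample column required")
    if float(np.var(y)) == 0.0:
        raise ValueError("degenerate input: all responses identical")
    group_names = list(dict.fromkeys(groups))
    if len(group_names) < 2:
        raise ValueError("need at least two distinct groups")
    gidx = np.array([group_names.index(g) for g in groups])
    n_groups = len(group_names)
    group_cols = [np.flatnonzero(gidx == k) for k in range(n_groups)]
    n_per_group = np.array([c.size * n_bins for c in group_cols], dtype=float)

    rng = np.random.default_rng(seed)
    beta = np.array([y[:, c].mean() for c in group_cols])
    u = np.zeros(n_bins)
    sigma2_u, sigma2_e = 1.0, float(np.var(y)) or 1.0
    a0, b0 = settings.prior_shape, settings.prior_rate
    tau2 = settings.effect_prior_var

    n_keep = (settings.n_iter - settings.burn_in) // settings.thin
    beta_draws = np.empty((n_keep, n_groups))
    s2u_draws = np.empty(n_keep)
    s2e_draws = np.empty(n_keep)
    kept = 0
    for it in range(settings.n_iter):
        # beta_g | rest
        resid_u = y - u[:, None]
        for k in range(n_groups):
            prec = n_per_group[k] / sigma2_e + 1.0 / tau2
            mean = resid_u[:, group_cols[k]].sum() / sigma2_e / prec
            beta[k] = rng.normal(mean, math.sqrt(1.0 / prec))
        # u_b | rest (vectorized over bins)
        resid_b = y - beta[gidx][None, :]
        prec_u = n_samples / sigma2_e + 1.0 / sigma2_u
        mean_u = resid_b.sum(axis=1) / sigma2_e / prec_u
        u = rng.normal(mean_u, math.sqrt(1.0 / prec_u))
        # variances
        sigma2_u = 1.0 / rng.gamma(
            a0 + 0.5 * n_bins, 1.0 / (b0 + 0.5 * float(np.dot(u, u)))
        )
        eps = resid_b - u[:, None]
        sigma2_e = 1.0 / rng.gamma(
            a0 + 0.5 * y.size, 1.0 / (b0 + 0.5 * float(np.sum(eps * eps)))
        )
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            if kept < n_keep:
                beta_draws[kept] = beta
                s2u_draws[kept] = sigma2_u
                s2e_draws[kept] = sigma2_e
                kept += 1
    return GibbsDraws(
        group_names=group_names,
        beta=beta_draws[:kept],
        sigma2_u=s2u_draws[:kept],
        sigma2_e=s2e_draws[:kept],
    )
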