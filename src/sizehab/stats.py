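"""Pairwise habitat comparison metrics and per-habitat summary statistics.

Five size-difference metrics: difference of log10 means, difference of
phylogenetic (GLS) means, Wilcoxon rank-sum, simulation-based phylogenetic
ANOVA (Brownian null), and PGLS ANOVA with residual randomisation.  Plus
observed-vs-simulated variance and the per-habitat summaries (richness,
migratory percentage, mean tip branch duration, trophic means) consumed by
the mechanism classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from sizehab.model import Dataset
from sizehab.tree import Phylogeny, bm_covariance, simulate_bm

__all__ = [
    "MetricOutcome",
    "VarianceOutcome",
    "mean_log10_diff",
    "gls_group_means",
    "phylo_ls_means",
    "wilcoxon_rank_sum",
    "phylo_anova_sim",
    "pgls_anova_perm",
    "variance_vs_sim",
    "habitat_summaries",
    "ml_bm_rate",
    "significance_band",
]

TEST_METRICS = ("wilcoxon", "phylo_anova", "pgls_anova")


@dataclass
class MetricOutcome:
    """One clade × habitat-pair × metric result.

    ``signed_difference`` is positive when the first habitat is larger;
    ``larger_habitat`` is the habitat name or ``"tie"``.
    """

    metric: str
    habitat_a: str
    habitat_b: str
    larger_habitat: str
    signed_difference: float
    n_first: int
    n_second: int
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0,1]")


@dataclass
class VarianceOutcome:
    habitat: str
    observed: float
    null_median: float
    quantile: float  # position of the observed variance in the BM null
    n: int
    n_sim: int


def _outcome(
    metric: str,
    habitat_a: str,
    habitat_b: str,
    diff: float,
    n_a: int,
    n_b: int,
    p: Optional[float] = None,
) -> MetricOutcome:
    if diff > 0:
        larger = habitat_a
    elif diff < 0:
        larger = habitat_b
    else:
        larger = "tie"
    return MetricOutcome(
        metric=metric,
        habitat_a=habitat_a,
        habitat_b=habitat_b,
        larger_habitat=larger,
        signed_difference=float(diff),
        n_first=int(n_a),
        n_second=int(n_b),
        p_value=p,
    )


def significance_band(p: Optional[float]) -> str:
    if p is None:
        return "none"
    if p < 0.05:
        return "p<0.05"
    if p < 0.1:
        return "p<0.1"
    return "none"


# ----------------------------------------------------------- metric (i)


def mean_log10_diff(
    values_a: Sequence[float],
    values_b: Sequence[float],
    habitat_a: str = "a",
    habitat_b: str = "b",
) -> MetricOutcome:
    """Difference of arithmetic means of (already log10) values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in mean_log10_diff")
    return _outcome("mean_log10", habitat_a, habitat_b, a.mean() - b.mean(), a.size, b.size)


# ---------------------------------------------------------- metric (ii)


def gls_group_means(
    C: np.ndarray, y: np.ndarray, groups: Sequence[str]
) -> dict[str, float]:
    """Generalised-least-squares group means under covariance C.

    Fits y = X β with X the group indicator matrix, giving
    β = (XᵀC⁻¹X)⁻¹ XᵀC⁻¹ y; β are the LS means directly.  Falls back to a
    small ridge on C with a warning if C is not invertible.
    """
    y = np.asarray(y, dtype=float)
    labels = sorted(set(groups))
    garr = np.asarray(list(groups))
    X = np.stack([(garr == g).astype(float) for g in labels], axis=1)
    if np.any(X.sum(axis=0) == 0):
        raise ValueError("a group has no observations (singular design)")
    try:
        cf = linalg.cho_factor(C)
    except np.linalg.LinAlgError:
        warnings.warn("covariance not positive definite; applying ridge")
        jitter = 1e-8 * np.trace(C) / C.shape[0] + 1e-12
        cf = linalg.cho_factor(C + jitter * np.eye(C.shape[0]))
    Ci_X = linalg.cho_solve(cf, X)
    Ci_y = linalg.cho_solve(cf, y)
    beta = np.linalg.solve(X.T @ Ci_X, X.T @ Ci_y)
    return dict(zip(labels, beta))


def phylo_ls_means(
    tree: Phylogeny, y: np.ndarray, groups: Sequence[str]
) -> dict[str, float]:
    """LS means with Brownian tip covariance from ``tree``."""
    return gls_group_means(bm_covariance(tree), y, groups)


def _chol_with_jitter(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        warnings.warn("covariance not positive definite; applying ridge")
        jitter = 1e-8 * np.trace(C) / C.shape[0] + 1e-12
        return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))


def _null_sims(
    tree: Optional[Phylogeny],
    C: Optional[np.ndarray],
    rate: float,
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """BM simulations at the tips: edge-walk if a tree is given, else
    Cholesky sampling from the supplied covariance."""
    if tree is not None:
        return simulate_bm(tree, rate, n_sim, rng)
    L = _chol_with_jitter(C)
    return np.sqrt(rate) * (L @ rng.standard_normal((C.shape[0], n_sim)))


def phylo_mean_outcome(
    tree: Optional[Phylogeny],
    y: np.ndarray,
    groups: Sequence[str],
    habitat_a: str,
    habitat_b: str,
    C: Optional[np.ndarray] = None,
) -> MetricOutcome:
    if C is None:
        C = bm_covariance(tree)
    means = gls_group_means(C, y, groups)
    garr = np.asarray(list(groups))
    return _outcome(
        "phylo_mean",
        habitat_a,
        habitat_b,
        means[habitat_a] - means[habitat_b],
        int((garr == habitat_a).sum()),
        int((garr == habitat_b).sum()),
    )


# --------------------------------------------------------- metric (iii)


def wilcoxon_rank_sum(
    values_a: Sequence[float],
    values_b: Sequence[float],
    habitat_a: str = "a",
    habitat_b: str = "b",
) -> MetricOutcome:
    """Two-sided rank-sum test.

    Exact null enumeration when n_a+n_b ≤ 12 with no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in wilcoxon_rank_sum")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return _outcome(
        "wilcoxon", habitat_a, habitat_b, a.mean() - b.mean(), a.size, b.size,
        p=float(res.pvalue),
    )


# ----------------------------------------------------------- metric (iv)


def ml_bm_rate(C: np.ndarray, y: np.ndarray) -> float:
    """ML Brownian rate for y under covariance C (intercept-only model)."""
    n = y.size
    cf = linalg.cho_factor(C)
    one = np.ones(n)
    Ci1 = linalg.cho_solve(cf, one)
    mu = (Ci1 @ y) / (Ci1 @ one)
    r = y - mu
    return float(r @ linalg.cho_solve(cf, r) / n)


def _anova_f(Y: np.ndarray, group_idx: np.ndarray, g: int) -> np.ndarray:
    """One-way ANOVA F for each column of Y (n × m)."""
    n = Y.shape[0]
    G = np.zeros((g, n))
    G[group_idx, np.arange(n)] = 1.0
    counts = G.sum(axis=1, keepdims=True)
    gmeans = (G @ Y) / counts
    grand = Y.mean(axis=0, keepdims=True)
    ssb = (counts * (gmeans - grand) ** 2).sum(axis=0)
    ssw = ((Y - G.T @ gmeans) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / (g - 1)) / (ssw / (n - g))


def phylo_anova_sim(
    tree: Optional[Phylogeny],
    y: np.ndarray,
    groups: Sequence[str],
    habitat_a: str,
    habitat_b: str,
    n_sim: int = 999,
    seed: int = 0,
    C: Optional[np.ndarray] = None,
) -> MetricOutcome:
    """Simulation-based phylogenetic ANOVA.

    The observed one-way F is compared with F values from ``n_sim``
    Brownian simulations on the clade tree (rate = ML estimate from the
    data) with group membership held fixed;
    p = (1 + #{F_sim ≥ F_obs}) / (1 + n_sim).
    """
    y = np.asarray(y, dtype=float)
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    garr = np.asarray(list(groups))
    gi = np.searchsorted(np.asarray(labels), garr)
    diff = y[garr == habitat_a].mean() - y[garr == habitat_b].mean()
    n_a = int((garr == habitat_a).sum())
    n_b = int((garr == habitat_b).sum())
    if np.allclose(y, y[0]):
        warnings.warn("zero-variance trait in phylo_anova_sim; p=1")
        return _outcome("phylo_anova", habitat_a, habitat_b, diff, n_a, n_b, p=1.0)
    if C is None:
        C = bm_covariance(tree)
    rate = ml_bm_rate(C, y)
    rng = np.random.default_rng(seed)
    f_obs = float(_anova_f(y[:, None], gi, len(labels))[0])
    sims = _null_sims(tree, C, rate, n_sim, rng)
    f_sim = _anova_f(sims, gi, len(labels))
    p = (1.0 + np.sum(f_sim >= f_obs)) / (1.0 + n_sim)
    return _outcome("phylo_anova", habitat_a, habitat_b, diff, n_a, n_b, p=float(p))


# ------------------------------------------------------------ metric (v)


def pgls_anova_perm(
    tree: Optional[Phylogeny],
    y: np.ndarray,
    groups: Sequence[str],
    habitat_a: str,
    habitat_b: str,
    n_perm: int = 999,
    seed: int = 0,
    C: Optional[np.ndarray] = None,
) -> MetricOutcome:
    """PGLS ANOVA assessed by residual randomisation.

    The statistic is the reduction in phylogenetically transformed residual
    sum of squares from the intercept-only model to the group model.  The
    null distribution permutes the null-model transformed residuals.
    """
    y = np.asarray(y, dtype=float)
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    garr = np.asarray(list(groups))
    X = np.stack([(garr == g).astype(float) for g in labels], axis=1)
    if np.any(X.sum(axis=0) == 0):
        raise ValueError("a group has no observations (singular design)")
    diff = y[garr == habitat_a].mean() - y[garr == habitat_b].mean()
    n_a = int((garr == habitat_a).sum())
    n_b = int((garr == habitat_b).sum())
    if np.allclose(y, y[0]):
        return _outcome("pgls_anova", habitat_a, habitat_b, diff, n_a, n_b, p=1.0)
    if C is None:
        C = bm_covariance(tree)
    L = _chol_with_jitter(C)
    yt = linalg.solve_triangular(L, y, lower=True)
    Xt = linalg.solve_triangular(L, X, lower=True)
    onet = linalg.solve_triangular(L, np.ones_like(y), lower=True)

    q_full, _ = np.linalg.qr(Xt)
    q_null = onet[:, None] / np.linalg.norm(onet)

    def rss_pair(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tot = (Y**2).sum(axis=0)
        rss_n = tot - ((q_null.T @ Y) ** 2).sum(axis=0)
        rss_f = tot - ((q_full.T @ Y) ** 2).sum(axis=0)
        return rss_n, rss_f

    rn, rf = rss_pair(yt[:, None])
    stat_obs = float(rn[0] - rf[0])
    beta0 = float(q_null[:, 0] @ yt) * q_null[:, 0]
    resid = yt - beta0
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((len(y), n_perm)), axis=0)
    Yp = beta0[:, None] + resid[perms]
    rn_p, rf_p = rss_pair(Yp)
    stat_perm = rn_p - rf_p
    p = (1.0 + np.sum(stat_perm >= stat_obs)) / (1.0 + n_perm)
    return _outcome("pgls_anova", habitat_a, habitat_b, diff, n_a, n_b, p=float(p))


# ------------------------------------------------- variance vs simulation


def variance_vs_sim(
    tree: Optional[Phylogeny],
    y: np.ndarray,
    subset: np.ndarray,
    habitat: str = "",
    n_sim: int = 999,
    seed: int = 0,
    C: Optional[np.ndarray] = None,
) -> VarianceOutcome:
    """Observed tip variance of a habitat subset vs. its BM-null variances.

    The null simulates the whole clade under the ML Brownian rate and takes
    the variance of the same tip subset.  Both observed and simulated
    variances are standardised by their own dataset's ML rate, making the
    statistic scale-pivotal so its null quantile is calibrated despite the
    plug-in rate estimate.  ``quantile`` is the mid-p position of the
    observed statistic in the null distribution.
    """
    y = np.asarray(y, dtype=float)
    subset = np.asarray(subset, dtype=bool)
    if subset.sum() < 2:
        raise ValueError("need at least 2 taxa for a variance comparison")
    obs = float(np.var(y[subset], ddof=1))
    if C is None:
        C = bm_covariance(tree)
    rate = ml_bm_rate(C, y)
    rng = np.random.default_rng(seed)
    sims = _null_sims(tree, C, rate, n_sim, rng)
    v = np.var(sims[subset], axis=0, ddof=1)
    if rate > 0:
        # per-simulation ML rates (vectorised intercept-model quadratic form)
        cf = linalg.cho_factor(C)
        one = np.ones(len(y))
        Ci1 = linalg.cho_solve(cf, one)
        denom = Ci1 @ one
        mu_sim = (Ci1 @ sims) / denom
        R = sims - mu_sim[None, :]
        rate_sim = np.einsum("ij,ij->j", R, linalg.cho_solve(cf, R)) / len(y)
        obs_stat = obs / rate
        v = v / np.where(rate_sim > 0, rate_sim, np.inf)
    else:
        obs_stat = obs
    quantile = (np.sum(v < obs_stat) + 0.5 * np.sum(v == obs_stat)) / n_sim
    return VarianceOutcome(
        habitat=habitat,
        observed=obs,
        null_median=float(np.median(v)),
        quantile=float(quantile),
        n=int(subset.sum()),
        n_sim=n_sim,
    )


# ------------------------------------------------------------- summaries


def habitat_summaries(dataset: Dataset) -> pd.DataFrame:
    """Per-habitat richness, migratory %, mean tip duration, trophic means.

    ``migratory_pct`` uses taxa with a known flag as the denominator; the
    phylogenetic trophic mean is a GLS group mean over the trophic-complete
    subset of the clade.
    """
    df = dataset.to_frame()
    tree = dataset.tree
    df["tip_duration"] = [
        tree.terminal_branch_length(s) for s in df["species"]
    ]
    troph = df.dropna(subset=["trophic_level"])
    phylo_troph: dict[str, float] = {}
    if len(troph) >= 2 and troph["habitat"].nunique() >= 1:
        sub = dataset.subset(troph["species"])
        try:
            phylo_troph = gls_group_means(
                bm_covariance(sub.tree),
                sub.trait_vector("trophic_level"),
                sub.habitats(),
            )
        except ValueError:
            phylo_troph = {}
    rows = []
    for habitat, grp in df.groupby("habitat", sort=True):
        known = grp["migratory"].dropna()
        rows.append(
            {
                "habitat": habitat,
                "richness": len(grp),
                "migratory_pct": 100.0 * known.astype(bool).mean() if len(known) else np.nan,
                "n_migratory_known": len(known),
                "mean_tip_duration": grp["tip_duration"].mean(),
                "trophic_mean": grp["trophic_level"].dropna().mean(),
                "trophic_phylo_mean": phylo_troph.get(habitat, np.nan),
                "mean_log10_size": grp["log10_size"].mean(),
            }
        )
    return pd.DataFrame(rows).set_index("habitat")
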