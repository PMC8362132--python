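"""Enumerate and run all clade × habitat-pair comparisons at every scale.

Also computes majority summaries (what fraction of clades have habitat X
larger than habitat Y under a given metric) and the reduced-and-retained
protocol: prune to trophic-complete taxa, rerun the size comparisons, and
keep only comparisons whose size direction survives the pruning.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from sizehab.model import HABITAT_PAIRS, Dataset
from sizehab.scales import CladeScale
from sizehab.stats import (
    MetricOutcome,
    bm_covariance,
    mean_log10_diff,
    pgls_anova_perm,
    phylo_anova_sim,
    phylo_mean_outcome,
    significance_band,
    wilcoxon_rank_sum,
)

__all__ = [
    "EngineConfig",
    "ComparisonResult",
    "enumerate_comparisons",
    "run_all",
    "majority_summaries",
    "reduce_and_retain",
    "results_to_frame",
    "donut_table",
]

DEFAULT_METRICS = ("mean_log10", "phylo_mean", "wilcoxon", "phylo_anova", "pgls_anova")


@dataclass
class EngineConfig:
    min_n: int = 3
    n_sim: int = 999
    n_perm: int = 999
    metrics: tuple[str, ...] = DEFAULT_METRICS
    seed: int = 0
    # retention anchor: "phylo_mean" (default) or "all" for strict
    # agreement across every size metric
    retain_mode: str = "phylo_mean"


@dataclass
class ComparisonResult:
    scale: str
    clade_id: str
    habitat_a: str
    habitat_b: str
    outcomes: dict[str, MetricOutcome] = field(default_factory=dict)
    retained: bool = True

    @property
    def pair(self) -> tuple[str, str]:
        return (self.habitat_a, self.habitat_b)

    def key(self) -> tuple[str, str, str, str]:
        return (self.scale, self.clade_id, self.habitat_a, self.habitat_b)


def _derive_seed(base: int, *parts: str) -> int:
    h = zlib.crc32("|".join(parts).encode())
    return (int(base) * 1_000_003 + h) % (2**32)


def enumerate_comparisons(
    dataset: Dataset,
    scales: list[CladeScale],
    min_n: int = 3,
) -> tuple[list[tuple[str, str, tuple[str, str]]], list[dict]]:
    """All (scale, clade, habitat pair) with both habitats at min_n taxa.

    Pairs come from the canonical 10 pairs over the five comparison
    habitats (exclusively-brackish taxa never enter pairwise comparisons).
    Skipped pairs are returned with a reason.
    """
    habitat_of = {r.species_id: r.habitat for r in dataset.records}
    jobs = []
    skipped = []
    for sc in scales:
        for cid, tips in sc.clades:
            counts: dict[str, int] = {}
            for t in tips:
                counts[habitat_of[t]] = counts.get(habitat_of[t], 0) + 1
            for a, b in HABITAT_PAIRS:
                n_a, n_b = counts.get(a, 0), counts.get(b, 0)
                if n_a >= min_n and n_b >= min_n:
                    jobs.append((sc.scale_name, cid, (a, b)))
                elif n_a > 0 and n_b > 0:
                    skipped.append(
                        {
                            "scale": sc.scale_name,
                            "clade_id": cid,
                            "habitat_a": a,
                            "habitat_b": b,
                            "reason": f"below min_n ({n_a} vs {n_b}, need {min_n})",
                        }
                    )
    return jobs, skipped


def run_all(
    dataset: Dataset,
    scales: list[CladeScale],
    config: Optional[EngineConfig] = None,
) -> list[ComparisonResult]:
    """Run every requested metric for every enumerated comparison.

    Deterministic under a fixed ``config.seed``: each stochastic metric
    gets a seed derived from (seed, scale, clade, pair, metric).
    Per-comparison failures are recorded, not fatal.
    """
    config = config or EngineConfig()
    jobs, _ = enumerate_comparisons(dataset, scales, config.min_n)
    habitat_of = {r.species_id: r.habitat for r in dataset.records}
    size_of = {r.species_id: r.log10_size for r in dataset.records}

    by_clade: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for scale, cid, pair in jobs:
        by_clade.setdefault((scale, cid), []).append(pair)
    clade_tips = {
        (sc.scale_name, cid): tips for sc in scales for cid, tips in sc.clades
    }

    # The Brownian covariance of any tip subset, measured from the subset's
    # MRCA, is a submatrix of the full-tree covariance minus the MRCA depth
    # (pruning preserves shared path lengths), so one full-tree C serves
    # every clade and pair without re-pruning trees.
    need_phylo = any(
        m in config.metrics for m in ("phylo_mean", "phylo_anova", "pgls_anova")
    )
    C_full = bm_covariance(dataset.tree) if need_phylo else None
    tip_idx = {lab: i for i, lab in enumerate(dataset.tree.tip_labels)}

    results = []
    for (scale, cid), pairs in by_clade.items():
        tips = clade_tips[(scale, cid)]
        for a, b in pairs:
            sp_a = sorted(t for t in tips if habitat_of[t] == a)
            sp_b = sorted(t for t in tips if habitat_of[t] == b)
            vals_a = np.array([size_of[s] for s in sp_a])
            vals_b = np.array([size_of[s] for s in sp_b])
            res = ComparisonResult(scale=scale, clade_id=cid, habitat_a=a, habitat_b=b)
            C_pair = None
            if need_phylo:
                idx = [tip_idx[s] for s in sp_a + sp_b]
                C_pair = C_full[np.ix_(idx, idx)]
                C_pair = C_pair - C_pair.min()
                y = np.concatenate([vals_a, vals_b])
                groups = [a] * len(sp_a) + [b] * len(sp_b)
            for metric in config.metrics:
                try:
                    if metric == "mean_log10":
                        out = mean_log10_diff(vals_a, vals_b, a, b)
                    elif metric == "phylo_mean":
                        out = phylo_mean_outcome(None, y, groups, a, b, C=C_pair)
                    elif metric == "phylo_anova":
                        out = phylo_anova_sim(
                            None, y, groups, a, b,
                            n_sim=config.n_sim,
                            seed=_derive_seed(config.seed, scale, cid, a, b, metric),
                            C=C_pair,
                        )
                    elif metric == "pgls_anova":
                        out = pgls_anova_perm(
                            None, y, groups, a, b,
                            n_perm=config.n_perm,
                            seed=_derive_seed(config.seed, scale, cid, a, b, metric),
                            C=C_pair,
                        )
                    elif metric == "wilcoxon":
                        out = wilcoxon_rank_sum(vals_a, vals_b, a, b)
                    else:
                        raise ValueError(f"unknown metric {metric!r}")
                except Exception as exc:  # logged, not fatal
                    res.outcomes[metric] = MetricOutcome(
                        metric=metric, habitat_a=a, habitat_b=b,
                        larger_habitat="error", signed_difference=np.nan,
                        n_first=len(sp_a), n_second=len(sp_b), p_value=None,
                    )
                    res.outcomes[metric].error = str(exc)  # type: ignore[attr-defined]
                    continue
                res.outcomes[metric] = out
            results.append(res)
    results.sort(key=lambda r: r.key())
    return results


def majority_summaries(
    results: list[ComparisonResult], metric: str = "phylo_mean"
) -> pd.DataFrame:
    """Per scale × habitat-pair tallies of which habitat is larger.

    ``pct_first_larger`` = 100 · n_first / (n_clades − n_tie); NA when every
    clade ties.  Errored outcomes are excluded from the tally.
    """
    rows: dict[tuple[str, str, str], dict] = {}
    for res in results:
        out = res.outcomes.get(metric)
        if out is None or out.larger_habitat == "error":
            continue
        key = (res.scale, res.habitat_a, res.habitat_b)
        row = rows.setdefault(
            key,
            {
                "scale": res.scale,
                "habitat_a": res.habitat_a,
                "habitat_b": res.habitat_b,
                "metric": metric,
                "n_clades": 0,
                "n_first_larger": 0,
                "n_second_larger": 0,
                "n_tie": 0,
            },
        )
        row["n_clades"] += 1
        if out.larger_habitat == res.habitat_a:
            row["n_first_larger"] += 1
        elif out.larger_habitat == res.habitat_b:
            row["n_second_larger"] += 1
        else:
            row["n_tie"] += 1
    out_rows = []
    for row in rows.values():
        denom = row["n_clades"] - row["n_tie"]
        row["pct_first_larger"] = (
            100.0 * row["n_first_larger"] / denom if denom else np.nan
        )
        out_rows.append(row)
    df = pd.DataFrame(out_rows)
    if len(df):
        df = df.sort_values(["scale", "habitat_a", "habitat_b"]).reset_index(drop=True)
    return df


def donut_table(results: list[ComparisonResult], metric: str = "mean_log10") -> pd.DataFrame:
    """Order-scale per-pair counts plus completeness = n_pair / max n_pair."""
    df = majority_summaries([r for r in results if r.scale == "order"], metric)
    if not len(df):
        return df
    df = df.copy()
    df["completeness"] = df["n_clades"] / df["n_clades"].max()
    return df


def reduce_and_retain(
    dataset: Dataset,
    scales: list[CladeScale],
    config: Optional[EngineConfig] = None,
    full_results: Optional[list[ComparisonResult]] = None,
) -> tuple[list[ComparisonResult], Dataset, list[CladeScale]]:
    """The reduced-and-retained protocol.

    Prunes to trophic-complete taxa, reruns the size comparisons on the
    pruned data, and flags ``retained=True`` only where the pruned-data
    direction matches the full-data direction (phylogenetic-mean metric by
    default; ``retain_mode='all'`` requires agreement on every metric run).
    Returns (pruned results with flags, pruned dataset, pruned scales).
    """
    config = config or EngineConfig()
    keep = [r.species_id for r in dataset.records if r.trophic_level is not None]
    if len(keep) < 2:
        raise ValueError("fewer than two taxa have trophic data")
    if full_results is None:
        full_results = run_all(dataset, scales, config)
    pruned_ds = dataset.subset(keep) if len(keep) < dataset.n_taxa else dataset
    keepset = set(keep)
    pruned_scales = []
    for sc in scales:
        clades = []
        for cid, tips in sc.clades:
            cut = frozenset(tips & keepset)
            if cut:
                clades.append((cid, cut))
        pruned_scales.append(CladeScale(scale_name=sc.scale_name, clades=clades))
    pruned_results = run_all(pruned_ds, pruned_scales, config)

    anchor_metrics = (
        list(config.metrics) if config.retain_mode == "all" else ["phylo_mean"]
    )
    full_by_key = {r.key(): r for r in full_results}
    for res in pruned_results:
        full = full_by_key.get(res.key())
        if full is None:
            res.retained = False
            continue
        ok = True
        for metric in anchor_metrics:
            po = res.outcomes.get(metric)
            fo = full.outcomes.get(metric)
            if (
                po is None
                or fo is None
                or po.larger_habitat in ("tie", "error")
                or po.larger_habitat != fo.larger_habitat
            ):
                ok = False
                break
        res.retained = ok
    return pruned_results, pruned_ds, pruned_scales


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Long-format per-comparison table (one row per metric outcome)."""
    rows = []
    for res in results:
        for metric, out in sorted(res.outcomes.items()):
            rows.append(
                {
                    "scale": res.scale,
                    "clade_id": res.clade_id,
                    "habitat_a": res.habitat_a,
                    "habitat_b": res.habitat_b,
                    "metric": metric,
                    "n_a": out.n_first,
                    "n_b": out.n_second,
                    "larger_habitat": out.larger_habitat,
                    "signed_difference": out.signed_difference,
                    "p_value": out.p_value if out.p_value is not None else np.nan,
                    "significance_band": significance_band(out.p_value),
                    "retained": res.retained,
                }
            )
    return pd.DataFrame(rows)
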