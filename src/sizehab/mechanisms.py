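"""Metric alignments, signed-difference regressions, and mechanism support.

A comparison's "direction" is which habitat holds the larger value.  Two
metrics are *aligned* in a clade when the same habitat is larger under both.
The mechanism classifier scores each retained comparison against four suites:

- A  — the size-larger habitat also has the higher phylogenetic mean
       trophic level (A′ uses the non-phylogenetic mean);
- Bi — the size-larger habitat has a migratory percentage at least 20
       percentage points above the other (20 exactly counts as supported);
- Bii  = A ∧ Bi;  Biii = Bi ∧ ¬A;
- C  — the size-larger habitat has the strictly larger mean tip branch
       duration;
- D  — the size-larger habitat has the strictly lower species richness.

Aggregates report per-pair and overall percentages, the Bii′ = Bii/Bi and
Biii′ = Biii/Bi ratios (NA when Bi = 0), the A∨Biii union and the
any-of-four union, counting no comparison more than once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from sizehab.engine import ComparisonResult
from sizehab.model import Dataset
from sizehab.scales import CladeScale
from sizehab.stats import habitat_summaries, variance_vs_sim

__all__ = [
    "AlignmentCell",
    "MechanismLedger",
    "clade_summaries",
    "metric_differences",
    "percentage_alignment",
    "continuous_association",
    "classify_mechanisms",
    "classify_all",
    "aggregate_mechanisms",
    "ledgers_to_frame",
    "annotate_migration",
    "migration_band",
]

MIGRATION_GAP_PP = 20.0  # percentage points for Bi support

ALIGNMENT_METRICS = (
    "mean_size",
    "phylo_size",
    "mean_trophic",
    "phylo_trophic",
    "size_var",
    "trophic_var",
    "richness",
    "tip_duration",
    "migratory_pct",
)


@dataclass
class AlignmentCell:
    scale: str
    habitat_a: str
    habitat_b: str
    metric_pair: tuple[str, str]
    n_compared: int
    n_aligned: int
    n_tied: int

    @property
    def pct_aligned(self) -> float:
        return 100.0 * self.n_aligned / self.n_compared if self.n_compared else float("nan")


@dataclass
class MechanismLedger:
    """Indicator vector for one retained comparison (None = unknown)."""

    scale: str
    clade_id: str
    habitat_a: str
    habitat_b: str
    larger_habitat: str
    A: Optional[bool] = None
    A_prime: Optional[bool] = None
    Bi: Optional[bool] = None
    C: Optional[bool] = None
    D: Optional[bool] = None

    @property
    def Bii(self) -> Optional[bool]:
        return _and(self.A, self.Bi)

    @property
    def Biii(self) -> Optional[bool]:
        return _and(_not(self.A), self.Bi)

    @property
    def A_or_Biii(self) -> Optional[bool]:
        return _or(self.A, self.Biii)

    @property
    def any_of_four(self) -> Optional[bool]:
        return _or(_or(self.A, self.Bi), _or(self.C, self.D))


def _and(x: Optional[bool], y: Optional[bool]) -> Optional[bool]:
    if x is False or y is False:
        return False
    if x is None or y is None:
        return None
    return True


def _or(x: Optional[bool], y: Optional[bool]) -> Optional[bool]:
    if x is True or y is True:
        return True
    if x is None or y is None:
        return None
    return False


def _not(x: Optional[bool]) -> Optional[bool]:
    return None if x is None else not x


# ------------------------------------------------------------ summaries


def clade_summaries(
    dataset: Dataset, scales: list[CladeScale]
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-habitat summary table for every clade of every scale."""
    out = {}
    for sc in scales:
        for cid, tips in sc.clades:
            sub = dataset.subset(tips) if len(tips) < dataset.n_taxa else dataset
            out[(sc.scale_name, cid)] = habitat_summaries(sub)
    return out


def metric_differences(
    results: list[ComparisonResult],
    summaries: dict[tuple[str, str], pd.DataFrame],
    dataset: Optional[Dataset] = None,
    scales: Optional[list[CladeScale]] = None,
    include_variance: bool = False,
    n_sim: int = 199,
    seed: int = 0,
    retained_only: bool = False,
) -> pd.DataFrame:
    """Wide signed-difference table: one row per comparison, one column per
    alignment metric (positive ⇔ larger in the first habitat)."""
    var_cache: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
    if include_variance:
        if dataset is None or scales is None:
            raise ValueError("variance metrics need the dataset and scales")
        clade_tips = {
            (sc.scale_name, cid): tips for sc in scales for cid, tips in sc.clades
        }
    rows = []
    for res in results:
        if retained_only and not res.retained:
            continue
        summ = summaries.get((res.scale, res.clade_id))
        if summ is None:
            continue
        a, b = res.habitat_a, res.habitat_b
        if a not in summ.index or b not in summ.index:
            continue

        def sdiff(col: str) -> float:
            return float(summ.loc[a, col] - summ.loc[b, col])

        row = {
            "scale": res.scale,
            "clade_id": res.clade_id,
            "habitat_a": a,
            "habitat_b": b,
            "retained": res.retained,
            "mean_size": _signed(res, "mean_log10"),
            "phylo_size": _signed(res, "phylo_mean"),
            "mean_trophic": sdiff("trophic_mean"),
            "phylo_trophic": sdiff("trophic_phylo_mean"),
            "richness": sdiff("richness"),
            "tip_duration": sdiff("mean_tip_duration"),
            "migratory_pct": sdiff("migratory_pct"),
        }
        if include_variance:
            key = (res.scale, res.clade_id)
            if key not in var_cache:
                var_cache[key] = _clade_variance_quantiles(
                    dataset, clade_tips[key], n_sim=n_sim, seed=seed
                )
            vq = var_cache[key]
            row["size_var"] = _qdiff(vq, "log10_size", a, b)
            row["trophic_var"] = _qdiff(vq, "trophic_level", a, b)
        else:
            row["size_var"] = np.nan
            row["trophic_var"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _signed(res: ComparisonResult, metric: str) -> float:
    out = res.outcomes.get(metric)
    if out is None or out.larger_habitat == "error":
        return np.nan
    return out.signed_difference


def _clade_variance_quantiles(
    dataset: Dataset, tips: frozenset, n_sim: int, seed: int
) -> dict[str, dict[str, float]]:
    """Observed-vs-simulated variance quantile per habitat and trait."""
    sub = dataset.subset(tips) if len(tips) < dataset.n_taxa else dataset
    habs = np.asarray(sub.habitats())
    out: dict[str, dict[str, float]] = {}
    for trait in ("log10_size", "trophic_level"):
        y = sub.trait_vector(trait)
        mask_known = ~np.isnan(y)
        qs: dict[str, float] = {}
        if mask_known.sum() >= 2:
            if trait == "trophic_level" and mask_known.sum() < len(y):
                sub2 = sub.subset(np.asarray(sub.tree.tip_labels)[mask_known])
                y2 = sub2.trait_vector(trait)
                habs2 = np.asarray(sub2.habitats())
            else:
                sub2, y2, habs2 = sub, y, habs
            for h in np.unique(habs2):
                m = habs2 == h
                if m.sum() >= 2 and np.var(y2[m]) > 0:
                    qs[h] = variance_vs_sim(
                        sub2.tree, y2, m, habitat=h, n_sim=n_sim, seed=seed
                    ).quantile
        out[trait] = qs
    return out


def _qdiff(vq: dict, trait: str, a: str, b: str) -> float:
    qa, qb = vq[trait].get(a), vq[trait].get(b)
    if qa is None or qb is None:
        return np.nan
    return qa - qb


# ------------------------------------------------------------ alignment


def percentage_alignment(
    table: pd.DataFrame, metric1: str, metric2: str
) -> list[AlignmentCell]:
    """Per scale × habitat-pair percentage of clades where two metrics agree
    on which habitat is larger.  Ties/missing are excluded and counted."""
    for m in (metric1, metric2):
        if m not in table.columns:
            raise KeyError(f"metric {m!r} not in table")
    cells = []
    for (scale, a, b), grp in table.groupby(
        ["scale", "habitat_a", "habitat_b"], sort=True
    ):
        d1 = grp[metric1].to_numpy(dtype=float)
        d2 = grp[metric2].to_numpy(dtype=float)
        usable = ~np.isnan(d1) & ~np.isnan(d2)
        tied = usable & ((d1 == 0) | (d2 == 0))
        ok = usable & ~tied
        aligned = int(np.sum(np.sign(d1[ok]) == np.sign(d2[ok])))
        cells.append(
            AlignmentCell(
                scale=scale,
                habitat_a=a,
                habitat_b=b,
                metric_pair=(metric1, metric2),
                n_compared=int(ok.sum()),
                n_aligned=aligned,
                n_tied=int(tied.sum()),
            )
        )
    return cells


def alignment_frame(cells: Sequence[AlignmentCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scale": c.scale,
                "habitat_a": c.habitat_a,
                "habitat_b": c.habitat_b,
                "metric_1": c.metric_pair[0],
                "metric_2": c.metric_pair[1],
                "n_compared": c.n_compared,
                "n_aligned": c.n_aligned,
                "n_tied": c.n_tied,
                "pct_aligned": c.pct_aligned,
            }
            for c in cells
        ]
    )


def continuous_association(
    table: pd.DataFrame,
    metric_x: str,
    metric_y: str,
    habitat_pair: tuple[str, str],
    scale: Optional[str] = None,
) -> dict:
    """OLS of ΔY on ΔX across clades for one habitat pair.

    Returns slope/r²/p, sign-quadrant counts (``++``/``--`` agree), and a
    leave-one-out report flagging clades whose removal flips either the
    slope sign or 0.05 significance.
    """
    sel = (table["habitat_a"] == habitat_pair[0]) & (
        table["habitat_b"] == habitat_pair[1]
    )
    if scale is not None:
        sel &= table["scale"] == scale
    grp = table[sel].dropna(subset=[metric_x, metric_y])
    x = grp[metric_x].to_numpy(dtype=float)
    y = grp[metric_y].to_numpy(dtype=float)
    quad = {
        "++": int(np.sum((x > 0) & (y > 0))),
        "+-": int(np.sum((x > 0) & (y < 0))),
        "-+": int(np.sum((x < 0) & (y > 0))),
        "--": int(np.sum((x < 0) & (y < 0))),
    }
    out = {
        "n": len(x),
        "quadrant_counts": quad,
        "slope": np.nan,
        "intercept": np.nan,
        "r2": np.nan,
        "p": np.nan,
        "influential_clades": [],
    }
    if len(x) < 3:
        return out
    if np.var(x) == 0:
        return out  # slope undefined; quadrants still reported
    fit = sps.linregress(x, y)
    out.update(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
    )
    ids = grp["clade_id"].tolist()
    sig = fit.pvalue < 0.05
    flags = []
    for i in range(len(x)):
        xs = np.delete(x, i)
        ys = np.delete(y, i)
        if len(xs) < 3 or np.var(xs) == 0:
            continue
        f2 = sps.linregress(xs, ys)
        if (f2.pvalue < 0.05) != sig or np.sign(f2.slope) != np.sign(fit.slope):
            flags.append(ids[i])
    out["influential_clades"] = flags
    return out


# ----------------------------------------------------------- mechanisms


def classify_mechanisms(
    comparison: ComparisonResult, summary: pd.DataFrame
) -> MechanismLedger:
    """Score one comparison against the mechanism suites.

    ``summary`` is the clade's per-habitat table from
    :func:`sizehab.stats.habitat_summaries`.  Missing trophic or migration
    data leave the affected indicators unknown (None).
    """
    size_out = comparison.outcomes.get("phylo_mean") or comparison.outcomes.get(
        "mean_log10"
    )
    if size_out is None or size_out.larger_habitat in ("tie", "error"):
        raise ValueError("comparison has no usable size direction")
    larger = size_out.larger_habitat
    other = (
        comparison.habitat_b if larger == comparison.habitat_a else comparison.habitat_a
    )

    def strictly_greater(col: str) -> Optional[bool]:
        va, vb = summary.loc[larger, col], summary.loc[other, col]
        if pd.isna(va) or pd.isna(vb):
            return None
        return bool(va > vb)

    def strictly_lower(col: str) -> Optional[bool]:
        va, vb = summary.loc[larger, col], summary.loc[other, col]
        if pd.isna(va) or pd.isna(vb):
            return None
        return bool(va < vb)

    mig_l = summary.loc[larger, "migratory_pct"]
    mig_o = summary.loc[other, "migratory_pct"]
    Bi = (
        None
        if pd.isna(mig_l) or pd.isna(mig_o)
        else bool(mig_l >= mig_o + MIGRATION_GAP_PP)
    )
    return MechanismLedger(
        scale=comparison.scale,
        clade_id=comparison.clade_id,
        habitat_a=comparison.habitat_a,
        habitat_b=comparison.habitat_b,
        larger_habitat=larger,
        A=strictly_greater("trophic_phylo_mean"),
        A_prime=strictly_greater("trophic_mean"),
        Bi=Bi,
        C=strictly_greater("mean_tip_duration"),
        D=strictly_lower("richness"),
    )


def classify_all(
    results: list[ComparisonResult],
    summaries: dict[tuple[str, str], pd.DataFrame],
    retained_only: bool = True,
) -> list[MechanismLedger]:
    ledgers = []
    for res in results:
        if retained_only and not res.retained:
            continue
        summ = summaries.get((res.scale, res.clade_id))
        if summ is None:
            continue
        try:
            ledgers.append(classify_mechanisms(res, summ))
        except (ValueError, KeyError):
            continue
    return ledgers


_COLUMNS = ("A", "A_prime", "Bi", "Bii", "Biii", "A_or_Biii", "C", "D", "any_of_four")


def aggregate_mechanisms(ledgers: Sequence[MechanismLedger]) -> pd.DataFrame:
    """Per habitat-pair and overall counts/percentages for every column.

    Unknown indicators are excluded from their column's denominator.
    ``Bii_prime_pct`` and ``Biii_prime_pct`` are Bii/Bi and Biii/Bi as
    percentages, NA when no Bi-supported comparison exists.
    """
    if not ledgers:
        raise ValueError("no ledgers to aggregate")
    groups: dict[tuple[str, str], list[MechanismLedger]] = {}
    for led in ledgers:
        groups.setdefault((led.habitat_a, led.habitat_b), []).append(led)
    rows = []
    for key in sorted(groups) + [("all", "all")]:
        sub = ledgers if key == ("all", "all") else groups[key]
        row: dict = {
            "habitat_a": key[0],
            "habitat_b": key[1],
            "n_comparisons": len(sub),
        }
        for col in _COLUMNS:
            vals = [getattr(led, col) for led in sub]
            known = [v for v in vals if v is not None]
            n_true = sum(bool(v) for v in known)
            row[f"{col}_n"] = n_true
            row[f"{col}_known"] = len(known)
            row[f"{col}_pct"] = (
                100.0 * n_true / len(known) if known else np.nan
            )
        n_bi = row["Bi_n"]
        row["Bii_prime_pct"] = 100.0 * row["Bii_n"] / n_bi if n_bi else np.nan
        row["Biii_prime_pct"] = 100.0 * row["Biii_n"] / n_bi if n_bi else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def ledgers_to_frame(ledgers: Sequence[MechanismLedger]) -> pd.DataFrame:
    def fmt(v: Optional[bool]) -> object:
        return np.nan if v is None else int(v)

    return pd.DataFrame(
        [
            {
                "scale": led.scale,
                "clade_id": led.clade_id,
                "habitat_a": led.habitat_a,
                "habitat_b": led.habitat_b,
                "larger_habitat": led.larger_habitat,
                "A": fmt(led.A),
                "A_prime": fmt(led.A_prime),
                "Bi": fmt(led.Bi),
                "Bii": fmt(led.Bii),
                "Biii": fmt(led.Biii),
                "A_or_Biii": fmt(led.A_or_Biii),
                "C": fmt(led.C),
                "D": fmt(led.D),
                "any_of_four": fmt(led.any_of_four),
            }
            for led in ledgers
        ]
    )


def migration_band(pct: float) -> str:
    """``M`` above 30%, ``m`` for 5–30% inclusive, ``none`` below 5%."""
    if np.isnan(pct):
        return "unknown"
    if pct > 30.0:
        return "M"
    if pct >= 5.0:
        return "m"
    return "none"


def annotate_migration(
    summaries: dict[tuple[str, str], pd.DataFrame]
) -> pd.DataFrame:
    rows = []
    for (scale, cid), summ in sorted(summaries.items()):
        for habitat, row in summ.iterrows():
            rows.append(
                {
                    "scale": scale,
                    "clade_id": cid,
                    "habitat": habitat,
                    "migratory_pct": row["migratory_pct"],
                    "band": migration_band(row["migratory_pct"]),
                }
            )
    return pd.DataFrame(rows)
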