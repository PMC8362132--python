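"""Observation scales: named clade sets over which all comparisons run.

Nine scales are supported: ``family`` and ``order`` (from table labels),
``tax3``–``tax6`` (deterministic partitions of the tree into 13, 9, 5 and 3
monophyletic sections by default), ``full`` (one clade), and ``hotspot`` /
``hotspot_expanded`` (clades ranked by stochastic-map transition events per
tip).

The tax-scale splitting criterion — repeatedly split the clade with the most
tips at its root, ties broken by lexicographically smallest contained tip
label — is a documented deterministic stand-in for a construction the source
analyses left unspecified, as is the hotspot ranking rule.  Both are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from sizehab.model import Dataset
from sizehab.tree import Phylogeny

__all__ = [
    "CladeScale",
    "DEFAULT_TAX_SECTIONS",
    "scale_from_labels",
    "partition_tree",
    "split_sequence",
    "hotspot_scale",
    "build_scales",
    "scales_to_frame",
    "scales_from_frame",
]

DEFAULT_TAX_SECTIONS = {"tax3": 13, "tax4": 9, "tax5": 5, "tax6": 3}

SCALE_NAMES = (
    "family",
    "order",
    "tax3",
    "tax4",
    "tax5",
    "tax6",
    "full",
    "hotspot",
    "hotspot_expanded",
)


@dataclass
class CladeScale:
    """One observation scale: a named list of (clade_id, tip-label set)."""

    scale_name: str
    clades: list[tuple[str, frozenset[str]]]
    warnings: list[str] = field(default_factory=list)

    def coverage(self) -> frozenset[str]:
        out: set[str] = set()
        for _, tips in self.clades:
            out |= tips
        return frozenset(out)

    def is_partition_of(self, tips: set[str]) -> bool:
        total = sum(len(t) for _, t in self.clades)
        return total == len(tips) and self.coverage() == frozenset(tips)


def scale_from_labels(dataset: Dataset, level: str) -> CladeScale:
    """One clade per distinct family/order label; monophyly is checked."""
    if level not in ("family", "order"):
        raise ValueError("level must be 'family' or 'order'")
    unlabeled = [r.species_id for r in dataset.records if getattr(r, level) is None]
    if unlabeled:
        raise ValueError(f"taxa missing {level} labels: {sorted(unlabeled)[:10]}")
    groups: dict[str, set[str]] = {}
    for r in dataset.records:
        groups.setdefault(getattr(r, level), set()).add(r.species_id)
    warnings = []
    clades = []
    tree = dataset.tree
    for name in sorted(groups):
        tips = groups[name]
        if len(tips) == 1:
            warnings.append(f"{level} {name!r} is a singleton")
        else:
            ids = tree.tip_ids(sorted(tips))
            mrca_tips = {tree.tip_labels[i] for i in tree.subtree_tips(tree.mrca(ids))}
            if mrca_tips != tips:
                warnings.append(f"{level} {name!r} is not monophyletic in the tree")
        clades.append((name, frozenset(tips)))
    return CladeScale(scale_name=level, clades=clades, warnings=warnings)


def split_sequence(tree: Phylogeny, k: int) -> list[int]:
    """Node ids of the k disjoint monophyletic sections covering all tips.

    Iteratively replaces the section with the most tips by its root's
    children; ties break on the lexicographically smallest contained tip
    label, making the result invariant to tip-order permutations of the
    input Newick.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > tree.n_tips:
        raise ValueError(f"k={k} exceeds n_tips={tree.n_tips}")
    counts = tree.n_subtree_tips()
    min_label = [""] * tree.n_nodes
    for nd in tree.postorder():
        if nd < tree.n_tips:
            min_label[nd] = tree.tip_labels[nd]
        else:
            min_label[nd] = min(min_label[c] for c in tree.children[nd])
    sections = [tree.root]
    while len(sections) < k:
        splittable = [nd for nd in sections if tree.children[nd]]
        if not splittable:
            break
        best_count = max(counts[nd] for nd in splittable)
        cands = [nd for nd in splittable if counts[nd] == best_count]
        target = min(cands, key=lambda nd: min_label[nd])
        sections = [nd for nd in sections if nd != target] + list(tree.children[target])
    return sorted(sections, key=lambda nd: min_label[nd])


def partition_tree(tree: Phylogeny, k: int, scale_name: Optional[str] = None) -> CladeScale:
    """Partition the tree into exactly k monophyletic sections."""
    nodes = split_sequence(tree, k)
    warnings = []
    if len(nodes) != k:
        warnings.append(
            f"requested {k} sections but produced {len(nodes)} (polytomy limit)"
        )
    width = max(2, len(str(k)))
    clades = []
    for j, nd in enumerate(nodes):
        tips = frozenset(tree.tip_labels[i] for i in tree.subtree_tips(nd))
        clades.append((f"c{j + 1:0{width}d}", tips))
    return CladeScale(scale_name=scale_name or f"tax_k{k}", clades=clades, warnings=warnings)


def hotspot_scale(
    dataset: Dataset,
    transition_summary,
    top_m: int = 2,
    expand: bool = False,
    base: Optional[CladeScale] = None,
) -> CladeScale:
    """Top clades by stochastic-map transition events per tip.

    Candidates come from the order scale unless ``base`` is given.  Each
    event is attributed fractionally to the tips below its edge, so a
    clade's score is the per-tip density of habitat changes in its history.
    With ``expand=True`` each hotspot is merged with its sister clade.
    """
    if transition_summary is None or not hasattr(transition_summary, "tip_event_rate"):
        raise ValueError("transition summary with tip_event_rate required")
    if base is None:
        base = scale_from_labels(dataset, "order")
    rate = transition_summary.tip_event_rate
    warnings = list(base.warnings)
    scored = []
    for cid, tips in base.clades:
        score = sum(rate.get(t, 0.0) for t in tips) / len(tips)
        scored.append((score, cid, tips))
    scored.sort(key=lambda x: (-x[0], x[1]))
    if top_m > len(scored):
        warnings.append(
            f"top_m={top_m} exceeds {len(scored)} candidate clades; returning all"
        )
        top_m = len(scored)
    chosen = scored[:top_m]
    tree = dataset.tree
    clades = []
    name = "hotspot_expanded" if expand else "hotspot"
    for _, cid, tips in chosen:
        if expand:
            ids = tree.tip_ids(sorted(tips))
            node = tree.mrca(ids) if len(ids) > 1 else ids[0]
            if node == tree.root:
                warnings.append(f"hotspot {cid!r} spans the root; no sister to merge")
                clades.append((f"{cid}+sister", tips))
                continue
            parent = tree.parent[node]
            merged = frozenset(
                tree.tip_labels[i] for i in tree.subtree_tips(parent)
            )
            clades.append((f"{cid}+sister", merged))
        else:
            clades.append((cid, tips))
    return CladeScale(scale_name=name, clades=clades, warnings=warnings)


def build_scales(
    dataset: Dataset,
    names: tuple[str, ...] = ("family", "order", "tax3", "tax4", "tax5", "tax6", "full"),
    tax_sections: Optional[dict[str, int]] = None,
    transition_summary=None,
    hotspot_top_m: int = 2,
) -> list[CladeScale]:
    """Build the requested scales in one call (hotspots need transitions)."""
    sections = dict(DEFAULT_TAX_SECTIONS)
    if tax_sections:
        sections.update(tax_sections)
    out = []
    for name in names:
        if name in ("family", "order"):
            out.append(scale_from_labels(dataset, name))
        elif name in sections:
            k = min(sections[name], dataset.tree.n_tips)
            out.append(partition_tree(dataset.tree, k, scale_name=name))
        elif name == "full":
            out.append(
                CladeScale("full", [("all", frozenset(dataset.species()))])
            )
        elif name in ("hotspot", "hotspot_expanded"):
            out.append(
                hotspot_scale(
                    dataset,
                    transition_summary,
                    top_m=hotspot_top_m,
                    expand=(name == "hotspot_expanded"),
                )
            )
        else:
            raise ValueError(f"unknown scale {name!r}")
    return out


def scales_to_frame(scales: list[CladeScale]) -> pd.DataFrame:
    rows = [
        {"scale": sc.scale_name, "clade_id": cid, "species": sp}
        for sc in scales
        for cid, tips in sc.clades
        for sp in sorted(tips)
    ]
    return pd.DataFrame(rows, columns=["scale", "clade_id", "species"])


def scales_from_frame(df: pd.DataFrame) -> list[CladeScale]:
    out = []
    for scale, grp in df.groupby("scale", sort=True):
        clades = [
            (cid, frozenset(sub["species"]))
            for cid, sub in grp.groupby("clade_id", sort=True)
        ]
        out.append(CladeScale(scale_name=str(scale), clades=clades))
    return out
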