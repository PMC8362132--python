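"""Domain types: taxon records, matched datasets, and the taxon-table format.

Sizes are stored as log10(cm) at ingest; the TSV interface carries raw
``max_length_cm`` and the transform is applied exactly once on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from sizehab.tree import Phylogeny

# All six habitat-use categories.  Exclusively-brackish taxa are retained in
# datasets and transition analyses but excluded from pairwise size
# comparisons, which run over the other five categories only.
ALL_HABITATS = (
    "marine",
    "freshwater",
    "brackish",
    "marine_brackish",
    "freshwater_brackish",
    "euryhaline",
)

# Canonical order fixing sign conventions: a positive signed difference
# means the first-listed habitat of a pair is larger.
COMPARISON_HABITATS = (
    "freshwater",
    "freshwater_brackish",
    "marine",
    "marine_brackish",
    "euryhaline",
)

HABITAT_PAIRS = tuple(
    (COMPARISON_HABITATS[i], COMPARISON_HABITATS[j])
    for i in range(len(COMPARISON_HABITATS))
    for j in range(i + 1, len(COMPARISON_HABITATS))
)


def normalise_name(name: str) -> str:
    return name.strip().replace(" ", "_")


@dataclass
class TaxonRecord:
    """One species: habitat use, size, and optional ecology/taxonomy."""

    species_id: str
    habitat: str
    log10_size: float
    trophic_level: Optional[float] = None
    migratory: Optional[bool] = None
    family: Optional[str] = None
    order: Optional[str] = None

    def __post_init__(self) -> None:
        self.species_id = normalise_name(self.species_id)
        if self.habitat not in ALL_HABITATS:
            raise ValueError(
                f"{self.species_id}: habitat {self.habitat!r} not one of {ALL_HABITATS}"
            )
        if not math.isfinite(self.log10_size):
            raise ValueError(f"{self.species_id}: non-finite log10_size")
        if self.trophic_level is not None and not (1.0 < self.trophic_level <= 6.0):
            raise ValueError(
                f"{self.species_id}: trophic_level {self.trophic_level} outside (1, 6]"
            )


@dataclass
class MatchReport:
    n_tips_dropped: int = 0
    n_records_dropped: int = 0
    dropped_tips: list[str] = field(default_factory=list)
    dropped_records: list[str] = field(default_factory=list)


@dataclass
class Dataset:
    """A phylogeny matched one-to-one with taxon records."""

    tree: Phylogeny
    records: list[TaxonRecord]

    def __post_init__(self) -> None:
        by_id = {r.species_id: r for r in self.records}
        if len(by_id) != len(self.records):
            raise ValueError("duplicate species_id in records")
        tipset = set(self.tree.tip_labels)
        if tipset != set(by_id):
            raise ValueError(
                "tree tips and records disagree: "
                f"{sorted(tipset ^ set(by_id))[:5]}..."
            )
        self._by_id = by_id

    def record(self, species_id: str) -> TaxonRecord:
        return self._by_id[species_id]

    @property
    def n_taxa(self) -> int:
        return len(self.records)

    def species(self) -> list[str]:
        return [r.species_id for r in self.records]

    def subset(self, species_ids: Iterable[str]) -> "Dataset":
        """Dataset pruned to the given species (tree depths preserved)."""
        keep = sorted(set(species_ids))
        tree = self.tree.prune_to(keep)
        recs = [self._by_id[s] for s in keep]
        return Dataset(tree=tree, records=recs)

    def trait_vector(self, trait: str = "log10_size") -> np.ndarray:
        """Trait values ordered by the tree's tip index (NaN for missing)."""
        vals = [getattr(self._by_id[lab], trait) for lab in self.tree.tip_labels]
        return np.array([np.nan if v is None else float(v) for v in vals])

    def habitats(self) -> list[str]:
        return [self._by_id[lab].habitat for lab in self.tree.tip_labels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species_id for r in self.records],
                "habitat": [r.habitat for r in self.records],
                "log10_size": [r.log10_size for r in self.records],
                "trophic_level": [r.trophic_level for r in self.records],
                "migratory": [r.migratory for r in self.records],
                "family": [r.family for r in self.records],
                "order": [r.order for r in self.records],
            }
        )


def match_tree_table(
    tree: Phylogeny, records: list[TaxonRecord]
) -> tuple[Dataset, MatchReport]:
    """Prune tree and table to their common species set.

    Matching is exact string equality after underscore/space normalisation.
    Raises ``ValueError`` on an empty intersection.
    """
    by_id = {r.species_id: r for r in records}
    tips = set(tree.tip_labels)
    common = tips & set(by_id)
    if not common:
        raise ValueError("no species shared between tree and table")
    report = MatchReport(
        dropped_tips=sorted(tips - common),
        dropped_records=sorted(set(by_id) - common),
    )
    report.n_tips_dropped = len(report.dropped_tips)
    report.n_records_dropped = len(report.dropped_records)
    pruned = tree.prune_to(common) if report.n_tips_dropped else tree
    dataset = Dataset(tree=pruned, records=[by_id[s] for s in sorted(common)])
    return dataset, report


_TABLE_COLUMNS = [
    "species",
    "habitat",
    "max_length_cm",
    "trophic_level",
    "migratory",
    "family",
    "order",
]


def read_taxon_table(path: str) -> list[TaxonRecord]:
    """Read the TSV taxon table (see README for the column contract)."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    required = {"species", "habitat", "max_length_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxon table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        size = float(row.max_length_cm)
        if not (size > 0 and math.isfinite(size)):
            raise ValueError(f"{row.species}: max_length_cm must be positive finite")
        troph = getattr(row, "trophic_level", None)
        troph = None if troph is None or pd.isna(troph) else float(troph)
        mig = getattr(row, "migratory", None)
        if mig is None or pd.isna(mig):
            mig = None
        else:
            mig = bool(int(mig)) if not isinstance(mig, bool) else mig
        fam = getattr(row, "family", None)
        fam = None if fam is None or pd.isna(fam) else str(fam)
        ord_ = getattr(row, "order", None)
        ord_ = None if ord_ is None or pd.isna(ord_) else str(ord_)
        records.append(
            TaxonRecord(
                species_id=str(row.species),
                habitat=str(row.habitat),
                log10_size=math.log10(size),
                trophic_level=troph,
                migratory=mig,
                family=fam,
                order=ord_,
            )
        )
    return records


def write_taxon_table(records: list[TaxonRecord], path: str) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species_id,
                "habitat": r.habitat,
                "max_length_cm": f"{10 ** r.log10_size:.10g}",
                "trophic_level": "" if r.trophic_level is None else f"{r.trophic_level:.10g}",
                "migratory": "" if r.migratory is None else int(r.migratory),
                "family": r.family or "",
                "order": r.order or "",
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
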