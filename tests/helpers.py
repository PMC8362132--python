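"""Shared construction helpers for the test suite."""

from sizehab.model import Dataset, TaxonRecord
from sizehab.tree import Phylogeny


def star_newick(n: int, depth: float = 1.0) -> str:
    tips = ",".join(f"t{i:02d}:{depth}" for i in range(n))
    return f"({tips}):0;"


def make_dataset(tree: Phylogeny, habitats, sizes, trophic=None, migratory=None,
                 family=None, order=None) -> Dataset:
    records = []
    for i, lab in enumerate(tree.tip_labels):
        records.append(
            TaxonRecord(
                species_id=lab,
                habitat=habitats[i],
                log10_size=float(sizes[i]),
                trophic_level=None if trophic is None else trophic[i],
                migratory=None if migratory is None else migratory[i],
                family=None if family is None else family[i],
                order=None if order is None else order[i],
            )
        )
    return Dataset(tree=tree, records=records)
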