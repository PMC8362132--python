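"""Seeded synthetic datasets with the statistical structure the analysis assumes.

The generator produces a birth–death tree, Mk-evolved habitat states with a
full event log (the "true history"), habitat-shifted Brownian log10 sizes,
size-correlated trophic levels, habitat-specific migratory fractions, and
monophyletic order/family labels.  Default parameters reproduce the
three-tier size pattern (freshwater < {freshwater-brackish, marine} <
{euryhaline, marine-brackish}) and a ~30% migratory fraction in euryhaline
taxa.

The habitat effect on size is a tip-level offset added to a neutral BM
realisation — a deliberate simplification that yields the mean-shift
structure while keeping BM-based tests approximately calibrated.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from sizehab.model import ALL_HABITATS, Dataset, TaxonRecord, write_taxon_table
from sizehab.tree import Phylogeny, simulate_bm, write_newick

__all__ = [
    "SimulationConfig",
    "TrueHistory",
    "SimResult",
    "default_q",
    "simulate_tree",
    "simulate_habitats",
    "simulate_traits",
    "generate_dataset",
    "write_dataset",
]

_MAX_RETRIES = 100


def default_q(scale: float = 1.0) -> np.ndarray:
    """Sparse 6×6 habitat generator over :data:`ALL_HABITATS`.

    Direct marine↔freshwater moves are rare; routes through the
    brackish-associated and euryhaline states are common.
    """
    idx = {h: i for i, h in enumerate(ALL_HABITATS)}
    Q = np.zeros((6, 6))

    def put(a: str, b: str, rate: float) -> None:
        Q[idx[a], idx[b]] = rate

    put("marine", "marine_brackish", 0.25)
    put("marine_brackish", "marine", 0.25)
    put("freshwater", "freshwater_brackish", 0.25)
    put("freshwater_brackish", "freshwater", 0.25)
    put("brackish", "marine_brackish", 0.20)
    put("marine_brackish", "brackish", 0.10)
    put("brackish", "freshwater_brackish", 0.20)
    put("freshwater_brackish", "brackish", 0.10)
    put("marine_brackish", "euryhaline", 0.12)
    put("euryhaline", "marine_brackish", 0.12)
    put("freshwater_brackish", "euryhaline", 0.12)
    put("euryhaline", "freshwater_brackish", 0.12)
    put("euryhaline", "marine", 0.10)
    put("euryhaline", "freshwater", 0.10)
    put("marine", "freshwater", 0.01)
    put("freshwater", "marine", 0.01)
    Q *= scale
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _default_offsets() -> dict[str, float]:
    return {
        "freshwater": 0.0,
        "freshwater_brackish": 0.2,
        "marine": 0.25,
        "brackish": 0.15,
        "euryhaline": 0.55,
        "marine_brackish": 0.6,
    }


def _default_trophic_offsets() -> dict[str, float]:
    return {h: 0.0 for h in ALL_HABITATS}


def _default_migration() -> dict[str, float]:
    return {
        "marine": 0.02,
        "freshwater": 0.02,
        "brackish": 0.05,
        "marine_brackish": 0.08,
        "freshwater_brackish": 0.08,
        "euryhaline": 0.30,
    }


@dataclass
class SimulationConfig:
    n_tips: int = 300
    birth_rate: float = 1.0
    death_rate: float = 0.0
    Q: np.ndarray = field(default_factory=default_q)
    root_habitat: str = "marine"
    habitat_size_offsets: dict[str, float] = field(default_factory=_default_offsets)
    bm_rate_size: float = 0.01
    root_size: float = 1.3  # log10 cm
    trophic_slope: float = 0.5
    trophic_intercept: float = 2.5
    trophic_noise_sd: float = 0.2
    trophic_habitat_offsets: dict[str, float] = field(
        default_factory=_default_trophic_offsets
    )
    trophic_missing_frac: float = 0.0
    migration_prob: dict[str, float] = field(default_factory=_default_migration)
    n_orders: int = 6
    n_families: int = 18
    seed: int = 0

    def validate(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (6, 6):
            raise ValueError("Q must be 6x6")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("Q off-diagonals must be non-negative")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-9:
            raise ValueError("Q rows must sum to zero")
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        for m in (self.habitat_size_offsets, self.trophic_habitat_offsets):
            for h, v in m.items():
                if h not in ALL_HABITATS or not np.isfinite(v):
                    raise ValueError(f"bad offset {h}={v}")
        for h, p in self.migration_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"migration_prob[{h}]={p} outside [0,1]")


@dataclass
class TrueHistory:
    """Habitat change events recorded while simulating, plus their tally."""

    states: tuple[str, ...]
    # (edge child node id, time from edge start, from_state, to_state)
    events: list[tuple[int, float, str, str]]
    counts: np.ndarray  # k×k, ordered from→to

    def check_conservation(self) -> bool:
        tally = np.zeros_like(self.counts)
        idx = {s: i for i, s in enumerate(self.states)}
        for _, _, a, b in self.events:
            tally[idx[a], idx[b]] += 1
        return bool(np.array_equal(tally, self.counts))


@dataclass
class SimResult:
    dataset: Dataset
    history: TrueHistory
    config: SimulationConfig


# --------------------------------------------------------------- tree


def simulate_tree(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> Phylogeny:
    """Forward birth–death tree stopped when ``n_tips`` lineages survive."""
    config.validate()
    if config.n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    b, d = config.birth_rate, config.death_rate
    for _ in range(_MAX_RETRIES):
        tree = _try_birth_death(config.n_tips, b, d, rng)
        if tree is not None:
            return tree
    raise RuntimeError(f"total extinction in {_MAX_RETRIES} consecutive attempts")


def _try_birth_death(
    n_target: int, b: float, d: float, rng: np.random.Generator
) -> Optional[Phylogeny]:
    birth_t = [0.0]
    split_t: list[Optional[float]] = [None]
    kids: list[list[int]] = [[]]
    alive = {0}
    t = 0.0
    while len(alive) < n_target:
        if not alive:
            return None
        total = len(alive) * (b + d)
        t += rng.exponential(1.0 / total)
        lin = sorted(alive)[rng.integers(len(alive))]
        if rng.random() < b / (b + d):
            split_t[lin] = t
            for _ in range(2):
                kids[lin].append(len(birth_t))
                birth_t.append(t)
                split_t.append(None)
                kids.append([])
                alive.add(len(birth_t) - 1)
            alive.discard(lin)
        else:
            alive.discard(lin)
            split_t[lin] = t  # marks death time; no kids ⇒ extinct tip
    # observe just before the next event so pendant edges are positive
    present = t + rng.exponential(1.0 / (len(alive) * (b + d)))

    label_of: dict[int, str] = {}
    counter = [0]

    def newick(node: int) -> Optional[str]:
        if not kids[node]:
            if node not in alive:
                return None
            counter[0] += 1
            lab = f"s{counter[0]:04d}"
            label_of[node] = lab
            return f"{lab}:{present - birth_t[node]:.12g}"
        sub = [newick(c) for c in kids[node]]
        sub = [s for s in sub if s is not None]
        if not sub:
            return None
        edge = split_t[node] - birth_t[node]
        if len(sub) == 1:
            # collapse unifurcation: absorb this edge into the child's
            inner, blen = sub[0].rsplit(":", 1)
            return f"{inner}:{float(blen) + edge:.12g}"
        return f"({','.join(sub)}):{edge:.12g}"

    text = newick(0)
    if text is None:
        return None
    if not text.startswith("("):  # single survivor — shouldn't happen with n>=2
        return None
    return Phylogeny.from_newick(text + ";")


# ------------------------------------------------------------ habitats


def simulate_habitats(
    tree: Phylogeny,
    Q: np.ndarray,
    root_state: str,
    rng: np.random.Generator,
    states: tuple[str, ...] = ALL_HABITATS,
) -> tuple[dict[str, str], TrueHistory]:
    """Continuous-time Markov simulation of habitat along every edge."""
    Q = np.asarray(Q, dtype=float)
    k = len(states)
    if Q.shape != (k, k):
        raise ValueError("Q shape does not match states")
    idx = {s: i for i, s in enumerate(states)}
    if root_state not in idx:
        raise ValueError(f"unknown root state {root_state!r}")
    node_state = np.empty(tree.n_nodes, dtype=np.int64)
    node_state[tree.root] = idx[root_state]
    events: list[tuple[int, float, str, str]] = []
    counts = np.zeros((k, k))
    for nd in tree.preorder():
        if nd == tree.root:
            continue
        s = node_state[tree.parent[nd]]
        t, t_end = 0.0, tree.edge_length[nd]
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= t_end:
                break
            probs = np.maximum(Q[s], 0.0)
            probs[s] = 0.0
            nxt = rng.choice(k, p=probs / probs.sum())
            events.append((nd, t, states[s], states[nxt]))
            counts[s, nxt] += 1
            s = nxt
        node_state[nd] = s
    tip_states = {tree.tip_labels[i]: states[node_state[i]] for i in range(tree.n_tips)}
    return tip_states, TrueHistory(states=states, events=events, counts=counts)


# -------------------------------------------------------------- traits


def simulate_traits(
    tree: Phylogeny,
    tip_habitats: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[TaxonRecord]:
    """Sizes, trophic levels, migratory flags and nested taxonomy labels."""
    from sizehab.scales import split_sequence

    n = tree.n_tips
    bm = simulate_bm(tree, config.bm_rate_size, 1, rng, root_value=config.root_size)[:, 0]
    habitats = [tip_habitats[lab] for lab in tree.tip_labels]
    size = bm + np.array([config.habitat_size_offsets.get(h, 0.0) for h in habitats])
    troph = (
        config.trophic_intercept
        + config.trophic_slope * size
        + np.array([config.trophic_habitat_offsets.get(h, 0.0) for h in habitats])
        + rng.normal(0.0, config.trophic_noise_sd, n)
    )
    troph = np.clip(troph, np.nextafter(1.0, 2.0), 6.0)
    troph_missing = rng.random(n) < config.trophic_missing_frac
    mig = rng.random(n) < np.array(
        [config.migration_prob.get(h, 0.0) for h in habitats]
    )

    n_orders = min(config.n_orders, n)
    n_families = min(max(config.n_families, n_orders), n)
    order_nodes = split_sequence(tree, n_orders)
    family_nodes = split_sequence(tree, n_families)
    order_of_tip: dict[int, str] = {}
    for j, nd in enumerate(order_nodes):
        for tip in tree.subtree_tips(nd):
            order_of_tip[tip] = f"O{j + 1:02d}"
    family_of_tip: dict[int, str] = {}
    for j, nd in enumerate(family_nodes):
        for tip in tree.subtree_tips(nd):
            family_of_tip[tip] = f"F{j + 1:03d}"

    records = []
    for i, lab in enumerate(tree.tip_labels):
        records.append(
            TaxonRecord(
                species_id=lab,
                habitat=habitats[i],
                log10_size=float(size[i]),
                trophic_level=None if troph_missing[i] else float(troph[i]),
                migratory=bool(mig[i]),
                family=family_of_tip[i],
                order=order_of_tip[i],
            )
        )
    return records


def generate_dataset(config: SimulationConfig) -> SimResult:
    """End-to-end seeded simulation: tree → habitats → traits."""
    config.validate()
    seqs = np.random.SeedSequence(config.seed).spawn(3)
    tree = simulate_tree(config, np.random.default_rng(seqs[0]))
    tip_states, history = simulate_habitats(
        tree, config.Q, config.root_habitat, np.random.default_rng(seqs[1])
    )
    records = simulate_traits(tree, tip_states, config, np.random.default_rng(seqs[2]))
    return SimResult(dataset=Dataset(tree=tree, records=records), history=history, config=config)


def write_dataset(result: SimResult, outdir: str) -> dict[str, str]:
    """Write tree.nwk, taxa.tsv and a truth.json sidecar; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "tree": os.path.join(outdir, "tree.nwk"),
        "taxa": os.path.join(outdir, "taxa.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_newick(result.dataset.tree, paths["tree"])
    write_taxon_table(result.dataset.records, paths["taxa"])
    cfg = result.config
    truth = {
        "seed": cfg.seed,
        "n_tips": cfg.n_tips,
        "birth_rate": cfg.birth_rate,
        "death_rate": cfg.death_rate,
        "Q": np.asarray(cfg.Q).tolist(),
        "states": list(ALL_HABITATS),
        "habitat_size_offsets": cfg.habitat_size_offsets,
        "bm_rate_size": cfg.bm_rate_size,
        "trophic_slope": cfg.trophic_slope,
        "trophic_intercept": cfg.trophic_intercept,
        "trophic_noise_sd": cfg.trophic_noise_sd,
        "migration_prob": cfg.migration_prob,
        "true_transition_counts": result.history.counts.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
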