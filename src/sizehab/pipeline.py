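"""Config-driven end-to-end runs with TSV reports and a run manifest.

Stage order: simulate/ingest → partition → transitions → compare →
reduce-retain → align → mechanisms.  All randomness flows from one root
seed through per-stage derived seeds recorded in the manifest.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

import sizehab
from sizehab.engine import (
    EngineConfig,
    donut_table,
    majority_summaries,
    reduce_and_retain,
    results_to_frame,
    run_all,
)
from sizehab.mechanisms import (
    ALIGNMENT_METRICS,
    aggregate_mechanisms,
    alignment_frame,
    annotate_migration,
    classify_all,
    clade_summaries,
    ledgers_to_frame,
    metric_differences,
    percentage_alignment,
)
from sizehab.model import match_tree_table, read_taxon_table
from sizehab.scales import build_scales, scales_to_frame
from sizehab.simulate import SimulationConfig, generate_dataset, write_dataset
from sizehab.transitions import StochasticMapSummary, fit_mk, stochastic_maps
from sizehab.tree import read_newick


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML/JSON on disk)."""

    tree_path: Optional[str] = None
    taxa_path: Optional[str] = None
    simulate: Optional[dict] = None
    scales: tuple[str, ...] = ("order", "tax3", "tax4", "tax5", "tax6", "full")
    tax_sections: dict = field(default_factory=dict)
    hotspot_top_m: int = 2
    min_n: int = 3
    n_sim: int = 999
    n_perm: int = 999
    n_maps: int = 100
    mk_constraint: str = "ARD"
    root_prior: str = "equal"
    retain_mode: str = "phylo_mean"
    metrics: tuple[str, ...] = ("mean_log10", "phylo_mean", "wilcoxon")
    include_variance: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        has_files = self.tree_path is not None and self.taxa_path is not None
        if not has_files and self.simulate is None:
            raise ConfigError("config needs either tree_path+taxa_path or a simulate block")
        if has_files and self.simulate is not None:
            raise ConfigError("give either input paths or a simulate block, not both")
        for s in self.scales:
            if s in ("hotspot", "hotspot_expanded"):
                continue  # built after transitions
        self.scales = tuple(self.scales)
        self.metrics = tuple(self.metrics)
        if self.min_n < 1:
            raise ConfigError("min_n must be >= 1")


def _stage_seed(root_seed: int, stage: str) -> int:
    import zlib

    return (int(root_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**32)


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute all stages, write TSVs + manifest, return the manifest."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "package_version": sizehab.__version__,
        "seed": config.seed,
        "stages": {},
    }
    t0 = time.time()

    def log_stage(name: str, **info) -> None:
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t0, 3), **info}

    # ---- stage 1: ingest / simulate
    history = None
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**{**config.simulate, "seed": _stage_seed(config.seed, "simulate")})
        result = generate_dataset(sim_cfg)
        write_dataset(result, outdir)
        dataset, history = result.dataset, result.history
        log_stage("simulate", n_taxa=dataset.n_taxa,
                  true_transitions=int(history.counts.sum()))
    else:
        tree = read_newick(config.tree_path)
        records = read_taxon_table(config.taxa_path)
        dataset, report = match_tree_table(tree, records)
        log_stage("ingest", n_taxa=dataset.n_taxa,
                  tips_dropped=report.n_tips_dropped,
                  records_dropped=report.n_records_dropped)

    # ---- stage 2: transitions (needed before hotspot scales)
    tip_states = {r.species_id: r.habitat for r in dataset.records}
    model = fit_mk(
        dataset.tree,
        tip_states,
        constraint=config.mk_constraint,
        root_prior=config.root_prior,
        seed=_stage_seed(config.seed, "fit_mk"),
    )
    summary = stochastic_maps(
        dataset.tree, tip_states, model,
        n_maps=config.n_maps, seed=_stage_seed(config.seed, "maps"),
    )
    write_transition_summary(summary, outdir)
    log_stage("transitions", constraint=config.mk_constraint,
              loglik=model.loglik, n_maps=summary.n_maps,
              mean_total_transitions=float(summary.mean_counts.sum()))

    # ---- stage 3: scales
    scales = build_scales(
        dataset,
        names=config.scales,
        tax_sections=config.tax_sections,
        transition_summary=summary,
        hotspot_top_m=config.hotspot_top_m,
    )
    scales_to_frame(scales).to_csv(os.path.join(outdir, "scales.tsv"), sep="\t", index=False)
    log_stage("partition", n_scales=len(scales),
              n_clades=sum(len(sc.clades) for sc in scales))

    # ---- stage 4: compare
    eng = EngineConfig(
        min_n=config.min_n, n_sim=config.n_sim, n_perm=config.n_perm,
        metrics=config.metrics, seed=_stage_seed(config.seed, "compare"),
        retain_mode=config.retain_mode,
    )
    results = run_all(dataset, scales, eng)
    results_to_frame(results).to_csv(os.path.join(outdir, "results.tsv"), sep="\t", index=False)
    maj = pd.concat(
        [majority_summaries(results, m) for m in config.metrics if
         len(majority_summaries(results, m))],
        ignore_index=True,
    ) if results else pd.DataFrame()
    maj.to_csv(os.path.join(outdir, "majority.tsv"), sep="\t", index=False)
    donut_table(results).to_csv(os.path.join(outdir, "donut.tsv"), sep="\t", index=False)
    log_stage("compare", n_comparisons=len(results))

    # ---- stage 5: reduce and retain
    has_trophic = sum(r.trophic_level is not None for r in dataset.records)
    if has_trophic >= 2:
        retained_results, pruned_ds, pruned_scales = reduce_and_retain(
            dataset, scales, eng, full_results=results
        )
        results_to_frame(retained_results).to_csv(
            os.path.join(outdir, "results_reduced.tsv"), sep="\t", index=False
        )
        n_retained = sum(r.retained for r in retained_results)
        log_stage("reduce_retain", n_comparisons=len(retained_results),
                  n_retained=n_retained)
    else:
        retained_results, pruned_ds, pruned_scales = [], dataset, scales
        log_stage("reduce_retain", n_comparisons=0, n_retained=0,
                  note="no trophic data")

    # ---- stage 6: alignment
    summaries = clade_summaries(pruned_ds, pruned_scales)
    table = metric_differences(
        retained_results or results, summaries,
        dataset=pruned_ds, scales=pruned_scales,
        include_variance=config.include_variance,
        seed=_stage_seed(config.seed, "variance"),
    )
    cells = []
    avail = [m for m in ALIGNMENT_METRICS if m in table.columns]
    for i, m1 in enumerate(avail):
        for m2 in avail[i + 1:]:
            cells.extend(percentage_alignment(table, m1, m2))
    alignment_frame(cells).to_csv(os.path.join(outdir, "alignment.tsv"), sep="\t", index=False)
    annotate_migration(summaries).to_csv(
        os.path.join(outdir, "migration_bands.tsv"), sep="\t", index=False
    )
    log_stage("align", n_cells=len(cells))

    # ---- stage 7: mechanisms
    ledgers = classify_all(retained_results or results, summaries, retained_only=bool(retained_results))
    if ledgers:
        ledgers_to_frame(ledgers).to_csv(
            os.path.join(outdir, "mechanism_ledger.tsv"), sep="\t", index=False
        )
        aggregate_mechanisms(ledgers).to_csv(
            os.path.join(outdir, "mechanism_summary.tsv"), sep="\t", index=False
        )
    log_stage("mechanisms", n_ledgers=len(ledgers))

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# --------------------------------------------------- transitions file io


def write_transition_summary(summary: StochasticMapSummary, outdir: str) -> None:
    summary.to_frame().to_csv(
        os.path.join(outdir, "transitions.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        sorted(summary.tip_event_rate.items()), columns=["species", "events_per_map"]
    ).to_csv(os.path.join(outdir, "tip_events.tsv"), sep="\t", index=False)


class _LoadedSummary:
    """Minimal stand-in for StochasticMapSummary read back from TSVs."""

    def __init__(self, frame: pd.DataFrame, tip_event_rate: dict[str, float]):
        self.frame = frame
        self.tip_event_rate = tip_event_rate


def read_transition_summary(outdir: str) -> _LoadedSummary:
    frame = pd.read_csv(os.path.join(outdir, "transitions.tsv"), sep="\t")
    tips = pd.read_csv(os.path.join(outdir, "tip_events.tsv"), sep="\t")
    return _LoadedSummary(
        frame, dict(zip(tips["species"], tips["events_per_map"]))
    )
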