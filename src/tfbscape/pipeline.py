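"""End-to-end pipeline: simulate -> score -> landscape -> topography -> evolve.

A pipeline run takes one configuration mapping and one output directory,
executes the enabled stages in order, writes every intermediate artifact as
TSV/JSON, and records a machine-readable manifest (package version, config
hash, per-stage seeds, and the filter funnel: genotype counts surviving each
quality filter and the giant-component extraction).  Identical configs and
seeds produce identical outputs; every stochastic stage derives its stream
from the global seed and the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np

from . import __version__, io
from .evolution import WalkConfig, run_walks, walk_summary
from .exceptions import ConfigurationError
from .landscape import build_network, find_peaks, giant_component, shuffle_null
from .scoring import score_pipeline
from .space import GenotypeSpace
from .synthetic import (
    SortSeqSimConfig,
    make_additive_landscape,
    make_hoc_landscape,
    make_nk_landscape,
    rescale_repression,
    simulate_sortseq,
)
from .topography import all_basins, epistasis_summary

log = logging.getLogger("tfbscape.pipeline")

DEFAULT_CONFIG: dict = {
    "space": {"length": 8},
    "stages": ["simulate", "score", "landscape", "topography", "evolve"],
    "simulate": {"model": "nk", "K": 2, "sim": {}},
    "score": {"min_reads": 30, "max_cv": 0.5, "per_bin_threshold": False},
    "landscape": {"epsilon": 0.0, "shuffles": 0},
    "topography": {"high_peak_threshold": 1.0, "max_basins": 50},
    "evolve": {"mode": "uniform", "walks_per_start": 100, "starts": "all-nonpeak"},
    "seed": 0,
}


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _build_space(cfg: dict) -> GenotypeSpace:
    sc = cfg.get("space", {})
    length = int(sc.get("length", 8))
    if length == 8:
        return GenotypeSpace()
    # smaller spaces (used for smoke runs) have no fixed context
    return GenotypeSpace(length=length, context=None, wildtype=None)


def _make_truth(cfg: dict, space: GenotypeSpace, seed: int):
    sim = cfg["simulate"]
    model = sim.get("model", "nk")
    if model == "hoc":
        truth = make_hoc_landscape(space, seed=seed)
    elif model == "nk":
        truth = make_nk_landscape(space, K=int(sim.get("K", 2)), seed=seed)
    elif model == "additive":
        rng = np.random.default_rng(seed)
        weights = [
            {a: float(w) for a, w in zip(space.alphabet, rng.random(space.n_alleles))}
            for _ in range(space.length)
        ]
        truth = make_additive_landscape(space, weights, seed=seed)
    else:
        raise ConfigurationError(f"unknown truth model {model!r}")
    return rescale_repression(truth)


def run_pipeline(config: dict | None = None, outdir="runs/run", seed: int | None = None) -> Path:
    """Execute the configured stages; return the run directory.

    ``config`` overrides :data:`DEFAULT_CONFIG` recursively.  ``seed``
    overrides the config's global seed.  Stages abort with the stage name
    on failure.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    meta = {"config_hash": chash, "version": __version__, "seed": cfg["seed"]}
    manifest: dict = {
        "version": __version__,
        "config_hash": chash,
        "seed": cfg["seed"],
        "stages": [],
        "funnel": {},
    }
    space = _build_space(cfg)
    stages = cfg["stages"]

    state: dict = {}
    try:
        if "simulate" in stages:
            s = stage_seed(cfg["seed"], "simulate")
            truth = _make_truth(cfg, space, s)
            sim_cfg = SortSeqSimConfig(**cfg["simulate"].get("sim", {}), seed=s)
            counts = simulate_sortseq(truth, sim_cfg)
            io.write_truth_table(truth, outdir / "truth.tsv", meta)
            io.write_count_table(counts, outdir / "counts.tsv", meta)
            state["truth"], state["counts"] = truth, counts
            manifest["stages"].append("simulate")
            manifest["funnel"]["simulated_genotypes"] = len(truth)

        if "score" in stages:
            counts = state.get("counts")
            if counts is None:
                counts = io.read_count_table(cfg["score"]["counts_path"])
            wildtype = cfg["score"].get("wildtype")
            if wildtype is None:
                if "truth" in state:
                    wildtype = str(state["truth"].scores.idxmax())
                elif space.wildtype:
                    wildtype = space.wildtype
                else:
                    raise ConfigurationError("score stage needs a wildtype genotype")
            scores = score_pipeline(
                counts,
                wildtype,
                min_reads=int(cfg["score"]["min_reads"]),
                max_cv=float(cfg["score"]["max_cv"]),
                per_bin_threshold=bool(cfg["score"]["per_bin_threshold"]),
            )
            io.write_score_table(scores, outdir / "scores.tsv", meta)
            state["scores"] = scores
            funnel = scores.attrs["funnel"]
            for name, count in funnel.items():
                log.info("filter funnel: %s -> %d genotypes", name, count)
            manifest["funnel"].update(funnel)
            manifest["stages"].append("score")

        if "landscape" in stages:
            scores = state.get("scores")
            if scores is None:
                scores = io.read_score_table(cfg["landscape"]["scores_path"])
            land = build_network(
                scores, space, epsilon=float(cfg["landscape"]["epsilon"])
            )
            land = giant_component(land)
            find_peaks(land)
            manifest["funnel"]["giant_component"] = len(land)
            manifest["landscape"] = {
                "n_nodes": len(land),
                "n_edges": land.n_edges,
                "n_peaks": land.n_peaks_,
                "n_plateaus": land.n_plateaus_,
            }
            n_shuffles = int(cfg["landscape"].get("shuffles", 0))
            if n_shuffles:
                null = shuffle_null(
                    land, n_shuffles, seed=stage_seed(cfg["seed"], "shuffle")
                )
                manifest["landscape"]["shuffle_null"] = {
                    "mean": null.mean,
                    "sd": null.sd,
                    "upper95": null.upper95,
                }
            io.write_node_table(land, outdir / "nodes.tsv", meta)
            io.write_edge_table(land, outdir / "edges.tsv", meta)
            state["landscape"] = land
            manifest["stages"].append("landscape")

        if "topography" in stages:
            land = state["landscape"]
            threshold = float(cfg["topography"]["high_peak_threshold"])
            peaks = land.genotypes[land.is_peak_]
            high = [p for p in peaks if land.scores[land.index[p]] > threshold]
            max_basins = int(cfg["topography"].get("max_basins", 50))
            basins = all_basins(land, high[:max_basins])
            basin_rows = [
                {"peak": b.peak, "size": b.size, "fraction": b.fraction}
                for b in basins
            ]
            epi = epistasis_summary(land)
            manifest["topography"] = {
                "n_peaks": int(len(peaks)),
                "n_high_peaks": int(len(high)),
                "epistasis": epi,
                "basins": basin_rows,
            }
            manifest["stages"].append("topography")

        if "evolve" in stages:
            land = state["landscape"]
            ev = cfg["evolve"]
            starts = ev.get("starts", "all-nonpeak")
            if isinstance(starts, str) and starts.startswith("sample:"):
                starts = ("sample", int(starts.split(":", 1)[1]))
            walk_cfg = WalkConfig(
                mode=ev.get("mode", "uniform"),
                population_size=float(ev.get("population_size", 1e8)),
                max_steps=int(ev.get("max_steps", 1000)),
                walks_per_start=int(ev.get("walks_per_start", 100)),
                starts=starts,
            )
            results = run_walks(land, walk_cfg, seed=stage_seed(cfg["seed"], "evolve"))
            summ = walk_summary(results, land, walk_cfg.high_peak_threshold)
            walk_rows = [
                {
                    "start": r.start,
                    "endpoint": r.endpoint,
                    "steps": r.steps,
                }
                for r in results
            ]
            import pandas as pd

            io._write_tsv(pd.DataFrame(walk_rows), outdir / "walks.tsv", meta)
            manifest["evolve"] = {
                "n_walks": summ.n_walks,
                "frac_end_on_peak": summ.frac_end_on_peak,
                "frac_reaching_high_peak": summ.frac_reaching_high_peak,
            }
            manifest["stages"].append("evolve")
    except Exception as exc:  # annotate with the failing stage
        done = set(manifest["stages"])
        current = next((s for s in stages if s not in done), "?")
        raise type(exc)(f"stage {current!r} failed: {exc}") from exc

    io.save_config(cfg, outdir / "config.yaml")
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
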