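"""End-to-end orchestration: counts -> preprocess -> differential expression
-> MI screen -> seed intersection -> network diffusion -> enrichment ->
panel evaluation, driven by one declarative config.

A run is fully determined by (config, rng_seed): identical inputs produce
byte-identical artifacts. Each run directory receives every intermediate
table plus a provenance JSON recording the config, its digest, the seed and
library versions.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexp import filter_degs, run_diffexp
from .diffusion import build_seed_set, diffuse, percentile_cutoff
from .enrichment import enrich
from .evaluation import evaluate_panel
from .io_formats import (PathwayDB, PPINetwork, read_counts, read_gmt,
                         read_sample_sheet, read_string_edges, write_counts,
                         write_table)
from .mi_select import mi_table, select_top_mi
from .preprocess import collapse_probes, normalize, size_factors
from .synthetic import simulate_counts, simulate_network, simulate_pathways

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

log = logging.getLogger("budnet")

DEFAULT_CONFIG: dict = {
    "inputs": {  # either real file paths or a simulate block
        "counts": None,
        "counts_level": "gene",
        "sample_sheet": None,
        "edges": None,
        "edges_min_score": 0.4,
        "gmt": None,
    },
    "simulate": None,  # dict of simulate_counts/network/pathway knobs
    "diffexp": {"alpha": 0.05, "min_abs_lfc": 1.5,
                "dispersion_mode": "gene-wise"},
    "mi": {"method": "equal_width", "n_bins": None, "select_mode": "max_ties",
           "k": None},
    "diffusion": {"alpha": 1.0, "percentile": 99.0, "exclude_seeds": True,
                  "weighted": True},
    "enrichment": {"min_size": 10, "max_size": 500, "alpha": 0.01},
    "rng_seed": 0,
}

_SIMULATE_DEFAULTS = {
    "n_genes": 2000, "n_high": 12, "n_low": 3, "de_fraction": 0.05,
    "lfc_location": 2.5, "dispersion": 0.1, "depth_range": [0.5, 2.0],
    "n_separators": 7, "n_network_nodes": 500, "network_m": 3,
    "n_sets": 50, "n_enriched": 3, "pathway_size_range": [10, 50],
}


def _merge(defaults: dict, user: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            errors.append(f"unknown config key {path}{key}")
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, f"{path}{key}.", errors)
        else:
            out[key] = val
    return out


def validate_config(cfg: dict | None) -> dict:
    """Fill defaults, reject unknown keys, and check every threshold domain.

    Raises ValueError listing every violation at once.
    """
    cfg = cfg or {}
    errors: list[str] = []
    sim = cfg.get("simulate")
    out = _merge(DEFAULT_CONFIG, {k: v for k, v in cfg.items()
                                  if k != "simulate"}, "", errors)
    if sim is not None:
        out["simulate"] = _merge(_SIMULATE_DEFAULTS, sim, "simulate.", errors)
    de = out["diffexp"]
    if not 0 < de["alpha"] < 1:
        errors.append("diffexp.alpha must lie in (0, 1)")
    if de["min_abs_lfc"] < 0:
        errors.append("diffexp.min_abs_lfc must be nonnegative")
    if de["dispersion_mode"] not in ("gene-wise", "trend"):
        errors.append("diffexp.dispersion_mode must be gene-wise or trend")
    mi = out["mi"]
    if mi["method"] not in ("equal_width", "equal_frequency", "distinct"):
        errors.append("mi.method invalid")
    if mi["select_mode"] not in ("max_ties", "top_k"):
        errors.append("mi.select_mode invalid")
    if mi["select_mode"] == "top_k" and (mi["k"] is None or mi["k"] <= 0):
        errors.append("mi.k must be >= 1 in top_k mode")
    dif = out["diffusion"]
    if dif["alpha"] < 0:
        errors.append("diffusion.alpha must be nonnegative")
    if not 0 < dif["percentile"] < 100:
        errors.append("diffusion.percentile must lie in (0, 100)")
    en = out["enrichment"]
    if en["min_size"] > en["max_size"]:
        errors.append("enrichment.min_size exceeds max_size")
    if not 0 < en["alpha"] <= 1:
        errors.append("enrichment.alpha must lie in (0, 1]")
    if out["simulate"] is None:
        inp = out["inputs"]
        needed = ["counts", "sample_sheet", "edges", "gmt"]
        for key in needed:
            if inp[key] is None:
                errors.append(f"inputs.{key} required without a simulate block")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return out


def _config_digest(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: dict | None, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Execute every stage and write all artifacts into ``outdir``.

    Returns a dict of the in-memory results keyed by stage. ``seed``
    overrides cfg['rng_seed'].
    """
    cfg = validate_config(cfg)
    if seed is not None:
        cfg["rng_seed"] = int(seed)
    rng_seed = int(cfg["rng_seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = _config_digest(cfg)
    log.info("run %s seed=%d -> %s", digest, rng_seed, outdir)

    truth = None
    stage = "inputs"
    try:
        if cfg["simulate"] is not None:
            sim = cfg["simulate"]
            cm, ann, truth = simulate_counts(
                n_genes=sim["n_genes"], n_high=sim["n_high"],
                n_low=sim["n_low"], de_fraction=sim["de_fraction"],
                lfc_location=sim["lfc_location"], dispersion=sim["dispersion"],
                depth_range=tuple(sim["depth_range"]),
                n_separators=sim["n_separators"], rng_seed=rng_seed)
            rng = np.random.default_rng(rng_seed + 1)
            others = [g for g in cm.gene_symbols
                      if g not in set(truth.seed_genes)]
            n_extra = sim["n_network_nodes"] - len(truth.seed_genes)
            extra = rng.choice(others, size=n_extra, replace=False).tolist()
            node_names = sorted(truth.seed_genes + extra)
            network = simulate_network(
                sim["n_network_nodes"], model="barabasi_albert",
                params={"m": sim["network_m"]}, rng_seed=rng_seed + 2,
                node_names=node_names)
            pathways = simulate_pathways(
                network, truth.seed_genes, n_sets=sim["n_sets"],
                size_range=tuple(sim["pathway_size_range"]),
                n_enriched=sim["n_enriched"], rng_seed=rng_seed + 3)
            truth.enriched_sets = [n for n, d in pathways.descriptions.items()
                                   if d == "planted"]
        else:
            inp = cfg["inputs"]
            cm = read_counts(inp["counts"], level=inp["counts_level"])
            ann = read_sample_sheet(inp["sample_sheet"])
            network = read_string_edges(inp["edges"],
                                        min_score=inp["edges_min_score"])
            pathways = read_gmt(inp["gmt"])

        stage = "preprocess"
        if cm.level == "probe":
            cm = collapse_probes(cm)
        write_counts(cm, outdir / "gene_counts.tsv")
        sf = size_factors(cm)
        write_table(pd.DataFrame({"sample_id": cm.sample_ids,
                                  "size_factor": sf}),
                    outdir / "size_factors.tsv")
        norm = normalize(cm, sf)

        stage = "diffexp"
        de = run_diffexp(cm, ann, size_factors=sf,
                         dispersion_mode=cfg["diffexp"]["dispersion_mode"])
        write_table(de, outdir / "de_table.tsv")
        degs = filter_degs(de, alpha=cfg["diffexp"]["alpha"],
                           min_abs_lfc=cfg["diffexp"]["min_abs_lfc"])

        stage = "mi_select"
        mi = mi_table(norm, ann, method=cfg["mi"]["method"],
                      n_bins=cfg["mi"]["n_bins"])
        write_table(mi, outdir / "mi_table.tsv")
        mi_genes = select_top_mi(mi, mode=cfg["mi"]["select_mode"],
                                 k=cfg["mi"]["k"])

        stage = "seeds"
        seeds = build_seed_set(degs, mi_genes, network)
        write_table(pd.DataFrame({
            "gene": seeds.genes,
            "in_network": [g in set(seeds.matched) for g in seeds.genes]}),
            outdir / "seed_genes.tsv")

        stage = "diffusion"
        diff = diffuse(network, seeds, alpha=cfg["diffusion"]["alpha"],
                       weighted=cfg["diffusion"]["weighted"])
        write_table(diff, outdir / "diffusion.tsv")
        candidates = percentile_cutoff(
            diff, percentile=cfg["diffusion"]["percentile"],
            exclude_seeds=cfg["diffusion"]["exclude_seeds"])
        write_table(pd.DataFrame({"gene": candidates}),
                    outdir / "candidates.tsv")

        stage = "enrichment"
        universe = network.node_ids
        enr = enrich(candidates + seeds.matched, pathways, universe,
                     min_size=cfg["enrichment"]["min_size"],
                     max_size=cfg["enrichment"]["max_size"],
                     alpha=cfg["enrichment"]["alpha"])
        write_table(enr, outdir / "enrichment.tsv")

        stage = "evaluation"
        panel = seeds.genes
        ev = evaluate_panel(norm, panel, ann)
        report = {
            "panel": panel,
            "separation_score": ev.separation_score,
            "explained_variance": list(ev.explained_variance),
        }
        (outdir / "evaluation.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        write_table(ev.pc_coordinates.reset_index(names="sample_id"),
                    outdir / "pca_coordinates.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r} "
                           f"(config {digest}): {exc}") from exc

    provenance = {
        "config": cfg,
        "config_digest": digest,
        "rng_seed": rng_seed,
        "budnet_version": __version__,
        "stages": ["preprocess", "diffexp", "mi_select", "seeds", "diffusion",
                   "enrichment", "evaluation"],
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n")

    return {
        "counts": cm, "annotation": ann, "normalized": norm,
        "size_factors": sf, "de_table": de, "degs": degs,
        "mi_table": mi, "mi_genes": mi_genes, "seeds": seeds,
        "network": network, "pathways": pathways, "diffusion": diff,
        "candidates": candidates, "enrichment": enr, "evaluation": ev,
        "truth": truth, "config": cfg,
    }
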