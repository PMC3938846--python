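"""End-to-end pipeline: DE -> methylation -> integration -> binarize -> contextualize.

The pipeline is driven by a single configuration mapping (usually a YAML
file) naming the input files, the target and reference cell types, the
thresholds, and the pruning hyperparameters.  Every run writes a JSON
manifest with input checksums, the fully resolved configuration, the seeds,
and per-stage record counts; re-running from a manifest reproduces all
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Any, Mapping

from . import __version__, io
from .contextualize import PruningConfig, prune_network
from .dynamics import BooleanState
from .omics import (
    call_de,
    call_differential_methylation,
    binarize_expression,
    integrate_meth_expression,
    promoter_methylation,
    site_methylation,
)

log = logging.getLogger("stabcore")

DEFAULTS: dict[str, Any] = {
    "target": "hCM",
    "refs": ["hESC", "hNSC"],
    "fc_threshold": 2.0,
    "p_threshold": 0.05,
    "min_cov": 10,
    "window_bp": 1000,
    "meth_delta": 0.05,
    "binarize_method": "midrange",
    "contextualize": True,
    "pruning": {},
    "seed": 0,
}


class ConfigurationError(ValueError):
    pass


def resolve_config(config: Mapping[str, Any]) -> dict[str, Any]:
    cfg = {**DEFAULTS, **dict(config)}
    required = ["expression", "design", "methylation", "tss", "out"]
    missing = [k for k in required if k not in cfg]
    if missing:
        raise ConfigurationError(f"configuration is missing required keys: {missing}")
    if cfg["contextualize"] and "network" not in cfg:
        raise ConfigurationError(
            "contextualize is enabled but no 'network' input is configured"
        )
    if not isinstance(cfg["methylation"], Mapping):
        raise ConfigurationError(
            "'methylation' must map cell type -> per-CpG count table path"
        )
    for key in ("expression", "design", "tss", *cfg["methylation"].values()):
        path = cfg[key] if key in cfg else key
        if not Path(path).exists():
            raise ConfigurationError(f"input file does not exist: {path}")
    if cfg["contextualize"] and not Path(cfg["network"]).exists():
        raise ConfigurationError(f"input file does not exist: {cfg['network']}")
    return cfg


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Any]:
    """Execute every configured stage in order; returns the run manifest."""
    cfg = resolve_config(config)
    outdir = Path(cfg["out"])
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    counts: dict[str, int] = {}

    mat = io.read_expression(cfg["expression"], cfg["design"])
    counts["genes_in_expression"] = len(mat.genes)
    target, refs = cfg["target"], list(cfg["refs"])

    # --- differential expression
    de = call_de(mat, target, refs, fc_threshold=cfg["fc_threshold"],
                 p_threshold=cfg["p_threshold"])
    io.write_de_calls(de, outdir / "de_calls.tsv")
    counts["de_up"] = sum(c.direction == "up" for c in de)
    counts["de_down"] = sum(c.direction == "down" for c in de)
    log.info("DE: %d up, %d down of %d genes", counts["de_up"], counts["de_down"], len(de))

    # --- methylation
    raw = {ct: io.read_methylation_table(p) for ct, p in cfg["methylation"].items()}
    counts["cpg_sites_in"] = min(len(t) for t in raw.values())
    sites = site_methylation(raw, min_cov=cfg["min_cov"])
    counts["cpg_sites_covered"] = len(sites)
    pm = promoter_methylation(sites, io.read_bed6(cfg["tss"]), window_bp=cfg["window_bp"])
    io.write_table(pm, outdir / "promoter_methylation.tsv")
    counts["promoters_defined"] = int((pm["n_sites"] > 0).sum())
    hyper, hypo, skipped = call_differential_methylation(
        pm, target, refs, delta=cfg["meth_delta"]
    )
    with (outdir / "dm_calls.tsv").open("w") as fh:
        fh.write("gene\tcall\n")
        for g in hyper:
            fh.write(f"{g}\thyper\n")
        for g in hypo:
            fh.write(f"{g}\thypo\n")
        for g in skipped:
            fh.write(f"{g}\tskipped\n")
    counts["meth_hyper"] = len(hyper)
    counts["meth_hypo"] = len(hypo)
    counts["meth_skipped"] = len(skipped)

    # --- integration
    integrated = integrate_meth_expression(hypo, de, pm=pm, target=target, refs=refs)
    io.write_integrated_calls(integrated, outdir / "integrated.tsv")
    counts["demethylated_upregulated"] = sum(
        c.category == "demethylated_upregulated" for c in integrated
    )

    manifest: dict[str, Any] = {
        "tool": "stabcore",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": _plain(cfg),
        "inputs": {
            "expression": io.file_sha256(cfg["expression"]),
            "design": io.file_sha256(cfg["design"]),
            "tss": io.file_sha256(cfg["tss"]),
            "methylation": {ct: io.file_sha256(p) for ct, p in cfg["methylation"].items()},
        },
        "seed": cfg["seed"],
        "counts": counts,
    }

    # --- binarize + contextualize
    if cfg["contextualize"]:
        net = io.read_signed_network(cfg["network"])
        manifest["inputs"]["network"] = io.file_sha256(cfg["network"])
        missing = [g for g in net.nodes if g not in mat.genes]
        if missing:
            raise ConfigurationError(
                f"network genes absent from expression matrix: {missing[:5]}"
            )
        states = binarize_expression(mat, method=cfg["binarize_method"], genes=net.nodes)
        io.write_table(states, outdir / "binarized_states.tsv")
        ref_state = BooleanState.from_mapping(net, states[refs[0]].to_dict())
        tgt_state = BooleanState.from_mapping(net, states[target].to_dict())
        pruning = PruningConfig(**{"seed": cfg["seed"], **dict(cfg["pruning"])})
        result = prune_network(net, (ref_state, tgt_state), pruning)
        io.write_contextualization(result, outdir)
        manifest["contextualization"] = {
            "best_fitness": result.best_fitness,
            "core_genes": sorted(result.core.genes),
            "n_core_components": len(result.core.components),
            "n_edges_kept": len(result.best_network.edges),
            "pruning": dataclasses.asdict(pruning),
        }
        counts["core_genes"] = len(result.core.genes)

    manifest["runtime_s"] = round(time.perf_counter() - t0, 3)
    io.write_manifest(manifest, outdir / "manifest.json")
    log.info("pipeline finished in %.2fs", manifest["runtime_s"])
    return manifest


def rerun_from_manifest(manifest_path: str | Path, out: str | Path | None = None) -> dict[str, Any]:
    """Re-execute a recorded run; with *out* unset, overwrites in place."""
    manifest = io.read_manifest(manifest_path)
    cfg = dict(manifest["config"])
    if out is not None:
        cfg["out"] = str(out)
    return run_pipeline(cfg)


def _plain(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
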