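"""End-to-end pipeline: network -> features -> resampled classification ->
candidate calling -> optional DE screen and intersection.

A run is described by one structured-text (YAML/JSON) config; every output
directory receives the result tables plus a manifest recording all resolved
parameters, input checksums and the base seed, sufficient to reproduce the
run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import intersect_candidates, screen_de, validate_de_table
from .network import read_edge_list, read_positive_genes
from .prioritize import RunConfig, call_candidates, repeated_runs

logger = logging.getLogger(__name__)

REQUIRED_KEYS = ("edges", "positives", "out_dir")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config: file does not contain a mapping")
    return cfg


def run_pipeline(config: dict | str | Path) -> Path:
    """Execute a full run from a config mapping or config-file path.

    Required keys: edges, positives, out_dir.  Optional: species_tag,
    de_table (gene,fold_change[,p][,adj_p] CSV), fc_threshold,
    adjp_threshold, and any RunConfig field (classifier, n_reps, base_seed,
    train_fraction, cv_folds, negative_ratio, resample_negatives_per_rep,
    tune_every_rep, candidate_rule, candidate_tau, grids).

    Writes metrics.csv, candidates.csv, manifest.json (and intersection.json
    when a DE table is given) to out_dir; returns out_dir.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    for key in REQUIRED_KEYS:
        if key not in config:
            raise PipelineError(f"config: missing required key {key!r}")

    run_kwargs = {
        k: config[k]
        for k in (
            "classifier",
            "train_fraction",
            "n_reps",
            "cv_folds",
            "base_seed",
            "grids",
            "negative_ratio",
            "resample_negatives_per_rep",
            "tune_every_rep",
            "candidate_rule",
            "candidate_tau",
        )
        if k in config
    }
    cfg = RunConfig(**run_kwargs)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        net = read_edge_list(config["edges"], config.get("species_tag", "unspecified"))
    except Exception as exc:
        raise PipelineError(f"network loading: {exc}") from exc
    try:
        positives = read_positive_genes(config["positives"])
    except Exception as exc:
        raise PipelineError(f"positive gene list: {exc}") from exc

    logger.info(
        "network: %d nodes, %d edges; %d positive genes listed",
        net.n_nodes, net.n_edges, len(positives),
    )
    try:
        result = repeated_runs(net, positives, cfg)
    except Exception as exc:
        raise PipelineError(f"resampled classification: {exc}") from exc
    candidates = call_candidates(
        result.votes, result.n_reps_scored, cfg.candidate_rule, cfg.candidate_tau
    )
    result.metrics_frame().to_csv(out_dir / "metrics.csv", index=False)
    candidates.to_csv(out_dir / "candidates.csv", index=False)

    manifest = {
        "aaanet_version": __version__,
        "inputs": {
            "edges": {"path": str(config["edges"]), "sha256": _sha256(config["edges"])},
            "positives": {
                "path": str(config["positives"]),
                "sha256": _sha256(config["positives"]),
            },
        },
        "species_tag": net.species_tag,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_positives_in_network": len(positives & net.nodes),
        "run_config": cfg.to_dict(),
        "chosen_params": result.chosen_params,
        "n_candidates_called": int(candidates["called"].sum()),
        "mean_metrics": {
            m: result.mean_metric(m)
            for m in ("accuracy", "precision", "recall", "f1", "auc")
        },
    }

    if "de_table" in config and config["de_table"]:
        try:
            de = validate_de_table(pd.read_csv(config["de_table"]))
            degs = screen_de(
                de,
                fc_threshold=config.get("fc_threshold", 1.5),
                adjp_threshold=config.get("adjp_threshold", 0.05),
            )
            overlap, frac = intersect_candidates(candidates, degs)
        except Exception as exc:
            raise PipelineError(f"DE screening: {exc}") from exc
        manifest["inputs"]["de_table"] = {
            "path": str(config["de_table"]),
            "sha256": _sha256(config["de_table"]),
        }
        with open(out_dir / "intersection.json", "w") as fh:
            json.dump(
                {
                    "n_degs": len(degs),
                    "n_candidates": int(candidates["called"].sum()),
                    "overlap": sorted(overlap),
                    "fraction_of_candidates": frac,
                },
                fh,
                indent=1,
            )
        manifest["n_degs"] = len(degs)
        manifest["overlap_fraction_of_candidates"] = frac

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out_dir
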