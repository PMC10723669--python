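"""Synthetic networks and expression matrices with known ground truth.

The generator encodes the premise behind guilt-by-association
prioritization: disease genes preferentially interact with one another.
It plants a module of ``module_size`` genes inside an Erdos-Renyi
background — module-internal pairs receive edges with probability
``p_in``, every other pair with ``p_out`` — and hides a fraction of the
module from the positive label set.  Those hidden module genes are the
discoverable candidates a good prioritizer should recover.

Expression matrices are log-normal two-group data with a planted set of
differentially expressed genes; the DE truth can be biased toward the
network module so the candidate/DEG intersection has a recoverable
planted overlap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .network import PPINetwork


@dataclass
class SyntheticConfig:
    """Parameters of the planted-module network and two-group expression.

    Network: ``n_genes`` total, a disease module of ``module_size`` with
    internal edge probability ``p_in`` over background ``p_out``;
    ``holdout_fraction`` of the module is hidden from the labeled
    positives.  Expression: ``n_case``/``n_control`` samples, a
    ``de_fraction`` of genes shifted by ``log2_effect`` (random sign) on
    top of Normal(0, ``noise_sd``) log2 noise.
    """

    n_genes: int = 500
    module_size: int = 50
    p_in: float = 0.3
    p_out: float = 0.02
    holdout_fraction: float = 0.3
    n_case: int = 10
    n_control: int = 10
    de_fraction: float = 0.1
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    seed: int = 123

    def __post_init__(self):
        if not 0 < self.module_size < self.n_genes:
            raise ValueError("need 0 < module_size < n_genes")
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in [0, 1)")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticNetwork:
    net: PPINetwork
    disease_truth: set[str]
    labeled_positives: set[str]
    hidden_positives: set[str]

    @property
    def background(self) -> set[str]:
        return self.net.nodes - self.disease_truth


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent child streams per generator so network and expression
    # draws never interleave
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(stream + 1)[stream])


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_network(cfg: SyntheticConfig) -> SyntheticNetwork:
    """Planted-partition network with a hidden-positive holdout.

    Deterministic per seed.  Warns (does not fail) when the expected number
    of module-internal edges is below 1 — such a module is invisible to any
    topology-based method.
    """
    rng = _rng(cfg, 0)
    genes = np.array(gene_names(cfg.n_genes))
    module = set(rng.choice(genes, size=cfg.module_size, replace=False))
    exp_module_edges = cfg.p_in * cfg.module_size * (cfg.module_size - 1) / 2
    if exp_module_edges < 1:
        warnings.warn(
            f"expected module edge count {exp_module_edges:.2f} < 1; "
            "the planted module will be invisible",
            stacklevel=2,
        )
    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    in_module = np.isin(genes, list(module))
    within = in_module[iu] & in_module[ju]
    p = np.where(within, cfg.p_in, cfg.p_out)
    keep = rng.random(p.shape) < p
    edges = [(genes[i], genes[j]) for i, j in zip(iu[keep], ju[keep])]
    net = PPINetwork.from_edges(edges, species_tag="synthetic", nodes=genes)

    n_hidden = round(cfg.holdout_fraction * cfg.module_size)
    hidden = set(rng.choice(sorted(module), size=n_hidden, replace=False))
    return SyntheticNetwork(
        net=net,
        disease_truth=module,
        labeled_positives=module - hidden,
        hidden_positives=hidden,
    )


def generate_expression(
    cfg: SyntheticConfig,
    genes: list[str],
    de_truth_bias: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Two-group linear-scale expression matrix with a planted DE set.

    Per-gene baselines are drawn once; every value gets Normal(0, noise_sd)
    log2 noise; DE genes (``de_fraction`` of genes, drawn first from
    ``de_truth_bias`` when given) are shifted by +/- ``log2_effect`` in
    cases.  Returns (matrix genes x samples on the linear scale, sample ->
    group labels, true DE gene set); deterministic per seed.
    """
    rng = _rng(cfg, 1)
    genes = list(genes)
    n_genes = len(genes)
    n_de = round(cfg.de_fraction * n_genes)
    gene_arr = np.array(genes)
    if de_truth_bias:
        bias = sorted(set(de_truth_bias) & set(genes))
        from_bias = list(rng.choice(bias, size=min(n_de, len(bias)), replace=False))
        rest_pool = sorted(set(genes) - set(bias))
        n_rest = n_de - len(from_bias)
        from_rest = list(rng.choice(rest_pool, size=n_rest, replace=False)) if n_rest else []
        de_truth = set(from_bias) | set(from_rest)
    else:
        de_truth = set(rng.choice(gene_arr, size=n_de, replace=False))

    samples = [f"case_{i}" for i in range(cfg.n_case)] + [
        f"ctrl_{i}" for i in range(cfg.n_control)
    ]
    groups = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control,
        index=pd.Index(samples, name="sample"),
        name="group",
    )
    baseline = rng.normal(8.0, 1.0, size=n_genes)  # typical log2 microarray level
    log2 = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_genes, len(samples)))
    is_de = np.isin(gene_arr, sorted(de_truth))
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    shift = np.where(is_de, sign * cfg.log2_effect, 0.0)
    log2[:, : cfg.n_case] += shift[:, None]
    expr = pd.DataFrame(
        2.0**log2, index=pd.Index(genes, name="gene"), columns=samples
    )
    return expr, groups, de_truth


def write_simulation(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Generate the linked network + expression study and write it as text.

    Files: edges.tsv, positives.txt, hidden.txt, expr.csv, groups.csv,
    truth.json.  DE truth is biased toward the planted module so the
    candidate/DEG intersection is recoverable.  Returns the truth record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = generate_network(cfg)
    expr, groups, de_truth = generate_expression(
        cfg, sorted(sim.net.nodes), de_truth_bias=sim.hidden_positives
    )
    sim.net.write_edge_list(out / "edges.tsv")
    (out / "positives.txt").write_text(
        "\n".join(sorted(sim.labeled_positives)) + "\n"
    )
    (out / "hidden.txt").write_text("\n".join(sorted(sim.hidden_positives)) + "\n")
    expr.to_csv(out / "expr.csv")
    groups.to_csv(out / "groups.csv")
    truth = {
        "config": cfg.to_dict(),
        "disease_truth": sorted(sim.disease_truth),
        "labeled_positives": sorted(sim.labeled_positives),
        "hidden_positives": sorted(sim.hidden_positives),
        "de_truth": sorted(de_truth),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
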