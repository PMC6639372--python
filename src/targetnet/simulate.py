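"""Seeded synthetic fixtures with the statistical structure the real
data exhibit.

The generator produces, from one master seed, a coherent quadruple of

* a scale-free-like interaction network (preferential attachment) in
  which drug-target-like and disease-associated-like genes receive extra
  edges (elevated centrality) and drug targets are preferentially wired
  to disease-associated / prognostically-unfavorable / up-regulated
  genes (short network distances),
* a gene-class catalog whose prognostically favorable and down-regulated
  classes are drawn from the low-degree periphery,
* a dependency matrix in which unfavorable/up-regulated genes score
  lower (more essential) and favorable/down-regulated genes higher,
* a paired tumor/normal expression matrix with planted log2 fold changes
  for the up-/down-regulated classes.

All outputs can be written in exactly the file dialects the package
loaders accept, and identical seeds give byte-identical files.  The
generator plants marginal class effects only; real interactomes and
screens carry correlation structure (shared complexes, batch effects,
screen quality differences) that it does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import CLASS_LABELS, GeneClassCatalog
from .dependency import DependencyMatrix
from .diffexpr import PairedExpressionMatrix
from .network import InteractionNetwork, write_edge_list


# class proportions of the mapped HCC gene classes on a 17,257-node
# interactome: 217 DTG / 322 DAG / 230 PFG / 2574 PUG / 4004 URG / 434 DRG
CLASS_FRACTIONS = {
    "DTG": 217 / 17257,
    "DAG": 322 / 17257,
    "PFG": 230 / 17257,
    "PUG": 2574 / 17257,
    "URG": 4004 / 17257,
    "DRG": 434 / 17257,
}


def proportional_class_sizes(n_genes: int) -> dict[str, int]:
    """Class sizes matching the real study's proportions at ``n_genes``."""
    return {lbl: max(5, round(f * n_genes)) for lbl, f in CLASS_FRACTIONS.items()}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    ``hub_boost`` extra edges are attached to every drug-target-like and
    disease-associated-like gene (a quarter of that to the unfavorable /
    up-regulated classes); ``proximity_boost`` is the probability that
    each of five candidate links from a drug-target gene to a random
    DAG/PUG/URG gene is realized.  Dependency effects shift the mean of
    the normal score distribution per class (lower = more essential).
    Expression is simulated on the log2 scale with planted fold changes
    for the URG/DRG classes across ``n_pairs`` tumor/normal pairs.
    """

    n_genes: int = 2000
    class_sizes: dict[str, int] | None = None  # None -> proportional
    m: int = 3  # preferential-attachment edges per new node
    hub_boost: int = 8
    proximity_boost: float = 0.6
    peripheral_favorable: bool = True  # sample PFG/DRG from low-degree nodes
    n_cell_lines: int = 14
    dependency_effects: dict[str, float] = field(
        default_factory=lambda: {
            "DTG": 0.0, "DAG": 0.0, "PFG": 0.3, "PUG": -0.4, "URG": -0.4, "DRG": 0.3,
        }
    )
    dependency_noise_sd: float = 0.3
    missing_gene_fraction: float = 0.05
    missing_cell_fraction: float = 0.01
    n_pairs: int = 43
    lfc_urg: float = 2.0
    lfc_drg: float = -2.0
    expression_noise_sd: float = 0.5
    seed: int = 0

    def resolved_class_sizes(self) -> dict[str, int]:
        if self.class_sizes is None:
            return proportional_class_sizes(self.n_genes)
        return {**proportional_class_sizes(self.n_genes), **self.class_sizes}

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        if self.class_sizes is not None and set(self.class_sizes) - set(CLASS_LABELS):
            raise ValueError(f"unknown class labels in class_sizes: {self.class_sizes}")
        if sum(self.resolved_class_sizes().values()) > self.n_genes:
            raise ValueError("class sizes exceed the number of genes")
        for v in list(self.dependency_effects.values()) + [
            self.lfc_urg, self.lfc_drg, self.proximity_boost,
        ]:
            if not np.isfinite(v):
                raise ValueError("effect sizes must be finite")


def null_config(**overrides) -> SimulationConfig:
    """A configuration with every planted effect switched off."""
    cfg = SimulationConfig(
        hub_boost=0,
        proximity_boost=0.0,
        peripheral_favorable=False,
        dependency_effects={label: 0.0 for label in CLASS_LABELS},
        lfc_urg=0.0,
        lfc_drg=0.0,
        **overrides,
    )
    return cfg


@dataclass
class SyntheticDataset:
    """In-memory bundle of one simulated study."""

    network: InteractionNetwork
    catalog: GeneClassCatalog
    dependency: DependencyMatrix
    expression: PairedExpressionMatrix
    truth: dict
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> Path:
        """Write every component in the loaders' file dialects."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_edge_list(self.network, out / "network.tsv")
        for label in CLASS_LABELS:
            (out / f"genes_{label}.txt").write_text(
                "".join(f"{g}\n" for g in sorted(self.catalog[label])),
                encoding="utf-8",
            )
        self.dependency.scores.to_csv(out / "dependency.csv", index_label="gene")
        expr = pd.DataFrame(
            np.hstack([self.expression.tumor, self.expression.normal]),
            index=pd.Index(self.expression.genes, name="gene"),
            columns=[f"{p}_T" for p in self.expression.pairs]
            + [f"{p}_N" for p in self.expression.pairs],
        )
        expr.to_csv(out / "expression.tsv", sep="\t")
        manifest = pd.DataFrame(
            {
                "pair_id": self.expression.pairs,
                "tumor_column": [f"{p}_T" for p in self.expression.pairs],
                "normal_column": [f"{p}_N" for p in self.expression.pairs],
            }
        )
        manifest.to_csv(out / "pairing.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True), encoding="utf-8"
        )
        return out


def _sample(rng: np.random.Generator, pool: list[str], size: int) -> set[str]:
    if size > len(pool):
        raise ValueError(f"cannot sample {size} genes from a pool of {len(pool)}")
    return set(rng.choice(pool, size=size, replace=False))


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate one synthetic study from the configuration's seed."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nodes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    # scale-free backbone
    ba_seed = int(rng.integers(0, 2**31 - 1))
    base = nx.barabasi_albert_graph(cfg.n_genes, cfg.m, seed=ba_seed)
    g = nx.relabel_nodes(base, {i: nodes[i] for i in range(cfg.n_genes)})

    sizes = cfg.resolved_class_sizes()
    classes: dict[str, set[str]] = {}
    classes["DTG"] = _sample(rng, nodes, sizes["DTG"])
    classes["DAG"] = _sample(rng, nodes, sizes["DAG"])
    classes["PUG"] = _sample(rng, nodes, sizes["PUG"])
    classes["URG"] = _sample(rng, nodes, sizes["URG"])
    # favorable / down-regulated genes live in the low-degree periphery;
    # PFG must not contradict PUG, DRG must not contradict URG
    if cfg.peripheral_favorable:
        by_degree = sorted(nodes, key=lambda n: (g.degree(n), n))
        low_pool = by_degree[: max(cfg.n_genes // 2, sizes["PFG"] + sizes["DRG"] + 1)]
    else:
        low_pool = nodes
    classes["PFG"] = _sample(rng, [n for n in low_pool if n not in classes["PUG"]],
                             sizes["PFG"])
    classes["DRG"] = _sample(
        rng, [n for n in low_pool if n not in classes["URG"]], sizes["DRG"]
    )

    # elevated connectivity for target- and disease-like genes
    def add_random_edges(gene: str, count: int) -> None:
        for _ in range(count):
            partner = nodes[int(rng.integers(0, cfg.n_genes))]
            if partner != gene:
                g.add_edge(gene, partner)

    mild = cfg.hub_boost // 4
    for gene in sorted(classes["DTG"] | classes["DAG"]):
        add_random_edges(gene, cfg.hub_boost)
    for gene in sorted((classes["PUG"] | classes["URG"]) - classes["DTG"] - classes["DAG"]):
        add_random_edges(gene, mild)

    # short paths from drug targets to each disease-like class
    if cfg.proximity_boost > 0:
        for partner_label in ("DAG", "PUG", "URG"):
            partners = sorted(classes[partner_label])
            if not partners:
                continue
            for gene in sorted(classes["DTG"]):
                for _ in range(2):
                    if rng.random() < cfg.proximity_boost:
                        partner = partners[int(rng.integers(0, len(partners)))]
                        if partner != gene:
                            g.add_edge(gene, partner)

    network = InteractionNetwork(g)
    catalog = GeneClassCatalog(members={k: set(v) for k, v in classes.items()})

    # dependency matrix with planted class shifts
    cell_lines = [f"HCC{i + 1:02d}" for i in range(cfg.n_cell_lines)]
    n_missing = int(round(cfg.missing_gene_fraction * cfg.n_genes))
    missing_genes = set(rng.choice(nodes, size=n_missing, replace=False)) if n_missing else set()
    scored = [n for n in nodes if n not in missing_genes]
    mu = np.zeros(len(scored))
    for j, gene in enumerate(scored):
        for label in CLASS_LABELS:
            if gene in classes[label]:
                mu[j] += cfg.dependency_effects.get(label, 0.0)
    scores = rng.normal(
        loc=mu[:, None], scale=cfg.dependency_noise_sd,
        size=(len(scored), cfg.n_cell_lines),
    )
    if cfg.missing_cell_fraction > 0:
        holes = rng.random(scores.shape) < cfg.missing_cell_fraction
        scores[holes] = np.nan
    dependency = DependencyMatrix(
        scores=pd.DataFrame(scores, index=scored, columns=cell_lines)
    )

    # paired expression with planted fold changes on the log2 scale
    baseline = rng.normal(5.0, 2.0, size=cfg.n_genes)
    lfc = np.zeros(cfg.n_genes)
    for i, gene in enumerate(nodes):
        if gene in classes["URG"]:
            lfc[i] += cfg.lfc_urg
        if gene in classes["DRG"]:
            lfc[i] += cfg.lfc_drg
    noise_t = rng.normal(0, cfg.expression_noise_sd, size=(cfg.n_genes, cfg.n_pairs))
    noise_n = rng.normal(0, cfg.expression_noise_sd, size=(cfg.n_genes, cfg.n_pairs))
    tumor_log = baseline[:, None] + lfc[:, None] + noise_t
    normal_log = baseline[:, None] + noise_n
    expression = PairedExpressionMatrix(
        genes=nodes,
        pairs=[f"P{j + 1:03d}" for j in range(cfg.n_pairs)],
        tumor=np.maximum(2.0**tumor_log - 1.0, 0.0),
        normal=np.maximum(2.0**normal_log - 1.0, 0.0),
    )

    truth = {
        "seed": cfg.seed,
        "classes": {label: sorted(classes[label]) for label in CLASS_LABELS},
        "dependency_effects": dict(cfg.dependency_effects),
        "planted_lfc": {"URG": cfg.lfc_urg, "DRG": cfg.lfc_drg},
        "missing_genes": sorted(missing_genes),
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
    }
    return SyntheticDataset(
        network=network,
        catalog=catalog,
        dependency=dependency,
        expression=expression,
        truth=truth,
        config=cfg,
    )


GOLDEN_SEEDS = {"small": 101, "medium": 202}


def make_golden_fixture(
    size: str = "small", out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Frozen-seed fixtures used throughout the test suite and docs.

    ``small`` is a 200-gene study (14 cell lines, 10 expression pairs)
    sized for fast unit tests; ``medium`` is the 2,000-gene default
    configuration used for end-to-end evaluation runs.
    """
    if size == "small":
        cfg = SimulationConfig(
            n_genes=200,
            class_sizes={"DTG": 20, "DAG": 20, "PFG": 15, "PUG": 30, "URG": 40, "DRG": 15},
            n_pairs=10,
            seed=GOLDEN_SEEDS["small"],
        )
    elif size == "medium":
        cfg = SimulationConfig(seed=GOLDEN_SEEDS["medium"])
    else:
        raise ValueError(f"size must be 'small' or 'medium', got {size!r}")
    ds = simulate(cfg)
    if out_dir is not None:
        ds.write(out_dir)
    return ds
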