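"""Per-gene feature-vector assembly and scaling.

The primary feature vector has 52 components per network node:

* 3 network centralities (degree, betweenness, closeness),
* 14 class-distance features (7 node types x {average, minimum}
  shortest-path length, self excluded, unreachable -> sentinel),
* 7 neighbor-type ratios,
* 14 per-cell-line dependency scores of the gene,
* 14 per-cell-line mean dependency scores of its network neighbors.

Variants drop or extend the centrality block, or swap in externally
computed rank-based propagation (DADA) scores:

============== ======================================================
variant        columns
============== ======================================================
primary        52
no_centrality  49 (no centrality block)
extended       55 (+ pagerank, eigenvector, katz)
dada_replace   56 (centralities replaced by 7 DADA scores)
dada_append    59 (52 + 7 DADA scores)
dada_only      7
============== ======================================================

Feature order is frozen as documented above; the class-distance block
iterates node types in label order (DTG, DAG, PFG, PUG, URG, DRG, OG)
with the average before the minimum; dependency blocks iterate cell
lines in sorted order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import NODE_TYPES, GeneClassCatalog
from .dependency import (
    DependencyMatrix,
    gene_dependency_features,
    neighbor_dependency_features,
)
from .network import (
    InteractionNetwork,
    all_class_distances,
    all_neighbor_ratios,
    centralities,
)

VARIANTS = ("primary", "no_centrality", "extended_centrality",
            "dada_replace", "dada_append", "dada_only")

VARIANT_WIDTHS = {
    "primary": 52,
    "no_centrality": 49,
    "extended_centrality": 55,
    "dada_replace": 56,
    "dada_append": 59,
    "dada_only": 7,
}

DADA_COLUMNS = tuple(f"dada_{label}" for label in NODE_TYPES)


@dataclass
class FeatureTable:
    """Gene x feature matrix with its variant tag and scaling metadata."""

    values: pd.DataFrame
    variant: str
    scaler: "FeatureScaler | None" = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class FeatureScaler:
    """Min-max or z-score scaling with stored per-feature statistics.

    Statistics are fitted once (on training data) and reapplied to new
    genes; constant features map to 0 under both methods.
    """

    method: str = "minmax"
    center: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    scale: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def fit(self, values: pd.DataFrame) -> "FeatureScaler":
        if self.method == "minmax":
            self.center = values.min(axis=0)
            self.scale = values.max(axis=0) - self.center
        elif self.method == "zscore":
            self.center = values.mean(axis=0)
            self.scale = values.std(axis=0, ddof=0)
        else:
            raise ValueError(f"unknown scaling method {self.method!r}")
        self.scale = self.scale.replace(0.0, np.nan)
        return self

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.center.index if c not in values.columns]
        extra = [c for c in values.columns if c not in self.center.index]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing={missing}, extra={extra}"
            )
        out = (values[self.center.index] - self.center) / self.scale
        return out.fillna(0.0)

    def inverse_transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return values * self.scale.fillna(1.0) + self.center


def assemble(
    net: InteractionNetwork,
    catalog: GeneClassCatalog,
    dep: DependencyMatrix,
    variant: str = "primary",
    dada_scores: pd.DataFrame | None = None,
    sentinel: int | None = None,
) -> FeatureTable:
    """Assemble the feature table for every node of ``net``.

    ``dada_scores`` (required by the dada_* variants) is a gene x 7
    table of externally computed propagation scores, one column per seed
    node type; genes absent from it get 0 (the score of the worst rank).
    Rows follow the network's node order; assembly is deterministic.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if variant.startswith("dada") and dada_scores is None:
        raise ValueError(f"variant {variant!r} requires dada_scores")
    nodes = list(net.nodes)
    blocks: list[pd.DataFrame] = []

    def centrality_block(measures) -> pd.DataFrame:
        c = centralities(net, measures=measures)
        return c.rename(columns={m: f"centrality_{m}" for m in measures}).loc[nodes]

    def dada_block() -> pd.DataFrame:
        assert dada_scores is not None
        if list(dada_scores.columns) != list(DADA_COLUMNS):
            raise ValueError(
                f"dada_scores must have columns {list(DADA_COLUMNS)}, "
                f"got {list(dada_scores.columns)}"
            )
        return dada_scores.reindex(nodes).fillna(0.0)

    def dependency_blocks() -> tuple[pd.DataFrame, pd.DataFrame]:
        lines = sorted(dep.cell_lines)
        own = pd.DataFrame(
            {g: gene_dependency_features(dep, g)[0] for g in nodes}
        ).T.loc[nodes, lines]
        own.columns = [f"dep_{cl}" for cl in lines]
        nbr = pd.DataFrame(
            {g: neighbor_dependency_features(dep, net, g)[0] for g in nodes}
        ).T.loc[nodes, lines]
        nbr.columns = [f"neighbor_dep_{cl}" for cl in lines]
        return own, nbr

    if variant == "dada_only":
        blocks.append(dada_block())
    else:
        if variant == "primary" or variant == "dada_append":
            blocks.append(centrality_block(("degree", "betweenness", "closeness")))
        elif variant == "extended_centrality":
            blocks.append(
                centrality_block(
                    ("degree", "betweenness", "closeness",
                     "pagerank", "eigenvector", "katz")
                )
            )
        elif variant == "dada_replace":
            blocks.append(dada_block())
        # no_centrality: no centrality block at all
        blocks.append(all_class_distances(net, catalog, exclude_self=True,
                                          sentinel=sentinel).loc[nodes])
        blocks.append(all_neighbor_ratios(net, catalog).loc[nodes])
        own, nbr = dependency_blocks()
        blocks.extend([own, nbr])
        if variant == "dada_append":
            blocks.append(dada_block())

    values = pd.concat(blocks, axis=1)
    values.index.name = "gene"
    if values.isna().any().any():
        raise AssertionError("feature table contains missing values after assembly")
    # the documented widths assume the standard 14-cell-line configuration
    if len(dep.cell_lines) == 14 and values.shape[1] != VARIANT_WIDTHS[variant]:
        raise AssertionError(
            f"variant {variant} produced {values.shape[1]} columns, "
            f"expected {VARIANT_WIDTHS[variant]}"
        )
    return FeatureTable(values=values, variant=variant)


def scale(
    table: FeatureTable,
    method: str = "minmax",
    fit_on: list[str] | None = None,
) -> FeatureTable:
    """Scale a feature table, storing the transform for reuse.

    ``fit_on`` restricts the rows used to fit the statistics (e.g. the
    training fold plus the unlabeled pool) while the transform is applied
    to every row.
    """
    scaler = FeatureScaler(method=method)
    fit_values = table.values.loc[fit_on] if fit_on is not None else table.values
    scaler.fit(fit_values)
    return FeatureTable(
        values=scaler.transform(table.values),
        variant=table.variant,
        scaler=scaler,
    )
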