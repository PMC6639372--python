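"""Genetic dependency (essentiality) score handling.

Dependency scores come from genome-scale loss-of-function screens
(DepMap/Avana-style); lower scores mean a gene is more essential for the
survival of the assayed cell line.  The predictor uses, per gene, its own
score in each cell line plus the average score of its network neighbors.

Genes missing from the screen are imputed with the per-cell-line mean
over all scored genes -- a neutral value that preserves the background
distribution -- and flagged.  Neighbor averages skip unscored neighbors
instead of imputing them, to avoid smoothing imputed values twice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GeneClassCatalog, node_type_sets, normalize_symbol
from .network import InteractionNetwork

# DepMap gene_effect header style: "SYMBOL (entrez_id)"
_DEPMAP_GENE_RE = re.compile(r"^([A-Za-z0-9./@-]+)\s+\((\d+)\)$")


@dataclass
class DependencyMatrix:
    """Gene x cell-line essentiality scores with explicit missingness."""

    scores: pd.DataFrame  # genes in rows, cell lines in columns; NaN = missing

    def __post_init__(self) -> None:
        if self.scores.columns.empty:
            raise ValueError("dependency matrix needs at least one cell line")
        if self.scores.columns.duplicated().any():
            raise ValueError("duplicate cell-line identifiers")
        self.scores.index = [normalize_symbol(str(g)) for g in self.scores.index]

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.scores.columns)

    def column_means(self) -> pd.Series:
        """Per-cell-line mean over all scored genes (imputation values)."""
        return self.scores.mean(axis=0, skipna=True)

    def has_gene(self, gene: str) -> bool:
        return gene in self.scores.index


def _looks_like_depmap_genes(labels: Sequence) -> bool:
    hits = sum(bool(_DEPMAP_GENE_RE.match(str(x))) for x in labels)
    return hits > len(labels) / 2


def load_dependency(
    path: str | Path, cell_line_filter: Sequence[str] | None = None
) -> DependencyMatrix:
    """Load a dependency CSV, auto-detecting its orientation.

    Two dialects are accepted: the plain layout with genes in rows and
    cell lines in columns, and the DepMap ``gene_effect`` layout with
    cell lines in rows and ``"SYMBOL (ENTREZ)"`` gene columns (detected
    by that header pattern and transposed, keeping the bare symbol).
    Blank cells become missing values.
    """
    df = pd.read_csv(path, index_col=0)
    if _looks_like_depmap_genes(df.columns):
        df = df.T
        df.index = [
            _DEPMAP_GENE_RE.match(str(g)).group(1) if _DEPMAP_GENE_RE.match(str(g)) else str(g)
            for g in df.index
        ]
    df = df.astype(float)
    df.index.name = "gene"
    df.columns.name = None
    if cell_line_filter is not None:
        missing = [c for c in cell_line_filter if c not in df.columns]
        if missing:
            raise ValueError(
                f"requested cell line(s) {missing} not in file; "
                f"available: {list(df.columns)}"
            )
        df = df[list(cell_line_filter)]
    return DependencyMatrix(scores=df)


def gene_dependency_features(
    dep: DependencyMatrix, gene: str
) -> tuple[pd.Series, bool]:
    """Per-cell-line scores for one gene, imputed where missing.

    Returns ``(vector, imputed)`` where ``imputed`` is True if any cell
    was filled with the column mean (including the whole-gene-absent
    case).
    """
    gene = normalize_symbol(gene)
    means = dep.column_means()
    if not dep.has_gene(gene):
        return means.copy(), True
    row = dep.scores.loc[gene].copy()
    imputed = bool(row.isna().any())
    row = row.fillna(means)
    return row, imputed


def neighbor_dependency_features(
    dep: DependencyMatrix, net: InteractionNetwork, gene: str
) -> tuple[pd.Series, bool]:
    """Mean per-cell-line score over a gene's scored network neighbors.

    Unscored neighbors are skipped.  A gene with no scored neighbor in a
    cell line falls back to the column mean and is flagged imputed.
    """
    gene = normalize_symbol(gene)
    if gene not in net.nodes:
        raise KeyError(f"gene {gene!r} not in network")
    nbrs = [n for n in net.neighbors(gene) if dep.has_gene(n)]
    if not nbrs:
        return dep.column_means().copy(), True
    sub = dep.scores.loc[nbrs]
    means = sub.mean(axis=0, skipna=True)
    imputed = bool(means.isna().any())
    if imputed:
        means = means.fillna(dep.column_means())
    return means, imputed


@dataclass
class GroupComparisonCell:
    """Wilcoxon rank-sum result for one (class, cell line) combination."""

    label: str
    cell_line: str
    n_class: int
    p_value: float
    direction: str  # bigger | smaller | none
    testable: bool


def dependency_group_comparison(
    dep: DependencyMatrix,
    catalog: GeneClassCatalog,
    mode: str = "gene",
    net: InteractionNetwork | None = None,
    include_class_in_background: bool = True,
) -> pd.DataFrame:
    """Compare each class's dependency scores against the background.

    For every class (six labels + OG) and every cell line, the scores of
    class genes (``mode="gene"``) or the neighbor-averaged scores of
    class genes (``mode="neighbor"``) are compared against all scored
    genes in that cell line with a two-sided Wilcoxon rank-sum test.
    Direction is by median ("smaller" = more essential).  Classes with
    fewer than two scored genes are flagged not testable.

    Returns a tidy DataFrame with one row per (label, cell_line).
    """
    if mode not in ("gene", "neighbor"):
        raise ValueError(f"mode must be 'gene' or 'neighbor', got {mode!r}")
    if mode == "neighbor" and net is None:
        raise ValueError("mode='neighbor' requires a network")
    if net is not None:
        sets = node_type_sets(catalog, net)
    else:
        sets = {label: catalog[label] for label in catalog.members}
        if catalog.universe is not None:
            sets["OG"] = catalog.universe - catalog.labeled_genes
        else:
            sets["OG"] = set()

    if mode == "neighbor":
        assert net is not None
        value_rows = {}
        for node in net.nodes:
            vec, _ = neighbor_dependency_features(dep, net, node)
            value_rows[node] = vec
        values = pd.DataFrame(value_rows).T
    else:
        values = dep.scores

    rows = []
    for label, members in sets.items():
        class_values = values.loc[[g for g in values.index if g in members]]
        for cl in dep.cell_lines:
            background = values[cl].dropna()
            x = class_values[cl].dropna() if not class_values.empty else pd.Series(dtype=float)
            if not include_class_in_background:
                background = background[~background.index.isin(members)]
            if len(x) < 2 or len(background) < 2:
                rows.append(GroupComparisonCell(label, cl, len(x), np.nan, "none", False))
                continue
            res = stats.mannwhitneyu(x, background, alternative="two-sided")
            med_x, med_bg = float(x.median()), float(background.median())
            direction = (
                "bigger" if med_x > med_bg else "smaller" if med_x < med_bg else "none"
            )
            rows.append(
                GroupComparisonCell(label, cl, len(x), float(res.pvalue), direction, True)
            )
    return pd.DataFrame([r.__dict__ for r in rows])
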