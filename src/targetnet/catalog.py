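"""Gene-class catalogs.

A catalog maps each of six gene classes onto sets of gene symbols:

* ``DTG`` -- drug target genes (the positive class for prediction),
* ``DAG`` -- disease-associated genes,
* ``PFG`` / ``PUG`` -- prognostically favorable / unfavorable genes,
* ``URG`` / ``DRG`` -- up- / down-regulated genes in tumor vs. normal tissue.

Network nodes carrying none of the six labels form the derived "other
genes" (``OG``) background.  A gene may carry several labels at once; the
only conflict treated specially is a gene listed as both prognostically
favorable and unfavorable, which is contradictory and resolved explicitly
on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

CLASS_LABELS: tuple[str, ...] = ("DTG", "DAG", "PFG", "PUG", "URG", "DRG")
#: The seven node types used in distance / neighbor-ratio analyses.
NODE_TYPES: tuple[str, ...] = CLASS_LABELS + ("OG",)


class CatalogError(ValueError):
    """Raised for invalid class labels or malformed gene-list inputs."""


def normalize_symbol(symbol: str) -> str:
    """Trim whitespace and uppercase a gene symbol.

    No alias or HGNC resolution is attempted: symbol standardization is a
    curation step upstream of this package.
    """
    return symbol.strip().upper()


@dataclass
class GeneClassCatalog:
    """Mapping from class label to a set of uppercase gene symbols.

    Parameters
    ----------
    members
        Mapping with keys drawn from :data:`CLASS_LABELS`.  Missing classes
        are stored as empty sets so every catalog exposes all six.
    universe
        Optional set of all known symbols (e.g. the node set the catalog
        was restricted to).
    """

    members: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.members) - set(CLASS_LABELS)
        if unknown:
            raise CatalogError(f"unknown class label(s): {sorted(unknown)}")
        for label in CLASS_LABELS:
            self.members.setdefault(label, set())

    def __getitem__(self, label: str) -> set[str]:
        if label not in CLASS_LABELS:
            raise CatalogError(f"unknown class label: {label!r}")
        return self.members[label]

    @property
    def labeled_genes(self) -> set[str]:
        """Union of all six class sets."""
        out: set[str] = set()
        for label in CLASS_LABELS:
            out |= self.members[label]
        return out

    def classes_of(self, gene: str) -> set[str]:
        return {label for label in CLASS_LABELS if gene in self.members[label]}

    def counts(self) -> dict[str, int]:
        return {label: len(self.members[label]) for label in CLASS_LABELS}

    def summary_tsv(self, mapped: Mapping[str, int] | None = None) -> str:
        """Render a per-class summary table (label, n_input, n_mapped)."""
        lines = ["label\tn_input\tn_mapped"]
        for label in CLASS_LABELS:
            n_in = len(self.members[label])
            n_map = mapped[label] if mapped is not None else n_in
            lines.append(f"{label}\t{n_in}\t{n_map}")
        return "\n".join(lines) + "\n"


def _read_gene_list(path: str | Path) -> set[str]:
    genes: set[str] = set()
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot read gene list {path}: {exc}") from exc
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        # single-column TSV: take the first field
        symbol = normalize_symbol(line.split("\t")[0])
        if symbol:
            genes.add(symbol)
    return genes


def load_gene_lists(
    paths: Mapping[str, str | Path],
    prognostic_conflict: str = "drop",
) -> GeneClassCatalog:
    """Load one-gene-per-line class files into a catalog.

    Parameters
    ----------
    paths
        Mapping from class label (subset of :data:`CLASS_LABELS`) to file
        path.  Files are UTF-8 text with one symbol per line; ``#`` starts
        a comment line; duplicates and empty lines are ignored.
    prognostic_conflict
        Policy for genes appearing in both PFG and PUG: ``"drop"``
        (default) removes them from both prognostic classes with a
        warning; ``"keep"`` retains the contradiction.
    """
    if prognostic_conflict not in ("drop", "keep"):
        raise CatalogError(
            f"prognostic_conflict must be 'drop' or 'keep', got {prognostic_conflict!r}"
        )
    unknown = set(paths) - set(CLASS_LABELS)
    if unknown:
        raise CatalogError(f"unknown class label(s) in paths: {sorted(unknown)}")
    members = {label: _read_gene_list(p) for label, p in paths.items()}
    catalog = GeneClassCatalog(members=members)
    conflict = catalog["PFG"] & catalog["PUG"]
    if conflict:
        warnings.warn(
            f"{len(conflict)} gene(s) listed as both prognostic favorable and "
            f"unfavorable: {sorted(conflict)[:5]}...; policy={prognostic_conflict}",
            stacklevel=2,
        )
        if prognostic_conflict == "drop":
            catalog.members["PFG"] -= conflict
            catalog.members["PUG"] -= conflict
    return catalog


def restrict_to_network(catalog: GeneClassCatalog, net) -> GeneClassCatalog:
    """Intersect every class set with the node set of ``net``.

    The returned catalog's ``universe`` is the network node set, so
    :func:`other_genes` is well-defined.  Idempotent.
    """
    nodes = set(net.nodes)
    if not nodes:
        raise CatalogError("cannot restrict catalog to an empty network")
    members = {label: catalog[label] & nodes for label in CLASS_LABELS}
    return GeneClassCatalog(members=members, universe=nodes)


def other_genes(catalog: GeneClassCatalog, net) -> set[str]:
    """Network nodes carrying no class label (the OG background)."""
    return set(net.nodes) - catalog.labeled_genes


def node_type_sets(catalog: GeneClassCatalog, net) -> dict[str, set[str]]:
    """All seven node-type sets (six classes + OG) restricted to ``net``."""
    restricted = restrict_to_network(catalog, net)
    sets = {label: restricted[label] for label in CLASS_LABELS}
    sets["OG"] = other_genes(restricted, net)
    return sets


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in sorted(genes)), encoding="utf-8"
    )
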