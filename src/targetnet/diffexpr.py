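"""Differential expression calling on paired tumor/normal samples.

Genes are tested with a paired t-test on ``log2(x + 1)`` values, effect
size is summarized as a linear fold change of pair-averaged expression,
p-values are corrected by Benjamini-Hochberg FDR, and genes passing
``q <= alpha`` with fold change ``>= fc_threshold`` (up) or
``<= 1/fc_threshold`` (down) are called URG / DRG respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedExpressionMatrix:
    """Gene x pair tumor and normal expression, aligned dimensions.

    ``tumor[i, j]`` and ``normal[i, j]`` are expression of gene ``i`` in
    the tumor and matched normal sample of pair ``j``.  Values are
    non-negative; missing values are rejected on construction.
    """

    genes: list[str]
    pairs: list[str]
    tumor: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        shape = (len(self.genes), len(self.pairs))
        if self.tumor.shape != shape or self.normal.shape != shape:
            raise ValueError(
                f"tumor/normal must be gene x pair matrices of shape {shape}"
            )
        for name, m in (("tumor", self.tumor), ("normal", self.normal)):
            if np.isnan(m).any():
                raise ValueError(f"{name} matrix contains missing values")
            if (m < 0).any():
                raise ValueError(f"{name} matrix contains negative values")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def load_paired_expression(
    expr_path: str | Path, manifest_path: str | Path
) -> PairedExpressionMatrix:
    """Load a genes-in-rows expression TSV plus a pairing manifest.

    The manifest is a TSV with columns ``pair_id``, ``tumor_column``,
    ``normal_column`` naming columns of the expression table.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"pair_id", "tumor_column", "normal_column"}
    if not required.issubset(manifest.columns):
        raise ValueError(
            f"pairing manifest must have columns {sorted(required)}, "
            f"got {list(manifest.columns)}"
        )
    missing = [
        c
        for c in pd.concat([manifest.tumor_column, manifest.normal_column])
        if c not in expr.columns
    ]
    if missing:
        raise ValueError(f"manifest names absent expression columns: {missing}")
    tumor = expr[manifest.tumor_column.tolist()].to_numpy(dtype=float)
    normal = expr[manifest.normal_column.tolist()].to_numpy(dtype=float)
    return PairedExpressionMatrix(
        genes=[str(g) for g in expr.index],
        pairs=[str(p) for p in manifest.pair_id],
        tumor=tumor,
        normal=normal,
    )


def paired_t_pvalues(
    expr: PairedExpressionMatrix, log_offset: float | None = 1.0
) -> np.ndarray:
    """Two-sided paired t-test p-value per gene.

    Values are transformed to ``log2(x + log_offset)`` first
    (``log_offset=None`` skips the transform).  Degenerate genes whose
    paired differences have zero variance get ``p = 1`` when the mean
    difference is also zero, and a machine-epsilon floor (with a warning)
    when it is not -- the t statistic diverges there and a literal zero
    would poison downstream log-odds.
    """
    if expr.n_pairs < 2:
        raise ValueError("paired t-test requires at least 2 sample pairs")
    if log_offset is not None:
        t_mat = np.log2(expr.tumor + log_offset)
        n_mat = np.log2(expr.normal + log_offset)
    else:
        t_mat, n_mat = expr.tumor, expr.normal
    d = t_mat - n_mat
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.ones(d.shape[0])
    ok = sd > 0
    tstat = np.zeros_like(mean)
    tstat[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df=n - 1)
    degenerate = (~ok) & (mean != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero-variance nonzero-mean "
            "paired differences; p floored at machine epsilon",
            stacklevel=2,
        )
        p[degenerate] = np.finfo(float).eps
    return p


def fold_changes(expr: PairedExpressionMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """Linear fold change (mean tumor + c) / (mean normal + c) per gene."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return (expr.tumor.mean(axis=1) + pseudocount) / (
        expr.normal.mean(axis=1) + pseudocount
    )


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    fc: np.ndarray,
    q: np.ndarray,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Classify each gene as ``URG``, ``DRG`` or ``none``.

    Thresholds are inclusive: ``q <= alpha`` and ``FC >= fc_threshold``
    calls up-regulated, ``FC <= 1/fc_threshold`` down-regulated.
    """
    fc = np.asarray(fc, dtype=float)
    q = np.asarray(q, dtype=float)
    if fc.shape != q.shape:
        raise ValueError("fold-change and q-value vectors must align")
    call = np.full(fc.shape, "none", dtype=object)
    sig = q <= alpha
    call[sig & (fc >= fc_threshold)] = "URG"
    call[sig & (fc <= 1.0 / fc_threshold)] = "DRG"
    return call


def deg_table(
    expr: PairedExpressionMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    log_offset: float | None = 1.0,
) -> pd.DataFrame:
    """Full DEG pipeline: test, fold change, FDR, call.

    Returns a DataFrame indexed by gene with columns
    ``fc, log2fc, p, q, call``.
    """
    p = paired_t_pvalues(expr, log_offset=log_offset)
    fc = fold_changes(expr, pseudocount=pseudocount)
    q = bh_fdr(p)
    call = call_degs(fc, q, fc_threshold=fc_threshold, alpha=alpha)
    return pd.DataFrame(
        {"fc": fc, "log2fc": np.log2(fc), "p": p, "q": q, "call": call},
        index=pd.Index(expr.genes, name="gene"),
    )
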