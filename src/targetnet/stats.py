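"""Evaluation statistics: classification metrics, ROC/AUC, enrichment,
rank-based group comparisons, and the rank-to-score transform used when
external gene-ranking algorithms supply alternative features.

Conventions
-----------
* MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)), with the
  value defined as 0 when any factor under the root vanishes.
* AUC handles score ties by midrank, i.e. AUC = P(s+ > s-) + P(s+ = s-)/2.
* Enrichment uses a one-sided (greater) Fisher exact test, matching the
  directional claim "predicted targets are enriched for reference
  targets".
* Wilcoxon rank-sum tests are two-sided; exact p-values for small
  tie-free samples, normal approximation with continuity correction
  otherwise.  Direction is reported separately from the p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .catalog import CLASS_LABELS, GeneClassCatalog


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """Sensitivity, specificity and Matthews correlation coefficient.

    ``Sn = TP/(TP+FN)``, ``Sp = TN/(TN+FP)``; MCC as in the module
    docstring, 0 by convention on degenerate margins.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("Sn/Sp need at least one positive and one negative")
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    denom_sq = float(tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = 0.0 if denom_sq == 0 else (tp * tn - fn * fp) / np.sqrt(denom_sq)
    return sn, sp, float(mcc)


def counts_from_rates(sn: float, sp: float, n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Reconstruct integer confusion counts from Sn, Sp and class sizes."""
    tp = round(sn * n_pos)
    tn = round(sp * n_neg)
    return tp, n_neg - tn, tn, n_pos - tp


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, pd.DataFrame]:
    """AUC plus the ROC curve points (fpr, tpr, threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both positive and negative labels")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class EnrichmentResult:
    """2x2 enrichment of reference positives inside a predicted set."""

    in_pred_ref: int
    in_pred_other: int
    out_pred_ref: int
    out_pred_other: int
    prop_predicted: float
    prop_background: float
    odds_ratio: float
    p_value: float


def enrichment_test(
    predicted: set[str], reference_positives: set[str], universe: set[str]
) -> EnrichmentResult:
    """Is the reference-positive rate higher inside the predicted set?

    One-sided (greater) Fisher exact test on the 2x2 table of
    (inside/outside predicted) x (reference positive or not), computed
    over ``universe``.  Sets straying outside the universe are clipped
    with a warning.
    """
    if not predicted:
        raise ValueError("predicted set is empty")
    if not predicted <= universe or not reference_positives <= universe:
        warnings.warn("predicted/reference sets clipped to the universe", stacklevel=2)
        predicted = predicted & universe
        reference_positives = reference_positives & universe
        if not predicted:
            raise ValueError("predicted set is empty after clipping to universe")
    background = universe - predicted
    a = len(predicted & reference_positives)
    b = len(predicted) - a
    c = len(background & reference_positives)
    d = len(background) - c
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(
        in_pred_ref=a,
        in_pred_other=b,
        out_pred_ref=c,
        out_pred_other=d,
        prop_predicted=a / len(predicted),
        prop_background=c / len(background) if background else 0.0,
        odds_ratio=float(odds),
        p_value=float(p),
    )


def alt_negative_evaluation(
    final_scores: pd.Series, positives: set[str], negative_set: set[str]
) -> tuple[float, pd.DataFrame]:
    """Re-estimate AUC of stored final scores against an alternative
    negative gene set (e.g. curated disease genes or cancer drivers).

    Negatives overlapping the positive set are dropped with a warning.
    """
    overlap = positives & negative_set
    if overlap:
        warnings.warn(
            f"{len(overlap)} gene(s) in both positive and negative sets "
            "dropped from negatives",
            stacklevel=2,
        )
        negative_set = negative_set - overlap
    pos = [g for g in final_scores.index if g in positives]
    neg = [g for g in final_scores.index if g in negative_set]
    if not neg:
        raise ValueError("no scored genes left in the negative set")
    if not pos:
        raise ValueError("no scored genes in the positive set")
    scores = final_scores.loc[pos + neg].to_numpy()
    labels = np.array([1] * len(pos) + [0] * len(neg))
    return roc_auc(scores, labels)


def dada_score(rank: int, n_candidates: int) -> float:
    """Rank-to-score transform ``(N - rank) / N`` for a ranked list of N
    candidates; rank 1 (best) scores ``(N-1)/N``, rank N scores 0."""
    if n_candidates < 1:
        raise ValueError("n_candidates must be positive")
    if not 1 <= rank <= n_candidates:
        raise ValueError(f"rank must be in [1, {n_candidates}], got {rank}")
    return (n_candidates - rank) / n_candidates


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) p-value and statistic.

    Exact distribution for tie-free samples with both sizes <= 25,
    normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    exact = (
        len(x) <= 25 and len(y) <= 25 and len(np.unique(pooled)) == len(pooled)
    )
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def centrality_group_tests(
    centr: pd.DataFrame,
    catalog: GeneClassCatalog,
    include_class_in_background: bool = True,
) -> pd.DataFrame:
    """Per class x centrality measure: Wilcoxon rank-sum vs. all nodes.

    ``centr`` is a node-indexed DataFrame of centrality values (as
    produced by :func:`targetnet.network.centralities`).  Every class is
    compared against the background of all nodes (optionally excluding
    the class itself); direction is by median.  Returns a tidy frame
    with columns label, measure, n_class, p_value, q_value (BH across
    the whole grid), direction, testable.
    """
    rows = []
    for label in CLASS_LABELS:
        members = catalog[label] & set(centr.index)
        for measure in centr.columns:
            background = centr[measure]
            x = background.loc[sorted(members)]
            if not include_class_in_background:
                background = background.drop(index=list(members))
            if len(x) < 2:
                rows.append((label, measure, len(x), np.nan, "none", False))
                continue
            _, p = rank_sum_test(x.to_numpy(), background.to_numpy())
            med_x, med_bg = float(x.median()), float(background.median())
            direction = (
                "higher" if med_x > med_bg else "lower" if med_x < med_bg else "none"
            )
            rows.append((label, measure, len(x), p, direction, True))
    df = pd.DataFrame(
        rows, columns=["label", "measure", "n_class", "p_value", "direction", "testable"]
    )
    q = np.full(len(df), np.nan)
    mask = df.p_value.notna()
    if mask.any():
        from statsmodels.stats.multitest import multipletests

        q[mask.to_numpy()] = multipletests(df.p_value[mask], method="fdr_bh")[1]
    df.insert(4, "q_value", q)
    return df
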