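"""One-class SVM drug-target predictor with repeated cross-validation.

The predictor is trained only on known drug-target genes (positives); all
other network genes form an unlabeled "negative" pool whose labels are
noisy by construction -- many of them may be undiscovered targets.  A
one-class SVM with an RBF kernel learns the region occupied by positives
in feature space; the signed decision value is the prediction score
(higher = more target-like) and the default call threshold is 0.

Evaluation follows a repeated k-fold protocol: per repeat, positives and
negatives are independently partitioned into k folds; for each fold a
model is fitted on the remaining positive folds (scaling statistics come
from the same training rows plus the training-side negatives, so no
held-out information leaks) and scores the held-out positives and
negatives.  Every gene thus receives exactly one out-of-fold score per
repeat.  Sensitivity/specificity/MCC pool the confusion counts across
the k folds of a repeat; AUC is computed on the pooled out-of-fold
scores.

The final prediction score of a gene is the mean of its per-repeat
out-of-fold scores, and the consensus predicted set contains the genes
called positive in *every* repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .features import FeatureScaler, FeatureTable
from .stats import confusion_metrics, roc_auc


@dataclass
class OneClassModel:
    """A fitted RBF one-class SVM plus the scaler it was trained with."""

    svm: OneClassSVM
    scaler: FeatureScaler
    feature_names: list[str]

    def decision_scores(self, values: pd.DataFrame) -> pd.Series:
        scaled = self.scaler.transform(values)
        return pd.Series(
            self.svm.decision_function(scaled.to_numpy()), index=values.index
        )


@dataclass
class CVRoundResult:
    """Out-of-fold scores, calls and pooled metrics for one CV repeat."""

    round_index: int
    seed: int
    fold_assignment: pd.Series = field(repr=False)
    scores: pd.Series = field(repr=False)
    calls: pd.Series = field(repr=False)
    sn: float = np.nan
    sp: float = np.nan
    mcc: float = np.nan
    auc: float = np.nan


@dataclass
class ConsensusPrediction:
    """Mean out-of-fold score and all-rounds-positive consensus calls."""

    final_scores: pd.Series
    predicted: set[str]
    n_rounds: int
    positives: set[str]
    hyperparameters: tuple[float, float]  # (nu, gamma)


def train(
    table: FeatureTable,
    positives: set[str],
    nu: float = 0.1,
    gamma: float | None = None,
    fit_scaler_on: list[str] | None = None,
    scaling: str = "minmax",
) -> OneClassModel:
    """Fit a one-class SVM on the positive rows of a feature table.

    ``gamma`` defaults to ``1/d`` for ``d`` features.  ``fit_scaler_on``
    names the rows used for scaling statistics (default: all rows of the
    table); the SVM itself always sees only positive rows.
    """
    pos_rows = [g for g in table.genes if g in positives]
    if len(pos_rows) < 2:
        raise ValueError(f"need at least 2 positive rows, got {len(pos_rows)}")
    if not (0 < nu <= 1):
        raise ValueError(f"nu must be in (0, 1], got {nu}")
    d = len(table.feature_names)
    if gamma is None:
        gamma = 1.0 / d
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    scaler = FeatureScaler(method=scaling).fit(
        table.values.loc[fit_scaler_on] if fit_scaler_on is not None else table.values
    )
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma)
    svm.fit(scaler.transform(table.values.loc[pos_rows]).to_numpy())
    return OneClassModel(svm=svm, scaler=scaler, feature_names=table.feature_names)


def _partition(items: list[str], k: int, rng: np.random.Generator) -> pd.Series:
    """Random assignment of items to k nearly equal folds."""
    items = list(items)
    perm = rng.permutation(len(items))
    folds = np.empty(len(items), dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = fold
    return pd.Series(folds, index=items)


def _run_round(
    table: FeatureTable,
    positives: set[str],
    negatives: list[str],
    pos_list: list[str],
    k: int,
    nu: float,
    gamma: float,
    round_index: int,
    seed: int,
    scaling: str,
) -> CVRoundResult:
    rng = np.random.default_rng(seed)
    pos_folds = _partition(pos_list, k, rng)
    neg_folds = _partition(negatives, k, rng)
    if (pos_folds.value_counts().reindex(range(k)).fillna(0) == 0).any():
        raise ValueError(
            f"a fold received 0 held-out positives; use a smaller k than {k}"
        )
    scores = pd.Series(np.nan, index=table.genes, dtype=float)
    for fold in range(k):
        train_pos = pos_folds.index[pos_folds != fold].tolist()
        held_pos = pos_folds.index[pos_folds == fold].tolist()
        held_neg = neg_folds.index[neg_folds == fold].tolist()
        train_neg = neg_folds.index[neg_folds != fold].tolist()
        model = train(
            table,
            set(train_pos),
            nu=nu,
            gamma=gamma,
            fit_scaler_on=train_pos + train_neg,
            scaling=scaling,
        )
        held = held_pos + held_neg
        scores.loc[held] = model.decision_scores(table.values.loc[held])
    calls = scores >= 0
    labels = pd.Series(
        [1 if g in positives else 0 for g in scores.index], index=scores.index
    )
    tp = int(((labels == 1) & calls).sum())
    fn = int(((labels == 1) & ~calls).sum())
    fp = int(((labels == 0) & calls).sum())
    tn = int(((labels == 0) & ~calls).sum())
    sn, sp, mcc = confusion_metrics(tp=tp, fp=fp, tn=tn, fn=fn)
    auc, _ = roc_auc(scores.to_numpy(), labels.to_numpy())
    return CVRoundResult(
        round_index=round_index,
        seed=seed,
        fold_assignment=pd.concat([pos_folds, neg_folds]),
        scores=scores,
        calls=calls,
        sn=sn,
        sp=sp,
        mcc=mcc,
        auc=auc,
    )


def cross_validate(
    table: FeatureTable,
    positives: set[str],
    k: int = 5,
    repeats: int = 10,
    grid: list[tuple[float, float]] | None = None,
    seed: int = 0,
    scaling: str = "minmax",
    grid_repeats: int = 3,
) -> tuple[list[CVRoundResult], tuple[float, float]]:
    """Repeated k-fold cross-validation of the one-class predictor.

    When ``grid`` (a list of ``(nu, gamma)`` pairs) is given, each pair
    is evaluated by ``grid_repeats`` repeats of k-fold CV on distinct
    partitions and the pair with the highest mean AUC is selected once;
    the reported rounds are then run with the selected pair.  With
    ``grid=None`` the defaults ``nu=0.1, gamma=1/d`` are used.

    Returns the per-repeat results and the ``(nu, gamma)`` used.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    pos_list = [g for g in table.genes if g in positives]
    negatives = [g for g in table.genes if g not in positives]
    master = np.random.default_rng(seed)
    # derive independent 31-bit seeds for selection and evaluation phases
    selection_seeds = master.integers(0, 2**31 - 1, size=grid_repeats)
    round_seeds = master.integers(0, 2**31 - 1, size=repeats)

    d = len(table.feature_names)
    if grid is None:
        chosen = (0.1, 1.0 / d)
    else:
        mean_aucs = []
        for nu, gamma in grid:
            aucs = [
                _run_round(table, positives, negatives, pos_list, k, nu, gamma,
                           r, int(selection_seeds[r]), scaling).auc
                for r in range(grid_repeats)
            ]
            mean_aucs.append(float(np.mean(aucs)))
        chosen = grid[int(np.argmax(mean_aucs))]

    nu, gamma = chosen
    results = [
        _run_round(table, positives, negatives, pos_list, k, nu, gamma,
                   r, int(round_seeds[r]), scaling)
        for r in range(repeats)
    ]
    return results, chosen


def default_grid(n_features: int) -> list[tuple[float, float]]:
    """nu in {0.05, 0.1, 0.2, 0.3, 0.5} x gamma in (1/d) * 4^{-2..2}."""
    base = 1.0 / n_features
    return [
        (nu, base * 4.0**e)
        for nu in (0.05, 0.1, 0.2, 0.3, 0.5)
        for e in (-2, -1, 0, 1, 2)
    ]


def consensus(
    results: list[CVRoundResult],
    positives: set[str] | None = None,
    hyperparameters: tuple[float, float] = (np.nan, np.nan),
) -> ConsensusPrediction:
    """Average per-round scores and intersect per-round positive calls."""
    if not results:
        raise ValueError("no CV rounds given")
    gene_index = results[0].scores.index
    for r in results[1:]:
        if not r.scores.index.equals(gene_index):
            raise ValueError("CV rounds cover different gene sets")
    score_mat = pd.concat([r.scores for r in results], axis=1)
    final_scores = score_mat.mean(axis=1)
    predicted = set(gene_index)
    for r in results:
        predicted &= set(r.calls.index[r.calls])
    return ConsensusPrediction(
        final_scores=final_scores,
        predicted=predicted,
        n_rounds=len(results),
        positives=set(positives) if positives is not None else set(),
        hyperparameters=hyperparameters,
    )


@dataclass
class PredictorEnsemble:
    """Per-round final models refit on all positives, for scoring new genes."""

    models: list[OneClassModel]

    @classmethod
    def fit(
        cls,
        table: FeatureTable,
        positives: set[str],
        nu: float,
        gamma: float,
        n_rounds: int = 10,
        scaling: str = "minmax",
    ) -> "PredictorEnsemble":
        models = [
            train(table, positives, nu=nu, gamma=gamma, scaling=scaling)
            for _ in range(n_rounds)
        ]
        return cls(models=models)

    def predict(self, table: FeatureTable) -> pd.DataFrame:
        """Mean decision score across round models; call = positive in all."""
        expected = self.models[0].feature_names
        if list(table.feature_names) != list(expected):
            missing = set(expected) - set(table.feature_names)
            extra = set(table.feature_names) - set(expected)
            raise ValueError(
                f"feature schema mismatch: missing={sorted(missing)}, "
                f"extra={sorted(extra)}"
            )
        per_model = pd.concat(
            [m.decision_scores(table.values) for m in self.models], axis=1
        )
        return pd.DataFrame(
            {
                "score": per_model.mean(axis=1),
                "call": (per_model >= 0).all(axis=1),
            }
        )
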