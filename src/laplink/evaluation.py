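"""Cross-validation protocols and ROC/AUC computation.

Three protocols mirror the standard evaluation of bipartite association
predictors:

* **global LOOCV** -- each known association is masked in turn, both GIP
  kernels are recomputed on the masked matrix, the model is refit, and the
  held-out pair is ranked against all unknown microbe-disease pairs across
  every disease;
* **local LOOCV** -- identical masking loop, but the held-out pair is ranked
  only against the unknown microbes of its own disease;
* **repeated 5-fold CV** -- the known pairs are randomly split into five
  groups; each group is masked simultaneously, the model refit, and its
  held-out positives ranked globally; repeated with fresh random splits.

Kernel recomputation after masking is mandatory in every protocol: the GIP
similarity is derived from the adjacency, so leaving it fixed would leak the
held-out labels into the similarity graph.

AUC uses the midrank (tie = 1/2) Mann-Whitney convention throughout, which
coincides with the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.stats

from .associations import AdjacencyNetwork
from .laprls import ModelParams, predict

__all__ = [
    "RocCurve",
    "CvResult",
    "UndefinedAUCError",
    "roc_auc",
    "global_loocv",
    "local_loocv",
    "five_fold_cv",
]

NegativesMode = Literal["full-model", "per-run"]


class UndefinedAUCError(ValueError):
    """AUC needs at least one positive and one negative label."""


@dataclass
class RocCurve:
    """ROC points (false-positive rate, true-positive rate) plus AUC.

    Points run from (0, 0) to (1, 1) at descending score thresholds, one
    step per distinct score; ties produce diagonal segments whose
    trapezoidal area equals the midrank Mann-Whitney statistic.
    """

    points: np.ndarray  # (k, 2) array of (fpr, tpr)
    auc: float


@dataclass
class CvResult:
    """Outcome of one cross-validation protocol."""

    protocol: str
    auc_mean: float
    auc_sd: float = 0.0
    n_repeats: int = 1
    seed: int | None = None
    roc: RocCurve | None = None
    per_fold: dict = field(default_factory=dict)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and AUC for real scores against 0/1 labels.

    The AUC is the tie-corrected Mann-Whitney statistic (probability that a
    random positive outscores a random negative, ties counted half), which
    equals the trapezoidal area under the emitted curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos + n_neg != len(y):
        raise ValueError("labels must be 0/1")
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("need at least one positive and one negative")

    ranks = scipy.stats.rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # one curve step per distinct score value
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted == 1)[distinct]
    fp = np.cumsum(y_sorted == 0)[distinct]
    points = np.vstack(
        [
            np.r_[0.0, fp / n_neg],
            np.r_[0.0, tp / n_pos],
        ]
    ).T
    return RocCurve(points=points, auc=float(auc))


def _masked_copy(
    network: AdjacencyNetwork, pairs: Iterable[tuple[int, int]]
) -> AdjacencyNetwork:
    Y = np.array(network.Y, copy=True)
    for i, j in pairs:
        Y[i, j] = 0
    return AdjacencyNetwork(
        Y, network.microbe_index, network.disease_index, ordering=network.ordering
    )


def _percentile(neg: np.ndarray, s: float) -> float:
    """Fraction of negatives scored strictly below s, ties counted half."""
    return float(((neg < s).sum() + 0.5 * (neg == s).sum()) / len(neg))


def global_loocv(
    network: AdjacencyNetwork,
    params: ModelParams = ModelParams(),
    negatives: NegativesMode = "full-model",
) -> CvResult:
    """Leave-one-out CV with a global ranking scope.

    Each known pair is masked, kernels recomputed, and its refit score
    collected. Negative scores (all unknown pairs, pooled across diseases)
    come from the full-data model by default (``negatives='full-model'``,
    one pooled ROC); ``negatives='per-run'`` instead ranks each held-out
    positive against the unknown-pair scores of its own masked run and
    averages the rank percentiles (a sensitivity-analysis variant; both
    quantities estimate the same probability of correct ordering).

    Deterministic; independent of the order the edges are processed.
    """
    known = list(zip(*np.nonzero(network.Y)))
    if len(known) < 2:
        raise ValueError("global LOOCV needs at least two known associations")
    unknown_mask = np.asarray(network.Y) == 0

    pos_scores = np.empty(len(known))
    percentiles = np.empty(len(known))
    per_run = negatives == "per-run"
    if not per_run:
        full = predict(network, params)
        neg_scores = full.values[unknown_mask]

    for k, (i, j) in enumerate(known):
        masked = _masked_copy(network, [(i, j)])
        F = predict(masked, params).values
        pos_scores[k] = F[i, j]
        if per_run:
            percentiles[k] = _percentile(F[unknown_mask], F[i, j])

    if per_run:
        auc = float(percentiles.mean())
        roc = None
    else:
        scores = np.r_[pos_scores, neg_scores]
        labels = np.r_[np.ones(len(pos_scores), int), np.zeros(len(neg_scores), int)]
        roc = roc_auc(scores, labels)
        auc = roc.auc
    return CvResult(protocol="global-loocv", auc_mean=auc, roc=roc)


def local_loocv(
    network: AdjacencyNetwork, params: ModelParams = ModelParams()
) -> CvResult:
    """Leave-one-out CV ranked within each held-out pair's own disease.

    For each masked pair (i, j) the refit score is ranked against the scores
    of the microbes not known to be associated with disease j; the resulting
    rank percentiles are pooled across all pairs into a single AUC (the mean
    percentile, i.e. the probability that the held-out microbe outscores a
    random unknown microbe of the same disease).
    """
    Y = np.asarray(network.Y)
    known = list(zip(*np.nonzero(Y)))
    if len(known) < 2:
        raise ValueError("local LOOCV needs at least two known associations")

    percentiles = []
    for i, j in known:
        cand = np.flatnonzero(Y[:, j] == 0)
        if len(cand) == 0:
            continue  # disease already linked to every microbe: no ranking scope
        masked = _masked_copy(network, [(i, j)])
        F = predict(masked, params).values
        percentiles.append(_percentile(F[cand, j], F[i, j]))
    if not percentiles:
        raise ValueError("no held-out pair has candidate microbes to rank against")
    p = np.sort(np.asarray(percentiles))[::-1]
    # curve: sweep the percentile threshold; FPR = 1 - t by construction
    thresholds = np.unique(p)[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        points.append((1.0 - t, float((p >= t).mean())))
    points.append((1.0, 1.0))
    roc = RocCurve(points=np.asarray(points), auc=float(p.mean()))
    return CvResult(protocol="local-loocv", auc_mean=roc.auc, roc=roc)


def five_fold_cv(
    network: AdjacencyNetwork,
    params: ModelParams = ModelParams(),
    repeats: int = 100,
    seed: int = 0,
) -> CvResult:
    """Repeated 5-fold CV over association pairs with global ranking.

    Per repeat, the known pairs are shuffled and split into five nearly
    equal groups; each group is masked simultaneously, kernels recomputed,
    and its held-out positives ranked (rank percentile) against the masked
    model's scores at all originally-unknown pairs. Percentiles pool across
    the five folds into one AUC per repeat; the result reports mean and
    standard deviation over repeats (fold-level AUCs are kept in
    ``per_fold`` for reference). Reproducible given ``seed``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    Y = np.asarray(network.Y)
    known = list(zip(*np.nonzero(Y)))
    if len(known) < 5:
        raise ValueError("5-fold CV needs at least five known associations")
    unknown_mask = Y == 0

    rng = np.random.default_rng(seed)
    repeat_aucs = np.empty(repeats)
    fold_aucs: list[float] = []
    for r in range(repeats):
        perm = rng.permutation(len(known))
        groups = np.array_split(perm, 5)
        percentiles: list[float] = []
        for g in groups:
            fold_pairs = [known[k] for k in g]
            masked = _masked_copy(network, fold_pairs)
            F = predict(masked, params).values
            neg = F[unknown_mask]
            fold_ps = [_percentile(neg, F[i, j]) for i, j in fold_pairs]
            percentiles.extend(fold_ps)
            fold_aucs.append(float(np.mean(fold_ps)))
        repeat_aucs[r] = np.mean(percentiles)

    sd = float(repeat_aucs.std(ddof=1)) if repeats > 1 else 0.0
    return CvResult(
        protocol="kfold",
        auc_mean=float(repeat_aucs.mean()),
        auc_sd=sd,
        n_repeats=repeats,
        seed=seed,
        per_fold={
            "repeat_aucs": repeat_aucs.tolist(),
            "fold_aucs": fold_aucs,
            "fold_sd": float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        },
    )
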