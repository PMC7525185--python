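"""Negative sampling, repeated k-fold cross-validation and candidate ranking.

Positives are the known circRNA-disease pairs; each repetition draws a fresh
negative sample (uniform over the zero cells of A, the same size as the
positive set), partitions positives and negatives into parallel folds, trains
the convolutional classifier on the remaining folds and evaluates precision,
sensitivity, accuracy, F1, Matthews correlation and AUC on the held-out fold.
AUC uses the Mann-Whitney rank statistic with midranks for ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, SamplingError, TrainingError
from .features import (
    MirnaProjector,
    PairFeature,
    build_dataset,
    fit_mirna_projector,
    stack_features,
)
from .io_net import BipartiteNetwork
from .model import CnnConfig, TrainedModel, build_cnn, score, train

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Pre", "Sen", "Acc", "F1", "MCC", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    Pre: float
    Sen: float
    Acc: float
    F1: float
    MCC: float
    AUC: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class CVReport:
    """Per-fold metric rows plus the seeds and negative samples behind them."""

    rows: pd.DataFrame
    seed: int
    folds: int
    repetitions: int
    negative_manifests: list[list[tuple[str, str]]] = field(repr=False)

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of each metric over all folds."""
        stats = self.rows[list(METRIC_NAMES)].agg(["mean", "std"])
        return stats

    def mean_auc(self) -> float:
        return float(self.rows["AUC"].mean())


# ---------------------------------------------------------------------------


def sample_negatives(
    A: np.ndarray, count: int, seed: int
) -> list[tuple[int, int]]:
    """Uniformly sample ``count`` zero cells of A without replacement."""
    A = np.asarray(A)
    zi, zj = np.nonzero(A == 0)
    if count > zi.size:
        raise SamplingError(
            f"requested {count} negatives but only {zi.size} zero cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zi.size, size=count, replace=False)
    return [(int(zi[k]), int(zj[k])) for k in chosen]


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks; NaN if a class is missing."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined: only one class present", stacklevel=2)
        return float("nan")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> MetricSet:
    """Precision, sensitivity, accuracy, F1, MCC from counts; AUC from scores."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    pre = _safe_div(tp, tp + fp, "precision")
    sen = _safe_div(tp, tp + fn, "sensitivity")
    acc = (tp + tn) / counts.total
    f1 = _safe_div(2.0 * sen * pre, sen + pre, "F1") if (sen == sen and pre == pre) else float("nan")
    mcc_den = np.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fn) * float(tn + fp)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")
    auc = auc_score(scores, labels) if scores is not None else float("nan")
    return MetricSet(Pre=pre, Sen=sen, Acc=acc, F1=f1, MCC=mcc, AUC=auc)


def confusion_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts at ``score >= threshold`` (softmax argmax at 0.5)."""
    pred = np.asarray(scores) >= threshold
    labels = np.asarray(labels).astype(bool)
    return ConfusionCounts(
        TP=int((pred & labels).sum()),
        TN=int((~pred & ~labels).sum()),
        FP=int((pred & ~labels).sum()),
        FN=int((~pred & labels).sum()),
    )


def _fold_slices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """A shuffled partition of range(n) into ``folds`` near-equal index folds."""
    order = rng.permutation(n)
    return [np.asarray(part) for part in np.array_split(order, folds)]


def cross_validate(
    network: BipartiteNetwork,
    Sc: np.ndarray,
    Sd: np.ndarray,
    cnn_config: CnnConfig = CnnConfig(),
    projector: MirnaProjector | None = None,
    n_components: int = 50,
    folds: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    mask_label: bool = True,
    shuffle_labels: bool = False,
) -> CVReport:
    """Repeated k-fold cross-validation of the full pair-classification stack.

    Per repetition: draw a fresh negative sample the size of the positive
    set, build (masked) pair features, partition both classes into parallel
    folds, train on the rest, test on the held-out fold.  With
    ``shuffle_labels`` the pair labels are permuted per repetition — a null
    control whose AUC should hover at 0.5.
    """
    positives = network.positive_pairs
    if len(positives) < folds:
        raise ConfigurationError(
            f"need at least {folds} positive pairs, have {len(positives)}"
        )
    if projector is None:
        projector = fit_mirna_projector(network.Y, network.O, n_components)

    master = np.random.default_rng(seed)
    rows = []
    manifests: list[list[tuple[str, str]]] = []
    for rep in range(repetitions):
        rep_seed = int(master.integers(2**31))
        rep_rng = np.random.default_rng(rep_seed)
        neg_idx = sample_negatives(network.A, len(positives), seed=rep_seed)
        negatives = [
            (network.circ.ids[i], network.disease.ids[j]) for i, j in neg_idx
        ]
        manifests.append(negatives)
        pairs = positives + negatives
        labels = [1] * len(positives) + [0] * len(negatives)
        dataset = build_dataset(
            pairs, labels, Sc, Sd, network, projector, mask_label=mask_label
        )
        X, y = stack_features(dataset)
        if shuffle_labels:
            y = y[rep_rng.permutation(len(y))]

        pos_idx = np.nonzero(y == 1)[0]
        neg_only = np.nonzero(y == 0)[0]
        pos_folds = _fold_slices(len(pos_idx), folds, rep_rng)
        neg_folds = _fold_slices(len(neg_only), folds, rep_rng)
        for fold in range(folds):
            test = np.concatenate(
                [pos_idx[pos_folds[fold]], neg_only[neg_folds[fold]]]
            )
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test] = False
            fold_seed = int(rep_rng.integers(2**31))
            cfg = replace(cnn_config, seed=fold_seed)
            try:
                fitted = train(
                    build_cnn(cfg, X.shape[2]), X[train_mask], y[train_mask], cfg
                )
            except TrainingError:
                logger.warning("rep %d fold %d: single-class training set", rep, fold)
                continue
            s = score(fitted, X[test])
            counts = confusion_from_scores(s, y[test])
            metrics = compute_metrics(counts, scores=s, labels=y[test])
            rows.append(
                {"repetition": rep, "fold": fold, "seed": fold_seed,
                 **metrics.as_dict()}
            )
    return CVReport(
        rows=pd.DataFrame(rows),
        seed=seed,
        folds=folds,
        repetitions=repetitions,
        negative_manifests=manifests,
    )


def rank_candidates(
    models: Sequence[TrainedModel],
    candidates: Sequence[PairFeature],
    per_disease: bool = False,
) -> pd.DataFrame:
    """Mean model score per unlabeled pair, ranked descending.

    Ties break deterministically by (score desc, circRNA id asc).  With
    ``per_disease`` an additional rank within each disease is added.
    """
    if not models:
        raise ConfigurationError("need at least one trained model")
    labeled = [pf for pf in candidates if pf.label != "unknown"]
    if labeled:
        raise ConfigurationError(
            f"candidate set contains labeled pairs, e.g. "
            f"({labeled[0].circ_id}, {labeled[0].disease_id})"
        )
    X, _ = stack_features(candidates)
    mean_scores = np.mean([score(m, X) for m in models], axis=0)
    table = pd.DataFrame(
        {
            "circRNA": [pf.circ_id for pf in candidates],
            "disease": [pf.disease_id for pf in candidates],
            "score": mean_scores,
        }
    ).sort_values(
        ["score", "circRNA"], ascending=[False, True], kind="mergesort"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    if per_disease:
        table["disease_rank"] = table.groupby("disease")["score"].rank(
            ascending=False, method="first"
        ).astype(int)
    return table.reset_index(drop=True)
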