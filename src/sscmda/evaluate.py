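"""Evaluation protocols: LOOCV (global and local), repeated k-fold CV, ROC/AUC.

Global LOOCV hides one known association at a time, rebuilds the whole
pipeline on the modified matrix, and ranks the hidden pair against every
pair that is unknown in the original matrix.  Local LOOCV restricts the
comparison set to the unknown pairs of the same disease.  In both protocols
the reported AUC is the mean, over held-out cases, of the fraction of
candidate pairs the case outranks (ties count one half) — the Mann-Whitney
reading of the ROC area, which makes global and local coincide exactly when
there is only one disease.

The standalone :func:`roc_auc` statistic is the Mann-Whitney U form with
midrank ties; it equals the trapezoidal area under the ROC built from all
distinct thresholds, a property the test suite asserts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .datamodel import AssociationMatrix, ScoreMatrix
from .pipeline import SuperAssociation, SuperScores, two_layer_values

__all__ = [
    "CVResult",
    "two_layer_score",
    "roc_auc",
    "growth_rate",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "random_scorer",
]

logger = logging.getLogger(__name__)

Scorer = Callable[[np.ndarray], np.ndarray]
"""Maps a (possibly perturbed) binary association matrix to a score matrix."""


@dataclass
class CVResult:
    """Outcome of one cross-validation protocol."""

    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list, repr=False)
    per_fold_aucs: list[float] | None = None
    mean: float | None = None
    std: float | None = None
    n_cases: int = 0
    n_skipped: int = 0
    #: LOOCV only: per-case fraction of candidates outranked (the AUC is their mean)
    case_fractions: list[float] | None = None


def two_layer_score(
    FSpy: ScoreMatrix, scores: SuperScores, SA: SuperAssociation
) -> ScoreMatrix:
    """Combine FSpy with the super-layer scores into the final score TS."""
    values = two_layer_values(
        FSpy.values, scores, SA, FSpy.disease_names, FSpy.mirna_names
    )
    return ScoreMatrix(
        values, list(FSpy.disease_names), list(FSpy.mirna_names), provenance="two_layer"
    )


def roc_auc(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> tuple[float, list[tuple[float, float]]]:
    """Mann-Whitney AUC (ties 0.5) plus the ROC polyline.

    Returns ``(auc, [(fpr, tpr), ...])`` with the curve running from (0, 0)
    to (1, 1).
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(labels, np.concatenate([pos, neg]), drop_intermediate=False)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def growth_rate(auc_new: float, auc_old: float) -> float:
    """Relative AUC improvement as a percentage, rounded half-up to 2 decimals."""
    if auc_old <= 0:
        raise ValueError("reference AUC must be positive")
    gr = 100.0 * (auc_new - auc_old) / auc_old
    return float(Decimal(repr(gr)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _beaten_fraction(score: float, candidates: np.ndarray) -> float:
    """Fraction of candidate scores strictly below, ties counted one half."""
    below = np.count_nonzero(candidates < score)
    ties = np.count_nonzero(candidates == score)
    return (below + 0.5 * ties) / candidates.size


def _roc_from_fractions(beaten: np.ndarray) -> list[tuple[float, float]]:
    """ROC polyline from per-case beaten-fractions against a uniform null.

    The normalized rank position of case i is ``v = 1 - beaten``; sweeping a
    threshold over [0, 1] gives TPR(t) = frac(v <= t) and FPR(t) = t.
    """
    v = np.sort(1.0 - beaten)
    points = [(0.0, 0.0)]
    for t in v:
        prev_tpr = points[-1][1]
        points.append((float(t), prev_tpr))
        points.append((float(t), float(np.count_nonzero(v <= t) / v.size)))
    points.append((1.0, 1.0))
    return points


def _loocv(
    A: AssociationMatrix,
    scorer: Scorer,
    local: bool,
) -> CVResult:
    values = A.values
    unknown = values == 0
    positives = np.argwhere(values == 1)
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    beaten, skipped = [], 0
    for i, j in positives:
        mask = unknown[i] if local else unknown
        n_candidates = int(mask.sum())
        if n_candidates == 0:
            skipped += 1
            continue
        mod = values.copy()
        mod[i, j] = 0
        ts = scorer(mod)
        cand = ts[i][mask] if local else ts[mask]
        beaten.append(_beaten_fraction(ts[i, j], cand))
    if skipped:
        logger.info("local LOOCV: skipped %d cases with no candidate pairs", skipped)
    if not beaten:
        raise ValueError("no LOOCV cases had candidate pairs")
    beaten_arr = np.array(beaten)
    return CVResult(
        auc=float(beaten_arr.mean()),
        roc_points=_roc_from_fractions(beaten_arr),
        n_cases=len(beaten),
        n_skipped=skipped,
        case_fractions=[float(b) for b in beaten],
    )


def global_loocv(A: AssociationMatrix, scorer: Scorer) -> CVResult:
    """Leave-one-out over known associations, ranked against all unknown pairs."""
    return _loocv(A, scorer, local=False)


def local_loocv(A: AssociationMatrix, scorer: Scorer) -> CVResult:
    """Leave-one-out ranked against the unknown pairs of the same disease only."""
    return _loocv(A, scorer, local=True)


def kfold_cv(
    A: AssociationMatrix,
    scorer: Scorer,
    k: int = 5,
    repetitions: int = 100,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation over the known associations.

    Per repetition the positives are shuffled and split into ``k`` near-equal
    folds (remainder cells distributed one per fold); each fold is hidden in
    turn, the pipeline is rebuilt, and the held-out scores are compared with
    the originally-unknown pairs by Mann-Whitney AUC.  Returns the mean and
    standard deviation over repetitions.
    """
    values = A.values
    positives = np.argwhere(values == 1)
    if len(positives) < k:
        raise ValueError(f"need at least k={k} known associations")
    unknown = values == 0
    rep_aucs = []
    all_fold_aucs: list[float] = []
    for rep in range(repetitions):
        rng = np.random.default_rng((seed, rep))
        perm = rng.permutation(len(positives))
        folds = np.array_split(perm, k)
        fold_aucs = []
        for fold in folds:
            held = positives[fold]
            mod = values.copy()
            mod[held[:, 0], held[:, 1]] = 0
            ts = scorer(mod)
            auc, _ = roc_auc(ts[held[:, 0], held[:, 1]], ts[unknown])
            fold_aucs.append(auc)
        rep_aucs.append(float(np.mean(fold_aucs)))
        all_fold_aucs.extend(fold_aucs)
    return CVResult(
        auc=float(np.mean(rep_aucs)),
        per_fold_aucs=all_fold_aucs,
        mean=float(np.mean(rep_aucs)),
        std=float(np.std(rep_aucs)),
        n_cases=len(positives),
    )


def random_scorer(seed: int) -> Scorer:
    """A seeded scorer assigning uniform random scores (the chance baseline)."""

    def scorer(values: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.random(values.shape)

    return scorer
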