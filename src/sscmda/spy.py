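"""Spy-based reliable-negative identification (positive-unlabeled learning).

Unknown miRNA-disease pairs are a mixture of undiscovered associations and
true negatives.  Each spy round hides a random 10% of the known positives
("spies"), rescores the matrix with the basic RLS classifier, and declares
every originally-unknown pair scoring strictly below the worst spy a
candidate reliable negative.  The final reliable-negative set is the
intersection over many rounds, which keeps only pairs that look negative no
matter which positives were hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import AssociationMatrix, LabeledMatrix, ScoreMatrix, SimilarityMatrix
from .rls import RLSParams, hat_matrix

__all__ = ["SpyParams", "spy_round", "reliable_negatives", "spy_score"]


@dataclass
class SpyParams:
    """Spy sampling parameters.

    spy_fraction
        Fraction of known positives hidden per round (default 0.10); the spy
        count is rounded but never below 1.
    rounds
        Number of independent rounds intersected (default 200).
    seed
        Base seed; round ``r`` draws from substream ``(seed, r)`` so rounds
        are order-independent and reproducible.
    """

    spy_fraction: float = 0.10
    rounds: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.spy_fraction < 1.0):
            raise ValueError("spy_fraction must lie strictly between 0 and 1")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


def _hats(SD: SimilarityMatrix, SR: SimilarityMatrix, rls: RLSParams):
    return hat_matrix(SD.values, rls.lambda_d), hat_matrix(SR.values, rls.lambda_r)


def _basic_scores(Hd: np.ndarray, Hr: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """FS for a label matrix, using precomputed hat matrices."""
    return (Hd.T @ labels + labels @ Hr) / 2.0


def spy_round(
    A: AssociationMatrix,
    SD: SimilarityMatrix,
    SR: SimilarityMatrix,
    params: SpyParams | None = None,
    rls_params: RLSParams | None = None,
    rng: np.random.Generator | None = None,
    hats: tuple[np.ndarray, np.ndarray] | None = None,
    similarity_builder=None,
) -> set[tuple[int, int]]:
    """One spy round: returns the index pairs flagged reliable-negative.

    The threshold is the minimum basic score over the hidden spies; only
    pairs that were 0 in the *original* matrix and score strictly below it
    qualify (pairs tying the worst spy are not counted).
    """
    params = params or SpyParams()
    rls_params = rls_params or RLSParams()
    rng = rng or np.random.default_rng(params.seed)
    positives = np.argwhere(A.values == 1)
    if len(positives) < 2:
        raise ValueError("spy strategy needs at least 2 known positives")
    n_spies = max(1, round(params.spy_fraction * len(positives)))
    spy_idx = positives[rng.choice(len(positives), size=n_spies, replace=False)]
    modified = A.values.astype(float)
    modified[spy_idx[:, 0], spy_idx[:, 1]] = 0.0
    if similarity_builder is not None:
        SD, SR = similarity_builder(modified)
        hats = None
    Hd, Hr = hats if hats is not None else _hats(SD, SR, rls_params)
    fs = _basic_scores(Hd, Hr, modified)
    threshold = fs[spy_idx[:, 0], spy_idx[:, 1]].min()
    below = (fs < threshold) & (A.values == 0)
    return {tuple(p) for p in np.argwhere(below)}


def reliable_negatives(
    A: AssociationMatrix,
    SD: SimilarityMatrix,
    SR: SimilarityMatrix,
    params: SpyParams | None = None,
    rls_params: RLSParams | None = None,
    similarity_builder=None,
) -> LabeledMatrix:
    """Intersect spy rounds into a ternary label matrix AN.

    +1 at the original positives, -1 at pairs flagged in *every* round,
    0 elsewhere.  By default the similarity matrices are held fixed across
    rounds (spies perturb labels, not similarities); pass a
    ``similarity_builder(values) -> (SD, SR)`` callable to rebuild the
    interaction-profile kernels with the spies hidden in every round
    (stricter, much slower).
    """
    params = params or SpyParams()
    rls_params = rls_params or RLSParams()
    hats = None if similarity_builder is not None else _hats(SD, SR, rls_params)
    rn_mask = A.values == 0
    for r in range(params.rounds):
        if not rn_mask.any():
            break
        rng = np.random.default_rng((params.seed, r))
        round_set = spy_round(
            A, SD, SR, params, rls_params, rng, hats=hats,
            similarity_builder=similarity_builder,
        )
        round_mask = np.zeros_like(rn_mask)
        if round_set:
            idx = np.array(sorted(round_set))
            round_mask[idx[:, 0], idx[:, 1]] = True
        rn_mask &= round_mask
    labels = A.values.astype(np.int8).copy()
    labels[rn_mask] = -1
    return LabeledMatrix(labels, list(A.disease_names), list(A.mirna_names))


def spy_score(
    AN: LabeledMatrix,
    SD: SimilarityMatrix,
    SR: SimilarityMatrix,
    params: RLSParams | None = None,
) -> ScoreMatrix:
    """FSpy: the basic RLS score computed on the ternary label matrix."""
    params = params or RLSParams()
    Hd, Hr = _hats(SD, SR, params)
    values = _basic_scores(Hd, Hr, AN.values.astype(float))
    return ScoreMatrix(
        values, list(AN.disease_names), list(AN.mirna_names), provenance="spy"
    )
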