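"""Closed-form regularized least squares (RLS) scoring.

Each side of the bipartite problem is scored through the hat matrix
``H = S (S + lambda I)^{-1}`` of its similarity network; the final basic
score averages the two sides.  The hat matrix is obtained by a linear solve,
never by forming the inverse explicitly; callers running many label matrices
against a fixed similarity (spy rounds, super-cluster scores) can reuse a
precomputed hat matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datamodel import AssociationMatrix, LabeledMatrix, ScoreMatrix, SimilarityMatrix

__all__ = ["RLSParams", "hat_matrix", "score_disease_side", "score_mirna_side", "combine"]

logger = logging.getLogger(__name__)

#: condition estimate beyond which a solve is considered ill-conditioned
COND_WARN = 1e8


@dataclass
class RLSParams:
    """Regularization strengths of the two RLS sides (both default to 2)."""

    lambda_d: float = 2.0
    lambda_r: float = 2.0

    def __post_init__(self) -> None:
        if self.lambda_d <= 0 or self.lambda_r <= 0:
            raise ValueError("regularization parameters must be strictly positive")


def hat_matrix(similarity: np.ndarray, lam: float, check_condition: bool = True) -> np.ndarray:
    """Compute ``(S + lambda I)^{-1} S`` by a linear solve.

    For symmetric ``S`` the transpose of the result is ``S (S + lambda I)^{-1}``,
    which is what the disease-side score applies on the left.
    Raises if the shifted matrix is numerically singular; logs a warning when
    its condition estimate exceeds ``1e8`` (integrated semantic similarity is
    not guaranteed positive semidefinite).
    """
    S = np.asarray(similarity, dtype=float)
    n = S.shape[0]
    M = S + lam * np.eye(n)
    if check_condition:
        cond = np.linalg.cond(M)
        if not np.isfinite(cond) or cond > 1e14:
            raise ValueError(f"(S + lambda I) is numerically singular (cond ~ {cond:.3g})")
        if cond > COND_WARN:
            logger.warning("(S + lambda I) ill-conditioned: cond ~ %.3g", cond)
    try:
        H = scipy.linalg.solve(M, S, assume_a="sym")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught above normally
        raise ValueError(f"(S + lambda I) is numerically singular: {exc}") from exc
    return H


def _labels(A: AssociationMatrix | LabeledMatrix | np.ndarray) -> np.ndarray:
    if isinstance(A, (AssociationMatrix, LabeledMatrix)):
        return A.values.astype(float)
    return np.asarray(A, dtype=float)


def _names(A, SD_or_SR: SimilarityMatrix, side: str):
    if isinstance(A, (AssociationMatrix, LabeledMatrix)):
        return list(A.disease_names), list(A.mirna_names)
    n_d, n_m = np.asarray(A).shape
    if side == "disease":
        return list(SD_or_SR.names), [f"m{j}" for j in range(n_m)]
    return [f"d{i}" for i in range(n_d)], list(SD_or_SR.names)


def score_disease_side(
    SD: SimilarityMatrix,
    A: AssociationMatrix | LabeledMatrix | np.ndarray,
    params: RLSParams | None = None,
) -> ScoreMatrix:
    """Disease-side RLS score: ``S[i, j] = SD_i (SD + lambda_d I)^{-1} A[:, j]``.

    Accepts ternary labels (reliable negatives enter as -1 and push scores
    down) as well as binary associations.
    """
    params = params or RLSParams()
    labels = _labels(A)
    if labels.shape[0] != SD.n:
        raise ValueError("label matrix row count does not match disease similarity")
    # hat_matrix returns (S+lam I)^{-1} S; its transpose is S (S+lam I)^{-1}
    H = hat_matrix(SD.values, params.lambda_d)
    d_names, m_names = _names(A, SD, "disease")
    return ScoreMatrix(H.T @ labels, d_names, m_names, provenance="basic")


def score_mirna_side(
    SR: SimilarityMatrix,
    A: AssociationMatrix | LabeledMatrix | np.ndarray,
    params: RLSParams | None = None,
) -> ScoreMatrix:
    """miRNA-side RLS score, oriented disease x miRNA to match the other side.

    ``S[i, j] = SR_j (SR + lambda_r I)^{-1} (miRNA profile of disease i)``.
    """
    params = params or RLSParams()
    labels = _labels(A)
    if labels.shape[1] != SR.n:
        raise ValueError("label matrix column count does not match miRNA similarity")
    H = hat_matrix(SR.values, params.lambda_r)
    d_names, m_names = _names(A, SR, "mirna")
    return ScoreMatrix(labels @ H, d_names, m_names, provenance="basic")


def combine(Sd: ScoreMatrix, Sm: ScoreMatrix) -> ScoreMatrix:
    """Average of the two RLS sides (the basic score FS)."""
    if Sd.values.shape != Sm.values.shape:
        raise ValueError("score matrices have different shapes")
    return ScoreMatrix(
        (Sd.values + Sm.values) / 2.0,
        list(Sd.disease_names),
        list(Sd.mirna_names),
        provenance="basic",
    )
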