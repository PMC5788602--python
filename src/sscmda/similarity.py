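"""Disease and miRNA similarity measures.

Three ingredients feed the integrated similarity networks:

* two DAG-based disease semantic similarity models — model 1 decays a term's
  contribution by Δ per generation of ancestry, model 2 weights a term by how
  informative it is (``-log`` of the fraction of disease DAGs containing it);
* the Gaussian interaction profile (GIP) kernel on binary association
  profiles, with bandwidth normalized by the mean squared profile norm;
* integration rules that prefer the semantic / functional value where one
  exists and fall back to the GIP kernel otherwise.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datamodel import AssociationMatrix, DiseaseDAGSet, SimilarityMatrix

__all__ = [
    "SemanticParams",
    "GIPParams",
    "semantic_contribution_m1",
    "semantic_similarity_m1",
    "semantic_similarity_m2",
    "gip_similarity",
    "integrate_disease",
    "integrate_mirna",
]


@dataclass
class SemanticParams:
    """Parameters of the semantic similarity models.

    delta
        Semantic contribution decay factor in (0, 1]; each generation of
        ancestry multiplies a term's contribution by ``delta``.
    log_base
        Base of the information-content logarithm in model 2.  ``None`` means
        natural log.  Model 2 similarity is invariant to this choice (the
        base cancels in the contribution ratio).
    """

    delta: float = 0.5
    log_base: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must lie in (0, 1]")
        if self.log_base is not None and (self.log_base <= 0 or self.log_base == 1):
            raise ValueError("log_base must be positive and != 1")


@dataclass
class GIPParams:
    """Original bandwidths of the Gaussian interaction profile kernel."""

    beta_prime_d: float = 1.0
    beta_prime_m: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_prime_d <= 0 or self.beta_prime_m <= 0:
            raise ValueError("GIP bandwidths must be strictly positive")


def semantic_contribution_m1(
    dags: DiseaseDAGSet, disease: str, params: SemanticParams | None = None
) -> tuple[dict[str, float], float]:
    """Model-1 contribution of every term of ``T(disease)`` plus its sum DV1.

    The disease itself contributes 1; every other term contributes
    ``delta * max(contribution of its children within the disease's DAG)``,
    which for a geometric decay equals ``delta ** (minimum hop distance from
    the disease along child->parent edges)``.
    """
    params = params or SemanticParams()
    if disease not in dags:
        raise KeyError(f"disease {disease!r} not in DAG vocabulary")
    members = dags.ancestors(disease)
    # breadth-first walk up the parent relation: depth = min #edges from D
    depth = {disease: 0}
    queue = deque([disease])
    while queue:
        term = queue.popleft()
        for parent in dags.parents(term):
            if parent in members and parent not in depth:
                depth[parent] = depth[term] + 1
                queue.append(parent)
    contrib = {t: params.delta ** d for t, d in depth.items()}
    return contrib, float(sum(contrib.values()))


def _membership_and_contrib(
    dags: DiseaseDAGSet, diseases: list[str], params: SemanticParams
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Dense (n_diseases x n_terms) membership mask and model-1 contributions."""
    terms: dict[str, int] = {}
    per_disease = []
    for d in diseases:
        contrib, _ = semantic_contribution_m1(dags, d, params)
        per_disease.append(contrib)
        for t in contrib:
            terms.setdefault(t, len(terms))
    member = np.zeros((len(diseases), len(terms)), dtype=bool)
    contrib_mat = np.zeros((len(diseases), len(terms)))
    for i, contrib in enumerate(per_disease):
        for t, v in contrib.items():
            member[i, terms[t]] = True
            contrib_mat[i, terms[t]] = v
    return member, contrib_mat, list(terms)


def _pairwise_semantic(member: np.ndarray, contrib: np.ndarray) -> np.ndarray:
    """Shared-ancestor similarity from per-term contributions.

    numerator(i, j) = sum over shared terms of (C_i[t] + C_j[t]);
    denominator(i, j) = DV_i + DV_j.  Pairs with a zero denominator get
    similarity 0 off-diagonal and 1 on the diagonal.
    """
    m = member.astype(float)
    numerator = contrib @ m.T + m @ contrib.T
    dv = contrib.sum(axis=1)
    denom = dv[:, None] + dv[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, numerator / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def semantic_similarity_m1(
    dags: DiseaseDAGSet,
    params: SemanticParams | None = None,
    diseases: list[str] | None = None,
) -> SimilarityMatrix:
    """Disease semantic similarity, model 1 (decay-weighted shared ancestry)."""
    params = params or SemanticParams()
    diseases = list(diseases) if diseases is not None else list(dags.diseases)
    if not diseases:
        raise ValueError("no diseases to compare")
    member, contrib, _ = _membership_and_contrib(dags, diseases, params)
    sim = SimilarityMatrix(_pairwise_semantic(member, contrib), diseases, kind="semantic1")
    return sim


def semantic_similarity_m2(
    dags: DiseaseDAGSet,
    params: SemanticParams | None = None,
    diseases: list[str] | None = None,
) -> SimilarityMatrix:
    """Disease semantic similarity, model 2 (information-content weighting).

    A term appearing in ``c`` of the ``n`` disease DAGs contributes
    ``-log(c / n)`` — identical for every disease whose DAG contains it.
    Terms present in every DAG contribute 0 and so never raise similarity.
    """
    params = params or SemanticParams()
    diseases = list(diseases) if diseases is not None else list(dags.diseases)
    if not diseases:
        raise ValueError("no diseases to compare")
    counting_set = dags.diseases  # DAG count is over the full disease set
    member_all, _, terms = _membership_and_contrib(dags, list(counting_set), params)
    dag_count = {t: int(member_all[:, k].sum()) for k, t in enumerate(terms)}
    n = len(counting_set)
    scale = math.log(params.log_base) if params.log_base is not None else 1.0

    member, _, q_terms = _membership_and_contrib(dags, diseases, params)
    ic = np.array(
        [-math.log(dag_count.get(t, 1) / n) / scale for t in q_terms]
    )
    contrib = member * ic[None, :]
    return SimilarityMatrix(_pairwise_semantic(member, contrib), diseases, kind="semantic2")


def gip_similarity(
    A: AssociationMatrix,
    axis: str = "disease",
    params: GIPParams | None = None,
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity along one axis of A.

    For diseases the profiles are the rows of A; the kernel bandwidth is the
    original bandwidth divided by the mean squared profile norm, so the
    similarity scale adapts to the density of the association matrix.
    """
    params = params or GIPParams()
    if axis == "disease":
        profiles = A.values.astype(float)
        names = A.disease_names
        beta_prime = params.beta_prime_d
    elif axis == "mirna":
        profiles = A.values.T.astype(float)
        names = A.mirna_names
        beta_prime = params.beta_prime_m
    else:
        raise ValueError("axis must be 'disease' or 'mirna'")
    values = gip_kernel(profiles, beta_prime)
    return SimilarityMatrix(values, list(names), kind="gip")


def gip_kernel(profiles: np.ndarray, beta_prime: float) -> np.ndarray:
    """GIP kernel matrix on raw profile rows (shared by both axes)."""
    mean_sq_norm = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("bandwidth undefined (division by zero): all profiles are zero")
    beta = beta_prime / mean_sq_norm
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-beta * sq_dists)
    np.fill_diagonal(values, 1.0)
    return values


def _align_submatrix(
    sub: SimilarityMatrix, names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Embed a similarity over a subset of ``names`` into full-size arrays.

    Returns (values nxn with zeros outside coverage, coverage mask length n).
    """
    idx = sub.index_of()
    n = len(names)
    covered = np.array([name in idx for name in names])
    full = np.zeros((n, n))
    pos = [idx[name] for name, c in zip(names, covered) if c]
    where = np.where(covered)[0]
    full[np.ix_(where, where)] = sub.values[np.ix_(pos, pos)]
    return full, covered


def integrate_disease(
    ss1: SimilarityMatrix,
    ss2: SimilarityMatrix,
    gd: SimilarityMatrix,
) -> SimilarityMatrix:
    """Integrated disease similarity SD.

    Where both diseases carry a DAG annotation and share any ancestry
    (``SS1 + SS2 > 0``) SD is the average of the two semantic models;
    otherwise the GIP kernel value stands in.  Diagonal forced to 1.
    """
    if ss1.names != ss2.names:
        raise ValueError("SS1 and SS2 cover different diseases")
    names = list(gd.names)
    s1, covered = _align_submatrix(ss1, names)
    s2, _ = _align_submatrix(ss2, names)
    semantic = (s1 + s2) / 2.0
    mask = covered[:, None] & covered[None, :] & ((s1 + s2) > 0)
    values = np.where(mask, semantic, gd.values)
    np.fill_diagonal(values, 1.0)
    sim = SimilarityMatrix(values, names, kind="integrated")
    sim.validate()
    return sim


def integrate_mirna(ms: SimilarityMatrix, gr: SimilarityMatrix) -> SimilarityMatrix:
    """Integrated miRNA similarity SR.

    The functional similarity value is used where both miRNAs are covered by
    the functional matrix and the value is positive; otherwise the GIP
    kernel.  Diagonal forced to 1.
    """
    names = list(gr.names)
    msv, covered = _align_submatrix(ms, names)
    mask = covered[:, None] & covered[None, :] & (msv > 0)
    values = np.where(mask, msv, gr.values)
    np.fill_diagonal(values, 1.0)
    sim = SimilarityMatrix(values, names, kind="integrated")
    sim.validate()
    return sim
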