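"""End-to-end SSCMDA scoring pipeline.

Chains the stages: integrated similarities -> basic RLS score FS -> spy
reliable negatives and FSpy -> Ward super-clusters and super-layer scores ->
two-layer score TS.  The :class:`SSCMDAModel` front-end works on the named
domain objects; the :class:`_Engine` fast path operates on pre-aligned
arrays so that cross-validation loops can rebuild the pipeline hundreds of
times cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .datamodel import (
    AssociationMatrix,
    DiseaseDAGSet,
    LabeledMatrix,
    ScoreMatrix,
    SimilarityMatrix,
)
from .rls import RLSParams, hat_matrix
from .similarity import (
    GIPParams,
    SemanticParams,
    gip_kernel,
    integrate_disease,
    integrate_mirna,
    semantic_similarity_m1,
    semantic_similarity_m2,
)
from .spy import SpyParams, reliable_negatives, spy_score
from .supercluster import (
    ClusterParams,
    SuperAssociation,
    SuperScores,
    build_super_associations,
    super_scores,
    ward_cluster,
)

__all__ = ["SSCMDAConfig", "SSCMDAModel", "two_layer_values"]


@dataclass
class SSCMDAConfig:
    """All tunable parameters of the pipeline, with the standard defaults."""

    delta: float = 0.5
    log_base: float | None = None
    beta_prime_d: float = 1.0
    beta_prime_m: float = 1.0
    lambda_d: float = 2.0
    lambda_r: float = 2.0
    spy_fraction: float = 0.10
    spy_rounds: int = 200
    spy_recompute_gip: bool = False
    cut_height_fraction: float = 0.70
    n_clusters: int | None = None
    k_neighbors: int = 5
    use_spy: bool = True
    use_supercluster: bool = True
    knn_filter: bool = True
    seed: int = 0

    @property
    def semantic(self) -> SemanticParams:
        return SemanticParams(self.delta, self.log_base)

    @property
    def gip(self) -> GIPParams:
        return GIPParams(self.beta_prime_d, self.beta_prime_m)

    @property
    def rls(self) -> RLSParams:
        return RLSParams(self.lambda_d, self.lambda_r)

    @property
    def spy(self) -> SpyParams:
        return SpyParams(self.spy_fraction, self.spy_rounds, self.seed)

    @property
    def cluster(self) -> ClusterParams:
        return ClusterParams(self.cut_height_fraction, self.n_clusters, self.k_neighbors)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SSCMDAConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def two_layer_values(
    fspy: np.ndarray, scores: SuperScores, SA: SuperAssociation, disease_names, mirna_names
) -> np.ndarray:
    """TS = FSpy * (super-disease score + super-miRNA score) / 2, elementwise.

    For pair (d_i, m_j): the super-disease score is that of d_i's cluster for
    m_j, the super-miRNA score is that of m_j's cluster for d_i.
    """
    try:
        p_of = np.array([SA.disease_cluster_of[d] for d in disease_names])
        q_of = np.array([SA.mirna_cluster_of[m] for m in mirna_names])
    except KeyError as exc:
        raise ValueError(f"entity missing from partition: {exc}") from exc
    sd_part = scores.super_disease_to_mirna[p_of, :]  # nd x nm
    sr_part = scores.disease_to_super_mirna[:, q_of]  # nd x nm
    return fspy * (sd_part + sr_part) / 2.0


@dataclass
class SSCMDAResult:
    """All intermediate and final score matrices of one pipeline run."""

    SD: SimilarityMatrix
    SR: SimilarityMatrix
    FS: ScoreMatrix
    AN: LabeledMatrix
    FSpy: ScoreMatrix
    SA: SuperAssociation | None
    super_scores: SuperScores | None
    TS: ScoreMatrix


class SSCMDAModel:
    """The full predictor over named domain objects.

    Parameters
    ----------
    dags
        Disease DAG set for the semantic similarity models; optional — without
        it the disease side falls back entirely to the GIP kernel.
    mirna_sim
        Functional miRNA similarity (may cover a subset of the miRNAs).
    config
        Pipeline parameters.
    """

    def __init__(
        self,
        dags: DiseaseDAGSet | None = None,
        mirna_sim: SimilarityMatrix | None = None,
        config: SSCMDAConfig | None = None,
    ) -> None:
        self.dags = dags
        self.mirna_sim = mirna_sim
        self.config = config or SSCMDAConfig()

    # -- similarity construction ------------------------------------------

    def integrated_similarities(
        self, A: AssociationMatrix
    ) -> tuple[SimilarityMatrix, SimilarityMatrix]:
        """SD and SR for an association matrix (GIP recomputed from A)."""
        cfg = self.config
        gd = SimilarityMatrix(
            gip_kernel(A.values.astype(float), cfg.beta_prime_d),
            list(A.disease_names),
            kind="gip",
        )
        gr = SimilarityMatrix(
            gip_kernel(A.values.T.astype(float), cfg.beta_prime_m),
            list(A.mirna_names),
            kind="gip",
        )
        if self.dags is not None:
            annotated = [d for d in A.disease_names if d in self.dags]
            if annotated:
                ss1 = semantic_similarity_m1(self.dags, cfg.semantic, annotated)
                ss2 = semantic_similarity_m2(self.dags, cfg.semantic, annotated)
                SD = integrate_disease(ss1, ss2, gd)
            else:
                SD = SimilarityMatrix(gd.values, gd.names, kind="integrated")
        else:
            SD = SimilarityMatrix(gd.values, gd.names, kind="integrated")
        if self.mirna_sim is not None:
            SR = integrate_mirna(self.mirna_sim, gr)
        else:
            SR = SimilarityMatrix(gr.values, gr.names, kind="integrated")
        return SD, SR

    def _spy_similarity_builder(self, A: AssociationMatrix):
        """Per-round similarity rebuild (spy strictness flag)."""
        d_names, m_names = list(A.disease_names), list(A.mirna_names)

        def build(values: np.ndarray):
            mod = AssociationMatrix((values > 0).astype(np.int8), d_names, m_names)
            return self.integrated_similarities(mod)

        return build

    # -- scoring -----------------------------------------------------------

    def run(self, A: AssociationMatrix) -> SSCMDAResult:
        """Full pipeline on an association matrix."""
        cfg = self.config
        SD, SR = self.integrated_similarities(A)
        Hd = hat_matrix(SD.values, cfg.lambda_d)
        Hr = hat_matrix(SR.values, cfg.lambda_r)
        fs_vals = (Hd.T @ A.values + A.values @ Hr) / 2.0
        FS = ScoreMatrix(fs_vals, list(A.disease_names), list(A.mirna_names), "basic")
        if cfg.use_spy:
            builder = self._spy_similarity_builder(A) if cfg.spy_recompute_gip else None
            AN = reliable_negatives(
                A, SD, SR, cfg.spy, cfg.rls, similarity_builder=builder
            )
            FSpy = spy_score(AN, SD, SR, cfg.rls)
        else:
            AN = LabeledMatrix(A.values.copy(), list(A.disease_names), list(A.mirna_names))
            FSpy = ScoreMatrix(fs_vals.copy(), list(A.disease_names), list(A.mirna_names), "spy")
        if cfg.use_supercluster:
            d_part, _ = ward_cluster(SD, cfg.cluster)
            m_part, _ = ward_cluster(SR, cfg.cluster)
            SA = build_super_associations(
                A, d_part, m_part, SD, SR, cfg.cluster, apply_filter=cfg.knn_filter
            )
            sup = super_scores(SD, SR, SA, cfg.rls)
            ts_vals = two_layer_values(
                FSpy.values, sup, SA, A.disease_names, A.mirna_names
            )
        else:
            SA, sup = None, None
            ts_vals = FSpy.values.copy()
        TS = ScoreMatrix(ts_vals, list(A.disease_names), list(A.mirna_names), "two_layer")
        return SSCMDAResult(SD, SR, FS, AN, FSpy, SA, sup, TS)

    def score(self, A: AssociationMatrix) -> ScoreMatrix:
        """Final two-layer score matrix TS."""
        return self.run(A).TS

    def make_scorer(self, template: AssociationMatrix, recompute_gip: bool = True):
        """A fast callable ``A_values -> TS_values`` for cross-validation.

        Semantic similarity and functional miRNA similarity do not depend on
        the association labels and are prepared once.  With
        ``recompute_gip=False`` the GIP kernels of the *template* matrix are
        reused for every perturbed matrix (faster, slightly leaky).
        """
        cfg = self.config
        cached: dict = {}
        if not recompute_gip:
            cached["sims"] = self.integrated_similarities(template)
        # pre-resolve semantic matrices once; integrate per call
        sem = None
        if self.dags is not None:
            annotated = [d for d in template.disease_names if d in self.dags]
            if annotated:
                sem = (
                    semantic_similarity_m1(self.dags, cfg.semantic, annotated),
                    semantic_similarity_m2(self.dags, cfg.semantic, annotated),
                )
        d_names = list(template.disease_names)
        m_names = list(template.mirna_names)

        def scorer(values: np.ndarray) -> np.ndarray:
            A = AssociationMatrix(values, d_names, m_names)
            if "sims" in cached:
                SD, SR = cached["sims"]
            else:
                gd = SimilarityMatrix(
                    gip_kernel(A.values.astype(float), cfg.beta_prime_d), d_names, kind="gip"
                )
                gr = SimilarityMatrix(
                    gip_kernel(A.values.T.astype(float), cfg.beta_prime_m), m_names, kind="gip"
                )
                SD = (
                    integrate_disease(sem[0], sem[1], gd)
                    if sem is not None
                    else SimilarityMatrix(gd.values, gd.names, kind="integrated")
                )
                SR = (
                    integrate_mirna(self.mirna_sim, gr)
                    if self.mirna_sim is not None
                    else SimilarityMatrix(gr.values, gr.names, kind="integrated")
                )
            Hd = hat_matrix(SD.values, cfg.lambda_d, check_condition=False)
            Hr = hat_matrix(SR.values, cfg.lambda_r, check_condition=False)
            if cfg.use_spy:
                builder = (
                    self._spy_similarity_builder(A) if cfg.spy_recompute_gip else None
                )
                AN = reliable_negatives(
                    A, SD, SR, cfg.spy, cfg.rls, similarity_builder=builder
                )
                labels = AN.values.astype(float)
            else:
                labels = A.values.astype(float)
            fspy = (Hd.T @ labels + labels @ Hr) / 2.0
            if not cfg.use_supercluster:
                return fspy
            d_part, _ = ward_cluster(SD, cfg.cluster)
            m_part, _ = ward_cluster(SR, cfg.cluster)
            SA = build_super_associations(
                A, d_part, m_part, SD, SR, cfg.cluster, apply_filter=cfg.knn_filter
            )
            sup = super_scores(SD, SR, SA, cfg.rls)
            return two_layer_values(fspy, sup, SA, d_names, m_names)

        return scorer
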