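"""Synthetic benchmark instances with planted ground truth.

The generator emulates the three real inputs — a MeSH-style disease DAG
forest, a MISIM-style miRNA functional similarity matrix and an HMDD-style
association list — under the method's own working assumption: diseases and
miRNAs fall into latent blocks, similar entities share a block, and
associations are far more likely within a block than across.  A configurable
fraction of the true positives is hidden from the observed matrix; those
hidden cells are the recoverable "potential associations" that evaluation
protocols and the spy strategy are measured against.

What it deliberately does not mimic: the heavy-tailed degree distribution of
real HMDD annotations, partial DAG annotation coverage, or correlated noise
between the similarity sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import (
    AssociationMatrix,
    DiseaseDAGSet,
    SimilarityMatrix,
    write_associations,
    write_dag_edges,
    write_similarity,
)

__all__ = ["SynthConfig", "SynthInstance", "generate_dag_forest",
           "generate_mirna_similarity", "generate_associations", "generate_instance"]


@dataclass
class SynthConfig:
    """Generator settings (defaults are the desk-scale benchmark conditions)."""

    n_diseases: int = 30
    n_mirnas: int = 40
    n_blocks: int = 3
    within_block_assoc_prob: float = 0.6
    cross_block_assoc_prob: float = 0.05
    hide_fraction: float = 0.3
    dag_depth: int = 3
    dag_branching: int = 2
    noise_sd: float = 0.05
    within_block_sim: float = 0.8
    cross_block_sim: float = 0.2
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_diseases < 2 or self.n_mirnas < 2:
            raise ValueError("need at least 2 diseases and 2 miRNAs")
        for p in (self.within_block_assoc_prob, self.cross_block_assoc_prob,
                  self.hide_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.within_block_assoc_prob <= self.cross_block_assoc_prob:
            raise ValueError("within-block association probability must exceed cross-block")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass
class SynthInstance:
    """One generated benchmark with its ground truth."""

    associations: AssociationMatrix  # observed (hidden positives removed)
    truth: np.ndarray  # full ground-truth binary matrix
    hidden: list[tuple[int, int]]  # true positives absent from the observed matrix
    dags: DiseaseDAGSet
    mirna_sim: SimilarityMatrix
    disease_blocks: np.ndarray
    mirna_blocks: np.ndarray


def _disease_names(cfg: SynthConfig) -> list[str]:
    return [f"disease{i:03d}" for i in range(cfg.n_diseases)]


def _mirna_names(cfg: SynthConfig) -> list[str]:
    return [f"mirna{j:03d}" for j in range(cfg.n_mirnas)]


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    return np.arange(n) % n_blocks


def generate_dag_forest(cfg: SynthConfig) -> DiseaseDAGSet:
    """A DAG forest of ``n_blocks`` subtrees; same-block diseases share a subtree.

    Each block gets an internal tree of the requested depth and branching;
    every disease of the block attaches below a uniformly chosen internal
    node, so semantic similarity is high within a block and zero across
    blocks.  With ``dag_depth=0`` every disease is an isolated root.
    """
    rng = np.random.default_rng((cfg.seed, 101))
    diseases = _disease_names(cfg)
    blocks = _blocks(cfg.n_diseases, cfg.n_blocks)
    edges: list[tuple[str, str]] = []
    internal_by_block: list[list[str]] = []
    for b in range(cfg.n_blocks):
        nodes = []
        if cfg.dag_depth > 0:
            root = f"term_b{b}_l0_0"
            nodes.append(root)
            prev_level = [root]
            for level in range(1, cfg.dag_depth):
                this_level = []
                for idx in range(len(prev_level) * cfg.dag_branching):
                    name = f"term_b{b}_l{level}_{idx}"
                    parent = prev_level[idx // cfg.dag_branching]
                    edges.append((name, parent))
                    this_level.append(name)
                    nodes.append(name)
                prev_level = this_level
        internal_by_block.append(nodes)
    for i, d in enumerate(diseases):
        nodes = internal_by_block[blocks[i]]
        if nodes:
            attach = nodes[int(rng.integers(len(nodes)))]
            edges.append((d, attach))
    vocab = set(diseases) | {t for e in edges for t in e}
    return DiseaseDAGSet(edges, vocab, diseases=diseases)


def generate_mirna_similarity(cfg: SynthConfig) -> SimilarityMatrix:
    """Block-structured functional similarity with truncated symmetric noise."""
    rng = np.random.default_rng((cfg.seed, 202))
    blocks = _blocks(cfg.n_mirnas, cfg.n_blocks)
    same = blocks[:, None] == blocks[None, :]
    values = np.where(same, cfg.within_block_sim, cfg.cross_block_sim).astype(float)
    if cfg.noise_sd > 0:
        noise = rng.normal(0.0, cfg.noise_sd, size=values.shape)
        noise = (noise + noise.T) / 2.0
        values = values + noise
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, _mirna_names(cfg), kind="functional")


def generate_associations(cfg: SynthConfig) -> tuple[AssociationMatrix, np.ndarray, list[tuple[int, int]]]:
    """Planted-block associations: (observed matrix, truth matrix, hidden pairs).

    Ground-truth cells are Bernoulli with the within- or cross-block
    probability; a ``hide_fraction`` of the true positives is removed from
    the observed matrix (recoverable potential associations).  An all-zero
    observed matrix triggers regeneration, at most 10 attempts.
    """
    d_blocks = _blocks(cfg.n_diseases, cfg.n_blocks)
    m_blocks = _blocks(cfg.n_mirnas, cfg.n_blocks)
    same = d_blocks[:, None] == m_blocks[None, :]
    probs = np.where(same, cfg.within_block_assoc_prob, cfg.cross_block_assoc_prob)
    for attempt in range(10):
        rng = np.random.default_rng((cfg.seed, 303, attempt))
        truth = (rng.random(probs.shape) < probs).astype(np.int8)
        pos = np.argwhere(truth == 1)
        n_hide = round(cfg.hide_fraction * len(pos))
        hidden_idx = rng.choice(len(pos), size=n_hide, replace=False) if n_hide else []
        observed = truth.copy()
        hidden = [tuple(pos[h]) for h in hidden_idx]
        for i, j in hidden:
            observed[i, j] = 0
        if observed.any():
            A = AssociationMatrix(observed, _disease_names(cfg), _mirna_names(cfg))
            return A, truth, hidden
    raise ValueError("failed to generate a nonempty observed matrix in 10 attempts")


def generate_instance(cfg: SynthConfig | None = None) -> SynthInstance:
    """Generate the full benchmark: DAG forest, similarity, associations."""
    cfg = cfg or SynthConfig()
    A, truth, hidden = generate_associations(cfg)
    return SynthInstance(
        associations=A,
        truth=truth,
        hidden=hidden,
        dags=generate_dag_forest(cfg),
        mirna_sim=generate_mirna_similarity(cfg),
        disease_blocks=_blocks(cfg.n_diseases, cfg.n_blocks),
        mirna_blocks=_blocks(cfg.n_mirnas, cfg.n_blocks),
    )


def write_instance(instance: SynthInstance, out_dir: str | Path) -> None:
    """Write assoc.tsv, mirna_sim.tsv, dag.tsv and truth.tsv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_associations(instance.associations, out / "assoc.tsv")
    write_similarity(instance.mirna_sim, out / "mirna_sim.tsv")
    write_dag_edges(instance.dags, out / "dag.tsv")
    truth_assoc = AssociationMatrix(
        instance.truth,
        list(instance.associations.disease_names),
        list(instance.associations.mirna_names),
    )
    write_associations(truth_assoc, out / "truth.tsv")
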