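"""Core containers and plain-text IO for miRNA-disease association data.

The whole package shares one orientation convention: association and score
matrices have diseases on the rows and miRNAs on the columns (``A`` is
``nd x nm``).  Entity names are normalized on input (lowercase, trimmed,
internal whitespace collapsed) because the upstream databases (HMDD, MISIM,
MeSH) disagree on casing and spacing; pass ``normalize=False`` to any reader
to keep names verbatim.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "LabeledMatrix",
    "DiseaseDAGSet",
    "SimilarityMatrix",
    "ScoreMatrix",
    "CycleError",
    "ParseError",
    "normalize_name",
    "read_associations",
    "write_associations",
    "read_dag_edges",
    "read_similarity",
    "write_similarity",
    "write_scores",
    "write_labels",
]

_WS = re.compile(r"\s+")

SIM_KINDS = ("semantic1", "semantic2", "functional", "gip", "integrated")
#: kinds whose diagonal is contractually 1
_UNIT_DIAG_KINDS = ("functional", "gip", "integrated")


class ParseError(ValueError):
    """Malformed input file (message carries the offending line number)."""


class CycleError(ValueError):
    """The child->parent edge list contains a directed cycle."""


def normalize_name(name: str) -> str:
    """Canonical entity name: lowercase, trimmed, internal whitespace collapsed.

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    """
    return _WS.sub(" ", name.strip()).lower()


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        seen, dup = set(), None
        for n in names:
            if n in seen:
                dup = n
                break
            seen.add(n)
        raise ValueError(f"duplicate {what} name after normalization: {dup!r}")


@dataclass
class AssociationMatrix:
    """Binary disease x miRNA adjacency matrix with name indices."""

    values: np.ndarray
    disease_names: list[str]
    mirna_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if self.values.shape != (len(self.disease_names), len(self.mirna_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.disease_names)} diseases x {len(self.mirna_names)} miRNAs"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association entries must be 0 or 1")
        _check_unique(self.disease_names, "disease")
        _check_unique(self.mirna_names, "miRNA")
        self.values = self.values.astype(np.int8)

    @property
    def nd(self) -> int:
        return self.values.shape[0]

    @property
    def nm(self) -> int:
        return self.values.shape[1]

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) with A[i, j] = 1, in row-major order."""
        return [tuple(p) for p in np.argwhere(self.values == 1)]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.disease_names), list(self.mirna_names)
        )


@dataclass
class LabeledMatrix:
    """Ternary label matrix: +1 known positive, -1 reliable negative, 0 unlabeled."""

    values: np.ndarray
    disease_names: list[str]
    mirna_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.disease_names), len(self.mirna_names)):
            raise ValueError("label matrix shape does not match name indices")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("labels must be in {-1, 0, +1}")
        self.values = self.values.astype(np.int8)

    def check_consistent(self, source: AssociationMatrix) -> None:
        """Every +1 label must be a known 1 of the source adjacency."""
        if (self.values == 1).astype(np.int8).__and__(1 - source.values).any():
            raise ValueError("a +1 label does not correspond to a known association")


@dataclass
class SimilarityMatrix:
    """Square symmetric nonnegative similarity matrix over named entities."""

    values: np.ndarray
    names: list[str]
    kind: str = "functional"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SIM_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if self.values.shape != (len(self.names), len(self.names)):
            raise ValueError("similarity matrix must be square over its names")
        _check_unique(self.names, "entity")

    def validate(self, tol: float = 1e-10) -> None:
        if np.abs(self.values - self.values.T).max(initial=0.0) > tol:
            raise ValueError("similarity matrix is not symmetric")
        if (self.values < -tol).any():
            raise ValueError("similarity matrix has negative entries")
        if self.kind in _UNIT_DIAG_KINDS:
            if np.abs(np.diag(self.values) - 1.0).max(initial=0.0) > tol:
                raise ValueError(f"kind={self.kind} requires a unit diagonal")

    @property
    def n(self) -> int:
        return len(self.names)

    def index_of(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}


@dataclass
class ScoreMatrix:
    """Real-valued disease x miRNA score matrix with a provenance tag."""

    values: np.ndarray
    disease_names: list[str]
    mirna_names: list[str]
    provenance: str = "basic"  # basic | spy | super | two_layer

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.disease_names), len(self.mirna_names)):
            raise ValueError("score matrix shape does not match name indices")
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite entries")


@dataclass
class DiseaseDAGSet:
    """Per-disease directed acyclic graphs over a shared term vocabulary.

    Edges run child -> parent.  ``T(D)`` (``ancestors``) is D plus everything
    reachable through parent edges; each disease's DAG is the subgraph induced
    on ``T(D)``.  ``diseases`` lists the terms that count as diseases when
    tallying "number of DAGs containing a term" (all vocabulary terms unless
    narrowed).
    """

    edges: list[tuple[str, str]]
    vocabulary: set[str]
    diseases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = [tuple(e) for e in self.edges]
        for child, parent in self.edges:
            self.vocabulary.add(child)
            self.vocabulary.add(parent)
        if not self.diseases:
            self.diseases = sorted(self.vocabulary)
        unknown = set(self.diseases) - self.vocabulary
        if unknown:
            raise ValueError(f"diseases not in vocabulary: {sorted(unknown)[:5]}")
        g = nx.DiGraph()
        g.add_nodes_from(self.vocabulary)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise CycleError(f"cycle detected in parent relation: {path}")
        self._graph = g
        self._ancestors: dict[str, frozenset[str]] = {}

    @property
    def roots(self) -> set[str]:
        return {t for t in self.vocabulary if self._graph.out_degree(t) == 0}

    def ancestors(self, term: str) -> frozenset[str]:
        """T(D): the term itself plus all transitive parents."""
        if term not in self.vocabulary:
            raise KeyError(f"unknown term {term!r}")
        cached = self._ancestors.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term)) | {term}
            self._ancestors[term] = cached
        return cached

    def parents(self, term: str) -> set[str]:
        return set(self._graph.successors(term))

    def children_within(self, term: str, members: frozenset[str]) -> set[str]:
        """Children of ``term`` restricted to a node set (one disease's DAG)."""
        return {c for c in self._graph.predecessors(term) if c in members}

    def __contains__(self, term: str) -> bool:
        return term in self.vocabulary


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _maybe_norm(name: str, normalize: bool) -> str:
    return normalize_name(name) if normalize else name.strip()


def read_associations(path: str | Path, normalize: bool = True) -> AssociationMatrix:
    """Read a 2-column TSV of (disease, miRNA) pairs into a binary matrix.

    A first line reading ``disease<TAB>mirna`` is treated as a header.
    Duplicate pairs collapse to a single 1.  Name order follows first
    appearance in the file.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 2 tab-separated fields, got {len(row)}"
                )
            d, m = (_maybe_norm(row[0], normalize), _maybe_norm(row[1], normalize))
            if not d or not m:
                raise ParseError(f"{path.name}:{lineno}: empty field")
            if lineno == 1 and (d, m) == ("disease", "mirna"):
                continue
            pairs.append((d, m))
    if not pairs:
        raise ParseError(f"{path.name}: no association pairs found")
    diseases: dict[str, int] = {}
    mirnas: dict[str, int] = {}
    for d, m in pairs:
        diseases.setdefault(d, len(diseases))
        mirnas.setdefault(m, len(mirnas))
    values = np.zeros((len(diseases), len(mirnas)), dtype=np.int8)
    for d, m in pairs:
        values[diseases[d], mirnas[m]] = 1
    return AssociationMatrix(values, list(diseases), list(mirnas))


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the positive pairs of an association matrix as a 2-column TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["disease", "mirna"])
        for i, j in assoc.positive_pairs():
            writer.writerow([assoc.disease_names[i], assoc.mirna_names[j]])


def read_dag_edges(
    path: str | Path,
    vocabulary: Iterable[str] | None = None,
    normalize: bool = True,
) -> DiseaseDAGSet:
    """Read a child->parent edge list TSV into a :class:`DiseaseDAGSet`.

    Terms may have several parents (DAG, not tree); a directed cycle raises
    :class:`CycleError` naming one offending cycle.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 2 tab-separated fields, got {len(row)}"
                )
            c, p = (_maybe_norm(row[0], normalize), _maybe_norm(row[1], normalize))
            if lineno == 1 and (c, p) == ("child", "parent"):
                continue
            edges.append((c, p))
    vocab = set(_maybe_norm(v, normalize) for v in vocabulary) if vocabulary else set()
    return DiseaseDAGSet(edges, vocab)


def write_dag_edges(dags: DiseaseDAGSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["child", "parent"])
        for child, parent in dags.edges:
            writer.writerow([child, parent])


def read_similarity(
    path: str | Path,
    kind: str = "functional",
    normalize: bool = True,
    asym_tol: float = 1e-8,
) -> SimilarityMatrix:
    """Read a square TSV (first row and column are names) as a similarity matrix.

    Asymmetry up to ``asym_tol`` is repaired by averaging ``(M + M.T) / 2``;
    anything larger is treated as data corruption and rejected.  The diagonal
    is forced to 1 for ``kind="functional"``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = [_maybe_norm(str(r), normalize) for r in df.index]
    cols = [_maybe_norm(str(c), normalize) for c in df.columns]
    if rows != cols:
        raise ValueError("row and column names of similarity matrix do not match")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("similarity matrix is not square")
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > asym_tol:
        raise ValueError(f"similarity matrix asymmetry {asym:.3g} exceeds tolerance {asym_tol:.0e}")
    values = (values + values.T) / 2.0
    if kind == "functional":
        np.fill_diagonal(values, 1.0)
    sim = SimilarityMatrix(values, rows, kind=kind)
    sim.validate()
    return sim


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.names, columns=sim.names).to_csv(path, sep="\t")


def write_labels(labels: LabeledMatrix, path: str | Path) -> None:
    """Export nonzero labels as a 3-column TSV (disease, mirna, label)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["disease", "mirna", "label"])
        for i, j in np.argwhere(labels.values != 0):
            writer.writerow(
                [labels.disease_names[i], labels.mirna_names[j], int(labels.values[i, j])]
            )


def write_scores(
    scores: ScoreMatrix, known: AssociationMatrix, path: str | Path
) -> pd.DataFrame:
    """Write candidate (unknown) pairs ranked by descending score.

    Only pairs with ``known == 0`` are emitted.  Ties are broken by
    (disease name, miRNA name); ranks are ordinal after that stable sort.
    Returns the emitted table as a DataFrame for convenience.
    """
    if scores.values.shape != known.values.shape:
        raise ValueError("score and association matrices have different shapes")
    if scores.disease_names != known.disease_names or scores.mirna_names != known.mirna_names:
        raise ValueError("score and association name indices differ")
    rows = [
        (scores.disease_names[i], scores.mirna_names[j], scores.values[i, j])
        for i, j in np.argwhere(known.values == 0)
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    table = pd.DataFrame(rows, columns=["disease", "mirna", "score"])
    table["rank"] = np.arange(1, len(table) + 1)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["disease", "mirna", "score", "rank"])
        for d, m, s, r in table.itertuples(index=False):
            writer.writerow([d, m, f"{s:.6g}", r])
    return table
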