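import numpy as np
import pytest

from sscmda.datamodel import AssociationMatrix, DiseaseDAGSet, SimilarityMatrix
from sscmda.pipeline import SSCMDAConfig, SSCMDAModel
from sscmda.simulate import SynthConfig, generate_instance


@pytest.fixture(scope="session")
def bench():
    """The default desk-scale synthetic benchmark (seed 1)."""
    return generate_instance(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def bench_model(bench):
    return SSCMDAModel(dags=bench.dags, mirna_sim=bench.mirna_sim, config=SSCMDAConfig(seed=1))


@pytest.fixture(scope="session")
def bench_sims(bench, bench_model):
    """Integrated SD, SR of the benchmark's observed association matrix."""
    return bench_model.integrated_similarities(bench.associations)


@pytest.fixture
def tiny_assoc():
    """2 diseases x 3 miRNAs with 3 known associations."""
    values = np.array([[1, 0, 1], [0, 1, 0]])
    return AssociationMatrix(values, ["d1", "d2"], ["m1", "m2", "m3"])


@pytest.fixture
def identity_sims():
    """Identity similarity on both sides of a 3x3 problem."""
    SD = SimilarityMatrix(np.eye(3), ["d1", "d2", "d3"], kind="integrated")
    SR = SimilarityMatrix(np.eye(3), ["m1", "m2", "m3"], kind="integrated")
    return SD, SR


@pytest.fixture
def chain_dags():
    """Single chain D -> p -> g."""
    return DiseaseDAGSet([("D", "p"), ("p", "g")], {"D", "p", "g"})


def random_dag_set(rng: np.random.Generator, n_terms: int = 8, p_edge: float = 0.4):
    """Random DAG over terms t0..t{n-1}: edges only from lower to higher index."""
    terms = [f"t{i}" for i in range(n_terms)]
    edges = []
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            if rng.random() < p_edge:
                edges.append((terms[i], terms[j]))
    return DiseaseDAGSet(edges, set(terms))
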