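import networkx as nx
import numpy as np
import pytest

from pathnet.io_formats import (
    ExpressionMatrix,
    OntologyDAG,
    PhenotypeVector,
)
from pathnet.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic study at the default conditions (planted signal 1.5 SD)."""
    return generate(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down conditions for fast pipeline-level tests."""
    return SyntheticSpec(
        n_genes=500,
        n_normal=30,
        n_tumor=30,
        n_pathways=20,
        pathway_size_range=(8, 15),
        n_planted=2,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate(small_spec)


@pytest.fixture()
def sibling_dag():
    """Root R with two is_a children A and B, all in BP."""
    g = nx.DiGraph()
    g.add_edge("A", "R", relation="is_a")
    g.add_edge("B", "R", relation="is_a")
    return OntologyDAG(g, {"R": "BP", "A": "BP", "B": "BP"})


@pytest.fixture()
def two_group_expr():
    """4 genes x 6 samples; gene g1 is [1,2,3] vs [4,5,6], g3 constant, g4
    zero-variance in both groups but with different means."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [0.1, -0.2, 0.05, 0.0, 0.15, -0.1],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            [1.0, 1.0, 1.0, 3.0, 3.0, 3.0],
        ]
    )
    expr = ExpressionMatrix(["g1", "g2", "g3", "g4"], [f"s{i}" for i in range(6)], values)
    pheno = PhenotypeVector(expr.sample_ids, np.array([1, 1, 1, 0, 0, 0]))
    return expr, pheno


def mi_bruteforce(a, c):
    """Independent joint-histogram MI oracle (bits): explicit count loops."""
    a = list(a)
    c = list(c)
    m = len(a)
    total = 0.0
    for x in set(a):
        for y in set(c):
            pxy = sum(1 for i in range(m) if a[i] == x and c[i] == y) / m
            px = sum(1 for v in a if v == x) / m
            py = sum(1 for v in c if v == y) / m
            if pxy > 0:
                total += pxy * np.log2(pxy / (px * py))
    return total


def generank_solve(ex_raw, w, d):
    """Direct linear-solve oracle: (I - d W^T D^-1) r = (1-d) ex."""
    ex = np.asarray(ex_raw, float)
    ex = ex / ex.sum()
    w = np.asarray(w, float)
    deg = w.sum(axis=1)
    inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
    n = ex.size
    a = np.eye(n) - d * (w.T * inv)
    return np.linalg.solve(a, (1 - d) * ex)
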