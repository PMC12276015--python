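"""Shared fixtures: the calibrated truth network, hand-built small networks,
and a seeded random-network factory for oracle-equivalence sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from haerisk import (
    CPT,
    Cohort,
    DagModel,
    DiscreteBN,
    FitConfig,
    NodeDef,
    default_ground_truth,
    default_model,
    fit_network,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dag() -> DagModel:
    return default_model()


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def fitted_441(truth):
    """A study-scale fitted network (n=441, alpha=1), reused across tests."""
    from haerisk import sample_cohort

    cohort = sample_cohort(truth, n=441, seed=11)
    return fit_network(cohort, truth.dag, FitConfig(alpha=1.0))


@pytest.fixture()
def chain_bn() -> DiscreteBN:
    """Hand-specified 3-node chain A -> B -> C with frozen CPTs.

    P(A)=(0.6,0.4); P(B=1|A)=(0.3,0.8); P(C=high|B)=(0.1,0.5).
    Hand-derived values used in tests: P(B=1)=0.5, P(C=high)=0.3,
    P(A=a1|C=high)=0.56.
    """
    dag = DagModel(
        nodes=(
            NodeDef("A", ("a0", "a1")),
            NodeDef("B", ("b0", "b1")),
            NodeDef("C", ("low", "high"), role="outcome"),
        ),
        edges=(("A", "B"), ("B", "C")),
    )
    cpts = {
        "A": CPT("A", (), np.array([0.6, 0.4])),
        "B": CPT("B", ("A",), np.array([[0.7, 0.3], [0.2, 0.8]])),
        "C": CPT("C", ("B",), np.array([[0.9, 0.1], [0.5, 0.5]])),
    }
    return DiscreteBN(dag=dag, cpts=cpts)


@pytest.fixture(scope="session")
def compact_truth() -> DiscreteBN:
    """A compact ground truth (22 CPT rows, every parent configuration with
    probability >= 0.03) where parameter recovery and Bayes-optimal scoring
    are attainable at simulation scale."""
    dag = DagModel(
        nodes=(
            NodeDef("X", ("x0", "x1", "x2")),
            NodeDef("Y", ("no", "yes")),
            NodeDef("Z", ("z0", "z1")),
            NodeDef("Out", ("low", "high"), role="outcome"),
        ),
        edges=(("X", "Y"), ("X", "Out"), ("Y", "Out"), ("Z", "Out")),
    )
    p_y = np.array([0.3, 0.5, 0.7])
    out_logit = (
        -0.4
        + np.array([-0.8, 0.1, 1.0])[:, None, None]
        + np.array([0.0, 1.2])[None, :, None]
        + np.array([-0.5, 0.6])[None, None, :]
    )
    p_high = 1.0 / (1.0 + np.exp(-out_logit))
    cpts = {
        "X": CPT("X", (), np.array([0.35, 0.4, 0.25])),
        "Y": CPT("Y", ("X",), np.stack([1 - p_y, p_y], axis=-1)),
        "Z": CPT("Z", (), np.array([0.55, 0.45])),
        "Out": CPT("Out", ("X", "Y", "Z"), np.stack([1 - p_high, p_high], axis=-1)),
    }
    return DiscreteBN(dag=dag, cpts=cpts)


def make_random_network(rng: np.random.Generator, max_nodes: int = 7) -> DiscreteBN:
    """Random small DAG (node i may only point at node j > i) with Dirichlet
    CPTs; the last node is the binary low/high outcome."""
    n = int(rng.integers(3, max_nodes + 1))
    nodes = []
    for i in range(n - 1):
        k = int(rng.integers(2, 4))
        nodes.append(NodeDef(f"N{i}", tuple(f"N{i}c{j}" for j in range(k))))
    nodes.append(NodeDef(f"N{n - 1}", ("low", "high"), role="outcome"))
    edges = []
    for j in range(1, n):
        parents = [i for i in range(j) if rng.random() < 0.5][:3]
        edges.extend((f"N{i}", f"N{j}") for i in parents)
    dag = DagModel(nodes=tuple(nodes), edges=tuple(edges))
    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node.name)
        shape = tuple(dag.node(p).cardinality for p in parents)
        k = node.cardinality
        rows = rng.dirichlet(np.ones(k), size=int(np.prod(shape, dtype=int)))
        cpts[node.name] = CPT(node.name, parents, rows.reshape(shape + (k,)))
    return DiscreteBN(dag=dag, cpts=cpts)


def make_random_evidence(rng: np.random.Generator, bn: DiscreteBN, query: str):
    """Random hard/soft evidence on a subset of non-query nodes."""
    from haerisk import Evidence, Hard, Soft

    entries = {}
    for node in bn.dag.nodes:
        if node.name == query or rng.random() < 0.5:
            continue
        if rng.random() < 0.5:
            entries[node.name] = Hard(node.categories[rng.integers(node.cardinality)])
        else:
            vec = rng.random(node.cardinality) + 0.05
            if rng.random() < 0.3:  # occasional zero entries
                vec[rng.integers(node.cardinality)] = 0.0
            if not vec.any():
                vec[0] = 1.0
            entries[node.name] = Soft(tuple(vec))
    return Evidence(entries)


@pytest.fixture()
def hand_cohort(dag) -> Cohort:
    """Four fixed records over the default schema (used for tally checks)."""
    base = {
        "Age": "40-64", "Race": "White", "Income": "Q3", "Payer": "Private",
        "Region": "South", "Hypertension": "no", "Autoimmune": "no",
        "Diabetes": "no", "Severity": "moderate", "MortalityRisk": "low",
    }
    rows = []
    for i in range(4):
        r = dict(base)
        if i == 1:
            r["MortalityRisk"] = "high"
            r["Severity"] = "major"
        if i == 3:
            r["Age"] = "≥65"
            r["Hypertension"] = "yes"
        rows.append(r)
    return Cohort(pd.DataFrame(rows), dag, {"source": "hand"})
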