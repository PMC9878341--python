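"""Shared fixtures: small hand-built networks, random-network generators,
and session-scoped heavyweight artifacts (ground-truth network, synthetic
cohorts) reused across test modules."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from prediabn.core import (
    CategoricalVariable,
    CohortTable,
    Cpt,
    Dag,
    DiscreteBayesianNetwork,
)


# ---------------------------------------------------------------------------
# Generators for random structures and networks


def random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.35) -> Dag:
    """Random DAG consistent with a random topological order."""
    names = [f"V{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    dag = Dag(names)
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < p_edge:
                dag.add_edge(names[order[a]], names[order[b]])
    return dag


def random_network(
    rng: np.random.Generator, n_nodes: int, max_card: int = 3, p_edge: float = 0.4
) -> DiscreteBayesianNetwork:
    """Random discrete BN with Dirichlet(1) CPT rows."""
    dag = random_dag(rng, n_nodes, p_edge)
    variables = []
    by_name = {}
    for name in dag.nodes:
        card = int(rng.integers(2, max_card + 1))
        v = CategoricalVariable(name, tuple(f"s{k}" for k in range(card)))
        variables.append(v)
        by_name[name] = v
    cpts = {}
    for v in variables:
        parents = dag.parents(v.name)
        pstates = [by_name[p].states for p in parents]
        q = int(np.prod([len(s) for s in pstates])) if parents else 1
        table = rng.dirichlet(np.ones(v.cardinality), size=q)
        cpts[v.name] = Cpt(v.name, v.states, parents, pstates, table)
    return DiscreteBayesianNetwork(variables, dag, cpts)


def enumerate_assignments(bn: DiscreteBayesianNetwork):
    """All full assignments as dicts (for brute-force oracles)."""
    names = bn.names
    state_lists = [bn.states(n) for n in names]
    for combo in itertools.product(*state_lists):
        yield dict(zip(names, combo))


# ---------------------------------------------------------------------------
# Small hand-built fixtures


@pytest.fixture
def chain_ab() -> DiscreteBayesianNetwork:
    """A -> B with a strong dependence (0.9 / 0.1)."""
    a = CategoricalVariable("A", ("a1", "a2"))
    b = CategoricalVariable("B", ("b1", "b2"))
    dag = Dag(["A", "B"], [("A", "B")])
    cpts = {
        "A": Cpt("A", a.states, (), (), np.array([[0.5, 0.5]])),
        "B": Cpt("B", b.states, ("A",), (a.states,), np.array([[0.9, 0.1], [0.1, 0.9]])),
    }
    return DiscreteBayesianNetwork([a, b], dag, cpts)


@pytest.fixture(scope="session")
def ground_truth():
    from prediabn.cohort import ground_truth_network

    return ground_truth_network()


@pytest.fixture(scope="session")
def cohort_16k():
    """One synthetic cohort at the study's sample size (seeded)."""
    from prediabn.cohort import generate_cohort

    return generate_cohort(16_648, seed=20_230_112)


@pytest.fixture(scope="session")
def cohort_200k():
    from prediabn.cohort import generate_cohort

    return generate_cohort(200_000, seed=42)
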