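"""Core containers, graph operations and the chain-rule primitives."""

import itertools
import math

import numpy as np
import pytest

from prediabn.cohort import reference_dag, study_variables
from prediabn.core import (
    CategoricalVariable,
    DiscreteBayesianNetwork,
    CohortTable,
    Cpt,
    Dag,
    d_separated,
    markov_blanket,
)
from prediabn.errors import InputError
from prediabn.examples import example_network

from conftest import enumerate_assignments, random_dag, random_network


# ---------------------------------------------------------------------------
# Variables and the study domain


class TestStudyVariables:
    def test_twelve_variables_with_expected_states(self):
        variables = study_variables()
        assert len(variables) == 12
        by_name = {v.name: v for v in variables}
        assert by_name["GENDER"].states == ("Men", "Women")
        assert by_name["T2D"].states == ("Yes", "No")
        assert by_name["FLI"].states == ("Less 30", "30–60", "More 60")
        assert by_name["BMI"].states == (
            "Underweight",
            "Normal weight",
            "Overweight",
            "Obesity",
        )
        assert by_name["AGE"].states == ("18-32", "33-47", "48-62")

    def test_total_state_count(self):
        assert sum(v.cardinality for v in study_variables()) == 33

    @pytest.mark.parametrize(
        "states", [(), ("only",), ("a", "a")], ids=["empty", "single", "duplicate"]
    )
    def test_invalid_state_sets_rejected(self, states):
        with pytest.raises(InputError):
            CategoricalVariable("X", states)


# ---------------------------------------------------------------------------
# DAG invariants


class TestDag:
    def test_rejects_cycles_self_loops_duplicates(self):
        dag = Dag(["A", "B", "C"], [("A", "B"), ("B", "C")])
        with pytest.raises(InputError):
            dag.add_edge("C", "A")
        with pytest.raises(InputError):
            dag.add_edge("A", "A")
        with pytest.raises(InputError):
            dag.add_edge("A", "B")
        with pytest.raises(InputError):
            Dag(["A", "A"])

    def test_topological_order_respects_edges_and_declaration(self):
        dag = Dag(["C", "B", "A"], [("A", "B")])
        order = dag.topological_order()
        assert order.index("A") < order.index("B")
        assert order[0] == "C"  # root ties broken by declaration order

    def test_parents_in_declaration_order(self):
        dag = Dag(["X", "Y", "Z"], [("Z", "Y"), ("X", "Y")])
        assert dag.parents("Y") == ("X", "Z")


# ---------------------------------------------------------------------------
# Markov blanket


class TestMarkovBlanket:
    def test_t2d_blanket_in_reference_structure(self):
        blanket = markov_blanket(reference_dag(), "T2D")
        assert blanket == {"PA", "AGE", "BMI", "FLI", "HbA1c"}

    def test_isolated_node_has_empty_blanket(self):
        assert markov_blanket(Dag(["A", "B"]), "A") == set()

    def test_unknown_node_error_names_it(self):
        with pytest.raises(InputError, match="NOPE"):
            markov_blanket(Dag(["A"]), "NOPE")

    def test_blanket_dseparates_rest_on_random_dags(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            dag = random_dag(rng, 8)
            for node in dag.nodes:
                blanket = markov_blanket(dag, node)
                outside = set(dag.nodes) - blanket - {node}
                for other in outside:
                    assert d_separated(dag, node, other, blanket)


# ---------------------------------------------------------------------------
# d-separation


def _oracle_d_separated(dag: Dag, x: str, y: str, z: frozenset) -> bool:
    """Brute force: enumerate all simple undirected paths, apply blocking."""

    def neighbours(n):
        return set(dag.parents(n)) | set(dag.children(n))

    def blocked(path):
        for i in range(1, len(path) - 1):
            prev, node, nxt = path[i - 1], path[i], path[i + 1]
            collider = dag.has_edge(prev, node) and dag.has_edge(nxt, node)
            if collider:
                if node not in z and not (dag.descendants(node) & z):
                    return True
            elif node in z:
                return True
        return False

    stack = [[x]]
    while stack:
        path = stack.pop()
        if path[-1] == y:
            if len(path) > 1 and not blocked(path):
                return False
            continue
        for nb in neighbours(path[-1]):
            if nb not in path:
                stack.append(path + [nb])
    return True


class TestDSeparation:
    def test_four_node_example_pa_vs_t2d(self):
        dag = Dag(
            ["AGE", "PA", "DIET", "T2D"],
            [("AGE", "PA"), ("PA", "DIET"), ("DIET", "T2D"), ("AGE", "T2D")],
        )
        assert d_separated(dag, "PA", "T2D", {"DIET", "AGE"})
        assert not d_separated(dag, "PA", "T2D", {"AGE"})

    def test_disconnected_nodes_are_separated(self):
        assert d_separated(Dag(["A", "B"]), "A", "B", set())

    def test_collider_opens_path(self):
        dag = Dag(["X", "Z", "Y", "D"], [("X", "Z"), ("Y", "Z"), ("Z", "D")])
        assert d_separated(dag, "X", "Y", set())
        assert not d_separated(dag, "X", "Y", {"Z"})
        assert not d_separated(dag, "X", "Y", {"D"})  # descendant of collider

    def test_agrees_with_path_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n = int(rng.integers(4, 8))
            dag = random_dag(rng, n, p_edge=0.4)
            nodes = list(dag.nodes)
            for x, y in itertools.combinations(nodes, 2):
                rest = [v for v in nodes if v not in (x, y)]
                zsets = [frozenset(), frozenset(rest)]
                for _ in range(4):
                    take = rng.random(len(rest)) < 0.4
                    zsets.append(frozenset(np.array(rest)[take].tolist()))
                for z in zsets:
                    assert d_separated(dag, x, y, z) == _oracle_d_separated(dag, x, y, z)

    def test_symmetric_in_x_and_y(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            dag = random_dag(rng, 6)
            nodes = list(dag.nodes)
            x, y = nodes[0], nodes[1]
            z = frozenset(nodes[3:5])
            assert d_separated(dag, x, y, z) == d_separated(dag, y, x, z)

    def test_rejects_degenerate_queries(self):
        dag = Dag(["A", "B"])
        with pytest.raises(InputError):
            d_separated(dag, "A", "A", set())
        with pytest.raises(InputError):
            d_separated(dag, "A", "B", {"A"})


# ---------------------------------------------------------------------------
# Chain rule, sampling, likelihood


class TestJointProbability:
    def test_worked_example_product(self):
        bn = example_network(0)
        expected = 0.1281 * 0.3727 * 0.8563 * 0.7625
        got = bn.joint_probability({"AGE": "18-32", "PA": "No", "DIET": "No", "T2D": "No"})
        assert got == pytest.approx(expected, abs=1e-12)

    def test_full_assignments_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            bn = random_network(rng, 4)
            total = sum(bn.joint_probability(a) for a in enumerate_assignments(bn))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_single_binary_node(self):
        v = CategoricalVariable("X", ("yes", "no"))
        bn_single = DiscreteBayesianNetwork(
            [v], Dag(["X"]), {"X": Cpt("X", v.states, (), (), np.array([[0.3, 0.7]]))}
        )
        assert bn_single.joint_probability({"X": "yes"}) == pytest.approx(0.3)

    def test_partial_assignment_rejected(self):
        bn = example_network(0)
        with pytest.raises(InputError):
            bn.joint_probability({"AGE": "18-32"})


class TestForwardSample:
    def test_deterministic_cpts_give_constant_records(self):
        a = CategoricalVariable("A", ("x", "y"))
        b = CategoricalVariable("B", ("u", "v"))
        dag = Dag(["A", "B"], [("A", "B")])
        bn = DiscreteBayesianNetwork(
            [a, b],
            dag,
            {
                "A": Cpt("A", a.states, (), (), np.array([[1.0, 0.0]])),
                "B": Cpt("B", b.states, ("A",), (a.states,), np.array([[0.0, 1.0], [1.0, 0.0]])),
            },
        )
        table = bn.forward_sample(50, seed=1)
        assert (table.frame["A"] == "x").all()
        assert (table.frame["B"] == "v").all()

    def test_reproducible_under_seed(self):
        bn = example_network(0)
        t1 = bn.forward_sample(500, seed=9)
        t2 = bn.forward_sample(500, seed=9)
        assert t1.frame.equals(t2.frame)

    def test_marginal_frequency_matches_root_probability(self):
        bn = example_network(0)
        n = 100_000
        table = bn.forward_sample(n, seed=123)
        freq = (table.frame["AGE"] == "18-32").mean()
        se = math.sqrt(0.1281 * (1 - 0.1281) / n)
        assert abs(freq - 0.1281) < 3 * se

    def test_joint_frequencies_consistent_chi_square(self):
        from scipy import stats

        rng = np.random.default_rng(17)
        bn = random_network(rng, 3, max_card=2, p_edge=0.6)
        n = 100_000
        table = bn.forward_sample(n, seed=2024)
        assignments = list(enumerate_assignments(bn))
        expected = np.array([bn.joint_probability(a) for a in assignments]) * n
        key = table.frame[list(bn.names)].agg("|".join, axis=1)
        labels = ["|".join(a[c] for c in bn.names) for a in assignments]
        observed = key.value_counts().reindex(labels).fillna(0.0).to_numpy()
        keep = expected > 5
        stat = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(stat, keep.sum() - 1)
        assert pval > 0.001


class TestLogLikelihood:
    def test_single_record_equals_log_joint(self):
        bn = example_network(0)
        table = bn.forward_sample(1, seed=4)
        rec = table.frame.iloc[0].to_dict()
        assert bn.log_likelihood(table) == pytest.approx(
            math.log(bn.joint_probability(rec)), abs=1e-12
        )

    def test_decomposes_into_family_terms(self):
        rng = np.random.default_rng(31)
        bn = random_network(rng, 5)
        data = bn.forward_sample(200, seed=8)
        total = 0.0
        codes = data.encoded(bn.names)
        col = {n: j for j, n in enumerate(bn.names)}
        for name in bn.names:
            cpt = bn.cpts[name]
            for i in range(data.n):
                assignment = {p: data.frame.iloc[i][p] for p in cpt.parent_order}
                row = cpt.table[cpt.row_index(assignment)]
                total += math.log(row[codes[i, col[name]]])
        assert bn.log_likelihood(data) == pytest.approx(total, rel=1e-10)

    def test_zero_probability_record_gives_neg_inf(self):
        a = CategoricalVariable("A", ("x", "y"))
        bn = DiscreteBayesianNetwork(
            [a], Dag(["A"]), {"A": Cpt("A", a.states, (), (), np.array([[1.0, 0.0]]))}
        )
        import pandas as pd

        data = CohortTable(pd.DataFrame({"A": ["y"]}), {"A": a.states})
        assert bn.log_likelihood(data) == float("-inf")

    def test_average_loglik_approaches_negative_entropy(self):
        from prediabn.inference import joint_entropy

        rng = np.random.default_rng(77)
        bn = random_network(rng, 3, max_card=3, p_edge=0.5)
        data = bn.forward_sample(60_000, seed=12)
        per_record = -bn.log_likelihood(data) / data.n
        assert per_record == pytest.approx(joint_entropy(bn), abs=0.03)


# ---------------------------------------------------------------------------
# Cohort table


class TestCohortTable:
    def test_rejects_out_of_domain_cells(self):
        import pandas as pd

        with pytest.raises(InputError, match="domain"):
            CohortTable(pd.DataFrame({"A": ["x", "zzz"]}), {"A": ("x", "y")})

    def test_missing_marker_allowed_but_encoding_rejects_it(self):
        import pandas as pd

        table = CohortTable(pd.DataFrame({"A": ["x", ""]}), {"A": ("x", "y")})
        assert table.has_missing()
        with pytest.raises(InputError, match="complete"):
            table.encoded()

    def test_csv_round_trip_preserves_cells(self, tmp_path, ground_truth):
        table = ground_truth.forward_sample(200, seed=6)
        path = tmp_path / "cohort.csv"
        table.write_csv(path)
        back = CohortTable.read_csv(path, ground_truth.variables)
        assert back.frame.equals(table.frame)
        assert back.domains == table.domains
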