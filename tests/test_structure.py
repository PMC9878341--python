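"""Blacklists, AIC scoring, hill climbing and bootstrap model averaging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from prediabn.cohort import study_blocks, study_variables
from prediabn.core import CohortTable, Dag
from prediabn.errors import InputError
from prediabn.structure import (
    ArcStrengthTable,
    Blacklist,
    BlockOrdering,
    HillClimbConfig,
    aic_score,
    averaged_network,
    blacklist_from_blocks,
    bootstrap_arc_strength,
    hill_climb,
)

from conftest import random_network


def _ab_cohort(n=10_000, seed=1, p=0.9):
    """Strongly dependent A -> B data: P(B=b1|A=a1)=p, P(B=b1|A=a2)=1-p."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = np.where(rng.random(n) < np.where(a == 0, p, 1 - p), 0, 1)
    frame = pd.DataFrame(
        {"A": np.array(["a1", "a2"])[a], "B": np.array(["b1", "b2"])[b]}
    )
    return CohortTable(frame, {"A": ("a1", "a2"), "B": ("b1", "b2")})


class TestBlocks:
    def test_study_blacklist_has_51_forbidden_arcs(self):
        # later->earlier pairs: 4*3 + 4*3 + 4*4 + 1*3 + 1*4 + 1*4 = 51
        assert len(blacklist_from_blocks(study_blocks())) == 51

    def test_single_block_gives_empty_blacklist(self):
        blocks = BlockOrdering([{v.name for v in study_variables()}])
        assert len(blacklist_from_blocks(blocks)) == 0

    def test_diagnostic_block_orientation(self):
        bl = blacklist_from_blocks(study_blocks())
        assert not bl.allows("T2D", "AGE")
        assert bl.allows("GENDER", "T2D")

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(InputError):
            BlockOrdering([{"A", "B"}, {"B"}])

    def test_unblocked_variable_errors(self):
        with pytest.raises(InputError):
            BlockOrdering([{"A"}]).block_of("Z")


class TestAicScore:
    def test_closed_form_single_binary_variable(self):
        frame = pd.DataFrame({"X": ["yes", "yes", "no", "no"]})
        data = CohortTable(frame, {"X": ("yes", "no")})
        score = aic_score(Dag(["X"]), data)
        assert score == pytest.approx(4 * math.log(0.5) - 1, abs=1e-12)

    def test_true_structure_beats_empty_graph_on_dependent_data(self):
        data = _ab_cohort(n=5_000, seed=3)
        with_edge = aic_score(Dag(["A", "B"], [("A", "B")]), data)
        empty = aic_score(Dag(["A", "B"]), data)
        assert with_edge > empty

    def test_penalty_grows_with_parent_configurations(self):
        """Adding a parent multiplies q_i, so the penalty strictly grows."""
        variables = study_variables()
        cards = {v.name: v.cardinality for v in variables}
        r, q = cards["T2D"], 1
        penalties = []
        for parent in ("PA", "AGE", "BMI"):
            q *= cards[parent]
            penalties.append((r - 1) * q)
        assert penalties == sorted(penalties) and len(set(penalties)) == 3

    def test_decomposability_matches_monolithic_recomputation(self):
        rng = np.random.default_rng(21)
        bn = random_network(rng, 5, p_edge=0.5)
        data = bn.forward_sample(2_000, seed=10)
        dag = bn.dag
        # family-wise: score each node's family on its own single-node DAG view
        total = 0.0
        for name in bn.names:
            sub_cols = [*dag.parents(name), name]
            sub = CohortTable(
                data.frame[sub_cols], {c: data.domains[c] for c in sub_cols}
            )
            sub_dag = Dag(sub_cols, [(p, name) for p in dag.parents(name)])
            total += aic_score(sub_dag, sub)
            # subtract the parents' own (empty-graph) family scores
            if dag.parents(name):
                pcols = list(dag.parents(name))
                psub = CohortTable(data.frame[pcols], {c: data.domains[c] for c in pcols})
                total -= aic_score(Dag(pcols), psub)
        assert total == pytest.approx(aic_score(dag, data), abs=1e-9)

    def test_empty_data_rejected(self):
        with pytest.raises(InputError):
            frame = pd.DataFrame({"X": []})
            CohortTable(frame, {"X": ("a", "b")})


class TestHillClimb:
    def test_single_variable_data_gives_empty_graph(self):
        frame = pd.DataFrame({"X": ["a", "b", "a"]})
        dag = hill_climb(CohortTable(frame, {"X": ("a", "b")}))
        assert dag.n_edges == 0

    def test_recovers_oriented_edge_under_blacklist(self):
        data = _ab_cohort()
        dag = hill_climb(data, blacklist=Blacklist([("B", "A")]))
        assert dag.edges == (("A", "B"),)

    def test_never_returns_blacklisted_arc(self):
        data = _ab_cohort()
        dag = hill_climb(data, blacklist=Blacklist([("A", "B"), ("B", "A")]))
        assert dag.n_edges == 0

    def test_start_violating_blacklist_rejected(self):
        data = _ab_cohort(n=100)
        start = Dag(["A", "B"], [("A", "B")])
        with pytest.raises(InputError):
            hill_climb(data, blacklist=Blacklist([("A", "B")]), start=start)

    def test_output_is_single_arc_local_optimum(self):
        """Exhaustive check: no single add/delete/reverse improves the score."""
        rng = np.random.default_rng(15)
        for trial in range(3):
            bn = random_network(rng, 4, p_edge=0.5)
            data = bn.forward_sample(1_500, seed=trial)
            dag = hill_climb(data)
            base = aic_score(dag, data)
            names = list(dag.nodes)
            for u, v in itertools.permutations(names, 2):
                neighbour = dag.copy()
                try:
                    if dag.has_edge(u, v):
                        neighbour.remove_edge(u, v)
                        assert aic_score(neighbour, data) <= base + 1e-9
                        neighbour.add_edge(v, u)  # reversal
                        assert aic_score(neighbour, data) <= base + 1e-9
                    else:
                        neighbour.add_edge(u, v)
                        assert aic_score(neighbour, data) <= base + 1e-9
                except InputError:  # move would create a cycle
                    continue

    def test_deterministic_given_data(self):
        data = _ab_cohort(n=2_000, seed=8)
        assert hill_climb(data) == hill_climb(data)


class TestBootstrap:
    def test_single_replicate_strengths_are_indicator(self):
        data = _ab_cohort(n=2_000, seed=5)
        table = bootstrap_arc_strength(data, replicates=1, seed=0)
        for u, v in itertools.permutations(["A", "B"], 2):
            assert table.strength(u, v) in (0.0, 1.0)

    def test_strong_dependence_has_high_strength(self):
        data = _ab_cohort(n=10_000, seed=2)
        table = bootstrap_arc_strength(
            data, replicates=100, blacklist=Blacklist([("B", "A")]), seed=7
        )
        assert table.strength("A", "B") >= 0.95
        assert table.direction_prob("A", "B") == 1.0

    def test_reproducible_under_seed(self):
        data = _ab_cohort(n=1_000, seed=4)
        t1 = bootstrap_arc_strength(data, replicates=10, seed=42)
        t2 = bootstrap_arc_strength(data, replicates=10, seed=42)
        assert t1.counts == t2.counts
        assert t1.to_frame().equals(t2.to_frame())

    def test_direction_probs_sum_to_one_where_arc_appears(self):
        data = _ab_cohort(n=3_000, seed=6)
        table = bootstrap_arc_strength(data, replicates=20, seed=1)
        for u, v in list(table.counts):
            assert table.direction_prob(u, v) + table.direction_prob(v, u) == pytest.approx(1.0)
            assert table.strength(u, v) == table.strength(v, u)


class TestAveragedNetwork:
    def test_all_below_threshold_gives_empty_graph(self):
        table = ArcStrengthTable(("A", "B"), {("A", "B"): 10}, replicates=100)
        assert averaged_network(table, 0.85).n_edges == 0

    def test_keeps_strong_arc_with_majority_direction(self):
        data = _ab_cohort(n=10_000, seed=2)
        table = bootstrap_arc_strength(
            data, replicates=50, blacklist=Blacklist([("B", "A")]), seed=3
        )
        assert averaged_network(table, 0.85).edges == (("A", "B"),)

    def test_threshold_is_inclusive(self):
        table = ArcStrengthTable(("A", "B"), {("A", "B"): 85, ("B", "A"): 0}, replicates=100)
        assert averaged_network(table, 0.85).edges == (("A", "B"),)

    def test_direction_tie_orients_to_later_declared(self):
        table = ArcStrengthTable(("A", "B"), {("A", "B"): 50, ("B", "A"): 50}, replicates=100)
        assert averaged_network(table, 0.85).edges == (("A", "B"),)

    def test_cycle_broken_by_dropping_weakest(self):
        counts = {("A", "B"): 100, ("B", "C"): 95, ("C", "A"): 90}
        table = ArcStrengthTable(("A", "B", "C"), counts, replicates=100)
        dag = averaged_network(table, 0.85)
        assert dag.has_edge("A", "B") and dag.has_edge("B", "C")
        assert not dag.has_edge("C", "A")

    def test_invalid_threshold_rejected(self):
        table = ArcStrengthTable(("A", "B"), {}, replicates=10)
        with pytest.raises(InputError):
            averaged_network(table, 0.0)
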