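"""Variable elimination against brute-force enumeration, and the worked
four-node example queries."""

import numpy as np
import pytest

from prediabn.core import CategoricalVariable, Cpt, Dag, DiscreteBayesianNetwork, d_separated
from prediabn.errors import InconsistentEvidenceError, InputError
from prediabn.examples import example_network
from prediabn.inference import joint_table, most_probable_state, posterior

from conftest import enumerate_assignments, random_network


def brute_force_posterior(bn, target, evidence):
    """Oracle: condition the fully enumerated joint."""
    states = bn.states(target)
    mass = dict.fromkeys(states, 0.0)
    for assignment in enumerate_assignments(bn):
        if all(assignment[k] == v for k, v in evidence.items()):
            mass[assignment[target]] += bn.joint_probability(assignment)
    z = sum(mass.values())
    return {s: p / z for s, p in mass.items()}


class TestWorkedExample:
    """The published queries on the four-node network, including the
    redundant-evidence variants justified by d-separation."""

    @pytest.mark.parametrize("completion_seed", [0, 1, 99])
    def test_t2d_given_age_diet_and_redundant_pa(self, completion_seed):
        bn = example_network(completion_seed)
        post = posterior(bn, "T2D", {"AGE": "18-32", "DIET": "No", "PA": "No"})
        assert post["No"] == pytest.approx(0.7625, abs=1e-12)

    @pytest.mark.parametrize("completion_seed", [0, 1, 99])
    def test_diet_given_pa_and_redundant_age(self, completion_seed):
        bn = example_network(completion_seed)
        post = posterior(bn, "DIET", {"PA": "No", "AGE": "18-32"})
        assert post["No"] == pytest.approx(0.8563, abs=1e-12)

    @pytest.mark.parametrize("completion_seed", [0, 1, 99])
    def test_pa_given_age(self, completion_seed):
        bn = example_network(completion_seed)
        assert posterior(bn, "PA", {"AGE": "18-32"})["No"] == pytest.approx(0.3727, abs=1e-12)

    def test_redundancy_is_justified_by_d_separation(self):
        dag = example_network(0).dag
        assert d_separated(dag, "PA", "T2D", {"AGE", "DIET"})
        assert d_separated(dag, "AGE", "DIET", {"PA"})


class TestVariableElimination:
    def test_matches_enumeration_on_random_networks(self):
        rng = np.random.default_rng(2023)
        for i in range(60):
            bn = random_network(rng, int(rng.integers(3, 7)))
            target = bn.names[int(rng.integers(len(bn.names)))]
            others = [n for n in bn.names if n != target]
            k = int(rng.integers(0, min(3, len(others)) + 1))
            ev_vars = list(rng.choice(others, size=k, replace=False))
            evidence = {v: bn.states(v)[int(rng.integers(bn.variable(v).cardinality))] for v in ev_vars}
            try:
                got = posterior(bn, target, evidence).as_dict()
            except InconsistentEvidenceError:
                continue
            want = brute_force_posterior(bn, target, evidence)
            for s in bn.states(target):
                assert got[s] == pytest.approx(want[s], abs=1e-9)

    def test_no_evidence_on_root_returns_prior_row(self):
        bn = example_network(0)
        post = posterior(bn, "AGE", {})
        assert post.as_dict() == pytest.approx(bn.cpts["AGE"].distribution({}), abs=1e-12)

    def test_conditioning_on_all_parents_reproduces_cpt_row(self):
        rng = np.random.default_rng(99)
        bn = random_network(rng, 5, p_edge=0.5)
        for name in bn.names:
            parents = bn.dag.parents(name)
            if not parents:
                continue
            assignment = {p: bn.states(p)[0] for p in parents}
            post = posterior(bn, name, assignment)
            row = bn.cpts[name].distribution(assignment)
            for s in bn.states(name):
                assert post[s] == pytest.approx(row[s], abs=1e-9)

    def test_inconsistent_evidence_raises(self):
        a = CategoricalVariable("A", ("x", "y"))
        b = CategoricalVariable("B", ("u", "v"))
        dag = Dag(["A", "B"], [("A", "B")])
        bn = DiscreteBayesianNetwork(
            [a, b],
            dag,
            {
                "A": Cpt("A", a.states, (), (), np.array([[1.0, 0.0]])),
                "B": Cpt("B", b.states, ("A",), (a.states,), np.array([[1.0, 0.0], [0.0, 1.0]])),
            },
        )
        with pytest.raises(InconsistentEvidenceError):
            posterior(bn, "B", {"A": "y"})

    def test_unknown_names_and_states_rejected(self):
        bn = example_network(0)
        with pytest.raises(InputError):
            posterior(bn, "NOPE", {})
        with pytest.raises(InputError):
            posterior(bn, "T2D", {"AGE": "banana"})
        with pytest.raises(InputError):
            posterior(bn, "T2D", {"T2D": "No"})

    def test_d_separation_faithfulness(self):
        """Evidence on a d-separated variable never moves the posterior."""
        rng = np.random.default_rng(41)
        checked = 0
        while checked < 20:
            bn = random_network(rng, 6, p_edge=0.35)
            names = list(bn.names)
            x, y = names[0], names[1]
            z = set(names[2:4])
            if not d_separated(bn.dag, x, y, z):
                continue
            ev = {v: bn.states(v)[0] for v in z}
            try:
                base = posterior(bn, x, ev).probabilities
                with_y = posterior(bn, x, {**ev, y: bn.states(y)[0]}).probabilities
            except InconsistentEvidenceError:
                continue
            np.testing.assert_allclose(base, with_y, atol=1e-9)
            checked += 1


class TestMostProbableState:
    def test_degenerate_posterior_picks_certain_state(self):
        a = CategoricalVariable("A", ("x", "y"))
        bn = DiscreteBayesianNetwork(
            [a], Dag(["A"]), {"A": Cpt("A", a.states, (), (), np.array([[1.0, 0.0]]))}
        )
        assert most_probable_state(bn, "A", {}) == "x"

    def test_worked_example_prediction(self):
        bn = example_network(0)
        assert most_probable_state(bn, "T2D", {"AGE": "18-32", "DIET": "No"}) == "No"

    def test_exact_tie_goes_to_first_declared_state(self):
        a = CategoricalVariable("A", ("first", "second"))
        bn = DiscreteBayesianNetwork(
            [a], Dag(["A"]), {"A": Cpt("A", a.states, (), (), np.array([[0.5, 0.5]]))}
        )
        assert most_probable_state(bn, "A", {}) == "first"


class TestJointTable:
    def test_marginals_from_joint_match_posteriors(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            bn = random_network(rng, 5)
            jt = joint_table(bn)
            for j, name in enumerate(bn.names):
                axes = tuple(k for k in range(len(bn.names)) if k != j)
                marg = jt.table.sum(axis=axes)
                post = posterior(bn, name, {}).probabilities
                np.testing.assert_allclose(marg, post, atol=1e-9)

    def test_elimination_order_invariance_via_permuted_declaration(self):
        """Re-declaring variables permutes the elimination heuristic's
        tie-breaks; posteriors must not move."""
        rng = np.random.default_rng(55)
        bn = random_network(rng, 6, p_edge=0.4)
        perm = list(bn.names[::-1])
        variables = [bn.variable(n) for n in perm]
        bn2 = DiscreteBayesianNetwork(variables, bn.dag.copy(), bn.cpts)
        ev = {bn.names[0]: bn.states(bn.names[0])[0]}
        target = bn.names[3]
        p1 = posterior(bn, target, ev).as_dict()
        p2 = posterior(bn2, target, ev).as_dict()
        for s in p1:
            assert p1[s] == pytest.approx(p2[s], abs=1e-9)
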