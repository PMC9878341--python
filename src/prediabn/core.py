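"""Core containers and operations for discrete Bayesian networks.

A discrete Bayesian network ``B = (G, theta)`` couples a directed acyclic
graph ``G`` over categorical variables with one conditional probability
table (CPT) per node.  The network encodes a joint distribution through
the chain rule

    P(x_1, ..., x_n) = prod_i P(x_i | pa(x_i)),

where ``pa(x_i)`` are the states of the parents of node ``i`` in ``G``.
This module provides the containers (:class:`CategoricalVariable`,
:class:`Dag`, :class:`Cpt`, :class:`DiscreteBayesianNetwork`,
:class:`EvidenceSet`, :class:`CohortTable`) and the graph-theoretic and
probabilistic primitives built directly on the factorisation: Markov
blankets, d-separation, the chain-rule joint, ancestral (forward)
sampling and data log-likelihood.

Conventions fixed here and relied on everywhere else:

* CPT rows are ordered lexicographically over the parent order, with each
  parent's states in their declared order (first parent most significant).
* A node's CPT parent order is the network's variable declaration order.
* Topological-order ties are broken by variable declaration order.
* State labels are compared verbatim after trimming outer whitespace.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "CategoricalVariable",
    "Dag",
    "Cpt",
    "DiscreteBayesianNetwork",
    "EvidenceSet",
    "CohortTable",
    "markov_blanket",
    "d_separated",
    "joint_probability",
    "forward_sample",
    "log_likelihood",
]


# ---------------------------------------------------------------------------
# Variables


@dataclass(frozen=True)
class CategoricalVariable:
    """A named variable with a finite, ordered set of mutually exclusive states.

    The state order is semantically meaningful: it fixes CPT column order,
    CPT row order (through parent combinations) and argmax tie-breaking.
    """

    name: str
    states: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(s.strip() for s in self.states))
        object.__setattr__(self, "name", self.name.strip())
        if not self.name:
            raise InputError("variable name must be non-empty")
        if len(self.states) < 2:
            raise InputError(
                f"variable {self.name!r} needs at least 2 states, got {len(self.states)}"
            )
        if len(set(self.states)) != len(self.states):
            raise InputError(f"variable {self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state.strip())
        except ValueError:
            raise InputError(
                f"{state!r} is not a state of {self.name!r}; states are {list(self.states)}"
            ) from None


# ---------------------------------------------------------------------------
# DAG


class Dag:
    """Directed acyclic graph over variable names.

    Nodes keep their declaration order; ``parents``/``children`` and
    ``topological_order`` return deterministically ordered results based on
    it.  Mutating operations (:meth:`add_edge`, :meth:`remove_edge`,
    :meth:`reverse_edge`) preserve acyclicity by construction and raise
    :class:`InputError` otherwise.
    """

    __slots__ = ("_nodes", "_index", "_parents", "_children")

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self._nodes = tuple(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise InputError("duplicate node names in DAG")
        self._index = {n: i for i, n in enumerate(self._nodes)}
        self._parents: dict[str, set[str]] = {n: set() for n in self._nodes}
        self._children: dict[str, set[str]] = {n: set() for n in self._nodes}
        for u, v in edges:
            self.add_edge(u, v)

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        out = []
        for u in self._nodes:
            for v in sorted(self._children[u], key=self._index.__getitem__):
                out.append((u, v))
        return tuple(out)

    @property
    def n_edges(self) -> int:
        return sum(len(c) for c in self._children.values())

    def _check(self, node: str) -> str:
        if node not in self._index:
            raise InputError(f"unknown node {node!r}")
        return node

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._index and v in self._children[u]

    def parents(self, node: str) -> tuple[str, ...]:
        self._check(node)
        return tuple(sorted(self._parents[node], key=self._index.__getitem__))

    def children(self, node: str) -> tuple[str, ...]:
        self._check(node)
        return tuple(sorted(self._children[node], key=self._index.__getitem__))

    def has_directed_path(self, u: str, v: str) -> bool:
        """True iff a directed path u ~> v exists (u == v counts)."""
        if u == v:
            return True
        stack, seen = [u], {u}
        while stack:
            for c in self._children[stack.pop()]:
                if c == v:
                    return True
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def descendants(self, node: str) -> set[str]:
        self._check(node)
        out: set[str] = set()
        stack = [node]
        while stack:
            for c in self._children[stack.pop()]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def ancestors(self, node: str) -> set[str]:
        self._check(node)
        out: set[str] = set()
        stack = [node]
        while stack:
            for p in self._parents[stack.pop()]:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; ties broken by node declaration order."""
        indeg = {n: len(self._parents[n]) for n in self._nodes}
        ready = [n for n in self._nodes if indeg[n] == 0]
        order: list[str] = []
        while ready:
            ready.sort(key=self._index.__getitem__)
            n = ready.pop(0)
            order.append(n)
            for c in sorted(self._children[n], key=self._index.__getitem__):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self._nodes):
            raise InputError("graph contains a directed cycle")
        return order

    # -- mutation ---------------------------------------------------------

    def add_edge(self, u: str, v: str) -> None:
        self._check(u)
        self._check(v)
        if u == v:
            raise InputError(f"self-loop {u!r} -> {v!r} not allowed")
        if v in self._children[u]:
            raise InputError(f"duplicate edge {u!r} -> {v!r}")
        if self.has_directed_path(v, u):
            raise InputError(f"edge {u!r} -> {v!r} would create a directed cycle")
        self._children[u].add(v)
        self._parents[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        if not self.has_edge(u, v):
            raise InputError(f"edge {u!r} -> {v!r} not in DAG")
        self._children[u].remove(v)
        self._parents[v].remove(u)

    def reverse_edge(self, u: str, v: str) -> None:
        self.remove_edge(u, v)
        self.add_edge(v, u)

    def copy(self) -> "Dag":
        d = Dag.__new__(Dag)
        d._nodes = self._nodes
        d._index = self._index
        d._parents = {n: set(s) for n, s in self._parents.items()}
        d._children = {n: set(s) for n, s in self._children.items()}
        return d

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Dag)
            and set(self._nodes) == set(other._nodes)
            and {(u, v) for u in self._nodes for v in self._children[u]}
            == {(u, v) for u in other._nodes for v in other._children[u]}
        )

    def __repr__(self) -> str:
        return f"Dag(nodes={len(self._nodes)}, edges={self.n_edges})"


def markov_blanket(dag: Dag, node: str) -> set[str]:
    """Parents, children and children's other parents (spouses) of ``node``.

    Given its Markov blanket, a node is d-separated from every variable
    outside the blanket (global Markov property).
    """
    dag._check(node)
    blanket = set(dag.parents(node)) | set(dag.children(node))
    for child in dag.children(node):
        blanket.update(dag.parents(child))
    blanket.discard(node)
    return blanket


def d_separated(dag: Dag, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """Test whether ``x`` and ``y`` are d-separated given the set ``z``.

    Every undirected path must be blocked: a serial or diverging
    intermediate node blocks when it is instantiated (in ``z``); a
    converging (collider) node blocks when neither it nor any of its
    descendants is in ``z``.  Implemented as the standard active-trail
    reachability walk rather than path enumeration, which the test suite
    cross-checks against a brute-force path oracle.
    """
    zset = frozenset(s.strip() for s in z)
    for name in (x, y, *zset):
        dag._check(name)
    if x == y:
        raise InputError("d-separation requires two distinct variables")
    if x in zset or y in zset:
        raise InputError("query variables may not appear in the conditioning set")

    # z together with all ancestors of z: colliders unblocked iff in here.
    anc_z = set(zset)
    stack = list(zset)
    while stack:
        for p in dag._parents[stack.pop()]:
            if p not in anc_z:
                anc_z.add(p)
                stack.append(p)

    # Walk (node, direction) pairs; "up" = arrived from a child (moving
    # toward parents is unrestricted), "down" = arrived from a parent.
    visited: set[tuple[str, str]] = set()
    frontier: list[tuple[str, str]] = [(x, "up")]
    while frontier:
        node, direction = frontier.pop()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node == y and node not in zset:
            return False
        if direction == "up" and node not in zset:
            for p in dag._parents[node]:
                frontier.append((p, "up"))
            for c in dag._children[node]:
                frontier.append((c, "down"))
        elif direction == "down":
            if node not in zset:
                for c in dag._children[node]:
                    frontier.append((c, "down"))
            if node in anc_z:
                for p in dag._parents[node]:
                    frontier.append((p, "up"))
    return True


# ---------------------------------------------------------------------------
# CPT


class Cpt:
    """Conditional probability table of one variable given its parents.

    ``table`` has shape ``(q, r)`` with ``q`` the number of parent-state
    combinations (product of parent cardinalities, 1 for a root) and ``r``
    the child's cardinality.  Row order is lexicographic over
    ``parent_order`` with each parent's states in declared order; the first
    parent is the most significant digit.  Every row must sum to 1 within
    1e-9 with entries in [0, 1].
    """

    __slots__ = ("variable", "states", "parent_order", "parent_states", "table")

    def __init__(
        self,
        variable: str,
        states: Sequence[str],
        parent_order: Sequence[str],
        parent_states: Sequence[Sequence[str]],
        table: np.ndarray,
    ):
        self.variable = variable
        self.states = tuple(states)
        self.parent_order = tuple(parent_order)
        self.parent_states = tuple(tuple(s) for s in parent_states)
        if len(self.parent_order) != len(self.parent_states):
            raise InputError(f"CPT for {variable!r}: parent order/state mismatch")
        q = int(np.prod([len(s) for s in self.parent_states], dtype=np.int64)) if self.parent_order else 1
        arr = np.asarray(table, dtype=float)
        if arr.shape != (q, len(self.states)):
            raise InputError(
                f"CPT for {variable!r}: expected shape {(q, len(self.states))}, got {arr.shape}"
            )
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise InputError(f"CPT for {variable!r}: entries outside [0, 1]")
        if np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
            raise InputError(f"CPT for {variable!r}: rows must sum to 1 within 1e-9")
        self.table = np.clip(arr, 0.0, 1.0)

    @property
    def n_rows(self) -> int:
        return self.table.shape[0]

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def parent_combinations(self) -> Iterable[tuple[str, ...]]:
        """Parent-state tuples in canonical (row) order."""
        if not self.parent_order:
            return [()]
        return itertools.product(*self.parent_states)

    def row_index(self, parent_assignment: Mapping[str, str]) -> int:
        """Mixed-radix row index of a *full* parent assignment."""
        idx = 0
        for parent, states in zip(self.parent_order, self.parent_states):
            if parent not in parent_assignment:
                raise InputError(
                    f"CPT lookup for {self.variable!r}: parent {parent!r} not assigned"
                )
            value = parent_assignment[parent].strip()
            try:
                k = states.index(value)
            except ValueError:
                raise InputError(
                    f"{value!r} is not a state of parent {parent!r}"
                ) from None
            idx = idx * len(states) + k
        return idx

    def distribution(self, parent_assignment: Mapping[str, str] | None = None) -> dict[str, float]:
        row = self.table[self.row_index(parent_assignment or {})]
        return dict(zip(self.states, row.tolist()))

    def copy(self) -> "Cpt":
        return Cpt(self.variable, self.states, self.parent_order, self.parent_states, self.table.copy())

    def __repr__(self) -> str:
        return f"Cpt({self.variable!r} | {list(self.parent_order)}, rows={self.n_rows})"


# ---------------------------------------------------------------------------
# Evidence


class EvidenceSet(Mapping):
    """Immutable mapping variable name -> observed state label."""

    __slots__ = ("_items",)

    def __init__(self, assignments: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        items = dict(assignments)
        self._items = {k.strip(): v.strip() for k, v in items.items()}
        if len(self._items) != len(items):
            raise InputError("a variable appears more than once in the evidence")

    def __getitem__(self, key):
        return self._items[key]

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def validate(self, bn: "DiscreteBayesianNetwork") -> None:
        for name, state in self._items.items():
            bn.variable(name).state_index(state)

    def __repr__(self):
        return f"EvidenceSet({self._items!r})"


# ---------------------------------------------------------------------------
# Cohort table


class CohortTable:
    """n records over named categorical columns; the empirical data ``D``.

    Wraps a :class:`pandas.DataFrame` of strings plus per-column domains
    (ordered state lists).  Cells must belong to their column's domain or
    equal the designated missing marker; learning and validation routines
    reject missing values explicitly (complete-case analysis).
    """

    MISSING = ""

    def __init__(
        self,
        frame: pd.DataFrame,
        domains: Mapping[str, Sequence[str]] | None = None,
        missing_marker: str = MISSING,
        validate: bool = True,
    ):
        if frame.shape[0] < 1:
            raise InputError("cohort table needs at least one record")
        if len(set(frame.columns)) != len(frame.columns):
            raise InputError("cohort table has duplicate column names")
        self.frame = frame.astype(str) if validate else frame
        self.missing_marker = missing_marker
        if domains is None:
            domains = {
                c: tuple(sorted(v for v in self.frame[c].unique() if v != missing_marker))
                for c in self.frame.columns
            }
        self.domains: dict[str, tuple[str, ...]] = {
            k: tuple(s.strip() for s in v) for k, v in domains.items()
        }
        missing_cols = [c for c in self.frame.columns if c not in self.domains]
        if missing_cols:
            raise InputError(f"no domain given for columns {missing_cols}")
        if validate:
            for c in self.frame.columns:
                allowed = set(self.domains[c]) | {missing_marker}
                bad = set(self.frame[c].unique()) - allowed
                if bad:
                    raise InputError(
                        f"column {c!r} contains values outside its domain: {sorted(bad)}"
                    )

    # -- basic properties -------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.frame.shape[0])

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def has_missing(self) -> bool:
        return bool((self.frame == self.missing_marker).any().any())

    def domain_variables(self) -> list[CategoricalVariable]:
        return [CategoricalVariable(c, self.domains[c]) for c in self.columns]

    # -- encoding ---------------------------------------------------------

    def encoded(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Integer-coded matrix (n, p) using each column's domain order.

        Raises :class:`InputError` if any missing values are present.
        """
        cols = list(order) if order is not None else list(self.columns)
        out = np.empty((self.n, len(cols)), dtype=np.int64)
        for j, c in enumerate(cols):
            if c not in self.domains:
                raise InputError(f"unknown column {c!r}")
            codes = pd.Categorical(self.frame[c], categories=self.domains[c]).codes
            if (codes < 0).any():
                raise InputError(
                    f"column {c!r} contains missing or out-of-domain values; "
                    "complete cases are required"
                )
            out[:, j] = codes
        return out

    @classmethod
    def from_codes(
        cls, codes: np.ndarray, variables: Sequence[CategoricalVariable]
    ) -> "CohortTable":
        """Trusted constructor from an integer code matrix (no validation)."""
        data = {
            v.name: pd.Categorical.from_codes(codes[:, j], categories=list(v.states)).astype(str)
            for j, v in enumerate(variables)
        }
        frame = pd.DataFrame(data, columns=[v.name for v in variables])
        return cls(frame, {v.name: v.states for v in variables}, validate=False)

    # -- I/O (CSV, UTF-8, comma separated, header row) ---------------------

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def read_csv(
        cls, path, variables: Sequence[CategoricalVariable] | None = None
    ) -> "CohortTable":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        domains = {v.name: v.states for v in variables} if variables else None
        return cls(frame, domains)

    def __repr__(self) -> str:
        return f"CohortTable(n={self.n}, columns={list(self.columns)})"


# ---------------------------------------------------------------------------
# Network


class DiscreteBayesianNetwork:
    """``B = (G, theta)``: a DAG plus one CPT per node.

    Invariants enforced at construction: every node has a CPT whose parent
    order equals the DAG parents in variable declaration order, parent state
    lists match the declared variables, and each CPT row is a distribution.
    """

    def __init__(
        self,
        variables: Sequence[CategoricalVariable],
        dag: Dag,
        cpts: Mapping[str, Cpt],
    ):
        self.variables = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise InputError("duplicate variable names in network")
        if set(names) != set(dag.nodes):
            raise InputError("DAG nodes and declared variables differ")
        self.dag = dag
        self._vars = {v.name: v for v in self.variables}
        self.cpts: dict[str, Cpt] = {}
        for v in self.variables:
            if v.name not in cpts:
                raise InputError(f"missing CPT for node {v.name!r}")
            cpt = cpts[v.name]
            expected_parents = dag.parents(v.name)
            if cpt.parent_order != expected_parents:
                raise InputError(
                    f"CPT for {v.name!r} has parent order {cpt.parent_order}, "
                    f"DAG implies {expected_parents}"
                )
            if cpt.states != v.states:
                raise InputError(f"CPT for {v.name!r} disagrees with declared states")
            for parent, pstates in zip(cpt.parent_order, cpt.parent_states):
                if pstates != self._vars[parent].states:
                    raise InputError(
                        f"CPT for {v.name!r}: parent {parent!r} states disagree"
                    )
            self.cpts[v.name] = cpt

    # -- lookups -----------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> CategoricalVariable:
        try:
            return self._vars[name]
        except KeyError:
            raise InputError(f"unknown variable {name!r}") from None

    def states(self, name: str) -> tuple[str, ...]:
        return self.variable(name).states

    def cardinalities(self) -> dict[str, int]:
        return {v.name: v.cardinality for v in self.variables}

    def copy(self) -> "DiscreteBayesianNetwork":
        return DiscreteBayesianNetwork(
            self.variables, self.dag.copy(), {n: c.copy() for n, c in self.cpts.items()}
        )

    # -- chain rule --------------------------------------------------------

    def joint_probability(self, assignment: Mapping[str, str]) -> float:
        """P(x_1, ..., x_n) for a *full* assignment, read off the CPTs."""
        missing = [n for n in self.names if n not in assignment]
        if missing:
            raise InputError(f"assignment does not cover nodes {missing}")
        p = 1.0
        for name in self.names:
            cpt = self.cpts[name]
            k = self.variable(name).state_index(assignment[name])
            p *= float(cpt.table[cpt.row_index(assignment), k])
        return p

    # -- sampling ----------------------------------------------------------

    def forward_sample(self, n: int, seed: int | np.random.Generator | None = None) -> CohortTable:
        """Ancestral sampling: draw each node in topological order given its
        parents.  Columns come out in variable declaration order; identical
        seeds give identical tables."""
        if n < 1:
            raise InputError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        order = self.dag.topological_order()
        col = {name: j for j, name in enumerate(self.names)}
        codes = np.empty((n, len(self.names)), dtype=np.int64)
        for name in order:
            cpt = self.cpts[name]
            rows = np.zeros(n, dtype=np.int64)
            for parent, pstates in zip(cpt.parent_order, cpt.parent_states):
                rows = rows * len(pstates) + codes[:, col[parent]]
            cum = np.cumsum(cpt.table, axis=1)
            u = rng.random(n)
            codes[:, col[name]] = np.minimum(
                (u[:, None] > cum[rows]).sum(axis=1), cpt.cardinality - 1
            )
        return CohortTable.from_codes(codes, self.variables)

    # -- likelihood --------------------------------------------------------

    def log_likelihood(self, data: CohortTable) -> float:
        """Sum over records of the natural log of the chain-rule joint.

        Returns ``-inf`` if any record has probability zero (Bayesian
        smoothing in fitted networks makes this unreachable for them).
        """
        if set(self.names) - set(data.columns):
            raise InputError("data columns do not cover the network's variables")
        codes = CohortTable(
            data.frame[list(self.names)],
            {n: self.states(n) for n in self.names},
            missing_marker=data.missing_marker,
        ).encoded(self.names)
        col = {name: j for j, name in enumerate(self.names)}
        total = 0.0
        for name in self.names:
            cpt = self.cpts[name]
            rows = np.zeros(data.n, dtype=np.int64)
            for parent, pstates in zip(cpt.parent_order, cpt.parent_states):
                rows = rows * len(pstates) + codes[:, col[parent]]
            probs = cpt.table[rows, codes[:, col[name]]]
            if np.any(probs <= 0.0):
                return float("-inf")
            total += float(np.log(probs).sum())
        return total

    # -- serialisation (dict form; JSON wrapper lives in prediabn.io) ------

    def to_dict(self) -> dict:
        cpts = {}
        for name in self.names:
            cpt = self.cpts[name]
            rows = {
                "|".join(combo): cpt.table[i].tolist()
                for i, combo in enumerate(cpt.parent_combinations())
            }
            cpts[name] = {"parents": list(cpt.parent_order), "rows": rows}
        return {
            "format": "prediabn-network",
            "version": 1,
            "variables": [{"name": v.name, "states": list(v.states)} for v in self.variables],
            "edges": [list(e) for e in self.dag.edges],
            "cpts": cpts,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DiscreteBayesianNetwork":
        try:
            variables = [
                CategoricalVariable(v["name"], tuple(v["states"])) for v in doc["variables"]
            ]
            dag = Dag([v.name for v in variables], [tuple(e) for e in doc["edges"]])
            by_name = {v.name: v for v in variables}
            cpts = {}
            for name, spec in doc["cpts"].items():
                if name not in by_name:
                    raise InputError(f"CPT for undeclared node {name!r}")
                parent_order = tuple(spec["parents"])
                parent_states = tuple(by_name[p].states for p in parent_order)
                q = int(np.prod([len(s) for s in parent_states], dtype=np.int64)) if parent_order else 1
                table = np.empty((q, by_name[name].cardinality), dtype=float)
                expected = {
                    "|".join(c): i
                    for i, c in enumerate(
                        itertools.product(*parent_states) if parent_order else [()]
                    )
                }
                if set(spec["rows"]) != set(expected):
                    raise InputError(f"CPT rows for node {name!r} do not match parent combinations")
                for key, row in spec["rows"].items():
                    table[expected[key]] = row
                cpts[name] = Cpt(name, by_name[name].states, parent_order, parent_states, table)
        except (KeyError, TypeError) as exc:
            raise InputError(f"malformed network document: {exc}") from exc
        return cls(variables, dag, cpts)

    def __repr__(self) -> str:
        return f"DiscreteBayesianNetwork(variables={len(self.variables)}, edges={self.dag.n_edges})"


# ---------------------------------------------------------------------------
# Module-level operation aliases (functional surface mirroring the methods)


def joint_probability(bn: DiscreteBayesianNetwork, assignment: Mapping[str, str]) -> float:
    return bn.joint_probability(assignment)


def forward_sample(
    bn: DiscreteBayesianNetwork, n: int, seed: int | np.random.Generator | None = None
) -> CohortTable:
    return bn.forward_sample(n, seed)


def log_likelihood(bn: DiscreteBayesianNetwork, data: CohortTable) -> float:
    return bn.log_likelihood(data)
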