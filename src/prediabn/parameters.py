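"""Bayesian CPT estimation under a uniform Dirichlet prior.

For node i with ``r_i`` states and ``q_i`` parent configurations, the
posterior-mean estimate of each CPT entry under a Dirichlet prior with
total imaginary (equivalent) sample size ``iss`` spread uniformly over
the ``r_i * q_i`` cells is

    theta_ijk = (n_ijk + iss / (r_i q_i)) / (n_ij + iss / q_i).

Every estimate is strictly inside (0, 1), so a fitted network never
assigns zero probability to an observable record; as ``iss -> 0`` the
estimator approaches the maximum-likelihood frequencies wherever
``n_ij > 0``, and with ``iss = r_i q_i`` it coincides with Laplace
add-one smoothing.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

from .core import CohortTable, Cpt, Dag, DiscreteBayesianNetwork
from .errors import InputError

__all__ = ["PriorSpec", "fit_bayes", "cpt_lookup"]


@dataclass(frozen=True)
class PriorSpec:
    """Uniform Dirichlet prior parameterised by its equivalent sample size."""

    equivalent_sample_size: float = 1.0

    def __post_init__(self):
        if not self.equivalent_sample_size > 0:
            raise InputError("equivalent sample size must be > 0")


def fit_bayes(
    dag: Dag, data: CohortTable, prior: PriorSpec | None = None
) -> DiscreteBayesianNetwork:
    """Estimate every CPT for the fixed ``dag`` from complete-case data."""
    prior = prior or PriorSpec()
    if data.has_missing():
        raise InputError("Bayesian fitting requires complete data (no missing marker)")
    missing_cols = [n for n in dag.nodes if n not in data.columns]
    if missing_cols:
        raise InputError(f"data lacks columns for nodes {missing_cols}")
    variables = [v for v in data.domain_variables() if v.name in set(dag.nodes)]
    order = [v.name for v in variables]
    codes = data.encoded(order)
    col = {n: j for j, n in enumerate(order)}
    cards = {v.name: v.cardinality for v in variables}
    states = {v.name: v.states for v in variables}
    iss = prior.equivalent_sample_size

    cpts: dict[str, Cpt] = {}
    for name in order:
        parents = dag.parents(name)
        r = cards[name]
        q = 1
        rows = np.zeros(data.n, dtype=np.int64)
        for p in parents:
            rows = rows * cards[p] + codes[:, col[p]]
            q *= cards[p]
        cell = rows * r + codes[:, col[name]]
        njk = np.bincount(cell, minlength=q * r).reshape(q, r).astype(float)
        table = (njk + iss / (r * q)) / (njk.sum(axis=1, keepdims=True) + iss / q)
        cpts[name] = Cpt(name, states[name], parents, [states[p] for p in parents], table)
    return DiscreteBayesianNetwork(variables, dag.copy(), cpts)


def cpt_lookup(
    bn: DiscreteBayesianNetwork, variable: str, parent_assignment: Mapping[str, str] | None = None
) -> dict[str, float]:
    """The stored CPT row for a full parent assignment (state -> probability).

    A root node takes an empty assignment and returns its marginal row.
    """
    cpt = bn.cpts.get(variable)
    if cpt is None:
        raise InputError(f"unknown variable {variable!r}")
    return cpt.distribution(parent_assignment or {})
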