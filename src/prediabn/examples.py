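"""A four-node teaching network (AGE, PA, DIET, T2D).

The published worked example pins four CPT entries:

    P(AGE = 18-32)                      = 0.1281
    P(PA = No | AGE = 18-32)            = 0.3727
    P(DIET = No | PA = No)              = 0.8563
    P(T2D = No | AGE = 18-32, DIET = No) = 0.7625

All remaining entries are unprinted and therefore free.  The three
classic queries on this network —

    P(T2D = No | AGE = 18-32, DIET = No, PA = No)  (PA redundant:
        both trails PA -> DIET -> T2D and PA <- AGE -> T2D are blocked),
    P(DIET = No | PA = No, AGE = 18-32)  (AGE redundant: the serial trail
        is blocked at PA and the converging trail at unobserved T2D),
    P(PA = No | AGE = 18-32)

— depend only on the pinned entries, so their values are invariant to how
the free entries are completed.  :func:`example_network` takes a seed for
the completion, letting callers verify that invariance directly.
"""

from __future__ import annotations

import numpy as np

from .core import CategoricalVariable, Cpt, Dag, DiscreteBayesianNetwork

__all__ = ["example_network", "PINNED"]

PINNED = {
    "P(AGE=18-32)": 0.1281,
    "P(PA=No|AGE=18-32)": 0.3727,
    "P(DIET=No|PA=No)": 0.8563,
    "P(T2D=No|AGE=18-32,DIET=No)": 0.7625,
}


def _free_row(rng: np.random.Generator, k: int) -> np.ndarray:
    return rng.dirichlet(np.ones(k))


def example_network(completion_seed: int | None = 0) -> DiscreteBayesianNetwork:
    """Build the four-node example with a seeded completion of free entries."""
    rng = np.random.default_rng(completion_seed)
    age = CategoricalVariable("AGE", ("18-32", "33-47", "48-62"))
    pa = CategoricalVariable("PA", ("Yes", "No"))
    diet = CategoricalVariable("DIET", ("Yes", "No"))
    t2d = CategoricalVariable("T2D", ("Yes", "No"))
    dag = Dag(
        ["AGE", "PA", "DIET", "T2D"],
        [("AGE", "PA"), ("PA", "DIET"), ("DIET", "T2D"), ("AGE", "T2D")],
    )

    rest = _free_row(rng, 2) * (1.0 - 0.1281)
    age_cpt = Cpt("AGE", age.states, (), (), np.array([[0.1281, rest[0], rest[1]]]))

    pa_rows = np.empty((3, 2))
    pa_rows[0] = (1.0 - 0.3727, 0.3727)  # AGE = 18-32 (pinned)
    pa_rows[1] = _free_row(rng, 2)
    pa_rows[2] = _free_row(rng, 2)
    pa_cpt = Cpt("PA", pa.states, ("AGE",), (age.states,), pa_rows)

    diet_rows = np.empty((2, 2))
    diet_rows[0] = _free_row(rng, 2)  # PA = Yes
    diet_rows[1] = (1.0 - 0.8563, 0.8563)  # PA = No (pinned)
    diet_cpt = Cpt("DIET", diet.states, ("PA",), (pa.states,), diet_rows)

    # Parent order is declaration order: (AGE, DIET); rows iterate AGE slow,
    # DIET fast, so row 1 is (AGE=18-32, DIET=No) — the pinned one.
    t2d_rows = np.array([_free_row(rng, 2) for _ in range(6)])
    t2d_rows[1] = (1.0 - 0.7625, 0.7625)
    t2d_cpt = Cpt("T2D", t2d.states, ("AGE", "DIET"), (age.states, diet.states), t2d_rows)

    return DiscreteBayesianNetwork(
        [age, pa, diet, t2d],
        dag,
        {"AGE": age_cpt, "PA": pa_cpt, "DIET": diet_cpt, "T2D": t2d_cpt},
    )
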