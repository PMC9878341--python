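"""The study domain and the packaged synthetic-cohort generator.

The package emulates a 5-year follow-up cohort of Spanish working adults
with prediabetes (n = 16,648; 12,080 men, 4,568 women) described by 12
categorical variables: demographics (GENDER, AGE, SOCIALs), lifestyle
(SMOKING, PA, DIET), clinical intermediates (BMI, TG, FLI, HbA1c, BP) and
the diagnostic outcome T2D (incident type 2 diabetes at follow-up).  The
original records are not deposited, so all pipeline stages are exercised
on a synthetic cohort drawn from a packaged ground-truth network whose

* structure is the reported parent-set DAG (28 arcs over 4 causal blocks),
* AGE table equals the published age-given-gender-and-social-status
  probabilities to four decimals, and
* remaining CPTs were calibrated by :mod:`prediabn.calibration` so that
  exact inference reproduces every published marginal and single-evidence
  conditional (see :data:`calibration_targets`).

The calibrated network ships as a JSON data file; :func:`calibrate_ground_truth`
re-runs the construction for audit, it is never executed at import time.
"""

from __future__ import annotations

import functools
import json
from importlib import resources

import numpy as np

from .calibration import (
    CalibrationTarget,
    InteractionKnob,
    ParentEffectKnob,
    StateOddsKnob,
    calibrate,
    center_within_bands,
)
from .core import CategoricalVariable, CohortTable, Cpt, Dag, DiscreteBayesianNetwork
from .errors import InputError
from .structure import BlockOrdering

__all__ = [
    "study_variables",
    "study_blocks",
    "reference_dag",
    "calibration_targets",
    "ground_truth_network",
    "generate_cohort",
    "initial_network",
    "calibrate_ground_truth",
]

N_COHORT = 16_648
N_MEN = 12_080
N_WOMEN = 4_568

_VARIABLES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("GENDER", ("Men", "Women")),
    ("T2D", ("Yes", "No")),
    ("SOCIALs", ("I", "II", "III")),
    ("SMOKING", ("No", "Former smoker", "Yes")),
    ("PA", ("Yes", "No")),
    ("DIET", ("Yes", "No")),
    ("HbA1c", ("Less 6.0", "More 6.0")),
    ("FLI", ("Less 30", "30–60", "More 60")),
    ("BMI", ("Underweight", "Normal weight", "Overweight", "Obesity")),
    ("BP", ("Normal", "High", "Grade 1", "Grade 2")),
    ("TG", ("Normal", "Limit", "Hyper")),
    ("AGE", ("18-32", "33-47", "48-62")),
)

# Parent sets of the reference structure.  Roots: GENDER, SOCIALs, SMOKING.
_PARENTS: dict[str, tuple[str, ...]] = {
    "GENDER": (),
    "SOCIALs": (),
    "SMOKING": (),
    "AGE": ("GENDER", "SOCIALs"),
    "PA": ("SMOKING",),
    "DIET": ("PA",),
    "BMI": ("SMOKING", "PA"),
    "TG": ("DIET", "PA", "GENDER", "BMI"),
    "FLI": ("GENDER", "DIET", "PA", "TG", "BMI"),
    "HbA1c": ("GENDER", "AGE", "FLI", "BMI"),
    "BP": ("GENDER", "AGE", "HbA1c", "FLI"),
    "T2D": ("PA", "AGE", "BMI", "FLI", "HbA1c"),
}

# Published age distribution conditional on gender and social status.
# Two rows sum to 0.9999/1.0001 as printed and are renormalised on load.
_AGE_TABLE = {
    ("Men", "I"): (0.0681, 0.4301, 0.5018),
    ("Men", "II"): (0.0726, 0.4716, 0.4558),
    ("Men", "III"): (0.1430, 0.4682, 0.3887),
    ("Women", "I"): (0.1147, 0.5301, 0.3552),
    ("Women", "II"): (0.1163, 0.5143, 0.3694),
    ("Women", "III"): (0.1306, 0.4279, 0.4416),
}


def study_variables() -> list[CategoricalVariable]:
    """The 12 study variables with their canonical state labels and order."""
    return [CategoricalVariable(name, states) for name, states in _VARIABLES]


def study_blocks() -> BlockOrdering:
    """The four expert blocks constraining the causal order.

    Background (GENDER, AGE, SOCIALs) -> lifestyle/conditional (DIET,
    SMOKING, PA, BMI) -> clinical intermediates (HbA1c, FLI, BP, TG) ->
    diagnostic (T2D).
    """
    return BlockOrdering(
        [
            {"GENDER", "AGE", "SOCIALs"},
            {"DIET", "SMOKING", "PA", "BMI"},
            {"HbA1c", "FLI", "BP", "TG"},
            {"T2D"},
        ]
    )


def reference_dag() -> Dag:
    """The ground-truth structure (28 arcs) as a fresh Dag."""
    names = [name for name, _ in _VARIABLES]
    edges = [(p, child) for child, parents in _PARENTS.items() for p in parents]
    return Dag(names, edges)


def calibration_targets() -> list[CalibrationTarget]:
    """Published probabilities the packaged network reproduces exactly.

    Marginals carry a ±0.005 tolerance, single-evidence conditionals
    ±0.01.  The published physical-activity split (40.4% practice, 58.6%
    no practice) sums to 99.0%; the no-practice figure is the one
    calibrated to.
    """
    m, c = 0.005, 0.01
    return [
        CalibrationTarget("PA", "No", 0.586, m),
        CalibrationTarget("BMI", "Overweight", 0.365, m),
        CalibrationTarget("TG", "Normal", 0.711, m),
        CalibrationTarget("FLI", "Less 30", 0.404, m),
        CalibrationTarget("HbA1c", "Less 6.0", 0.633, m),
        CalibrationTarget("BP", "High", 0.482, m),
        CalibrationTarget("T2D", "Yes", 0.223, m),
        CalibrationTarget("T2D", "Yes", 0.673, c, (("BMI", "Obesity"),)),
        CalibrationTarget("T2D", "Yes", 0.635, c, (("HbA1c", "More 6.0"),)),
        CalibrationTarget("T2D", "Yes", 0.564, c, (("FLI", "More 60"),)),
        CalibrationTarget("T2D", "Yes", 0.372, c, (("PA", "No"),)),
        CalibrationTarget("T2D", "Yes", 0.307, c, (("AGE", "48-62"),)),
    ]


# ---------------------------------------------------------------------------
# Initial (pre-calibration) CPT construction
#
# Non-root CPTs are built from additive log-linear scores: each row's
# distribution is softmax(base + sum of per-parent-state effect vectors).
# Effect sizes are chosen once, on epidemiological grounds (direction and
# rough magnitude of each dependency; every arc carries a clearly nonzero
# effect so the dependency structure is statistically visible at cohort
# sample sizes).  Calibration then tilts these tables to match the
# published probabilities without altering the qualitative effect pattern.

_BASE: dict[str, tuple[float, ...]] = {
    "PA": (0.0, 0.2),
    "DIET": (0.0, 0.0),
    "BMI": (-3.0, 0.1, 0.45, 0.0),
    "TG": (1.4, 0.0, -0.2),
    "FLI": (1.2, 0.2, -0.8),
    "HbA1c": (1.6, 0.0),
    "BP": (0.3, 0.8, -0.6, -1.6),
    "T2D": (-5.2, 0.0),
}

_EFFECTS: dict[str, dict[str, dict[str, tuple[float, ...]]]] = {
    "PA": {"SMOKING": {"No": (0, 0), "Former smoker": (0, 0.1), "Yes": (0, 0.5)}},
    "DIET": {"PA": {"Yes": (0.4, 0), "No": (0, 0.45)}},
    "BMI": {
        "SMOKING": {
            "No": (0, 0, 0, 0),
            "Former smoker": (0, -0.15, 0.1, 0.35),
            "Yes": (0.3, 0.25, 0, -0.2),
        },
        "PA": {"Yes": (0, 0.3, 0, -0.3), "No": (0, 0, 0.05, 0.3)},
    },
    "TG": {
        "DIET": {"Yes": (0.3, 0, -0.3), "No": (0, 0.1, 0.35)},
        "PA": {"Yes": (0.25, 0, -0.25), "No": (0, 0, 0.25)},
        "GENDER": {"Men": (0, 0.1, 0.35), "Women": (0.25, 0, -0.2)},
        "BMI": {
            "Underweight": (0.4, -0.1, -0.5),
            "Normal weight": (0.35, 0, -0.35),
            "Overweight": (0, 0.1, 0.3),
            "Obesity": (-0.3, 0.15, 0.7),
        },
    },
    "FLI": {
        "GENDER": {"Men": (-0.3, 0.1, 0.4), "Women": (0.4, 0, -0.4)},
        "DIET": {"Yes": (0.25, 0, -0.25), "No": (0, 0.05, 0.3)},
        "PA": {"Yes": (0.3, 0, -0.3), "No": (0, 0.05, 0.25)},
        "TG": {
            "Normal": (0.7, 0, -0.8),
            "Limit": (0, 0.25, 0.15),
            "Hyper": (-0.8, 0.1, 1.1),
        },
        "BMI": {
            "Underweight": (2.0, -0.5, -2.5),
            "Normal weight": (1.6, -0.2, -1.8),
            "Overweight": (-0.2, 0.5, 0.1),
            "Obesity": (-1.8, -0.2, 1.9),
        },
    },
    "HbA1c": {
        "GENDER": {"Men": (0, 0.15), "Women": (0.1, 0)},
        "AGE": {"18-32": (0.5, 0), "33-47": (0, 0.1), "48-62": (0, 0.6)},
        "FLI": {"Less 30": (0.4, 0), "30–60": (0, 0.2), "More 60": (0, 0.9)},
        "BMI": {
            "Underweight": (0.4, 0),
            "Normal weight": (0.3, 0),
            "Overweight": (0, 0.35),
            "Obesity": (0, 1.4),
        },
    },
    "BP": {
        "GENDER": {"Men": (0, 0.15, 0.2, 0.2), "Women": (0.3, 0, -0.1, -0.2)},
        "AGE": {
            "18-32": (0.5, 0, -0.4, -0.7),
            "33-47": (0, 0.1, 0, 0),
            "48-62": (-0.4, 0, 0.35, 0.5),
        },
        "HbA1c": {"Less 6.0": (0.2, 0, -0.2, -0.3), "More 6.0": (0, 0.05, 0.3, 0.4)},
        "FLI": {
            "Less 30": (0.5, 0, -0.5, -0.7),
            "30–60": (0, 0.1, 0, 0),
            "More 60": (-0.5, 0, 0.45, 0.6),
        },
    },
    "T2D": {
        "PA": {"Yes": (0, 0), "No": (2.2, 0)},
        "AGE": {"18-32": (0, 0), "33-47": (0.45, 0), "48-62": (0.9, 0)},
        "BMI": {
            "Underweight": (0, 0),
            "Normal weight": (0, 0),
            "Overweight": (1.1, 0),
            "Obesity": (2.6, 0),
        },
        "FLI": {"Less 30": (0, 0), "30–60": (1.4, 0), "More 60": (2.8, 0)},
        "HbA1c": {"Less 6.0": (0, 0), "More 6.0": (3.2, 0)},
    },
}


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    z = np.exp(scores - scores.max(axis=1, keepdims=True))
    return z / z.sum(axis=1, keepdims=True)


def initial_network() -> DiscreteBayesianNetwork:
    """The pre-calibration ground-truth network (deterministic construction)."""
    variables = study_variables()
    by_name = {v.name: v for v in variables}
    dag = reference_dag()
    cpts: dict[str, Cpt] = {}

    p_men = N_MEN / N_COHORT
    roots = {
        "GENDER": (p_men, 1.0 - p_men),
        "SOCIALs": (0.22, 0.46, 0.32),
        "SMOKING": (0.47, 0.22, 0.31),
    }
    for name, row in roots.items():
        cpts[name] = Cpt(name, by_name[name].states, (), (), np.array([row]))

    age_parents = dag.parents("AGE")
    age_pstates = [by_name[p].states for p in age_parents]
    rows = []
    import itertools as _it

    for combo in _it.product(*age_pstates):
        row = np.array(_AGE_TABLE[combo], dtype=float)
        rows.append(row / row.sum())
    cpts["AGE"] = Cpt("AGE", by_name["AGE"].states, age_parents, age_pstates, np.array(rows))

    for name in ("PA", "DIET", "BMI", "TG", "FLI", "HbA1c", "BP", "T2D"):
        parents = dag.parents(name)
        pstates = [by_name[p].states for p in parents]
        r = by_name[name].cardinality
        combos = list(_it.product(*pstates))
        scores = np.tile(np.array(_BASE[name], dtype=float), (len(combos), 1))
        for i, combo in enumerate(combos):
            for parent, value in zip(parents, combo):
                scores[i] += np.array(_EFFECTS[name][parent][value], dtype=float)
        cpts[name] = Cpt(name, by_name[name].states, parents, pstates, _softmax_rows(scores))
    return DiscreteBayesianNetwork(variables, dag, cpts)


def ground_truth_knobs() -> list:
    """The knob set used to calibrate the packaged network."""
    return [
        StateOddsKnob("PA", "No"),
        StateOddsKnob("DIET", "No"),
        StateOddsKnob("BMI", "Overweight"),
        StateOddsKnob("BMI", "Obesity"),
        StateOddsKnob("TG", "Normal"),
        StateOddsKnob("FLI", "Less 30"),
        StateOddsKnob("FLI", "More 60"),
        StateOddsKnob("HbA1c", "Less 6.0"),
        ParentEffectKnob("HbA1c", "More 6.0", "BMI", "Obesity"),
        ParentEffectKnob("HbA1c", "More 6.0", "BMI", "Overweight"),
        ParentEffectKnob("HbA1c", "More 6.0", "FLI", "More 60"),
        ParentEffectKnob("HbA1c", "More 6.0", "AGE", "48-62"),
        ParentEffectKnob("FLI", "More 60", "BMI", "Obesity"),
        ParentEffectKnob("FLI", "More 60", "TG", "Hyper"),
        StateOddsKnob("BP", "High"),
        StateOddsKnob("T2D", "Yes"),
        ParentEffectKnob("T2D", "Yes", "PA", "No"),
        ParentEffectKnob("T2D", "Yes", "AGE", "48-62"),
        ParentEffectKnob("T2D", "Yes", "AGE", "33-47"),
        ParentEffectKnob("T2D", "Yes", "BMI", "Obesity"),
        ParentEffectKnob("T2D", "Yes", "BMI", "Overweight"),
        ParentEffectKnob("T2D", "Yes", "FLI", "More 60"),
        ParentEffectKnob("T2D", "Yes", "FLI", "30–60"),
        ParentEffectKnob("T2D", "Yes", "HbA1c", "More 6.0"),
        # Interaction terms: published conditionals imply that normal HbA1c
        # gates conversion even in otherwise high-risk strata.
        InteractionKnob("T2D", "Yes", (("HbA1c", "Less 6.0"), ("BMI", "Obesity"))),
        InteractionKnob("T2D", "Yes", (("HbA1c", "Less 6.0"), ("FLI", "More 60"))),
        InteractionKnob("T2D", "Yes", (("HbA1c", "Less 6.0"), ("PA", "No"))),
        InteractionKnob("T2D", "Yes", (("HbA1c", "Less 6.0"), ("AGE", "48-62"))),
    ]


def calibrate_ground_truth(seed: int | None = None, trace: list | None = None):
    """Re-run the packaged network's construction: initial CPTs,
    calibration to every published probability, then a centering pass that
    re-balances the solution inside the tolerance bands (the published
    values are only jointly satisfiable near the band edges, see
    docs/methods.md).  Provided for audit and regeneration; the shipped
    JSON is the frozen output of exactly this call.  Takes tens of
    minutes; never executed at import time.
    """
    targets = calibration_targets()
    knobs = ground_truth_knobs()
    net = calibrate(initial_network(), targets, knobs=knobs, seed=seed, trace=trace)
    return center_within_bands(net, targets, knobs)


@functools.lru_cache(maxsize=1)
def _load_packaged() -> DiscreteBayesianNetwork:
    ref = resources.files("prediabn").joinpath("data/ground_truth_network.json")
    with ref.open("r", encoding="utf-8") as fh:
        return DiscreteBayesianNetwork.from_dict(json.load(fh))


def ground_truth_network() -> DiscreteBayesianNetwork:
    """The packaged, calibrated ground-truth network (a defensive copy)."""
    return _load_packaged().copy()


def generate_cohort(n: int = N_COHORT, seed: int | None = None) -> CohortTable:
    """Forward-sample a synthetic cohort from the ground-truth network.

    Columns come out in the canonical variable order; the same seed always
    yields the identical table.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    return ground_truth_network().forward_sample(n, seed)
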