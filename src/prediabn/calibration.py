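"""Calibration of CPTs against printed probability targets.

Given a network with plausible initial CPTs and a list of targets — each
an exact-inference query (a marginal or a conditional of one variable
state, optionally given evidence) with a published value and tolerance —
``calibrate`` adjusts a set of low-dimensional "knobs" until every query
matches its value within tolerance.

A knob is a one-parameter multiplicative tilt of CPT rows:

* :class:`StateOddsKnob` multiplies the odds of one state of a node in
  every row of its CPT (moves that node's marginal);
* :class:`ParentEffectKnob` multiplies the odds of one state only in the
  rows where a given parent takes a given state (moves the strength of
  that parent's effect).

Optimisation is coordinate descent with exact 1-D line searches (bounded
scalar minimisation of the tolerance-scaled squared error, computed by
exact enumeration of the joint), accepting only improving steps, followed
by an optional joint least-squares refinement over all knob parameters —
useful because jointly feasible regions implied by published values can be
narrow corners that axis-aligned moves approach slowly.
"""

from __future__ import annotations

import itertools
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import DiscreteBayesianNetwork
from .errors import CalibrationError, InputError
from .inference import joint_table

__all__ = [
    "CalibrationTarget",
    "StateOddsKnob",
    "ParentEffectKnob",
    "InteractionKnob",
    "calibrate",
    "center_within_bands",
    "calibration_report",
]

_KNOB_BOUND = 12.0


@dataclass(frozen=True)
class CalibrationTarget:
    """One exact-inference query with its published value and tolerance."""

    variable: str
    state: str
    value: float
    tolerance: float
    evidence: tuple[tuple[str, str], ...] = ()

    def label(self) -> str:
        if not self.evidence:
            return f"P({self.variable}={self.state})"
        ev = ", ".join(f"{k}={v}" for k, v in self.evidence)
        return f"P({self.variable}={self.state} | {ev})"


@dataclass(frozen=True)
class StateOddsKnob:
    variable: str
    state: str


@dataclass(frozen=True)
class ParentEffectKnob:
    variable: str
    state: str
    parent: str
    parent_state: str


@dataclass(frozen=True)
class InteractionKnob:
    """Tilts the odds of one state only in rows where *all* the listed
    parent conditions hold — an interaction term, needed when published
    conditionals imply effect modification (e.g. a biomarker stratum that
    gates the outcome)."""

    variable: str
    state: str
    conditions: tuple[tuple[str, str], ...]


def _row_parent_codes(cpt, parent: str) -> np.ndarray:
    """Per-row state index of ``parent`` in the canonical row order."""
    pos = cpt.parent_order.index(parent)
    shape = tuple(len(s) for s in cpt.parent_states)
    return np.indices(shape)[pos].reshape(-1)


class _Machine:
    """Applies a knob-parameter vector to the initial network and evaluates
    the tolerance-scaled residuals of all targets by joint enumeration."""

    def __init__(
        self,
        bn: DiscreteBayesianNetwork,
        targets: Sequence[CalibrationTarget],
        knobs: Sequence[StateOddsKnob | ParentEffectKnob | InteractionKnob],
    ):
        self.base = bn
        self.targets = list(targets)
        self.knobs = list(knobs)
        self.axis = {n: i for i, n in enumerate(bn.names)}
        for t in self.targets:
            bn.variable(t.variable).state_index(t.state)
            for name, state in t.evidence:
                bn.variable(name).state_index(state)
        # Precompute each knob's (node, state column, row mask).
        self._ops = []
        for knob in self.knobs:
            cpt = bn.cpts.get(knob.variable)
            if cpt is None:
                raise InputError(f"knob references unknown variable {knob.variable!r}")
            k = bn.variable(knob.variable).state_index(knob.state)
            if isinstance(knob, ParentEffectKnob):
                conditions = ((knob.parent, knob.parent_state),)
            elif isinstance(knob, InteractionKnob):
                conditions = tuple(knob.conditions)
            else:
                conditions = ()
            mask = np.ones(cpt.n_rows, dtype=bool)
            for parent, pstate in conditions:
                if parent not in cpt.parent_order:
                    raise InputError(
                        f"{parent!r} is not a parent of {knob.variable!r}"
                    )
                pk = bn.variable(parent).state_index(pstate)
                mask &= _row_parent_codes(cpt, parent) == pk
            self._ops.append((knob.variable, k, mask))

    def network(self, deltas: np.ndarray) -> DiscreteBayesianNetwork:
        net = self.base.copy()
        touched = set()
        for (name, k, mask), d in zip(self._ops, deltas):
            if d != 0.0:
                net.cpts[name].table[mask, k] *= float(np.exp(d))
                touched.add(name)
        for name in touched:
            t = net.cpts[name].table
            t /= t.sum(axis=1, keepdims=True)
        return net

    def _tilted_tables(self, deltas: np.ndarray) -> dict[str, np.ndarray]:
        tables = {}
        for (name, k, mask), d in zip(self._ops, deltas):
            if d != 0.0 and name not in tables:
                tables[name] = self.base.cpts[name].table.copy()
        for (name, k, mask), d in zip(self._ops, deltas):
            if d != 0.0:
                tables[name][mask, k] *= float(np.exp(d))
        for name, t in tables.items():
            t /= t.sum(axis=1, keepdims=True)
        return tables

    def _joint(self, deltas: np.ndarray) -> np.ndarray:
        """Joint table in declaration-axis order, without rebuilding the
        network object (calibration's inner loop runs this thousands of
        times)."""
        from .inference import Factor

        tilted = self._tilted_tables(deltas)
        result = Factor((), np.array(1.0))
        for node in self.base.names:
            cpt = self.base.cpts[node]
            table = tilted.get(node, cpt.table)
            names = cpt.parent_order + (node,)
            shape = tuple(len(s) for s in cpt.parent_states) + (cpt.cardinality,)
            result = result.multiply(Factor(names, table.reshape(shape)))
        order = [result.names.index(n) for n in self.base.names]
        return np.transpose(result.table, order)

    def predictions(self, deltas: np.ndarray) -> np.ndarray:
        jt = self._joint(deltas)
        out = np.empty(len(self.targets))
        for i, t in enumerate(self.targets):
            idx: list = [slice(None)] * jt.ndim
            for name, state in t.evidence:
                idx[self.axis[name]] = self.base.variable(name).state_index(state)
            sub = jt[tuple(idx)]
            denom = float(sub.sum())
            tgt_axis = self.axis[t.variable] - sum(
                1 for name, _ in t.evidence if self.axis[name] < self.axis[t.variable]
            )
            k = self.base.variable(t.variable).state_index(t.state)
            num = float(np.take(sub, k, axis=tgt_axis).sum())
            out[i] = num / denom if denom > 0 else np.nan
        return out

    def residuals(self, deltas: np.ndarray) -> np.ndarray:
        """Soft-margin residuals in tolerance units.

        A target contributes ~nothing while it sits inside its tolerance
        band and grows linearly outside it; a small tether term keeps the
        objective smooth and weakly prefers band centres.  Plain squared
        error would be the wrong objective here: when published values are
        only jointly consistent at the edges of their tolerance bands, it
        can prefer one out-of-band target over several in-band ones.
        """
        preds = self.predictions(deltas)
        scaled = np.array(
            [(p - t.value) / t.tolerance for p, t in zip(preds, self.targets)]
        )
        excess = np.sign(scaled) * np.maximum(0.0, np.abs(scaled) - 1.0)
        return excess + 0.01 * scaled

    def sse(self, deltas: np.ndarray) -> float:
        return float((self.residuals(deltas) ** 2).sum())

    def unmet(self, deltas: np.ndarray):
        preds = self.predictions(deltas)
        return [
            (t, float(p))
            for p, t in zip(preds, self.targets)
            if not np.isfinite(p) or abs(p - t.value) > t.tolerance
        ]


def calibrate(
    bn: DiscreteBayesianNetwork,
    targets: Sequence[CalibrationTarget],
    knobs: Sequence[StateOddsKnob | ParentEffectKnob | InteractionKnob] | None = None,
    max_cycles: int = 30,
    refine: bool = True,
    seed: int | None = None,
    trace: list | None = None,
) -> DiscreteBayesianNetwork:
    """Adjust ``knobs`` until every target matches within tolerance.

    Default knobs are one :class:`StateOddsKnob` per distinct
    (variable, state) appearing in the targets — enough for marginal
    targets; conditional-effect targets usually need explicit
    :class:`ParentEffectKnob` entries.  ``trace``, if given, collects the
    objective after every accepted step (it is non-increasing).  Raises
    :class:`CalibrationError` listing the offending targets when the
    tolerances cannot all be met.

    The procedure is deterministic; ``seed`` is accepted for interface
    uniformity and recorded in no way affects the outcome.
    """
    if knobs is None:
        seen = []
        for t in targets:
            key = StateOddsKnob(t.variable, t.state)
            if key not in seen:
                seen.append(key)
        knobs = seen
    machine = _Machine(bn, targets, knobs)
    deltas = np.zeros(len(knobs))
    best = machine.sse(deltas)
    if trace is not None:
        trace.append(best)

    def descent_cycles(deltas, best, cycles):
        for _ in range(cycles):
            if not machine.unmet(deltas):
                break
            improved = False
            for i in range(len(knobs)):
                def objective(x, i=i):
                    trial = deltas.copy()
                    trial[i] = x
                    return machine.sse(trial)

                res = optimize.minimize_scalar(
                    objective,
                    bounds=(-_KNOB_BOUND, _KNOB_BOUND),
                    method="bounded",
                    options={"xatol": 1e-7},
                )
                if res.fun < best - 1e-14:
                    deltas[i] = float(res.x)
                    best = float(res.fun)
                    improved = True
                    if trace is not None:
                        trace.append(best)
            if not improved:
                break
        return deltas, best

    rounds = 3 if refine else 1
    for _ in range(rounds):
        deltas, best = descent_cycles(deltas, best, max_cycles)
        if not machine.unmet(deltas):
            break
        if refine:
            res = optimize.least_squares(
                machine.residuals,
                deltas,
                bounds=(-_KNOB_BOUND, _KNOB_BOUND),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if float((res.fun**2).sum()) < best:
                deltas = res.x
                best = float((res.fun**2).sum())
                if trace is not None:
                    trace.append(best)
            if not machine.unmet(deltas):
                break

    unmet = machine.unmet(deltas)
    if unmet:
        lines = "; ".join(
            f"{t.label()} = {p:.4f}, want {t.value} ± {t.tolerance}" for t, p in unmet
        )
        raise CalibrationError(f"calibration failed for: {lines}", offending=[t for t, _ in unmet])
    return machine.network(deltas)


def center_within_bands(
    bn: DiscreteBayesianNetwork,
    targets: Sequence[CalibrationTarget],
    knobs: Sequence[StateOddsKnob | ParentEffectKnob | InteractionKnob],
    anchor: CalibrationTarget | None = None,
    margin: float = 0.95,
    max_nfev: int = 6000,
) -> DiscreteBayesianNetwork:
    """Re-balance an already-calibrated network inside its tolerance bands.

    When targets are only jointly satisfiable near the edges of their
    bands, ``calibrate`` may park one of them at exactly 100% of its
    tolerance, where the hinge objective exerts no further force.  This
    pass minimises the utilisation of ``anchor`` (default: the first
    no-evidence target) subject to soft walls holding every target below
    ``margin`` of its band, pulling the solution off the boundary.
    Raises :class:`CalibrationError` if the result leaves any band.
    """
    machine = _Machine(bn, targets, knobs)
    if anchor is None:
        anchor = next(t for t in targets if not t.evidence)
    anchor_idx = machine.targets.index(anchor)

    def scaled(d):
        preds = machine.predictions(d)
        return np.array(
            [(p - t.value) / t.tolerance for p, t in zip(preds, machine.targets)]
        )

    def residuals(d):
        s = scaled(d)
        wall = 30.0 * np.maximum(np.abs(s) - margin, 0.0)
        return np.concatenate([wall, [s[anchor_idx]], 0.02 * s])

    res = optimize.least_squares(
        residuals,
        np.zeros(len(machine.knobs)),
        bounds=(-_KNOB_BOUND, _KNOB_BOUND),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    unmet = machine.unmet(res.x)
    if unmet:
        lines = "; ".join(
            f"{t.label()} = {p:.4f}, want {t.value} ± {t.tolerance}" for t, p in unmet
        )
        raise CalibrationError(f"centering left targets out of band: {lines}")
    return machine.network(res.x)


def calibration_report(
    bn: DiscreteBayesianNetwork, targets: Sequence[CalibrationTarget]
):
    """Achieved value vs target for each query, as a DataFrame."""
    import pandas as pd

    machine = _Machine(bn, targets, [])
    preds = machine.predictions(np.zeros(0))
    return pd.DataFrame(
        {
            "query": [t.label() for t in targets],
            "target": [t.value for t in targets],
            "achieved": preds,
            "tolerance": [t.tolerance for t in targets],
            "met": [abs(p - t.value) <= t.tolerance for p, t in zip(preds, targets)],
        }
    )
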