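"""Risk-factor analyses built on exact inference.

Three procedures mirror how an epidemiologist interrogates a fitted
network about a diagnostic variable:

* :func:`rank_markov_blanket` — for each variable in the target's Markov
  blanket, find the single state that maximises the posterior of the
  target state and rank the blanket variables by that maximum ("warning
  factor" ranking).
* :func:`stepwise_trajectory` — instantiate evidence one variable at a
  time along a fixed plan and record the posterior after each step,
  producing the risk trajectories plotted step-vs-probability.
* :func:`scenario_compare` — evaluate the target posterior under named
  evidence sets (intercausal what-if scenarios, possibly outside the
  Markov blanket).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .core import DiscreteBayesianNetwork, markov_blanket
from .errors import BayesNetError, InputError
from .inference import posterior

__all__ = [
    "RankingRow",
    "RankingTable",
    "TrajectoryStep",
    "TrajectoryResult",
    "rank_markov_blanket",
    "stepwise_trajectory",
    "scenario_compare",
    "branching_trajectories",
]


@dataclass(frozen=True)
class RankingRow:
    rank: int
    variable: str
    state: str
    posterior: float


@dataclass(frozen=True)
class RankingTable:
    """Markov-blanket variables ranked by maximised target posterior."""

    target: str
    target_state: str
    baseline: float
    rows: tuple[RankingRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": r.rank,
                    "variable": r.variable,
                    "state": r.state,
                    "posterior": r.posterior,
                }
                for r in self.rows
            ],
            columns=["rank", "variable", "state", "posterior"],
        )

    def order(self) -> tuple[str, ...]:
        return tuple(r.variable for r in self.rows)


def rank_markov_blanket(
    bn: DiscreteBayesianNetwork, target: str, target_state: str
) -> RankingTable:
    """Rank the target's Markov-blanket variables as single-evidence risk factors.

    For each blanket variable V the maximising state is the s achieving the
    largest P(target = target_state | V = s) (ties to the earlier declared
    state); rows are sorted by that posterior, descending, ties broken
    alphabetically by variable name.  An empty blanket yields an empty
    table with the baseline still reported.
    """
    bn.variable(target).state_index(target_state)
    baseline = posterior(bn, target, {})[target_state]
    entries = []
    for name in sorted(markov_blanket(bn.dag, target)):
        best_state, best_p = None, -1.0
        for s in bn.states(name):
            p = posterior(bn, target, {name: s})[target_state]
            if p > best_p:
                best_state, best_p = s, p
        entries.append((best_p, name, best_state))
    entries.sort(key=lambda t: (-t[0], t[1]))
    rows = tuple(
        RankingRow(rank=i + 1, variable=name, state=state, posterior=p)
        for i, (p, name, state) in enumerate(entries)
    )
    return RankingTable(target=target, target_state=target_state, baseline=baseline, rows=rows)


@dataclass(frozen=True)
class TrajectoryStep:
    index: int
    added: tuple[str, str] | None
    posterior: float


@dataclass(frozen=True)
class TrajectoryResult:
    """Posterior of the target state after each cumulative evidence step."""

    target: str
    target_state: str
    branch: str | None
    steps: tuple[TrajectoryStep, ...]

    def probabilities(self) -> tuple[float, ...]:
        return tuple(s.posterior for s in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.index,
                    "variable": s.added[0] if s.added else "",
                    "state": s.added[1] if s.added else "",
                    "posterior": s.posterior,
                }
                for s in self.steps
            ],
            columns=["step", "variable", "state", "posterior"],
        )


def stepwise_trajectory(
    bn: DiscreteBayesianNetwork,
    target: str,
    target_state: str,
    step_plan: Sequence[tuple[str, str]],
    branch: str | None = None,
) -> TrajectoryResult:
    """Accumulate evidence along ``step_plan`` and track the target posterior.

    Step 0 is the no-evidence baseline; step k conditions on the union of
    the first k plan entries, so each recorded value equals an independent
    posterior call with the accumulated evidence.  Inference errors are
    re-raised with the offending step index attached.
    """
    seen: set[str] = set()
    for var, _ in step_plan:
        if var == target:
            raise InputError(f"step plan instantiates the target {target!r}")
        if var in seen:
            raise InputError(f"step plan instantiates {var!r} twice")
        seen.add(var)
    steps = [TrajectoryStep(0, None, posterior(bn, target, {})[target_state])]
    evidence: dict[str, str] = {}
    for i, (var, state) in enumerate(step_plan, start=1):
        evidence[var] = state
        try:
            p = posterior(bn, target, evidence)[target_state]
        except BayesNetError as exc:
            raise type(exc)(f"step {i} ({var}={state}): {exc}") from exc
        steps.append(TrajectoryStep(i, (var, state), p))
    return TrajectoryResult(
        target=target, target_state=target_state, branch=branch, steps=tuple(steps)
    )


def branching_trajectories(
    bn: DiscreteBayesianNetwork,
    target: str,
    target_state: str,
    branch_variable: str,
    steps: Sequence[tuple[str, str]],
) -> list[TrajectoryResult]:
    """One trajectory per state of ``branch_variable`` fixed at step 1.

    This is the layout of the published risk figures: the first step picks
    the branch (e.g. each BMI category), the remaining steps are shared.
    """
    out = []
    for s in bn.states(branch_variable):
        plan = [(branch_variable, s), *steps]
        out.append(stepwise_trajectory(bn, target, target_state, plan, branch=s))
    return out


def scenario_compare(
    bn: DiscreteBayesianNetwork,
    target: str,
    target_state: str,
    scenarios: Mapping[str, Mapping[str, str]],
) -> pd.Series:
    """Posterior of the target state under each named evidence set."""
    values = {
        name: posterior(bn, target, dict(ev))[target_state]
        for name, ev in scenarios.items()
    }
    return pd.Series(values, name=f"P({target}={target_state})")


def plot_trajectories(trajectories: Sequence[TrajectoryResult], path=None, title=None):
    """Step-vs-probability plot of one or more trajectories (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for t in trajectories:
        xs = [s.index for s in t.steps]
        ys = [s.posterior for s in t.steps]
        ax.plot(xs, ys, marker="o", label=t.branch or "trajectory")
    ax.set_xlabel("step")
    ax.set_ylabel(f"P({trajectories[0].target} = {trajectories[0].target_state})")
    ax.set_ylim(0, 1)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
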