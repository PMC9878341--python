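"""Packaged step plans for the published risk trajectories.

Each plan is data, not code: a YAML document naming the target variable
and state, the branch variable fixed at step 1, and the shared later
steps.  Shipping them as config files makes the figure analyses
re-runnable verbatim from the CLI.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import InputError

__all__ = ["StepPlan", "load_plan", "packaged_plans", "packaged_plan"]

from dataclasses import dataclass


def _coerce(value) -> str:
    # YAML 1.1 reads bare Yes/No as booleans; map them back to the labels.
    if value is True:
        return "Yes"
    if value is False:
        return "No"
    return str(value)


@dataclass(frozen=True)
class StepPlan:
    name: str
    target: str
    target_state: str
    branch_variable: str | None
    steps: tuple[tuple[str, str], ...]


def _parse(doc: dict, fallback_name: str) -> StepPlan:
    try:
        steps = tuple((_coerce(v), _coerce(s)) for v, s in doc.get("steps", []))
        return StepPlan(
            name=str(doc.get("name", fallback_name)),
            target=_coerce(doc["target"]),
            target_state=_coerce(doc["target_state"]),
            branch_variable=_coerce(doc["branch_variable"]) if doc.get("branch_variable") else None,
            steps=steps,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise InputError(f"malformed step plan {fallback_name!r}: {exc}") from exc


def load_plan(path) -> StepPlan:
    p = Path(path)
    return _parse(yaml.safe_load(p.read_text(encoding="utf-8")), p.stem)


def packaged_plans() -> dict[str, StepPlan]:
    """All step plans shipped with the package, keyed by name."""
    out = {}
    root = resources.files("prediabn").joinpath("data/plans")
    for ref in sorted(root.iterdir(), key=lambda r: r.name):
        if ref.name.endswith(".yaml"):
            plan = _parse(yaml.safe_load(ref.read_text(encoding="utf-8")), Path(ref.name).stem)
            out[plan.name] = plan
    return out


def packaged_plan(name: str) -> StepPlan:
    plans = packaged_plans()
    if name not in plans:
        raise InputError(f"no packaged plan {name!r}; have {sorted(plans)}")
    return plans[name]
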