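"""Network and cohort serialisation.

Networks round-trip losslessly through a JSON document (variables with
state lists, edges, CPT rows keyed by '|'-joined parent-state tuples in
canonical row order).  A read-only parser for the classic BIF (Bayesian
Interchange Format) dialect is provided for interoperability.  Cohort
tables round-trip through UTF-8 CSV with a header row.
"""

from __future__ import annotations

import json
import re
from collections.abc import Sequence
from pathlib import Path

import numpy as np

from .core import CategoricalVariable, CohortTable, Cpt, Dag, DiscreteBayesianNetwork
from .errors import InputError

__all__ = [
    "write_network",
    "read_network",
    "read_network_bif",
    "read_cohort",
    "write_cohort",
]


def write_network(bn: DiscreteBayesianNetwork, path) -> None:
    doc = bn.to_dict()
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_network(path) -> DiscreteBayesianNetwork:
    p = Path(path)
    if p.suffix.lower() == ".bif":
        return read_network_bif(p)
    try:
        doc = json.loads(p.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise InputError(f"{p}: not valid JSON ({exc})") from exc
    return DiscreteBayesianNetwork.from_dict(doc)


_BIF_VARIABLE = re.compile(
    r"variable\s+(\S+)\s*\{[^{}]*type\s+discrete\s*\[\s*\d+\s*\]\s*\{([^}]*)\}\s*;[^{}]*\}",
    re.DOTALL,
)
_BIF_PROBABILITY = re.compile(
    r"probability\s*\(\s*([^)|]+?)\s*(?:\|\s*([^)]+?)\s*)?\)\s*\{([^}]*)\}", re.DOTALL
)


def read_network_bif(path) -> DiscreteBayesianNetwork:
    """Parse a discrete network from BIF text (read-only support).

    Variable declaration order in the file becomes the network's variable
    order; CPT parent order is normalised to that declaration order.
    """
    text = Path(path).read_text(encoding="utf-8")
    text = re.sub(r"//[^\n]*", "", text)

    variables: list[CategoricalVariable] = []
    for m in _BIF_VARIABLE.finditer(text):
        states = tuple(s.strip() for s in m.group(2).split(",") if s.strip())
        variables.append(CategoricalVariable(m.group(1), states))
    if not variables:
        raise InputError(f"{path}: no variable declarations found")
    by_name = {v.name: v for v in variables}
    order = {v.name: i for i, v in enumerate(variables)}

    cpts: dict[str, Cpt] = {}
    edges: list[tuple[str, str]] = []
    for m in _BIF_PROBABILITY.finditer(text):
        child = m.group(1).strip()
        if child not in by_name:
            raise InputError(f"{path}: probability block for undeclared node {child!r}")
        raw_parents = (
            [p.strip() for p in m.group(2).split(",")] if m.group(2) else []
        )
        for p in raw_parents:
            if p not in by_name:
                raise InputError(f"{path}: undeclared parent {p!r} of {child!r}")
            edges.append((p, child))
        parent_order = tuple(sorted(raw_parents, key=order.__getitem__))
        parent_states = tuple(by_name[p].states for p in parent_order)
        body = m.group(3)
        r = by_name[child].cardinality
        q = int(np.prod([len(s) for s in parent_states], dtype=np.int64)) if parent_order else 1
        table = np.full((q, r), np.nan)

        if not raw_parents:
            tm = re.search(r"table([^;]*);", body)
            if tm is None:
                raise InputError(f"{path}: root node {child!r} lacks a table row")
            table[0] = [float(x) for x in tm.group(1).split(",")]
        else:
            radix = {p: len(by_name[p].states) for p in parent_order}
            for row_m in re.finditer(r"\(([^)]*)\)\s*([^;]*);", body):
                values = [v.strip() for v in row_m.group(1).split(",")]
                if len(values) != len(raw_parents):
                    raise InputError(
                        f"{path}: row of {child!r} names {len(values)} parent states, "
                        f"expected {len(raw_parents)}"
                    )
                assign = dict(zip(raw_parents, values))
                idx = 0
                for p in parent_order:
                    idx = idx * radix[p] + by_name[p].state_index(assign[p])
                table[idx] = [float(x) for x in row_m.group(2).split(",")]
        if np.isnan(table).any():
            raise InputError(f"{path}: CPT of {child!r} has unspecified rows")
        cpts[child] = Cpt(child, by_name[child].states, parent_order, parent_states, table)

    missing = [v.name for v in variables if v.name not in cpts]
    if missing:
        raise InputError(f"{path}: no probability block for nodes {missing}")
    dag = Dag([v.name for v in variables], edges)
    return DiscreteBayesianNetwork(variables, dag, cpts)


def write_cohort(table: CohortTable, path) -> None:
    table.write_csv(path)


def read_cohort(path, variables: Sequence[CategoricalVariable] | None = None) -> CohortTable:
    return CohortTable.read_csv(path, variables)
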