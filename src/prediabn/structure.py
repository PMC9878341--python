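"""Score-based structure learning under expert block constraints.

The DAG is learned by greedy hill climbing: starting from the empty graph,
repeatedly apply the single arc addition, deletion or reversal that most
improves a decomposable score, until no move improves it.  The score is
the Akaike Information Criterion in its "higher is better" form,

    AIC(G; D) = logL_hat(D | G) - k(G),
    k(G) = sum_i (r_i - 1) * q_i,

with ``r_i`` the number of states of node i and ``q_i`` its number of
parent configurations.  Expert knowledge enters as an ordered partition of
the variables into blocks; every arc from a later block to an earlier
block is blacklisted, restricting model selection to structures compatible
with the assumed causal order.

Because a single greedy run from one dataset is a point estimate of the
structure, arc support is quantified by nonparametric bootstrap model
averaging: the learner is re-run on ``R`` resamples (size n, drawn with
replacement) and each arc's strength is its inclusion frequency; arcs at
or above a strength threshold, oriented by majority direction, form the
consensus network.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CohortTable, Dag
from .errors import InputError

__all__ = [
    "BlockOrdering",
    "Blacklist",
    "ArcStrengthTable",
    "HillClimbConfig",
    "blacklist_from_blocks",
    "aic_score",
    "hill_climb",
    "bootstrap_arc_strength",
    "averaged_network",
]


# ---------------------------------------------------------------------------
# Expert blocks and blacklists


@dataclass(frozen=True)
class BlockOrdering:
    """Ordered partition of the variables into causal blocks."""

    blocks: tuple[frozenset[str], ...]

    def __init__(self, blocks: Iterable[Iterable[str]]):
        object.__setattr__(
            self, "blocks", tuple(frozenset(str(v).strip() for v in b) for b in blocks)
        )
        seen: set[str] = set()
        for b in self.blocks:
            if b & seen:
                raise InputError(f"blocks overlap on {sorted(b & seen)}")
            seen |= b

    @property
    def variables(self) -> frozenset[str]:
        return frozenset().union(*self.blocks) if self.blocks else frozenset()

    def block_of(self, name: str) -> int:
        for i, b in enumerate(self.blocks):
            if name in b:
                return i
        raise InputError(f"variable {name!r} belongs to no block")


@dataclass(frozen=True)
class Blacklist:
    """Set of forbidden directed arcs."""

    forbidden: frozenset[tuple[str, str]]

    def __init__(self, forbidden: Iterable[tuple[str, str]] = ()):
        pairs = [tuple(p) for p in forbidden]
        if len(set(pairs)) != len(pairs):
            raise InputError("a pair appears twice in the blacklist")
        object.__setattr__(self, "forbidden", frozenset(pairs))

    def allows(self, u: str, v: str) -> bool:
        return (u, v) not in self.forbidden

    def __len__(self) -> int:
        return len(self.forbidden)


def blacklist_from_blocks(blocks: BlockOrdering) -> Blacklist:
    """Forbid every arc from a strictly later block to an earlier block.

    Within-block arcs and forward arcs remain permitted.
    """
    forbidden = []
    for i, later in enumerate(blocks.blocks):
        for j in range(i):
            for u in sorted(later):
                for v in sorted(blocks.blocks[j]):
                    forbidden.append((u, v))
    return Blacklist(forbidden)


# ---------------------------------------------------------------------------
# Decomposable AIC scoring on integer-coded data


class _ScoreCache:
    """Per-dataset cache of family AIC terms.

    ``family(child, parents)`` returns  logL_hat(child | parents) - (r-1) q,
    computed from a contingency table built by mixed-radix coding +
    bincount.  Zero-count parent configurations contribute nothing to the
    likelihood but still count toward q (the penalty uses the full
    parent-state product, matching the parameter count of the CPT).
    """

    def __init__(self, codes: np.ndarray, cards: Sequence[int]):
        if codes.shape[0] < 1:
            raise InputError("empty data")
        self.codes = codes
        self.cards = tuple(int(c) for c in cards)
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def family(self, child: int, parents: frozenset[int]) -> float:
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        r = self.cards[child]
        q = 1
        rows = np.zeros(self.codes.shape[0], dtype=np.int64)
        for p in sorted(parents):
            rows = rows * self.cards[p] + self.codes[:, p]
            q *= self.cards[p]
        cell = rows * r + self.codes[:, child]
        njk = np.bincount(cell, minlength=q * r).reshape(q, r)
        nj = njk.sum(axis=1)
        nz = njk > 0
        ll = float((njk[nz] * np.log(njk[nz])).sum())
        nzj = nj > 0
        ll -= float((nj[nzj] * np.log(nj[nzj])).sum())
        score = ll - (r - 1) * q
        self._cache[key] = score
        return score


def aic_score(dag: Dag, data: CohortTable) -> float:
    """AIC of ``dag`` for the complete-case ``data`` (higher is better)."""
    if data.has_missing():
        raise InputError("AIC scoring requires complete data")
    names = list(dag.nodes)
    codes = data.encoded(names)
    cards = [len(data.domains[n]) for n in names]
    cache = _ScoreCache(codes, cards)
    idx = {n: i for i, n in enumerate(names)}
    return sum(
        cache.family(idx[n], frozenset(idx[p] for p in dag.parents(n))) for n in names
    )


# ---------------------------------------------------------------------------
# Hill climbing


@dataclass(frozen=True)
class HillClimbConfig:
    """Greedy-search settings.

    ``epsilon`` is the strict-improvement margin (prevents cycling on
    score-equivalent moves); ``restarts`` adds optional random restarts from
    perturbed graphs (off by default: a single run from the empty graph is
    the canonical procedure).
    """

    score: str = "aic"
    epsilon: float = 1e-9
    max_iter: int = 10_000
    restarts: int = 0
    restart_seed: int | None = None

    def __post_init__(self):
        if self.score != "aic":
            raise InputError(f"unknown score {self.score!r}; only 'aic' is built in")


def _hill_climb_codes(
    codes: np.ndarray,
    names: Sequence[str],
    cards: Sequence[int],
    blacklist: Blacklist,
    start: Dag | None,
    config: HillClimbConfig,
) -> Dag:
    cache = _ScoreCache(codes, cards)
    idx = {n: i for i, n in enumerate(names)}
    dag = start.copy() if start is not None else Dag(names)

    def fam(node: str, parents: Iterable[str]) -> float:
        return cache.family(idx[node], frozenset(idx[p] for p in parents))

    current = {n: set(dag.parents(n)) for n in names}
    fam_score = {n: fam(n, current[n]) for n in names}

    for _ in range(config.max_iter):
        best_delta = config.epsilon
        best_move = None
        # Pair-major enumeration in declaration order; within a pair the
        # candidate moves are tried as add, then delete, then reverse.
        for u in names:
            for v in names:
                if u == v:
                    continue
                if not dag.has_edge(u, v):
                    if blacklist.allows(u, v) and not dag.has_directed_path(v, u):
                        delta = fam(v, current[v] | {u}) - fam_score[v]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("add", u, v)
                else:
                    delta = fam(v, current[v] - {u}) - fam_score[v]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("delete", u, v)
                    if blacklist.allows(v, u):
                        dag.remove_edge(u, v)
                        acyclic = not dag.has_directed_path(u, v)
                        dag.add_edge(u, v)
                        if acyclic:
                            delta = (
                                fam(u, current[u] | {v})
                                - fam_score[u]
                                + fam(v, current[v] - {u})
                                - fam_score[v]
                            )
                            if delta > best_delta:
                                best_delta, best_move = delta, ("reverse", u, v)
        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            dag.add_edge(u, v)
            current[v].add(u)
            fam_score[v] = fam(v, current[v])
        elif op == "delete":
            dag.remove_edge(u, v)
            current[v].discard(u)
            fam_score[v] = fam(v, current[v])
        else:
            dag.reverse_edge(u, v)
            current[v].discard(u)
            current[u].add(v)
            fam_score[u] = fam(u, current[u])
            fam_score[v] = fam(v, current[v])
    return dag


def _validate_start(start: Dag, blacklist: Blacklist) -> None:
    for u, v in start.edges:
        if not blacklist.allows(u, v):
            raise InputError(f"start graph contains blacklisted arc {u!r} -> {v!r}")


def hill_climb(
    data: CohortTable,
    blacklist: Blacklist | None = None,
    start: Dag | None = None,
    config: HillClimbConfig | None = None,
) -> Dag:
    """Greedy search for a local AIC optimum over DAGs.

    Deterministic given the data and configuration: candidate moves are
    enumerated in a fixed order and a move is taken only on strict score
    improvement.  The returned DAG contains no blacklisted arc and no
    single-arc neighbour of it scores higher.
    """
    if data.has_missing():
        raise InputError("structure learning requires complete data")
    blacklist = blacklist or Blacklist()
    config = config or HillClimbConfig()
    names = list(data.columns)
    if start is not None:
        _validate_start(start, blacklist)
    codes = data.encoded(names)
    cards = [len(data.domains[n]) for n in names]
    best = _hill_climb_codes(codes, names, cards, blacklist, start, config)
    if config.restarts:
        cache = _ScoreCache(codes, cards)
        idx = {n: i for i, n in enumerate(names)}

        def total(dag: Dag) -> float:
            return sum(
                cache.family(idx[n], frozenset(idx[p] for p in dag.parents(n)))
                for n in names
            )

        rng = np.random.default_rng(config.restart_seed)
        best_score = total(best)
        for _ in range(config.restarts):
            seed_dag = Dag(names)
            order = rng.permutation(len(names))
            for a in range(len(names)):
                for b in range(a + 1, len(names)):
                    u, v = names[order[a]], names[order[b]]
                    if rng.random() < 0.15 and blacklist.allows(u, v):
                        try:
                            seed_dag.add_edge(u, v)
                        except InputError:
                            pass
            cand = _hill_climb_codes(codes, names, cards, blacklist, seed_dag, config)
            if total(cand) > best_score + config.epsilon:
                best, best_score = cand, total(cand)
    return best


# ---------------------------------------------------------------------------
# Bootstrap model averaging


@dataclass
class ArcStrengthTable:
    """Directed inclusion counts over bootstrap replicates.

    ``strength(u, v)`` is the fraction of replicates containing the arc in
    either direction (so ``strength(u, v) == strength(v, u)``);
    ``direction_prob(u, v)`` is, among those, the fraction oriented u -> v.
    """

    variables: tuple[str, ...]
    counts: dict[tuple[str, str], int]
    replicates: int

    def strength(self, u: str, v: str) -> float:
        return (self.counts.get((u, v), 0) + self.counts.get((v, u), 0)) / self.replicates

    def direction_prob(self, u: str, v: str) -> float:
        both = self.counts.get((u, v), 0) + self.counts.get((v, u), 0)
        if both == 0:
            return 0.5
        return self.counts.get((u, v), 0) / both

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "from": u,
                "to": v,
                "strength": self.strength(u, v),
                "direction_prob": self.direction_prob(u, v),
            }
            for (u, v) in sorted(self.counts)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction_prob"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bootstrap_arc_strength(
    data: CohortTable,
    replicates: int = 500,
    blacklist: Blacklist | None = None,
    seed: int | None = None,
    config: HillClimbConfig | None = None,
) -> ArcStrengthTable:
    """Arc inclusion frequencies over ``replicates`` bootstrap re-learns.

    Each replicate draws n records with replacement (seeded), re-runs the
    hill climber under the same blacklist and records the learned arcs.
    Identical seeds give identical tables.
    """
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    if data.has_missing():
        raise InputError("structure learning requires complete data")
    blacklist = blacklist or Blacklist()
    config = config or HillClimbConfig()
    names = list(data.columns)
    codes = data.encoded(names)
    cards = [len(data.domains[n]) for n in names]
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    n = codes.shape[0]
    for _ in range(replicates):
        take = rng.integers(0, n, size=n)
        dag = _hill_climb_codes(codes[take], names, cards, blacklist, None, config)
        for arc in dag.edges:
            counts[arc] = counts.get(arc, 0) + 1
    return ArcStrengthTable(tuple(names), counts, replicates)


def averaged_network(
    strengths: ArcStrengthTable, threshold: float = 0.85
) -> Dag:
    """Consensus DAG: arcs with strength >= threshold, majority orientation.

    Direction ties (exactly 0.5) orient from the earlier declared variable
    to the later.  If the kept arcs form a cycle, arcs are dropped in
    increasing strength order until the graph is acyclic.
    """
    if not (0.0 < threshold <= 1.0):
        raise InputError("threshold must lie in (0, 1]")
    order = {n: i for i, n in enumerate(strengths.variables)}
    undirected = {tuple(sorted(arc, key=order.__getitem__)) for arc in strengths.counts}
    kept: list[tuple[str, str, float]] = []
    for u, v in undirected:
        s = strengths.strength(u, v)
        if s >= threshold:
            d_uv = strengths.direction_prob(u, v)
            if d_uv > 0.5 or (d_uv == 0.5 and order[u] < order[v]):
                kept.append((u, v, s))
            else:
                kept.append((v, u, s))
    # strongest first; ties by endpoint declaration order for determinism
    kept.sort(key=lambda t: (-t[2], order[t[0]], order[t[1]]))
    while True:
        dag = Dag(strengths.variables)
        cyclic: list[tuple[str, str, float]] = []
        for u, v, s in kept:
            try:
                dag.add_edge(u, v)
            except InputError:
                cyclic.append((u, v, s))
        if not cyclic:
            return dag
        # drop the globally weakest arc involved in a conflict
        weakest = min(cyclic, key=lambda t: t[2])
        kept.remove(weakest)
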