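"""Cross-validated model validation.

``cross_validate`` runs k-fold cross-validation of the full learning
pipeline (block blacklist, hill climbing, Bayesian parameter fitting) with
a log-likelihood loss: the expected loss is the mean negative natural-log
joint probability per held-out record.  For a well-specified model and
large n this converges to the joint entropy of the generating
distribution, which is why the synthetic-cohort tests compare it against
the exactly enumerated entropy of the ground-truth network.

``feature_scores`` evaluates the same folds as a per-feature classifier:
each held-out record's variable V is predicted from the other variables
via P(V | rest), scored by one-vs-rest AUC per state and by argmax
accuracy per variable.  P(V | rest) is computed in closed form from the
families touching V (its own CPT and its children's CPTs) — by the global
Markov property this equals the full-evidence posterior produced by
variable elimination, and the test suite asserts that equality.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import CohortTable, Dag, DiscreteBayesianNetwork
from .errors import InputError
from .parameters import PriorSpec, fit_bayes
from .structure import (
    Blacklist,
    BlockOrdering,
    HillClimbConfig,
    blacklist_from_blocks,
    hill_climb,
)

__all__ = [
    "LearnerConfig",
    "CvResult",
    "FeatureScoreTable",
    "cross_validate",
    "feature_scores",
]


@dataclass(frozen=True)
class LearnerConfig:
    """Settings for one train-fold pipeline run.

    ``fixed_dag`` skips structure learning (faster, but no longer honest
    CV of the full pipeline); it is off by default.
    """

    blocks: BlockOrdering | None = None
    iss: float = 1.0
    hc: HillClimbConfig = field(default_factory=HillClimbConfig)
    fixed_dag: Dag | None = None

    def blacklist(self) -> Blacklist:
        return blacklist_from_blocks(self.blocks) if self.blocks else Blacklist()


@dataclass(frozen=True)
class CvResult:
    """Expected log-likelihood loss from k-fold cross-validation."""

    expected_loss: float
    fold_losses: tuple[float, ...]
    fold_sizes: tuple[int, ...]
    seed: int | None


@dataclass(frozen=True)
class FeatureScoreTable:
    """Per-(variable, state) AUC and per-variable accuracy."""

    frame: pd.DataFrame  # columns: variable, state, auc, accuracy

    def auc(self, variable: str, state: str) -> float:
        sel = self.frame[(self.frame.variable == variable) & (self.frame.state == state)]
        if sel.empty:
            raise InputError(f"no score for {variable!r} = {state!r}")
        return float(sel.auc.iloc[0])

    def accuracy(self, variable: str) -> float:
        sel = self.frame[self.frame.variable == variable]
        if sel.empty:
            raise InputError(f"no score for {variable!r}")
        return float(sel.accuracy.iloc[0])


def _folds(n: int, k: int, seed: int | None) -> list[np.ndarray]:
    if k < 2:
        raise InputError("k must be >= 2")
    if n < k:
        raise InputError("need at least k records")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def _subtable(data: CohortTable, idx: np.ndarray) -> CohortTable:
    return CohortTable(
        data.frame.iloc[idx].reset_index(drop=True),
        data.domains,
        missing_marker=data.missing_marker,
        validate=False,
    )


def _fit_fold(train: CohortTable, config: LearnerConfig) -> DiscreteBayesianNetwork:
    dag = config.fixed_dag
    if dag is None:
        dag = hill_climb(train, blacklist=config.blacklist(), config=config.hc)
    return fit_bayes(dag, train, PriorSpec(config.iss))


def cross_validate(
    data: CohortTable,
    k: int = 10,
    config: LearnerConfig | None = None,
    seed: int | None = None,
) -> CvResult:
    """k-fold CV of the learning pipeline with log-likelihood loss.

    The fold split is a seeded random partition (no stratification).  Each
    fold's loss is the mean -ln joint probability of its held-out records
    under the network learned from the remaining folds; the expected loss
    aggregates per record, i.e. weights folds by size.  Bayesian smoothing
    keeps every held-out record's probability strictly positive, so the
    loss is always finite.
    """
    if data.has_missing():
        raise InputError("cross-validation requires complete data")
    config = config or LearnerConfig()
    folds = _folds(data.n, k, seed)
    fold_losses, fold_sizes = [], []
    total = 0.0
    for test_idx in folds:
        mask = np.ones(data.n, dtype=bool)
        mask[test_idx] = False
        bn = _fit_fold(_subtable(data, np.flatnonzero(mask)), config)
        test = _subtable(data, test_idx)
        ll = bn.log_likelihood(test)
        fold_losses.append(-ll / test.n)
        fold_sizes.append(test.n)
        total += -ll
    return CvResult(
        expected_loss=total / data.n,
        fold_losses=tuple(fold_losses),
        fold_sizes=tuple(fold_sizes),
        seed=seed,
    )


def _full_evidence_posteriors(
    bn: DiscreteBayesianNetwork, codes: np.ndarray, variable: str
) -> np.ndarray:
    """P(variable | all other variables) per record, shape (n, r).

    Closed form: only the families containing ``variable`` (its own CPT and
    its children's) depend on it, so the posterior is their product over
    the variable's states, normalised per record.
    """
    col = {n: j for j, n in enumerate(bn.names)}
    n = codes.shape[0]
    r = bn.variable(variable).cardinality
    log_score = np.zeros((n, r))
    members = [variable, *bn.dag.children(variable)]
    for child in members:
        cpt = bn.cpts[child]
        for k in range(r):
            rows = np.zeros(n, dtype=np.int64)
            for parent, pstates in zip(cpt.parent_order, cpt.parent_states):
                pcode = np.full(n, k) if parent == variable else codes[:, col[parent]]
                rows = rows * len(pstates) + pcode
            obs = np.full(n, k) if child == variable else codes[:, col[child]]
            log_score[:, k] += np.log(cpt.table[rows, obs])
    log_score -= log_score.max(axis=1, keepdims=True)
    p = np.exp(log_score)
    return p / p.sum(axis=1, keepdims=True)


def feature_scores(
    data: CohortTable,
    k: int = 10,
    config: LearnerConfig | None = None,
    seed: int | None = None,
    return_posteriors: bool = False,
):
    """Held-out per-feature AUC and accuracy over the same k folds as CV.

    AUC is one-vs-rest with the posterior probability as score (midrank
    ties); accuracy is the fraction of records whose argmax-predicted state
    matches the observed one — a per-variable quantity repeated on each of
    its state rows.  With ``return_posteriors`` the per-record held-out
    posteriors are also returned as a DataFrame (one column per
    variable=state), a hook for external classifier comparisons.
    """
    if data.has_missing():
        raise InputError("feature scoring requires complete data")
    config = config or LearnerConfig()
    folds = _folds(data.n, k, seed)
    post: dict[str, np.ndarray] = {}
    obs_codes = np.empty((data.n, len(data.columns)), dtype=np.int64)
    first = True
    for test_idx in folds:
        mask = np.ones(data.n, dtype=bool)
        mask[test_idx] = False
        bn = _fit_fold(_subtable(data, np.flatnonzero(mask)), config)
        test = _subtable(data, test_idx)
        codes = test.encoded(bn.names)
        if first:
            for name in bn.names:
                post[name] = np.empty((data.n, bn.variable(name).cardinality))
            first = False
        obs_codes[test_idx] = codes
        for name in bn.names:
            post[name][test_idx] = _full_evidence_posteriors(bn, codes, name)

    names = list(post)
    col = {n: j for j, n in enumerate(names)}
    rows = []
    for name in names:
        states = data.domains[name]
        y = obs_codes[:, col[name]]
        acc = float(np.mean(np.argmax(post[name], axis=1) == y))
        for j, s in enumerate(states):
            truth = (y == j).astype(int)
            if truth.min() == truth.max():  # single class observed
                auc = float("nan")
            else:
                auc = float(roc_auc_score(truth, post[name][:, j]))
            rows.append({"variable": name, "state": s, "auc": auc, "accuracy": acc})
    table = FeatureScoreTable(pd.DataFrame(rows, columns=["variable", "state", "auc", "accuracy"]))
    if not return_posteriors:
        return table
    frames = {
        f"{name}={s}": post[name][:, j]
        for name in names
        for j, s in enumerate(data.domains[name])
    }
    return table, pd.DataFrame(frames)
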