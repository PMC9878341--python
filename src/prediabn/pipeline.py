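"""End-to-end pipeline: cohort CSV in, analysis artifacts out.

Stages: block blacklist -> bootstrap model averaging (hill climbing on
resamples) -> consensus DAG -> Bayesian parameter fitting -> Markov
blanket risk ranking -> packaged trajectory plans -> cross-validation.
A manifest records the configuration, its hash, the seed and per-stage
wall-clock timings so two runs with identical config and seed produce
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .cohort import study_blocks, study_variables
from .core import CohortTable
from .errors import InputError
from .io import read_cohort, write_network
from .parameters import PriorSpec, fit_bayes
from .plans import packaged_plans
from .risk import branching_trajectories, rank_markov_blanket, stepwise_trajectory
from .structure import (
    BlockOrdering,
    HillClimbConfig,
    averaged_network,
    blacklist_from_blocks,
    bootstrap_arc_strength,
)
from .validation import LearnerConfig, cross_validate

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Defaults mirror the reference analysis: the four expert blocks,
    AIC hill climbing, 500-replicate model averaging at threshold 0.85,
    Dirichlet fitting with iss = 1 and 10-fold CV."""

    input_csv: str | None = None
    out_dir: str = "prediabn-out"
    blocks: list[list[str]] | None = None  # None -> the study's four blocks
    score: str = "aic"
    replicates: int = 500
    threshold: float = 0.85
    iss: float = 1.0
    cv_folds: int = 10
    seed: int | None = None
    target: str = "T2D"
    target_state: str = "Yes"
    run_cv: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def block_ordering(self) -> BlockOrdering:
        if self.blocks is None:
            return study_blocks()
        return BlockOrdering(self.blocks)

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _load_cohort(path) -> CohortTable:
    table = read_cohort(path)
    study = {v.name: v for v in study_variables()}
    if set(table.columns) == set(study):
        # canonical state order for the study domain
        return CohortTable(
            table.frame[list(study)], {n: v.states for n, v in study.items()}
        )
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write artifacts under ``config.out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    if config.input_csv is None:
        raise InputError("pipeline config needs input_csv")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 3)

        return _Timer()

    with stage("load"):
        data = _load_cohort(config.input_csv)
        manifest["n_records"] = data.n
        manifest["columns"] = list(data.columns)

    with stage("blacklist"):
        ordering = config.block_ordering()
        uncovered = set(data.columns) - ordering.variables
        if uncovered:
            raise InputError(f"variables in no block: {sorted(uncovered)}")
        blacklist = blacklist_from_blocks(ordering)
        manifest["forbidden_arcs"] = len(blacklist)

    with stage("model_averaging"):
        hc = HillClimbConfig(score=config.score)
        strengths = bootstrap_arc_strength(
            data,
            replicates=config.replicates,
            blacklist=blacklist,
            seed=config.seed,
            config=hc,
        )
        strengths.write_csv(out / "arc_strengths.csv")
        dag = averaged_network(strengths, config.threshold)
        (out / "learned_dag.json").write_text(
            json.dumps({"nodes": list(dag.nodes), "edges": [list(e) for e in dag.edges]}, indent=1)
        )
        manifest["learned_arcs"] = dag.n_edges

    with stage("fit"):
        bn = fit_bayes(dag, data, PriorSpec(config.iss))
        write_network(bn, out / "fitted_network.json")

    with stage("ranking"):
        if config.target in bn.names:
            ranking = rank_markov_blanket(bn, config.target, config.target_state)
            frame = ranking.to_frame()
            frame.insert(0, "baseline", ranking.baseline)
            frame.to_csv(out / "ranking.csv", index=False)
            manifest["baseline_posterior"] = ranking.baseline

    with stage("trajectories"):
        applicable = {
            name: plan
            for name, plan in packaged_plans().items()
            if plan.target in bn.names
            and all(v in bn.names for v, _ in plan.steps)
            and (plan.branch_variable is None or plan.branch_variable in bn.names)
        }
        for name, plan in applicable.items():
            if plan.branch_variable:
                results = branching_trajectories(
                    bn, plan.target, plan.target_state, plan.branch_variable, plan.steps
                )
            else:
                results = [stepwise_trajectory(bn, plan.target, plan.target_state, plan.steps)]
            frames = []
            for r in results:
                f = r.to_frame()
                f.insert(0, "branch", r.branch or "")
                frames.append(f)
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(
                out / f"trajectory_{name}.csv", index=False
            )
        manifest["trajectory_plans"] = sorted(applicable)

    if config.run_cv:
        with stage("cross_validation"):
            cv = cross_validate(
                data,
                k=config.cv_folds,
                config=LearnerConfig(blocks=ordering, iss=config.iss),
                seed=config.seed,
            )
            (out / "cv.json").write_text(
                json.dumps(
                    {
                        "expected_loss": cv.expected_loss,
                        "fold_losses": list(cv.fold_losses),
                        "fold_sizes": list(cv.fold_sizes),
                        "seed": cv.seed,
                    },
                    indent=1,
                )
            )
            manifest["cv_expected_loss"] = cv.expected_loss

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
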