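"""Simulation-study driver: generate cases, summarize, rank methods.

Each case draws a coalescent tree, simulates an alignment, builds a
pseudo-posterior around the truth, runs every configured summary method
and records the error measures.  Likelihood measures are negated before
ranking so that lower is uniformly better; the ranking protocol itself
lives in :mod:`treesum.evaluate`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .core import TreeSample
from .evaluate import RankTable, error_report
from .error_measures import ErrorVector, write_error_table
from .methods import DEFAULT_METHODS, summarize
from .min_distance import OptimizerOptions
from .simulate import SimConfig, pseudo_posterior, sample_coalescent, \
    simulate_jc

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

#: error measures ranked in the final tables (all lower-is-better; the
#: likelihood columns are negated log densities)
MEASURES = (
    "root_height_error", "heights_error", "divergence_error",
    "clades_missed", "clades_called",
    "neg_tree_loglik", "neg_coalescent_loglik", "neg_model_fit",
)


@dataclass
class ExperimentConfig:
    grid_n: tuple[int, ...] = (8,)
    grid_ne: tuple[float, ...] = (1.0,)
    cases_per_setting: int = 5
    posterior_size: int = 100
    seq_length: int = 800
    mut_rate: float = 0.005
    topo_moves_mean: float = 1.0
    height_cv: float = 0.1
    methods: tuple[str, ...] = DEFAULT_METHODS
    bootstrap_reps: int = 4000
    dominance_threshold: float = 0.9
    seed: int = 0
    with_likelihoods: bool = True


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    errors: list[ErrorVector]
    table: RankTable
    wall_time: float = 0.0

    def write(self, outdir) -> None:
        from pathlib import Path

        import json

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_error_table(self.errors, out / "errors.tsv")
        self.table.write_tsv(out / "ranks.tsv")
        report = {
            "config": self.config.__dict__,
            "wall_time": self.wall_time,
            "methods": self.table.methods,
            "measures": {
                meas: {
                    "mean_rank": self.table.mean_ranks[meas].tolist(),
                    "comparison_score":
                        self.table.comparison_scores[meas].tolist(),
                    "magnitude_score":
                        self.table.magnitude_scores[meas].tolist(),
                }
                for meas in self.table.measures
            },
        }
        (out / "report.json").write_text(
            json.dumps(report, default=list, indent=1)
        )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full (scaled-down) simulation comparison."""
    if config.cases_per_setting < 1 or not config.grid_n:
        raise ValueError("need at least one case and one grid setting")
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    opts = OptimizerOptions(seed=int(rng.integers(2**31)))
    rows: list[ErrorVector] = []
    per_measure: dict[str, list[list[float]]] = {m: [] for m in MEASURES}
    for n in config.grid_n:
        for ne in config.grid_ne:
            for rep in range(config.cases_per_setting):
                case = f"n{n}_ne{ne}_r{rep}"
                truth = sample_coalescent(n, ne, rng)
                aln = (
                    simulate_jc(truth, config.seq_length, config.mut_rate, rng)
                    if config.with_likelihoods else None
                )
                sample = pseudo_posterior(
                    truth, config.posterior_size,
                    config.topo_moves_mean, config.height_cv, rng,
                )
                case_rows = []
                for method in config.methods:
                    res = summarize(sample, method, opts)
                    ev = error_report(
                        res.tree, truth, aln, config.mut_rate, ne,
                        method=method, case=case,
                    )
                    case_rows.append(ev)
                rows.extend(case_rows)
                for meas in MEASURES:
                    per_measure[meas].append(
                        [_measure(ev, meas) for ev in case_rows]
                    )
    matrices = {
        m: np.asarray(v) for m, v in per_measure.items()
        if np.all(np.isfinite(v))
    }
    table = RankTable.from_errors(
        list(config.methods), matrices,
        reps=config.bootstrap_reps,
        dominance_threshold=config.dominance_threshold,
        rng=np.random.default_rng(config.seed),
    )
    return ExperimentResult(config, rows, table, time.time() - t0)


def _measure(ev: ErrorVector, measure: str) -> float:
    if measure.startswith("neg_"):
        return -getattr(ev, measure[4:])
    return float(getattr(ev, measure))
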