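"""Benchmark orchestration: replicates x methods x settings.

Each replicate simulates a model tree and input trees, runs the selected
supertree methods, prunes the outgroup from both supertree and model, and
records the comparison metrics.  The Build method may legitimately fail on
conflicting inputs; such replicates are recorded with a status flag rather
than aborting the run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .build import Incompatible, build_supertree, mincut_supertree, modified_mincut_supertree
from .bwd import bwd_supertree
from .metrics import compare_nonplenary
from .simulate import SimulationConfig, make_input_trees
from .tree import RootedTree, restrict

logger = logging.getLogger(__name__)

METHODS = {
    "build": build_supertree,
    "mc": mincut_supertree,
    "mmc": modified_mincut_supertree,
    "bwd_sac": lambda trees: bwd_supertree(trees, support="sac"),
    "bwd_sacmax": lambda trees: bwd_supertree(trees, support="sacmax"),
}


@dataclass
class BenchmarkConfig:
    """Grid of benchmark settings; every cell runs ``n_replicates`` times."""

    methods: list[str] = field(default_factory=lambda: ["mc", "mmc", "bwd_sac"])
    n_taxa: int = 48
    deletion_ratios: list[float] = field(default_factory=lambda: [0.5])
    n_input_trees: list[int] = field(default_factory=lambda: [10])
    input_mode: str = "clean_restriction"
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _prune_outgroup(tree: RootedTree, outgroup: str) -> RootedTree:
    if outgroup in tree.leaf_labels:
        return restrict(tree, tree.leaf_labels - {outgroup})
    return tree


def run_replicate(
    sim: SimulationConfig, methods: list[str]
) -> list[dict]:
    """Simulate one replicate and evaluate every method on it."""
    model, inputs = make_input_trees(sim)
    model_ingroup = _prune_outgroup(model, sim.outgroup)
    rows = []
    base = {
        "n_taxa": sim.n_taxa,
        "deletion_ratio": sim.deletion_ratio,
        "n_input_trees": sim.n_input_trees,
        "input_mode": sim.input_mode,
        "seed": sim.seed,
    }
    for method in methods:
        t0 = time.perf_counter()
        result = METHODS[method](inputs)
        wall = time.perf_counter() - t0
        row = dict(base, method=method, wall_time=wall)
        if isinstance(result, Incompatible):
            row["status"] = "incompatible"
            rows.append(row)
            continue
        supertree = _prune_outgroup(result, sim.outgroup)
        report = compare_nonplenary(model_ingroup, supertree)
        trip = report.triplet
        row.update(
            status="ok",
            resolution=report.resolution,
            rf_norm=report.rf_norm,
            d_tr=report.d_tr,
            same=trip.same,
            diff=trip.diff,
            r1=trip.r1,
            r2=trip.r2,
            x=trip.x,
            mast=report.mast_size,
            mast_norm=report.mast_norm,
            n_excluded=report.n_excluded_taxa,
        )
        rows.append(row)
    return rows


def run_benchmark(config: BenchmarkConfig, out_csv=None) -> pd.DataFrame:
    """Run the full grid; returns one row per (replicate, method, setting).

    Per-replicate seeds are spawned deterministically from ``config.seed``,
    so any row can be regenerated from its recorded seed alone.
    """
    rows: list[dict] = []
    for ratio in config.deletion_ratios:
        for n_inputs in config.n_input_trees:
            ss = np.random.SeedSequence(
                [config.seed, int(round(ratio * 1000)), n_inputs]
            )
            child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_replicates)]
            for rep, rep_seed in enumerate(child_seeds):
                sim = SimulationConfig(
                    n_taxa=config.n_taxa,
                    deletion_ratio=ratio,
                    n_input_trees=n_inputs,
                    input_mode=config.input_mode,
                    seed=rep_seed,
                )
                for row in run_replicate(sim, config.methods):
                    row["replicate"] = rep
                    rows.append(row)
                if out_csv is not None:
                    pd.DataFrame(rows).to_csv(out_csv, index=False)
    return pd.DataFrame(rows)


METRIC_COLUMNS = ["resolution", "rf_norm", "d_tr", "mast_norm", "n_excluded"]


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of each metric per setting and method."""
    if results.empty:
        raise ValueError("no results to summarize")
    ok = results[results["status"] == "ok"]
    keys = ["method", "n_taxa", "deletion_ratio", "n_input_trees"]
    present = [c for c in METRIC_COLUMNS if c in ok.columns]
    return ok.groupby(keys)[present].agg(["mean", "std"]).reset_index()


def plot_summary(results: pd.DataFrame, out_path) -> None:
    """Metric-versus-input-count panels, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = results[results["status"] == "ok"]
    metrics = [c for c in ("resolution", "mast_norm", "rf_norm", "d_tr") if c in ok.columns]
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        for method, grp in ok.groupby("method"):
            means = grp.groupby("n_input_trees")[metric].mean()
            ax.plot(means.index, means.values, marker="o", label=method)
        ax.set_xlabel("number of input trees")
        ax.set_ylabel(metric)
        ax.set_ylim(-0.02, 1.02)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
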