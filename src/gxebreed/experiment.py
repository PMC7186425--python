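"""Experiment grids: cells, replicates, summaries and scenario comparisons.

A *cell* is one (scenario, h2, rg, population mode) combination; a grid runs
every cell for a number of replicates with deterministic per-replicate seeds.
Replicate seeds are shared across cells so that a cooperative scenario and
its independent baseline run on common founder and base-population
randomness and diverge only when their policies first differ — mirroring a
paired experimental design.  Completed cells are detected by a configuration
hash and skipped on rerun, so a finished grid reproduces byte-identical
summaries without re-simulating.

Two scale presets exist:

* ``full`` — the full-scale design (30 chromosomes, 40k SNPs, 2k QTL,
  1000-2000 dams per environment, 20 generations, 50 replicates); CPU-days
  of work, intended for batch execution cell by cell.
* ``desk`` — a structurally identical small design that runs in seconds per
  replicate and is meant for mechanism and ordering checks, not for
  reproducing full-scale magnitudes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import metrics
from .engine import RunResult, desk_config, full_config, run_scenario
from .founders import FounderSet, simulate_founders
from .rng import replicate_seed, stream

__all__ = ["ExperimentGrid", "FOUNDER_PRESETS", "run_cell", "run_grid",
           "compare_scenarios", "split_point_table", "format_report"]

FOUNDER_PRESETS = {
    "full": dict(n_chromosomes=30, chrom_length=1.0, n_snp=40_000,
                  n_qtl=2_000, n_tracer_per_chrom=200,
                  n_hist_generations=400, n_males=300, n_females=300,
                  oversample=1.3, maf_min=0.01),
    "desk": dict(n_chromosomes=5, chrom_length=1.0, n_snp=2_000, n_qtl=200,
                 n_tracer_per_chrom=100, n_hist_generations=100,
                 n_males=100, n_females=100, oversample=1.5, maf_min=0.05),
}

_CONFIG_PRESETS = {"full": full_config, "desk": desk_config}

# cooperative scenario -> its matched independent baseline
BASELINES = {"AG-AS": "WG-WS", "AP-AS": "WP-WS", "AG-WS": "WG-WS"}


@dataclass
class ExperimentGrid:
    scenarios: tuple[str, ...]
    h2_levels: tuple[float, ...]
    rg_levels: tuple[float, ...]
    pop_mode: str = "equal"
    scale: str = "desk"
    n_replicates: int = 10
    seed: int = 1

    def cells(self):
        for scenario in self.scenarios:
            for h2 in self.h2_levels:
                for rg in self.rg_levels:
                    yield scenario, float(h2), float(rg)


def cell_hash(scenario: str, h2: float, rg: float, pop_mode: str,
              scale: str, seed: int, n_replicates: int) -> str:
    payload = json.dumps([scenario, h2, rg, pop_mode, scale, seed,
                          n_replicates], sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def build_founder(scale: str, master_seed: int, replicate: int,
                  ) -> FounderSet:
    """Founder genome for one replicate (shared across a grid's cells)."""
    rng = stream(master_seed, "founders", extra=replicate)
    return simulate_founders(rng, **FOUNDER_PRESETS[scale])


def _metric_window(n_generations: int) -> tuple[int, int]:
    return (n_generations // 2, n_generations)


def summarize_run(run: RunResult, replicate: int) -> tuple[list[dict], list[dict]]:
    """Per-environment endpoint metrics and external-sire proportions."""
    window = _metric_window(run.config.n_generations)
    rows = []
    for env in (1, 2):
        rows.append({
            "replicate": replicate, "env": env,
            "delta_g": metrics.genetic_gain(run.mean_tbv(env), window),
            "delta_f": metrics.rate_of_inbreeding(run.f_trajectory(env),
                                                  window),
        })
    props = metrics.external_sire_proportion(run)
    props = props[props["event"] >= run.config.scenario_start]
    prop_rows = [dict(replicate=replicate, **rec)
                 for rec in props.to_dict("records")]
    return rows, prop_rows


def run_cell(scenario: str, h2: float, rg: float, *, pop_mode: str = "equal",
             scale: str = "desk", seed: int = 1, n_replicates: int = 10,
             founders: dict[int, FounderSet] | None = None,
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one cell; returns (replicate metrics, proportion trajectories)."""
    make_config = _CONFIG_PRESETS[scale]
    metric_rows, prop_rows = [], []
    for rep in range(n_replicates):
        if founders is not None and rep in founders:
            fs = founders[rep]
        else:
            fs = build_founder(scale, seed, rep)
            if founders is not None:
                founders[rep] = fs
        config = make_config(scenario, h2=h2, rg=rg, pop_mode=pop_mode)
        run = run_scenario(config, fs, replicate_seed(seed, rep))
        rows, props = summarize_run(run, rep)
        metric_rows.extend(rows)
        prop_rows.extend(props)
    return pd.DataFrame(metric_rows), pd.DataFrame(prop_rows)


def run_grid(grid: ExperimentGrid, outdir: str | Path,
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute (or resume) a grid; returns (summary, proportions) tables.

    Each cell writes ``cell_<hash>.csv`` (per-replicate metrics) and
    ``props_<hash>.csv``; existing files are loaded instead of re-simulated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    founders: dict[int, FounderSet] = {}
    summaries, proportions = [], []
    for scenario, h2, rg in grid.cells():
        h = cell_hash(scenario, h2, rg, grid.pop_mode, grid.scale,
                      grid.seed, grid.n_replicates)
        cell_file = outdir / f"cell_{h}.csv"
        prop_file = outdir / f"props_{h}.csv"
        if cell_file.exists() and prop_file.exists():
            cell = pd.read_csv(cell_file)
            props = pd.read_csv(prop_file)
        else:
            cell, props = run_cell(scenario, h2, rg, pop_mode=grid.pop_mode,
                                   scale=grid.scale, seed=grid.seed,
                                   n_replicates=grid.n_replicates,
                                   founders=founders)
            for df, f in ((cell, cell_file), (props, prop_file)):
                df.insert(0, "scenario", scenario)
                df.insert(1, "h2", h2)
                df.insert(2, "rg", rg)
                df.to_csv(f, index=False)
            cell, props = pd.read_csv(cell_file), pd.read_csv(prop_file)
        summaries.append(cell)
        proportions.append(props)
    summary = pd.concat(summaries, ignore_index=True)
    props = (pd.concat(proportions, ignore_index=True) if proportions
             else pd.DataFrame())
    agg = (summary.groupby(["scenario", "h2", "rg", "env"])
           .agg(delta_g_mean=("delta_g", "mean"),
                delta_g_sd=("delta_g", "std"),
                delta_f_mean=("delta_f", "mean"),
                delta_f_sd=("delta_f", "std"),
                n_replicates=("replicate", "nunique"))
           .reset_index())
    agg.to_csv(outdir / "summary.csv", index=False)
    return agg, props


def compare_scenarios(summary: pd.DataFrame) -> pd.DataFrame:
    """Cooperation-benefit table: percentage increment of each cooperative
    scenario's dG / dF over its matched independent baseline, computed from
    unrounded replicate means per (h2, rg, env) cell."""
    out = []
    for coop, indep in BASELINES.items():
        c = summary[summary["scenario"] == coop]
        b = summary[summary["scenario"] == indep]
        if c.empty or b.empty:
            continue
        merged = c.merge(b, on=["h2", "rg", "env"], suffixes=("", "_base"))
        if merged.empty:
            raise ValueError(f"missing baseline cells for {coop} vs {indep}")
        for _, row in merged.iterrows():
            out.append({
                "scenario": coop, "baseline": indep, "h2": row["h2"],
                "rg": row["rg"], "env": row["env"],
                "delta_g": row["delta_g_mean"],
                "delta_g_base": row["delta_g_mean_base"],
                "ici_gain_pct": metrics.improvement_pct(
                    row["delta_g_mean"], row["delta_g_mean_base"]),
                "delta_f": row["delta_f_mean"],
                "delta_f_base": row["delta_f_mean_base"],
                "ici_inbreeding_pct": metrics.improvement_pct(
                    row["delta_f_mean"], row["delta_f_mean_base"]),
            })
    return pd.DataFrame(out)


def split_point_table(props: pd.DataFrame, threshold: float = 0.02,
                      ) -> pd.DataFrame:
    """Split-point rg per (scenario, h2, env) from proportion trajectories."""
    rows = []
    for (scenario, h2, env), sub in props.groupby(["scenario", "h2", "env"]):
        by_rg = {}
        for rg, traj in sub.groupby("rg"):
            by_rg[float(rg)] = (traj.groupby("event")["proportion"]
                                .mean().to_numpy())
        if len(by_rg) < 2:
            continue
        sp = metrics.split_point(by_rg, threshold)
        if sp is None:
            text = "none"
        elif isinstance(sp, tuple):
            text = f"{sp[0]:g}~{sp[1]:g}"
        else:
            text = f"{sp:g}"
        rows.append({"scenario": scenario, "h2": h2, "env": env,
                     "split_point": text})
    return pd.DataFrame(rows)


def format_report(summary: pd.DataFrame, comparison: pd.DataFrame,
                  ) -> pd.DataFrame:
    """Rounded presentation table (dG 2 decimals, dF 4, increments 1)."""
    rep = comparison.copy()
    if rep.empty:
        return rep
    rep["delta_g"] = rep["delta_g"].round(2)
    rep["delta_g_base"] = rep["delta_g_base"].round(2)
    rep["delta_f"] = rep["delta_f"].round(4)
    rep["delta_f_base"] = rep["delta_f_base"].round(4)
    rep["ici_gain_pct"] = rep["ici_gain_pct"].round(1)
    rep["ici_inbreeding_pct"] = rep["ici_inbreeding_pct"].round(1)
    return rep
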