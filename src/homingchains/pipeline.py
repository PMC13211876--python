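"""End-to-end driver: synthetic population -> fitted strategies -> chains ->
strategy contrasts -> flock curve and effective group sizes.

This is the synthetic analogue of the full published analysis: it generates a
population of idiosyncratic routes, fits every strategy's free weights by
grid search against mean generation-5 efficiency, runs transmission chains
under each strategy, compares efficiencies and social weights to a reference
strategy via bird-level bootstrap with Dunnett-style adjustment, and maps
per-generation efficiencies to effective group sizes.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import chains as chain_mod
from . import flock, stats, strategies, synth
from .config import RunConfig
from .geo import write_trajectory

__all__ = ["fit_all_strategies", "run_full_pipeline"]

log = logging.getLogger("homingchains")


def fit_all_strategies(population, geom, names, n_fit_chains=300, seed=0, grid_step=0.01):
    """Grid-fit the free weight of every strategy that has one."""
    sequences = chain_mod.sample_sequences(len(population), n_fit_chains, seed)
    specs: dict[str, strategies.StrategySpec] = {}
    for name in names:
        t0 = time.perf_counter()
        if name in ("averaging", "all_or_nothing"):
            specs[name] = strategies.StrategySpec(name)
        elif name == "maximize_flight":
            specs[name] = strategies.StrategySpec(name, {"grid_step": grid_step})
        elif name == "maximize_generation":
            specs[name] = strategies.optimize_generation_weights(
                population, sequences, geom, grid_step
            )
        else:
            specs[name] = strategies.optimize_constant_weight(
                name, population, sequences, geom, grid_step
            )
        log.info("fitted %s in %.1fs: %s", name, time.perf_counter() - t0,
                 specs[name].params or "(no parameters)")
    return specs


def run_full_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write all artifacts under ``outdir``.

    Outputs: population manifest + route CSVs, fitted weights, per-strategy
    tidy chain tables, per-generation summaries, bootstrap contrasts vs. the
    reference strategy (Dunnett-adjusted), the flock curve with effective
    group sizes, and ``summary.json``.  Identical configs give identical
    outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = config.geometry()
    t0 = time.perf_counter()

    log.info("stage 1: generating %d synthetic birds (seed %d)", config.n_birds, config.seed)
    cfg = config.synthetic
    population = synth.generate_population(cfg, config.n_birds)
    routes_dir = outdir / "routes"
    routes_dir.mkdir(exist_ok=True)
    manifest = pd.DataFrame(
        {
            "bird_id": [b.bird_id for b in population],
            "seed": cfg.seed,
            "efficiency": [b.solo_efficiency for b in population],
            "file": [f"routes/solo_{b.bird_id}_1_12.csv" for b in population],
        }
    )
    for b in population:
        write_trajectory(b.route, routes_dir / f"solo_{b.bird_id}_1_12.csv")
    manifest.to_csv(outdir / "population.csv", index=False)

    log.info("stage 2: fitting strategy weights over %d chains", config.fit_n_chains)
    specs = fit_all_strategies(
        population, geom, config.strategies,
        n_fit_chains=config.fit_n_chains, seed=config.seed, grid_step=config.grid_step,
    )
    (outdir / "fitted_weights.json").write_text(
        json.dumps({k: v.params for k, v in specs.items()}, indent=2, default=float)
    )

    log.info("stage 3: running %s chains per strategy", config.chain_mode)
    frames = []
    all_runs = {}
    for name, spec in specs.items():
        runs = chain_mod.run_all_chains(
            population, spec, geom, mode=config.chain_mode,
            n=config.n_chains, seed=config.seed + 1,
        )
        all_runs[name] = runs
        df = chain_mod.chains_to_frame(runs)
        df.insert(0, "dataset", name)
        frames.append(df)
        log.info("  %s: %d chains", name, len(runs))
    tidy = pd.concat(frames, ignore_index=True)
    tidy.to_csv(outdir / "chains.csv", index=False)

    summaries = pd.concat(
        [
            chain_mod.summarize_generations(all_runs[n], seed=config.seed)
            .assign(dataset=n)
            for n in specs
        ],
        ignore_index=True,
    )
    summaries.to_csv(outdir / "generation_summary.csv", index=False)

    log.info("stage 4: bootstrap contrasts vs %s (%d runs)",
             config.reference_strategy, config.n_boot)
    table = tidy[tidy["generation"] >= 2].rename(columns={"bird_id": "bird"})
    contrast_rows = []
    for statistic, col in (("efficiency", "efficiency"), ("weight", "weight_E")):
        sub = table[["dataset", "generation", "bird", col]].rename(columns={col: statistic})
        res, reps = stats.bootstrap_contrasts(
            sub, statistic=statistic, reference=config.reference_strategy,
            n_boot=config.n_boot, seed=config.seed + 2,
        )
        adjusted = stats.dunnett_adjust(res, reps)
        for c in adjusted:
            contrast_rows.append(
                {"statistic": statistic, "strategy": c.label, "generation": c.generation,
                 "estimate": c.estimate, "ci_lo": c.ci_lo, "ci_hi": c.ci_hi,
                 "p_adj": c.p_value, "scale": c.scale}
            )
    contrasts = pd.DataFrame(contrast_rows)
    contrasts.to_csv(outdir / "contrasts.csv", index=False)

    log.info("stage 5: flock curve and effective group sizes")
    sizes, effs = flock.flock_size_table(
        population, geom, max_n=config.max_flock_n or config.n_birds,
        mode="sample" if config.n_birds > 12 else "exhaustive",
        k=200, seed=config.seed + 3,
    )
    curve = flock.fit_hyperbolic(sizes, effs, pool_size=config.n_birds)
    neff_rows = []
    for name in specs:
        gen5 = float(
            summaries.loc[
                (summaries["dataset"] == name) & (summaries["generation"] == 5),
                "mean_efficiency",
            ].iloc[0]
        )
        try:
            n_eff, extrapolated = flock.effective_group_size(curve, gen5)
        except ValueError:
            n_eff, extrapolated = float("inf"), True
        neff_rows.append(
            {"dataset": name, "gen5_efficiency": gen5,
             "effective_group_size": n_eff, "extrapolated": extrapolated}
        )
    neff = pd.DataFrame(neff_rows)
    neff.to_csv(outdir / "effective_group_size.csv", index=False)

    summary = {
        "seed": config.seed,
        "n_birds": config.n_birds,
        "population_mean_efficiency": float(manifest["efficiency"].mean()),
        "fitted_weights": {k: v.params for k, v in specs.items()},
        "gen5_mean_efficiency": {
            n: float(
                summaries.loc[
                    (summaries["dataset"] == n) & (summaries["generation"] == 5),
                    "mean_efficiency",
                ].iloc[0]
            )
            for n in specs
        },
        "flock_curve": {"form": curve.form, "c0": curve.c0, "c1": curve.c1},
        "effective_group_size": {
            r["dataset"]: r["effective_group_size"] for r in neff_rows
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    log.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return summary
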