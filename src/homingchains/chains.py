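"""Transmission chains: sample birds, fuse per generation, propagate.

A chain is a five-generation "telephone game": generation 1 is one bird's
solo route; in each later generation the current experienced route is fused
with a freshly sampled naive bird's route, and the fused route becomes the
experienced route of the next generation.  Because each fusion is a convex
combination, every founding bird's share of the final route follows the
affine recursion  c_new = w * c_E + (1 - w) * e_N,  which under plain
averaging (w = 0.5) produces the geometric forgetting pattern
(1/16, 1/16, 1/8, 1/4, 1/2) at generation 5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geo import SiteGeometry, Trajectory
from .metrics import EfficiencyResult, route_efficiency
from .pairing import synchronize, weighted_average
from .strategies import PairContext, StrategySpec, resolve_weights

__all__ = [
    "N_GENERATIONS",
    "ChainRun",
    "run_chain",
    "run_all_chains",
    "sample_sequences",
    "contribution_trace",
    "summarize_generations",
    "chains_to_frame",
]

N_GENERATIONS = 5
EXHAUSTIVE_CAP = 100_000


@dataclass(frozen=True)
class ChainRun:
    """One simulated five-generation chain.

    ``weights[g]`` is the experienced bird's (time-averaged) social weight in
    generation g+2; ``contributions[g]`` the fraction of each of the five
    chain slots in the generation-(g+1) route (unused slots are zero).
    """

    bird_ids: tuple[str, ...]
    routes: tuple[Trajectory, ...]
    efficiencies: tuple[float, ...]
    weights: tuple[float, ...]
    contributions: tuple[np.ndarray, ...]


def run_chain(
    population,
    spec: StrategySpec,
    sequence,
    geom: SiteGeometry,
) -> ChainRun:
    """Run one chain over a 5-bird sequence (indices into ``population``).

    Generation 1 is the founder's solo route; generations 2-5 fuse the
    current experienced route with the next naive route under ``spec``.
    """
    if len(sequence) != N_GENERATIONS:
        raise ValueError(f"a chain needs {N_GENERATIONS} birds, got {len(sequence)}")
    founder = population[sequence[0]]
    current = founder.route
    current_eff = founder.solo_efficiency
    routes = [current]
    effs = [current_eff]
    weights: list[float] = []
    contrib = np.zeros(N_GENERATIONS)
    contrib[0] = 1.0
    contributions = [contrib.copy()]

    for gen in range(2, N_GENERATIONS + 1):
        naive = population[sequence[gen - 1]]
        E, N = synchronize(current, naive.route)
        ctx = PairContext(
            experienced=E,
            naive=N,
            generation=gen,
            eff_experienced=current_eff,
            eff_naive=naive.solo_efficiency,
        )
        w = resolve_weights(spec, ctx, geom)
        fused = weighted_average(E, N, w)
        w_scalar = float(np.mean(w))
        contrib = w_scalar * contrib
        contrib[gen - 1] += 1.0 - w_scalar
        current = fused
        current_eff = route_efficiency(fused, geom).efficiency
        routes.append(fused)
        effs.append(current_eff)
        weights.append(w_scalar)
        contributions.append(contrib.copy())

    return ChainRun(
        bird_ids=tuple(population[i].bird_id for i in sequence),
        routes=tuple(routes),
        efficiencies=tuple(effs),
        weights=tuple(weights),
        contributions=tuple(contributions),
    )


def sample_sequences(n_birds: int, n: int, seed: int) -> list[tuple[int, ...]]:
    """Reproducibly draw ``n`` ordered 5-bird sequences with replacement."""
    rng = np.random.default_rng(int(seed) % 2**31)
    draws = rng.integers(0, n_birds, size=(n, N_GENERATIONS))
    return [tuple(int(v) for v in row) for row in draws]


def run_all_chains(
    population,
    spec: StrategySpec,
    geom: SiteGeometry,
    mode: str = "exhaustive",
    n: int | None = None,
    seed: int | None = None,
) -> list[ChainRun]:
    """Run chains over all |pop|^5 sequences, or a reproducible subsample.

    Exhaustive mode refuses to run above ``EXHAUSTIVE_CAP`` sequences;
    switch to ``mode='sample'`` with an explicit ``n`` and ``seed`` there.
    """
    if not population:
        raise ValueError("population is empty")
    n_birds = len(population)
    if mode == "exhaustive":
        total = n_birds**N_GENERATIONS
        if total > EXHAUSTIVE_CAP:
            raise ValueError(
                f"{total} sequences exceed the exhaustive cap ({EXHAUSTIVE_CAP}); "
                "use mode='sample' with n and seed"
            )
        sequences = itertools.product(range(n_birds), repeat=N_GENERATIONS)
    elif mode == "sample":
        if n is None or seed is None:
            raise ValueError("sample mode needs n and seed")
        sequences = sample_sequences(n_birds, n, seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [run_chain(population, spec, seq, geom) for seq in sequences]


def contribution_trace(chain: ChainRun) -> list[np.ndarray]:
    """Per-generation contribution fractions of each founding bird.

    Fractions are exact for uniform per-flight weights; for per-step weight
    vectors the time-averaged weight is used.  Each generation's fractions
    sum to 1.
    """
    return [c.copy() for c in chain.contributions]


def chains_to_frame(chains) -> "pandas.DataFrame":
    """Tidy per-(chain, generation) table of efficiency, weight, contributions."""
    import pandas as pd

    rows = []
    for ci, run in enumerate(chains):
        for g in range(N_GENERATIONS):
            rows.append(
                {
                    "chain_id": ci,
                    "generation": g + 1,
                    "bird_id": run.bird_ids[g],
                    "efficiency": run.efficiencies[g],
                    "weight_E": np.nan if g == 0 else run.weights[g - 1],
                    **{
                        f"contrib_{k + 1}": run.contributions[g][k]
                        for k in range(N_GENERATIONS)
                    },
                }
            )
    return pd.DataFrame(rows)


def summarize_generations(
    chains,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> "pandas.DataFrame":
    """Mean, SD and bootstrap CI of efficiency and weight per generation."""
    import pandas as pd

    rng = np.random.default_rng(int(seed) % 2**31)
    eff = np.array([run.efficiencies for run in chains])  # (n_chains, 5)
    wts = np.array([(np.nan,) + run.weights for run in chains])
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    n = eff.shape[0]
    for g in range(N_GENERATIONS):
        e = eff[:, g]
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = e[idx].mean(axis=1)
        rows.append(
            {
                "generation": g + 1,
                "n_chains": n,
                "mean_efficiency": float(e.mean()),
                "sd_efficiency": float(e.std(ddof=1)) if n > 1 else 0.0,
                "eff_ci_lo": float(np.quantile(boot_means, alpha)),
                "eff_ci_hi": float(np.quantile(boot_means, 1 - alpha)),
                "mean_weight_E": float(np.nanmean(wts[:, g])) if g > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
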