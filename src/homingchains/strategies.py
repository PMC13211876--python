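"""The seven pair-fusion strategies and their weight-optimization procedures.

Strategies are grouped by the information they require:

* T1 — no information: ``averaging`` (both routes weighted 0.5).
* T2 — recognizing relative experience: ``experienced_bird_weighting`` (one
  constant weight w_E fitted to maximize mean generation-5 efficiency) and
  ``maximize_generation`` (a separate w_E per generation, fitted greedily).
* T3 — evaluating route performance: ``better_bird_weighting`` (fitted weight
  w_B to whichever bird's route is shorter), ``all_or_nothing`` (the shorter
  route takes full control, w_B = 1), ``maximize_flight`` (per-pair grid
  argmax of fused-route efficiency), and ``maximize_time_steps`` (per-step
  weight w_near to whichever bird is nearer the beeline).

All fitted weights live on a grid of step 0.01; optimization ties break
toward the smaller weight for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geo import SiteGeometry, Trajectory
from .metrics import route_efficiency
from .pairing import synchronize, timestep_weights_closer_to_beeline, weighted_average

__all__ = [
    "STRATEGY_NAMES",
    "TYPE_CLASS",
    "StrategySpec",
    "PairContext",
    "UnfittedStrategyError",
    "resolve_weights",
    "weight_grid",
    "optimize_constant_weight",
    "optimize_generation_weights",
    "experienced_weight_report",
]

TYPE_CLASS = {
    "averaging": "T1",
    "experienced_bird_weighting": "T2",
    "maximize_generation": "T2",
    "better_bird_weighting": "T3",
    "all_or_nothing": "T3",
    "maximize_flight": "T3",
    "maximize_time_steps": "T3",
}
STRATEGY_NAMES = tuple(TYPE_CLASS)


class UnfittedStrategyError(ValueError):
    """A strategy that needs fitted weights was used before fitting."""


@dataclass(frozen=True)
class StrategySpec:
    """One strategy plus its (possibly fitted) weight parameters.

    params keys by strategy: ``w_E`` (experienced_bird_weighting),
    ``w_by_generation`` mapping {2..5} -> weight (maximize_generation),
    ``w_B`` (better_bird_weighting), ``w_near`` (maximize_time_steps),
    ``grid_step`` (maximize_flight; default 0.01).  averaging and
    all_or_nothing take no parameters.
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in TYPE_CLASS:
            raise ValueError(
                f"unknown strategy {self.name!r}; expected one of {list(TYPE_CLASS)}"
            )

    @property
    def type_class(self) -> str:
        return TYPE_CLASS[self.name]


@dataclass(frozen=True)
class PairContext:
    """One pairing event inside a chain: synchronized routes plus metadata."""

    experienced: Trajectory
    naive: Trajectory
    generation: int
    eff_experienced: float
    eff_naive: float

    def __post_init__(self) -> None:
        if self.generation < 2:
            raise ValueError("pairings happen from generation 2 onward")


def weight_grid(step: float = 0.01, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


def _experienced_is_better(ctx: PairContext) -> bool:
    # shorter trimmed route == higher efficiency (shared adjusted beeline);
    # ties go to the experienced bird
    return ctx.eff_experienced >= ctx.eff_naive


def _grid_argmax_weight(
    trajE: Trajectory, trajN: Trajectory, geom: SiteGeometry, step: float
) -> float:
    """Exhaustive scan of the fused-route efficiency over the weight grid."""
    best_w, best_eff = 0.0, -np.inf
    for w in weight_grid(step):
        eff = route_efficiency(weighted_average(trajE, trajN, w), geom).efficiency
        if eff > best_eff + 1e-12:
            best_w, best_eff = float(w), eff
    return best_w


def resolve_weights(spec: StrategySpec, ctx: PairContext, geom: SiteGeometry):
    """Experienced-bird weight(s) for one pairing under a strategy.

    Returns a scalar, or a per-step vector for ``maximize_time_steps``.  The
    two routes in ``ctx`` must already be synchronized.
    """
    name, p = spec.name, spec.params
    if name == "averaging":
        return 0.5
    if name == "experienced_bird_weighting":
        if "w_E" not in p:
            raise UnfittedStrategyError("experienced_bird_weighting needs a fitted w_E")
        return float(p["w_E"])
    if name == "maximize_generation":
        if "w_by_generation" not in p:
            raise UnfittedStrategyError("maximize_generation needs fitted per-generation weights")
        return float(p["w_by_generation"][ctx.generation])
    if name == "better_bird_weighting":
        if "w_B" not in p:
            raise UnfittedStrategyError("better_bird_weighting needs a fitted w_B")
        w_B = float(p["w_B"])
        return w_B if _experienced_is_better(ctx) else 1.0 - w_B
    if name == "all_or_nothing":
        return 1.0 if _experienced_is_better(ctx) else 0.0
    if name == "maximize_flight":
        return _grid_argmax_weight(
            ctx.experienced, ctx.naive, geom, float(p.get("grid_step", 0.01))
        )
    if name == "maximize_time_steps":
        if "w_near" not in p:
            raise UnfittedStrategyError("maximize_time_steps needs a fitted w_near")
        return timestep_weights_closer_to_beeline(
            ctx.experienced, ctx.naive, geom, float(p["w_near"])
        )
    raise AssertionError(name)


# --------------------------------------------------------------------------
# Weight fitting.  The objective throughout is the mean route efficiency of
# the fifth (final) generation over an evaluated set of chains.

def _mean_final_efficiency(population, spec, sequences, geom) -> float:
    from .chains import run_chain  # local import to avoid a cycle

    effs = [run_chain(population, spec, seq, geom).efficiencies[-1] for seq in sequences]
    return float(np.mean(effs))


def _param_key(strategy: str) -> str:
    return {"experienced_bird_weighting": "w_E",
            "better_bird_weighting": "w_B",
            "maximize_time_steps": "w_near"}[strategy]


def optimize_constant_weight(
    strategy: str,
    population,
    sequences,
    geom: SiteGeometry,
    grid_step: float = 0.01,
) -> StrategySpec:
    """Fit the single weight of a constant-weight strategy by grid search.

    Scans the 0.01 grid (the [0.5, 1] half for ``maximize_time_steps``, whose
    parameter is the advantage of the bird nearer the beeline) and keeps the
    weight maximizing mean generation-5 efficiency over ``sequences``.  Ties
    break toward the smaller weight.  A degenerate population in which every
    route is identical makes the objective flat; 0.5 is returned with a
    warning.
    """
    key = _param_key(strategy)
    lo = 0.5 if strategy == "maximize_time_steps" else 0.0
    grid = weight_grid(grid_step, lo=lo)
    best_w, best_obj = None, -np.inf
    for w in grid:
        obj = _mean_final_efficiency(
            population, StrategySpec(strategy, {key: float(w)}), sequences, geom
        )
        if obj > best_obj + 1e-12:
            best_w, best_obj = float(w), obj
    flat = _mean_final_efficiency(
        population, StrategySpec(strategy, {key: float(grid[0])}), sequences, geom
    )
    if abs(flat - best_obj) <= 1e-12:
        warnings.warn(
            "objective is flat over the weight grid (identical routes?); returning 0.5",
            stacklevel=2,
        )
        best_w = 0.5
    return StrategySpec(strategy, {key: best_w})


def optimize_generation_weights(
    population,
    sequences,
    geom: SiteGeometry,
    grid_step: float = 0.01,
) -> StrategySpec:
    """Fit per-generation weights for ``maximize_generation``, greedily.

    Generation M's weight is chosen to maximize the mean generation-M
    efficiency with generations < M frozen at their fitted values; the fitted
    fused routes then propagate forward.  On independent zero-mean route
    errors the optimum approaches (M-1)/M: the experienced route is already
    an average of M-1 routes, so inverse-variance weighting favours it
    (M-1):1 over a fresh bird.
    """
    grid = weight_grid(grid_step)
    fitted: dict[int, float] = {}
    # per-chain state: current experienced route and its efficiency
    states = [
        (population[seq[0]].route, population[seq[0]].solo_efficiency, seq)
        for seq in sequences
    ]
    for gen in range(2, 6):
        pairs = []
        for route, eff, seq in states:
            naive = population[seq[gen - 1]]
            E, N = synchronize(route, naive.route)
            pairs.append((E, N))
        best_w, best_obj = grid[0], -np.inf
        for w in grid:
            mean_eff = np.mean(
                [route_efficiency(weighted_average(E, N, w), geom).efficiency
                 for E, N in pairs]
            )
            if mean_eff > best_obj + 1e-12:
                best_w, best_obj = float(w), float(mean_eff)
        fitted[gen] = best_w
        new_states = []
        for (E, N), (route, eff, seq) in zip(pairs, states):
            fused = weighted_average(E, N, best_w)
            new_states.append(
                (fused, route_efficiency(fused, geom).efficiency, seq)
            )
        states = new_states
    if len({tuple(map(float, b.route.x)) for b in population}) == 1:
        warnings.warn("identical routes: objective flat, weights default to 0.5", stacklevel=2)
        fitted = {g: 0.5 for g in fitted}
    return StrategySpec("maximize_generation", {"w_by_generation": fitted})


def experienced_weight_report(chain_runs) -> "pandas.DataFrame":
    """Mean experienced-bird social weight per generation over chains.

    Vector (per-step) weights are time-averaged within a flight first;
    better/worse-bird weights were already mapped to the experienced side
    when the chains ran.  Generation 1 has no pairing and is omitted.
    """
    import pandas as pd

    rows = [
        {"generation": gen, "weight_E": w}
        for run in chain_runs
        for gen, w in zip(range(2, 2 + len(run.weights)), run.weights)
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby("generation", as_index=False)["weight_E"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "mean_weight_E", "std": "sd_weight_E", "count": "n"})
    )
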