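"""Democratic flocks, the efficiency-vs-group-size curve, and effective group size.

A democratic flock of size n flies the equal-weight average of its members'
preferred routes.  Averaging n independent zero-mean route errors shrinks the
error variance like 1/n, so mean route efficiency rises with n along a
saturating curve; fitting E(n) = c0 - c1/n and inverting it maps any observed
efficiency to the size of a democratic flock with equivalent performance —
the *effective group size*.  A chain of five birds whose effective group size
falls below five is combining its members' information less efficiently than
a flock would.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .geo import SiteGeometry, Trajectory
from .metrics import route_efficiency
from .pairing import resample_to_length
from .synth import BirdRoute

__all__ = [
    "FlockCurve",
    "equal_weight_mean",
    "democratic_flock_efficiency",
    "flock_size_table",
    "fit_hyperbolic",
    "effective_group_size",
]


def _as_routes(pool) -> list[Trajectory]:
    return [p.route if isinstance(p, BirdRoute) else p for p in pool]


def equal_weight_mean(routes: list[Trajectory]) -> Trajectory:
    """Equal-weight average of any number of routes (synchronized first)."""
    routes = _as_routes(routes)
    L = max(r.n_points for r in routes)
    resampled = [resample_to_length(r, L) for r in routes]
    x = np.mean([r.x for r in resampled], axis=0)
    y = np.mean([r.y for r in resampled], axis=0)
    return Trajectory(resampled[0].times, x, y)


def democratic_flock_efficiency(
    pool,
    n: int,
    geom: SiteGeometry,
    mode: str = "exhaustive",
    k: int | None = None,
    seed: int | None = None,
) -> float:
    """Mean route efficiency of equally weighted flocks of size ``n``.

    Flocks are n-subsets of the pool drawn *without* replacement — either all
    of them or ``k`` sampled reproducibly.
    """
    routes = _as_routes(pool)
    if not 1 <= n <= len(routes):
        raise ValueError(f"group size {n} outside 1..{len(routes)}")
    if mode == "exhaustive":
        subsets = itertools.combinations(range(len(routes)), n)
    elif mode == "sample":
        if k is None or seed is None:
            raise ValueError("sample mode needs k and seed")
        rng = np.random.default_rng(int(seed) % 2**31)
        subsets = [tuple(rng.choice(len(routes), size=n, replace=False)) for _ in range(k)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    effs = [
        route_efficiency(equal_weight_mean([routes[i] for i in idx]), geom).efficiency
        for idx in subsets
    ]
    return float(np.mean(effs))


def flock_size_table(
    pool, geom: SiteGeometry, max_n: int | None = None, mode: str = "exhaustive",
    k: int | None = None, seed: int | None = None,
):
    """(sizes, mean efficiencies) for group sizes 1..max_n over a pool."""
    routes = _as_routes(pool)
    max_n = max_n or len(routes)
    sizes = np.arange(1, max_n + 1)
    effs = np.array(
        [democratic_flock_efficiency(routes, int(n), geom, mode, k, seed) for n in sizes]
    )
    return sizes, effs


_FORMS = {
    # (model, inverse) — inverse solves E = f(n) for n
    "hyperbolic": (
        lambda n, c0, c1: c0 - c1 / n,
        lambda e, c0, c1: c1 / (c0 - e),
    ),
    "michaelis_menten": (
        lambda n, c0, c1: c0 * n / (c1 + n),
        lambda e, c0, c1: c1 * e / (c0 - e),
    ),
}


@dataclass(frozen=True)
class FlockCurve:
    """Fitted efficiency-vs-group-size curve and its inverse."""

    c0: float
    c1: float
    form: str = "hyperbolic"
    residual_ss: float = float("nan")
    n_obs: int = 0
    pool_size: int = 0

    def predict(self, n) -> np.ndarray:
        return _FORMS[self.form][0](np.asarray(n, float), self.c0, self.c1)


def fit_hyperbolic(sizes, efficiencies, form: str = "hyperbolic",
                   pool_size: int | None = None) -> FlockCurve:
    """Least-squares fit of E(n) = c0 - c1/n (or a saturating alternative).

    ``c0`` is the asymptotic efficiency of an infinitely large democratic
    flock and ``c1`` the hyperbolic scale of the finite-size penalty.  At
    least three distinct group sizes are required.
    """
    sizes = np.asarray(sizes, float)
    effs = np.asarray(efficiencies, float)
    if len(np.unique(sizes)) < 3:
        raise ValueError("need at least 3 distinct group sizes to fit the curve")
    model = _FORMS[form][0]
    try:
        popt, _ = curve_fit(model, sizes, effs, p0=[float(effs.max()), 1.0], maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"flock-curve fit did not converge: {err}") from err
    c0, c1 = (float(v) for v in popt)
    resid = effs - model(sizes, c0, c1)
    if not (0.0 < c0 <= 1.0 + 1e-9) or c1 <= 0:
        raise RuntimeError(
            f"fitted curve not monotone-increasing on (0,1]: c0={c0:.4f}, c1={c1:.4f}"
        )
    return FlockCurve(
        c0=c0, c1=c1, form=form,
        residual_ss=float(resid @ resid), n_obs=int(sizes.size),
        pool_size=int(pool_size or sizes.max()),
    )


def effective_group_size(curve: FlockCurve, efficiency: float) -> tuple[float, bool]:
    """Size of the democratic flock matching an observed efficiency.

    Returns ``(n_eff, extrapolated)``; the flag marks values beyond the pool
    the curve was built from.  Efficiencies at or above the asymptote ``c0``
    have no finite equivalent and raise.
    """
    if efficiency >= curve.c0:
        raise ValueError(
            f"efficiency {efficiency:.4f} is at or beyond the curve asymptote c0={curve.c0:.4f}"
        )
    n_eff = float(_FORMS[curve.form][1](efficiency, curve.c0, curve.c1))
    return n_eff, bool(curve.pool_size and n_eff > curve.pool_size)
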