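"""Synthetic homing routes with idiosyncratic, zero-mean perpendicular biases.

Each simulated bird owns a preferred route between a release site and a home
site 8.4 km apart.  The route is the beeline plus a perpendicular displacement
field made of two parts:

* a bird-level bias — a sum of half-sine modes anchored at zero at both
  endpoints, with bird-specific Gaussian amplitudes shrinking as 1/mode.
  Across birds these biases are independent with mean zero, so averaging
  routes cancels error: the statistical structure that makes a wisdom-of-
  crowds improvement possible in the first place.
* a smooth per-flight wiggle — an Ornstein-Uhlenbeck bridge pinned to zero at
  release and home, giving each route realistic small-scale tortuosity.

Amplitudes are calibrated by bisection so the population mean route
efficiency hits a configurable target (default 0.75, a plausible efficiency
for birds that have settled on an idiosyncratic route).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .geo import SiteGeometry, Trajectory
from .metrics import route_efficiency
from .pairing import fuse_pair

__all__ = [
    "SyntheticConfig",
    "BirdRoute",
    "site_geometry",
    "generate_solo_route",
    "generate_population",
    "calibrate_bias",
    "generate_paired_flight",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic route generator.

    ``bias_sd_m`` scales the bird-level route idiosyncrasy, and
    ``flight_noise_sd_m`` the within-route wiggle; both are perpendicular
    displacement scales in metres.  ``target_mean_efficiency`` drives the
    calibration loop in :func:`generate_population`.
    """

    beeline_m: float = 8400.0
    speed_mps: float = 20.0
    sample_hz: float = 1.0
    n_modes: int = 6
    bias_sd_m: float = 400.0
    flight_noise_sd_m: float = 60.0
    noise_corr_len_m: float = 400.0
    target_mean_efficiency: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beeline_m", "speed_mps", "sample_hz", "noise_corr_len_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bias_sd_m < 0 or self.flight_noise_sd_m < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0.0 < self.target_mean_efficiency < 1.0:
            raise ValueError("target_mean_efficiency must lie in (0, 1)")
        if self.n_modes < 1:
            raise ValueError("n_modes must be at least 1")


@dataclass(frozen=True)
class BirdRoute:
    """A bird's preferred route plus identity and solo performance."""

    bird_id: str
    route: Trajectory
    experience: str = "naive"
    solo_efficiency: float = float("nan")


def site_geometry(config: SyntheticConfig) -> SiteGeometry:
    """Release at (0, beeline), home at the origin, default exclusion radii."""
    return SiteGeometry(release=(0.0, config.beeline_m), home=(0.0, 0.0))


def _bird_rng(seed: int, bird_id: str) -> np.random.Generator:
    """Per-bird substream: stable under execution order and population size."""
    tag = zlib.crc32(str(bird_id).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, tag]))


def _ou_bridge(rng: np.random.Generator, s: np.ndarray, sd: float, corr_len: float) -> np.ndarray:
    """Stationary OU sample along s, pinned to zero at both endpoints."""
    if sd == 0.0:
        return np.zeros_like(s)
    ds = np.diff(s)
    a = np.exp(-ds / corr_len)
    x = np.empty(s.size)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd, size=ds.size) * np.sqrt(1.0 - a**2)
    for i in range(ds.size):  # short loop; routes are a few hundred points
        x[i + 1] = a[i] * x[i] + innov[i]
    frac = (s - s[0]) / (s[-1] - s[0])
    return x - (1.0 - frac) * x[0] - frac * x[-1]


def generate_solo_route(config: SyntheticConfig, bird_id: str) -> BirdRoute:
    """One bird's preferred route (deterministic in ``(config.seed, bird_id)``).

    The route runs from release to home, sampled at ``sample_hz`` along the
    beeline coordinate at the nominal flight speed.  Perpendicular
    displacement = half-sine bias modes + OU-bridge flight noise, both zero
    at the two endpoints.
    """
    rng = _bird_rng(config.seed, bird_id)
    B = config.beeline_m
    ds = config.speed_mps / config.sample_hz
    n_seg = int(np.ceil(B / ds))
    s = np.minimum(np.arange(n_seg + 1) * ds, B)

    k = np.arange(1, config.n_modes + 1)
    amps = rng.normal(0.0, config.bias_sd_m / k)
    d = np.sin(np.pi * np.outer(s / B, k)) @ amps
    d += _ou_bridge(rng, s, config.flight_noise_sd_m, config.noise_corr_len_m)

    times = np.arange(s.size) / config.sample_hz
    traj = Trajectory(times, d, B - s)
    eff = route_efficiency(traj, site_geometry(config)).efficiency
    return BirdRoute(bird_id=str(bird_id), route=traj, experience="naive", solo_efficiency=eff)


def _mean_efficiency(config: SyntheticConfig, bird_ids: list[str]) -> float:
    return float(
        np.mean([generate_solo_route(config, b).solo_efficiency for b in bird_ids])
    )


def calibrate_bias(config: SyntheticConfig, n_birds: int = 9, tol: float = 0.005,
                   max_iter: int = 40) -> SyntheticConfig:
    """Scale the noise amplitudes so the population mean efficiency hits target.

    Bisection on a common multiplier of ``bias_sd_m`` and
    ``flight_noise_sd_m``; mean efficiency is monotone decreasing in the
    multiplier, so the bracket is expanded upward until it straddles the
    target and then halved.
    """
    ids = [f"bird{i:02d}" for i in range(n_birds)]
    target = config.target_mean_efficiency

    def eff_at(scale: float) -> float:
        c = replace(
            config,
            bias_sd_m=config.bias_sd_m * scale,
            flight_noise_sd_m=config.flight_noise_sd_m * scale,
        )
        return _mean_efficiency(c, ids)

    lo, hi = 0.0, 1.0
    while eff_at(hi) > target:
        lo, hi = hi, hi * 2.0
        if hi > 1e4:
            raise RuntimeError("calibration bracket expansion failed")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        e = eff_at(mid)
        if abs(e - target) < tol:
            lo = hi = mid
            break
        if e > target:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    return replace(
        config,
        bias_sd_m=config.bias_sd_m * scale,
        flight_noise_sd_m=config.flight_noise_sd_m * scale,
    )


def generate_population(
    config: SyntheticConfig, n_birds: int = 9, calibrate: bool = True
) -> list[BirdRoute]:
    """Independent naive routes for ``n_birds`` birds.

    With ``calibrate=True`` (default) the noise amplitudes are first rescaled
    so the population mean solo efficiency matches
    ``config.target_mean_efficiency``.
    """
    if n_birds < 1:
        raise ValueError("n_birds must be at least 1")
    if calibrate:
        config = calibrate_bias(config, n_birds=n_birds)
    return [generate_solo_route(config, f"bird{i:02d}") for i in range(n_birds)]


def generate_paired_flight(
    routeE: BirdRoute | Trajectory,
    routeN: BirdRoute | Trajectory,
    w: float,
    jitter_sd_m: float = 5.0,
    lead_scale_m: float = 8.0,
    seed: int = 0,
) -> tuple[Trajectory, Trajectory]:
    """Two jittered realizations of a paired flight with social weight ``w``.

    The pair's center of mass tracks the w-weighted average of the two
    preferred routes, and the experienced bird is displaced forward along the
    direction of motion in proportion to (2w - 1): at w = 0.5 neither bird
    leads in expectation, at w = 1 the experienced bird is strictly ahead.
    Used as ground truth when validating the front-back leadership statistic.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    tE = routeE.route if isinstance(routeE, BirdRoute) else routeE
    tN = routeN.route if isinstance(routeN, BirdRoute) else routeN
    fused = fuse_pair(tE, tN, w)

    disp = np.diff(fused.xy, axis=0)
    norms = np.linalg.norm(disp, axis=1)
    u = np.zeros_like(disp)
    nz = norms > 0
    u[nz] = disp[nz] / norms[nz, None]
    u = np.vstack([u, u[-1]])  # direction at the final sample

    offset = 0.5 * lead_scale_m * (2.0 * w - 1.0)
    rng = np.random.default_rng(int(seed) % 2**31)
    s_axis = np.linspace(0.0, 1.0, fused.n_points)
    jitE = np.column_stack(
        [_ou_bridge(rng, s_axis, jitter_sd_m, 0.05) for _ in range(2)]
    )
    jitN = np.column_stack(
        [_ou_bridge(rng, s_axis, jitter_sd_m, 0.05) for _ in range(2)]
    )
    posE = fused.xy + offset * u + jitE
    posN = fused.xy - offset * u + jitN
    return (
        Trajectory(fused.times, posE[:, 0], posE[:, 1]),
        Trajectory(fused.times, posN[:, 0], posN[:, 1]),
    )
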