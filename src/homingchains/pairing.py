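"""Synchronizing two routes and fusing them by weighted averaging.

The core model of paired flight: the joint route of an experienced bird E and
a naive bird N is the convex combination

    X_avg(t) = w * X_E(t) + (1 - w) * X_N(t)
    Y_avg(t) = w * Y_E(t) + (1 - w) * Y_N(t)

where w in [0, 1] is the social weight (influence) of the experienced bird.
Before averaging, the shorter of the two tracks is resampled to the point
count of the longer one, so the combination is taken index-by-index.
"""

from __future__ import annotations

import numpy as np

from .geo import SiteGeometry, Trajectory

__all__ = [
    "resample_to_length",
    "weighted_average",
    "synchronize",
    "fuse_pair",
    "timestep_weights_closer_to_beeline",
]


def resample_to_length(traj: Trajectory, L_target: int) -> Trajectory:
    """Upsample a track to exactly ``L_target`` points.

    New sample times are uniform over the track's own time span; positions
    are linearly interpolated, so the polyline geometry (and hence the path
    length) is preserved up to the original vertices.  Only upsampling is
    defined: ``L_target`` must be at least the current point count.
    """
    L = traj.n_points
    if L_target < L:
        raise ValueError(f"resample_to_length only upsamples: {L_target} < {L}")
    if L_target == L:
        return traj
    grid = np.linspace(traj.times[0], traj.times[-1], L_target)
    x = np.interp(grid, traj.times, traj.x)
    y = np.interp(grid, traj.times, traj.y)
    return Trajectory(grid, x, y)


def synchronize(trajE: Trajectory, trajN: Trajectory) -> tuple[Trajectory, Trajectory]:
    """Bring two tracks to the same point count (the longer one's)."""
    L = max(trajE.n_points, trajN.n_points)
    return resample_to_length(trajE, L), resample_to_length(trajN, L)


def _as_weight_array(weights, L: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim == 0:
        w = np.full(L, float(w))
    if w.shape != (L,):
        raise ValueError(f"weight vector length {w.shape} does not match track length {L}")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    return w


def weighted_average(trajE: Trajectory, trajN: Trajectory, weights) -> Trajectory:
    """Convex combination of two synchronized tracks, per time step.

    ``weights`` is the experienced bird's social weight: a scalar w applied
    uniformly, or a length-L vector w(t) applied per step.  w = 0 returns the
    naive track, w = 1 the experienced track.
    """
    if trajE.n_points != trajN.n_points:
        raise ValueError(
            "tracks must be synchronized before averaging: "
            f"{trajE.n_points} vs {trajN.n_points} points"
        )
    w = _as_weight_array(weights, trajE.n_points)
    return Trajectory(
        trajE.times,
        w * trajE.x + (1.0 - w) * trajN.x,
        w * trajE.y + (1.0 - w) * trajN.y,
    )


def fuse_pair(trajE: Trajectory, trajN: Trajectory, weights) -> Trajectory:
    """Synchronize then weighted-average; the one-call pair-fusion operation."""
    E, N = synchronize(trajE, trajN)
    return weighted_average(E, N, weights)


def timestep_weights_closer_to_beeline(
    trajE: Trajectory,
    trajN: Trajectory,
    geom: SiteGeometry,
    w_near: float,
) -> np.ndarray:
    """Per-step weights favouring whichever bird is nearer the beeline.

    At each step the bird whose position lies at a smaller perpendicular
    distance from the release-to-home line receives weight ``w_near`` (the
    other ``1 - w_near``); exact ties get 0.5 each.  Returned as the
    experienced bird's weight vector.
    """
    if not 0.5 <= w_near <= 1.0:
        raise ValueError("w_near must lie in [0.5, 1]")
    if trajE.n_points != trajN.n_points:
        raise ValueError("tracks must be synchronized")
    u = geom.beeline_unit()
    normal = np.array([-u[1], u[0]])
    rel = np.asarray(geom.release, float)
    dE = np.abs((trajE.xy - rel) @ normal)
    dN = np.abs((trajN.xy - rel) @ normal)
    w = np.where(dE < dN, w_near, np.where(dN < dE, 1.0 - w_near, 0.5))
    return w
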