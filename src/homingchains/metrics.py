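"""Route efficiency: exclusion-zone trimming, path length and the joint route.

Route efficiency is the ratio of the (adjusted) beeline distance between
release and home to the distance actually flown: 1 means a perfectly straight
flight, values near 0 an arbitrarily tortuous one.  Because pigeons circle
near the release and home sites, points within fixed radii of the two sites
are removed first and the beeline is shortened by the same radii, so a
straight flight still scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import SiteGeometry, Trajectory

__all__ = [
    "EfficiencyResult",
    "TrimError",
    "trim_exclusion_zones",
    "route_efficiency",
    "joint_route",
]


class TrimError(ValueError):
    """Trajectory never leaves the release zone or never reaches the home zone."""


@dataclass(frozen=True)
class EfficiencyResult:
    """Route efficiency of one trimmed flight."""

    efficiency: float
    path_length_m: float
    adjusted_beeline_m: float
    n_points_used: int

    def __post_init__(self) -> None:
        if self.path_length_m < self.adjusted_beeline_m - 1e-6:
            raise ValueError("path length shorter than the adjusted beeline")


def _circle_exit_point(p0, p1, center, radius):
    """Point where the segment p0 -> p1 crosses the circle boundary.

    Solves |p0 + f (p1 - p0) - center| = radius for f in [0, 1] exactly, so
    the returned point lies on the boundary to machine precision (which makes
    trimming idempotent).
    """
    d = p1 - p0
    rel = p0 - center
    a = float(d @ d)
    if a == 0.0:
        return p1.copy()
    b = 2.0 * float(rel @ d)
    c = float(rel @ rel) - radius**2
    disc = b * b - 4.0 * a * c
    if disc < 0:  # grazing segment with rounding noise
        disc = 0.0
    roots = ((-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a))
    in_range = [f for f in roots if -1e-12 <= f <= 1 + 1e-12]
    if not in_range:  # numerically tangent; fall back to the nearer endpoint
        return p1.copy()
    f = min(max(in_range[0] if len(in_range) == 1 else max(in_range), 0.0), 1.0)
    return p0 + f * d


def trim_exclusion_zones(traj: Trajectory, geom: SiteGeometry) -> Trajectory:
    """Cut a flight to the segment outside both exclusion circles.

    Keeps the piece from the *last* exit of the release circle to the *first
    subsequent* entry of the home circle, with the two boundary crossing
    points included (interpolated on the bracketing segments).  This removes
    circling at both ends of the flight.
    """
    tol = 1e-9
    rel = np.asarray(geom.release, float)
    hom = np.asarray(geom.home, float)
    xy = traj.xy
    d_rel = np.hypot(xy[:, 0] - rel[0], xy[:, 1] - rel[1])
    d_hom = np.hypot(xy[:, 0] - hom[0], xy[:, 1] - hom[1])

    inside_rel = d_rel < geom.release_excl_m - tol
    # last strict inside -> outside transition of the release circle
    exits = np.nonzero(inside_rel[:-1] & ~inside_rel[1:])[0]
    if exits.size > 0:
        i = int(exits[-1])
        exit_pt = _circle_exit_point(xy[i], xy[i + 1], rel, geom.release_excl_m)
        seg = np.hypot(*(xy[i + 1] - xy[i]))
        frac = 0.0 if seg == 0 else np.hypot(*(exit_pt - xy[i])) / seg
        t_exit = traj.times[i] + frac * (traj.times[i + 1] - traj.times[i])
        first_keep = i + 1
    elif d_rel[0] >= geom.release_excl_m - 1e-6:
        # already trimmed: the track starts on or outside the boundary
        exit_pt, t_exit, first_keep = xy[0], float(traj.times[0]), 1
    else:
        raise TrimError("trajectory never leaves the release exclusion zone")

    inside_hom = d_hom < geom.home_excl_m - tol
    entries = np.nonzero(~inside_hom[:-1] & inside_hom[1:])[0]
    entries = entries[entries >= first_keep - 1]
    if entries.size > 0:
        j = int(entries[0])
        entry_pt = _circle_exit_point(xy[j], xy[j + 1], hom, geom.home_excl_m)
        seg = np.hypot(*(xy[j + 1] - xy[j]))
        frac = 0.0 if seg == 0 else np.hypot(*(entry_pt - xy[j])) / seg
        t_entry = traj.times[j] + frac * (traj.times[j + 1] - traj.times[j])
        last_keep = j + 1  # slice end (exclusive) for interior samples
    elif d_hom[-1] <= geom.home_excl_m + 1e-6:
        # already trimmed: the track ends on the home boundary
        entry_pt, t_entry, last_keep = xy[-1], float(traj.times[-1]), traj.n_points - 1
    else:
        raise TrimError("trajectory never enters the home exclusion zone after leaving release")

    times = np.concatenate([[t_exit], traj.times[first_keep:last_keep], [t_entry]])
    x = np.concatenate([[exit_pt[0]], traj.x[first_keep:last_keep], [entry_pt[0]]])
    y = np.concatenate([[exit_pt[1]], traj.y[first_keep:last_keep], [entry_pt[1]]])
    # crossing points can coincide with the bracketing samples; drop dup times
    ok = np.concatenate([[True], np.diff(times) > 1e-12])
    if ok.sum() < 2:
        raise TrimError("trimmed segment degenerate")
    return Trajectory(times[ok], x[ok], y[ok])


def route_efficiency(traj: Trajectory, geom: SiteGeometry) -> EfficiencyResult:
    """Adjusted beeline over trimmed path length.

    Efficiency 1 corresponds to a straight release-to-home flight; smaller
    values to longer (less direct) flights.
    """
    trimmed = trim_exclusion_zones(traj, geom)
    length = trimmed.path_length()
    adj = geom.adjusted_beeline_m
    return EfficiencyResult(
        efficiency=adj / length,
        path_length_m=length,
        adjusted_beeline_m=adj,
        n_points_used=trimmed.n_points,
    )


def joint_route(trajA: Trajectory, trajB: Trajectory) -> Trajectory:
    """Center of mass of two synchronized tracks at each time point."""
    if trajA.n_points != trajB.n_points:
        raise ValueError(
            "tracks must share a common grid (resample first): "
            f"{trajA.n_points} vs {trajB.n_points} points"
        )
    return Trajectory(
        trajA.times,
        0.5 * (trajA.x + trajB.x),
        0.5 * (trajA.y + trajB.y),
    )
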