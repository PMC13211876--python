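"""Front-back leadership statistic for paired flights.

At each time step the experienced-minus-naive position vector is projected
onto the pair centroid's direction of motion over the following step; the
sign of that projection d_EN says which bird is in front.  The fraction of
steps with a positive sign is the flight's leadership fraction — the
empirical counterpart of the social weight w in the fusion model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import Trajectory

__all__ = ["LeadershipResult", "d_en_series", "leadership_fraction"]

MOTION_THRESHOLD_M = 0.5  # steps where the centroid moves less are dropped


@dataclass(frozen=True)
class LeadershipResult:
    """Signed front-back series and the summary front fraction."""

    d_en: np.ndarray
    front_fraction: float
    n_steps_used: int


def d_en_series(
    trajE: Trajectory,
    trajN: Trajectory,
    motion_threshold_m: float = MOTION_THRESHOLD_M,
) -> np.ndarray:
    """Signed front-back displacement of E relative to N, per step.

    d_EN(t) = (posE(t) - posN(t)) . u(t), with u(t) the unit vector of the
    pair-centroid displacement from t to t+1.  Steps where the centroid moves
    less than ``motion_threshold_m`` are dropped (their direction is
    numerically meaningless); positive values mean the experienced bird is in
    front.
    """
    if trajE.n_points != trajN.n_points:
        raise ValueError("tracks must be synchronized")
    if trajE.n_points < 3:
        raise ValueError("need at least 3 points for a direction of motion")
    centroid = 0.5 * (trajE.xy + trajN.xy)
    disp = np.diff(centroid, axis=0)
    norms = np.linalg.norm(disp, axis=1)
    moving = norms >= motion_threshold_m
    if not moving.any():
        raise ValueError("pair centroid is stationary throughout; no motion direction")
    rel = (trajE.xy - trajN.xy)[:-1]
    u = disp[moving] / norms[moving, None]
    return np.einsum("ij,ij->i", rel[moving], u)


def leadership_fraction(
    trajE: Trajectory,
    trajN: Trajectory,
    motion_threshold_m: float = MOTION_THRESHOLD_M,
) -> LeadershipResult:
    """Proportion of (retained) steps with the experienced bird in front.

    Exact zeros of d_EN (birds abreast) count half, so swapping the two birds
    maps a fraction f to exactly 1 - f.
    """
    d = d_en_series(trajE, trajN, motion_threshold_m)
    frac = float((np.sum(d > 0) + 0.5 * np.sum(d == 0)) / d.size)
    return LeadershipResult(d_en=d, front_fraction=frac, n_steps_used=int(d.size))
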