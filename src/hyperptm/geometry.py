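"""Primitives of the two-dimensional hyperbolic plane (curvature K = -1).

In the popularity-similarity picture a node lives at polar coordinates
``(r, theta)`` on a hyperbolic disc: the radius encodes popularity/seniority
and the angle encodes similarity.  Distances between nodes combine both
dimensions through the hyperbolic law of cosines and are what both the
embedding likelihood and the edge-level classifier features consume.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolarCoordinate",
    "angular_separation",
    "hyperbolic_distance",
    "radial_difference",
]

TWO_PI = 2.0 * np.pi

#: Below this angular separation the law-of-cosines argument suffers
#: catastrophic cancellation; the distance degenerates to |r1 - r2|.
_COLLINEAR_EPS = 1e-12


@dataclass(frozen=True)
class PolarCoordinate:
    """A point on the hyperbolic disc: radius ``r >= 0``, angle in ``[0, w)``."""

    r: float
    theta: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"radius must be nonnegative, got {self.r}")


def angular_separation(theta1, theta2, w: float = TWO_PI):
    """Shortest angular distance between two angles on a circle of span ``w``.

    Returns a value in ``[0, w/2]``.
    """
    diff = np.abs(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float))
    sep = np.minimum(diff, w - diff)
    return sep if sep.ndim else float(sep)


def hyperbolic_distance(r1, theta1, r2, theta2, w: float = TWO_PI):
    """Distance in H^2 via the hyperbolic law of cosines.

    ``d = acosh(cosh r1 cosh r2 - sinh r1 sinh r2 cos(dtheta))`` with the
    angular separation taken on a circle of span ``w``.  The acosh argument
    is clamped at 1 against round-off, and nearly collinear pairs
    (``dtheta < 1e-12``) short-circuit to ``|r1 - r2|`` where the closed
    form is exact but numerically hostile.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    dtheta = angular_separation(theta1, theta2, w)
    arg = np.cosh(r1) * np.cosh(r2) - np.sinh(r1) * np.sinh(r2) * np.cos(dtheta)
    d = np.arccosh(np.maximum(arg, 1.0))
    d = np.where(np.asarray(dtheta) < _COLLINEAR_EPS, np.abs(r1 - r2), d)
    return d if d.ndim else float(d)


def pair_distance(c1: PolarCoordinate, c2: PolarCoordinate, w: float = TWO_PI) -> float:
    """`hyperbolic_distance` on two :class:`PolarCoordinate` points."""
    return hyperbolic_distance(c1.r, c1.theta, c2.r, c2.theta, w)


def radial_difference(r1, r2):
    """Absolute difference of radii, ``|r1 - r2|``.

    Equals the hyperbolic distance when the angular separation is zero.
    """
    out = np.abs(np.asarray(r1, dtype=float) - np.asarray(r2, dtype=float))
    return out if out.ndim else float(out)
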