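"""Periodic B-spline bases on the color circle.

The population encoding models map an angle theta in [0, 2pi) to a
K-dimensional feature vector f(theta) built from K periodic B-splines with
uniform knots at k*2pi/K.  ``order=1`` gives piecewise-linear "tent"
functions (one-hot at the knots); ``order=2`` quadratic B-splines.  In
either case the basis is a partition of unity (components are nonnegative
and sum to 1 for every theta) and periodic: f(theta) = f(theta + 2pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .circular import TWO_PI, wrap_to_pi


@dataclass(frozen=True)
class SplineBasisSpec:
    """Specification of a periodic spline basis.

    Parameters
    ----------
    n_knots : int
        Number of basis functions K (uniform knots at k*2pi/K).
        Must satisfy K >= order + 2.
    order : int
        Polynomial degree of each piece: 1 = piecewise linear, 2 = quadratic.
    """

    n_knots: int = 5
    order: int = 1

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.n_knots < self.order + 2:
            raise ValueError(
                f"need K >= order + 2 basis functions (got K={self.n_knots}, "
                f"order={self.order})"
            )

    @property
    def knots(self) -> np.ndarray:
        return TWO_PI * np.arange(self.n_knots) / self.n_knots


def spline_basis(theta, spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate the periodic B-spline basis at ``theta``.

    Parameters
    ----------
    theta : float or array
        Angle(s) in radians; periodicity is handled internally.
    spec : SplineBasisSpec

    Returns
    -------
    ndarray
        Shape ``theta.shape + (K,)``; each row is nonnegative and sums to 1.
    """
    theta = np.asarray(theta, dtype=float)
    K, p = spec.n_knots, spec.order
    h = TWO_PI / K
    # Cardinal B-spline of degree p on knots [0, h, ..., (p+1)h], peak at the
    # support midpoint. K >= p + 2 guarantees the support half-width
    # (p+1)h/2 < pi, so a single wrapped evaluation per basis function covers
    # the circle.
    proto = BSpline.basis_element(h * np.arange(p + 2), extrapolate=False)
    half_support = (p + 1) * h / 2.0

    arg = wrap_to_pi(theta[..., None] - spec.knots) + half_support
    out = np.zeros(arg.shape)
    inside = (arg >= 0) & (arg <= 2 * half_support)
    out[inside] = np.nan_to_num(proto(arg[inside]))
    return out
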