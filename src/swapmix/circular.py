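"""Circular (angular) utilities shared across the package.

All colors live on the hue circle, represented in radians in [0, 2pi).
Errors between angles are wrapped differences in (-pi, pi].  Dispersion is
modelled with a wrapped normal density, computed as a truncated wrap sum
over offsets k*2pi with |k| <= WRAP_K (density error < 1e-12 for
sigma <= 1 rad).
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

#: number of wrap offsets on each side of zero used in wrapped-normal sums
WRAP_K = 3

_OFFSETS = TWO_PI * np.arange(-WRAP_K, WRAP_K + 1)  # shape (2K+1,)


def wrap_to_2pi(theta):
    """Map angles onto [0, 2pi)."""
    wrapped = np.mod(theta, TWO_PI)
    # np.mod of a tiny negative float can round to the modulus itself
    return np.where(wrapped >= TWO_PI, 0.0, wrapped)


def wrap_to_pi(theta):
    """Map angular differences onto (-pi, pi]."""
    wrapped = np.mod(-np.asarray(theta, dtype=float) + np.pi, TWO_PI)
    return -(wrapped - np.pi)


def circ_dist(a, b):
    """Wrapped difference a - b in (-pi, pi]."""
    return wrap_to_pi(np.asarray(a, dtype=float) - b)


def color_grid(n: int = 64) -> np.ndarray:
    """The discrete stimulus grid: ``n`` uniform points k*2pi/n on the circle."""
    return TWO_PI * np.arange(n) / n


def wrapped_normal_pdf(err, sigma):
    """Wrapped normal density at wrapped error ``err`` (mean 0, SD ``sigma``).

    ``err`` and ``sigma`` broadcast against each other.
    """
    err = np.asarray(err, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    # widen the wrap sum for large dispersions so the density stays within
    # 1e-12 of the infinite sum (k_max ~ 4 sigma / 2pi suffices)
    k_max = max(WRAP_K, int(np.ceil(4.0 * float(np.max(sigma)) / TWO_PI)) + 1)
    offsets = _OFFSETS if k_max == WRAP_K else TWO_PI * np.arange(-k_max, k_max + 1)
    z = (err[..., None] + offsets) / sigma[..., None]
    dens = np.exp(-0.5 * z * z).sum(axis=-1) / (np.sqrt(TWO_PI) * sigma)
    return dens


def wrapped_normal_logpdf(err, sigma):
    """Log of :func:`wrapped_normal_pdf` (computed with the same wrap sum)."""
    return np.log(wrapped_normal_pdf(err, sigma))


def wrapped_normal_sample(rng: np.random.Generator, sigma, size=None):
    """Sample wrapped-normal errors in (-pi, pi]: a normal draw, wrapped."""
    return wrap_to_pi(rng.normal(0.0, sigma, size=size))
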