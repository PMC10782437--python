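"""Coordinate handling for the generative latent space.

The molecule generator's latent space has independent standard-normal
coordinates (56 dimensions for the pretrained junction-tree VAE).  The
optimizer works in the unit hypercube instead; points move between the two
via the probit transform: ``u = Phi(z)`` maps the Gaussian prior to a
per-coordinate uniform distribution on (0, 1), and ``z = Phi^{-1}(u)``
recovers latent coordinates from hypercube points.  Coordinates are clamped
to ``[EPS, 1-EPS]`` so the inverse transform never produces infinities.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["EPS", "LATENT_DIM", "to_hypercube", "from_hypercube", "sample_latent_prior"]

#: Hypercube boundary clamp.  1e-10 keeps the probit finite while leaving
#: the round trip exact through |z| <= 6 (Phi(6) ~ 1 - 1e-9 is not clipped).
EPS = 1e-10

#: Default latent dimensionality (junction-tree VAE).
LATENT_DIM = 56


def to_hypercube(z: np.ndarray) -> np.ndarray:
    """Map standard-normal latent coordinates to the unit hypercube.

    Applies the standard normal CDF elementwise, then clamps to
    ``[EPS, 1-EPS]``.  Works on a single vector or a batch (last axis =
    dimension).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("latent coordinates must be finite")
    return np.clip(ndtr(z), EPS, 1.0 - EPS)


def from_hypercube(u: np.ndarray) -> np.ndarray:
    """Map hypercube coordinates back to standard-normal latent coordinates
    via the normal quantile function."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0) or not np.all(np.isfinite(u)):
        raise ValueError("hypercube coordinates must lie in [0, 1]")
    return ndtri(np.clip(u, EPS, 1.0 - EPS))


def sample_latent_prior(
    n: int, dim: int = LATENT_DIM, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` i.i.d. latent vectors from the standard-normal prior.

    Returns an ``(n, dim)`` array; reproducible for a fixed integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, dim))
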