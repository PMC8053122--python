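"""Stationary AR(1) sampling and the Gaussian-copula marginal transform.

Shared by the synthetic-trajectory generator and the correlated bootstrap.
The serial-correlation strength is parametrized by the integrated
autocorrelation time tau = 1 + 2*sum_k rho(k); for an AR(1) process with
lag-1 coefficient phi this equals (1+phi)/(1-phi), hence

    phi = (tau - 1) / (tau + 1),

clipped to 0 for tau <= 1 (i.i.d. limit).  Target marginals are imposed by
mapping the Gaussian through its CDF and then through the inverse CDF of the
target distribution (Gaussian copula), which preserves tau to first order
and the marginal exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter
from scipy.special import ndtr

__all__ = ["phi_from_tau", "tau_from_phi", "sample_ar1", "gaussian_copula_map"]


def phi_from_tau(tau: float) -> float:
    """Lag-1 AR coefficient with integrated autocorrelation time ``tau``."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    return max(0.0, (tau - 1.0) / (tau + 1.0))


def tau_from_phi(phi: float) -> float:
    """Integrated autocorrelation time (1+phi)/(1-phi) of an AR(1) process."""
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    return (1.0 + phi) / (1.0 - phi)


def sample_ar1(shape: tuple[int, int], phi: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance Gaussian AR(1) rows, z_t = phi z_{t-1} + e_t.

    Innovations have variance 1 - phi^2 so the marginal is exactly N(0, 1)
    from the first sample on.
    """
    m, n = shape
    e = rng.standard_normal((m, n)) * np.sqrt(1.0 - phi * phi)
    # Scale the first innovation so z_0 ~ N(0,1) (stationary start).
    e[:, 0] /= np.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], e, axis=1)


def gaussian_copula_map(z: np.ndarray, ppf) -> np.ndarray:
    """Map standard-normal draws through Phi then a target inverse CDF."""
    return ppf(ndtr(z))
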