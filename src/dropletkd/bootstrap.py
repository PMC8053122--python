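"""Autocorrelation-aware bootstrap bands for binned probability densities.

Molecular-dynamics observables such as the radius of gyration are strongly
serially correlated, so a naive i.i.d. bootstrap of the trajectory badly
understates the uncertainty of its histogram density.  This module first
estimates the integrated autocorrelation time tau of the scalar series, then
resamples synthetic trajectories that share both the empirical marginal
distribution and tau (Gaussian-copula AR(1) through the empirical inverse
CDF; a moving-block bootstrap is available as a cross-check), and reports
pointwise 95% confidence bands of the binned density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._ar1 import gaussian_copula_map, phi_from_tau, sample_ar1

__all__ = ["RgSample", "BootstrapCI", "autocorrelation_time", "bootstrap_pdf"]

#: Sokal window factor: truncate the ACF sum at the first lag W >= c * tau(W)
SOKAL_C = 5.0


@dataclass(frozen=True)
class RgSample:
    """A scalar series (e.g. radius of gyration, nm) with its tau."""

    values: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_series(cls, values: np.ndarray) -> "RgSample":
        """Build a sample, estimating tau from the series itself."""
        return cls(values=np.asarray(values, float),
                   tau=autocorrelation_time(values))


@dataclass(frozen=True)
class BootstrapCI:
    """Binned density with a pointwise bootstrap confidence band."""

    bin_edges: np.ndarray
    p_hat: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_boot: int
    n_per: int
    tau: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def autocorrelation_time(values: np.ndarray, c: float = SOKAL_C) -> float:
    """Integrated autocorrelation time with the self-consistent window.

    tau_int(W) = 1 + 2 sum_{k=1}^{W} rho(k), evaluated at the smallest
    window W >= c * tau_int(W) (Sokal's criterion, c = 5).  The ACF is
    computed by FFT on the mean-subtracted series.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 points to estimate tau, got {n}")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0.0:
        raise ValueError("constant series: autocorrelation time undefined")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n] / n
    rho = acov / acov[0]
    csum = 1.0 + 2.0 * np.cumsum(rho[1:])
    w_max = n // 3
    for w in range(1, w_max):
        if w >= c * csum[w - 1]:
            return float(max(csum[w - 1], 1.0))
    raise ValueError(
        "series too short for the self-consistent window: no W < n/3 "
        f"satisfies W >= {c}*tau(W); tau(n/3) ~ {csum[w_max - 2]:.3g}"
    )


def _empirical_ppf(values: np.ndarray):
    """Inverse CDF of the empirical distribution (linear interpolation)."""
    xs = np.sort(values)
    n = xs.size
    us = (np.arange(n) + 0.5) / n
    return lambda u: np.interp(u, us, xs)


def _copula_resamples(values, tau, n_boot, n_per, rng, chunk_elems=20_000_000):
    phi = phi_from_tau(tau)
    ppf = _empirical_ppf(values)
    done = 0
    while done < n_boot:
        m = min(n_boot - done, max(1, chunk_elems // n_per))
        z = sample_ar1((m, n_per), phi, rng)
        yield gaussian_copula_map(z, ppf)
        done += m


def _block_resamples(values, tau, n_boot, n_per, rng):
    n = values.size
    block = max(1, int(round(2.0 * max(tau, 1.0))))
    n_blocks = int(np.ceil(n_per / block))
    for _ in range(n_boot):
        starts = rng.integers(0, n - block + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n_per]
        yield values[idx][None, :]


def bootstrap_pdf(
    sample: RgSample,
    n_boot: int = 2000,
    n_per: int | None = None,
    bins: int | str | np.ndarray = "fd",
    seed: int | None = None,
    method: str = "copula",
    ci: float = 95.0,
) -> BootstrapCI:
    """Bootstrap a binned density with serial-correlation-aware resampling.

    Each of the ``n_boot`` resamples contains ``n_per`` points drawn to
    follow the empirical distribution of ``sample.values`` with integrated
    autocorrelation time ``sample.tau`` (``method="copula"``: Gaussian-copula
    AR(1) through the empirical inverse CDF; ``method="block"``: moving-block
    bootstrap with block length ~2*tau).  The band is the pointwise
    ``ci``% percentile interval of the resampled densities.  Production-scale
    workloads (10^6 resamples of 10^5 points) are supported by chunked
    generation; defaults are scaled down.
    """
    values = np.asarray(sample.values, dtype=float)
    if n_boot < 100 or (n_per is not None and n_per < 100):
        raise ValueError("n_boot and n_per must both be >= 100")
    if n_per is None:
        n_per = values.size
    if method not in ("copula", "block", "iid"):
        raise ValueError("method must be 'copula', 'block' or 'iid'")
    rng = np.random.default_rng(seed)

    edges = np.histogram_bin_edges(values, bins=bins)
    p_hat, _ = np.histogram(values, bins=edges, density=True)

    tau = sample.tau if method != "iid" else 0.0
    if method == "block":
        gen = _block_resamples(values, tau, n_boot, n_per, rng)
    else:
        gen = _copula_resamples(values, tau, n_boot, n_per, rng)

    alpha = 0.5 * (100.0 - ci)
    dens = np.empty((n_boot, p_hat.size))
    row = 0
    for chunk in gen:
        for series in chunk:
            dens[row], _ = np.histogram(series, bins=edges, density=True)
            row += 1
    lo = np.percentile(dens, alpha, axis=0)
    hi = np.percentile(dens, 100.0 - alpha, axis=0)

    empty_frac = np.mean(dens.mean(axis=0) == 0.0)
    if empty_frac > 0.5:
        warnings.warn(
            f"{empty_frac:.0%} of bins are empty across resamples; the band "
            "is undefined there", stacklevel=2)
    # The band brackets the resampling distribution; clip so the point
    # estimate is inside (guards against percentile/interp edge effects).
    lo = np.minimum(lo, p_hat)
    hi = np.maximum(hi, p_hat)
    return BootstrapCI(bin_edges=edges, p_hat=p_hat, lo=lo, hi=hi,
                       n_boot=n_boot, n_per=n_per, tau=tau)
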