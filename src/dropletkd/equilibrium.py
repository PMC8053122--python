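"""Surface-localized binding equilibrium for DNA-functionalized droplets.

A cholesterol-tagged ssDNA handle anchors at the water-oil interface of a
spherical droplet (radius ``r0``) and recruits a fluorescently labelled tsDNA
from the droplet volume.  Binding is confined to a thin reaction layer of
apparent thickness ``eps`` adjacent to the surface.  At steady state the
peripheral-to-inner fluorescence intensity ratio reads

    I_peri / I_in = 1 + S_tot / (T_eq + K_D)

where ``S_tot`` is the handle (site) concentration referenced to the reaction
layer, ``T_eq`` the free tsDNA concentration and ``K_D = k_off/k_on`` the
apparent dissociation constant.  Requiring mass-action equilibrium together
with conservation of the total tsDNA amount per droplet,

    T_tot = T_eq + g * C_eq,    g = 3*eps/r0,

yields a quadratic in ``T_eq`` whose non-negative root is

    T_eq = 1/2 * [-(g*S_tot + K_D - T_tot)
                  + sqrt((g*S_tot + K_D - T_tot)^2 + 4*T_tot*K_D)].

``g`` is the thin-shell volume fraction of the reaction layer.  Inverting the
measured ratio for ``K_D`` and propagating the measurement uncertainties of
``I_peri``, ``I_in``, ``r0`` and ``eps`` turns per-droplet image statistics
into per-droplet apparent dissociation constants.

Concentrations are in uM, lengths in um throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "EquilibriumSystem",
    "EquilibriumState",
    "KdEstimate",
    "steady_state",
    "predict_ratio",
    "invert_kd",
    "propagate_error",
    "bulk_to_layer",
    "layer_to_bulk",
    "estimate_kd_table",
]

#: bracket for the scalar K_D root search, in uM
_KD_BRACKET = (1e-6, 1e6)


class DomainError(ValueError):
    """Raised when a physical parameter violates the model's domain."""


@dataclass(frozen=True)
class EquilibriumSystem:
    """Physical parameters of one droplet's binding equilibrium.

    Parameters
    ----------
    S_tot : float
        ssDNA site concentration referenced to the reaction layer (uM).
    T_tot : float
        Total tsDNA concentration per droplet volume (uM).
    K_D : float
        Apparent dissociation constant (uM); ``K_D = 0`` is the
        tight-binding limit.
    eps : float
        Apparent reaction-layer thickness (um).
    r0 : float
        Droplet radius (um).
    """

    S_tot: float
    T_tot: float
    K_D: float
    eps: float
    r0: float

    def __post_init__(self) -> None:
        for name in ("S_tot", "T_tot", "K_D"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("eps", "r0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and > 0, got {v!r}")
        if self.eps >= self.r0:
            raise DomainError(
                f"eps must be smaller than r0 (got eps={self.eps}, r0={self.r0})"
            )

    @property
    def g(self) -> float:
        """Thin-shell layer/volume coupling factor ``3*eps/r0`` (in (0, 3))."""
        return 3.0 * self.eps / self.r0


@dataclass(frozen=True)
class EquilibriumState:
    """Steady state of one droplet: free tsDNA, bound complex, intensity ratio."""

    T_eq: float   #: free tsDNA concentration (uM)
    C_eq: float   #: bound complex, referenced to the reaction layer (uM)
    ratio: float  #: predicted I_peri / I_in (dimensionless, >= 1)


@dataclass(frozen=True)
class KdEstimate:
    """Apparent K_D with propagated uncertainty.

    ``is_unbound_sentinel`` marks measurements with ratio <= 1, i.e. no
    detectable peripheral enrichment; these correspond to K_D >> all
    concentrations and carry ``kd = inf``.
    """

    kd: float
    sigma_kd: float = float("nan")
    is_unbound_sentinel: bool = False


def bulk_to_layer(c_bulk: float, r0: float, eps: float) -> float:
    """Convert a concentration prepared per droplet volume to layer reference.

    A species confined to the thin surface shell occupies the volume fraction
    g = 3*eps/r0 of the droplet, so its layer-referenced concentration is the
    bulk one divided by g.
    """
    return c_bulk * r0 / (3.0 * eps)


def layer_to_bulk(c_layer: float, r0: float, eps: float) -> float:
    """Inverse of :func:`bulk_to_layer`."""
    return c_layer * 3.0 * eps / r0


def steady_state(sys: EquilibriumSystem) -> EquilibriumState:
    """Solve the binding equilibrium of one droplet.

    Returns the non-negative root of the mass-action + conservation quadratic
    together with the bound-complex concentration and the predicted
    peripheral-to-inner intensity ratio.
    """
    S, T, K, g = sys.S_tot, sys.T_tot, sys.K_D, sys.g
    b = g * S + K - T
    disc = math.sqrt(b * b + 4.0 * T * K)
    # Cancellation-free form of the non-negative quadratic root: for b > 0
    # the textbook (-b + disc)/2 loses precision when 4*T*K << b^2.
    T_eq = 2.0 * T * K / (b + disc) if b > 0 else 0.5 * (disc - b)
    if K == 0.0:
        # Tight-binding limit: sites soak up tsDNA until either species runs out.
        T_eq = max(0.0, T - g * S)
        C_eq = (T - T_eq) / g if g > 0 else 0.0
    else:
        T_eq = max(0.0, T_eq)
        C_eq = S * T_eq / (K + T_eq)
    denom = T_eq + K
    ratio = 1.0 + S / denom if denom > 0 else float("inf")
    return EquilibriumState(T_eq=T_eq, C_eq=C_eq, ratio=ratio)


def predict_ratio(sys: EquilibriumSystem) -> float:
    """Predicted I_peri/I_in for a droplet at equilibrium (>= 1)."""
    return steady_state(sys).ratio


def _kd_closed_form(ratio: float, S_tot: float, T_tot: float, g: float) -> float:
    """Algebraic inversion; cross-check for the root-finding path.

    With u = S_tot/(ratio - 1) = T_eq + K_D, conservation gives
    K_D = u * (u + g*S_tot - T_tot) / (u + g*S_tot).
    """
    u = S_tot / (ratio - 1.0)
    return u * (u + g * S_tot - T_tot) / (u + g * S_tot)


def invert_kd(
    ratio: float,
    S_tot: float,
    T_tot: float,
    eps: float,
    r0: float,
    sigma_inputs: dict[str, float] | None = None,
    I_in: float | None = None,
    I_peri: float | None = None,
) -> KdEstimate:
    """Invert a measured intensity ratio for the apparent K_D.

    The primary path brackets K_D in [1e-6, 1e6] uM and solves
    ``predict_ratio(K_D) = ratio`` by Brent's method (with a bisection
    fallback); the algebraic closed form serves as a consistency check.

    Parameters
    ----------
    ratio : float
        Measured I_peri / I_in.  ``ratio <= 1`` yields the unbound sentinel.
    S_tot, T_tot : float
        Layer-referenced site and total tsDNA concentrations (uM).
    eps, r0 : float
        Reaction-layer thickness and droplet radius (um).
    sigma_inputs : dict, optional
        Standard uncertainties keyed by ``{"I_in", "I_peri", "r0", "eps"}``.
        When given (together with ``I_in``/``I_peri``), first-order error
        propagation fills ``sigma_kd``.
    I_in, I_peri : float, optional
        Raw intensities; required only for error propagation (the ratio
        alone does not fix the partials with respect to I_in and I_peri).
    """
    if not math.isfinite(ratio):
        raise DomainError(f"ratio must be finite, got {ratio!r}")
    # Validate geometry/concentrations through the dataclass invariants.
    probe = EquilibriumSystem(S_tot=S_tot, T_tot=T_tot, K_D=1.0, eps=eps, r0=r0)
    if ratio <= 1.0:
        return KdEstimate(kd=float("inf"), sigma_kd=float("nan"),
                          is_unbound_sentinel=True)
    g = probe.g
    u = S_tot / (ratio - 1.0)  # = T_eq + K_D
    kd_cf = _kd_closed_form(ratio, S_tot, T_tot, g)
    if kd_cf < 0.0:
        raise DomainError(
            "inconsistent inputs: the measured ratio implies a negative free "
            f"tsDNA concentration (closed-form K_D = {kd_cf:.4g} uM < 0; "
            f"u = {u:.4g} uM). Check S_tot/T_tot reference volumes and eps."
        )

    def resid(kd: float) -> float:
        return predict_ratio(replace(probe, K_D=kd)) - ratio

    lo, hi = _KD_BRACKET
    kd: float
    if kd_cf < lo or kd_cf > hi or resid(lo) * resid(hi) > 0:
        # Outside the search bracket (extremely tight or loose binding):
        # fall back on the closed form, which is exact algebraically.
        kd = kd_cf
    else:
        try:
            kd = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-12)
        except ValueError:
            # bisection fallback (resid is monotone decreasing in K_D)
            a, b_ = lo, hi
            for _ in range(200):
                m = 0.5 * (a + b_)
                if resid(m) > 0:
                    a = m
                else:
                    b_ = m
            kd = 0.5 * (a + b_)

    sigma = float("nan")
    if sigma_inputs is not None:
        if I_in is None or I_peri is None:
            raise ValueError("error propagation requires I_in and I_peri")
        sigma = propagate_error(
            I_in=I_in, I_peri=I_peri, r0=r0, eps=eps,
            S_tot=S_tot, T_tot=T_tot, sigma_inputs=sigma_inputs,
        )
    return KdEstimate(kd=kd, sigma_kd=sigma, is_unbound_sentinel=False)


def _kd_of_inputs(I_peri: float, I_in: float, r0: float, eps: float,
                  S_tot: float, T_tot: float, layer_ref_fixed: bool) -> float:
    """K_D as a function of the four measured quantities.

    ``layer_ref_fixed=True`` treats S_tot as already layer-referenced and
    independent of (r0, eps); ``False`` treats S_tot as a bulk concentration
    that is re-referenced with the *measured* r0 and eps (the imaging
    pipeline's situation).
    """
    S = S_tot if layer_ref_fixed else bulk_to_layer(S_tot, r0, eps)
    est = invert_kd(I_peri / I_in, S_tot=S, T_tot=T_tot, eps=eps, r0=r0)
    return est.kd


def propagate_error(
    I_in: float,
    I_peri: float,
    r0: float,
    eps: float,
    S_tot: float,
    T_tot: float,
    sigma_inputs: dict[str, float],
    layer_ref_fixed: bool = True,
    rel_step: float = 1e-6,
) -> float:
    """First-order propagation of measurement uncertainty into sigma(K_D).

    sigma^2(K_D) = sum_i (dK_D/dx_i)^2 sigma^2(x_i) over
    x in {I_peri, I_in, r0, eps}, with partials taken by central finite
    differences at relative step ``rel_step`` and the uncertainties treated
    as independent.

    Raises
    ------
    DomainError
        If the central estimate is the unbound sentinel (ratio <= 1), for
        which sigma is undefined.
    """
    ratio = I_peri / I_in
    if ratio <= 1.0:
        raise DomainError("sigma_kd is undefined for unbound (ratio <= 1) droplets")
    for k, v in sigma_inputs.items():
        if k not in ("I_in", "I_peri", "r0", "eps"):
            raise ValueError(f"unknown uncertainty key {k!r}")
        if v < 0:
            raise ValueError(f"sigma({k}) must be >= 0")
    x0 = {"I_peri": I_peri, "I_in": I_in, "r0": r0, "eps": eps}
    var = 0.0
    for name, sig in sigma_inputs.items():
        if sig == 0.0:
            continue
        h = rel_step * abs(x0[name]) or rel_step
        hi = dict(x0)
        lo = dict(x0)
        hi[name] += h
        lo[name] -= h
        f_hi = _kd_of_inputs(**hi, S_tot=S_tot, T_tot=T_tot,
                             layer_ref_fixed=layer_ref_fixed)
        f_lo = _kd_of_inputs(**lo, S_tot=S_tot, T_tot=T_tot,
                             layer_ref_fixed=layer_ref_fixed)
        var += ((f_hi - f_lo) / (2.0 * h)) ** 2 * sig ** 2
    return math.sqrt(var)


def estimate_kd_table(
    df: pd.DataFrame,
    *,
    concentration_reference: str = "layer",
) -> pd.DataFrame:
    """Batch K_D estimation over a per-droplet measurement table.

    Expects columns ``droplet_id, r0_um, eps_um, I_in, I_peri, sd_I_in,
    sd_I_peri, S_tot_uM, T_tot_uM`` and returns a copy with
    ``ratio, K_D_uM, sigma_K_D_uM, sentinel`` appended.

    ``concentration_reference`` declares how ``S_tot_uM`` is referenced:
    ``"layer"`` (used as-is) or ``"bulk"`` (converted per droplet with its
    own r0 and eps).
    """
    if concentration_reference not in ("layer", "bulk"):
        raise ValueError("concentration_reference must be 'layer' or 'bulk'")
    layer_fixed = concentration_reference == "layer"
    out = df.copy()
    ratios, kds, sigmas, sentinels = [], [], [], []
    for row in df.itertuples(index=False):
        ratio = row.I_peri / row.I_in
        S = (row.S_tot_uM if layer_fixed
             else bulk_to_layer(row.S_tot_uM, row.r0_um, row.eps_um))
        est = invert_kd(ratio, S_tot=S, T_tot=row.T_tot_uM,
                        eps=row.eps_um, r0=row.r0_um)
        sigma = float("nan")
        if not est.is_unbound_sentinel:
            sigma = propagate_error(
                I_in=row.I_in, I_peri=row.I_peri, r0=row.r0_um, eps=row.eps_um,
                S_tot=row.S_tot_uM, T_tot=row.T_tot_uM,
                sigma_inputs={"I_in": row.sd_I_in, "I_peri": row.sd_I_peri},
                layer_ref_fixed=layer_fixed,
            )
        ratios.append(ratio)
        kds.append(est.kd)
        sigmas.append(sigma)
        sentinels.append(est.is_unbound_sentinel)
    out["ratio"] = ratios
    out["K_D_uM"] = kds
    out["sigma_K_D_uM"] = sigmas
    out["sentinel"] = sentinels
    return out
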