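"""Synthetic inputs with known ground truth for the droplet pipeline.

Everything the analysis consumes can be generated here as a pure function of
(parameters, seed): droplet cross-section images whose rim/interior
intensity ratio obeys the surface-binding equilibrium, sigmoidal
pH-response curves with per-condition replicate noise, detachment time
traces under light-triggered acidification, and stationary correlated
scalar series mimicking radius-of-gyration trajectories.

The image forward model paints each droplet as a uniform interior disk at
``gain * T_eq`` plus a rim annulus of thickness ``eps`` at
``gain * (T_eq + C_eq)``, so that rim/interior equals the equilibrium
prediction 1 + S_tot/(T_eq + K_D) exactly before optics; a Gaussian PSF
blur and pixel noise are applied afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._ar1 import gaussian_copula_map, phi_from_tau, sample_ar1
from .bootstrap import RgSample
from .equilibrium import EquilibriumSystem, bulk_to_layer, steady_state
from .fitting import ResponseCurve, sigmoid10
from .quantify import DropletImage

__all__ = [
    "SyntheticGroundTruth",
    "make_droplet_image",
    "make_ph_response",
    "make_detachment_traces",
    "make_correlated_samples",
]

PH_RANGE = (4.3, 8.0)  #: experimentally accessible pH window


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Ground-truth parameter set for droplet-image generation.

    Concentrations are prepared per droplet volume (bulk) as in the wet
    protocol; each droplet's layer-referenced site concentration follows
    from its own radius and the rim thickness.  Defaults reproduce the
    standard assay conditions: 1.66/1.25 uM ssDNA/tsDNA, 0.5 um PSF,
    Gaussian noise at 2% of the image dynamic range, 0.5 um pixels and a
    3 um rim (several PSF widths, keeping rim quantification resolved).
    """

    kd_um: float
    s_bulk_um: float = 1.66
    t_tot_um: float = 1.25
    eps_um: float = 3.0
    psf_sigma_um: float = 0.5
    noise_model: str = "gaussian"      #: one of {none, gaussian, poisson}
    noise_sd_frac: float = 0.02        #: gaussian SD as fraction of dynamic range
    poisson_scale: float = 100.0       #: expected counts at unit intensity
    background: float = 0.0
    gain: float = 100.0
    pixel_size_um: float = 0.5
    radius_range_um: tuple[float, float] = (20.5, 24.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be none, gaussian or poisson")

    def system_for_radius(self, r0_um: float) -> EquilibriumSystem:
        return EquilibriumSystem(
            S_tot=bulk_to_layer(self.s_bulk_um, r0_um, self.eps_um),
            T_tot=self.t_tot_um, K_D=self.kd_um,
            eps=self.eps_um, r0=r0_um,
        )


def _place_centers(n: int, r_max_px: float, margin_px: float,
                   rng: np.random.Generator,
                   touching_pairs: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Jittered grid placement guaranteeing non-overlap (plus optional
    tangent pairs appended at the end)."""
    cell = 2.0 * (r_max_px + margin_px)
    n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    extra_cols = 2 if touching_pairs else 0  # strip for tangent pairs
    width = int(cell * (n_cols + extra_cols)) + 1
    height = int(cell * max(n_rows, touching_pairs, 1)) + 1
    centers = []
    jitter = 0.35 * margin_px
    for k in range(n):
        i, j = divmod(k, n_cols)
        cx = (j + 0.5) * cell + rng.uniform(-jitter, jitter)
        cy = (i + 0.5) * cell + rng.uniform(-jitter, jitter)
        centers.append((cx, cy))
    return np.asarray(centers, float), (height, width)


def make_droplet_image(
    gt: SyntheticGroundTruth,
    n_droplets: int,
    image_size: tuple[int, int] | None = None,
    pixel_size: float | None = None,
    touching_pairs: int = 0,
) -> tuple[DropletImage, pd.DataFrame]:
    """Render a field of synthetic droplets plus a per-droplet truth table.

    Droplet radii are drawn uniformly from ``gt.radius_range_um``;
    placement uses a jittered grid so droplets never overlap unless
    ``touching_pairs`` tangent pairs are requested (appended on the right).
    The truth table lists center, radius, K_D and the expected intensity
    ratio of every droplet.  When ``image_size`` is given, a placement that
    does not fit raises ``ValueError``.
    """
    px_um = pixel_size if pixel_size is not None else gt.pixel_size_um
    rng = np.random.default_rng(gt.seed)
    r_lo, r_hi = gt.radius_range_um
    radii_um = rng.uniform(r_lo, r_hi, size=n_droplets)
    r_max_px = r_hi / px_um
    margin_px = max(6.0, 4.0 * gt.psf_sigma_um / px_um)
    centers, auto_size = _place_centers(n_droplets, r_max_px, margin_px, rng,
                                        touching_pairs)
    shape = image_size if image_size is not None else auto_size
    img = np.full(shape, float(gt.background))
    yy, xx = np.indices(shape)

    records = []
    pairs: list[tuple[float, float, float]] = []
    if touching_pairs:
        # Tangent pairs in the spare strip on the right of the grid.
        cell = 2.0 * (r_max_px + margin_px)
        base_x = auto_size[1] - 2 * cell
        for p in range(touching_pairs):
            r = 0.5 * (r_lo + r_hi) / px_um
            cy = (p + 0.5) * cell
            cx = base_x + margin_px + r
            pairs.append((cx, cy, r))
            pairs.append((cx + 2 * r, cy, r))

    def paint(cx, cy, r0_um, interior, rim):
        r_px = r0_um / px_um
        eps_px = gt.eps_um / px_um
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        disk = d2 <= r_px ** 2
        ring = disk & (d2 > (r_px - eps_px) ** 2)
        if not disk.any() or (cx + r_px > shape[1]) or (cy + r_px > shape[0]) \
                or (cx - r_px < 0) or (cy - r_px < 0):
            raise ValueError(
                "requested droplets cannot be placed inside the image; "
                "increase image_size or reduce n_droplets")
        img[disk] = interior
        img[ring] = rim

    for k in range(n_droplets):
        cx, cy = centers[k]
        r0_um = float(radii_um[k])
        sys = gt.system_for_radius(r0_um)
        st = steady_state(sys)
        interior = gt.background + gt.gain * st.T_eq
        rim = gt.background + gt.gain * (st.T_eq + st.C_eq)
        paint(cx, cy, r0_um, interior, rim)
        records.append({
            "droplet_id": k, "cx": cx, "cy": cy, "r0_um": r0_um,
            "eps_um": gt.eps_um, "kd_um": gt.kd_um,
            "S_tot_layer_uM": sys.S_tot, "T_tot_uM": sys.T_tot,
            "T_eq_uM": st.T_eq, "C_eq_uM": st.C_eq, "ratio": st.ratio,
        })
    for cx, cy, r_px in pairs:
        r0_um = r_px * px_um
        sys = gt.system_for_radius(r0_um)
        st = steady_state(sys)
        paint(cx, cy, r0_um, gt.background + gt.gain * st.T_eq,
              gt.background + gt.gain * (st.T_eq + st.C_eq))

    if gt.psf_sigma_um > 0:
        img = gaussian_filter(img, sigma=gt.psf_sigma_um / px_um)
    if gt.noise_model == "gaussian":
        dyn = np.ptp(img)
        img = img + rng.normal(0.0, gt.noise_sd_frac * dyn, size=img.shape)
    elif gt.noise_model == "poisson":
        counts = np.clip(img, 0, None) * gt.poisson_scale
        img = rng.poisson(counts).astype(float) / gt.poisson_scale
    truth = pd.DataFrame(records)
    return DropletImage(pixels=img, pixel_size=px_um), truth


def make_ph_response(
    x_turn: float,
    alpha: float = 2.0,
    I_min: float = 0.0,
    I_max: float = 1.0,
    ph_grid: np.ndarray | None = None,
    n_per_ph: int = 20,
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> ResponseCurve:
    """Synthetic pH titration of the interior intensity (falling sigmoid).

    Per pH value, ``n_per_ph`` droplet intensities are drawn Gaussian around
    the base-10 sigmoid (default 20 droplets per condition); the returned
    curve carries the per-pH means, SDs and replicate counts.  The pH grid
    (default: 8 points spanning 4.3-8.0) must stay in the experimentally
    accessible window.
    """
    ph = (np.linspace(*PH_RANGE, 8) if ph_grid is None
          else np.asarray(ph_grid, float))
    if ph.min() < PH_RANGE[0] - 1e-9 or ph.max() > PH_RANGE[1] + 1e-9:
        raise ValueError(f"pH grid must lie within {PH_RANGE}")
    rng = np.random.default_rng(seed)
    truth = sigmoid10(ph, I_min, I_max, alpha, x_turn, "falling")
    reps = truth[:, None] + rng.normal(0.0, noise_sd, size=(ph.size, n_per_ph))
    if noise_sd == 0.0:
        return ResponseCurve(x=ph, y=truth, yerr=np.zeros_like(ph),
                             n=np.full(ph.size, n_per_ph))
    return ResponseCurve(x=ph, y=reps.mean(axis=1), yerr=reps.std(axis=1, ddof=1),
                         n=np.full(ph.size, n_per_ph))


def _ph_trace(t: np.ndarray, t_mid: float = 33.0, alpha_ph: float = 0.12,
              ph_hi: float = 8.0, ph_lo: float = 4.5) -> np.ndarray:
    """Phenomenological light-triggered acidification: buffered plateau at
    pH 8 until ~20 s, then a drop levelling below pH 5 by ~50 s."""
    return sigmoid10(t, ph_lo, ph_hi, alpha_ph, t_mid, "falling")


def make_detachment_traces(
    t_turn: float,
    alpha: float,
    plateau: float = 1.0,
    floor: float = 0.0,
    t_grid: np.ndarray | None = None,
    n_droplets: int = 26,
    noise_sd: float = 0.05,
    seed: int | None = None,
    mode: str = "sigmoid",
    ph_turn: float = 6.7,
    alpha_bind: float = 2.0,
) -> ResponseCurve:
    """Synthetic detachment time course (rising sigmoid in time).

    The canonical mode draws per-droplet traces around the base-10 time
    sigmoid with turning point ``t_turn`` and decay constant ``alpha``
    (decay time t_d = 1/alpha).  The mechanistic extension
    (``mode="mechanistic"``) instead couples a logistic pH(t) drop to a
    pH-dependent bound fraction, so the interior intensity rises as
    tsDNA detaches; it is a labelled extension, not what the assay fits.
    """
    t = (np.arange(0.0, 61.0, 1.0) if t_grid is None
         else np.asarray(t_grid, float))
    if not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if mode == "sigmoid":
        truth = sigmoid10(t, floor, plateau, alpha, t_turn, "rising")
    elif mode == "mechanistic":
        ph = _ph_trace(t)
        bound = sigmoid10(ph, 0.0, 1.0, alpha_bind, ph_turn, "rising")
        truth = floor + (plateau - floor) * (1.0 - bound)
    else:
        raise ValueError("mode must be 'sigmoid' or 'mechanistic'")
    rng = np.random.default_rng(seed)
    if noise_sd == 0.0:
        return ResponseCurve(x=t, y=truth, yerr=np.zeros_like(t),
                             n=np.full(t.size, n_droplets))
    reps = truth[:, None] + rng.normal(0.0, noise_sd, size=(t.size, n_droplets))
    return ResponseCurve(x=t, y=reps.mean(axis=1), yerr=reps.std(axis=1, ddof=1),
                         n=np.full(t.size, n_droplets))


def make_correlated_samples(
    p,
    tau: float,
    n: int,
    seed: int | None = None,
) -> RgSample:
    """Stationary correlated draws with marginal ``p`` and integrated
    autocorrelation time ``tau`` (Gaussian-copula AR(1)).

    ``p`` may be a frozen scipy.stats distribution (uses ``p.ppf``) or a
    1-D array of samples defining an empirical distribution.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    rng = np.random.default_rng(seed)
    phi = phi_from_tau(tau)
    z = sample_ar1((1, n), phi, rng)[0]
    if hasattr(p, "ppf"):
        ppf = p.ppf
    else:
        ref = np.sort(np.asarray(p, dtype=float))
        if ref.ndim != 1 or ref.size < 2 or not np.all(np.isfinite(ref)):
            raise ValueError("p must be a frozen distribution or a finite 1-D "
                             "sample array")
        us = (np.arange(ref.size) + 0.5) / ref.size
        ppf = lambda u: np.interp(u, us, ref)  # noqa: E731
    values = gaussian_copula_map(z, ppf)
    if not np.all(np.isfinite(values)):
        raise ValueError("target distribution produced non-finite draws "
                         "(non-normalizable or unbounded ppf)")
    return RgSample(values=values, tau=tau)
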