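"""Base-10 sigmoidal fits for pH titrations and detachment time courses.

The interior tsDNA intensity of a droplet follows a logistic curve in pH
(titration of the triplex switch) or in time (light-triggered acidification).
The model, written base-10 so that the decay constant alpha matches the
titration literature, is

    I(x) = I_min + (I_max - I_min) / (1 + 10^(+/- alpha (x - x_turn)))

with the ``+`` sign for a falling curve (high plateau at small x, e.g.
interior intensity vs pH) and ``-`` for a rising one (detachment vs time).
``x_turn`` is the turning point — the effective pKa for pH fits, the
half-detachment time for kinetic fits — and ``t_d = 1/alpha`` the decay time
characterizing transition sharpness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ResponseCurve",
    "SigmoidFit",
    "sigmoid10",
    "normalize",
    "fit_sigmoid",
    "turning_point_separation",
    "separation_sigma",
]


class FitError(RuntimeError):
    """Raised when the sigmoid fit cannot be computed."""


@dataclass(frozen=True)
class ResponseCurve:
    """A mean response curve: x (pH or seconds), per-point mean, SD and n."""

    x: np.ndarray
    y: np.ndarray
    yerr: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not np.all(np.diff(x) > 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        for name in ("yerr", "n"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != x.shape:
                    raise ValueError(f"{name} must match x in shape")
                object.__setattr__(self, name, v)
        if self.n is not None and np.any(self.n < 1):
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted base-10 logistic parameters with standard errors.

    ``covariance`` is the 4x4 matrix over (I_min, I_max, alpha, x_turn);
    ``t_d = 1/alpha`` with a delta-method standard error is provided for
    time fits.
    """

    I_min: float
    I_max: float
    alpha: float
    x_turn: float
    orientation: str
    covariance: np.ndarray
    se: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")

    @property
    def t_d(self) -> float:
        """Decay time 1/alpha (units of x)."""
        return 1.0 / self.alpha

    @property
    def se_t_d(self) -> float:
        """Delta-method SE of t_d: se(alpha)/alpha^2."""
        return self.se["alpha"] / self.alpha ** 2

    def predict(self, x: np.ndarray) -> np.ndarray:
        return sigmoid10(np.asarray(x, float), self.I_min, self.I_max,
                         self.alpha, self.x_turn, self.orientation)


def sigmoid10(x: np.ndarray, I_min: float, I_max: float, alpha: float,
              x_turn: float, orientation: str = "falling") -> np.ndarray:
    """Base-10 logistic; falling decays from I_max to I_min as x grows."""
    s = 1.0 if orientation == "falling" else -1.0
    z = np.clip(s * alpha * (np.asarray(x, float) - x_turn), -300, 300)
    return I_min + (I_max - I_min) / (1.0 + 10.0 ** z)


def normalize(curve: ResponseCurve) -> tuple[ResponseCurve, dict[str, float]]:
    """Min-max scale y to [0, 1]; returns the scaled curve and the transform.

    The returned dict has keys ``offset`` and ``scale`` such that
    ``y_original = offset + scale * y_normalized``; ``yerr`` is divided by
    ``scale``.
    """
    ymin = float(np.min(curve.y))
    ymax = float(np.max(curve.y))
    scale = ymax - ymin
    if scale <= 0:
        raise FitError("cannot normalize a flat curve (max(y) == min(y))")
    yerr = None if curve.yerr is None else curve.yerr / scale
    out = ResponseCurve(x=curve.x, y=(curve.y - ymin) / scale, yerr=yerr,
                        n=curve.n)
    return out, {"offset": ymin, "scale": scale}


def _initial_guess(x: np.ndarray, y: np.ndarray, orientation: str
                   ) -> tuple[float, float, float, float]:
    I_min, I_max = float(np.min(y)), float(np.max(y))
    half = 0.5 * (I_min + I_max)
    yy = y if orientation == "rising" else y[::-1]
    xx = x if orientation == "rising" else x[::-1]
    # first crossing of the half height in the rising direction
    above = np.nonzero(yy >= half)[0]
    x_turn = float(xx[above[0]]) if above.size else float(np.median(x))
    alpha = 2.0 / (x[-1] - x[0])
    return I_min, I_max, alpha, x_turn


def fit_sigmoid(
    curve: ResponseCurve,
    orientation: str = "falling",
    weighted: bool = True,
    n_restarts: int = 5,
    max_nfev: int = 10_000,
) -> SigmoidFit:
    """Weighted least-squares fit of the base-10 sigmoid.

    Weights are 1/yerr^2 where per-point SDs are available and positive
    (relative weights: the parameter covariance is scaled by the reduced
    chi-square, so the SEs reflect the actual scatter).  Initial values come
    from the data extremes and the half-height crossing; on failure the fit
    restarts up to ``n_restarts`` times from +/-50% jittered (seeded)
    starting points.
    """
    if orientation not in ("falling", "rising"):
        raise ValueError("orientation must be 'falling' or 'rising'")
    x, y = curve.x, curve.y
    if x.size < 5:
        raise FitError(f"need >= 5 points to fit 4 parameters, got {x.size}")
    sigma = None
    if weighted and curve.yerr is not None and np.all(curve.yerr > 0):
        sigma = curve.yerr

    def model(xv, I_min, I_max, alpha, x_turn):
        return sigmoid10(xv, I_min, I_max, alpha, x_turn, orientation)

    p0 = np.array(_initial_guess(x, y, orientation))
    span = x[-1] - x[0]
    dx = float(np.min(np.diff(x)))
    lb = [-np.inf, -np.inf, 1e-9, x[0] - span]
    ub = [np.inf, np.inf, np.inf, x[-1] + span]
    rng = np.random.default_rng(0)  # deterministic restarts
    last_exc: Exception | None = None
    for attempt in range(n_restarts + 1):
        trial = p0.copy()
        if attempt > 0:
            trial = trial * (1.0 + rng.uniform(-0.5, 0.5, size=4))
            trial[2] = max(trial[2], 1e-6)
            trial[3] = float(np.clip(trial[3], x[0], x[-1]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, x, y, p0=trial, sigma=sigma, absolute_sigma=False,
                    bounds=(lb, ub), max_nfev=max_nfev,
                )
            if not np.all(np.isfinite(popt)):
                raise RuntimeError("non-finite parameters")
            break
        except Exception as exc:  # noqa: BLE001 - curve_fit raises RuntimeError
            last_exc = exc
    else:
        resid = y - model(x, *p0)
        raise FitError(
            f"sigmoid fit did not converge after {n_restarts} restarts "
            f"({last_exc}); last residual norm {np.linalg.norm(resid):.3g}"
        )

    I_min_f, I_max_f, alpha_f, x_turn_f = (float(v) for v in popt)
    if I_max_f < I_min_f:
        # Relabel the plateaus; the model is symmetric under the swap
        # combined with an orientation flip of the exponent's sign, which
        # the optimizer can exploit. Keep the user-facing convention.
        I_min_f, I_max_f = I_max_f, I_min_f
        perm = np.array([1, 0, 2, 3])
        pcov = pcov[np.ix_(perm, perm)]
    if not (x[0] - dx <= x_turn_f <= x[-1] + dx):
        raise FitError(
            f"fitted turning point {x_turn_f:.4g} lies outside the data "
            f"range [{x[0]:.4g}, {x[-1]:.4g}] extended by one grid spacing"
        )
    resid = y - sigmoid10(x, I_min_f, I_max_f, alpha_f, x_turn_f, orientation)
    names = ("I_min", "I_max", "alpha", "x_turn")
    se = {nm: float(np.sqrt(pcov[i, i])) for i, nm in enumerate(names)}
    yspan = I_max_f - I_min_f
    if yspan > 0:
        lo_cov = (np.min(y) - I_min_f) / yspan
        hi_cov = (I_max_f - np.max(y)) / yspan
        if lo_cov > 0.2 or hi_cov > 0.2:
            warnings.warn(
                "data do not reach within 20% of both fitted plateaus; "
                "asymptotes are extrapolated", stacklevel=2)
    return SigmoidFit(
        I_min=I_min_f, I_max=I_max_f, alpha=alpha_f, x_turn=x_turn_f,
        orientation=orientation, covariance=pcov, se=se,
        residual_norm=float(np.linalg.norm(resid)),
    )


def separation_sigma(x1: float, se1: float, x2: float, se2: float) -> float:
    """|x1 - x2| in units of the combined standard deviation."""
    denom = math.hypot(se1, se2)
    if denom == 0.0:
        raise ValueError("both standard errors are zero; separation undefined")
    return abs(x1 - x2) / denom


def turning_point_separation(fitA: SigmoidFit, fitB: SigmoidFit) -> float:
    """Turning-point separation of two fits in combined-sigma units."""
    return separation_sigma(fitA.x_turn, fitA.se["x_turn"],
                            fitB.x_turn, fitB.se["x_turn"])
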