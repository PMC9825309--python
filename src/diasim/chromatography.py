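"""Gradient mapping and exponentially modified Gaussian (EMG) elution models.

Library retention coordinates (Prosit iRT scores or MaxQuant observed
retention times) are mapped affinely onto the simulated gradient, keeping a
configurable elution-free padding at both ends of the run.  Each precursor
then elutes as an EMG peak — a Gaussian of width ``sigma`` convolved with an
exponential tail of time constant ``tau`` — whose area equals the
precursor's per-sample abundance.

The EMG density is evaluated through the scaled complementary error
function ``erfcx`` where the naive formula would overflow (small ``tau``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import erfc, erfcx

logger = logging.getLogger(__name__)

__all__ = [
    "ElutionProfile",
    "GradientModel",
    "map_rt",
    "emg_density",
    "emg_intensity",
    "profile_support",
    "make_profiles",
]

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ElutionProfile:
    """One precursor's chromatographic peak in one run.

    ``apex_rt`` is the Gaussian location parameter mu (seconds); for
    ``tau > 0`` the actual profile mode lies slightly later.  ``area_scale``
    is the total area under the profile in intensity*seconds.
    """

    apex_rt: float
    sigma: float
    tau: float = 0.0
    area_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class GradientModel:
    """Affine map from library retention coordinates to run seconds."""

    run_length: float
    rt_window: tuple[float, float]
    padding: float

    def __post_init__(self) -> None:
        if self.run_length <= 2 * self.padding:
            raise ValueError(
                f"run_length {self.run_length} must exceed twice the padding "
                f"{self.padding}"
            )
        if self.rt_window[1] < self.rt_window[0]:
            raise ValueError(f"invalid rt_window {self.rt_window}")


def map_rt(coordinate: float, gradient: GradientModel) -> float:
    """Affine, order-preserving map of a library retention coordinate onto
    ``[padding, run_length - padding]``.  Coordinates outside the gradient's
    window are clamped (with a warning)."""
    lo, hi = gradient.rt_window
    if coordinate < lo or coordinate > hi:
        logger.warning(
            "retention coordinate %.4f outside library window [%.4f, %.4f]; clamped",
            coordinate, lo, hi,
        )
        coordinate = min(max(coordinate, lo), hi)
    span = hi - lo
    frac = 0.5 if span == 0 else (coordinate - lo) / span
    return gradient.padding + frac * (gradient.run_length - 2 * gradient.padding)


def emg_density(t: np.ndarray | float, mu: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-area EMG density.

    For ``tau -> 0`` this degenerates to the Gaussian density; the
    computation switches between the direct formula and the erfcx-stable
    form depending on the sign of the erfc argument, so it neither
    overflows for ``sigma >> tau`` nor loses precision for ``tau >> sigma``.
    """
    t = np.asarray(t, dtype=float)
    u = (t - mu) / sigma
    if tau <= sigma * 1e-12:
        return np.exp(-0.5 * u * u) / (sigma * _SQRT2PI)
    z = (sigma / tau - u) / _SQRT2
    out = np.empty_like(u)
    pos = z >= 0
    # stable branch: 1/(2 tau) * erfcx(z) * exp(-u^2/2)
    out[pos] = erfcx(z[pos]) * np.exp(-0.5 * u[pos] ** 2) / (2.0 * tau)
    if (~pos).any():
        zn, un = z[~pos], u[~pos]
        expo = sigma**2 / (2 * tau**2) - un * sigma / tau
        out[~pos] = np.exp(expo) * erfc(zn) / (2.0 * tau)
    return out


def emg_intensity(profile: ElutionProfile, t: np.ndarray | float) -> np.ndarray:
    """Profile intensity at time(s) ``t``, scaled so the total area under
    the curve equals ``profile.area_scale``."""
    return profile.area_scale * emg_density(t, profile.apex_rt, profile.sigma, profile.tau)


def _mode(profile: ElutionProfile) -> float:
    """Time of maximum intensity."""
    if profile.tau <= profile.sigma * 1e-12:
        return profile.apex_rt
    res = minimize_scalar(
        lambda t: -emg_density(t, profile.apex_rt, profile.sigma, profile.tau),
        bounds=(profile.apex_rt - profile.sigma, profile.apex_rt + profile.tau + profile.sigma),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)


def profile_support(profile: ElutionProfile, frac: float) -> tuple[float, float]:
    """Smallest interval outside which intensity < ``frac`` x apex intensity."""
    if not 0 < frac < 1:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    mu, sigma, tau = profile.apex_rt, profile.sigma, profile.tau
    if tau <= sigma * 1e-12:
        half_width = sigma * math.sqrt(2.0 * math.log(1.0 / frac))
        return mu - half_width, mu + half_width
    mode = _mode(profile)
    apex = float(emg_density(mode, mu, sigma, tau))
    target = frac * apex

    def rel(t: float) -> float:
        return float(emg_density(t, mu, sigma, tau)) - target

    left_lo = mu - sigma * (2.0 + math.sqrt(2.0 * math.log(1.0 / frac)))
    while rel(left_lo) > 0:  # pragma: no cover - generous initial bracket
        left_lo -= 4 * sigma
    t_start = brentq(rel, left_lo, mode, xtol=1e-9)
    right_hi = mode + sigma * math.sqrt(2.0 * math.log(1.0 / frac)) + tau * math.log(1.0 / frac) + 4 * (sigma + tau)
    while rel(right_hi) > 0:
        right_hi += 4 * (sigma + tau)
    t_end = brentq(rel, mode, right_hi, xtol=1e-9)
    return float(t_start), float(t_end)


def make_profiles(
    apex_rts: np.ndarray,
    sigma: float,
    tau: float,
    sigma_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[ElutionProfile]:
    """Build per-precursor profiles with an optional lognormal width jitter.

    ``sigma_cv`` is the coefficient of variation of the per-precursor peak
    width around the global ``sigma``; 0 gives identical widths.
    """
    n = len(apex_rts)
    if sigma_cv > 0:
        if rng is None:
            raise ValueError("sigma_cv > 0 requires an rng")
        s = math.sqrt(math.log(1.0 + sigma_cv**2))
        sigmas = sigma * np.exp(rng.normal(-0.5 * s * s, s, size=n))
    else:
        sigmas = np.full(n, sigma)
    return [
        ElutionProfile(apex_rt=float(apex_rts[i]), sigma=float(sigmas[i]), tau=tau)
        for i in range(n)
    ]
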