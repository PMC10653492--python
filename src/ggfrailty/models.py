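"""Closed-form Gompertz and gamma-Gompertz model functions.

The Gompertz law describes adult human mortality as an exponentially
increasing force of mortality (hazard)

    mu(x) = a * exp(b * x),

where ``a`` is the mortality level at the starting age of the analysis
(age offset ``x = 0``) and ``b`` is the rate of aging.  Unobserved
heterogeneity is introduced through a multiplicative gamma-distributed
frailty ``Z`` with mean 1 and variance ``sigma2``: an individual with
frailty ``z`` has hazard ``z * mu(x)``.  Marginalising over ``Z`` gives the
population (marginal) hazard

    mubar(x) = a e^{bx} / (1 + sigma2 * (a/b) * (e^{bx} - 1)),

which deviates downward from the Gompertz exponential at high ages and
approaches the plateau ``b / sigma2``.  Setting ``sigma2 = 0`` recovers the
Gompertz model exactly, so the frailty variance is the single parameter
that encodes mortality deceleration.

All functions take ages as offsets from the start age of the model (e.g.
``x = 0`` means calendar age 70 when fitting data above age 70) and are
vectorised over ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThetaGG",
    "gompertz_hazard",
    "gompertz_cum_hazard",
    "gompertz_survival",
    "gg_marginal_hazard",
    "gg_marginal_cum_hazard",
    "gg_marginal_survival",
    "gg_marginal_density",
    "gg_quantile",
]

# Below this value the frailty variance is numerically indistinguishable
# from zero: survival and quantile switch to the Gompertz limit formula to
# avoid catastrophic cancellation in the (.)^(-1/sigma2) power.
SIGMA2_SMALL = 1e-8

# b*x beyond which exp(b*x) overflows double precision; handled in log space.
_EXP_MAX = 700.0


@dataclass(frozen=True)
class ThetaGG:
    """Parameter vector (a, b, sigma2) of the gamma-Gompertz model.

    ``sigma2 = 0`` is a valid member and selects the Gompertz sub-model.
    """

    a: float
    b: float
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ValueError(f"a must be positive and finite, got {self.a}")
        if not (self.b > 0 and np.isfinite(self.b)):
            raise ValueError(f"b must be positive and finite, got {self.b}")
        if not (self.sigma2 >= 0 and np.isfinite(self.sigma2)):
            raise ValueError(
                f"sigma2 must be non-negative and finite, got {self.sigma2}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.sigma2], dtype=float)

    @property
    def is_gompertz(self) -> bool:
        return self.sigma2 == 0.0

    @property
    def plateau(self) -> float:
        """Asymptotic hazard level b / sigma2 (inf for the Gompertz model)."""
        return np.inf if self.sigma2 == 0.0 else self.b / self.sigma2


def _check_age(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError("ages must be finite and non-negative")
    return x


def _maybe_scalar(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def gompertz_hazard(x, theta: ThetaGG):
    """Gompertz force of mortality a*exp(b*x); ignores theta.sigma2."""
    xa = _check_age(x)
    scalar = xa.ndim == 0
    bx = theta.b * xa
    with np.errstate(over="ignore"):
        out = np.where(bx > _EXP_MAX, np.inf, theta.a * np.exp(np.minimum(bx, _EXP_MAX)))
    return _maybe_scalar(out, scalar)


def gompertz_cum_hazard(x, theta: ThetaGG):
    """Integrated Gompertz hazard H(x) = (a/b) * (e^{bx} - 1)."""
    xa = _check_age(x)
    scalar = xa.ndim == 0
    bx = np.minimum(theta.b * xa, _EXP_MAX)
    out = (theta.a / theta.b) * np.expm1(bx)
    return _maybe_scalar(out, scalar)


def gompertz_survival(x, theta: ThetaGG):
    """Gompertz survival S(x) = exp(-(a/b)(e^{bx} - 1))."""
    xa = _check_age(x)
    scalar = xa.ndim == 0
    out = np.exp(-gompertz_cum_hazard(xa, theta))
    return _maybe_scalar(np.asarray(out), scalar)


def gg_marginal_hazard(x, theta: ThetaGG):
    """Population hazard of the gamma-Gompertz model.

    Evaluated in the overflow-safe form a / ((1-s) e^{-bx} + s) with
    s = sigma2*a/b, which is algebraically identical to
    a e^{bx} / (1 + sigma2 (a/b)(e^{bx}-1)) but remains finite for any bx
    and approaches the plateau b/sigma2 monotonically.
    """
    xa = _check_age(x)
    scalar = xa.ndim == 0
    if theta.sigma2 == 0.0:
        return gompertz_hazard(x, theta)
    s = theta.sigma2 * theta.a / theta.b
    out = theta.a / ((1.0 - s) * np.exp(-theta.b * xa) + s)
    return _maybe_scalar(np.asarray(out), scalar)


def gg_marginal_cum_hazard(x, theta: ThetaGG):
    """Integrated marginal hazard ln(1 + sigma2 (a/b)(e^{bx}-1)) / sigma2."""
    xa = _check_age(x)
    scalar = xa.ndim == 0
    if theta.sigma2 < SIGMA2_SMALL:
        return gompertz_cum_hazard(x, theta)
    with np.errstate(over="ignore"):
        hg = gompertz_cum_hazard(xa, theta)
        out = np.log1p(theta.sigma2 * hg) / theta.sigma2
    return _maybe_scalar(np.asarray(out), scalar)


def gg_marginal_survival(x, theta: ThetaGG):
    """Marginal survival (1 + sigma2 (a/b)(e^{bx}-1))^(-1/sigma2).

    For sigma2 below ``SIGMA2_SMALL`` the Gompertz limit formula is used.
    """
    xa = _check_age(x)
    scalar = xa.ndim == 0
    out = np.exp(-gg_marginal_cum_hazard(xa, theta))
    return _maybe_scalar(np.asarray(out), scalar)


def gg_marginal_density(x, theta: ThetaGG):
    """Marginal lifespan density f(x) = mubar(x) * Sbar(x)."""
    xa = _check_age(x)
    scalar = xa.ndim == 0
    out = gg_marginal_hazard(xa, theta) * gg_marginal_survival(xa, theta)
    return _maybe_scalar(np.asarray(out), scalar)


def gg_quantile(u, theta: ThetaGG):
    """Age offset x at which marginal survival equals ``u`` (0 < u < 1).

    Analytic inverse of :func:`gg_marginal_survival`:

        x = (1/b) ln(1 + (b/(a sigma2)) (u^{-sigma2} - 1))

    with the Gompertz branch x = (1/b) ln(1 - (b/a) ln u) when sigma2 is
    numerically zero.  ``u^{-sigma2} - 1`` is computed as
    ``expm1(-sigma2 ln u)`` for accuracy at small sigma2.
    """
    ua = np.asarray(u, dtype=float)
    scalar = ua.ndim == 0
    if np.any(ua <= 0) or np.any(ua >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    lnu = np.log(ua)
    r = theta.b / theta.a
    if theta.sigma2 < SIGMA2_SMALL:
        out = np.log1p(-r * lnu) / theta.b
    else:
        out = np.log1p(r * np.expm1(-theta.sigma2 * lnu) / theta.sigma2) / theta.b
    return _maybe_scalar(np.asarray(out), scalar)
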