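"""Closed-form machinery for the six candidate survival families.

Every family used for overall-survival extrapolation is exposed through one
small interface: log-density, log-survival, survival, random sampling,
median, and a one-dimensional calibration that solves S(median) = 1/2 for
the family's free scale/location parameter while the shape parameters are
held fixed.

Parameterizations
-----------------
exponential   rate ``lam``; S(t) = exp(-lam*t)
weibull       shape ``k``, scale ``lam``; S(t) = exp(-(t/lam)**k)
gompertz      shape ``a`` (any sign), rate ``b`` > 0;
              h(t) = b*exp(a*t), S(t) = exp(-(b/a)*(exp(a*t)-1)).
              ``a`` < 0 gives a defective (plateau) survival curve with
              S(inf) = exp(b/a) > 0; ``a`` -> 0 degenerates to exponential.
lognormal     ``meanlog``, ``sdlog`` > 0 of log event time.
loglogistic   shape ``beta`` > 0, scale ``alpha`` > 0;
              S(t) = 1/(1 + (t/alpha)**beta)
gengamma      Prentice (mu, sigma > 0, Q): with w = (log t - mu)/sigma and
              gamma = Q**-2, the density is
              |Q| * gamma**gamma / (sigma*t*Gamma(gamma)) *
              exp(gamma*(Q*w - exp(Q*w))).
              Q = 0 is the lognormal limit; Q = 1 the gamma family;
              sigma = 1, Q = 1 the exponential; Q = 1/... the Weibull
              family arises for sigma = 1/k, Q = 1.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats

FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "loglogistic",
    "lognormal",
    "gengamma",
)

#: number of free parameters per family (the k in AIC/BIC)
N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "loglogistic": 2,
    "lognormal": 2,
    "gengamma": 3,
}

PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
    "gengamma": ("mu", "sigma", "Q"),
}

_GOMPERTZ_A_TINY = 1e-10
_GG_Q_TINY = 1e-6
_EXP_CLIP = 700.0  # exp() overflow guard


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family: {family!r}")


def validate_params(family: str, params) -> np.ndarray:
    """Validate a parameter vector for ``family``; returns it as an array."""
    _check_family(family)
    p = np.asarray(params, dtype=float)
    if p.shape != (N_PARAMS[family],):
        raise ValueError(
            f"{family} expects {N_PARAMS[family]} parameters "
            f"{PARAM_NAMES[family]}, got {p.tolist()}"
        )
    if not np.all(np.isfinite(p)):
        raise ValueError(f"non-finite parameters for {family}: {p.tolist()}")
    positive = {
        "exponential": [0],
        "weibull": [0, 1],
        "gompertz": [1],
        "loglogistic": [0, 1],
        "lognormal": [1],
        "gengamma": [1],
    }[family]
    for i in positive:
        if p[i] <= 0:
            raise ValueError(
                f"{family} parameter {PARAM_NAMES[family][i]!r} must be "
                f"positive, got {p[i]}"
            )
    return p


def logsf(family: str, params, t) -> np.ndarray:
    """log S(t). Vectorized over ``t``; t < 0 is an error, S(0) = 1."""
    p = validate_params(family, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be non-negative")
    if family == "exponential":
        return -p[0] * t
    if family == "weibull":
        k, lam = p
        return -((t / lam) ** k)
    if family == "gompertz":
        a, b = p
        if abs(a) < _GOMPERTZ_A_TINY:
            return -b * t
        return -(b / a) * np.expm1(np.minimum(a * t, _EXP_CLIP))
    if family == "loglogistic":
        beta, alpha = p
        with np.errstate(divide="ignore"):
            z = beta * (np.log(t) - np.log(alpha))
        return -np.logaddexp(0.0, z)
    if family == "lognormal":
        mu, sd = p
        with np.errstate(divide="ignore"):
            w = (np.log(t) - mu) / sd
        return stats.norm.logsf(np.where(t > 0, w, -np.inf))
    # gengamma
    mu, sigma, q = p
    if abs(q) < _GG_Q_TINY:
        return logsf("lognormal", (mu, sigma), t)
    gam = q**-2
    with np.errstate(divide="ignore"):
        w = (np.log(t) - mu) / sigma
    u = gam * np.exp(np.minimum(q * w, _EXP_CLIP))
    u = np.where(t > 0, u, 0.0)
    with np.errstate(divide="ignore"):
        if q > 0:
            return np.log(special.gammaincc(gam, u))
        return np.where(t > 0, np.log(special.gammainc(gam, u)), 0.0)


def sf(family: str, params, t) -> np.ndarray:
    """Survival function S(t)."""
    return np.exp(logsf(family, params, t))


def logpdf(family: str, params, t) -> np.ndarray:
    p = validate_params(family, params)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("event times must be positive")
    logt = np.log(t)
    if family == "exponential":
        return np.log(p[0]) - p[0] * t
    if family == "weibull":
        k, lam = p
        z = t / lam
        return np.log(k / lam) + (k - 1) * np.log(z) - z**k
    if family == "gompertz":
        a, b = p
        # log h(t) + log S(t)
        return np.log(b) + a * t + logsf(family, p, t)
    if family == "loglogistic":
        beta, alpha = p
        z = beta * (logt - np.log(alpha))
        return np.log(beta) - logt + z - 2.0 * np.logaddexp(0.0, z)
    if family == "lognormal":
        mu, sd = p
        w = (logt - mu) / sd
        return stats.norm.logpdf(w) - np.log(sd) - logt
    mu, sigma, q = p
    if abs(q) < _GG_Q_TINY:
        return logpdf("lognormal", (mu, sigma), t)
    gam = q**-2
    w = (logt - mu) / sigma
    qw = np.minimum(q * w, _EXP_CLIP)
    return (
        np.log(abs(q))
        - np.log(sigma)
        - logt
        - special.gammaln(gam)
        + gam * np.log(gam)
        + gam * (qw - np.exp(qw))
    )


def rvs(family: str, params, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw event times. Defective Gompertz mass that never dies -> inf."""
    p = validate_params(family, params)
    if family == "exponential":
        return rng.exponential(1.0 / p[0], size)
    if family == "weibull":
        k, lam = p
        return lam * rng.weibull(k, size)
    if family == "gompertz":
        a, b = p
        u = rng.random(size)
        if abs(a) < _GOMPERTZ_A_TINY:
            return -np.log(u) / b
        arg = 1.0 - (a / b) * np.log(u)
        out = np.full(size, np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / a
        return out
    if family == "loglogistic":
        beta, alpha = p
        u = rng.random(size)
        return alpha * (u / (1.0 - u)) ** (1.0 / beta)
    if family == "lognormal":
        mu, sd = p
        return rng.lognormal(mu, sd, size)
    mu, sigma, q = p
    if abs(q) < _GG_Q_TINY:
        return rng.lognormal(mu, sigma, size)
    g = rng.gamma(q**-2, 1.0, size)
    return np.exp(mu) * (q * q * g) ** (sigma / q)


def median(family: str, params) -> float:
    """Closed-form median survival time (inf for a defective curve that
    never crosses one half)."""
    p = validate_params(family, params)
    ln2 = math.log(2.0)
    if family == "exponential":
        return ln2 / p[0]
    if family == "weibull":
        k, lam = p
        return lam * ln2 ** (1.0 / k)
    if family == "gompertz":
        a, b = p
        if abs(a) < _GOMPERTZ_A_TINY:
            return ln2 / b
        arg = 1.0 + (a / b) * ln2
        if arg <= 0:  # plateau above 0.5: median undefined
            return math.inf
        return math.log(arg) / a
    if family == "loglogistic":
        return float(p[1])
    if family == "lognormal":
        return math.exp(p[0])
    mu, sigma, q = p
    if abs(q) < _GG_Q_TINY:
        return math.exp(mu)
    gam = q**-2
    u = special.gammaincinv(gam, 0.5)
    w = math.log(u / gam) / q
    return math.exp(mu + sigma * w)


def calibrate_to_median(family: str, target_median: float, fixed_shape_params=()):
    """Solve S(target_median) = 1/2 for the family's free parameter.

    The shape parameters are held fixed so the solve is one-dimensional;
    every family admits a closed form. Returns the full parameter vector.

    fixed_shape_params per family: exponential (), weibull (shape,),
    gompertz (shape,), loglogistic (shape,), lognormal (sdlog,),
    gengamma (sigma, Q).
    """
    _check_family(family)
    m = float(target_median)
    if m <= 0:
        raise ValueError("target median must be positive")
    ln2 = math.log(2.0)
    fx = tuple(float(x) for x in fixed_shape_params)
    if family == "exponential":
        params = (ln2 / m,)
    elif family == "weibull":
        (k,) = fx
        params = (k, m / ln2 ** (1.0 / k))
    elif family == "gompertz":
        (a,) = fx
        if abs(a) < _GOMPERTZ_A_TINY:
            params = (a, ln2 / m)
        else:
            params = (a, a * ln2 / math.expm1(a * m))
        if params[1] <= 0:
            raise ValueError(
                f"no positive gompertz rate reaches median {m} at shape {a}"
            )
    elif family == "loglogistic":
        (beta,) = fx
        params = (beta, m)
    elif family == "lognormal":
        (sd,) = fx
        params = (math.log(m), sd)
    else:  # gengamma: solve for mu with (sigma, Q) fixed
        sigma, q = fx
        if abs(q) < _GG_Q_TINY:
            params = (math.log(m), sigma, q)
        else:
            gam = q**-2
            u = special.gammaincinv(gam, 0.5)
            w = math.log(u / gam) / q
            params = (math.log(m) - sigma * w, sigma, q)
    validate_params(family, params)
    resid = sf(family, params, m) - 0.5
    if abs(resid) > 1e-8:
        raise RuntimeError(
            f"median calibration failed for {family}: S({m}) = {0.5 + resid}"
        )
    return np.asarray(params, dtype=float)
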