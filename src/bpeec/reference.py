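"""Reference conditionally-specified bivariate models: BPEC and BEC.

Both serve as comparison baselines for the mixed discrete–continuous
BPEEC model:

* **BPEC** (bivariate Poisson exponential conditionals): a fully discrete
  law ``P(x, y) = N^-1 exp(theta1*y - theta3*x*y + theta2*x)`` whose two
  conditionals are geometric-type "Poisson exponential" distributions.
  Its canonical support starts at 1; an explicit ``support_start`` of 0 is
  offered because real count data often contain zeros.
* **BEC** (bivariate exponential conditionals, Arnold–Strauss): a fully
  continuous law ``f(x, y) = N^-1 exp(-lambda1*y - lambda2*x + lambda3*x*y)``
  on the positive quadrant with exponential conditionals; ``lambda3 <= 0``
  is required for normalizability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .model import (
    SeriesControl,
    SeriesResult,
    InvalidParameterError,
    SeriesConvergenceError,
    _CHUNK,
)

__all__ = [
    "BPECParams",
    "BECParams",
    "validate_bpec",
    "validate_bec",
    "bpec_normalizing_constant",
    "bpec_pmf",
    "bpec_loglik",
    "bpec_support_violations",
    "bec_normalizing_constant",
    "bec_pdf",
    "bec_loglik",
    "sample_bpec",
    "sample_bec",
]


@dataclass(frozen=True)
class BPECParams:
    """Parameters of the discrete BPEC model.

    Convergence of the double series requires theta1 < 0, theta2 < 0 and
    theta3 >= 0.  ``support_start`` selects the lattice origin: 1 is the
    canonical support, 0 accommodates data containing zeros.
    """

    theta1: float
    theta2: float
    theta3: float
    support_start: int = 1


@dataclass(frozen=True)
class BECParams:
    """Parameters of the continuous Arnold–Strauss BEC model: rates
    lambda1, lambda2 > 0 and dependence lambda3 <= 0."""

    lambda1: float
    lambda2: float
    lambda3: float


def validate_bpec(p: BPECParams) -> None:
    vals = (p.theta1, p.theta2, p.theta3)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite parameter")
    bad = []
    if not p.theta1 < 0:
        bad.append("theta1 < 0")
    if not p.theta2 < 0:
        bad.append("theta2 < 0")
    if not p.theta3 >= 0:
        bad.append("theta3 >= 0")
    if p.support_start not in (0, 1):
        bad.append("support_start in {0, 1}")
    if bad:
        raise InvalidParameterError(
            "invalid BPEC parameters: violated " + ", ".join(bad)
        )


def validate_bec(p: BECParams) -> None:
    vals = (p.lambda1, p.lambda2, p.lambda3)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite parameter")
    bad = []
    if not p.lambda1 > 0:
        bad.append("lambda1 > 0")
    if not p.lambda2 > 0:
        bad.append("lambda2 > 0")
    if not p.lambda3 <= 0:
        bad.append("lambda3 <= 0")
    if bad:
        raise InvalidParameterError("invalid BEC parameters: violated " + ", ".join(bad))


# ---------------------------------------------------------------------------
# BPEC
# ---------------------------------------------------------------------------


def _bpec_inner_geom(p: BPECParams, x: np.ndarray) -> np.ndarray:
    """Closed-form inner sum over y >= s: exp((theta1 - theta3 x) s) /
    (1 - exp(theta1 - theta3 x))."""
    s = p.support_start
    r = p.theta1 - p.theta3 * x
    return np.exp(r * s) / (1.0 - np.exp(r))


def bpec_normalizing_constant(
    p: BPECParams, ctl: SeriesControl | None = None
) -> SeriesResult:
    """Certified N = sum_{x>=s} sum_{y>=s} exp(theta1 y - theta3 x y + theta2 x).

    The inner geometric sum over y is closed-form, reducing the double sum
    to a single series in x whose terms are bounded by the geometric
    sequence exp(theta1 s) exp((theta2 - theta3 s) x) / (1 - exp(theta1)).
    """
    if p.theta3 < 0:
        raise SeriesConvergenceError("series divergent: theta3 < 0")
    validate_bpec(p)
    ctl = ctl or SeriesControl()
    s = p.support_start
    e1 = math.exp(p.theta1)
    r = math.exp(p.theta2 - p.theta3 * s)

    total = 0.0
    x0 = s
    while x0 < ctl.max_terms:
        xs = np.arange(x0, x0 + _CHUNK, dtype=float)
        total += float(np.sum(np.exp(p.theta2 * xs) * _bpec_inner_geom(p, xs)))
        x0 += _CHUNK
        tail = math.exp(p.theta1 * s) * r**x0 / ((1.0 - e1) * (1.0 - r))
        if tail <= ctl.rel_tol * total:
            return SeriesResult(total, math.log(total), x0 - s, tail)
    raise SeriesConvergenceError("series not converged")


def bpec_pmf(x, y, p: BPECParams, N: SeriesResult) -> np.ndarray | float:
    """P(X = x, Y = y); points below the support return 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    below = (x < p.support_start) | (y < p.support_start)
    out = np.exp(p.theta1 * y - p.theta3 * x * y + p.theta2 * x - N.log_value)
    if np.any(below):
        warnings.warn("pmf evaluated below the BPEC support; returning 0")
        out = np.where(below, 0.0, out)
    return out if out.ndim else float(out)


def bpec_support_violations(x, y, p: BPECParams) -> list[int]:
    """Indices of observations falling below the model support."""
    x = np.asarray(x)
    y = np.asarray(y)
    below = (x < p.support_start) | (y < p.support_start)
    return list(np.nonzero(below)[0])


def bpec_loglik(
    x, y, p: BPECParams, ctl: SeriesControl | None = None
) -> float:
    """Log-likelihood sum_i log P(x_i, y_i).

    Observations below the support make the likelihood zero: the function
    returns -inf and warns with the offending indices.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("dataset is empty")
    bad = bpec_support_violations(x, y, p)
    if bad:
        warnings.warn(
            f"{len(bad)} observations below the BPEC support "
            f"(support_start={p.support_start}): indices {bad}"
        )
        return -math.inf
    N = bpec_normalizing_constant(p, ctl)
    return float(
        np.sum(p.theta1 * y - p.theta3 * x * y + p.theta2 * x) - x.size * N.log_value
    )


def sample_bpec(
    p: BPECParams, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exact BPEC sampling: inverse CDF on the X marginal, then the
    geometric-type conditional Y | X = x."""
    validate_bpec(p)
    if p.theta3 < 0:
        raise SeriesConvergenceError("series divergent: theta3 < 0")
    if n < 1:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = p.support_start
    e1 = math.exp(p.theta1)
    r = math.exp(p.theta2 - p.theta3 * s)

    # unnormalized marginal pmf of X with certified 1e-15 tail
    terms = []
    total = 0.0
    x0 = s
    while x0 < 2_000_000:
        xs = np.arange(x0, x0 + _CHUNK, dtype=float)
        t = np.exp(p.theta2 * xs) * _bpec_inner_geom(p, xs)
        terms.append(t)
        total += float(t.sum())
        x0 += _CHUNK
        tail = math.exp(p.theta1 * s) * r**x0 / ((1.0 - e1) * (1.0 - r))
        if tail <= 1e-15 * total:
            break
    else:
        raise SeriesConvergenceError("marginal cdf table not converged")
    cdf = np.cumsum(np.concatenate(terms)) / (total + tail)
    u = rng.random(n)
    x = s + np.minimum(np.searchsorted(cdf, u, side="right"), len(cdf) - 1)

    q = np.exp(p.theta1 - p.theta3 * x)  # geometric ratio of Y | X = x
    y = s + rng.geometric(1.0 - q) - 1
    return x.astype(np.int64), y.astype(np.int64)


# ---------------------------------------------------------------------------
# BEC
# ---------------------------------------------------------------------------


def bec_normalizing_constant(p: BECParams) -> SeriesResult:
    """N = integral over the positive quadrant of the BEC kernel.

    The inner y-integral is 1/(lambda1 - lambda3 x), leaving the smooth,
    exponentially decaying one-dimensional integral
    ``int_0^inf exp(-lambda2 x) / (lambda1 - lambda3 x) dx`` evaluated by
    adaptive quadrature to 1e-12 relative accuracy.
    """
    if p.lambda3 > 0:
        raise InvalidParameterError("density not normalizable: lambda3 > 0")
    validate_bec(p)
    val, err = integrate.quad(
        lambda x: math.exp(-p.lambda2 * x) / (p.lambda1 - p.lambda3 * x),
        0.0,
        np.inf,
        epsabs=0.0,
        epsrel=1e-12,
        limit=200,
    )
    return SeriesResult(val, math.log(val), 0, err)


def bec_pdf(x, y, p: BECParams, N: SeriesResult) -> np.ndarray | float:
    """Density f(x, y) = N^-1 exp(-lambda1 y - lambda2 x + lambda3 x y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.exp(
        -p.lambda1 * y - p.lambda2 * x + p.lambda3 * x * y - N.log_value
    )
    return out if out.ndim else float(out)


def bec_loglik(x, y, p: BECParams) -> float:
    """Log-likelihood sum_i log f(x_i, y_i) of the BEC model."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("dataset is empty")
    N = bec_normalizing_constant(p)
    return float(
        np.sum(-p.lambda1 * y - p.lambda2 * x + p.lambda3 * x * y)
        - x.size * N.log_value
    )


def sample_bec(
    p: BECParams, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exact BEC sampling.

    X is drawn by rejection from an Exp(lambda2) envelope — the acceptance
    probability is lambda1 / (lambda1 - lambda3 x), which is exact because
    the X marginal is proportional to exp(-lambda2 x)/(lambda1 - lambda3 x)
    — then Y | X = x is exponential with rate lambda1 - lambda3 x.
    """
    validate_bec(p)
    if n < 1:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs = np.empty(0)
    while xs.size < n:
        m = max(2 * (n - xs.size), 128)
        cand = rng.exponential(scale=1.0 / p.lambda2, size=m)
        accept = rng.random(m) < p.lambda1 / (p.lambda1 - p.lambda3 * cand)
        xs = np.concatenate([xs, cand[accept]])
    x = xs[:n]
    y = rng.exponential(scale=1.0 / (p.lambda1 - p.lambda3 * x))
    return x, y
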