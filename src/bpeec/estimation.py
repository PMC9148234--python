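"""Likelihood and pseudolikelihood inference for the BPEEC, BPEC and BEC models.

Maximum likelihood fits the full joint density, which for BPEEC and BPEC
means evaluating the normalizing-constant series at every step.  Maximum
pseudolikelihood instead maximizes the product of the two conditional
densities and never touches the normalizing constant — its selling point
for conditionally specified families.

Optimization runs box-constrained quasi-Newton (L-BFGS-B) on a log
transform of the parameters, so the search cannot leave each model's valid
region, followed by a root polish of the (pseudo-)score.  Standard errors
come from the inverse observed information (central-difference Hessian of
the maximized objective on the natural scale), giving symmetric Wald-type
confidence intervals.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from . import model as _m
from . import reference as _ref
from .data import Dataset
from .model import BPEECParams, SeriesControl, SeriesConvergenceError
from .reference import BPECParams, BECParams

__all__ = [
    "FitResult",
    "ComparisonResult",
    "bpeec_loglik",
    "bpeec_score",
    "bpeec_log_pseudolik",
    "bpeec_pseudo_score",
    "fit_mle",
    "fit_mple",
    "asymptotic_ci",
    "information_criteria",
    "compare_models",
]

_BIG = 1e12  # objective value returned where the likelihood is not evaluable


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------


def bpeec_loglik(
    data: Dataset, p: BPEECParams, ctl: SeriesControl | None = None
) -> float:
    """BPEEC log-likelihood
    ``l = -n log N(A) + sum_i [alpha1 (x_i+1) - (alpha2 - alpha3 (x_i+1)) y_i]``.

    Identical to the sum of pointwise log joint densities.
    """
    ctl = ctl or SeriesControl()
    N = _m.normalizing_constant(p, ctl)
    x = data.x.astype(float)
    xp1 = x + 1.0
    return float(
        -data.n * N.log_value
        + np.sum(p.alpha1 * xp1 - (p.alpha2 - p.alpha3 * xp1) * data.y)
    )


def bpeec_score(
    data: Dataset, p: BPEECParams, ctl: SeriesControl | None = None
) -> np.ndarray:
    """Analytic score of the BPEEC log-likelihood.

    Each component is ``-n (dN/dalpha_j)/N`` plus the matching data sum:
    sum(x+1), -sum(y), sum((x+1) y).
    """
    ctl = ctl or SeriesControl()
    nval, grad = _m._normalizing_gradient(p, ctl)
    xp1 = data.x.astype(float) + 1.0
    data_terms = np.array(
        [np.sum(xp1), -np.sum(data.y), np.sum(xp1 * data.y)]
    )
    return -data.n * grad / nval + data_terms


def bpeec_log_pseudolik(data: Dataset, p: BPEECParams) -> float:
    """BPEEC log-pseudolikelihood
    ``sum_i [log f(x_i | y_i) + log f(y_i | x_i)]``.

    Involves only the conditional laws; the normalizing constant of the
    joint is never evaluated.
    """
    x = data.x.astype(float)
    y = data.y
    w = -p.alpha1 - p.alpha3 * y  # log(1 + lambda(y_i))
    beta = p.alpha2 - p.alpha3 * (x + 1.0)
    bad = np.nonzero((w <= 0) | (beta <= 0))[0]
    if bad.size:
        raise _m.InvalidParameterError(
            f"conditional undefined at observation index {int(bad[0])}"
        )
    log_lam = w + np.log1p(-np.exp(-w))
    return float(
        np.sum(log_lam - (x + 1.0) * w) + np.sum(np.log(beta) - beta * y)
    )


def bpeec_pseudo_score(data: Dataset, p: BPEECParams) -> np.ndarray:
    """Analytic gradient of the log-pseudolikelihood.

    With w_i = -alpha1 - alpha3 y_i and r_i = e^{w_i}/(e^{w_i} - 1):
      d/dalpha1 = sum(-r_i + x_i + 1)
      d/dalpha2 = sum(1/beta_i - y_i)
      d/dalpha3 = sum(-y_i r_i + 2 (x_i+1) y_i - (x_i+1)/beta_i)
    """
    x = data.x.astype(float)
    y = data.y
    xp1 = x + 1.0
    w = -p.alpha1 - p.alpha3 * y
    beta = p.alpha2 - p.alpha3 * xp1
    r = 1.0 / (-np.expm1(-w))  # e^w / (e^w - 1)
    g1 = np.sum(-r + xp1)
    g2 = np.sum(1.0 / beta - y)
    g3 = np.sum(-y * r + 2.0 * xp1 * y - xp1 / beta)
    return np.array([g1, g2, g3])


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------


def information_criteria(loglik: float, k: int, n: int) -> dict[str, float]:
    """Standard and legacy information criteria.

    Standard (smaller is better): AIC = 2k - 2l, BIC = k ln n - 2l.
    Legacy variants (larger is better), as printed in some applied reports:
    AIC' = l - 2k and BIC' = l - (k/2) ln n.  Model rankings agree across
    conventions because AIC' = -AIC/2 and BIC' = -BIC/2.
    """
    if k < 0 or n < 1:
        raise ValueError("require k >= 0 and n >= 1")
    return {
        "aic": 2.0 * k - 2.0 * loglik,
        "bic": k * math.log(n) - 2.0 * loglik,
        "aic_paper_variant": loglik - 2.0 * k,
        "bic_paper_variant": loglik - 0.5 * k * math.log(n),
    }


# ---------------------------------------------------------------------------
# fit machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """A fitted model: point estimates with Wald inference and criteria.

    ``loglik_or_logPL`` holds the maximized log-likelihood (MLE) or
    log-pseudolikelihood (MPLE); the information criteria are computed
    from it.  ``grad_norm`` is the sup-norm of the (pseudo-)score at the
    returned optimum on the natural parameter scale.
    """

    model: str
    method: str
    estimates: tuple[float, float, float]
    se: tuple[float, float, float] | None
    ci: tuple[tuple[float, float], ...] | None
    ci_level: float
    loglik_or_logPL: float
    aic: float
    bic: float
    aic_paper_variant: float
    bic_paper_variant: float
    n: int
    converged: bool
    iterations: int
    seed: int | None = None
    grad_norm: float = math.nan
    support_start: int | None = None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "method": self.method,
            "estimates": list(self.estimates),
            "se": list(self.se) if self.se is not None else None,
            "ci": [list(c) for c in self.ci] if self.ci is not None else None,
            "ci_level": self.ci_level,
            "loglik_or_logPL": self.loglik_or_logPL,
            "aic": self.aic,
            "bic": self.bic,
            "aic_paper_variant": self.aic_paper_variant,
            "bic_paper_variant": self.bic_paper_variant,
            "n": self.n,
            "converged": self.converged,
            "iterations": self.iterations,
            "seed": self.seed,
            "grad_norm": self.grad_norm,
            "support_start": self.support_start,
            "notes": list(self.notes),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


# Each model is optimized on u in R^3 with theta_j = sign_j * exp(u_j):
# the box constraints below keep every series/integral evaluable.
_TRANSFORMS: dict[str, dict] = {
    "bpeec": {
        "signs": np.array([-1.0, 1.0, -1.0]),
        "bounds": [(-7.0, 5.0), (-10.0, 10.0), (-15.0, 3.0)],
        "param_cls": BPEECParams,
    },
    "bpec": {
        "signs": np.array([-1.0, -1.0, 1.0]),
        "bounds": [(-8.0, 5.0), (-8.0, 5.0), (-15.0, 5.0)],
        "param_cls": BPECParams,
    },
    "bec": {
        "signs": np.array([1.0, 1.0, -1.0]),
        "bounds": [(-10.0, 8.0), (-10.0, 8.0), (-30.0, 5.0)],
        "param_cls": BECParams,
    },
}


def _to_natural(model: str, u: np.ndarray) -> np.ndarray:
    return _TRANSFORMS[model]["signs"] * np.exp(u)


def _to_u(model: str, theta: Sequence[float]) -> np.ndarray:
    signs = _TRANSFORMS[model]["signs"]
    theta = np.asarray(theta, dtype=float)
    if np.any(theta * signs <= 0):
        raise ValueError("initial value outside the model's valid region")
    return np.log(theta * signs)


def _auto_init(model: str, data: Dataset) -> np.ndarray:
    """Method-of-moments-style starting values on the natural scale."""
    mx = float(np.mean(data.x))
    my = float(np.mean(data.y))
    if model == "bpeec":
        a1 = math.log(mx / (1.0 + mx)) if mx > 0 else math.log(0.5)
        a2 = 1.0 / my if my > 0 else 1.0
        return np.array([a1, a2, -0.01])
    if model == "bpec":
        t1 = math.log(my / (1.0 + my)) if my > 0 else math.log(0.5)
        t2 = math.log(mx / (1.0 + mx)) if mx > 0 else math.log(0.5)
        return np.array([t1, t2, 1e-3])
    if model == "bec":
        l1 = 1.0 / my if my > 0 else 1.0
        l2 = 1.0 / mx if mx > 0 else 1.0
        return np.array([l1, l2, -0.1 * l1 * l2])
    raise ValueError(f"unknown model '{model}'")


def _objective_factory(
    model: str, method: str, data: Dataset, ctl: SeriesControl,
    support_start: int,
) -> tuple[Callable, Callable | None]:
    """Return (negative objective in u, analytic u-gradient or None)."""
    if model == "bpeec" and method == "MLE":
        def f(u):
            p = BPEECParams(*_to_natural("bpeec", u))
            try:
                return -bpeec_loglik(data, p, ctl)
            except (SeriesConvergenceError, OverflowError):
                return _BIG

        def g(u):
            theta = _to_natural("bpeec", u)
            p = BPEECParams(*theta)
            try:
                score = bpeec_score(data, p, ctl)
            except (SeriesConvergenceError, OverflowError):
                # fall back to finite differences so no fake stationary
                # point is reported where the gradient series stalls
                return optimize.approx_fprime(u, f, 1e-7)
            return -score * theta  # chain rule: dtheta/du = theta

        return f, g
    if model == "bpeec" and method == "MPLE":
        def f(u):
            p = BPEECParams(*_to_natural("bpeec", u))
            try:
                return -bpeec_log_pseudolik(data, p)
            except (_m.InvalidParameterError, OverflowError):
                return _BIG

        def g(u):
            theta = _to_natural("bpeec", u)
            return -bpeec_pseudo_score(data, BPEECParams(*theta)) * theta

        return f, g
    if model == "bpec":
        def f(u):
            t = _to_natural("bpec", u)
            p = BPECParams(t[0], t[1], t[2], support_start)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ll = _ref.bpec_loglik(data.x, data.y, p, ctl)
            except (SeriesConvergenceError, OverflowError):
                return _BIG
            return _BIG if not math.isfinite(ll) else -ll

        return f, None
    if model == "bec":
        def f(u):
            t = _to_natural("bec", u)
            try:
                return -_ref.bec_loglik(data.x, data.y, BECParams(*t))
            except (OverflowError, ValueError):
                return _BIG

        return f, None
    raise ValueError(f"unknown model/method '{model}'/'{method}'")


def _feasible(model: str, theta: np.ndarray) -> bool:
    signs = _TRANSFORMS[model]["signs"]
    strict = theta * signs > 0
    # the dependence parameter may sit exactly on zero
    strict[2] = theta[2] * signs[2] >= 0
    return bool(np.all(strict))


def _numeric_hessian(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    feasible: Callable[[np.ndarray], bool],
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central-difference Hessian with boundary-aware one-sided stencils."""
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    # choose a direction per coordinate: central if both sides feasible
    central = np.ones(k, dtype=bool)
    sgn = np.ones(k)
    for j in range(k):
        e = np.zeros(k)
        e[j] = h[j]
        if feasible(x + e) and feasible(x - e):
            continue
        central[j] = False
        sgn[j] = 1.0 if feasible(x + 2 * e) else -1.0
    f0 = f(x)
    H = np.empty((k, k))
    for j in range(k):
        ej = np.zeros(k)
        ej[j] = h[j]
        if central[j]:
            H[j, j] = (f(x + ej) - 2 * f0 + f(x - ej)) / h[j] ** 2
        else:
            s = sgn[j] * ej
            H[j, j] = (f(x + 2 * s) - 2 * f(x + s) + f0) / h[j] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if central[i] and central[j]:
                H[i, j] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
            else:
                si = sgn[i] * ei if not central[i] else ei
                sj = sgn[j] * ej if not central[j] else ej
                H[i, j] = (
                    f(x + si + sj) - f(x + si) - f(x + sj) + f0
                ) / (si[i] * sj[j])
            H[j, i] = H[i, j]
    return H


def _wald(estimates: np.ndarray, se: np.ndarray | None, level: float):
    if se is None:
        return None
    z = stats.norm.ppf(0.5 + level / 2.0)
    return tuple(
        (float(e - z * s), float(e + z * s)) for e, s in zip(estimates, se)
    )


def _fit(
    data: Dataset,
    model: str,
    method: str,
    init,
    *,
    n_starts: int = 3,
    seed: int = 0,
    ctl: SeriesControl | None = None,
    max_iter: int = 500,
    ci_level: float = 0.95,
    support_start: int = 1,
    compute_se: bool = True,
) -> FitResult:
    if data.n < 1:
        raise ValueError("dataset is empty")
    ctl = ctl or SeriesControl()
    notes: list[str] = []
    tinfo = _TRANSFORMS[model]
    f, g = _objective_factory(model, method, data, ctl, support_start)

    if model == "bpec":
        bad = _ref.bpec_support_violations(
            data.x, data.y, BPECParams(-1.0, -1.0, 0.0, support_start)
        )
        if bad:
            raise ValueError(
                f"all observations must satisfy the BPEC support "
                f"(support_start={support_start}); offending indices {bad}"
            )

    theta0 = _auto_init(model, data) if isinstance(init, str) else np.asarray(
        init, dtype=float
    )
    if theta0[2] == 0.0:  # zero dependence sits at the transform's limit
        theta0 = theta0.copy()
        theta0[2] = tinfo["signs"][2] * 1e-6
    u0 = _to_u(model, theta0)
    lo = np.array([b[0] for b in tinfo["bounds"]])
    hi = np.array([b[1] for b in tinfo["bounds"]])
    u0 = np.clip(u0, lo + 1e-6, hi - 1e-6)

    rng = np.random.default_rng(seed)
    starts = [u0] + [
        np.clip(u0 + rng.normal(0.0, 0.25, size=3), lo + 1e-6, hi - 1e-6)
        for _ in range(max(0, n_starts - 1))
    ]

    best = None
    iterations = 0
    for u_start in starts:
        res = optimize.minimize(
            f, u_start, jac=g, method="L-BFGS-B",
            bounds=tinfo["bounds"],
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
        )
        iterations += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res
    u_opt = np.asarray(best.x, dtype=float)

    # polish: drive the analytic (pseudo-)score to zero where available
    if g is not None and best.fun < _BIG / 2:
        try:
            root = optimize.root(lambda u: g(u), u_opt, method="hybr", tol=1e-12)
            # hybr's success flag is pessimistic near flat directions; judge
            # the polished point by what it achieves
            if (
                np.all(root.x > lo) and np.all(root.x < hi)
                and f(root.x) <= best.fun + 1e-8 * (1.0 + abs(best.fun))
                and np.max(np.abs(g(root.x))) < np.max(np.abs(g(u_opt)))
            ):
                u_opt = np.asarray(root.x, dtype=float)
        except Exception:
            pass

    theta = _to_natural(model, u_opt)
    obj = -f(u_opt)

    # natural-scale gradient norm at the optimum
    if model == "bpeec" and method == "MLE":
        grad_nat = bpeec_score(data, BPEECParams(*theta), ctl)
    elif model == "bpeec" and method == "MPLE":
        grad_nat = bpeec_pseudo_score(data, BPEECParams(*theta))
    else:
        grad_nat = optimize.approx_fprime(
            u_opt, f, 1e-7
        ) / np.maximum(np.abs(theta), 1e-12)
    grad_norm = float(np.max(np.abs(grad_nat)))
    on_bound = np.any(u_opt <= lo + 1e-9) or np.any(u_opt >= hi - 1e-9)
    if g is None:  # finite-difference models: trust the optimizer status
        converged = bool(best.success and obj > -_BIG / 2)
    else:
        converged = bool(best.success and obj > -_BIG / 2 and
                         (grad_norm < 1e-6 or on_bound))
    if on_bound:
        notes.append("estimate on the boundary of the search region")

    se = None
    if compute_se and obj > -_BIG / 2:
        # objective as a function of the natural parameters, for the Hessian
        def obj_nat(th):
            th = np.asarray(th, dtype=float)
            if model == "bpeec":
                p = BPEECParams(*th)
                if method == "MLE":
                    return bpeec_loglik(data, p, ctl)
                return bpeec_log_pseudolik(data, p)
            if model == "bpec":
                p = BPECParams(th[0], th[1], th[2], support_start)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return _ref.bpec_loglik(data.x, data.y, p, ctl)
            p = BECParams(*th)
            return _ref.bec_loglik(data.x, data.y, p)

        try:
            H = _numeric_hessian(obj_nat, theta, lambda t: _feasible(model, t))
            info = -H
            eigs = np.linalg.eigvalsh(info)
            if np.all(eigs > 0):
                se = tuple(float(s) for s in np.sqrt(np.diag(np.linalg.inv(info))))
            else:
                notes.append("information matrix not positive definite")
        except Exception as exc:  # pragma: no cover - diagnostic path
            notes.append(f"standard errors unavailable: {exc}")

    ic = information_criteria(obj, 3, data.n)
    est = tuple(float(t) for t in theta)
    return FitResult(
        model=model,
        method=method,
        estimates=est,
        se=se,
        ci=_wald(np.asarray(est), np.asarray(se) if se else None, ci_level),
        ci_level=ci_level,
        loglik_or_logPL=float(obj),
        aic=ic["aic"],
        bic=ic["bic"],
        aic_paper_variant=ic["aic_paper_variant"],
        bic_paper_variant=ic["bic_paper_variant"],
        n=data.n,
        converged=converged,
        iterations=iterations,
        seed=seed,
        grad_norm=grad_norm,
        support_start=support_start if model == "bpec" else None,
        notes=tuple(notes),
    )


def fit_mle(
    data: Dataset,
    model: str = "bpeec",
    init="auto",
    **opts,
) -> FitResult:
    """Maximum-likelihood fit of one of the three models.

    ``init`` is 'auto' (method-of-moments-style start) or a parameter
    triple in the valid region.  Options: ``n_starts`` (default 3 jittered
    initializations), ``seed`` (jitter seed, recorded), ``ctl``
    (series truncation policy), ``max_iter``, ``ci_level``,
    ``support_start`` (BPEC only), ``compute_se``.
    """
    return _fit(data, model.lower(), "MLE", init, **opts)


def fit_mple(data: Dataset, init="auto", **opts) -> FitResult:
    """Maximum-pseudolikelihood fit of the BPEEC model (normalizing
    constant never evaluated)."""
    return _fit(data, "bpeec", "MPLE", init, **opts)


def asymptotic_ci(fit: FitResult, level: float = 0.95) -> FitResult:
    """Re-derive symmetric Wald intervals at a new confidence level from
    the stored standard errors."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if fit.se is None:
        raise ValueError("information matrix not positive definite")
    ci = _wald(np.asarray(fit.estimates), np.asarray(fit.se), level)
    return replace(fit, ci=ci, ci_level=level)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """All-model comparison on one dataset, ranked by AIC (standard,
    ascending; identical ranking under the legacy larger-is-better
    variants)."""

    fits: dict[str, FitResult]
    notes: tuple[str, ...]

    def to_frame(self):
        import pandas as pd

        rows = []
        for key, fit in self.fits.items():
            rows.append({
                "model": fit.model.upper(),
                "method": fit.method,
                "loglik_or_logPL": fit.loglik_or_logPL,
                "aic": fit.aic,
                "bic": fit.bic,
                "aic_paper_variant": fit.aic_paper_variant,
                "bic_paper_variant": fit.bic_paper_variant,
                "converged": fit.converged,
                "estimates": fit.estimates,
            })
        df = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
        return df

    def ranking(self) -> list[str]:
        """Model/method keys of likelihood-based fits, best AIC first."""
        keys = [k for k, f in self.fits.items() if f.method == "MLE"]
        return sorted(keys, key=lambda k: self.fits[k].aic)

    def to_json(self) -> str:
        return json.dumps(
            {
                "fits": {k: f.to_dict() for k, f in self.fits.items()},
                "ranking_by_aic": self.ranking(),
                "notes": list(self.notes),
            },
            indent=2,
        )


def compare_models(
    data: Dataset,
    *,
    seed: int = 0,
    n_starts: int = 3,
    ci_level: float = 0.95,
    bpec_support_start: int | None = None,
) -> ComparisonResult:
    """Fit BPEEC (MLE and MPLE), BPEC (MLE) and BEC (MLE) to one dataset.

    Support violations are reported per model, never silently dropped: if
    the data contain zeros, the canonical BPEC support (starting at 1) is
    unusable and the fit falls back to ``support_start=0`` with a note.
    BPEC additionally requires integer y.
    """
    notes: list[str] = []
    fits: dict[str, FitResult] = {}
    failures: list[str] = []

    for key, kwargs in (
        ("bpeec_mle", dict(model="bpeec", method="MLE")),
        ("bpeec_mple", dict(model="bpeec", method="MPLE")),
    ):
        try:
            fits[key] = _fit(data, kwargs["model"], kwargs["method"], "auto",
                             seed=seed, n_starts=n_starts, ci_level=ci_level)
        except Exception as exc:
            failures.append(f"{key}: {exc}")

    # BPEC needs an integer lattice
    if np.all(np.asarray(data.y) == np.round(data.y)):
        ss = bpec_support_start
        if ss is None:
            probe = BPECParams(-1.0, -1.0, 0.0, 1)
            bad = _ref.bpec_support_violations(data.x, data.y, probe)
            if bad:
                notes.append(
                    f"BPEC support_start=1 violated by {len(bad)} observations "
                    f"(indices {bad}); fitted with support_start=0"
                )
                ss = 0
            else:
                ss = 1
        try:
            fits["bpec_mle"] = _fit(data, "bpec", "MLE", "auto", seed=seed,
                                    n_starts=n_starts, ci_level=ci_level,
                                    support_start=ss)
        except Exception as exc:
            failures.append(f"bpec_mle: {exc}")
    else:
        notes.append("BPEC skipped: y is not integer-valued")

    try:
        fits["bec_mle"] = _fit(data, "bec", "MLE", "auto", seed=seed,
                               n_starts=n_starts, ci_level=ci_level)
    except Exception as exc:
        failures.append(f"bec_mle: {exc}")

    notes.extend(failures)
    if not fits:
        raise RuntimeError("all model fits failed: " + "; ".join(failures))
    return ComparisonResult(fits=fits, notes=tuple(notes))
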