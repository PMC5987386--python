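"""Benchmark-dose estimation for continuous endpoints.

The dose-response mean is taken from the nested exponential family commonly
used by benchmark-dose software for continuous toxicology data:

    m1: y = a
    m2: y = a * exp(b x)
    m3: y = a * exp(b x^d)
    m4: y = a * (c - (c - 1) exp(-b x))
    m5: y = a * (c - (c - 1) exp(-b x^d))

with background level ``a > 0``, potency ``b > 0``, asymptote fold-change
``c > 1`` (models 4-5) and shape exponent ``d in [1, 4]`` (models 3 and 5);
only increasing responses are modelled.  Replicate responses are strictly
positive with lognormal error: ``log y ~ Normal(log m(x), sigma^2)``.

The critical effect dose (CED) is the dose at which the mean reaches
``(1 + CES)`` times background (CES = 0.20 by default).  Its two-sided
confidence interval (BMDL, BMDU) is obtained by profile likelihood: the CED
is made an explicit parameter, all nuisance parameters are re-optimised at
each candidate CED, and the bounds are where the profile log-likelihood
drops below its maximum by a threshold that equals the asymptotic
``chi2_1(confidence) / 2`` for large samples but carries the exact
linear-Gaussian finite-sample (F-based) calibration at the replicate
counts typical of these studies (see :func:`_profile_drop`).

Numerical conventions: doses are scaled internally by the highest tested
dose and log-responses centred by their mean, so fits are exactly
equivariant under dose rescaling and response rescaling; the background
``a`` and error SD are concentrated out in closed form, leaving 1-3
free nonlinear parameters per model, optimised by bounded quasi-Newton
iterations from a deterministic multi-start grid plus seeded jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, f as f_dist

__all__ = [
    "ENDPOINTS",
    "ResponseTable",
    "ExponentialFit",
    "BmdResult",
    "FittingError",
    "model_mean",
    "ced_closed_form",
    "fit_exponential_family",
    "select_model",
    "profile_interval",
    "fit_bmd",
]

#: the four pro-inflammatory mediators scored in the study
ENDPOINTS = ("IL-1b", "IL-6", "IL-8", "TNF-a")

_MODEL_IDS = (1, 2, 3, 4, 5)
#: free parameters per model, counting a and sigma
_N_PARAMS = {1: 2, 2: 3, 3: 4, 4: 4, 5: 5}

_RSS_FLOOR = 1e-24  # guards log(0) on noise-free data


class FittingError(RuntimeError):
    """No model of the family could be fitted to a response table."""


@dataclass
class ResponseTable:
    """Replicate-level responses versus dose for one material/method/endpoint.

    ``doses`` and ``responses`` are parallel arrays (one entry per
    animal/well); the table must contain a control (dose 0), at least two
    distinct dose levels, and strictly positive responses, all in a single
    dose metric.
    """

    material_id: str
    context_id: str
    endpoint: str
    metric: str
    doses: np.ndarray
    responses: np.ndarray
    replicate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape or self.doses.ndim != 1:
            raise ValueError("doses and responses must be parallel 1-D arrays")
        if not np.all(np.isfinite(self.doses)) or np.any(self.doses < 0):
            raise ValueError("doses must be finite and >= 0")
        if not np.all(np.isfinite(self.responses)) or np.any(self.responses <= 0):
            raise ValueError("responses must be finite and > 0 (lognormal error model)")
        levels = np.unique(self.doses)
        if levels.size < 2:
            raise ValueError("need at least two distinct dose levels")
        if levels[0] != 0.0:
            raise ValueError("a control group (dose 0) is required")

    @property
    def dose_levels(self) -> np.ndarray:
        return np.unique(self.doses)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "material_id": self.material_id,
                "context_id": self.context_id,
                "endpoint": self.endpoint,
                "dose_metric": self.metric,
                "dose_value": self.doses,
                "response": self.responses,
            }
        )
        frame["replicate_id"] = (
            self.replicate_ids
            if self.replicate_ids is not None
            else np.arange(len(self.doses))
        )
        return frame


@dataclass
class ExponentialFit:
    """One maximum-likelihood fit of an exponential-family model."""

    model_id: int
    a: float
    b: float | None
    c: float | None
    d: float | None
    sigma: float
    loglik: float
    converged: bool

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model_id]

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def params(self) -> dict[str, float]:
        out = {"a": self.a}
        if self.b is not None:
            out["b"] = self.b
        if self.c is not None:
            out["c"] = self.c
        if self.d is not None:
            out["d"] = self.d
        return out


@dataclass
class BmdResult:
    """CED point estimate with its profile-likelihood interval."""

    material_id: str
    context_id: str
    endpoint: str
    metric: str
    ces: float
    confidence: float
    ced: float | None
    bmdl: float | None
    bmdu: float | None
    status: str  # ok | no_response | unbounded_upper
    selected_model: ExponentialFit | None = None

    @property
    def defined(self) -> bool:
        return self.status in ("ok", "unbounded_upper") and self.ced is not None


def _check_params(model_id: int, p: dict) -> None:
    if model_id not in _MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    if not p.get("a", 1.0) > 0:
        raise ValueError("background a must be > 0")
    if model_id >= 2 and not p.get("b", 0.0) > 0:
        raise ValueError(f"model {model_id} requires potency b > 0")
    if model_id in (4, 5) and not p.get("c", 0.0) > 1:
        raise ValueError(f"model {model_id} requires asymptote fold-change c > 1")
    if model_id in (3, 5) and not p.get("d", 0.0) >= 1:
        raise ValueError(f"model {model_id} requires shape exponent d >= 1")


def _log_relative(model_id: int, b: float, c: float | None, d: float | None, x):
    """log(m(x) / a) for the given model, vectorised over doses ``x``."""
    x = np.asarray(x, dtype=float)
    if model_id == 1:
        return np.zeros_like(x)
    if model_id == 2:
        return b * x
    if model_id == 3:
        return b * x ** d
    if model_id == 4:
        return np.log(c - (c - 1.0) * np.exp(-b * x))
    if model_id == 5:
        return np.log(c - (c - 1.0) * np.exp(-b * x ** d))
    raise ValueError(f"unknown model id {model_id!r}")


def model_mean(model_id: int, params: dict, dose):
    """Expected response of model ``model_id`` at ``dose``.

    ``params`` maps the parameter names ``a``, ``b``, ``c``, ``d`` (only
    those the model uses) to values; ``model_mean(model_id, params, 0) == a``
    for every model.
    """
    _check_params(model_id, params)
    rel = _log_relative(
        model_id, params.get("b"), params.get("c"), params.get("d"), dose
    )
    out = params["a"] * np.exp(rel)
    return float(out) if np.ndim(dose) == 0 else out


def ced_closed_form(model_id: int, params: dict, ces: float) -> float | None:
    """Dose at which the mean reaches ``(1 + ces) * a``; exact inversion.

    Returns ``None`` when the model cannot reach that level (constant model,
    or saturating models whose asymptote ``c <= 1 + ces``).
    """
    if not ces > 0:
        raise ValueError("ces must be > 0")
    _check_params(model_id, params)
    if model_id == 1:
        return None
    b = params["b"]
    target = math.log1p(ces)
    if model_id == 2:
        return target / b
    if model_id == 3:
        return (target / b) ** (1.0 / params["d"])
    c = params["c"]
    if c <= 1.0 + ces:
        return None  # asymptote at or below the benchmark response
    inner = math.log((c - 1.0) / (c - 1.0 - ces)) / b
    if model_id == 4:
        return inner
    return inner ** (1.0 / params["d"])


# ---------------------------------------------------------------------------
# internal fitting machinery (dose scaled to [0, 1], log-responses centred)
# ---------------------------------------------------------------------------


def _prepare(table: ResponseTable):
    s = float(np.max(table.doses))
    if s <= 0:
        raise ValueError("all doses are zero")
    u = table.doses / s
    logy = np.log(table.responses)
    lbar = float(np.mean(logy))
    l = logy - lbar
    return u, l, s, lbar


def _concentrated(model_id: int, b, c, d, u, l):
    """Profile out log(a); return (loga, rss)."""
    g = _log_relative(model_id, b, c, d, u)
    resid = l - g
    loga = float(np.mean(resid))
    rss = float(np.sum((resid - loga) ** 2))
    return loga, rss


def _nll(rss: float, n: int) -> float:
    return 0.5 * n * math.log(max(rss, _RSS_FLOOR) / n)


def _full_loglik(rss: float, n: int, logy_sum: float) -> float:
    sigma2 = max(rss, _RSS_FLOOR) / n
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0) - logy_sum


_BLOG = (-30.0, 16.0)  # lower bound close enough to b = 0 to reach m1
_CLOG = (-8.0, 8.0)
_DRANGE = (1.0, 4.0)


def _unpack(model_id: int, z):
    if model_id == 2:
        return math.exp(z[0]), None, None
    if model_id == 3:
        return math.exp(z[0]), None, z[1]
    if model_id == 4:
        return math.exp(z[0]), 1.0 + math.exp(z[1]), None
    return math.exp(z[0]), 1.0 + math.exp(z[1]), z[2]


def _starts(model_id: int, u, l, rng: np.random.Generator, n_extra: int):
    """Data-driven deterministic starts plus seeded jitter."""
    top = u == np.max(u)
    ctrl = u == 0.0
    lf = float(np.mean(l[top]) - np.mean(l[ctrl]))  # log fold-change at top dose
    slope = max(lf, 0.05)
    logb = math.log(slope)
    logc = math.log(max(math.expm1(max(lf, 0.1)), 0.05))
    base: list[list[float]] = []
    if model_id == 2:
        base = [[logb - 1.0], [logb], [logb + 1.5]]
    elif model_id == 3:
        base = [[logb, 1.0], [logb, 2.0], [logb + 1.0, 3.0], [logb - 1.0, 1.5]]
    elif model_id == 4:
        base = [[logb + 1.0, logc], [logb + 2.5, logc], [logb, logc + 1.5]]
    elif model_id == 5:
        base = [[logb + 1.0, logc, 1.0], [logb + 2.0, logc, 2.0],
                [logb, logc + 1.5, 1.5]]
    lo, hi = _bounds(model_id)
    for _ in range(n_extra):
        z = [float(rng.uniform(a, b)) for a, b in zip(lo, hi)]
        base.append(z)
    return [np.clip(z, lo, hi) for z in base]


def _bounds(model_id: int):
    if model_id == 2:
        return np.array([_BLOG[0]]), np.array([_BLOG[1]])
    if model_id == 3:
        return (np.array([_BLOG[0], _DRANGE[0]]), np.array([_BLOG[1], _DRANGE[1]]))
    if model_id == 4:
        return (np.array([_BLOG[0], _CLOG[0]]), np.array([_BLOG[1], _CLOG[1]]))
    return (
        np.array([_BLOG[0], _CLOG[0], _DRANGE[0]]),
        np.array([_BLOG[1], _CLOG[1], _DRANGE[1]]),
    )


def _fit_one(model_id: int, u, l, rng, n_extra_starts: int):
    """Minimise the concentrated negative log-likelihood for one model."""
    n = l.size
    if model_id == 1:
        loga, rss = _concentrated(1, None, None, None, u, l)
        return {"z": None, "loga": loga, "rss": rss, "nll": _nll(rss, n),
                "converged": True}

    def objective(z):
        b, c, d = _unpack(model_id, z)
        _, rss = _concentrated(model_id, b, c, d, u, l)
        return _nll(rss, n)

    lo, hi = _bounds(model_id)
    best = None
    ok = False
    for z0 in _starts(model_id, u, l, rng, n_extra_starts):
        res = optimize.minimize(
            objective, z0, method="L-BFGS-B",
            bounds=list(zip(lo, hi)), options={"maxiter": 200},
        )
        ok = ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    b, c, d = _unpack(model_id, best.x)
    loga, rss = _concentrated(model_id, b, c, d, u, l)
    return {"z": best.x, "b": b, "c": c, "d": d, "loga": loga, "rss": rss,
            "nll": _nll(rss, n), "converged": ok}


def _externalise(model_id: int, raw: dict, s: float, lbar: float, n: int,
                 logy_sum: float) -> ExponentialFit:
    a = math.exp(raw["loga"] + lbar)
    sigma = math.sqrt(max(raw["rss"], _RSS_FLOOR) / n)
    ll = _full_loglik(raw["rss"], n, logy_sum)
    b = c = d = None
    if model_id >= 2:
        d = raw.get("d")
        c = raw.get("c")
        scale = s ** d if model_id in (3, 5) else s
        b = raw["b"] / scale
    return ExponentialFit(model_id, a, b, c, d, sigma, ll, raw["converged"])


def fit_exponential_family(
    table: ResponseTable,
    models: Sequence[int] = _MODEL_IDS,
    seed: int = 20180604,
    n_extra_starts: int = 2,
) -> list[ExponentialFit]:
    """Fit each requested exponential model by maximum likelihood.

    Returns one :class:`ExponentialFit` per model, each flagged
    converged/failed; raises :class:`FittingError` only if every fit fails.
    """
    u, l, s, lbar = _prepare(table)
    logy_sum = float(np.sum(np.log(table.responses)))
    rng = np.random.default_rng(seed)
    fits = []
    for model_id in models:
        if model_id not in _MODEL_IDS:
            raise ValueError(f"unknown model id {model_id!r}")
        raw = _fit_one(model_id, u, l, rng, n_extra_starts)
        fits.append(_externalise(model_id, raw, s, lbar, l.size, logy_sum))
    if not any(f.converged for f in fits):
        raise FittingError(
            f"all exponential fits failed for {table.material_id}/"
            f"{table.context_id}/{table.endpoint}"
        )
    return fits


def select_model(
    fits: Iterable[ExponentialFit],
    rule: str = "lr",
    alpha: float = 0.05,
) -> ExponentialFit:
    """Pick the accepted model from the fitted family.

    ``rule='lr'`` walks the nested ladder m1 -> m2 -> {m3, m4} -> m5,
    accepting an extra parameter only when the likelihood-ratio test is
    significant at ``alpha`` (AIC breaks the m3-vs-m4 tie).  ``rule='aic'``
    simply minimises AIC over converged fits.
    """
    converged = {f.model_id: f for f in fits if f.converged}
    if not converged:
        raise FittingError("no converged fit to select from")
    if len(converged) == 1:
        return next(iter(converged.values()))
    if rule == "aic":
        return min(converged.values(), key=lambda f: (f.aic, f.model_id))
    if rule != "lr":
        raise ValueError(f"unknown selection rule {rule!r}; use 'lr' or 'aic'")

    crit1 = chi2.ppf(1.0 - alpha, 1)

    def better(complex_fit, simple_fit):
        df = complex_fit.n_params - simple_fit.n_params
        crit = chi2.ppf(1.0 - alpha, df) if df > 0 else 0.0
        return 2.0 * (complex_fit.loglik - simple_fit.loglik) > crit

    accepted = converged.get(1) or min(converged.values(), key=lambda f: f.n_params)
    if 2 in converged and accepted.model_id == 1:
        if better(converged[2], accepted):
            accepted = converged[2]
        else:
            return accepted
    if accepted.model_id == 2:
        step = [converged[m] for m in (3, 4) if m in converged
                and better(converged[m], accepted)]
        if step:
            accepted = max(step, key=lambda f: f.loglik)
    if accepted.model_id in (3, 4) and 5 in converged:
        if 2.0 * (converged[5].loglik - accepted.loglik) > crit1:
            accepted = converged[5]
    return accepted


# ---------------------------------------------------------------------------
# profile likelihood for the CED
# ---------------------------------------------------------------------------

#: mean-function parameters per model (a plus the nonlinear ones)
_N_MEAN_PARAMS = {2: 2, 3: 3, 4: 3, 5: 4}


def _profile_drop(confidence: float, n: int, model_id: int) -> float:
    """Log-likelihood drop defining the profile interval bounds.

    Uses the finite-sample calibration that is exact for a linear Gaussian
    model with unknown variance, ``(n/2) log(1 + F(conf; 1, n-p)/(n-p))``
    with ``p`` mean-function parameters; it converges to the asymptotic
    ``chi2_1(conf)/2`` from above as ``n`` grows, and falls back to the
    chi-square value when the residual degrees of freedom vanish.
    """
    dof = n - _N_MEAN_PARAMS[model_id]
    if dof < 1:
        return chi2.ppf(confidence, 1) / 2.0
    return 0.5 * n * math.log1p(f_dist.ppf(confidence, 1, dof) / dof)


def _profile_nll_factory(model_id: int, u, l, ces: float, fit_internal: dict):
    """Return prof(ced_u) = concentrated nll with the CED fixed.

    The potency ``b`` is expressed through the CED, so fixing the CED leaves
    ``d`` (model 3), the asymptote parameter (model 4) or both (model 5) as
    nuisances, optimised at every candidate CED; ``a`` and ``sigma`` are
    always concentrated in closed form.
    """
    n = l.size
    target = math.log1p(ces)

    if model_id == 2:

        def prof(ced):
            b = target / ced
            _, rss = _concentrated(2, b, None, None, u, l)
            return _nll(rss, n)

        return prof

    if model_id == 3:
        d_grid = np.append(np.linspace(*_DRANGE, 13), fit_internal.get("d", 1.0))

        def prof(ced):
            def inner(d):
                b = target / ced ** d
                _, rss = _concentrated(3, b, None, d, u, l)
                return _nll(rss, n)

            # the d-profile can be multimodal: coarse grid, then refine
            values = [inner(d) for d in d_grid]
            d0 = d_grid[int(np.argmin(values))]
            res = optimize.minimize_scalar(
                inner,
                bounds=(max(_DRANGE[0], d0 - 0.3), min(_DRANGE[1], d0 + 0.3)),
                method="bounded", options={"xatol": 1e-4},
            )
            return min(res.fun, min(values))

        return prof

    # models 4/5: nuisance t = log(c - 1 - ces) keeps c above 1 + ces, and
    # b = log(1 + ces * exp(-t)) / ced^d solves the CED constraint exactly
    def rss_45(t, d, ced):
        c = 1.0 + ces + math.exp(t)
        dd = d if model_id == 5 else None
        b = math.log1p(ces * math.exp(-t)) / (ced ** (d if model_id == 5 else 1.0))
        _, rss = _concentrated(model_id, b, c, dd, u, l)
        return rss

    c_fit = fit_internal.get("c")
    t_fit = math.log(max(c_fit - 1.0 - ces, 1e-8)) if c_fit else 0.0

    t_grid = np.append(np.linspace(-12.0, 12.0, 13), np.clip(t_fit, -12.0, 12.0))

    if model_id == 4:

        def prof(ced):
            def inner(t):
                return _nll(rss_45(t, 1.0, ced), n)

            values = [inner(t) for t in t_grid]
            t0 = t_grid[int(np.argmin(values))]
            res = optimize.minimize_scalar(
                inner, bounds=(max(-12.0, t0 - 2.0), min(12.0, t0 + 2.0)),
                method="bounded", options={"xatol": 1e-4},
            )
            return min(res.fun, min(values))

        return prof

    d_fit = fit_internal.get("d", 1.5)

    def prof(ced):
        def inner(z):
            return _nll(rss_45(z[0], z[1], ced), n)

        coarse = [
            (inner([t, d]), t, d)
            for t in (-8.0, -4.0, 0.0, 4.0, 8.0)
            for d in (1.0, 2.0, 3.0, 4.0)
        ]
        coarse_best = min(coarse)
        best = coarse_best[0]
        for z0 in ([t_fit, d_fit], list(coarse_best[1:])):
            res = optimize.minimize(
                inner, np.clip(z0, [-12.0, 1.0], [12.0, 4.0]),
                method="L-BFGS-B", bounds=[(-12.0, 12.0), _DRANGE],
                options={"maxiter": 100},
            )
            best = min(best, res.fun)
        return best

    return prof


def _internal_params(fit: ExponentialFit, s: float) -> dict:
    out: dict[str, float] = {}
    if fit.b is not None:
        scale = s ** fit.d if fit.model_id in (3, 5) else s
        out["b"] = fit.b * scale
    if fit.c is not None:
        out["c"] = fit.c
    if fit.d is not None:
        out["d"] = fit.d
    return out


def _bisect_bound(prof, lo, hi, excess_lo, excess_hi, rel_tol=5e-4, max_iter=60):
    """Log-space bisection for the CED where the profile excess crosses 0."""
    for _ in range(max_iter):
        if hi / lo < 1.0 + rel_tol:
            break
        mid = math.sqrt(lo * hi)
        if (prof(mid) > 0) == (excess_hi > 0):
            hi = mid
        else:
            lo = mid
    return math.sqrt(lo * hi)


def profile_interval(
    table: ResponseTable,
    fit: ExponentialFit,
    ces: float = 0.20,
    confidence: float = 0.90,
    grid_size: int = 60,
    max_factor: float = 100.0,
) -> tuple[float, float | None, str]:
    """Profile-likelihood (BMDL, BMDU) for the fitted model's CED.

    Returns ``(bmdl, bmdu, status)``; ``bmdu`` is ``None`` with status
    ``unbounded_upper`` when the profile has not dropped by the chi-square
    threshold below ``max_factor`` times the highest tested dose.
    """
    if fit.model_id == 1:
        raise ValueError("the constant model has no CED to profile")
    u, l, s, _ = _prepare(table)
    internal = _internal_params(fit, s)
    ced_u = ced_closed_form(fit.model_id, {"a": 1.0, **internal}, ces)
    if ced_u is None:
        raise ValueError("fitted model does not reach the benchmark response")
    prof = _profile_nll_factory(fit.model_id, u, l, ces, internal)
    crit = _profile_drop(confidence, u.size, fit.model_id)
    nll_hat = min(prof(ced_u), _nll_at_fit(fit.model_id, internal, u, l))

    def excess(ced):
        return prof(ced) - nll_hat - crit

    lo_limit = min(float(np.min(u[u > 0])) / 100.0, ced_u / 100.0)
    hi_limit = max_factor
    grid = np.geomspace(lo_limit, hi_limit, grid_size)

    # walk down from the CED to bracket the lower crossing
    bmdl_u = lo_limit
    below = grid[grid < ced_u][::-1]
    prev = ced_u
    for point in below:
        if excess(point) > 0:
            bmdl_u = _bisect_bound(excess, point, prev, 1.0, -1.0)
            break
        prev = point
    # walk up for the upper crossing
    status = "ok"
    bmdu_u: float | None = None
    above = grid[grid > ced_u]
    prev = ced_u
    for point in above:
        if excess(point) > 0:
            bmdu_u = _bisect_bound(excess, prev, point, -1.0, 1.0)
            break
        prev = point
    else:
        status = "unbounded_upper"

    bmdl = min(bmdl_u, ced_u) * s
    bmdu = max(bmdu_u, ced_u) * s if bmdu_u is not None else None
    return bmdl, bmdu, status


def _nll_at_fit(model_id, internal, u, l):
    _, rss = _concentrated(
        model_id, internal.get("b"), internal.get("c"), internal.get("d"), u, l
    )
    return _nll(rss, l.size)


def fit_bmd(
    table: ResponseTable,
    ces: float = 0.20,
    confidence: float = 0.90,
    models: Sequence[int] = _MODEL_IDS,
    selection: str = "lr",
    alpha: float = 0.05,
    seed: int = 20180604,
) -> BmdResult:
    """Full benchmark-dose procedure for one response table.

    Fits the exponential family, selects the accepted model, inverts it for
    the CED at ``ces`` and profiles the ``confidence``-level interval.
    Deterministic for a given table and seed.
    """
    fits = fit_exponential_family(table, models=models, seed=seed)
    selected = select_model(fits, rule=selection, alpha=alpha)
    meta = dict(
        material_id=table.material_id,
        context_id=table.context_id,
        endpoint=table.endpoint,
        metric=table.metric,
        ces=ces,
        confidence=confidence,
    )
    ced = (
        None
        if selected.model_id == 1
        else ced_closed_form(selected.model_id, selected.params(), ces)
    )
    if ced is None:
        return BmdResult(**meta, ced=None, bmdl=None, bmdu=None,
                         status="no_response", selected_model=selected)
    bmdl, bmdu, status = profile_interval(
        table, selected, ces=ces, confidence=confidence
    )
    return BmdResult(**meta, ced=ced, bmdl=bmdl, bmdu=bmdu, status=status,
                     selected_model=selected)
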