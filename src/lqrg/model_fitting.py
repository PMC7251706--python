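"""Fitting TCP(t) curves to observed LPFS samples.

The cost function is the pooled mean absolute error (MAE) between the
model-implied TCP at each sample time and the Kaplan-Meier LPFS value there;
all groups' samples are pooled with equal weight. Minimizing the MAE is the
maximum-likelihood fit under Laplace-distributed residuals, which is how the
surrogate log-likelihood and AIC reported alongside the fit are defined
(see :mod:`lqrg.model_selection`).

Optimization is plain gradient descent with central finite-difference
gradients and a backtracking (Armijo) line search, run in log-parameter
space so positivity is automatic, from multiple deterministic starts.

Confidence intervals come from the curvature of the surrogate likelihood at
the optimum (default) or from seeded case-resampling bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .cell_survival import LQParams, LQRGParams
from .schedule import FractionationSchedule
from .tcp import TumorSpec, tcp_time_curve

__all__ = [
    "GroupData",
    "FitResult",
    "MODEL_PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "default_params",
    "mae_cost",
    "fit_model",
    "fitting_errors",
    "parameter_confidence_intervals",
]

log = logging.getLogger(__name__)

#: Free-parameter vectors per model (every fitted quantity in the paper sense).
MODEL_PARAM_NAMES = {
    "lq": ("rho_per_cm3", "alpha", "beta", "tau_p_days", "t_k_h"),
    "lqrg": (
        "rho_per_cm3",
        "alpha",
        "beta",
        "sigma2",
        "tau_r_h",
        "tau_s_h",
        "tau_p_days",
        "t_k_h",
        "k_cr",
        "sigma_k",
        "delta",
    ),
}

#: Wide positivity bounds used to keep log-space search sane.
DEFAULT_BOUNDS = {
    "alpha": (1e-4, 10.0),
    "beta": (1e-5, 10.0),
    "sigma2": (1e-6, 10.0),
    "tau_r_h": (0.1, 200.0),
    "tau_s_h": (0.1, 200.0),
    "tau_p_days": (1.0, 3000.0),
    "t_k_h": (1e-2, 8000.0),
    "delta": (1e-3, 1.0),
    "rho_per_cm3": (1e5, 1e13),
    "k_cr": (1e5, 1e13),
    "sigma_k": (1e5, 1e13),
}

_PARAM_CLS = {"lq": LQParams, "lqrg": LQRGParams}


def default_params(model: str):
    """Packaged default parameter set for ``model`` ('lq' or 'lqrg')."""
    try:
        return _PARAM_CLS[model]()
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None


@dataclass(frozen=True)
class GroupData:
    """Fitting data for one treatment group.

    ``times_months``/``lpfs`` are the KM samples (sorted); the schedule and
    tumor are the group-representative delivery and mean-volume tumor.
    """

    name: str
    schedule: FractionationSchedule
    tumor: TumorSpec
    times_months: tuple
    lpfs: tuple

    def __post_init__(self):
        t = tuple(float(x) for x in np.asarray(self.times_months, dtype=float))
        p = tuple(float(x) for x in np.asarray(self.lpfs, dtype=float))
        object.__setattr__(self, "times_months", t)
        object.__setattr__(self, "lpfs", p)
        if len(t) != len(p):
            raise ValueError("times and lpfs must have equal length")
        if any(b < a for a, b in zip(t, t[1:])):
            raise ValueError("times must be sorted ascending")

    @property
    def n_samples(self) -> int:
        return len(self.times_months)

    def drop_sample(self, index: int) -> "GroupData":
        t = list(self.times_months)
        p = list(self.lpfs)
        del t[index], p[index]
        return GroupData(self.name, self.schedule, self.tumor, tuple(t), tuple(p))

    def subset(self, indices) -> "GroupData":
        t = [self.times_months[i] for i in indices]
        p = [self.lpfs[i] for i in indices]
        order = np.argsort(t, kind="stable")
        return GroupData(
            self.name,
            self.schedule,
            self.tumor,
            tuple(t[i] for i in order),
            tuple(p[i] for i in order),
        )


def mae_cost(model: str, params, groups) -> float:
    """Pooled mean absolute error between TCP(t_i) and LPFS(t_i)."""
    groups = list(groups)
    total = 0.0
    m = 0
    for g in groups:
        if g.n_samples == 0:
            continue
        pred = np.asarray(
            tcp_time_curve(model, params, g.schedule, g.tumor, np.asarray(g.times_months))
        )
        total += float(np.sum(np.abs(pred - np.asarray(g.lpfs))))
        m += g.n_samples
    if m == 0:
        raise ValueError("no fitting samples")
    return total / m


def fitting_errors(predicted, observed):
    """Average absolute and relative fitting errors, both in percent.

    absolute = 100 * mean|p_i - o_i|; relative = 100 * mean(|p_i - o_i|/o_i).
    The relative error is NaN (undefined) whenever any observed value is 0.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must be equal-length and non-empty")
    abs_err = 100.0 * float(np.mean(np.abs(p - o)))
    if np.any(o == 0):
        rel_err = float("nan")
    else:
        rel_err = 100.0 * float(np.mean(np.abs(p - o) / o))
    return abs_err, rel_err


@dataclass
class FitResult:
    """Outcome of a model fit."""

    model: str
    params: object
    free: tuple
    cost: float
    n_samples: int
    log_likelihood: float
    aic: float
    iterations: int
    converged: bool
    seed: int
    n_starts: int
    start_costs: tuple = ()
    ci: dict | None = None
    ci_method: str | None = None

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params.to_dict(),
            "free": list(self.free),
            "cost_mae": self.cost,
            "n_samples": self.n_samples,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "k": self.k,
            "iterations": self.iterations,
            "converged": self.converged,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "start_costs": list(self.start_costs),
            "ci": self.ci,
            "ci_method": self.ci_method,
        }


# -- optimizer internals ----------------------------------------------------


def _make_cost_fn(model, base_params, free, groups):
    def cost_fn(x):
        updates = {name: math.exp(v) for name, v in zip(free, x)}
        try:
            params = base_params.replace(**updates)
        except ValueError:
            return float("inf")
        try:
            return mae_cost(model, params, groups)
        except (OverflowError, FloatingPointError):
            return float("inf")

    return cost_fn


def _gradient(cost_fn, x, f0, h_rel=1e-5):
    g = np.empty_like(x)
    for i in range(x.size):
        h = h_rel * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (cost_fn(xp) - cost_fn(xm)) / (2.0 * h)
    return g


def _descend(cost_fn, x0, lb, ub, max_iter, tol, patience):
    """Gradient descent with backtracking line search in a box."""
    x = np.clip(x0, lb, ub)
    f = cost_fn(x)
    step = 1.0
    no_improve = 0
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        g = _gradient(cost_fn, x, f)
        gnorm2 = float(g @ g)
        if not np.isfinite(gnorm2) or gnorm2 == 0.0:
            converged = True
            break
        s = step
        accepted = False
        for _ in range(30):
            xn = np.clip(x - s * g, lb, ub)
            fn = cost_fn(xn)
            if fn <= f - 1e-4 * s * gnorm2 or fn < f - 1e-15:
                accepted = True
                break
            s *= 0.5
        if accepted:
            improvement = f - fn
            x, f = xn, fn
            step = min(s * 2.0, 1e3)
            no_improve = no_improve + 1 if improvement < tol else 0
        else:
            step = max(step * 0.5, 1e-12)
            no_improve += 1
        if no_improve >= patience:
            converged = True
            break
    return x, f, iterations, converged


def _log_bounds(free, bounds):
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    lb = np.array([math.log(merged[n][0]) for n in free])
    ub = np.array([math.log(merged[n][1]) for n in free])
    return lb, ub


def fit_model(
    model: str,
    groups,
    *,
    init=None,
    free=None,
    bounds=None,
    seed: int = 0,
    n_starts: int = 16,
    max_iter: int = 5000,
    tol: float = 1e-7,
    patience: int = 50,
    init_spread: float = 0.5,
) -> FitResult:
    """Fit a TCP model to pooled LPFS samples by MAE minimization.

    Parameters are optimized in log-space (positivity for free) within wide
    box bounds; ``n_starts`` deterministic starts (the first at ``init``, the
    rest log-normal perturbations of it) guard against local minima.
    Convergence: best-cost improvement below ``tol`` for ``patience``
    consecutive iterations, or ``max_iter`` iterations. Deterministic given
    ``seed``.
    """
    groups = list(groups)
    if model not in MODEL_PARAM_NAMES:
        raise ValueError(f"unknown model {model!r}")
    base = init if init is not None else default_params(model)
    free = tuple(free) if free is not None else MODEL_PARAM_NAMES[model]
    unknown = set(free) - set(MODEL_PARAM_NAMES[model])
    if unknown:
        raise ValueError(f"free parameters not in model {model!r}: {sorted(unknown)}")
    lb, ub = _log_bounds(free, bounds)
    x_init = np.array([math.log(getattr(base, n)) for n in free])
    if np.any(x_init < lb) or np.any(x_init > ub):
        raise ValueError("init lies outside bounds")

    cost_fn = _make_cost_fn(model, base, free, groups)
    if not np.isfinite(cost_fn(x_init)):
        raise ValueError("cost is non-finite at init")

    rng = np.random.default_rng(seed)
    starts = [x_init]
    for _ in range(n_starts - 1):
        starts.append(np.clip(x_init + rng.normal(0.0, init_spread, x_init.size), lb, ub))

    best = None
    start_costs = []
    for x0 in starts:
        x, f, iters, conv = _descend(cost_fn, x0, lb, ub, max_iter, tol, patience)
        start_costs.append(f)
        if best is None or f < best[1]:
            best = (x, f, iters, conv)
    x_best, f_best, iters, conv = best
    if not conv:
        log.debug("no start converged within %d iterations; result flagged", max_iter)

    fitted = base.replace(**{n: math.exp(v) for n, v in zip(free, x_best)})
    m = sum(g.n_samples for g in groups)
    from .model_selection import aic as _aic, log_likelihood_from_mae

    ll = log_likelihood_from_mae(f_best, m) if f_best > 0 else float("inf")
    return FitResult(
        model=model,
        params=fitted,
        free=free,
        cost=f_best,
        n_samples=m,
        log_likelihood=ll,
        aic=_aic(len(free), ll),
        iterations=iters,
        converged=conv,
        seed=seed,
        n_starts=n_starts,
        start_costs=tuple(start_costs),
    )


# -- confidence intervals ---------------------------------------------------


def _hessian(fn, x, h_rel=1e-4):
    n = x.size
    H = np.empty((n, n))
    h = np.array([h_rel * max(1.0, abs(v)) for v in x])
    f0 = fn(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (fn(xp) - 2.0 * f0 + fn(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += h[[i, j]]
                xmm[[i, j]] -= h[[i, j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                H[i, j] = H[j, i] = (fn(xpp) - fn(xpm) - fn(xmp) + fn(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    return H


def parameter_confidence_intervals(
    fit: FitResult,
    groups,
    method: str = "hessian",
    seed: int = 0,
    n_boot: int = 200,
    refit_kwargs: dict | None = None,
) -> dict:
    """95% confidence intervals for the free parameters of a converged fit.

    ``hessian``: curvature of the surrogate (Laplace-residual) log-likelihood
    at the optimum, in log-parameter space, transformed back; falls back to
    bootstrap with a logged notice if the curvature matrix is singular or not
    positive definite. ``bootstrap``: percentile intervals over ``n_boot``
    seeded case resamples of the fitting samples (refits warm-start at the
    point estimate). Returns {name: (lower, upper)}.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    groups = list(groups)
    free = fit.free
    x_opt = np.array([math.log(getattr(fit.params, n)) for n in free])
    if method == "hessian":
        cost_fn = _make_cost_fn(fit.model, fit.params, free, groups)
        m = fit.n_samples

        def neg_ll(x):
            c = cost_fn(x)
            if not np.isfinite(c) or c <= 0:
                return float("inf")
            return m * (math.log(2.0 * c) + 1.0)

        H = _hessian(neg_ll, x_opt)
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
            if not np.all(np.isfinite(se)):
                raise np.linalg.LinAlgError("non-finite standard errors")
        except np.linalg.LinAlgError:
            log.warning("singular curvature at optimum; falling back to bootstrap CIs")
            return parameter_confidence_intervals(
                fit, groups, method="bootstrap", seed=seed, n_boot=n_boot,
                refit_kwargs=refit_kwargs,
            )
        ci = {
            name: (math.exp(x - 1.96 * s), math.exp(x + 1.96 * s))
            for name, x, s in zip(free, x_opt, se)
        }
        fit.ci, fit.ci_method = ci, "hessian"
        return ci
    if method == "bootstrap":
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        rng = np.random.default_rng(seed)
        kwargs = dict(n_starts=1, max_iter=300, patience=20, tol=1e-6)
        if refit_kwargs:
            kwargs.update(refit_kwargs)
        draws = {name: [] for name in free}
        for _ in range(n_boot):
            resampled = []
            for g in groups:
                if g.n_samples == 0:
                    continue
                idx = rng.integers(0, g.n_samples, g.n_samples)
                resampled.append(g.subset(idx))
            refit = fit_model(
                fit.model, resampled, init=fit.params, free=free, seed=0, **kwargs
            )
            for name in free:
                draws[name].append(getattr(refit.params, name))
        ci = {
            name: (
                float(np.percentile(draws[name], 2.5)),
                float(np.percentile(draws[name], 97.5)),
            )
            for name in free
        }
        fit.ci, fit.ci_method = ci, "bootstrap"
        return ci
    raise ValueError(f"unknown CI method {method!r}")
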