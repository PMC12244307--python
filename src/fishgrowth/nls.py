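"""Frequentist nonlinear least-squares fits of the growth models.

Both models are fitted by Levenberg-Marquardt with analytic residual
Jacobians and a small multi-start grid (the von Bertalanffy surface is
multimodal under weak designs, e.g. samples lacking old fish).  95%
confidence intervals are profile-likelihood by default with a Wald
(curvature-based) fallback; both methods are exposed.

Parameters are deliberately unconstrained: when the data cannot separate
``l_inf`` from ``k`` (flat-ish curves), the fit is allowed to wander to
enormous asymptotic lengths — an honest symptom of a weakly informative
design rather than something to hide behind box constraints.  A bounded
mode is available for production use.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .growth import GrowthParams
from .result import FitResult

__all__ = ["fit_vbgm_nls", "fit_fabens_nls", "confidence_intervals"]

_XTOL = 1e-10
_FTOL = 1e-8    # relative SSE change tolerance
_MAX_ITER = 500


def _vbgm_residuals(theta, age, length):
    l_inf, k, t0 = theta
    e = np.exp(-k * (age - t0))
    return length - l_inf * (1.0 - e)


def _vbgm_jac(theta, age, length):
    l_inf, k, t0 = theta
    e = np.exp(-k * (age - t0))
    J = np.empty((age.size, 3))
    J[:, 0] = -(1.0 - e)
    J[:, 1] = -l_inf * (age - t0) * e
    J[:, 2] = l_inf * k * e
    return J


def _fabens_residuals(theta, l_m, dt, l_r):
    l_inf, k = theta
    g = 1.0 - np.exp(-k * dt)
    return l_r - (l_m + (l_inf - l_m) * g)


def _fabens_jac(theta, l_m, dt, l_r):
    l_inf, k = theta
    e = np.exp(-k * dt)
    J = np.empty((l_m.size, 2))
    J[:, 0] = -(1.0 - e)
    J[:, 1] = -(l_inf - l_m) * dt * e
    return J


def _run_multistart(residuals, jac, starts, args, bounds=None):
    best = None
    for x0 in starts:
        try:
            if bounds is None:
                res = optimize.least_squares(
                    residuals, x0, jac=jac, args=args, method="lm",
                    xtol=_XTOL, ftol=_FTOL, max_nfev=_MAX_ITER * (len(x0) + 1),
                )
            else:
                res = optimize.least_squares(
                    residuals, x0, jac=jac, args=args, method="trf",
                    bounds=bounds, xtol=_XTOL, ftol=_FTOL,
                    max_nfev=_MAX_ITER * (len(x0) + 1),
                )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best


def _wald(res, n, level):
    """Wald standard errors and t-intervals from the final Jacobian."""
    p = res.x.size
    dof = max(n - p, 1)
    sse = 2.0 * res.cost
    s2 = sse / dof
    JtJ = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        cond = np.linalg.cond(JtJ)
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
        cond = np.inf
    tq = stats.t.ppf(0.5 + level / 2.0, dof)
    lo = res.x - tq * se
    hi = res.x + tq * se
    return se, lo, hi, np.sqrt(s2), cond


def fit_vbgm_nls(
    records: pd.DataFrame,
    start: GrowthParams | None = None,
    level: float = 0.95,
    bounded: bool = False,
    ci_method: str = "wald",
) -> FitResult:
    """Fit the von Bertalanffy curve to age-at-length data by NLS.

    ``records`` needs columns ``age`` and ``length``.  Multi-start from
    ``l_inf = 1.1 * max(length)``, ``k in {0.1, 0.3, 0.6}``, ``t0 = 0``
    (plus the user start, if given), keeping the lowest-SSE solution.
    Intervals in the returned result are Wald; use
    :func:`confidence_intervals` for profile-likelihood intervals.
    """
    age = np.asarray(records["age"], dtype=float)
    length = np.asarray(records["length"], dtype=float)
    n = age.size
    if n < 4:
        raise ValueError("need at least 4 records")
    if np.unique(age).size < 3:
        raise ValueError("need at least 3 distinct ages")

    starts = [np.array([1.1 * length.max(), k0, 0.0]) for k0 in (0.1, 0.3, 0.6)]
    if start is not None:
        starts.insert(0, np.array([start.l_inf, start.k, start.t0]))
    bounds = ([1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.inf]) if bounded else None
    res = _run_multistart(_vbgm_residuals, _vbgm_jac, starts, (age, length), bounds)
    se, lo, hi, sigma, cond = _wald(res, n, level)
    converged = bool(res.status > 0) and np.all(np.isfinite(se))
    names = ["l_inf", "k", "t0"]
    return FitResult(
        method="vBGM",
        mode="frequentist",
        estimates={**dict(zip(names, map(float, res.x))), "sigma": float(sigma)},
        intervals={nm: (float(l), float(h)) for nm, l, h in zip(names, lo, hi)},
        fit_stats={
            "sigma": float(sigma), "n": int(n), "converged": converged,
            "sse": float(2 * res.cost), "se": dict(zip(names, map(float, se))),
            "condition_number": float(cond), "ci_method": "wald", "level": level,
        },
    )


def fit_fabens_nls(
    pairs: pd.DataFrame,
    start: GrowthParams | None = None,
    level: float = 0.95,
    bounded: bool = False,
) -> FitResult:
    """Fit the Fabens increment model to mark-recapture pairs by NLS.

    ``pairs`` needs columns ``l_m``, ``l_r`` and ``dt``.  Only
    ``(l_inf, k)`` are estimated; there is no ``t0`` in this model.  A
    design in which neither marking length nor elapsed time varies is
    rejected; near-degenerate designs (all ``dt`` close to zero) are
    flagged as non-converged via the curvature condition number.
    """
    l_m = np.asarray(pairs["l_m"], dtype=float)
    l_r = np.asarray(pairs["l_r"], dtype=float)
    dt = np.asarray(pairs["dt"], dtype=float)
    n = l_m.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(l_m) == 0 and np.ptp(dt) == 0:
        raise ValueError("degenerate design: l_m and dt both constant")

    starts = [np.array([1.1 * max(l_r.max(), l_m.max()), k0]) for k0 in (0.1, 0.3, 0.6)]
    if start is not None:
        starts.insert(0, np.array([start.l_inf, start.k]))
    bounds = ([1e-6, 1e-6], [np.inf, np.inf]) if bounded else None
    res = _run_multistart(_fabens_residuals, _fabens_jac, starts, (l_m, dt, l_r), bounds)
    se, lo, hi, sigma, cond = _wald(res, n, level)
    # a parameter whose SE is a multiple of its estimate marks an
    # unidentifiable design (e.g. all recapture intervals near zero)
    rel_se = se / np.maximum(np.abs(res.x), 1e-12)
    converged = bool(res.status > 0) and np.all(np.isfinite(se)) and np.max(rel_se) <= 2.0
    names = ["l_inf", "k"]
    return FitResult(
        method="Fabens",
        mode="frequentist",
        estimates={**dict(zip(names, map(float, res.x))), "sigma": float(sigma)},
        intervals={nm: (float(l), float(h)) for nm, l, h in zip(names, lo, hi)},
        fit_stats={
            "sigma": float(sigma), "n": int(n), "converged": converged,
            "sse": float(2 * res.cost), "se": dict(zip(names, map(float, se))),
            "condition_number": float(cond), "ci_method": "wald", "level": level,
        },
    )


def _profile_funcs(fit, data):
    if fit.method == "vBGM":
        age = np.asarray(data["age"], dtype=float)
        length = np.asarray(data["length"], dtype=float)
        names = ["l_inf", "k", "t0"]
        resid, jac, args = _vbgm_residuals, _vbgm_jac, (age, length)
    elif fit.method == "Fabens":
        names = ["l_inf", "k"]
        l_m = np.asarray(data["l_m"], dtype=float)
        l_r = np.asarray(data["l_r"], dtype=float)
        dt = np.asarray(data["dt"], dtype=float)
        resid, jac, args = _fabens_residuals, _fabens_jac, (l_m, dt, l_r)
    else:
        raise ValueError(f"no profiling for method {fit.method!r}")
    return names, resid, jac, args


def _profile_sse(fixed_idx, fixed_val, x_full, resid, jac, args):
    """SSE minimised over the free parameters with one parameter pinned."""
    free_idx = [i for i in range(x_full.size) if i != fixed_idx]

    def r(xf):
        x = x_full.copy()
        x[fixed_idx] = fixed_val
        x[free_idx] = xf
        return resid(x, *args)

    def J(xf):
        x = x_full.copy()
        x[fixed_idx] = fixed_val
        x[free_idx] = xf
        return jac(x, *args)[:, free_idx]

    res = optimize.least_squares(r, x_full[free_idx], jac=J, method="lm",
                                 xtol=_XTOL, ftol=_FTOL)
    return 2.0 * res.cost


def confidence_intervals(
    fit: FitResult,
    data: pd.DataFrame,
    level: float = 0.95,
    method: str = "profile",
) -> FitResult:
    """Recompute per-parameter intervals on a converged NLS fit.

    ``method="profile"`` inverts the profile-likelihood ratio (the SSE
    with one parameter pinned, minimised over the rest, compared against
    an F(1, n-p) cut-off); ``method="wald"`` uses the curvature-based
    t-intervals.  Any parameter whose profile cannot be bracketed falls
    back to Wald with a warning recorded in ``fit_stats``.
    """
    if not fit.converged:
        raise ValueError("cannot compute intervals for a non-converged fit")
    if method not in ("profile", "wald"):
        raise ValueError("method must be 'profile' or 'wald'")
    names, resid, jac, args = _profile_funcs(fit, data)
    x_hat = np.array([fit.estimates[nm] for nm in names])
    n = int(fit.fit_stats["n"])
    p = len(names)
    dof = max(n - p, 1)
    sse_hat = float(fit.fit_stats["sse"])
    se = np.array([fit.fit_stats["se"][nm] for nm in names])
    tq = stats.t.ppf(0.5 + level / 2.0, dof)

    intervals = {}
    ci_warnings = []
    if method == "wald" or sse_hat == 0.0:
        # zero-residual data: intervals collapse onto the point estimates
        for i, nm in enumerate(names):
            w = tq * se[i] if sse_hat > 0 else 0.0
            intervals[nm] = (float(x_hat[i] - w), float(x_hat[i] + w))
        used = "wald"
    else:
        fcrit = stats.f.ppf(level, 1, dof)
        sse_target = sse_hat * (1.0 + fcrit / dof)

        def excess(val, i):
            return _profile_sse(i, val, x_hat, resid, jac, args) - sse_target

        for i, nm in enumerate(names):
            bnds = []
            for sign in (-1.0, +1.0):
                step = max(se[i], 1e-8 * max(abs(x_hat[i]), 1.0))
                lo_val = None
                prev = x_hat[i]
                for mult in (1, 2, 4, 8, 16, 32, 64, 128, 256):
                    cand = x_hat[i] + sign * mult * step
                    try:
                        if excess(cand, i) > 0:
                            lo_val = optimize.brentq(
                                excess, min(prev, cand), max(prev, cand),
                                args=(i,), xtol=1e-6 * step,
                            )
                            break
                    except Exception:
                        break
                    prev = cand
                bnds.append(lo_val)
            if bnds[0] is None or bnds[1] is None:
                w = tq * se[i]
                intervals[nm] = (float(x_hat[i] - w), float(x_hat[i] + w))
                ci_warnings.append(f"profile failed for {nm}; Wald fallback")
                warnings.warn(f"profile CI failed for {nm}; using Wald", RuntimeWarning)
            else:
                intervals[nm] = (float(min(bnds)), float(max(bnds)))
        used = "profile"

    stats_out = dict(fit.fit_stats)
    stats_out.update({"ci_method": used, "level": level})
    if ci_warnings:
        stats_out["ci_warnings"] = ci_warnings
    return FitResult(
        method=fit.method, mode=fit.mode,
        estimates=dict(fit.estimates), intervals=intervals, fit_stats=stats_out,
    )
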