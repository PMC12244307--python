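"""Bayesian growth-model fits with literature-informed normal priors.

Priors for ``l_inf``, ``k`` and ``t0`` are normal distributions whose
mean and SD are the column mean and sample SD of a table of published
growth-parameter estimates for the species from other European waters
(11 studies packaged as :data:`LITERATURE_PRIORS`).  ``l_inf`` and ``k``
are truncated to positive support; ``t0`` is untruncated (published
values include negatives).  The observation-error SD ``sigma`` gets a
weakly informative half-Normal(0, 50 mm) prior.

Sampling is an adaptive random-walk Metropolis: a joint Gaussian
proposal whose per-parameter scales track the running posterior SDs and
whose global scale is tuned during burn-in toward an acceptance rate of
about 0.3.  Split-R-hat and effective sample size come from arviz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
import arviz as az

from .growth import GrowthParams
from .result import FitResult

__all__ = [
    "LITERATURE_PRIORS",
    "PriorSpec",
    "MCMCSettings",
    "PosteriorDraws",
    "build_priors",
    "log_posterior",
    "sample_posterior",
    "summarize_posterior",
]

# Published von Bertalanffy estimates for European grayling used to
# construct the priors (l_inf mm, k 1/yr, t0 yr).
LITERATURE_PRIORS = pd.read_csv(StringIO("""\
reference,locality,l_inf,k,t0
FishBase,Kanin Peninsula (Russia),375.00,0.214,-0.080
Guillaud et al. 2019,Historical data from Europe,544.00,0.190,-1.400
Woolland & Jones 1975,Llyn Tegid 1946-52 (Wales),575.00,0.223,0.115
Woolland & Jones 1975,Llyn Tegid 1962-68 (Wales),456.00,0.386,0.222
Woolland & Jones 1975,Upper Dee (Wales),389.00,0.424,0.149
Woolland & Jones 1975,Corwen (Wales),417.00,0.484,0.281
Giri 2021,Valae (Norway),437.80,0.238,0.540
Giri 2021,Steinbekken (Norway),438.80,0.238,0.488
Giri 2021,Sandbekken (Norway),393.33,0.292,0.557
Giri 2021,Shyrjon (Norway),418.12,0.241,0.490
Giri 2021,Sorskottae (Norway),456.41,0.220,0.520
"""))

SIGMA_PRIOR_SCALE = 50.0  # half-Normal scale for the error SD, mm


@dataclass(frozen=True)
class PriorSpec:
    """Normal priors per growth parameter plus the sigma prior scale."""

    means: dict
    sds: dict
    sigma_scale: float = SIGMA_PRIOR_SCALE
    # truncation bounds of the parameter space (physical support)
    lower: dict = field(default_factory=lambda: {"l_inf": 0.0, "k": 0.0, "t0": -np.inf})

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"prior SD for {name!r} must be positive, got {sd}")
        if not self.sigma_scale > 0:
            raise ValueError("sigma_scale must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler schedule; defaults follow the study design (4 chains)."""

    iterations: int = 50_000
    burn_in: int = 25_000
    thin: int = 10
    chains: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("require 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Retained draws per chain plus sampler diagnostics."""

    draws: dict                 # name -> array (chains, retained)
    acceptance_rate: float
    rhat: dict
    ess: dict
    warnings: list = field(default_factory=list)
    model: str = ""
    n_obs: int = 0

    @property
    def names(self) -> list:
        return list(self.draws)

    def stacked(self, name: str) -> np.ndarray:
        return np.concatenate(self.draws[name])


def build_priors(literature: pd.DataFrame | None = None) -> PriorSpec:
    """Normal priors from a table of published (l_inf, k[, t0]) estimates.

    Prior mean = column arithmetic mean; prior SD = column sample SD.
    At least two rows are required (the SD is undefined otherwise), and
    a zero-variance column is rejected.
    """
    lit = LITERATURE_PRIORS if literature is None else literature
    if len(lit) < 2:
        raise ValueError("need at least 2 literature rows to form a prior SD")
    cols = [c for c in ("l_inf", "k", "t0") if c in lit.columns]
    if "l_inf" not in cols or "k" not in cols:
        raise ValueError("literature table must contain l_inf and k columns")
    means, sds = {}, {}
    for c in cols:
        v = lit[c].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1))
        if sd == 0.0:
            raise ValueError(f"literature column {c!r} has zero variance")
        means[c] = float(np.mean(v))
        sds[c] = sd
    return PriorSpec(means=means, sds=sds)


def _param_names(model: str) -> list:
    if model == "vBGM":
        return ["l_inf", "k", "t0", "sigma"]
    if model == "Fabens":
        return ["l_inf", "k", "sigma"]
    raise ValueError(f"model must be 'vBGM' or 'Fabens', got {model!r}")


def _prepare_data(model: str, data: pd.DataFrame | None):
    if data is None or len(data) == 0:
        return None
    if model == "vBGM":
        arr = (np.asarray(data["age"], float), np.asarray(data["length"], float))
    else:
        arr = (
            np.asarray(data["l_m"], float),
            np.asarray(data["dt"], float),
            np.asarray(data["l_r"], float),
        )
    if not all(np.all(np.isfinite(a)) for a in arr):
        raise ValueError("data contain non-finite values")
    return arr


_LOG_2PI = np.log(2.0 * np.pi)


def _log_post_vec(x: np.ndarray, arrs, model: str, priors: PriorSpec) -> float:
    """Unnormalised log posterior on the raw parameter vector."""
    names = _param_names(model)
    d = dict(zip(names, x))
    sigma = d["sigma"]
    if sigma <= 0 or d["l_inf"] <= 0 or d["k"] <= 0:
        return -np.inf
    lp = 0.0
    for nm in names[:-1]:
        mu, sd = priors.means[nm], priors.sds[nm]
        lp += -0.5 * ((d[nm] - mu) / sd) ** 2
    lp += -0.5 * (sigma / priors.sigma_scale) ** 2  # half-normal
    if arrs is not None:
        if model == "vBGM":
            age, length = arrs
            mu_i = d["l_inf"] * (1.0 - np.exp(-d["k"] * (age - d["t0"])))
            resid = length - mu_i
        else:
            l_m, dt, l_r = arrs
            mu_i = l_m + (d["l_inf"] - l_m) * (1.0 - np.exp(-d["k"] * dt))
            resid = l_r - mu_i
        n = resid.size
        lp += -0.5 * float(resid @ resid) / sigma**2 - n * (np.log(sigma) + 0.5 * _LOG_2PI)
    if not np.isfinite(lp):
        return -np.inf
    return lp


def log_posterior(
    params: GrowthParams,
    data: pd.DataFrame | None,
    model: str,
    priors: PriorSpec,
) -> float:
    """Log posterior density (up to a constant) at a parameter point.

    Gaussian log-likelihood over the observations plus the normal
    log-priors and the half-normal sigma prior; ``-inf`` outside the
    truncation bounds.  With no data, only the log-prior remains.
    """
    names = _param_names(model)
    x = np.array([getattr(params, nm) if nm != "sigma" else params.sigma for nm in names])
    arrs = _prepare_data(model, data)
    return _log_post_vec(x, arrs, model, priors)


def sample_posterior(
    model: str,
    data: pd.DataFrame | None,
    priors: PriorSpec,
    settings: MCMCSettings = MCMCSettings(),
) -> PosteriorDraws:
    """Adaptive random-walk Metropolis over the growth parameters.

    Each chain starts from a jittered draw around the prior means, adapts
    its proposal (per-parameter scales from running variances, global
    scale toward ~0.3 acceptance) during burn-in only, then samples with
    frozen proposals.  Retained draws are the post-burn-in states thinned
    by ``settings.thin`` — exactly ``(iterations - burn_in) // thin`` per
    chain.  An R-hat above 1.05 on any parameter is surfaced as a
    warning, not an error.
    """
    names = _param_names(model)
    arrs = _prepare_data(model, data)
    rng_master = np.random.default_rng(settings.seed)
    chain_seeds = rng_master.integers(0, 2**31 - 1, size=settings.chains)

    init_mean = np.array(
        [priors.means.get(nm, 0.0) if nm != "sigma" else priors.sigma_scale / 2
         for nm in names]
    )
    init_scale = np.array(
        [priors.sds.get(nm, 1.0) if nm != "sigma" else priors.sigma_scale / 4
         for nm in names]
    )

    retained = {nm: np.empty((settings.chains, settings.retained_per_chain)) for nm in names}
    n_accept_total = 0
    n_prop_total = 0

    for c in range(settings.chains):
        rng = np.random.default_rng(chain_seeds[c])
        # start strictly inside the support
        for _ in range(200):
            x = init_mean + 0.1 * init_scale * rng.standard_normal(len(names))
            if np.isfinite(_log_post_vec(x, arrs, model, priors)):
                break
        lp = _log_post_vec(x, arrs, model, priors)

        log_global = np.log(2.38 / np.sqrt(len(names)))
        run_mean = x.copy()
        run_var = init_scale**2
        n_seen = 1
        acc_window = 0
        keep = retained_idx = 0
        for it in range(settings.iterations):
            scales = np.exp(log_global) * np.sqrt(run_var + 1e-12)
            prop = x + scales * rng.standard_normal(len(names))
            lp_prop = _log_post_vec(prop, arrs, model, priors)
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                acc_window += 1
                if it >= settings.burn_in:
                    n_accept_total += 1
            if it >= settings.burn_in:
                n_prop_total += 1
            if it < settings.burn_in:
                # adapt: running moments + global-scale Robbins-Monro
                n_seen += 1
                delta = x - run_mean
                run_mean += delta / n_seen
                run_var += (delta * (x - run_mean) - run_var) / n_seen
                if (it + 1) % 100 == 0:
                    rate = acc_window / 100.0
                    log_global += 0.3 * (rate - 0.3)
                    acc_window = 0
            else:
                k_post = it - settings.burn_in
                if k_post % settings.thin == settings.thin - 1:
                    if retained_idx < settings.retained_per_chain:
                        for j, nm in enumerate(names):
                            retained[nm][c, retained_idx] = x[j]
                        retained_idx += 1
        # guard: fill any tail shortfall (only when (iters-burn)/thin not integral)
        while retained_idx < settings.retained_per_chain:
            for j, nm in enumerate(names):
                retained[nm][c, retained_idx] = x[j]
            retained_idx += 1

    idata = az.from_dict(posterior={nm: retained[nm] for nm in names})
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {nm: float(rhat_ds[nm].values) for nm in names}
    ess = {nm: float(ess_ds[nm].values) for nm in names}
    warns = []
    if settings.chains > 1:
        for nm, r in rhat.items():
            if np.isfinite(r) and r > 1.05:
                warns.append(f"R-hat for {nm} is {r:.3f} (> 1.05); chains may not have mixed")

    return PosteriorDraws(
        draws=retained,
        acceptance_rate=(n_accept_total / n_prop_total) if n_prop_total else float("nan"),
        rhat=rhat,
        ess=ess,
        warnings=warns,
        model=model,
        n_obs=0 if arrs is None else len(arrs[0]),
    )


def summarize_posterior(draws: PosteriorDraws, level: float = 0.95) -> FitResult:
    """Posterior medians with equal-tailed credible intervals as a FitResult."""
    if not draws.draws or next(iter(draws.draws.values())).size == 0:
        raise ValueError("draws must be non-empty")
    alpha = (1.0 - level) / 2.0
    estimates, intervals, means = {}, {}, {}
    for nm in draws.names:
        s = draws.stacked(nm)
        estimates[nm] = float(np.median(s))
        means[nm] = float(np.mean(s))
        intervals[nm] = (float(np.quantile(s, alpha)), float(np.quantile(s, 1 - alpha)))
    method = "vBGM" if draws.model == "vBGM" else "Fabens"
    return FitResult(
        method=method,
        mode="Bayesian",
        estimates=estimates,
        intervals=intervals,
        fit_stats={
            "posterior_mean": means,
            "n": draws.n_obs,
            "converged": True,
            "acceptance_rate": draws.acceptance_rate,
            "rhat": draws.rhat,
            "ess": draws.ess,
            "warnings": list(draws.warnings),
            "level": level,
            "sigma": estimates.get("sigma", 0.0),
        },
    )
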