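"""Electronic length-frequency analysis (ELEFAN) from first principles.

The pipeline: individual lengths per sampling date are binned into a
length-frequency matrix; each date's histogram is *restructured* with
the classic moving-average ratio recipe so that modes become positive
scores and troughs negative ones; a family of von Bertalanffy cohort
curves — one per plausible birth year, all sharing ``(l_inf, k,
t_anchor)`` — is traced through the matrix and scored by the sum of
peak scores it explains (ESP) against the total available (ASP),
yielding the goodness criterion ``Rn = 10^(ESP/ASP) / 10``; a
real-coded genetic algorithm maximises Rn; percentile bootstrap over
fish within sampling dates supplies 95% confidence intervals.

Restructuring recipe (per date column):

1. moving average of the counts over ``ma_window`` bins (edge windows
   average over the bins that exist, so a flat histogram scores zero);
2. score = count/MA - 1 where MA > 0, else 0;
3. isolated-peak de-emphasis: each positive score is multiplied by
   ``1 - nz/(ma_window - 1)`` where ``nz`` counts zero-count bins among
   its ``ma_window - 1`` nearest neighbours;
4. negatives rescaled so the positive and negative sums cancel, with a
   floor at -1 (a short fixed-point loop keeps both the floor and the
   zero-sum contract exact).

Each maximal run of adjacent positive bins within a date is a *peak*;
ASP is the sum of positive scores over all peaks.  A traversing cohort
curve that hits a peak is credited with the peak's whole score, each
peak at most once across the curve family (so ESP <= ASP by
construction); hits on non-positive bins add that bin's score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime as _dt
import math
import warnings

import numpy as np
import pandas as pd

from .result import FitResult
from .simulate import LFQSample

__all__ = [
    "LFQMatrix",
    "RestructuredLFQ",
    "ELEFANParams",
    "GASettings",
    "bin_lengths",
    "restructure",
    "score_growth_curve",
    "ga_optimize",
    "bootstrap_elefan",
    "date_to_decimal_year",
]

DAYS_PER_YEAR = 365.25


def date_to_decimal_year(d: _dt.date) -> float:
    return d.year + (d - _dt.date(d.year, 1, 1)).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class LFQMatrix:
    """Length-frequency counts: sampling dates x equally spaced length bins."""

    dates: tuple
    bin_mids: np.ndarray   # mm
    counts: np.ndarray     # (n_dates, n_bins) non-negative ints
    bin_width: float       # mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_mids", np.asarray(self.bin_mids, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts))
        if self.counts.shape != (len(self.dates), self.bin_mids.size):
            raise ValueError("counts must be (n_dates, n_bins)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_mids.size > 1:
            steps = np.diff(self.bin_mids)
            if not np.allclose(steps, self.bin_width, atol=1e-9):
                raise ValueError("bins must be equally spaced by bin_width")
        if any(b >= a for a, b in zip(self.dates[1:], self.dates[:-1])):
            raise ValueError("dates must be strictly increasing")

    @property
    def dates_decimal(self) -> np.ndarray:
        return np.array([date_to_decimal_year(d) for d in self.dates])


@dataclass(frozen=True)
class RestructuredLFQ:
    """Restructured scores, same shape as the source LFQMatrix."""

    dates: tuple
    bin_mids: np.ndarray
    values: np.ndarray
    bin_width: float
    ma_window: int

    @property
    def dates_decimal(self) -> np.ndarray:
        return np.array([date_to_decimal_year(d) for d in self.dates])


@dataclass(frozen=True)
class ELEFANParams:
    """Growth parameters searched by ELEFAN.

    ``t_anchor`` is the within-year timing (fraction of the calendar
    year in [0, 1)) that anchors each cohort's birth to the calendar; it
    plays the role of ``t0`` on the calendar axis.
    """

    l_inf: float
    k: float
    t_anchor: float

    def __post_init__(self) -> None:
        if not self.l_inf > 0:
            raise ValueError("l_inf must be positive")
        if not self.k > 0:
            raise ValueError("k must be positive")
        if not (0.0 <= self.t_anchor < 1.0):
            raise ValueError("t_anchor must lie in [0, 1)")


@dataclass(frozen=True)
class GASettings:
    """Real-coded genetic algorithm settings."""

    population: int = 50
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    bounds: dict | None = None   # name -> (lo, hi); defaults derived from data
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.mutation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")
        if self.bounds is not None:
            for nm, (lo, hi) in self.bounds.items():
                if not lo < hi:
                    raise ValueError(f"degenerate bounds for {nm!r}: ({lo}, {hi})")


def bin_lengths(samples: list[LFQSample], bin_width: float = 10.0) -> LFQMatrix:
    """Bin individual lengths into a length-frequency matrix.

    Bins are half-open ``[mid - w/2, mid + w/2)`` (lower-inclusive), with
    midpoints on the ``(j + 1/2) * w`` grid, so a 154 mm fish falls in
    the bin with midpoint 155 at 10 mm width.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not samples:
        raise ValueError("samples must be non-empty")
    samples = sorted(samples, key=lambda s: s.date)
    all_len = np.concatenate([s.lengths for s in samples])
    idx_max = int(all_len.max() // bin_width)
    mids = (np.arange(idx_max + 1) + 0.5) * bin_width
    counts = np.zeros((len(samples), mids.size), dtype=int)
    for i, s in enumerate(samples):
        idx = (s.lengths // bin_width).astype(int)
        np.add.at(counts[i], idx, 1)
    return LFQMatrix(
        dates=tuple(s.date for s in samples),
        bin_mids=mids,
        counts=counts,
        bin_width=float(bin_width),
    )


def _restructure_column(counts: np.ndarray, ma_window: int) -> np.ndarray:
    n = counts.size
    half = ma_window // 2
    padded = np.concatenate([np.zeros(half), counts.astype(float), np.zeros(half)])
    sums = np.convolve(padded, np.ones(ma_window), mode="valid")
    # edge windows are shorter: average over the bins that exist, so a
    # perfectly uniform histogram scores zero everywhere
    width = np.convolve(np.ones(n), np.ones(ma_window), mode="full")[half:half + n]
    ma = sums / width
    scores = np.zeros(n)
    nzma = ma > 0
    scores[nzma] = counts[nzma] / ma[nzma] - 1.0

    # de-emphasise isolated peaks surrounded by empty bins
    zero_count = np.concatenate([np.ones(half), counts == 0, np.ones(half)]).astype(float)
    kernel = np.ones(ma_window)
    kernel[half] = 0.0  # neighbours only, not the bin itself
    nz = np.convolve(zero_count, kernel, mode="valid")
    pos = scores > 0
    scores[pos] *= 1.0 - nz[pos] / (ma_window - 1)
    scores = np.maximum(scores, -1.0)

    # zero-sum normalisation with the -1 floor kept exact
    possum = scores[scores > 0].sum()
    neg_idx = np.where(scores < 0)[0]
    if possum > 0 and neg_idx.size:
        raw_neg = scores[neg_idx].copy()
        floored = np.zeros(neg_idx.size, dtype=bool)
        for _ in range(50):
            remaining = possum - floored.sum() * 1.0
            free_sum = -raw_neg[~floored].sum()
            if free_sum <= 0 or remaining <= 0:
                scaled = np.where(floored, -1.0, 0.0)
                break
            f = remaining / free_sum
            scaled = np.where(floored, -1.0, raw_neg * f)
            newly = scaled < -1.0
            if not np.any(newly & ~floored):
                scaled = np.maximum(scaled, -1.0)
                break
            floored |= newly
        scores[neg_idx] = scaled
    elif possum == 0:
        # nothing positive: keep non-positive scores as-is (all-zero column stays zero)
        pass
    return scores


def restructure(lfq: LFQMatrix, ma_window: int = 5) -> RestructuredLFQ:
    """Apply the moving-average ratio restructuring to every date column."""
    if ma_window < 3 or ma_window % 2 == 0:
        raise ValueError("ma_window must be an odd integer >= 3")
    values = np.vstack([
        _restructure_column(lfq.counts[i], ma_window) for i in range(len(lfq.dates))
    ])
    return RestructuredLFQ(
        dates=lfq.dates, bin_mids=lfq.bin_mids, values=values,
        bin_width=lfq.bin_width, ma_window=ma_window,
    )


def _peaks(values: np.ndarray):
    """Label maximal runs of adjacent positive bins per date.

    Returns (peak_id matrix with -1 for non-peak bins, per-peak summed
    score array).
    """
    nd, nb = values.shape
    peak_id = np.full((nd, nb), -1, dtype=int)
    peak_scores = []
    for d in range(nd):
        in_run = False
        for b in range(nb):
            if values[d, b] > 0:
                if not in_run:
                    peak_scores.append(0.0)
                    in_run = True
                peak_id[d, b] = len(peak_scores) - 1
                peak_scores[-1] += values[d, b]
            else:
                in_run = False
    return peak_id, np.array(peak_scores)


def _curve_hits(r: RestructuredLFQ, p: ELEFANParams):
    """Unique (date, bin) cells crossed by the cohort-curve family.

    Cells are deduplicated: near the asymptote many cohort curves pile
    into the same bins, and a cell's score is counted once however many
    curves of the family pass through it.
    """
    t = r.dates_decimal
    lo_edge = r.bin_mids[0] - r.bin_width / 2.0
    top_edge = r.bin_mids[-1] + r.bin_width / 2.0
    # curves are followed until they reach the top bin or 95% of l_inf,
    # whichever comes first: beyond that the whole family piles into the
    # same asymptotic bins and traversal carries no cohort information
    max_len = min(top_edge, 0.95 * p.l_inf)
    a_max = min(-math.log(1.0 - max_len / p.l_inf) / p.k, 80.0)
    y_last = int(math.floor(t.max()))
    y_first = int(math.floor(t.min() - a_max)) - 1
    births = np.arange(y_first, y_last + 1) + p.t_anchor     # (n_cohorts,)
    ages = t[None, :] - births[:, None]                       # (n_cohorts, n_dates)
    L = p.l_inf * (1.0 - np.exp(-p.k * np.maximum(ages, 0.0)))
    valid = (ages > 0) & (L >= lo_edge) & (L < top_edge) & (L <= max_len)
    ci, di = np.nonzero(valid)
    bi = ((L[ci, di] - lo_edge) // r.bin_width).astype(int)
    nb = r.bin_mids.size
    cells = np.unique(di * nb + bi)
    return cells // nb, cells % nb


def score_growth_curve(r: RestructuredLFQ, p: ELEFANParams):
    """Score a candidate parameter triple against the restructured matrix.

    Returns ``(esp, asp, rn)``.  ASP sums the positive scores of all
    peaks; ESP credits each peak's score once if any cohort curve passes
    through it and adds the (non-positive) score of every other bin
    crossed; ``rn = 10^(esp/asp) / 10``.
    """
    peak_id, peak_scores = _peaks(r.values)
    asp = float(peak_scores.sum())
    if asp == 0.0:
        raise ValueError("ASP is zero: no peaks in the restructured data")
    di, bi = _curve_hits(r, p)
    pid = peak_id[di, bi]
    hit_peaks = np.unique(pid[pid >= 0])
    esp = float(peak_scores[hit_peaks].sum())
    esp += float(r.values[di[pid < 0], bi[pid < 0]].sum())
    rn = 10.0 ** (esp / asp) / 10.0
    return esp, asp, rn


def _default_bounds(lfq: LFQMatrix) -> dict:
    occupied = lfq.counts.sum(axis=0) > 0
    l_max = float(lfq.bin_mids[occupied][-1] + lfq.bin_width / 2.0)
    return {
        "l_inf": (0.8 * l_max, 1.5 * l_max),
        "k": (0.01, 1.0),
        "t_anchor": (0.0, 1.0 - 1e-9),
    }


_GENE_ORDER = ("l_inf", "k", "t_anchor")


def ga_optimize(
    lfq: LFQMatrix,
    settings: GASettings = GASettings(),
    ma_window: int = 5,
) -> FitResult:
    """Maximise Rn over (l_inf, k, t_anchor) with a real-coded GA.

    Tournament selection (size 3), blend (BLX-0.5) crossover, Gaussian
    mutation (SD = 10% of each parameter's range), elitism of one: the
    best individual always survives, so the best fitness is
    non-decreasing across generations.  Deterministic under
    ``settings.seed``.
    """
    bounds = dict(_default_bounds(lfq))
    if settings.bounds:
        bounds.update(settings.bounds)
    lo = np.array([bounds[g][0] for g in _GENE_ORDER])
    hi = np.array([bounds[g][1] for g in _GENE_ORDER])
    if np.any(lo >= hi):
        raise ValueError("degenerate search bounds")
    r = restructure(lfq, ma_window)
    peak_id, peak_scores = _peaks(r.values)
    if peak_scores.sum() == 0:
        raise ValueError("ASP is zero: no peaks in the restructured data")
    rng = np.random.default_rng(settings.seed)

    def fitness(genome: np.ndarray) -> float:
        p = ELEFANParams(*genome)
        di, bi = _curve_hits(r, p)
        pid = peak_id[di, bi]
        esp = float(peak_scores[np.unique(pid[pid >= 0])].sum())
        esp += float(r.values[di[pid < 0], bi[pid < 0]].sum())
        return 10.0 ** (esp / peak_scores.sum()) / 10.0

    pop = rng.uniform(lo, hi, size=(settings.population, 3))
    fit = np.array([fitness(g) for g in pop])
    history = []
    for _ in range(settings.generations):
        order = np.argsort(fit)[::-1]
        elite = pop[order[0]].copy()
        elite_fit = fit[order[0]]
        history.append(float(elite_fit))
        new_pop = [elite]
        while len(new_pop) < settings.population:
            # tournament selection of two parents
            cand = rng.integers(0, settings.population, size=(2, 3))
            parents = pop[[c[np.argmax(fit[c])] for c in cand]]
            a, b = parents
            if rng.uniform() < settings.crossover_prob:
                alpha = 0.5
                span = np.abs(a - b)
                c_lo = np.minimum(a, b) - alpha * span
                c_hi = np.maximum(a, b) + alpha * span
                child = rng.uniform(c_lo, c_hi)
            else:
                child = a.copy()
            mut = rng.uniform(size=3) < settings.mutation_prob
            child[mut] += rng.normal(0.0, 0.1 * (hi - lo))[mut]
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        fit = np.array([fitness(g) for g in pop])
    best_idx = int(np.argmax(fit))
    best = pop[best_idx]
    esp, asp, rn = score_growth_curve(r, ELEFANParams(*best))
    return FitResult(
        method="ELEFAN",
        mode="frequentist",
        estimates={"l_inf": float(best[0]), "k": float(best[1]),
                   "t_anchor": float(best[2])},
        fit_stats={
            "rn": float(rn), "esp": float(esp), "asp": float(asp),
            "n": int(lfq.counts.sum()), "converged": True,
            "generations": settings.generations, "population": settings.population,
            "fitness_history": history, "bounds": {g: list(bounds[g]) for g in _GENE_ORDER},
        },
    )


def _resample_matrix(lfq: LFQMatrix, rng) -> LFQMatrix:
    """Resample fish with replacement within each sampling date."""
    counts = np.zeros_like(lfq.counts)
    for i in range(len(lfq.dates)):
        total = int(lfq.counts[i].sum())
        if total == 0:
            continue
        probs = lfq.counts[i] / total
        counts[i] = rng.multinomial(total, probs)
    return LFQMatrix(dates=lfq.dates, bin_mids=lfq.bin_mids,
                     counts=counts, bin_width=lfq.bin_width)


def bootstrap_elefan(
    lfq: LFQMatrix,
    B: int = 200,
    settings: GASettings = GASettings(),
    seed: int | None = None,
    ma_window: int = 5,
    level: float = 0.95,
) -> FitResult:
    """Percentile bootstrap confidence intervals for the ELEFAN fit.

    Fish are resampled with replacement within each sampling date, the
    matrix rebinned, and the GA rerun per replicate; equal-tailed
    percentile intervals are taken over the replicate estimates.  The
    point estimate is the GA fit to the original data.  Replicates whose
    restructured matrix has no peaks are dropped with a warning; more
    than 20% drops is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    point = ga_optimize(lfq, GASettings(
        population=settings.population, generations=settings.generations,
        crossover_prob=settings.crossover_prob, mutation_prob=settings.mutation_prob,
        bounds=settings.bounds, seed=int(rng.integers(2**31 - 1)),
    ), ma_window)

    reps = {g: [] for g in _GENE_ORDER}
    dropped = 0
    for _ in range(B):
        boot = _resample_matrix(lfq, rng)
        try:
            fitb = ga_optimize(lfq=boot, settings=GASettings(
                population=settings.population, generations=settings.generations,
                crossover_prob=settings.crossover_prob,
                mutation_prob=settings.mutation_prob,
                bounds=settings.bounds, seed=int(rng.integers(2**31 - 1)),
            ), ma_window=ma_window)
        except ValueError:
            dropped += 1
            warnings.warn("bootstrap replicate dropped (no peaks)", RuntimeWarning)
            continue
        for g in _GENE_ORDER:
            reps[g].append(fitb.estimates[g])
    if dropped > 0.2 * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates dropped")

    alpha = (1.0 - level) / 2.0
    intervals = {}
    for g in _GENE_ORDER:
        arr = np.array(reps[g])
        lo_q, hi_q = np.quantile(arr, [alpha, 1.0 - alpha])
        # widen to include the point estimate if resampling skirted it
        intervals[g] = (float(min(lo_q, point.estimates[g])),
                        float(max(hi_q, point.estimates[g])))
    stats_out = dict(point.fit_stats)
    stats_out.update({
        "bootstrap_B": B, "bootstrap_dropped": dropped, "level": level,
        "bootstrap_replicates": {g: list(map(float, reps[g])) for g in _GENE_ORDER},
    })
    return FitResult(
        method="ELEFAN", mode="frequentist",
        estimates=dict(point.estimates), intervals=intervals, fit_stats=stats_out,
    )
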