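"""CSV formats, validation, and the five-way model-comparison pipeline.

Canonical file formats (comma-separated, UTF-8, ISO-8601 dates, lengths
in mm unless a ``unit`` column says ``cm``):

* age-at-length: ``fish_id, age, length_mm``
* mark-recapture: ``fish_id, l_m_mm, l_r_mm, marking_date, recapture_date``
* length-frequency samples: ``date, length_mm`` (one row per fish)
* length-frequency matrix: ``date, bin_mid_mm, count``

``run_compare`` executes all five fits (vBGM frequentist + Bayesian,
Fabens frequentist + Bayesian, ELEFAN) on supplied or simulated data and
writes a comparison table, zero-t0 growth curves on a shared age grid,
and a JSON report with full provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime as _dt
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .ageing import DAYS_PER_YEAR
from .growth import GrowthParams, growth_curve_table
from .result import FitResult
from .simulate import (
    LFQSample,
    simulate_age_length,
    simulate_mark_recapture,
    simulate_length_frequency,
)
from .nls import fit_vbgm_nls, fit_fabens_nls
from .bayes import MCMCSettings, build_priors, sample_posterior, summarize_posterior
from .elefan import GASettings, bin_lengths, bootstrap_elefan, ga_optimize

__all__ = [
    "CompareReport",
    "ValidationError",
    "read_age_length_csv",
    "read_mark_recapture_csv",
    "read_lfq_csv",
    "read_lfq_matrix_csv",
    "write_lfq_matrix_csv",
    "run_compare",
]

log = logging.getLogger("fishgrowth")

EXIT_VALIDATION = 2
EXIT_FIT_FAILURE = 3


class ValidationError(ValueError):
    """Input-file validation failure; carries itemised row errors."""

    def __init__(self, path, problems: list[str]):
        self.path = str(path)
        self.problems = problems
        super().__init__(f"{path}: " + "; ".join(problems))


def _unit_factor(row, problems, lineno) -> float:
    unit = str(row.get("unit", "mm")).strip().lower()
    if unit in ("mm", "", "nan"):
        return 1.0
    if unit == "cm":
        return 10.0
    problems.append(f"line {lineno}: unknown unit {unit!r}")
    return float("nan")


def _require_columns(df, required, path):
    missing = sorted(set(required) - set(df.columns))
    if missing:
        raise ValidationError(path, [f"missing columns {missing}"])


def read_age_length_csv(path) -> pd.DataFrame:
    """Read age-at-length records; returns columns fish_id, age, length (mm)."""
    df = pd.read_csv(path)
    _require_columns(df, ["fish_id", "age", "length_mm"], path)
    problems, rows = [], []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        f = _unit_factor(row, problems, lineno)
        age, length = row["age"], row["length_mm"] * f
        if not np.isfinite(age) or age < 0:
            problems.append(f"line {lineno}: invalid age {row['age']!r}")
            continue
        if not np.isfinite(length) or length <= 0:
            problems.append(f"line {lineno}: invalid length {row['length_mm']!r}")
            continue
        rows.append({"fish_id": str(row["fish_id"]), "age": float(age),
                     "length": float(length)})
    if problems:
        raise ValidationError(path, problems)
    return pd.DataFrame(rows)


def read_mark_recapture_csv(path) -> pd.DataFrame:
    """Read mark-recapture pairs; returns fish_id, l_m, l_r (mm), dt (years).

    Elapsed time is computed from the marking and recapture dates with
    365.25 days per year; a recapture on or before the marking date is a
    validation error.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["fish_id", "l_m_mm", "l_r_mm", "marking_date", "recapture_date"], path)
    problems, rows = [], []
    for i, row in df.iterrows():
        lineno = i + 2
        f = _unit_factor(row, problems, lineno)
        try:
            d0 = _dt.date.fromisoformat(str(row["marking_date"]))
            d1 = _dt.date.fromisoformat(str(row["recapture_date"]))
        except ValueError:
            problems.append(f"line {lineno}: invalid ISO date")
            continue
        if d1 <= d0:
            problems.append(
                f"line {lineno}: recapture date {d1} not after marking date {d0}"
            )
            continue
        l_m, l_r = row["l_m_mm"] * f, row["l_r_mm"] * f
        if not (np.isfinite(l_m) and l_m > 0 and np.isfinite(l_r) and l_r > 0):
            problems.append(f"line {lineno}: invalid length")
            continue
        rows.append({
            "fish_id": str(row["fish_id"]), "l_m": float(l_m), "l_r": float(l_r),
            "dt": (d1 - d0).days / DAYS_PER_YEAR,
        })
    if problems:
        raise ValidationError(path, problems)
    return pd.DataFrame(rows)


def read_lfq_csv(path) -> list[LFQSample]:
    """Read per-fish length-frequency rows (date, length_mm) into samples."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "length_mm"], path)
    problems = []
    lengths_by_date: dict[_dt.date, list[float]] = {}
    for i, row in df.iterrows():
        lineno = i + 2
        f = _unit_factor(row, problems, lineno)
        try:
            d = _dt.date.fromisoformat(str(row["date"]))
        except ValueError:
            problems.append(f"line {lineno}: invalid ISO date {row['date']!r}")
            continue
        length = row["length_mm"] * f
        if not (np.isfinite(length) and length > 0):
            problems.append(f"line {lineno}: invalid length {row['length_mm']!r}")
            continue
        lengths_by_date.setdefault(d, []).append(float(length))
    if problems:
        raise ValidationError(path, problems)
    return [
        LFQSample(date=d, lengths=np.array(ls))
        for d, ls in sorted(lengths_by_date.items())
    ]


def read_lfq_matrix_csv(path):
    """Read a binned length-frequency matrix CSV (date, bin_mid_mm, count)."""
    from .elefan import LFQMatrix

    df = pd.read_csv(path)
    _require_columns(df, ["date", "bin_mid_mm", "count"], path)
    dates = sorted({_dt.date.fromisoformat(str(d)) for d in df["date"]})
    mids = np.sort(df["bin_mid_mm"].unique().astype(float))
    width = float(np.min(np.diff(mids))) if mids.size > 1 else 10.0
    full = np.arange(mids[0], mids[-1] + width / 2, width)
    counts = np.zeros((len(dates), full.size), dtype=int)
    didx = {d: i for i, d in enumerate(dates)}
    bidx = {round(m, 6): i for i, m in enumerate(full)}
    for _, row in df.iterrows():
        d = _dt.date.fromisoformat(str(row["date"]))
        counts[didx[d], bidx[round(float(row["bin_mid_mm"]), 6)]] += int(row["count"])
    return LFQMatrix(dates=tuple(dates), bin_mids=full, counts=counts, bin_width=width)


def write_lfq_matrix_csv(lfq, path) -> None:
    rows = [
        {"date": d.isoformat(), "bin_mid_mm": float(m), "count": int(c)}
        for i, d in enumerate(lfq.dates)
        for m, c in zip(lfq.bin_mids, lfq.counts[i])
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class CompareReport:
    """All five fits plus zero-t0 curves and a provenance block."""

    fits: dict[str, FitResult]
    curves: pd.DataFrame
    provenance: dict
    failures: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for key, fr in self.fits.items():
            li_lo, li_hi = fr.intervals.get("l_inf", (np.nan, np.nan))
            k_lo, k_hi = fr.intervals.get("k", (np.nan, np.nan))
            rows.append({
                "method": fr.method, "type": fr.mode,
                "l_inf": fr.estimates["l_inf"], "l_inf_lo": li_lo, "l_inf_hi": li_hi,
                "k": fr.estimates["k"], "k_lo": k_lo, "k_hi": k_hi,
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "fits": {k: v.to_dict() for k, v in self.fits.items()},
            "failures": dict(self.failures),
            "provenance": self.provenance,
        }


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_compare(config: dict, output_dir=None) -> CompareReport:
    """Run the five-way growth-model comparison.

    ``config`` keys (all optional except one data source per pathway):

    * ``seed`` — master seed; every stochastic stage derives its own
      sub-seed from it.
    * ``data`` — ``{"age_length": path, "mark_recapture": path,
      "length_frequency": path}``.
    * ``simulate`` — ``{"age_length": {params...}, ...}`` used for any
      pathway without a file; parameter dicts accept ``l_inf``, ``k``,
      ``t0``, ``sigma`` and generator keyword arguments.
    * ``mcmc`` — MCMCSettings overrides; ``elefan`` — GASettings
      overrides plus ``ma_window``, ``bin_width``, ``bootstrap_B``.

    Individual fit failures are recorded in the report and the run
    continues.  Outputs (table CSV, curves CSV, report JSON) are written
    when ``output_dir`` is given.
    """
    t_start = time.time()
    seed = int(config.get("seed", 0))
    ss = np.random.SeedSequence(seed)
    sub = dict(zip(
        ("sim_al", "sim_mr", "sim_lfq", "vbgm_bayes", "fabens_bayes", "elefan"),
        (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(6)),
    ))
    data_cfg = config.get("data", {})
    sim_cfg = config.get("simulate", {})

    def _params(d, defaults):
        merged = {**defaults, **{k: v for k, v in d.items()
                                 if k in ("l_inf", "k", "t0", "sigma")}}
        return GrowthParams(**merged)

    # --- assemble the three datasets ------------------------------------
    if "age_length" in data_cfg:
        records = read_age_length_csv(data_cfg["age_length"])
    else:
        d = sim_cfg.get("age_length", {})
        records = simulate_age_length(
            _params(d, {"l_inf": 524.46, "k": 0.21, "t0": 0.0, "sigma": 35.0}),
            n=int(d.get("n", 122)), seed=sub["sim_al"],
        )
    if "mark_recapture" in data_cfg:
        pairs = read_mark_recapture_csv(data_cfg["mark_recapture"])
    else:
        d = sim_cfg.get("mark_recapture", {})
        pairs = simulate_mark_recapture(
            _params(d, {"l_inf": 536.82, "k": 0.38, "t0": 0.0, "sigma": 15.0}),
            n=int(d.get("n", 121)), seed=sub["sim_mr"],
        )
    if "length_frequency" in data_cfg:
        samples = read_lfq_csv(data_cfg["length_frequency"])
    else:
        d = sim_cfg.get("length_frequency", {})
        samples = simulate_length_frequency(
            _params(d, {"l_inf": 436.50, "k": 0.12, "t0": 0.0, "sigma": 0.0}),
            selectivity=bool(d.get("selectivity", True)), seed=sub["sim_lfq"],
        )

    mcmc_cfg = config.get("mcmc", {})
    elefan_cfg = config.get("elefan", {})
    priors = build_priors()
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}

    def _stage(name, fn):
        t0 = time.time()
        try:
            fits[name] = fn()
            log.info("%s finished in %.1f s", name, time.time() - t0)
        except Exception as exc:  # recorded, run continues
            failures[name] = f"{type(exc).__name__}: {exc}"
            log.warning("%s FAILED: %s", name, failures[name])

    _stage("vbgm_freq", lambda: fit_vbgm_nls(records))
    _stage("vbgm_bayes", lambda: summarize_posterior(sample_posterior(
        "vBGM", records, priors,
        MCMCSettings(seed=sub["vbgm_bayes"], **mcmc_cfg))))
    _stage("fabens_freq", lambda: fit_fabens_nls(pairs))
    _stage("fabens_bayes", lambda: summarize_posterior(sample_posterior(
        "Fabens", pairs, priors,
        MCMCSettings(seed=sub["fabens_bayes"], **mcmc_cfg))))

    def _elefan():
        lfq = bin_lengths(samples, bin_width=float(elefan_cfg.get("bin_width", 10.0)))
        ga = GASettings(
            population=int(elefan_cfg.get("population", 50)),
            generations=int(elefan_cfg.get("generations", 100)),
            seed=sub["elefan"],
        )
        B = int(elefan_cfg.get("bootstrap_B", 0))
        ma = int(elefan_cfg.get("ma_window", 5))
        if B >= 2:
            return bootstrap_elefan(lfq, B=B, settings=ga, seed=sub["elefan"], ma_window=ma)
        return ga_optimize(lfq, ga, ma_window=ma)

    _stage("elefan", _elefan)

    # --- zero-t0 curves on a shared grid --------------------------------
    grid = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 3)
    curve_rows = []
    for key, fr in fits.items():
        try:
            curve = growth_curve_table(fr.params, grid, zero_t0=True, label=key)
        except Exception:
            continue
        curve_rows.append(pd.DataFrame(
            {"age": curve.ages, "length": curve.lengths, "method": key}))
    curves = pd.concat(curve_rows, ignore_index=True) if curve_rows else pd.DataFrame(
        columns=["age", "length", "method"])

    provenance = {
        "seed": seed,
        "sub_seeds": sub,
        "config_hash": _config_hash(config),
        "config": {k: v for k, v in config.items()},
        "inputs": {k: str(v) for k, v in data_cfg.items()},
        "n": {"age_length": len(records), "mark_recapture": len(pairs),
              "length_frequency_events": len(samples)},
        "runtime_s": round(time.time() - t_start, 2),
    }
    report = CompareReport(fits=fits, curves=curves, provenance=provenance,
                           failures=failures)

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.table().to_csv(out / "comparison_table.csv", index=False)
        curves.to_csv(out / "growth_curves.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True, default=str) + "\n")
        if config.get("plot", False):
            _plot_curves(curves, out / "growth_curves.png")
    return report


def _plot_curves(curves: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for key, grp in curves.groupby("method"):
        ax.plot(grp["age"], grp["length"], label=key)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("total length (mm)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
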