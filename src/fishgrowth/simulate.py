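"""Synthetic datasets with the statistical structure the growth analysis assumes.

Three generators emulate the structure of a multi-year river monitoring
programme on European grayling:

* ``simulate_age_length`` — scale-aged fish: integer ages with a
  truncated-geometric cohort weighting plus the within-year fraction for
  an autumn capture, lengths on the von Bertalanffy curve plus normal
  noise.
* ``simulate_mark_recapture`` — PIT-tagged fish measured at marking and
  again up to about a year later; recapture lengths follow the Fabens
  increment expectation plus normal noise.
* ``simulate_length_frequency`` — a seasonal electrofishing survey: for
  each sampling event every living cohort contributes normally
  distributed lengths around its cohort mean, with exponential survival
  thinning and optional logistic size-selective capture so that large
  fish are rare.

All generators are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthParams, vbgm_length, fabens_expected_recapture
from .ageing import DAYS_PER_YEAR, HATCH_MONTH_DAY

__all__ = [
    "LFQSample",
    "simulate_age_length",
    "simulate_mark_recapture",
    "simulate_length_frequency",
    "default_survey",
    "write_fixtures",
]

# Study-condition defaults: sample sizes and ranges of the River-Inn-like
# datasets the generators stand in for.
N_AGE_LENGTH = 122
N_MARK_RECAPTURE = 121
LM_RANGE = (119.0, 503.0)
DT_RANGE = (0.09, 1.01)
AGE_LENGTH_SIGMA = 35.0
RECAPTURE_SIGMA = 15.0
AGE_DECAY = 0.65          # geometric decay of cohort abundance over ages 0..7
LFQ_COHORT_SD = 15.0      # within-cohort length SD, mm
LFQ_SURVIVAL = 0.6        # annual survival of a cohort
LFQ_RECRUITS = 600        # recruits entering each cohort at age 0
LFQ_CATCHABILITY = 0.12   # per-event capture probability before selectivity
LFQ_SELECT_L50 = 80.0     # logistic selectivity: length at 50% capture, mm
LFQ_SELECT_SLOPE = 15.0   # logistic selectivity slope, mm
LFQ_MAX_AGE = 20


@dataclass(frozen=True)
class LFQSample:
    """Individual lengths measured at one sampling event (pre-binning)."""

    date: _dt.date
    lengths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
        if np.any(self.lengths <= 0):
            raise ValueError("all lengths must be positive")


def _truncated_normal_positive(rng, mean, sd):
    """Normal(mean, sd) draws redrawn until positive (vectorised)."""
    mean = np.asarray(mean, dtype=float)
    out = rng.normal(mean, sd)
    bad = out <= 0
    for _ in range(1000):
        if not np.any(bad):
            break
        out[bad] = rng.normal(mean[bad] if mean.ndim else mean, sd)
        bad = out <= 0
    return np.abs(out) if np.any(out <= 0) else out


def simulate_age_length(
    params: GrowthParams,
    n: int = N_AGE_LENGTH,
    age_range: tuple[int, int] = (0, 7),
    seed=None,
    age_decay: float = AGE_DECAY,
    capture_month_day: tuple[int, int] = (9, 15),
) -> pd.DataFrame:
    """Simulate scale-derived age-at-length records.

    Integer ages are drawn from a truncated geometric distribution over
    ``age_range`` (weight ``age_decay**a``, so young fish dominate), then
    shifted by the within-year fraction between the April 1 hatch date
    and an autumn capture date.  Lengths are the vBGM expectation plus
    Normal(0, params.sigma) noise, redrawn to stay positive.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = int(age_range[0]), int(age_range[1])
    classes = np.arange(lo, hi + 1)
    weights = age_decay ** (classes - lo)
    weights = weights / weights.sum()
    ages_int = rng.choice(classes, size=n, p=weights)

    cm, cd = capture_month_day
    hm, hd = HATCH_MONTH_DAY
    year = 2022
    frac = (_dt.date(year, cm, cd) - _dt.date(year, hm, hd)).days / DAYS_PER_YEAR
    ages = ages_int + frac

    mu = vbgm_length(params, ages)
    if params.sigma > 0:
        lengths = _truncated_normal_positive(rng, mu, params.sigma)
    else:
        lengths = np.asarray(mu, dtype=float)
    return pd.DataFrame(
        {
            "fish_id": [f"AL{i:04d}" for i in range(n)],
            "age": ages,
            "length": lengths,
        }
    )


def simulate_mark_recapture(
    params: GrowthParams,
    n: int = N_MARK_RECAPTURE,
    lm_range: tuple[float, float] = LM_RANGE,
    dt_range: tuple[float, float] = DT_RANGE,
    seed=None,
) -> pd.DataFrame:
    """Simulate mark-recapture pairs under the Fabens increment model.

    Marking lengths are uniform on ``lm_range`` truncated below
    ``l_inf``; elapsed times uniform on ``dt_range``; recapture lengths
    are the Fabens expectation plus Normal(0, params.sigma) noise.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = lm_range
    if lo >= params.l_inf:
        raise ValueError("lm_range lies entirely above l_inf; no growth possible")
    hi = min(hi, params.l_inf)
    rng = np.random.default_rng(seed)
    l_m = rng.uniform(lo, hi, size=n)
    dt = rng.uniform(dt_range[0], dt_range[1], size=n)
    mu = fabens_expected_recapture(l_m, params, dt)
    l_r = mu + rng.normal(0.0, params.sigma, size=n) if params.sigma > 0 else mu
    mark_date = _dt.date(2022, 9, 15)
    rec_dates = [mark_date + _dt.timedelta(days=round(d * DAYS_PER_YEAR)) for d in dt]
    return pd.DataFrame(
        {
            "fish_id": [f"MR{i:04d}" for i in range(n)],
            "l_m": l_m,
            "l_r": l_r,
            "dt": dt,
            "marking_date": [mark_date.isoformat()] * n,
            "recapture_date": [d.isoformat() for d in rec_dates],
        }
    )


def default_survey() -> list[_dt.date]:
    """The 25-event seasonal survey layout: autumn 2013 through spring 2022.

    Spring/summer/autumn sampling most years, winter events in 2019 and
    2021, and only a summer event in 2020.
    """
    spring, summer, autumn, winter = (5, 15), (7, 15), (10, 1), (1, 15)
    events: list[_dt.date] = [_dt.date(2013, *autumn)]
    for year in range(2014, 2019):
        events += [_dt.date(year, *spring), _dt.date(year, *summer), _dt.date(year, *autumn)]
    events += [
        _dt.date(2019, *winter),
        _dt.date(2019, *spring),
        _dt.date(2019, *summer),
        _dt.date(2019, *autumn),
        _dt.date(2020, *summer),
        _dt.date(2021, *winter),
        _dt.date(2021, *spring),
        _dt.date(2021, *summer),
        _dt.date(2022, *spring),
    ]
    return events


def _selectivity(lengths, l50, slope):
    return 1.0 / (1.0 + np.exp(-(lengths - l50) / slope))


def simulate_length_frequency(
    params: GrowthParams,
    survey: list[_dt.date] | None = None,
    cohort_sd: float = LFQ_COHORT_SD,
    recruits_per_year: int = LFQ_RECRUITS,
    max_age: int = LFQ_MAX_AGE,
    survival: float = LFQ_SURVIVAL,
    catchability: float = LFQ_CATCHABILITY,
    selectivity: bool = True,
    select_l50: float = LFQ_SELECT_L50,
    select_slope: float = LFQ_SELECT_SLOPE,
    seed=None,
) -> list[LFQSample]:
    """Simulate a seasonal length-frequency survey.

    For each sampling event, each living cohort (hatched April 1 of its
    birth year) has age = event date minus hatch date in decimal years,
    mean length on the vBGM curve, abundance
    ``recruits_per_year * survival**age_class``, and contributes a
    Poisson number of captured fish with individual lengths
    Normal(cohort mean, cohort_sd) truncated positive.  With
    ``selectivity`` on, capture probability is additionally scaled by a
    logistic curve of length, making small fish under-represented and
    leaving large fish rare, as in real electrofishing catches.
    """
    if cohort_sd <= 0:
        raise ValueError("cohort_sd must be positive")
    if survey is None:
        survey = default_survey()
    if len(survey) == 0:
        raise ValueError("survey must be non-empty")
    if len(set(survey)) != len(survey):
        raise ValueError("survey dates must be unique")
    rng = np.random.default_rng(seed)
    hm, hd = HATCH_MONTH_DAY
    samples = []
    for event in sorted(survey):
        lengths_out = []
        for birth_year in range(event.year - max_age, event.year + 1):
            hatch = _dt.date(birth_year, hm, hd)
            if hatch > event:
                continue
            age = (event - hatch).days / DAYS_PER_YEAR
            mean_len = vbgm_length(params, age)
            if mean_len <= 0:
                continue
            abundance = recruits_per_year * survival ** int(age)
            p_capture = catchability
            if selectivity:
                p_capture *= _selectivity(mean_len, select_l50, select_slope)
            n_caught = rng.poisson(abundance * p_capture)
            if n_caught == 0:
                continue
            lens = _truncated_normal_positive(
                rng, np.full(n_caught, mean_len), cohort_sd
            )
            lengths_out.append(lens)
        if lengths_out:
            all_len = np.concatenate(lengths_out)
            # monitoring resolution: measured to the closest centimetre
            all_len = np.maximum(np.round(all_len / 10.0) * 10.0, 10.0)
            samples.append(LFQSample(date=event, lengths=all_len))
    return samples


def write_fixtures(
    output_dir,
    scenario: str = "all",
    seed=None,
    vbgm_params: GrowthParams | None = None,
    fabens_params: GrowthParams | None = None,
    elefan_params: GrowthParams | None = None,
    selectivity: bool = True,
) -> list[Path]:
    """Write CSV fixtures (plus a JSON manifest) for one or all dataset types.

    ``scenario`` is one of ``age_length``, ``mark_recapture``,
    ``length_frequency`` or ``all``.  Default generating parameters are
    plausible River-Inn-like values per pathway.  Deterministic under
    ``seed``; sub-seeds are derived per dataset so scenarios are
    independent of each other.
    """
    valid = {"age_length", "mark_recapture", "length_frequency", "all"}
    if scenario not in valid:
        raise ValueError(f"scenario must be one of {sorted(valid)}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sub = {name: s for name, s in zip(
        ("age_length", "mark_recapture", "length_frequency"), ss.spawn(3)
    )}
    vbgm_params = vbgm_params or GrowthParams(524.46, 0.21, t0=0.0, sigma=AGE_LENGTH_SIGMA)
    fabens_params = fabens_params or GrowthParams(536.82, 0.38, sigma=RECAPTURE_SIGMA)
    elefan_params = elefan_params or GrowthParams(436.50, 0.12)

    written: list[Path] = []
    manifest: dict = {"seed": seed, "scenario": scenario, "datasets": {}}

    if scenario in ("age_length", "all"):
        df = simulate_age_length(vbgm_params, seed=sub["age_length"])
        path = out / "age_length.csv"
        df.rename(columns={"length": "length_mm"}).to_csv(path, index=False)
        written.append(path)
        manifest["datasets"]["age_length"] = {
            "file": path.name, "n": len(df),
            "params": {"l_inf": vbgm_params.l_inf, "k": vbgm_params.k,
                       "t0": vbgm_params.t0, "sigma": vbgm_params.sigma},
        }
    if scenario in ("mark_recapture", "all"):
        df = simulate_mark_recapture(fabens_params, seed=sub["mark_recapture"])
        path = out / "mark_recapture.csv"
        df.rename(columns={"l_m": "l_m_mm", "l_r": "l_r_mm"}).drop(columns="dt").to_csv(
            path, index=False
        )
        written.append(path)
        manifest["datasets"]["mark_recapture"] = {
            "file": path.name, "n": len(df),
            "params": {"l_inf": fabens_params.l_inf, "k": fabens_params.k,
                       "sigma": fabens_params.sigma},
        }
    if scenario in ("length_frequency", "all"):
        samples = simulate_length_frequency(
            elefan_params, selectivity=selectivity, seed=sub["length_frequency"]
        )
        rows = [
            {"date": s.date.isoformat(), "length_mm": float(l)}
            for s in samples
            for l in s.lengths
        ]
        path = out / "length_frequency.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
        manifest["datasets"]["length_frequency"] = {
            "file": path.name,
            "n_events": len(samples),
            "n_fish": int(sum(len(s.lengths) for s in samples)),
            "params": {"l_inf": elefan_params.l_inf, "k": elefan_params.k},
            "selectivity": selectivity,
        }

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written
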