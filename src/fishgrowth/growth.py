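"""Deterministic von Bertalanffy growth mathematics.

All fitting pathways (age-at-length, mark-recapture increments,
length-frequency cohort tracking) share the same underlying curve

    L(t) = L_inf * (1 - exp(-K * (t - t0)))

with lengths in millimetres and ages in decimal years.  ``L_inf`` is the
mean asymptotic length, ``K`` (1/yr) the Brody growth coefficient, and
``t0`` the nominal age at zero length — a curve-shifting parameter, not a
biological hatching age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

__all__ = [
    "GrowthParams",
    "GrowthCurve",
    "vbgm_length",
    "vbgm_inverse_age",
    "fabens_expected_recapture",
    "growth_curve_table",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameter vector of the von Bertalanffy family.

    Parameters
    ----------
    l_inf : float
        Mean asymptotic length, mm.  Must be positive.
    k : float
        Brody growth coefficient, 1/yr.  Must be positive.
    t0 : float
        Age at length zero, years.  Fixed at zero for the Fabens
        increment model and for cross-method comparison curves.
    sigma : float
        Standard deviation of the additive normal observation error, mm.
    """

    l_inf: float
    k: float
    t0: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.l_inf) and self.l_inf > 0):
            raise ValueError(f"l_inf must be positive and finite, got {self.l_inf}")
        if not (math.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be positive and finite, got {self.k}")
        if not math.isfinite(self.t0):
            raise ValueError(f"t0 must be finite, got {self.t0}")
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    def with_zero_t0(self) -> "GrowthParams":
        return replace(self, t0=0.0)


@dataclass(frozen=True)
class GrowthCurve:
    """A growth trajectory evaluated on an age grid, tagged by method."""

    ages: np.ndarray
    lengths: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
        if self.ages.shape != self.lengths.shape:
            raise ValueError("ages and lengths must have the same shape")


def vbgm_length(params: GrowthParams, age):
    """Expected length at ``age`` under the von Bertalanffy curve.

    Accepts scalar or array ages.  For ``age < t0`` the predicted length
    is negative; it is returned as-is (callers decide whether to
    truncate), which is the standard convention for this model.
    """
    age = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(age)):
        raise ValueError("age must be finite")
    out = params.l_inf * (1.0 - np.exp(-params.k * (age - params.t0)))
    return float(out) if out.ndim == 0 else out


def vbgm_inverse_age(params: GrowthParams, length):
    """Age at which the curve reaches ``length`` (inverse of vbgm_length).

    Defined for ``0 <= length < l_inf``; the asymptote is never reached,
    so lengths at or above ``l_inf`` raise.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length < 0) or np.any(length >= params.l_inf):
        raise ValueError("length must satisfy 0 <= length < l_inf")
    out = params.t0 - np.log(1.0 - length / params.l_inf) / params.k
    return float(out) if out.ndim == 0 else out


def fabens_expected_recapture(l_m, params: GrowthParams, dt):
    """Expected recapture length after ``dt`` years for a fish marked at ``l_m``.

    The Fabens reparameterisation of the von Bertalanffy model:

        L_r = L_m + (L_inf - L_m) * (1 - exp(-K * dt))

    The expected increment is positive for ``l_m < l_inf`` and declines
    linearly with marking length; no ``t0`` is involved.
    """
    l_m = np.asarray(l_m, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be non-negative")
    out = l_m + (params.l_inf - l_m) * (1.0 - np.exp(-params.k * dt))
    return float(out) if out.ndim == 0 else out


def growth_curve_table(
    params: GrowthParams, age_grid, zero_t0: bool = False, label: str = ""
) -> GrowthCurve:
    """Evaluate the growth curve on an age grid for cross-method overlays.

    With ``zero_t0`` the curve is drawn with ``t0`` forced to zero, the
    convention used when overlaying curves from methods that do and do
    not estimate ``t0``.
    """
    grid = np.asarray(age_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("age_grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("age_grid must be sorted ascending")
    p = params.with_zero_t0() if zero_t0 else params
    return GrowthCurve(ages=grid, lengths=vbgm_length(p, grid), label=label)
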