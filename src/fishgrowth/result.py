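"""Shared fit-result container used by all three estimation pathways."""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math
from typing import Any

from .growth import GrowthParams

__all__ = ["FitResult"]

_METHODS = {"vBGM", "Fabens", "ELEFAN"}
_MODES = {"frequentist", "Bayesian"}


@dataclass
class FitResult:
    """Point estimates with 95% uncertainty intervals and method tags.

    ``estimates`` maps parameter names (``l_inf``, ``k``, ``t0``,
    ``sigma``, ``t_anchor``) to point values; ``intervals`` maps a subset
    of those names to ``(lower, upper)`` bounds.  ``fit_stats`` carries
    method-specific diagnostics (residual SD, n, convergence flag,
    acceptance rate, R-hat, GA score ...).
    """

    method: str
    mode: str
    estimates: dict[str, float]
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    fit_stats: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        for name, (lo, hi) in self.intervals.items():
            pt = self.estimates.get(name)
            if pt is not None and math.isfinite(lo) and math.isfinite(hi):
                if not (lo <= pt <= hi):
                    raise ValueError(
                        f"interval for {name!r} does not bracket the point "
                        f"estimate: {lo} <= {pt} <= {hi} fails"
                    )

    @property
    def converged(self) -> bool:
        return bool(self.fit_stats.get("converged", True))

    @property
    def params(self) -> GrowthParams:
        """The estimates as a GrowthParams vector (t0 defaults to 0)."""
        return GrowthParams(
            l_inf=self.estimates["l_inf"],
            k=self.estimates["k"],
            t0=self.estimates.get("t0", 0.0),
            sigma=max(self.estimates.get("sigma", self.fit_stats.get("sigma", 0.0)), 0.0),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "mode": self.mode,
            "estimates": dict(self.estimates),
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            "fit_stats": {
                k: (v if isinstance(v, (int, float, str, bool, type(None), list, dict)) else str(v))
                for k, v in self.fit_stats.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FitResult":
        return cls(
            method=d["method"],
            mode=d["mode"],
            estimates=dict(d["estimates"]),
            intervals={k: tuple(v) for k, v in d.get("intervals", {}).items()},
            fit_stats=dict(d.get("fit_stats", {})),
        )
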