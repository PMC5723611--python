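"""Rarefaction and extrapolation of species richness over area.

Given a fitted area-based logseries, expected richness at any target
area ``A*`` inside the region is

    S(A*) = S_a * alpha_a / alpha_A*,

interpolating for ``A* <= a`` and extrapolating for ``a <= A* <= A``.
The variance combines two sources by the delta method and a variance
decomposition conditional on ``S_a``:

* uncertainty in omega, through the derivative
  ``d S(A*)/d omega = S(A*) * [g(a) - g(A*)]`` with
  ``g(area) = alpha(area) * area / (omega**2 + omega*area)``;
* binomial sampling of the observed species,
  ``Var(S_a) = S_a * (1 - S_a / S_A)`` with the regional richness
  estimate ``S_A`` from the fit.

Confidence intervals are symmetric normal, ``point +/- z * SE``, floored
at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import alpha_of_area
from .fit import LogseriesFit

__all__ = [
    "RichnessEstimate",
    "estimate_at_area",
    "variance_at_area",
    "curve",
    "curve_table",
]


@dataclass(frozen=True)
class RichnessEstimate:
    """A richness point estimate with its SE and 95% CI."""

    method: str
    target: float  # target area (or individual count for rarefaction methods)
    point: float
    se: float
    ci_low: float
    ci_high: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"inconsistent interval [{self.ci_low}, {self.ci_high}] "
                f"around {self.point}"
            )

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "target": self.target,
            "point": self.point,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }
        d.update(self.extras)
        return d


def _g(area: float, omega: float) -> float:
    # d/d omega of ln alpha(area): alpha(area) * area / (omega^2 + omega*area)
    return alpha_of_area(area, omega) * area / (omega**2 + omega * area)


def variance_at_area(fit: LogseriesFit, target_area: float) -> float:
    """Delta-method variance of the richness estimate at ``target_area``."""
    if not 0 < target_area <= fit.design.A:
        raise ValueError(
            f"target area {target_area} outside (0, A = {fit.design.A}]: "
            "extrapolation beyond the fitted region is not defined"
        )
    if not np.isfinite(fit.var_omega):
        raise ValueError("fit carries no omega variance")
    omega = fit.omega
    point = fit.s_obs * fit.alpha_local / alpha_of_area(target_area, omega)
    slope = _g(fit.design.a, omega) - _g(target_area, omega)
    var_sa = fit.s_obs * (1.0 - fit.s_obs / fit.s_regional)
    return float(
        point**2 * slope**2 * fit.var_omega + (point / fit.s_obs) ** 2 * var_sa
    )


def estimate_at_area(
    fit: LogseriesFit, target_area: float, level: float = 0.95
) -> RichnessEstimate:
    """Expected species richness at ``target_area``, with SE and CI.

    ``target_area`` may sit anywhere in ``(0, A]``; at the sampled area
    the estimate equals the observed richness exactly.
    """
    if not 0 < target_area <= fit.design.A:
        raise ValueError(
            f"target area {target_area} outside (0, A = {fit.design.A}]: "
            "extrapolation beyond the fitted region is not defined"
        )
    point = fit.s_obs * fit.alpha_local / alpha_of_area(target_area, fit.omega)
    se = float(np.sqrt(variance_at_area(fit, target_area)))
    z = norm.ppf(0.5 + level / 2)
    return RichnessEstimate(
        method="area_logseries",
        target=float(target_area),
        point=float(point),
        se=se,
        ci_low=max(point - z * se, 0.0),
        ci_high=point + z * se,
        extras={
            "omega_hat": fit.omega,
            "s_regional_hat": fit.s_regional,
            "a": fit.design.a,
            "A": fit.design.A,
        },
    )


def curve(fit: LogseriesFit, areas, level: float = 0.95) -> list[RichnessEstimate]:
    """Rarefaction/extrapolation curve over a grid of target areas."""
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("empty area grid")
    return [estimate_at_area(fit, float(t), level=level) for t in areas]


def curve_table(estimates: list[RichnessEstimate]) -> pd.DataFrame:
    """Tabulate a curve as (area, estimate, se, ci_low, ci_high)."""
    return pd.DataFrame(
        {
            "area": [e.target for e in estimates],
            "estimate": [e.point for e in estimates],
            "se": [e.se for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
        }
    )
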