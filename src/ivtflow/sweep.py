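"""Single-factor turning-radius sweep and the plateau criterion.

The surgical recommendation rests on a sweep of the turning radius: the
pressure difference falls steeply at small radii and flattens out, and the
recommended radius is where the curve has plateaued — every further 1 mm
step changes the pressure difference by less than a 5% threshold.

The per-step change rate is the backward relative difference

    rate[i] = 100 * |dP[i+1] - dP[i]| / dP[i]     (percent)

and the plateau radius is the smallest swept value from which *all*
subsequent steps stay below the threshold (requiring all steps, not just
the first, avoids false plateaus on noisy curves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .geometry import InfeasibleGeometryError, TunnelParams


@dataclass(frozen=True)
class SweepConfig:
    """Sweep of one factor on a regular grid."""

    factor: str = "r_tt"
    start: float = 0.0  # mm
    step: float = 1.0  # mm
    count: int = 12
    threshold: float = 5.0  # percent

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.count < 2:
            raise ValueError(f"count must be >= 2, got {self.count}")
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.count)


def change_rates(responses: np.ndarray) -> np.ndarray:
    """Backward per-step relative change, percent (length n-1)."""
    y = np.asarray(responses, dtype=float)
    prev = y[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = 100.0 * np.abs(np.diff(y)) / np.abs(prev)
    rates = np.where(np.abs(np.diff(y)) == 0, 0.0, rates)
    return np.where(np.isfinite(rates), rates, np.inf)


@dataclass(frozen=True)
class SweepCurve:
    """Response curve of one swept factor with its plateau diagnosis."""

    values: np.ndarray  # factor levels, mm
    responses: np.ndarray  # delta-P, mmHg
    change_rates: np.ndarray = field(default=None)  # percent, length n-1
    plateau_value: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "responses", np.asarray(self.responses, dtype=float)
        )
        if len(self.values) != len(self.responses):
            raise ValueError("values and responses must have equal length")
        if self.change_rates is None:
            object.__setattr__(self, "change_rates", change_rates(self.responses))

    def with_plateau(self, threshold: float) -> "SweepCurve":
        return replace(self, plateau_value=plateau_radius(self, threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_tt_mm": self.values,
                "delta_p_mmhg": self.responses,
                "change_rate_pct": np.concatenate([[np.nan], self.change_rates]),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def plateau_radius(curve: SweepCurve, threshold: float) -> float | None:
    """Smallest swept value from which every subsequent per-step change
    rate stays below ``threshold`` percent; None if never satisfied.

    The step *into* a candidate value counts: the plateau starts at the
    first point reached by a sub-threshold step with no super-threshold
    step after it.
    """
    rates = curve.change_rates
    below = rates < threshold
    # candidate j (index >= 1) qualifies iff all rates[j-1:] are below.
    ok_from = len(rates)
    for k in range(len(rates) - 1, -1, -1):
        if below[k]:
            ok_from = k
        else:
            break
    j = ok_from + 1
    if j < len(curve.values):
        return float(curve.values[j])
    return None


def single_factor_sweep(
    base: TunnelParams,
    config: SweepConfig,
    model: Callable[[TunnelParams], float],
) -> SweepCurve:
    """Sweep one tunnel factor, holding the others at the base values.

    Infeasible configurations (the tunnel overshoots the valve plane at
    large radii) are dropped with a warning; at least 2 feasible points
    are required.
    """
    field_name = {"r_tt": "r_tt", "d_sa": "d_sa", "a_lt": "a_lt"}.get(
        config.factor
    )
    if field_name is None:
        raise ValueError(f"unknown sweep factor {config.factor!r}")
    values, responses = [], []
    for v in config.values:
        params = replace(base, **{field_name: float(v)})
        try:
            responses.append(float(model(params)))
            values.append(float(v))
        except InfeasibleGeometryError as err:
            warnings.warn(
                f"{config.factor}={v:g} infeasible, dropped: {err}",
                stacklevel=2,
            )
    if len(values) < 2:
        raise ValueError(
            f"sweep produced {len(values)} feasible point(s); need >= 2"
        )
    curve = SweepCurve(values=np.array(values), responses=np.array(responses))
    return curve.with_plateau(config.threshold)
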