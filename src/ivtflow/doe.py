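"""Balanced orthogonal design (L25: 3 factors, 5 levels) and experiments.

The study design is an L25(5^3) orthogonal array over the three tunnel
factors.  Orthogonality here means two things, both checked by
:func:`verify_balance`:

* every level of every factor occurs exactly 5 times in the 25 runs, and
* for each pair of factors, every ordered pair of levels occurs exactly
  once ("uniform dispersion and uniform comparison").

The published 25-run experiment — factor levels and the CFD pressure
differences in mmHg — ships as a packaged fixture and is returned verbatim
by :func:`reference_design`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from .geometry import InfeasibleGeometryError, TunnelParams

#: Canonical CSV dialect: header row, '.' decimal separator, LF endings.
CSV_COLUMNS = ["model", "d_sa_mm", "a_lt_deg", "r_tt_mm", "delta_p_mmhg"]
FACTOR_COLUMNS = ["d_sa_mm", "a_lt_deg", "r_tt_mm"]

#: Published factor levels: distances mm, angles degrees, radii mm.
REFERENCE_LEVELS = {
    "d_sa_mm": (10.0, 15.0, 20.0, 25.0, 30.0),
    "a_lt_deg": (0.0, 10.0, 20.0, 30.0, 40.0),
    "r_tt_mm": (0.0, 2.5, 5.0, 7.5, 10.0),
}


@dataclass(frozen=True)
class Factor:
    """One design factor with its five ordered numeric levels."""

    name: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != 5 or len(set(self.levels)) != 5:
            raise ValueError(
                f"factor {self.name!r} needs exactly 5 distinct levels, "
                f"got {self.levels}"
            )


@dataclass(frozen=True)
class Design:
    """A (nominally balanced) 25-run design, optionally with responses."""

    factors: tuple[Factor, Factor, Factor]
    runs: pd.DataFrame  # columns = factor names; one row per run
    responses: np.ndarray | None = None  # delta-P, mmHg

    def __post_init__(self) -> None:
        missing = [f.name for f in self.factors if f.name not in self.runs]
        if missing:
            raise ValueError(f"runs frame lacks factor columns {missing}")
        if self.responses is not None and len(self.responses) != len(self.runs):
            raise ValueError("responses length must match number of runs")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def with_responses(self, responses) -> "Design":
        return replace(self, responses=np.asarray(responses, dtype=float))

    def level_index(self, factor_name: str) -> np.ndarray:
        """Map each run's level to its index in the factor's ordered levels.

        Levels are matched by exact value, not by position in the file.
        """
        factor = next(f for f in self.factors if f.name == factor_name)
        lookup = {lv: i for i, lv in enumerate(factor.levels)}
        try:
            return np.array(
                [lookup[v] for v in self.runs[factor_name]], dtype=np.intp
            )
        except KeyError as err:
            raise ValueError(
                f"run level {err.args[0]!r} not among declared levels of "
                f"{factor_name}: {factor.levels}"
            ) from None

    def tunnel_params(self, lumen_diameter: float | None = None) -> list[TunnelParams]:
        kw = {} if lumen_diameter is None else {"lumen_diameter": lumen_diameter}
        return [
            TunnelParams(d_sa=r.d_sa_mm, a_lt=r.a_lt_deg, r_tt=r.r_tt_mm, **kw)
            for r in self.runs.itertuples()
        ]

    def to_frame(self) -> pd.DataFrame:
        frame = self.runs.copy()
        frame.insert(0, "model", np.arange(1, len(frame) + 1))
        frame["delta_p_mmhg"] = (
            self.responses if self.responses is not None else np.nan
        )
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "Design":
        frame = pd.read_csv(path)
        missing = [c for c in FACTOR_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"design CSV lacks columns {missing}")
        factors = tuple(
            Factor(name, tuple(sorted(frame[name].unique())))
            for name in FACTOR_COLUMNS
        )
        responses = None
        if "delta_p_mmhg" in frame and frame["delta_p_mmhg"].notna().all():
            responses = frame["delta_p_mmhg"].to_numpy(dtype=float)
        return cls(
            factors=factors,
            runs=frame[FACTOR_COLUMNS].astype(float).reset_index(drop=True),
            responses=responses,
        )


def reference_design() -> Design:
    """The packaged 25-run reference experiment, responses included.

    Returned verbatim from the packaged fixture; a checksum test pins the
    25 pressure-difference values.
    """
    with resources.files("ivtflow.data").joinpath("reference_design.csv").open() as fh:
        return Design.from_csv(fh)


def construct_balanced_design(levels: dict[str, tuple] | list[tuple]) -> Design:
    """Build a 25-run balanced design from 3 lists of 5 levels.

    Uses the Latin-square index rule ``C = (A + 2*B) mod 5`` over the full
    5x5 grid of the first two factors, which satisfies both balance
    invariants for any level labelling.
    """
    if isinstance(levels, dict):
        names = list(levels)
        level_lists = [tuple(levels[n]) for n in names]
    else:
        names = FACTOR_COLUMNS
        level_lists = [tuple(lv) for lv in levels]
    if len(level_lists) != 3 or any(len(lv) != 5 for lv in level_lists):
        raise ValueError("construct_balanced_design needs 3 factors x 5 levels")
    factors = tuple(Factor(n, lv) for n, lv in zip(names, level_lists))
    rows = []
    for a in range(5):
        for b in range(5):
            c = (a + 2 * b) % 5
            rows.append(
                {
                    names[0]: level_lists[0][a],
                    names[1]: level_lists[1][b],
                    names[2]: level_lists[2][c],
                }
            )
    return Design(factors=factors, runs=pd.DataFrame(rows, dtype=float))


@dataclass(frozen=True)
class BalanceReport:
    balanced: bool
    violations: tuple[str, ...]


def verify_balance(design: Design) -> BalanceReport:
    """Brute-force check of the two orthogonal-array invariants."""
    violations: list[str] = []
    n = design.n_runs
    if n != 25:
        violations.append(f"expected 25 runs, found {n}")
    for factor in design.factors:
        counts = design.runs[factor.name].value_counts()
        for level in factor.levels:
            c = int(counts.get(level, 0))
            if c != 5:
                rows = list(
                    design.runs.index[design.runs[factor.name] == level]
                )
                violations.append(
                    f"{factor.name} level {level} occurs {c} times "
                    f"(rows {rows}), expected 5"
                )
    for fa, fb in combinations(design.factors, 2):
        pairs = list(zip(design.runs[fa.name], design.runs[fb.name]))
        for la in fa.levels:
            for lb in fb.levels:
                c = pairs.count((la, lb))
                if c != 1:
                    rows = [i for i, p in enumerate(pairs) if p == (la, lb)]
                    violations.append(
                        f"pair ({fa.name}={la}, {fb.name}={lb}) occurs "
                        f"{c} times (rows {rows}), expected 1"
                    )
    return BalanceReport(balanced=not violations, violations=tuple(violations))


def run_experiment(
    design: Design, model, lumen_diameter: float | None = None
) -> Design:
    """Evaluate a pressure-difference model on every design row.

    ``model`` maps a :class:`TunnelParams` to a pressure difference in mmHg
    (e.g. a closure over :func:`ivtflow.flow_model.pressure_difference`).
    Infeasible rows are collected, reported via warnings and left NaN; the
    run aborts only when every row fails.
    """
    responses = np.full(design.n_runs, np.nan)
    failures: list[tuple[int, str]] = []
    for i, params in enumerate(design.tunnel_params(lumen_diameter)):
        try:
            responses[i] = float(model(params))
        except InfeasibleGeometryError as err:
            failures.append((i, str(err)))
    if len(failures) == design.n_runs:
        detail = "; ".join(f"run {i + 1}: {m}" for i, m in failures[:3])
        raise RuntimeError(f"every design row is infeasible ({detail} ...)")
    for i, msg in failures:
        warnings.warn(f"run {i + 1} infeasible: {msg}", stacklevel=2)
    return design.with_responses(responses)
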