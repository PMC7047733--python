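"""Balanced three-factor main-effects ANOVA and Fisher-LSD comparisons.

For a balanced L25(5^3) design with responses ``y`` the main-effects
decomposition has the closed form

    SS_factor = sum_l T_l^2 / r  -  G^2 / N        (df = L - 1 = 4)
    SS_total  = sum y^2          -  G^2 / N        (df = N - 1 = 24)
    SS_error  = SS_total - sum SS_factor           (df = 12)

where ``T_l`` is the response total at level ``l``, ``r = 5`` the
replicates per level, ``G`` the grand total and ``N = 25``.  Because the
design is balanced, type I and type III sums of squares coincide, so the
closed form is exact.  F statistics use the pooled 12-df error mean square
and upper-tail F(4, 12) p-values.

Post-hoc pairwise comparisons use Fisher's least significant difference:
unadjusted two-sided t tests on level-mean differences with the pooled
error term, ``SE = sqrt(2 * MS_err / r)`` and 12 error df.  No multiplicity
adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .doe import Design, verify_balance


class UnbalancedDesignError(ValueError):
    """Design fails the orthogonal-array balance invariants."""


@dataclass(frozen=True)
class AnovaTable:
    """Main-effects ANOVA decomposition of a balanced design."""

    factors: tuple[str, ...]
    ss: dict[str, float]
    df: dict[str, int]
    ms: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    ss_err: float
    df_err: int
    ms_err: float
    ss_total: float
    df_total: int
    zero_variance: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": name,
                "sum_sq": self.ss[name],
                "df": self.df[name],
                "mean_sq": self.ms[name],
                "F": self.f[name],
                "p_value": self.p[name],
            }
            for name in self.factors
        ]
        rows.append(
            {
                "source": "error",
                "sum_sq": self.ss_err,
                "df": self.df_err,
                "mean_sq": self.ms_err,
                "F": np.nan,
                "p_value": np.nan,
            }
        )
        rows.append(
            {
                "source": "total",
                "sum_sq": self.ss_total,
                "df": self.df_total,
                "mean_sq": np.nan,
                "F": np.nan,
                "p_value": np.nan,
            }
        )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False, float_format="%.4f")


def _check_ready(design: Design) -> np.ndarray:
    report = verify_balance(design)
    if not report.balanced:
        raise UnbalancedDesignError(
            "design is not a balanced orthogonal array; run verify_balance "
            f"for details ({len(report.violations)} violations, first: "
            f"{report.violations[0]})"
        )
    if design.responses is None:
        raise ValueError("design has no responses; run the experiment first")
    y = np.asarray(design.responses, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses contain missing/non-finite values")
    return y


def anova_main_effects(design: Design) -> AnovaTable:
    """Main-effects ANOVA of a balanced design.

    A zero-variance response vector (all SS = 0) is reported with all
    p-values set to 1 and the ``zero_variance`` flag raised, rather than
    as an error.
    """
    y = _check_ready(design)
    n = len(y)
    grand = y.sum()
    ss_total = float(y @ y - grand**2 / n)
    names = tuple(f.name for f in design.factors)
    ss, df, ms, fstat, pval = {}, {}, {}, {}, {}
    for factor in design.factors:
        idx = design.level_index(factor.name)
        n_levels = len(factor.levels)
        reps = n // n_levels
        totals = np.bincount(idx, weights=y, minlength=n_levels)
        ss[factor.name] = float(totals @ totals / reps - grand**2 / n)
        df[factor.name] = n_levels - 1

    df_err = (n - 1) - sum(df.values())
    ss_err = max(ss_total - sum(ss.values()), 0.0)
    ms_err = ss_err / df_err
    zero_variance = ss_total <= 1e-12 * max(1.0, float(y @ y))
    for name in names:
        ms[name] = ss[name] / df[name]
        if zero_variance or ms_err == 0.0:
            fstat[name] = np.inf if ms[name] > 0 else 0.0
            pval[name] = 1.0 if zero_variance else 0.0
        else:
            fstat[name] = ms[name] / ms_err
            # Upper tail of F(df, df_err) via the regularized incomplete beta.
            pval[name] = float(stats.f.sf(fstat[name], df[name], df_err))
    return AnovaTable(
        factors=names,
        ss=ss,
        df=df,
        ms=ms,
        f=fstat,
        p=pval,
        ss_err=ss_err,
        df_err=df_err,
        ms_err=ms_err,
        ss_total=ss_total,
        df_total=n - 1,
        zero_variance=zero_variance,
    )


@dataclass(frozen=True)
class PairwiseTable:
    """Fisher-LSD pairwise comparisons for one factor."""

    factor: str
    table: pd.DataFrame  # level_a, level_b, mean_difference, se, t, p_value
    ms_err: float
    df_err: int

    def p_value(self, level_a: float, level_b: float) -> float:
        mask = (self.table.level_a == min(level_a, level_b)) & (
            self.table.level_b == max(level_a, level_b)
        )
        if not mask.any():
            raise KeyError(f"no pair ({level_a}, {level_b}) for {self.factor}")
        return float(self.table.loc[mask, "p_value"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n")

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format="%.4f")


def lsd_pairwise(design: Design, factor_name: str) -> PairwiseTable:
    """Fisher's LSD over all level pairs of one factor.

    The pooled error mean square comes from the full main-effects model
    (all three factors fitted), so the pairwise standard error is the same
    for every pair: ``sqrt(2 * MS_err / r)`` with ``r`` replicates per
    level.  P-values are two-sided from the t distribution on the pooled
    error df, with no multiplicity adjustment.
    """
    anova = anova_main_effects(design)
    if factor_name not in anova.factors:
        raise KeyError(f"unknown factor {factor_name!r}; have {anova.factors}")
    y = np.asarray(design.responses, dtype=float)
    factor = next(f for f in design.factors if f.name == factor_name)
    idx = design.level_index(factor_name)
    reps = len(y) // len(factor.levels)
    means = np.bincount(idx, weights=y, minlength=len(factor.levels)) / reps
    se = float(np.sqrt(2.0 * anova.ms_err / reps))
    rows = []
    for (ia, la), (ib, lb) in combinations(enumerate(factor.levels), 2):
        diff = float(means[ia] - means[ib])
        if se == 0.0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), anova.df_err))
        if anova.zero_variance:
            t, p = 0.0, 1.0
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "mean_difference": diff,
                "se": se,
                "t": t,
                "p_value": p,
            }
        )
    return PairwiseTable(
        factor=factor_name,
        table=pd.DataFrame(rows),
        ms_err=anova.ms_err,
        df_err=anova.df_err,
    )


@dataclass(frozen=True)
class FactorRanking:
    """Factors ordered by explained sum of squares, with significance flags."""

    table: pd.DataFrame  # factor, sum_sq, p_value, significant
    alpha: float

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format="%.4f")


def significance_report(anova: AnovaTable, alpha: float = 0.05) -> FactorRanking:
    """Rank factors by SS (descending) and flag p < alpha."""
    rows = sorted(
        (
            {
                "factor": name,
                "sum_sq": anova.ss[name],
                "p_value": anova.p[name],
                "significant": bool(anova.p[name] < alpha),
            }
            for name in anova.factors
        ),
        key=lambda r: -r["sum_sq"],
    )
    return FactorRanking(table=pd.DataFrame(rows), alpha=alpha)
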