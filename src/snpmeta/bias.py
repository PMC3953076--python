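"""Publication-bias diagnostics, leave-one-out sensitivity, Bonferroni.

Egger's test regresses the standardized effect y_i/se_i on the precision
1/se_i by ordinary least squares (the original unweighted formulation); a
non-zero intercept signals small-study/funnel asymmetry and is tested with
a t statistic on k - 2 df.

Begg's rank-correlation test computes Kendall's tau between the
variance-stabilized deviates

    u_i = (y_i - mu_fixed) / sqrt(v_i - 1/sum(w))

and the variances v_i, with the continuity-corrected normal approximation
z = (|S| - 1) / sqrt(k (k-1) (2k+5) / 18) on the concordant-discordant
count S.

Leave-one-out re-pools (DerSimonian-Laird) after omitting each study in
turn; the largest absolute shift of the pooled log OR summarizes influence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .effects import EffectEstimate, normal_quantile
from .pooling import PooledResult, pool_dl, pool_fixed

logger = logging.getLogger("snpmeta")

__all__ = [
    "EggerResult",
    "BeggResult",
    "LeaveOneOutReport",
    "egger_test",
    "begg_test",
    "leave_one_out",
    "bonferroni",
    "funnel_data",
]


class InsufficientStudiesError(ValueError):
    pass


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    slope: float
    t: float
    df: int
    p: float
    low_dispersion: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    z: float
    p: float
    continuity_corrected: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class LeaveOneOutReport:
    rows: tuple[tuple[str, PooledResult], ...]
    max_abs_shift: float

    def to_dict(self) -> dict:
        return {
            "rows": [
                {"omitted_study_id": sid, **res.to_dict()} for sid, res in self.rows
            ],
            "max_abs_shift": self.max_abs_shift,
        }


def _require_k(effects: Sequence[EffectEstimate], k_min: int, what: str) -> None:
    if len(effects) < k_min:
        raise InsufficientStudiesError(
            f"{what} requires at least {k_min} studies, got {len(effects)}"
        )


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's linear regression test for funnel-plot asymmetry."""
    _require_k(effects, 3, "Egger's test")
    y = np.array([e.log_or for e in effects])
    se = np.array([e.se for e in effects])
    snd = y / se  # standardized normal deviate
    precision = 1.0 / se
    low_dispersion = bool(np.ptp(precision) < 1e-12)
    if low_dispersion:
        logger.warning("egger_test low_dispersion=true all se equal")
    x = sm.add_constant(precision, has_constant="add")
    fit = sm.OLS(snd, x).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    intercept_se = float(fit.bse[0])
    df = len(effects) - 2
    t = intercept / intercept_se if intercept_se > 0 else 0.0
    p = float(2.0 * stats.t.sf(abs(t), df=df)) if intercept_se > 0 else 1.0
    return EggerResult(
        intercept=intercept,
        intercept_se=intercept_se,
        slope=slope,
        t=float(t),
        df=df,
        p=p,
        low_dispersion=low_dispersion,
    )


def _kendall_s(u: np.ndarray, v: np.ndarray) -> int:
    """Concordant-minus-discordant pair count over all pairs (vectorized)."""
    su = np.sign(u[:, None] - u[None, :])
    sv = np.sign(v[:, None] - v[None, :])
    return int(np.sum(np.triu(su * sv, k=1)))


def begg_test(
    effects: Sequence[EffectEstimate], continuity: bool = True
) -> BeggResult:
    """Begg-Mazumdar rank correlation between effect deviates and variances."""
    _require_k(effects, 3, "Begg's test")
    k = len(effects)
    y = np.array([e.log_or for e in effects])
    v = np.array([e.se for e in effects]) ** 2
    fixed = pool_fixed(effects)
    sum_w = float(np.sum(1.0 / v))
    vstar = v - 1.0 / sum_w
    # vstar > 0 whenever k >= 2; guard against rounding at the boundary
    vstar = np.maximum(vstar, 1e-300)
    u = (y - fixed.pooled_log_or) / np.sqrt(vstar)
    if np.ptp(u) == 0.0 or np.ptp(v) == 0.0:
        logger.warning("begg_test degenerate=true zero variance in a ranking")
        return BeggResult(0.0, 0.0, 1.0, continuity, degenerate=True)
    s = _kendall_s(u, v)
    n_pairs = k * (k - 1) // 2
    tau = s / n_pairs
    var_s = k * (k - 1) * (2 * k + 5) / 18.0
    if continuity:
        z = 0.0 if s == 0 else math.copysign((abs(s) - 1) / math.sqrt(var_s), s)
    else:
        z = s / math.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BeggResult(
        kendall_tau=float(tau), z=float(z), p=p, continuity_corrected=continuity
    )


def leave_one_out(
    effects: Sequence[EffectEstimate], ci_level: float = 0.95
) -> LeaveOneOutReport:
    """Omit each study in turn and re-pool the rest (random effects)."""
    _require_k(effects, 3, "leave-one-out sensitivity analysis")
    full = pool_dl(effects, ci_level=ci_level)
    rows = []
    max_shift = 0.0
    for i, omitted in enumerate(effects):
        rest = [e for j, e in enumerate(effects) if j != i]
        res = pool_dl(rest, ci_level=ci_level)
        rows.append((omitted.study_id, res))
        max_shift = max(max_shift, abs(res.pooled_log_or - full.pooled_log_or))
    return LeaveOneOutReport(rows=tuple(rows), max_abs_shift=float(max_shift))


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni adjustment p_adj = min(1, m * p), order preserved.

    ``m`` defaults to the number of p-values and must be at least that many.
    """
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError(f"m must be a positive integer, got {m}")
    if m < len(ps):
        raise ValueError(f"m={m} is smaller than the {len(ps)} p-values tested")
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-values must lie in [0, 1], got {p}")
    return [min(1.0, m * p) for p in ps]


def funnel_data(
    effects: Sequence[EffectEstimate],
    pooled: PooledResult,
    n_grid: int = 50,
) -> dict[str, pd.DataFrame]:
    """Plot-ready funnel data: per-study points and pseudo-CI guide lines.

    Returns ``points`` (study_id, log_or, se) and ``guides`` (se, lower,
    upper) where the guides trace pooled_log_or +/- z * se over an se grid
    from 0 to the largest observed se; no rendering is done here.
    """
    if len(effects) == 0:
        raise ValueError("empty input")
    points = pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "log_or": [e.log_or for e in effects],
            "se": [e.se for e in effects],
        }
    )
    z = normal_quantile(pooled.ci_level)
    se_grid = np.linspace(0.0, float(points["se"].max()), n_grid)
    guides = pd.DataFrame(
        {
            "se": se_grid,
            "lower": pooled.pooled_log_or - z * se_grid,
            "upper": pooled.pooled_log_or + z * se_grid,
        }
    )
    return {"points": points, "guides": guides}
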