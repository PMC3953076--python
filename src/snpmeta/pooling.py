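"""Inverse-variance pooling: fixed-effect and DerSimonian-Laird random-effects.

The fixed-effect step weights each study's log OR by the reciprocal of its
squared standard error and yields Cochran's Q, which drives both the I^2
heterogeneity index, ``max(0, (Q - df)/Q) * 100``, and the one-step
DerSimonian-Laird moment estimate of the between-study variance,

    tau^2 = max(0, (Q - (k - 1)) / C),   C = sum(w) - sum(w^2)/sum(w).

Random-effects pooling then reweights by 1/(se_i^2 + tau^2).  The overall
significance is a two-sided Z-test on pooled_log_or / pooled_se.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate, normal_quantile

logger = logging.getLogger("snpmeta")

__all__ = ["PoolMethod", "PooledResult", "pool_fixed", "pool_dl", "z_test"]


class PoolMethod(str, enum.Enum):
    FIXED_IV = "FixedIV"
    DL_RANDOM = "DLRandom"


@dataclass(frozen=True)
class PooledResult:
    """Pooled log OR with heterogeneity statistics.

    ``q``/``q_df``/``q_p`` always come from the fixed-effect weights; ``tau2``
    is zero under ``FixedIV``.  The CI is pooled_log_or +/- z_crit * pooled_se
    exponentiated to the OR scale.
    """

    k: int
    pooled_log_or: float
    pooled_se: float
    or_value: float
    ci_low: float
    ci_high: float
    ci_level: float
    z: float
    p: float
    q: float
    q_df: int
    q_p: float
    i2_pct: float
    tau2: float
    method: PoolMethod

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["method"] = self.method.value
        return d


def z_test(pooled_log_or: float, pooled_se: float) -> tuple[float, float]:
    """Two-sided normal test of the pooled log OR; returns (z, p)."""
    if not pooled_se > 0:
        raise ValueError(f"pooled_se must be positive, got {pooled_se}")
    z = pooled_log_or / pooled_se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _i2(q: float, q_df: int) -> float:
    if q <= 0.0 or q_df < 1:
        return 0.0
    return max(0.0, (q - q_df) / q) * 100.0


def _assemble(
    k: int,
    pooled: float,
    se: float,
    q: float,
    q_df: int,
    tau2: float,
    method: PoolMethod,
    ci_level: float,
) -> PooledResult:
    z, p = z_test(pooled, se)
    q_p = 1.0 if q_df < 1 else float(stats.chi2.sf(q, df=q_df))
    zc = normal_quantile(ci_level)
    return PooledResult(
        k=k,
        pooled_log_or=float(pooled),
        pooled_se=float(se),
        or_value=math.exp(pooled),
        ci_low=math.exp(pooled - zc * se),
        ci_high=math.exp(pooled + zc * se),
        ci_level=ci_level,
        z=z,
        p=p,
        q=float(q),
        q_df=q_df,
        q_p=q_p,
        i2_pct=_i2(q, q_df),
        tau2=float(tau2),
        method=method,
    )


def _arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) == 0:
        raise ValueError("empty input: need at least one effect to pool")
    y = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(se)):
        raise ValueError("all effects must have finite log_or and positive se")
    return y, se


def pool_fixed(
    effects: Sequence[EffectEstimate], ci_level: float = 0.95
) -> PooledResult:
    """Fixed-effect inverse-variance pool with Cochran's Q (df = k - 1)."""
    y, se = _arrays(effects)
    w = 1.0 / se**2
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (y - pooled) ** 2))
    k = len(y)
    return _assemble(k, pooled, pooled_se, q, k - 1, 0.0, PoolMethod.FIXED_IV, ci_level)


def pool_dl(
    effects: Sequence[EffectEstimate], ci_level: float = 0.95
) -> PooledResult:
    """DerSimonian-Laird random-effects pool (one-step moment tau^2).

    With a single study there is no between-study information: the fixed
    pool is returned with a logged notice.  Degenerate C = 0 (only possible
    when k = 1 here) likewise falls back to tau^2 = 0.
    """
    fixed = pool_fixed(effects, ci_level=ci_level)
    k = fixed.k
    if k < 2:
        logger.info("pool_dl k=%d fallback=fixed reason=single_study", k)
        return replace(fixed, method=PoolMethod.DL_RANDOM)
    y, se = _arrays(effects)
    w = 1.0 / se**2
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0.0:
        logger.info("pool_dl k=%d tau2=0 reason=degenerate_C", k)
        tau2 = 0.0
    else:
        tau2 = max(0.0, (fixed.q - (k - 1)) / c)
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    pooled_se = float(1.0 / math.sqrt(np.sum(w_star)))
    return _assemble(
        k, pooled, pooled_se, fixed.q, fixed.q_df, tau2, PoolMethod.DL_RANDOM, ci_level
    )
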