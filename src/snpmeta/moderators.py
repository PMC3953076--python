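"""Subgroup (stratified) meta-analysis and method-of-moments meta-regression.

Subgroups are pooled per stratum with DerSimonian-Laird random effects; the
between-subgroup test is Cochran's Q over the stratum summary estimates,

    Q_between = sum_g W_g (mu_g - mu_bar)^2,  W_g = 1 / pooled_se_g^2,

chi-square with (number of strata - 1) df.  A fixed-weight decomposition
(Q_total = sum Q_within + Q_between with fixed-effect weights throughout) is
kept as an internal consistency oracle, not the reported statistic.

Meta-regression follows the classical two-pass moment scheme: a 1/se^2
weighted least-squares fit yields the residual heterogeneity Q_E, from which

    tau^2 = max(0, (Q_E - (k - p)) / (sum w - tr((X'WX)^-1 X'W^2 X)))

and a final fit with weights 1/(se^2 + tau^2) gives Wald z inference per
coefficient.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate
from .pooling import PoolMethod, PooledResult, pool_dl, pool_fixed

logger = logging.getLogger("snpmeta")

__all__ = [
    "SubgroupFactor",
    "SubgroupReport",
    "MetaRegressionResult",
    "subgroup_pool",
    "meta_regression",
    "q_decomposition_fixed",
]


class SubgroupFactor(str, enum.Enum):
    ETHNICITY = "Ethnicity"
    SAMPLE_SIZE = "SampleSize"
    CONTROL_SOURCE = "ControlSource"
    SUBTYPE = "Subtype"


@dataclass(frozen=True)
class SubgroupReport:
    factor: SubgroupFactor
    strata: dict[str, PooledResult]
    q_between: float
    q_between_df: int
    q_between_p: float
    excluded: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "factor": self.factor.value,
            "strata": {k: v.to_dict() for k, v in self.strata.items()},
            "q_between": self.q_between,
            "q_between_df": self.q_between_df,
            "q_between_p": self.q_between_p,
            "excluded": list(self.excluded),
        }


@dataclass(frozen=True)
class MetaRegressionResult:
    coefficients: dict[str, dict[str, float]]  # name -> {beta, se, z, p}
    tau2: float
    k_used: int
    residual_q: float

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "tau2": self.tau2,
            "k_used": self.k_used,
            "residual_q": self.residual_q,
        }


def subgroup_pool(
    effects: Sequence[EffectEstimate],
    labels: Mapping[str, Optional[str]],
    factor: SubgroupFactor = SubgroupFactor.ETHNICITY,
    ci_level: float = 0.95,
) -> SubgroupReport:
    """Pool per stratum and test between-stratum heterogeneity.

    ``labels`` maps study_id to a stratum name; a None label (or a missing
    study_id) excludes the study from this factor, with the exclusion
    recorded and logged.  Single-study strata are pooled with the
    fixed-effect fallback and keep the random-effects method tag.
    """
    strata_members: dict[str, list[EffectEstimate]] = {}
    excluded: list[str] = []
    for e in effects:
        label = labels.get(e.study_id)
        if label is None:
            excluded.append(e.study_id)
            continue
        strata_members.setdefault(str(label), []).append(e)
    if not strata_members:
        raise ValueError("no non-empty stratum: every study lacks a label")
    if excluded:
        logger.info(
            "subgroup_pool factor=%s excluded=%d ids=%s",
            factor.value,
            len(excluded),
            ",".join(excluded),
        )
    strata = {
        name: pool_dl(members, ci_level=ci_level)
        for name, members in strata_members.items()
    }
    g = len(strata)
    if g == 1:
        return SubgroupReport(factor, strata, 0.0, 0, 1.0, tuple(excluded))
    mu = np.array([r.pooled_log_or for r in strata.values()])
    big_w = np.array([1.0 / r.pooled_se**2 for r in strata.values()])
    mu_bar = float(np.sum(big_w * mu) / np.sum(big_w))
    q_between = float(np.sum(big_w * (mu - mu_bar) ** 2))
    p = float(stats.chi2.sf(q_between, df=g - 1))
    return SubgroupReport(factor, strata, q_between, g - 1, p, tuple(excluded))


def q_decomposition_fixed(
    effects: Sequence[EffectEstimate], labels: Mapping[str, str]
) -> tuple[float, float, float]:
    """Fixed-weight heterogeneity decomposition (internal oracle).

    Returns (sum of within-stratum Q, between-stratum Q, total Q), all with
    fixed-effect weights, which satisfy the exact ANOVA-like identity
    Q_within + Q_between = Q_total.
    """
    total = pool_fixed(effects)
    groups: dict[str, list[EffectEstimate]] = {}
    for e in effects:
        groups.setdefault(str(labels[e.study_id]), []).append(e)
    q_within = 0.0
    q_between = 0.0
    for members in groups.values():
        sub = pool_fixed(members)
        q_within += sub.q
        w_g = 1.0 / sub.pooled_se**2
        q_between += w_g * (sub.pooled_log_or - total.pooled_log_or) ** 2
    return q_within, q_between, total.q


class EstimabilityError(ValueError):
    """The design matrix is rank deficient or has too few studies."""


def _collinear_columns(x: np.ndarray, names: Sequence[str]) -> list[str]:
    # QR: columns whose R diagonal is negligible are linearly dependent on
    # the columns before them
    _, r = np.linalg.qr(x)
    tol = max(abs(r[0, 0]), 1.0) * max(x.shape) * np.finfo(float).eps * 100
    bad = [
        names[j] for j in range(x.shape[1]) if j < r.shape[0] and abs(r[j, j]) <= tol
    ]
    if not bad:  # rank deficiency the diagonal did not localize
        bad = list(names[np.linalg.matrix_rank(x) :])
    return bad


def _wls(y: np.ndarray, x: np.ndarray, w: np.ndarray):
    xtw = x.T * w
    xtwx = xtw @ x
    beta = np.linalg.solve(xtwx, xtw @ y)
    resid = y - x @ beta
    return beta, resid, xtwx


def meta_regression(
    effects: Sequence[EffectEstimate],
    design: np.ndarray,
    names: Sequence[str],
) -> MetaRegressionResult:
    """Random-effects meta-regression with moment tau^2 and Wald z tests.

    ``design`` is the k x p covariate matrix *including* the intercept
    column; categorical covariates must be pre-expanded to indicators.
    """
    y = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    x = np.asarray(design, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(y):
        raise ValueError("design must be a k x p matrix aligned with the effects")
    k, p = x.shape
    if len(names) != p:
        raise ValueError("need one name per design column")
    if k <= p:
        raise EstimabilityError(
            f"insufficient studies: k={k} must exceed p={p} coefficients"
        )
    if np.linalg.matrix_rank(x) < p:
        bad = _collinear_columns(x, list(names))
        raise EstimabilityError(
            f"design is rank deficient; collinear column(s): {', '.join(bad)}"
        )

    # pass 1: fixed-effect weights -> residual heterogeneity Q_E
    w = 1.0 / se**2
    beta_f, resid_f, xtwx = _wls(y, x, w)
    q_e = float(np.sum(w * resid_f**2))

    # moment estimator of tau^2
    xtw2x = (x.T * w**2) @ x
    denom = float(np.sum(w) - np.trace(np.linalg.solve(xtwx, xtw2x)))
    tau2 = 0.0 if denom <= 0 else max(0.0, (q_e - (k - p)) / denom)

    # pass 2: random-effects weights -> Wald inference
    w_star = 1.0 / (se**2 + tau2)
    beta, _, xtwx_star = _wls(y, x, w_star)
    cov = np.linalg.inv(xtwx_star)
    beta_se = np.sqrt(np.diag(cov))
    coefs = {}
    for j, name in enumerate(names):
        z = beta[j] / beta_se[j]
        coefs[str(name)] = {
            "beta": float(beta[j]),
            "se": float(beta_se[j]),
            "z": float(z),
            "p": float(2.0 * stats.norm.sf(abs(z))),
        }
    return MetaRegressionResult(
        coefficients=coefs, tau2=float(tau2), k_used=k, residual_q=q_e
    )
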