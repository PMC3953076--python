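"""Log odds-ratio effects from genotype counts or reported ORs.

Genotype counts (n_RR, n_RN, n_NN) collapse to a 2x2 contrast under each
genetic model; the log OR and its Woolf standard error
``sqrt(1/a + 1/b + 1/c + 1/d)`` follow from the four cells.  A
Haldane-Anscombe continuity correction (+0.5 to every cell) is applied only
when at least one raw cell is zero, and the estimate is flagged as corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .io import GeneticModel, StudyRecord

logger = logging.getLogger("snpmeta")

__all__ = [
    "ContrastTable",
    "EffectEstimate",
    "build_contrast",
    "odds_ratio_woolf",
    "effect_from_reported",
    "effect_from_record",
]


class EmptyGroupError(ValueError):
    """A case or control group contributes no observations."""


def normal_quantile(ci_level: float) -> float:
    """Two-sided normal critical value for a confidence level in (0, 1)."""
    if not (0.0 < ci_level < 1.0):
        raise ValueError(f"ci_level must lie in (0, 1), got {ci_level}")
    return float(stats.norm.ppf(0.5 + ci_level / 2.0))


@dataclass(frozen=True)
class ContrastTable:
    """2x2 exposure table: a,b = cases exposed/unexposed; c,d = controls."""

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False


@dataclass(frozen=True)
class EffectEstimate:
    """A per-study log-OR with Woolf-type standard error and Wald CI.

    The CI is symmetric about ``log_or`` on the log scale at ``ci_level``;
    ``p`` is the two-sided normal p-value for log_or/se.
    """

    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    ci_level: float
    model: GeneticModel
    study_id: str = ""
    p: float = float("nan")
    corrected: bool = False

    @property
    def variance(self) -> float:
        return self.se * self.se


def build_contrast(
    case_counts: tuple[int, int, int],
    control_counts: tuple[int, int, int],
    model: GeneticModel,
) -> ContrastTable:
    """Collapse genotype counts to the 2x2 table of the given genetic model.

    Allele contrast counts alleles (a = 2*n_RR + n_RN vs b = 2*n_NN + n_RN);
    dominant counts carriers (a = n_RR + n_RN vs b = n_NN); recessive counts
    risk homozygotes (a = n_RR vs b = n_RN + n_NN).
    """
    for label, triple in (("case", case_counts), ("control", control_counts)):
        if len(triple) != 3 or any(x < 0 for x in triple):
            raise ValueError(f"{label} counts must be three non-negative integers")
        if sum(triple) == 0:
            raise EmptyGroupError(f"{label} group has zero total count")

    def split(t):
        rr, rn, nn = t
        if model is GeneticModel.ALLELE:
            return 2 * rr + rn, 2 * nn + rn
        if model is GeneticModel.DOMINANT:
            return rr + rn, nn
        if model is GeneticModel.RECESSIVE:
            return rr, rn + nn
        raise ValueError(f"unknown genetic model {model!r}")

    a, b = split(case_counts)
    c, d = split(control_counts)
    return ContrastTable(a=float(a), b=float(b), c=float(c), d=float(d))


def odds_ratio_woolf(
    table: ContrastTable,
    ci_level: float = 0.95,
    study_id: str = "",
    model: GeneticModel = GeneticModel.ALLELE,
) -> EffectEstimate:
    """Woolf's log-OR estimate from a 2x2 table.

    log OR = ln(ad/bc), se = sqrt(1/a + 1/b + 1/c + 1/d).  When any raw cell
    is zero, 0.5 is added to all four cells first (Haldane-Anscombe) and the
    estimate is flagged ``corrected``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) < 0:
        raise ValueError("contrast cells must be non-negative")
    if a + b == 0 or c + d == 0:
        raise EmptyGroupError("a group with zero total cannot yield an odds ratio")
    corrected = table.corrected
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = normal_quantile(ci_level)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        ci_level=ci_level,
        model=model,
        study_id=study_id,
        p=float(p),
        corrected=corrected,
    )


def effect_from_reported(
    or_value: float,
    ci_low: float,
    ci_high: float,
    ci_level: float = 0.95,
    study_id: str = "",
    model: GeneticModel = GeneticModel.ALLELE,
) -> EffectEstimate:
    """Reconstruct (log OR, se) from a reported OR and Wald CI.

    se = (ln ci_high - ln ci_low) / (2 z), assuming the source built the CI
    symmetrically on the log scale with the normal quantile at ``ci_level``.
    """
    if not (or_value > 0 and ci_low > 0 and ci_high > 0):
        raise ValueError("OR and CI bounds must be positive")
    if not (ci_low < or_value < ci_high):
        raise ValueError(
            f"CI must bracket the OR: need {ci_low} < {or_value} < {ci_high}"
        )
    z = normal_quantile(ci_level)
    log_or = math.log(or_value)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
        model=model,
        study_id=study_id,
        p=float(p),
    )


def effect_from_record(
    record: StudyRecord,
    model: GeneticModel,
    ci_level: float = 0.95,
) -> Optional[EffectEstimate]:
    """Derive the study's effect under ``model``, preferring genotype counts.

    Counts support every genetic model; a reported effect is usable only for
    the model it was reported under.  Returns None when the study cannot
    contribute to this model.  When a study carries both counts and a
    reported effect, the counts win and the choice is logged.
    """
    if record.has_genotypes:
        if record.reported_effect is not None:
            logger.info(
                "effect_source study_id=%s choice=counts reported_effect=ignored",
                record.study_id,
            )
        table = build_contrast(record.case_genotypes, record.control_genotypes, model)
        return odds_ratio_woolf(
            table, ci_level=ci_level, study_id=record.study_id, model=model
        )
    rep = record.reported_effect
    if rep is not None and rep.model is model:
        return effect_from_reported(
            rep.or_value,
            rep.ci_low,
            rep.ci_high,
            ci_level=rep.ci_level,
            study_id=record.study_id,
            model=model,
        )
    return None
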