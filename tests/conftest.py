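"""Shared fixtures: quick effect construction and a realistic 21-study table."""

from __future__ import annotations

import math

import pytest
from hypothesis import settings

from snpmeta import (
    Covariates,
    ControlSource,
    EffectEstimate,
    Ethnicity,
    GeneticModel,
    StudyRecord,
    Subtype,
)
from snpmeta.effects import normal_quantile
from snpmeta.simulate import genotype_probs

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_effect(
    log_or: float,
    se: float,
    study_id: str = "s",
    model: GeneticModel = GeneticModel.ALLELE,
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Build a self-consistent EffectEstimate from (log OR, se)."""
    z = normal_quantile(ci_level)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        ci_level=ci_level,
        model=model,
        study_id=study_id,
    )


# (study_id, year, ethnicity, n_cases, n_controls, control source) for a
# 21-study ischemic-stroke literature; counts below are synthetic.
STUDY_ROSTER = [
    ("Zee", 2007, Ethnicity.CAUCASIAN, 254, 254, ControlSource.POPULATION),
    ("Matarin", 2008, Ethnicity.CAUCASIAN, 249, 268, ControlSource.POPULATION),
    ("Helgadottir", 2008, Ethnicity.CAUCASIAN, 705, 14993, ControlSource.POPULATION),
    ("Smith", 2009, Ethnicity.CAUCASIAN, 2725, 1840, ControlSource.POPULATION),
    ("Gschwendtner", 2009, Ethnicity.CAUCASIAN, 932, 4150, ControlSource.POPULATION),
    ("Lemmens", 2009, Ethnicity.CAUCASIAN, 636, 809, ControlSource.POPULATION),
    ("Karvanen", 2009, Ethnicity.CAUCASIAN, 209, 2064, ControlSource.POPULATION),
    ("Ikram", 2009, Ethnicity.CAUCASIAN, 1164, 18438, ControlSource.POPULATION),
    ("Luke", 2009, Ethnicity.CAUCASIAN, 503, 784, ControlSource.POPULATION),
    ("Yamagishi", 2009, Ethnicity.CAUCASIAN, 524, 12856, ControlSource.POPULATION),
    ("Ding", 2009, Ethnicity.EAST_ASIAN, 999, 1055, ControlSource.POPULATION),
    ("Wahlstrand", 2009, Ethnicity.CAUCASIAN, 163, 5099, ControlSource.HOSPITAL),
    ("Hu", 2009, Ethnicity.EAST_ASIAN, 352, 423, ControlSource.HOSPITAL),
    ("Plant", 2011, Ethnicity.CAUCASIAN, 229, 229, ControlSource.POPULATION),
    ("Olsson", 2011, Ethnicity.CAUCASIAN, 834, 665, ControlSource.POPULATION),
    ("Lin", 2011, Ethnicity.EAST_ASIAN, 642, 1361, ControlSource.POPULATION),
    ("Bellenguez", 2012, Ethnicity.CAUCASIAN, 1780, 12253, ControlSource.POPULATION),
    ("Traylor", 2012, Ethnicity.CAUCASIAN, 12389, 65004, ControlSource.POPULATION),
    ("Cheng", 2012, Ethnicity.CAUCASIAN, 6865, 11395, ControlSource.POPULATION),
    ("Zhang", 2012, Ethnicity.EAST_ASIAN, 1195, 1664, ControlSource.POPULATION),
    ("Heckman", 2013, Ethnicity.CAUCASIAN, 879, 824, ControlSource.POPULATION),
]

_FREQ = {Ethnicity.CAUCASIAN: 0.48, Ethnicity.EAST_ASIAN: 0.50}


def _rounded_counts(n: int, probs) -> tuple[int, int, int]:
    rr = int(round(n * probs[0]))
    rn = int(round(n * probs[1]))
    return (rr, rn, n - rr - rn)


def roster_records(per_allele_or: float = 1.11) -> list[StudyRecord]:
    """Deterministic 21-study table: HWE controls, tilted cases, no noise."""
    records = []
    for sid, year, eth, n_cases, n_controls, source in STUDY_ROSTER:
        ctrl_p, case_p = genotype_probs(_FREQ[eth], math.log(per_allele_or))
        records.append(
            StudyRecord(
                study_id=sid,
                year=year,
                ethnicity=eth,
                subtype=Subtype.MIXED,
                control_source=source,
                case_genotypes=_rounded_counts(n_cases, case_p),
                control_genotypes=_rounded_counts(n_controls, ctrl_p),
                covariates=Covariates(
                    mean_age=65.0 + (year - 2007),
                    pct_male=0.55,
                    mean_bmi=25.0,
                    n_cases=n_cases,
                    n_controls=n_controls,
                ),
            )
        )
    return records


@pytest.fixture
def table1_like_records() -> list[StudyRecord]:
    return roster_records()
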