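"""Synthetic case-control genotype tables for a biallelic risk SNP.

Each simulated study draws control genotypes from Hardy-Weinberg proportions
(q^2, 2pq, p^2 ordered as NN, RN, RR with p the risk-allele frequency) and
case genotypes from the exponentially tilted law

    P(case genotype g) ~ P(control genotype g) * exp(theta_i * g),

g in {0, 1, 2} risk-allele copies -- the logistic per-allele model.  Tilting
HWE proportions yields HWE case proportions with allele odds multiplied by
exp(theta_i), so the population allele-contrast OR equals exp(theta_i)
exactly and the genotype-level ORs are exp(theta_i) and exp(2 theta_i).

Study-level true effects are theta_i = ln(true_or) + Normal(0, tau^2),
the additive-heterogeneity model assumed by DerSimonian-Laird pooling.
Ethnicity governs the control risk-allele frequency; defaults put the
frequency near one half in European- and East-Asian-ancestry strata and
substantially lower in African-ancestry strata, the qualitative pattern
reported for the 9p21 locus.

Reproducibility: each study uses an independent RNG substream keyed on
(seed, study_index), so regenerating with a larger k leaves earlier
studies bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .io import (
    ControlSource,
    Covariates,
    Ethnicity,
    StudyRecord,
    Subtype,
)

logger = logging.getLogger("snpmeta")

__all__ = ["SimulationConfig", "SyntheticStudy", "simulate_study", "simulate_meta"]


def _default_freqs() -> dict[Ethnicity, float]:
    return {
        Ethnicity.CAUCASIAN: 0.48,
        Ethnicity.EAST_ASIAN: 0.50,
        Ethnicity.AFRICAN_AMERICAN: 0.25,
        Ethnicity.OTHER: 0.40,
    }


def _default_ethnicity_mix() -> dict[Ethnicity, float]:
    # 26 Caucasian, 5 East Asian, 4 African American data sets out of 35
    return {
        Ethnicity.CAUCASIAN: 26 / 35,
        Ethnicity.EAST_ASIAN: 5 / 35,
        Ethnicity.AFRICAN_AMERICAN: 4 / 35,
    }


def _default_subtype_mix() -> dict[Subtype, float]:
    # subtype-specific data sets: 9 large-vessel, 5 cardioembolic, 6
    # small-vessel, 2 other-determined, 2 undetermined; the rest unsplit
    return {
        Subtype.LARGE_VESSEL: 9 / 35,
        Subtype.CARDIOEMBOLIC: 5 / 35,
        Subtype.SMALL_VESSEL: 6 / 35,
        Subtype.OTHER_DETERMINED: 2 / 35,
        Subtype.UNDETERMINED: 2 / 35,
        Subtype.MIXED: 11 / 35,
    }


@dataclass
class SimulationConfig:
    """Study-generation parameters.

    ``true_or`` is the per-allele (multiplicative) odds ratio; ``tau`` is the
    standard deviation of study-level log-OR deviations, so ``tau**2`` is the
    between-study variance of the random-effects model.  Study sizes are
    drawn log-uniformly over the given inclusive ranges, reflecting the
    orders-of-magnitude spread typical of genetic-association literatures.
    """

    k: int = 21
    true_or: float = 1.11
    tau: float = 0.04
    allele_freq_by_ethnicity: dict[Ethnicity, float] = field(
        default_factory=_default_freqs
    )
    ethnicity_mix: dict[Ethnicity, float] = field(default_factory=_default_ethnicity_mix)
    n_cases_range: tuple[int, int] = (150, 12500)
    n_controls_range: tuple[int, int] = (250, 65000)
    subtype_mix: dict[Subtype, float] = field(default_factory=_default_subtype_mix)
    hospital_fraction: float = 2 / 35
    seed: int = 0

    def validate(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if not self.true_or > 0:
            raise ValueError("true_or must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        for name, mix in (
            ("ethnicity_mix", self.ethnicity_mix),
            ("subtype_mix", self.subtype_mix),
        ):
            total = sum(mix.values())
            if mix and abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1, got {total}")
        for eth, freq in self.allele_freq_by_ethnicity.items():
            if not (0.0 < freq < 1.0):
                raise ValueError(
                    f"degenerate risk-allele frequency {freq} for {eth}"
                )
        for name, rng in (
            ("n_cases_range", self.n_cases_range),
            ("n_controls_range", self.n_controls_range),
        ):
            lo, hi = rng
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval, got {rng}")
        if not (0.0 <= self.hospital_fraction <= 1.0):
            raise ValueError("hospital_fraction must be a fraction")

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        """Load a config from a YAML mapping (path or stream)."""
        if isinstance(source, (str, bytes)):
            with open(source, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(source)
        raw = dict(raw or {})
        if "allele_freq_by_ethnicity" in raw:
            raw["allele_freq_by_ethnicity"] = {
                Ethnicity(k): float(v)
                for k, v in raw["allele_freq_by_ethnicity"].items()
            }
        if "ethnicity_mix" in raw:
            raw["ethnicity_mix"] = {
                Ethnicity(k): float(v) for k, v in raw["ethnicity_mix"].items()
            }
        if "subtype_mix" in raw:
            raw["subtype_mix"] = {
                Subtype(k): float(v) for k, v in raw["subtype_mix"].items()
            }
        for key in ("n_cases_range", "n_controls_range"):
            if key in raw:
                raw[key] = tuple(int(v) for v in raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class SyntheticStudy:
    """A simulated StudyRecord plus its generating truth.

    The truth block (theta_i, control allele frequency) is for recovery
    tests only and is never written into the analysis input table.
    """

    record: StudyRecord
    theta: float
    p_ctrl: float


def genotype_probs(p: float, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """(control, case) genotype probability vectors ordered (RR, RN, NN)."""
    q = 1.0 - p
    ctrl = np.array([p * p, 2 * p * q, q * q])
    tilt = np.exp(theta * np.array([2.0, 1.0, 0.0]))
    case = ctrl * tilt
    case /= case.sum()
    return ctrl, case


def _draw_choice(rng: np.random.Generator, mix: dict) -> object:
    keys = list(mix.keys())
    weights = np.array([mix[k] for k in keys], dtype=float)
    weights /= weights.sum()
    return keys[int(rng.choice(len(keys), p=weights))]


def _draw_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def simulate_study(
    config: SimulationConfig,
    study_index: int,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticStudy:
    """Draw one study; deterministic given (config.seed, study_index)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, study_index])
    ethnicity = _draw_choice(rng, config.ethnicity_mix)
    subtype = _draw_choice(rng, config.subtype_mix)
    source = (
        ControlSource.HOSPITAL
        if rng.uniform() < config.hospital_fraction
        else ControlSource.POPULATION
    )
    p = config.allele_freq_by_ethnicity[ethnicity]
    theta = float(np.log(config.true_or) + config.tau * rng.standard_normal())
    ctrl_probs, case_probs = genotype_probs(p, theta)
    n_cases = _draw_size(rng, *config.n_cases_range)
    n_controls = _draw_size(rng, *config.n_controls_range)
    case_counts = tuple(int(x) for x in rng.multinomial(n_cases, case_probs))
    ctrl_counts = tuple(int(x) for x in rng.multinomial(n_controls, ctrl_probs))
    cov = Covariates(
        mean_age=float(round(rng.normal(68.0, 4.0), 1)),
        pct_male=float(round(rng.uniform(0.40, 0.70), 3)),
        mean_bmi=float(round(rng.normal(25.5, 1.5), 1)),
        n_cases=n_cases,
        n_controls=n_controls,
    )
    record = StudyRecord(
        study_id=f"sim{study_index:03d}",
        year=int(2007 + rng.integers(0, 7)),
        ethnicity=ethnicity,
        subtype=subtype,
        control_source=source,
        case_genotypes=case_counts,
        control_genotypes=ctrl_counts,
        covariates=cov,
    )
    return SyntheticStudy(record=record, theta=theta, p_ctrl=p)


def simulate_meta(config: SimulationConfig) -> tuple[list[StudyRecord], pd.DataFrame]:
    """Draw a k-study table plus its truth sidecar.

    The sidecar DataFrame carries per-study theta_i and the control
    risk-allele frequency for parameter-recovery checks; it is a companion
    output, never part of the analysis input.
    """
    config.validate()
    studies = [simulate_study(config, i) for i in range(config.k)]
    records = [s.record for s in studies]
    sidecar = pd.DataFrame(
        {
            "study_id": [s.record.study_id for s in studies],
            "theta": [s.theta for s in studies],
            "p_ctrl": [s.p_ctrl for s in studies],
            "ethnicity": [s.record.ethnicity.value for s in studies],
        }
    )
    logger.info(
        "simulate_meta k=%d true_or=%g tau=%g seed=%d",
        config.k,
        config.true_or,
        config.tau,
        config.seed,
    )
    return records, sidecar
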