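"""End-to-end analysis: effects -> HWE screen -> pooling -> moderators -> bias.

``run_full_analysis`` produces one nested report mirroring the usual summary
table of a genetic-association meta-analysis: for each genetic model an
overall pooled row, subgroup blocks (ethnicity, sample size, control source,
disease subtype), publication-bias tests, leave-one-out sensitivity, a
forest-plot data table, and Bonferroni-adjusted overall p-values across the
genetic models.
"""

from __future__ import annotations

import enum
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import bias as bias_mod
from .effects import EffectEstimate, effect_from_record
from .hwe import HWE_ALPHA, hwe_chisq
from .io import GeneticModel, StudyRecord, classify_sample_size
from .moderators import SubgroupFactor, subgroup_pool
from .pooling import PooledResult, pool_dl, pool_fixed

logger = logging.getLogger("snpmeta")

__all__ = ["HwePolicy", "AnalysisConfig", "PipelineError", "run_full_analysis"]

ALL_MODELS = (GeneticModel.ALLELE, GeneticModel.DOMINANT, GeneticModel.RECESSIVE)
ALL_FACTORS = (
    SubgroupFactor.ETHNICITY,
    SubgroupFactor.SAMPLE_SIZE,
    SubgroupFactor.CONTROL_SOURCE,
    SubgroupFactor.SUBTYPE,
)


class HwePolicy(str, enum.Enum):
    FLAG_ONLY = "flag_only"
    EXCLUDE = "exclude"
    BOTH_RUNS = "both_runs"


class PipelineError(RuntimeError):
    pass


@dataclass
class AnalysisConfig:
    genetic_models: tuple[GeneticModel, ...] = ALL_MODELS
    ci_level: float = 0.95
    hwe_policy: HwePolicy = HwePolicy.FLAG_ONLY
    subgroup_factors: tuple[SubgroupFactor, ...] = ALL_FACTORS
    bonferroni_m: int = 3
    seed: int = 0
    output_format: str = "json"

    def validate(self) -> None:
        if not self.genetic_models:
            raise ValueError("genetic_models must be non-empty")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")

    def digest(self) -> str:
        payload = {
            "genetic_models": [m.value for m in self.genetic_models],
            "ci_level": self.ci_level,
            "hwe_policy": self.hwe_policy.value,
            "subgroup_factors": [f.value for f in self.subgroup_factors],
            "bonferroni_m": self.bonferroni_m,
            "seed": self.seed,
            "output_format": self.output_format,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _subgroup_labels(
    records: Sequence[StudyRecord], factor: SubgroupFactor
) -> dict[str, Optional[str]]:
    labels: dict[str, Optional[str]] = {}
    for r in records:
        if factor is SubgroupFactor.ETHNICITY:
            labels[r.study_id] = r.ethnicity.value
        elif factor is SubgroupFactor.SAMPLE_SIZE:
            try:
                labels[r.study_id] = classify_sample_size(r).value
            except ValueError:
                labels[r.study_id] = None
        elif factor is SubgroupFactor.CONTROL_SOURCE:
            labels[r.study_id] = r.control_source.value
        elif factor is SubgroupFactor.SUBTYPE:
            # unsplit/mixed cohorts contribute to overall but not to the
            # subtype-specific contrast
            labels[r.study_id] = (
                None if r.subtype.value == "Mixed" else r.subtype.value
            )
    return labels


def _forest_table(effects: Sequence[EffectEstimate], overall: PooledResult) -> list[dict]:
    weights = [1.0 / (e.se**2 + overall.tau2) for e in effects]
    total = sum(weights)
    return [
        {
            "study_id": e.study_id,
            "or_value": e.or_value,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "log_or": e.log_or,
            "se": e.se,
            "weight_pct": 100.0 * w / total,
            "corrected": e.corrected,
        }
        for e, w in zip(effects, weights)
    ]


def _model_block(
    records: Sequence[StudyRecord],
    model: GeneticModel,
    config: AnalysisConfig,
    hwe_fail_ids: set[str],
) -> dict:
    effects_all: list[EffectEstimate] = []
    skipped: list[str] = []
    for r in records:
        eff = effect_from_record(r, model, ci_level=config.ci_level)
        if eff is None:
            skipped.append(r.study_id)
        else:
            effects_all.append(eff)
    if skipped:
        logger.info(
            "model=%s skipped=%d ids=%s", model.value, len(skipped), ",".join(skipped)
        )
    effects_kept = [e for e in effects_all if e.study_id not in hwe_fail_ids]
    primary = (
        effects_kept if config.hwe_policy is HwePolicy.EXCLUDE else effects_all
    )
    if len(primary) < 2:
        raise PipelineError(
            f"fewer than 2 usable studies for model {model.value} "
            f"(k={len(primary)})"
        )
    overall = pool_dl(primary, ci_level=config.ci_level)
    overall_fixed = pool_fixed(primary, ci_level=config.ci_level)

    block: dict = {
        "k": len(primary),
        "overall": overall.to_dict(),
        "overall_fixed": overall_fixed.to_dict(),
        "skipped_study_ids": skipped,
    }
    if config.hwe_policy is HwePolicy.BOTH_RUNS:
        if len(effects_kept) >= 2 and len(effects_kept) < len(effects_all):
            block["overall_hwe_excluded"] = pool_dl(
                effects_kept, ci_level=config.ci_level
            ).to_dict()
        else:
            block["overall_hwe_excluded"] = (
                overall.to_dict() if len(effects_kept) == len(effects_all) else None
            )

    primary_records = [r for r in records if r.study_id in {e.study_id for e in primary}]
    for factor in config.subgroup_factors:
        key = {
            SubgroupFactor.ETHNICITY: "by_ethnicity",
            SubgroupFactor.SAMPLE_SIZE: "by_sample_size",
            SubgroupFactor.CONTROL_SOURCE: "by_control_source",
            SubgroupFactor.SUBTYPE: "by_subtype",
        }[factor]
        labels = _subgroup_labels(primary_records, factor)
        if all(v is None for v in labels.values()):
            logger.warning("factor=%s skipped reason=all_labels_missing", factor.value)
            block[key] = None
            continue
        block[key] = subgroup_pool(
            primary, labels, factor=factor, ci_level=config.ci_level
        ).to_dict()

    bias_block: dict = {"egger": None, "begg": None, "funnel": None}
    if len(primary) >= 3:
        bias_block["egger"] = bias_mod.egger_test(primary).to_dict()
        bias_block["begg"] = bias_mod.begg_test(primary).to_dict()
    else:
        logger.warning("bias tests skipped reason=k_lt_3 model=%s", model.value)
    funnel = bias_mod.funnel_data(primary, overall)
    bias_block["funnel"] = funnel["points"].to_dict(orient="records")
    block["bias"] = bias_block

    sensitivity: dict = {
        "hwe_excluded_study_ids": sorted(
            hwe_fail_ids & {e.study_id for e in effects_all}
        ),
        "leave_one_out": None,
    }
    if len(primary) >= 3:
        sensitivity["leave_one_out"] = bias_mod.leave_one_out(
            primary, ci_level=config.ci_level
        ).to_dict()
    block["sensitivity"] = sensitivity

    block["forest"] = _forest_table(primary, overall)
    return block


def run_full_analysis(
    studies: Sequence[StudyRecord], config: Optional[AnalysisConfig] = None
) -> dict:
    """Run the complete meta-analysis and return the structured report.

    The report is deterministic for a given (studies, config) pair: there is
    no resampling anywhere in the analysis path.
    """
    config = config or AnalysisConfig()
    config.validate()
    if len(studies) < 2:
        raise PipelineError(f"fewer than 2 usable studies (k={len(studies)})")

    hwe_block: dict[str, Optional[dict]] = {}
    hwe_fail_ids: set[str] = set()
    for r in studies:
        if r.control_genotypes is None:
            hwe_block[r.study_id] = None  # nothing to test; flagged no_genotypes
            continue
        res = hwe_chisq(r.control_genotypes)
        hwe_block[r.study_id] = {
            "chi2": res.chi2,
            "p": res.p,
            "risk_allele_freq": res.risk_allele_freq,
            "in_hwe_at_005": res.in_hwe_at_005,
            "monomorphic": res.monomorphic,
        }
        if not res.in_hwe_at_005:
            hwe_fail_ids.add(r.study_id)
    logger.info(
        "run_full_analysis k=%d hwe_violations=%d policy=%s config_digest=%s",
        len(studies),
        len(hwe_fail_ids),
        config.hwe_policy.value,
        config.digest(),
    )

    models_block = {}
    overall_ps = []
    for model in config.genetic_models:
        block = _model_block(studies, model, config, hwe_fail_ids)
        models_block[model.value] = block
        overall_ps.append(block["overall"]["p"])

    m = max(config.bonferroni_m, len(overall_ps))
    adjusted = bias_mod.bonferroni(overall_ps, m=m)
    report = {
        "config": {
            "digest": config.digest(),
            "ci_level": config.ci_level,
            "hwe_policy": config.hwe_policy.value,
            "genetic_models": [mod.value for mod in config.genetic_models],
            "bonferroni_m": m,
        },
        "n_studies": len(studies),
        "hwe": hwe_block,
        "models": models_block,
        "bonferroni": {
            mod.value: p_adj
            for mod, p_adj in zip(config.genetic_models, adjusted)
        },
    }
    return report


def report_tsv_rows(report: dict) -> list[dict]:
    """Flatten a report into pooled-result rows for TSV serialization."""
    rows: list[dict] = []

    def _row(section: str, model: str, stratum: str, d: dict) -> dict:
        return {
            "section": section,
            "model": model,
            "stratum": stratum,
            "k": d["k"],
            "or_value": d["or_value"],
            "ci_low": d["ci_low"],
            "ci_high": d["ci_high"],
            "p": d["p"],
            "q": d["q"],
            "q_p": d["q_p"],
            "i2_pct": d["i2_pct"],
            "tau2": d["tau2"],
        }

    for model, block in report.get("models", {}).items():
        rows.append(_row("overall", model, "", block["overall"]))
        for key in ("by_ethnicity", "by_sample_size", "by_control_source", "by_subtype"):
            sub = block.get(key)
            if not sub:
                continue
            for stratum, pooled in sub["strata"].items():
                rows.append(_row(key, model, stratum, pooled))
    return rows
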