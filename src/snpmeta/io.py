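"""Study-table data model, validated reading/writing, and results serialization.

A *study table* is one delimited (TSV or CSV) file with a header row and one
row per study data set.  Each row carries either case/control genotype counts
for a biallelic SNP (columns ``case_rr, case_rn, case_nn, ctrl_rr, ctrl_rn,
ctrl_nn``, where ``rr`` = homozygous for the risk allele) or a reported odds
ratio with its confidence interval (columns ``or_value, ci_low, ci_high,
ci_level, model``), plus study-level covariates.  Risk-allele orientation is
the curator's responsibility; the optional boolean ``flip`` column inverts a
reported OR (1/OR, swapped CI bounds) and swaps risk/non-risk genotype counts.

A study enrolling several ethnic groups appears as one row per ethnic
stratum, each with its own ``study_id``.
"""

from __future__ import annotations

import dataclasses
import enum
import io as _io
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("snpmeta")

__all__ = [
    "Ethnicity",
    "Subtype",
    "ControlSource",
    "GeneticModel",
    "SampleSizeClass",
    "ReportedEffect",
    "Covariates",
    "StudyRecord",
    "SchemaError",
    "StudyValidationError",
    "read_study_table",
    "write_study_table",
    "classify_sample_size",
    "write_results",
]


class Ethnicity(str, enum.Enum):
    CAUCASIAN = "Caucasian"
    EAST_ASIAN = "EastAsian"
    AFRICAN_AMERICAN = "AfricanAmerican"
    OTHER = "Other"


class Subtype(str, enum.Enum):
    LARGE_VESSEL = "LargeVessel"
    CARDIOEMBOLIC = "Cardioembolic"
    SMALL_VESSEL = "SmallVessel"
    OTHER_DETERMINED = "OtherDetermined"
    UNDETERMINED = "Undetermined"
    MIXED = "Mixed"


class ControlSource(str, enum.Enum):
    POPULATION = "Population"
    HOSPITAL = "Hospital"


class GeneticModel(str, enum.Enum):
    """The three contrasts derivable from biallelic genotype counts.

    * ``ALLELE`` -- allele contrast: effect of each additional risk allele.
    * ``DOMINANT`` -- presence vs. absence of the risk allele.
    * ``RECESSIVE`` -- presence vs. absence of two copies of the risk allele.
    """

    ALLELE = "allele"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class SampleSizeClass(str, enum.Enum):
    SMALL = "Small"
    LARGE = "Large"


#: Case-count threshold separating Small from Large studies (Large iff >= 500).
LARGE_STUDY_MIN_CASES = 500


class SchemaError(ValueError):
    """The table is missing a mandatory column or is not a delimited table."""


class StudyValidationError(ValueError):
    """One or more rows violate the study-record invariants.

    ``errors`` is a list of (row_index, message) pairs; row indices are
    0-based positions in the data section of the file.
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {i}: {m}" for i, m in self.errors)
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}")


@dataclass(frozen=True)
class ReportedEffect:
    """An odds ratio with confidence interval as printed by a source study."""

    or_value: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    model: GeneticModel = GeneticModel.ALLELE

    def validate(self) -> list[str]:
        errs = []
        if not (self.or_value > 0 and self.ci_low > 0 and self.ci_high > 0):
            errs.append("reported OR and CI bounds must be positive")
        elif not (self.ci_low < self.or_value < self.ci_high):
            errs.append(
                f"reported CI must bracket the OR: got {self.ci_low} < "
                f"{self.or_value} < {self.ci_high}"
            )
        if not (0.0 < self.ci_level < 1.0):
            errs.append("ci_level must lie in (0, 1)")
        return errs


@dataclass(frozen=True)
class Covariates:
    """Optional study-level covariates used by moderator analyses."""

    mean_age: Optional[float] = None  # years
    pct_male: Optional[float] = None  # fraction in [0, 1]
    mean_bmi: Optional[float] = None  # kg/m^2
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None


@dataclass(frozen=True)
class StudyRecord:
    """One study data set: genotype counts and/or a reported effect, plus covariates.

    ``case_genotypes``/``control_genotypes`` are (n_RR, n_RN, n_NN) count
    triples with R the risk allele.  At least one of (both genotype triples)
    or ``reported_effect`` must be present; when both are, downstream effect
    derivation prefers the counts.
    """

    study_id: str
    year: int
    ethnicity: Ethnicity
    subtype: Subtype
    control_source: ControlSource
    case_genotypes: Optional[tuple[int, int, int]] = None
    control_genotypes: Optional[tuple[int, int, int]] = None
    reported_effect: Optional[ReportedEffect] = None
    covariates: Covariates = field(default_factory=Covariates)

    @property
    def has_genotypes(self) -> bool:
        return self.case_genotypes is not None and self.control_genotypes is not None

    @property
    def n_cases(self) -> Optional[int]:
        if self.case_genotypes is not None:
            return int(sum(self.case_genotypes))
        return self.covariates.n_cases

    @property
    def n_controls(self) -> Optional[int]:
        if self.control_genotypes is not None:
            return int(sum(self.control_genotypes))
        return self.covariates.n_controls

    def validate(self) -> list[str]:
        """Return a list of invariant-violation messages (empty when valid)."""
        errs: list[str] = []
        if not self.study_id:
            errs.append("study_id must be non-empty")
        half = (self.case_genotypes is None) != (self.control_genotypes is None)
        if half:
            errs.append("genotype counts must be given for both cases and controls")
        if not self.has_genotypes and self.reported_effect is None:
            errs.append("need either genotype counts or a reported OR with CI")
        for label, triple in (
            ("case", self.case_genotypes),
            ("ctrl", self.control_genotypes),
        ):
            if triple is None:
                continue
            if len(triple) != 3:
                errs.append(f"{label} genotype counts must be a triple")
                continue
            if any((not float(x).is_integer()) or x < 0 for x in triple):
                errs.append(f"{label} genotype counts must be non-negative integers")
        if self.reported_effect is not None:
            errs.extend(self.reported_effect.validate())
        cov = self.covariates
        if (
            cov.n_cases is not None
            and self.case_genotypes is not None
            and int(cov.n_cases) != int(sum(self.case_genotypes))
        ):
            errs.append(
                f"n_cases={cov.n_cases} disagrees with case genotype sum "
                f"{int(sum(self.case_genotypes))}"
            )
        if cov.pct_male is not None and not (0.0 <= cov.pct_male <= 1.0):
            errs.append("pct_male must be a fraction in [0, 1]")
        return errs


# ---------------------------------------------------------------------------
# Table schema
# ---------------------------------------------------------------------------

MANDATORY_COLUMNS = ("study_id", "year", "ethnicity", "subtype", "control_source")
GENOTYPE_COLUMNS = ("case_rr", "case_rn", "case_nn", "ctrl_rr", "ctrl_rn", "ctrl_nn")
EFFECT_COLUMNS = ("or_value", "ci_low", "ci_high", "ci_level", "model")
COVARIATE_COLUMNS = ("mean_age", "pct_male", "mean_bmi", "n_cases", "n_controls")
ALL_COLUMNS = (
    MANDATORY_COLUMNS + GENOTYPE_COLUMNS + EFFECT_COLUMNS + ("flip",) + COVARIATE_COLUMNS
)

_SEP = {"tsv": "\t", "csv": ","}


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def _parse_count(value, label: str, errs: list[str]) -> Optional[int]:
    if _is_missing(value):
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        errs.append(f"{label} is not a number: {value!r}")
        return None
    if not x.is_integer():
        errs.append(f"{label} must be an integer count, got {value!r}")
        return None
    if x < 0:
        errs.append(f"{label} must be non-negative, got {int(x)}")
        return None
    return int(x)


def _parse_triple(row, prefix: str, errs: list[str]) -> Optional[tuple[int, int, int]]:
    raw = [row.get(f"{prefix}_{g}") for g in ("rr", "rn", "nn")]
    present = [not _is_missing(v) for v in raw]
    if not any(present):
        return None
    if not all(present):
        errs.append(f"incomplete {prefix} genotype triple (need {prefix}_rr/_rn/_nn)")
        return None
    vals = [_parse_count(v, f"{prefix}_{g}", errs) for v, g in zip(raw, ("rr", "rn", "nn"))]
    if any(v is None for v in vals):
        return None
    return (vals[0], vals[1], vals[2])


def _parse_enum(enum_cls, value, label: str, errs: list[str]):
    try:
        return enum_cls(str(value).strip())
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        errs.append(f"{label} {value!r} not one of {{{allowed}}}")
        return None


def _parse_row(row: Mapping, errs: list[str]) -> Optional[StudyRecord]:
    ethnicity = _parse_enum(Ethnicity, row["ethnicity"], "ethnicity", errs)
    subtype = _parse_enum(Subtype, row["subtype"], "subtype", errs)
    source = _parse_enum(ControlSource, row["control_source"], "control_source", errs)
    try:
        year = int(float(row["year"]))
    except (TypeError, ValueError):
        errs.append(f"year is not an integer: {row['year']!r}")
        year = 0

    case = _parse_triple(row, "case", errs)
    ctrl = _parse_triple(row, "ctrl", errs)

    reported = None
    if not _is_missing(row.get("or_value")):
        model = GeneticModel.ALLELE
        if not _is_missing(row.get("model")):
            model = _parse_enum(GeneticModel, row.get("model"), "model", errs) or model
        level = 0.95 if _is_missing(row.get("ci_level")) else float(row.get("ci_level"))
        try:
            reported = ReportedEffect(
                or_value=float(row["or_value"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                ci_level=level,
                model=model,
            )
        except (TypeError, ValueError, KeyError):
            errs.append("reported effect needs numeric or_value, ci_low and ci_high")

    flip = False
    if not _is_missing(row.get("flip")):
        flip = str(row.get("flip")).strip().lower() in ("1", "true", "yes")
    if flip:
        if case is not None:
            case = (case[2], case[1], case[0])
        if ctrl is not None:
            ctrl = (ctrl[2], ctrl[1], ctrl[0])
        if reported is not None:
            reported = ReportedEffect(
                or_value=1.0 / reported.or_value,
                ci_low=1.0 / reported.ci_high,
                ci_high=1.0 / reported.ci_low,
                ci_level=reported.ci_level,
                model=reported.model,
            )

    def _opt_float(col):
        v = row.get(col)
        return None if _is_missing(v) else float(v)

    def _opt_int(col):
        v = row.get(col)
        return None if _is_missing(v) else int(float(v))

    cov = Covariates(
        mean_age=_opt_float("mean_age"),
        pct_male=_opt_float("pct_male"),
        mean_bmi=_opt_float("mean_bmi"),
        n_cases=_opt_int("n_cases"),
        n_controls=_opt_int("n_controls"),
    )

    if errs or ethnicity is None or subtype is None or source is None:
        return None
    rec = StudyRecord(
        study_id=str(row["study_id"]).strip(),
        year=year,
        ethnicity=ethnicity,
        subtype=subtype,
        control_source=source,
        case_genotypes=case,
        control_genotypes=ctrl,
        reported_effect=reported,
        covariates=cov,
    )
    errs.extend(rec.validate())
    return None if errs else rec


def read_study_table(source, dialect: str = "tsv") -> list[StudyRecord]:
    """Read and validate a study table, returning records in file order.

    ``source`` is a path or an open text stream.  Every malformed row
    produces a row-indexed diagnostic; nothing is silently coerced.

    Raises
    ------
    SchemaError
        if a mandatory column is absent.
    StudyValidationError
        collecting every invalid row with its 0-based data-row index.
    """
    if dialect not in _SEP:
        raise ValueError(f"dialect must be one of {sorted(_SEP)}, got {dialect!r}")
    try:
        df = pd.read_csv(source, sep=_SEP[dialect], dtype=object, keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("empty input: no header row") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    failures: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    for idx, row in enumerate(df.to_dict(orient="records")):
        errs: list[str] = []
        rec = _parse_row(row, errs)
        if rec is not None and rec.study_id in seen_ids:
            errs.append(f"duplicate study_id {rec.study_id!r}")
            rec = None
        if errs:
            failures.extend((idx, m) for m in errs)
        else:
            assert rec is not None
            seen_ids.add(rec.study_id)
            records.append(rec)
    if failures:
        raise StudyValidationError(failures)
    logger.info("read_study_table k=%d dialect=%s", len(records), dialect)
    return records


def study_table_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    """Render records as a DataFrame in the canonical column order."""
    rows = []
    for r in records:
        row: dict = {c: None for c in ALL_COLUMNS}
        row.update(
            study_id=r.study_id,
            year=r.year,
            ethnicity=r.ethnicity.value,
            subtype=r.subtype.value,
            control_source=r.control_source.value,
        )
        if r.case_genotypes is not None:
            row["case_rr"], row["case_rn"], row["case_nn"] = r.case_genotypes
        if r.control_genotypes is not None:
            row["ctrl_rr"], row["ctrl_rn"], row["ctrl_nn"] = r.control_genotypes
        if r.reported_effect is not None:
            e = r.reported_effect
            row.update(
                or_value=e.or_value,
                ci_low=e.ci_low,
                ci_high=e.ci_high,
                ci_level=e.ci_level,
                model=e.model.value,
            )
        c = r.covariates
        row.update(
            mean_age=c.mean_age,
            pct_male=c.pct_male,
            mean_bmi=c.mean_bmi,
            n_cases=c.n_cases,
            n_controls=c.n_controls,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


def write_study_table(records: Iterable[StudyRecord], sink, dialect: str = "tsv") -> None:
    """Write records so that ``read_study_table`` reproduces them field-for-field."""
    if dialect not in _SEP:
        raise ValueError(f"dialect must be one of {sorted(_SEP)}, got {dialect!r}")
    df = study_table_frame(records)
    df.to_csv(sink, sep=_SEP[dialect], index=False)


def classify_sample_size(record: StudyRecord) -> SampleSizeClass:
    """Large iff the study has at least 500 cases, else Small."""
    n = record.n_cases
    if n is None:
        raise ValueError(
            f"study {record.study_id!r}: case count unavailable "
            "(no genotype counts and no n_cases covariate)"
        )
    return SampleSizeClass.LARGE if n >= LARGE_STUDY_MIN_CASES else SampleSizeClass.SMALL


# ---------------------------------------------------------------------------
# Results serialization
# ---------------------------------------------------------------------------

#: TSV result-row columns, in fixed order.
RESULT_COLUMNS = (
    "section",
    "model",
    "stratum",
    "k",
    "or_value",
    "ci_low",
    "ci_high",
    "p",
    "q",
    "q_p",
    "i2_pct",
    "tau2",
)


def _sig6(x: float) -> float:
    return float(f"{x:.6g}")


def _round_floats(obj):
    """Recursively round all floats to 6 significant digits for serialization."""
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return _sig6(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _round_floats(dataclasses.asdict(obj))
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if obj is None or isinstance(obj, (int, str)):
        return obj
    if hasattr(obj, "item"):  # numpy scalar
        return _round_floats(obj.item())
    raise TypeError(f"unserializable value of type {type(obj).__name__}: {obj!r}")


def write_results(report, sink, format: str = "json") -> None:
    """Serialize a structured report with deterministic field order.

    JSON keeps the full nested structure; TSV expects the report to expose
    flat pooled-result rows (an iterable of mappings with ``RESULT_COLUMNS``
    keys).  All floats are written with 6 significant digits; NaN becomes an
    explicit missing marker (empty TSV cell / JSON null).
    """
    close = False
    if isinstance(sink, (str, bytes)):
        sink = open(sink, "w", encoding="utf-8")
        close = True
    try:
        if format == "json":
            json.dump(_round_floats(report), sink, indent=2)
            sink.write("\n")
        elif format == "tsv":
            rows = list(report)
            sink.write("\t".join(RESULT_COLUMNS) + "\n")
            for row in rows:
                cells = []
                for col in RESULT_COLUMNS:
                    v = _round_floats(row.get(col))
                    cells.append("" if v is None else str(v))
                sink.write("\t".join(cells) + "\n")
        else:
            raise ValueError(f"format must be 'json' or 'tsv', got {format!r}")
    finally:
        if close:
            sink.close()


def results_to_string(report, format: str = "json") -> str:
    buf = _io.StringIO()
    write_results(report, buf, format=format)
    return buf.getvalue()
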