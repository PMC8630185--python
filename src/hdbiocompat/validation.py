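"""Consensus prediction across model families and predicted-vs-actual validation.

Within the calibrated property range the five family equations for a
biomarker agree to within a few percent; the recommended point estimate is
their arithmetic mean, bracketed by the lowest and highest family
responses. The validation machinery recomputes percent errors between
predicted and measured serum concentrations and summarises them per
biomarker, reproducing the published predicted-vs-actual arithmetic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .biomarkers import Biomarker, PredictorFamily
from .equations import FAMILY_PROPERTY, Concentration, get_coefficients, predict_base
from .membranes import MembraneProperties, OperatingConditions, get_membrane


@dataclass
class PredictionResult:
    """Per-family predictions with their consensus mean and bounds (pg/mL)."""

    biomarker: Biomarker
    per_family: dict[PredictorFamily, float]
    consensus_mean: float
    lower: float
    upper: float
    warnings: list[str] = field(default_factory=list)


def consensus(
    m: MembraneProperties,
    oc: OperatingConditions,
    b: Biomarker,
    families: Sequence[PredictorFamily] = tuple(PredictorFamily),
) -> PredictionResult:
    """Combine the applicable family predictions for one biomarker.

    Families whose membrane property is unknown (NaN) are omitted with a
    warning; with no applicable family at all the prediction is undefined
    and a ``ValueError`` is raised.
    """
    b = Biomarker(b)
    per_family: dict[PredictorFamily, float] = {}
    warnings: list[str] = []
    for fam in families:
        fam = PredictorFamily(fam)
        prop = m.property_value(FAMILY_PROPERTY[fam])
        if math.isnan(prop):
            warnings.append(f"family {fam.value} omitted: property {FAMILY_PROPERTY[fam]} unknown")
            continue
        conc = predict_base(get_coefficients(fam, b), m, oc)
        per_family[fam] = conc.value
        for w in conc.warnings:
            if w not in warnings:
                warnings.append(w)
    if not per_family:
        raise ValueError(f"no applicable model family for membrane {m.name!r}")
    values = list(per_family.values())
    return PredictionResult(
        biomarker=b,
        per_family=per_family,
        consensus_mean=sum(values) / len(values),
        lower=min(values),
        upper=max(values),
        warnings=warnings,
    )


def percent_error(predicted: float, actual: float) -> float:
    """Unsigned relative error in percent: 100*|predicted - actual| / |actual|.

    The absolute value in the denominator keeps the error finite and
    positive for negative predictions; undefined for actual = 0.
    """
    if actual == 0:
        raise ZeroDivisionError("percent error undefined for actual = 0")
    return 100.0 * abs(predicted - actual) / abs(actual)


@dataclass(frozen=True)
class ValidationRecord:
    """One predicted-vs-measured pair; pct_error is always recomputed."""

    biomarker: Biomarker
    membrane: str
    Qb: float
    t: float
    predicted: float
    actual: float
    printed_pct_error: float | None = None
    transcription_confidence: str = "high"

    def __post_init__(self) -> None:
        if self.actual == 0:
            raise ValueError("actual concentration must be nonzero")

    @property
    def pct_error(self) -> float:
        return percent_error(self.predicted, self.actual)


def default_model(membrane: str, oc: OperatingConditions, b: Biomarker) -> float:
    """Affinity-family base prediction for a built-in membrane (the published choice)."""
    m = get_membrane(membrane)
    return predict_base(get_coefficients(PredictorFamily.affinity, b), m, oc).value


@dataclass
class ValidationReport:
    rows: list[dict]
    per_biomarker_mean_error: dict[str, float]        # mean of recomputed errors
    per_biomarker_mean_printed_error: dict[str, float]
    min_mean_error: float
    max_mean_error: float
    row_errors: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows": self.rows,
                "per_biomarker_mean_error": self.per_biomarker_mean_error,
                "per_biomarker_mean_printed_error": self.per_biomarker_mean_printed_error,
                "min_mean_error": self.min_mean_error,
                "max_mean_error": self.max_mean_error,
                "row_errors": self.row_errors,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [
            f"{'membrane':<10} {'Qb':>5} {'t':>5} {'biomarker':<10} "
            f"{'predicted':>12} {'actual':>12} {'%err':>8} {'recomputed':>12}"
        ]
        for r in self.rows:
            rp = r["recomputed_prediction"]
            lines.append(
                f"{r['membrane']:<10} {r['Qb']:>5g} {r['t']:>5g} {r['biomarker']:<10} "
                f"{r['predicted']:>12.4G} {r['actual']:>12.4G} {r['pct_error']:>8.2f} "
                f"{(f'{rp:.4G}' if rp is not None else 'n/a'):>12}"
            )
        lines.append("")
        lines.append("per-biomarker mean % error (recomputed from predicted/actual pairs):")
        for b, e in self.per_biomarker_mean_error.items():
            lines.append(f"  {b:<10} {e:8.2f}")
        lines.append(
            f"mean-error range: {self.min_mean_error:.2f}% .. {self.max_mean_error:.2f}%"
        )
        for err in self.row_errors:
            lines.append(f"row error: {err}")
        return "\n".join(lines)


def validate_fixture(
    fixture: Iterable[ValidationRecord],
    model: Callable[[str, OperatingConditions, Biomarker], float] | None = default_model,
) -> ValidationReport:
    """Recompute the predicted-vs-actual arithmetic over a fixture.

    For each row: the model's recomputed prediction (where the membrane is
    resolvable), the percent error of the fixture's predicted value against
    the measured one, and per-biomarker unweighted mean errors with their
    min/max. Unresolvable membranes yield a row-level error but the report
    is still produced.
    """
    rows: list[dict] = []
    row_errors: list[str] = []
    by_biomarker: dict[str, list[float]] = {}
    printed_by_biomarker: dict[str, list[float]] = {}
    for rec in fixture:
        recomputed = None
        if model is not None:
            try:
                recomputed = model(rec.membrane, OperatingConditions(rec.Qb, rec.t), rec.biomarker)
            except (KeyError, ValueError) as err:
                row_errors.append(f"{rec.membrane}/{rec.biomarker.value}: {err}")
        err_pct = rec.pct_error
        rows.append(
            {
                "membrane": rec.membrane,
                "Qb": rec.Qb,
                "t": rec.t,
                "biomarker": rec.biomarker.value,
                "predicted": rec.predicted,
                "actual": rec.actual,
                "pct_error": err_pct,
                "printed_pct_error": rec.printed_pct_error,
                "recomputed_prediction": recomputed,
                "transcription_confidence": rec.transcription_confidence,
            }
        )
        by_biomarker.setdefault(rec.biomarker.value, []).append(err_pct)
        if rec.printed_pct_error is not None:
            printed_by_biomarker.setdefault(rec.biomarker.value, []).append(rec.printed_pct_error)
    means = {b: sum(v) / len(v) for b, v in by_biomarker.items()}
    printed_means = {b: sum(v) / len(v) for b, v in printed_by_biomarker.items()}
    return ValidationReport(
        rows=rows,
        per_biomarker_mean_error=means,
        per_biomarker_mean_printed_error=printed_means,
        min_mean_error=min(means.values()) if means else math.nan,
        max_mean_error=max(means.values()) if means else math.nan,
        row_errors=row_errors,
    )
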