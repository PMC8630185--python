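"""The 40 base prediction equations as data-driven coefficient sets.

Each (predictor family, biomarker) pair has one calibrated linear model

    C = b0 + b_p*p + b_Qb*Qb + b_t*t + b_pQb*p*Qb + b_pT*p*t + b_QbT*Qb*t

where p is the membrane property of the family and C is a concentration in
pg/mL. Coefficients are stored verbatim at the calibration's printed
precision in a packaged CSV. For the signed properties (zeta potential and
fibrinogen affinity K) each equation carries an explicit sign-convention
flag: ``signed`` evaluates the property as stored, ``magnitude`` evaluates
its absolute value. The flags are calibration data, fixed by auditing each
equation against the published predicted concentrations.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .biomarkers import Biomarker, PredictorFamily
from .membranes import (
    EXPANDED_MODEL_RANGE,
    MembraneProperties,
    OperatingConditions,
    check_applicability,
)

#: Membrane attribute used by each family.
FAMILY_PROPERTY = {
    PredictorFamily.pore_size: "Dp",
    PredictorFamily.roughness: "Ra",
    PredictorFamily.sulfur: "S",
    PredictorFamily.zeta: "zeta",
    PredictorFamily.affinity: "K",
}


@dataclass(frozen=True)
class CoefficientSet:
    """Coefficients of one equation; absent terms are stored as zero."""

    equation_id: int
    family: PredictorFamily
    biomarker: Biomarker
    intercept: float
    b_prop: float
    b_Qb: float
    b_t: float
    b_propQb: float
    b_propT: float
    b_QbT: float
    prop_sign: str = "signed"  # 'signed' | 'magnitude'

    def __post_init__(self) -> None:
        if self.prop_sign not in ("signed", "magnitude"):
            raise ValueError(f"prop_sign must be 'signed' or 'magnitude', got {self.prop_sign!r}")

    def evaluate(self, prop: float, Qb: float, t: float) -> float:
        """Evaluate at a raw property value and operating conditions."""
        p = abs(prop) if self.prop_sign == "magnitude" else prop
        return (
            self.intercept
            + self.b_prop * p
            + self.b_Qb * Qb
            + self.b_t * t
            + self.b_propQb * p * Qb
            + self.b_propT * p * t
            + self.b_QbT * Qb * t
        )


@dataclass
class Concentration:
    """A predicted concentration in pg/mL with any attached warnings.

    Values may legitimately be negative (the linear models extrapolate);
    negative values always carry a warning and are never clamped.
    """

    value: float
    warnings: list[str] = field(default_factory=list)


def _normalize_number(text: str) -> float:
    # unicode minus and thin spaces appear in published coefficient strings
    return float(text.replace("−", "-").replace(" ", "").replace(" ", ""))


def parse_coefficient_csv(text: str) -> dict[tuple[PredictorFamily, Biomarker], CoefficientSet]:
    table = {}
    for row in csv.DictReader(io.StringIO(text)):
        cs = CoefficientSet(
            equation_id=int(row["equation_id"]),
            family=PredictorFamily(row["family"]),
            biomarker=Biomarker(row["biomarker"]),
            intercept=_normalize_number(row["intercept"]),
            b_prop=_normalize_number(row["b_prop"]),
            b_Qb=_normalize_number(row["b_Qb"]),
            b_t=_normalize_number(row["b_t"]),
            b_propQb=_normalize_number(row["b_propQb"]),
            b_propT=_normalize_number(row["b_propT"]),
            b_QbT=_normalize_number(row["b_QbT"]),
            prop_sign=row["prop_sign"],
        )
        key = (cs.family, cs.biomarker)
        if key in table:
            raise ValueError(f"duplicate coefficient set for {key}")
        table[key] = cs
    if len(table) != 40:
        raise ValueError(f"expected 40 coefficient sets, got {len(table)}")
    return table


@lru_cache(maxsize=1)
def coefficient_table() -> dict[tuple[PredictorFamily, Biomarker], CoefficientSet]:
    """The packaged table of all 40 coefficient sets, keyed by (family, biomarker)."""
    text = resources.files("hdbiocompat.data").joinpath("coefficients.csv").read_text()
    return parse_coefficient_csv(text)


def get_coefficients(family: PredictorFamily, biomarker: Biomarker) -> CoefficientSet:
    try:
        return coefficient_table()[(PredictorFamily(family), Biomarker(biomarker))]
    except KeyError as err:
        raise KeyError(f"no equation for family={family}, biomarker={biomarker}") from err


def predict_base(
    cs: CoefficientSet, m: MembraneProperties, oc: OperatingConditions
) -> Concentration:
    """Evaluate one base equation for a membrane at given operating conditions.

    The result carries applicability-range warnings (the prediction is still
    computed: the calibration itself evaluates boundary conditions such as
    Qb = 0) and a warning whenever the predicted concentration is negative.
    """
    prop = m.property_value(FAMILY_PROPERTY[cs.family])
    value = cs.evaluate(prop, oc.Qb, oc.t)
    warnings = [
        f"range: {v}" for v in check_applicability(m, EXPANDED_MODEL_RANGE)
    ]
    if value < 0:
        warnings.append(
            f"negative predicted concentration {value:.4G} pg/mL for "
            f"{cs.biomarker.value} (eq {cs.equation_id}); linear extrapolation"
        )
    return Concentration(value=value, warnings=warnings)


def predict_panel(
    family: PredictorFamily, m: MembraneProperties, oc: OperatingConditions
) -> dict[Biomarker, Concentration]:
    """Predict all eight biomarkers with one family's equations."""
    family = PredictorFamily(family)
    return {
        b: predict_base(get_coefficients(family, b), m, oc) for b in Biomarker
    }
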