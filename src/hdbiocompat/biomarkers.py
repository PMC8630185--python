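"""Closed enumerations for the biomarker panel and the predictor families."""

from __future__ import annotations

import enum


class Biomarker(str, enum.Enum):
    """The eight inflammatory biomarkers modelled, all in pg/mL.

    C5a, C5b-9 and properdin track complement activation; serpin
    (antithrombin-III) coagulation; IL-1alpha, IL-1beta and IL-6 are
    pro-inflammatory cytokines; vWF (von Willebrand factor) marks
    thrombosis/hemolysis.
    """

    C5a = "C5a"
    properdin = "properdin"
    C5b9 = "C5b9"
    serpin = "serpin"
    IL1beta = "IL1beta"
    IL1alpha = "IL1alpha"
    IL6 = "IL6"
    vWF = "vWF"


class PredictorFamily(str, enum.Enum):
    """Which membrane property a model family uses as its third factor.

    Each biomarker has one equation per family; within the calibrated
    property range the five families agree to within a few percent, so a
    membrane characterised by any one property can be scored.
    """

    pore_size = "pore_size"  # Dp, nm
    roughness = "roughness"  # Ra, nm
    sulfur = "sulfur"        # %S
    zeta = "zeta"            # zeta potential, mV
    affinity = "affinity"    # docking affinity to fibrinogen K, kcal/mol


#: CLI / table aliases for the families.
FAMILY_ALIASES = {
    "Dp": PredictorFamily.pore_size,
    "Ra": PredictorFamily.roughness,
    "S": PredictorFamily.sulfur,
    "%S": PredictorFamily.sulfur,
    "zeta": PredictorFamily.zeta,
    "K": PredictorFamily.affinity,
}


def resolve_family(name: str) -> PredictorFamily:
    """Resolve a family from its enum value or a property alias (Dp, Ra, ...)."""
    if name in FAMILY_ALIASES:
        return FAMILY_ALIASES[name]
    return PredictorFamily(name)
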