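"""Expanded models: range-keyed additive correction factors.

Two correction schemes extend the base equations:

* hydrodynamic factors (phi_E), keyed on treatment time {30, 90, 240} min
  and a blood-flow-rate bin between 200 and 500 mL/min, extend the flow/time
  range for the two calibration membranes;
* material factors (phi_M), keyed on conjunctive intervals of all five
  membrane properties, extend the model to other membrane chemistries but
  only describe static incubation, so they force Qb = 0 and t = 30 min.

The two schemes are mutually exclusive, and a zero correction restores the
base model exactly. Offsets are stored verbatim as published; cells whose
column assignment is typographically ambiguous in the source are flagged
unverified in the packaged data and surfaced as warnings.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .biomarkers import Biomarker
from .equations import CoefficientSet, Concentration, predict_base
from .membranes import MembraneProperties, OperatingConditions


class CorrectionMode(str, enum.Enum):
    none = "none"
    hydrodynamic = "hydrodynamic"
    material = "material"


class CorrectionLookupError(KeyError):
    """No correction row matches the requested conditions/membrane."""


class UnsupportedBiomarkerError(KeyError):
    """The correction table has no column for the requested biomarker."""


@dataclass(frozen=True)
class Interval:
    lo: float
    lo_open: bool
    hi: float
    hi_open: bool

    def contains(self, x: float) -> bool:
        above = x > self.lo if self.lo_open else x >= self.lo
        below = x < self.hi if self.hi_open else x <= self.hi
        return above and below

    def __str__(self) -> str:
        return f"{'(' if self.lo_open else '['}{self.lo}, {self.hi}{')' if self.hi_open else ']'}"


@dataclass(frozen=True)
class HydroCorrectionEntry:
    t_point: float                       # min; one of 30, 90, 240
    Qb_interval: Interval                # mL/min
    phi: dict[Biomarker, float]          # pg/mL offsets, all 8 biomarkers
    unverified: frozenset[Biomarker] = field(default_factory=frozenset)


@dataclass(frozen=True)
class MaterialCorrectionEntry:
    row: int
    S_range: Interval
    K_range: Interval
    Ra_range: Interval
    zeta_range: Interval
    Dp_range: Interval
    phi: dict[Biomarker, float]          # 7 biomarkers; vWF absent
    verified: bool = True

    def matches(self, m: MembraneProperties) -> bool:
        return (
            self.S_range.contains(m.sulfur_pct)
            and self.K_range.contains(m.K)
            and self.Ra_range.contains(m.Ra)
            and self.zeta_range.contains(m.zeta)
            and self.Dp_range.contains(m.Dp)
        )


def _bool(s: str) -> bool:
    return s.strip().lower() == "true"


@lru_cache(maxsize=1)
def hydro_table() -> tuple[HydroCorrectionEntry, ...]:
    """The nine hydrodynamic correction rows, tiling {30,90,240} x (200,500)."""
    text = resources.files("hdbiocompat.data").joinpath("phi_E.csv").read_text()
    entries = []
    for row in csv.DictReader(io.StringIO(text)):
        phi = {b: float(row[b.value]) for b in Biomarker}
        unv = frozenset(
            Biomarker(x) for x in (row.get("unverified_cells") or "").split(";") if x
        )
        entries.append(
            HydroCorrectionEntry(
                t_point=float(row["t_min"]),
                Qb_interval=Interval(
                    float(row["Qb_lo"]), _bool(row["Qb_lo_open"]),
                    float(row["Qb_hi"]), _bool(row["Qb_hi_open"]),
                ),
                phi=phi,
                unverified=unv,
            )
        )
    return tuple(entries)


@lru_cache(maxsize=1)
def material_table() -> tuple[MaterialCorrectionEntry, ...]:
    """The four material correction rows (no vWF column)."""
    text = resources.files("hdbiocompat.data").joinpath("phi_M.csv").read_text()
    entries = []
    for row in csv.DictReader(io.StringIO(text)):
        phi = {b: float(row[b.value]) for b in Biomarker if b is not Biomarker.vWF}

        def iv(prefix: str) -> Interval:
            return Interval(
                float(row[f"{prefix}_lo"]), _bool(row[f"{prefix}_lo_open"]),
                float(row[f"{prefix}_hi"]), _bool(row[f"{prefix}_hi_open"]),
            )

        entries.append(
            MaterialCorrectionEntry(
                row=int(row["row"]),
                S_range=iv("S"),
                K_range=iv("K"),
                Ra_range=iv("Ra"),
                zeta_range=iv("zeta"),
                Dp_range=iv("Dp"),
                phi=phi,
                verified=_bool(row["verified"]),
            )
        )
    return tuple(entries)


_T_POINTS = (30.0, 90.0, 240.0)


def lookup_phi_E(oc: OperatingConditions, b: Biomarker) -> float:
    """Hydrodynamic offset (pg/mL) for the row matching (t, Qb).

    t must be one of the tabled time points and Qb inside (200, 500) per the
    published bin inequalities; anything else raises a lookup error naming
    the valid grid.
    """
    b = Biomarker(b)
    if oc.t not in _T_POINTS:
        raise CorrectionLookupError(
            f"t={oc.t} min not on the correction grid; tabled times: {_T_POINTS}"
        )
    for entry in hydro_table():
        if entry.t_point == oc.t and entry.Qb_interval.contains(oc.Qb):
            return entry.phi[b]
    bins = sorted({str(e.Qb_interval) for e in hydro_table()})
    raise CorrectionLookupError(
        f"Qb={oc.Qb} mL/min outside the correction grid at t={oc.t}; Qb bins: {bins}"
    )


def lookup_phi_M(m: MembraneProperties, b: Biomarker) -> float:
    """Material offset (pg/mL) from the first row matching all five property intervals.

    vWF has no material correction column. If several rows match with
    different offsets the ambiguity is reported in the raised error text of
    :func:`material_matches`; here the first match wins (documented contract).
    """
    b = Biomarker(b)
    if b is Biomarker.vWF:
        raise UnsupportedBiomarkerError(
            "vWF has no material correction factor (column absent from the table)"
        )
    matches = [e for e in material_table() if e.matches(m)]
    if not matches:
        raise CorrectionLookupError(
            f"membrane {m.name!r} matches no material correction row on all five "
            "property intervals"
        )
    return matches[0].phi[b]


def material_matches(m: MembraneProperties) -> list[MaterialCorrectionEntry]:
    """All material rows matching a membrane (the rows are not mutually exclusive)."""
    return [e for e in material_table() if e.matches(m)]


def predict_expanded(
    cs: CoefficientSet,
    m: MembraneProperties,
    oc: OperatingConditions,
    mode: CorrectionMode = CorrectionMode.none,
) -> Concentration:
    """Base prediction plus the looked-up correction offset.

    ``none`` is the identity (offset 0). ``material`` is only defined for the
    incubation condition and raises unless Qb = 0 and t = 30 min.
    """
    mode = CorrectionMode(mode)
    base = predict_base(cs, m, oc)
    if mode is CorrectionMode.none:
        return base
    if mode is CorrectionMode.hydrodynamic:
        offset = lookup_phi_E(oc, cs.biomarker)
    else:
        if oc.Qb != 0 or oc.t != 30:
            raise ValueError(
                f"material correction is calibrated for incubation (Qb=0, t=30 min); "
                f"got Qb={oc.Qb}, t={oc.t}"
            )
        offset = lookup_phi_M(m, cs.biomarker)
        ambiguous = material_matches(m)
        if len(ambiguous) > 1:
            offs = {e.row: e.phi[cs.biomarker] for e in ambiguous}
            if len(set(offs.values())) > 1:
                base.warnings.append(
                    f"ambiguous material correction rows {sorted(offs)} with offsets "
                    f"{offs}; first match (row {ambiguous[0].row}) used"
                )
    value = base.value + offset
    warnings = list(base.warnings) + [f"correction mode: {mode.value}, offset {offset:+.4G} pg/mL"]
    if value < 0 and base.value >= 0:
        warnings.append(f"negative corrected concentration {value:.4G} pg/mL")
    return Concentration(value=value, warnings=warnings)
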