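"""Membrane property records, built-in clinical membranes, range checking.

A membrane is described by five descriptors: pore size Dp (nm), average
surface roughness Ra (nm), elemental sulfur abundance %S, surface zeta
potential (mV, signed) and docking affinity to fibrinogen K (kcal/mol,
signed, more negative = stronger adsorption tendency). The built-in records
are the two clinical dialyzer chemistries the models were calibrated on:
cellulose triacetate (CTA) and polyarylethersulfone-polyvinylpyrrolidone
(PAES-PVP).
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable

_CSV_HEADER = ["name", "Dp_nm", "Ra_nm", "S_pct", "zeta_mV", "K_kcalmol"]


@dataclass(frozen=True)
class MembraneProperties:
    """One membrane's five descriptors.

    ``K_derived`` marks records whose affinity constant was fixed from the
    calibrated applicability interval rather than printed directly.
    """

    name: str
    Dp: float          # pore size, nm
    Ra: float          # average roughness, nm
    sulfur_pct: float  # elemental sulfur, %
    zeta: float        # zeta potential, mV (signed)
    K: float           # affinity to fibrinogen, kcal/mol (signed, <= 0)
    K_derived: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        # NaN marks an unknown property; the families needing it are skipped
        if not (math.isnan(self.Dp) or self.Dp > 0):
            raise ValueError(f"Dp must be positive, got {self.Dp}")
        if not (math.isnan(self.Ra) or self.Ra > 0):
            raise ValueError(f"Ra must be positive, got {self.Ra}")
        if not (math.isnan(self.sulfur_pct) or 0 <= self.sulfur_pct <= 100):
            raise ValueError(f"sulfur_pct must be in [0, 100], got {self.sulfur_pct}")
        if self.K > 0:
            raise ValueError(f"K is a binding energy and must be <= 0, got {self.K}")

    def property_value(self, attr: str) -> float:
        """Return one of the five descriptors by short name (Dp, Ra, S, zeta, K)."""
        return {
            "Dp": self.Dp,
            "Ra": self.Ra,
            "S": self.sulfur_pct,
            "zeta": self.zeta,
            "K": self.K,
        }[attr]

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "Dp_nm": self.Dp,
                "Ra_nm": self.Ra,
                "S_pct": self.sulfur_pct,
                "zeta_mV": self.zeta,
                "K_kcalmol": self.K,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MembraneProperties":
        d = json.loads(text)
        return cls(
            name=d["name"],
            Dp=d["Dp_nm"],
            Ra=d["Ra_nm"],
            sulfur_pct=d["S_pct"],
            zeta=d["zeta_mV"],
            K=d["K_kcalmol"],
        )


@dataclass(frozen=True)
class OperatingConditions:
    """Clinical operating conditions: blood flow rate and contact time."""

    Qb: float  # blood flow rate, mL/min
    t: float   # treatment (contact) time, min

    def __post_init__(self) -> None:
        if self.Qb < 0:
            raise ValueError(f"Qb must be >= 0, got {self.Qb}")
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")


@dataclass(frozen=True)
class ApplicabilityRange:
    """Open intervals of membrane properties inside which the models are calibrated."""

    Dp_lo: float
    Dp_hi: float
    Ra_lo: float
    Ra_hi: float
    zeta_lo: float
    zeta_hi: float
    S_lo: float
    S_hi: float
    K_lo: float
    K_hi: float

    def __post_init__(self) -> None:
        for prop in ("Dp", "Ra", "zeta", "S", "K"):
            lo = getattr(self, f"{prop}_lo")
            hi = getattr(self, f"{prop}_hi")
            if not lo < hi:
                raise ValueError(f"{prop}: lower bound {lo} must be < upper bound {hi}")


#: Calibrated property ranges of the expanded flow/time model.
EXPANDED_MODEL_RANGE = ApplicabilityRange(
    Dp_lo=0.851, Dp_hi=8.24,
    Ra_lo=5.4, Ra_hi=10.4,
    zeta_lo=-68.0, zeta_hi=-34.0,
    S_lo=0.0, S_hi=3.83,
    K_lo=-6.0, K_hi=-5.3,
)


def _parse_rows(rows: Iterable[dict]) -> list[MembraneProperties]:
    out = []
    for row in rows:
        out.append(
            MembraneProperties(
                name=row["name"],
                Dp=float(row["Dp_nm"]),
                Ra=float(row["Ra_nm"]),
                sulfur_pct=float(row["S_pct"]),
                zeta=float(row["zeta_mV"]),
                K=float(row["K_kcalmol"]),
                K_derived=str(row.get("K_derived", "false")).lower() == "true",
            )
        )
    return out


def read_membranes_csv(text: str) -> list[MembraneProperties]:
    """Parse membrane records from the CSV dialect ``name,Dp_nm,Ra_nm,S_pct,zeta_mV,K_kcalmol``."""
    return _parse_rows(csv.DictReader(io.StringIO(text)))


def write_membranes_csv(membranes: Iterable[MembraneProperties]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(_CSV_HEADER)
    for m in membranes:
        w.writerow([m.name, repr(m.Dp), repr(m.Ra), repr(m.sulfur_pct), repr(m.zeta), repr(m.K)])
    return buf.getvalue()


def builtin_membranes() -> dict[str, MembraneProperties]:
    """The packaged clinical membrane records, keyed by name.

    CTA: Dp 0.851 nm, Ra 5.4 nm, 0 %S, zeta -38 mV, K -5.3 kcal/mol.
    PAES-PVP: Dp 8.24 nm, Ra 10.4 nm, 3.83 %S, zeta -64 mV, K -6.0 kcal/mol.
    Both K values are the endpoints of the calibrated affinity interval and
    are flagged ``K_derived``.
    """
    text = resources.files("hdbiocompat.data").joinpath("membranes.csv").read_text()
    return {m.name: m for m in read_membranes_csv(text)}


def get_membrane(name: str) -> MembraneProperties:
    """Look up a built-in membrane by name (case-insensitive, 'PAES' resolves to PAES-PVP)."""
    reg = builtin_membranes()
    if name in reg:
        return reg[name]
    folded = {k.lower(): v for k, v in reg.items()}
    key = name.lower()
    if key in folded:
        return folded[key]
    if key in ("paes", "paes-pvp", "paes_pvp"):
        return reg["PAES-PVP"]
    raise KeyError(f"unknown membrane {name!r}; built-ins: {sorted(reg)}")


def check_applicability(
    m: MembraneProperties, r: ApplicabilityRange = EXPANDED_MODEL_RANGE
) -> list[str]:
    """Return violation descriptors for properties not strictly inside the range.

    Empty list iff every property lies strictly inside its open interval.
    A value sitting exactly on a bound is reported as a boundary violation;
    checking never raises.
    """
    violations = []
    for prop, value in (
        ("Dp", m.Dp),
        ("Ra", m.Ra),
        ("zeta", m.zeta),
        ("S", m.sulfur_pct),
        ("K", m.K),
    ):
        lo = getattr(r, f"{prop}_lo")
        hi = getattr(r, f"{prop}_hi")
        if value <= lo:
            kind = "boundary" if value == lo else "outside"
            violations.append(
                f"{prop}={value} {kind}: not strictly above lower bound {prop}_lo={lo}"
            )
        elif value >= hi:
            kind = "boundary" if value == hi else "outside"
            violations.append(
                f"{prop}={value} {kind}: not strictly below upper bound {prop}_hi={hi}"
            )
    return violations
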