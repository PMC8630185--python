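"""Synthetic 2^3-design responses with controllable truth and noise.

The clinical serum measurements behind the published equations are not
publicly available, so the fitting and validation pipelines are exercised
on synthetic designs: a known linear-with-interaction truth (typically one
of the 40 shipped coefficient sets) evaluated at the eight corners of a
2^3 design, plus i.i.d. Gaussian noise. Identical seeds give identical
datasets (NumPy default_rng, generator version noted in the methods note).

Default factor levels reconstruct the study conditions: the membrane
property spans the two clinical membranes (CTA low, PAES-PVP high), the
blood flow rate spans 0-300 mL/min and the contact time 0-30 min — the
static-incubation and early-session conditions of the calibration data.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .biomarkers import Biomarker
from .equations import FAMILY_PROPERTY, CoefficientSet
from .factorial import FactorialDesign
from .membranes import builtin_membranes

#: low/high Qb and t levels of the reconstructed calibration design
DEFAULT_QB_LEVELS = (0.0, 300.0)
DEFAULT_T_LEVELS = (0.0, 30.0)


def default_property_levels(cs: CoefficientSet) -> tuple[float, float]:
    """CTA/PAES-PVP values of the family's property, ordered low < high."""
    reg = builtin_membranes()
    attr = FAMILY_PROPERTY[cs.family]
    vals = sorted(m.property_value(attr) for m in reg.values())
    return (vals[0], vals[-1])


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic 2^3 design.

    ``noise_sd`` is an absolute standard deviation in pg/mL unless
    ``noise_mode='fraction_of_span'``, in which case it is a fraction of the
    noise-free corner-response span.
    """

    truth: CoefficientSet
    levels_A: tuple[float, float] | None = None  # defaults to CTA/PAES property values
    levels_B: tuple[float, float] = DEFAULT_QB_LEVELS
    levels_C: tuple[float, float] = DEFAULT_T_LEVELS
    replicates: int = 3
    noise_sd: float = 0.0
    noise_mode: str = "absolute"  # 'absolute' | 'fraction_of_span'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_mode not in ("absolute", "fraction_of_span"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")


def _truth_value(cs: CoefficientSet, prop: float, Qb: float, t: float) -> float:
    # the generator realises the raw polynomial; sign conventions are an
    # evaluation-time concern of the membrane pathway, not of the truth model
    return (
        cs.intercept
        + cs.b_prop * prop
        + cs.b_Qb * Qb
        + cs.b_t * t
        + cs.b_propQb * prop * Qb
        + cs.b_propT * prop * t
        + cs.b_QbT * Qb * t
    )


def generate_design(spec: SyntheticSpec) -> FactorialDesign:
    """Realise a 2^3 design from the spec's truth, levels, replicates and noise."""
    levels_A = spec.levels_A or default_property_levels(spec.truth)
    for name, (lo, hi) in (("A", levels_A), ("B", spec.levels_B), ("C", spec.levels_C)):
        if lo == hi:
            raise ValueError(f"degenerate levels for factor {name}: {lo}")
    lows = (levels_A[0], spec.levels_B[0], spec.levels_C[0])
    highs = (levels_A[1], spec.levels_B[1], spec.levels_C[1])

    corners = list(itertools.product((-1, 1), repeat=3))
    clean = {}
    for corner in corners:
        actual = [
            lows[i] if corner[i] == -1 else highs[i] for i in range(3)
        ]
        clean[corner] = _truth_value(spec.truth, *actual)

    if spec.noise_mode == "fraction_of_span":
        span = max(clean.values()) - min(clean.values())
        sd = spec.noise_sd * span
    else:
        sd = spec.noise_sd

    rng = np.random.default_rng(spec.seed)
    runs = {}
    for corner in corners:
        noise = rng.normal(0.0, sd, size=spec.replicates) if sd > 0 else np.zeros(spec.replicates)
        runs[corner] = list(clean[corner] + noise)

    attr = FAMILY_PROPERTY[spec.truth.family]
    return FactorialDesign(
        factor_names=(attr, "Qb", "t"),
        lows=lows,
        highs=highs,
        runs=runs,
    )


def design_to_csv(d: FactorialDesign) -> str:
    """Long-format CSV dialect ``A,B,C,replicate,response`` (coded levels)."""
    lines = ["A,B,C,replicate,response"]
    for corner in sorted(d.runs):
        for i, resp in enumerate(d.runs[corner], start=1):
            lines.append(f"{corner[0]},{corner[1]},{corner[2]},{i},{float(resp)!r}")
    return "\n".join(lines) + "\n"


def design_from_csv(text: str, factor_names, lows, highs) -> FactorialDesign:
    runs: dict[tuple[int, int, int], list[float]] = {}
    df = pd.read_csv(pd.io.common.StringIO(text))
    for _, row in df.iterrows():
        corner = (int(row["A"]), int(row["B"]), int(row["C"]))
        runs.setdefault(corner, []).append(float(row["response"]))
    return FactorialDesign(
        factor_names=tuple(factor_names), lows=tuple(lows), highs=tuple(highs), runs=runs
    )


_FIXTURE_SHA256 = {
    # frozen checksums of the packaged validation tables; mismatches mean
    # the installed data files are corrupted
    "table3.csv": "589dbcba7b9cc0ac1a7949f11227df7e3799d8e7c709bff4e64e28c820738568",
    "table4.csv": "7527a0a2f02a722c187e61f1a1b915f47188aa5ef44e74170466358f93179d16",
}


def _read_fixture(name: str) -> pd.DataFrame:
    raw = resources.files("hdbiocompat.data").joinpath(name).read_bytes()
    expected = _FIXTURE_SHA256.get(name)
    if expected is not None:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != expected:
            raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    df = pd.read_csv(pd.io.common.BytesIO(raw))
    df["biomarker"] = df["biomarker"].map(Biomarker)
    return df


def load_paper_fixtures() -> dict[str, pd.DataFrame]:
    """The transcribed predicted/actual validation tables with confidence flags.

    ``table3``: 16 expanded-condition rows x 8 biomarkers (128 records);
    ``table4``: 6 membrane materials x 7 biomarkers (42 incubation records).
    """
    t3 = _read_fixture("table3.csv")
    t4 = _read_fixture("table4.csv")
    if len(t3) != 128 or len(t4) != 42:
        raise ValueError(
            f"fixture row counts wrong: table3 {len(t3)} (want 128), table4 {len(t4)} (want 42)"
        )
    return {"table3": t3, "table4": t4}


def fixture_records(df: pd.DataFrame):
    """Convert a fixture DataFrame into ValidationRecord objects."""
    from .validation import ValidationRecord

    return [
        ValidationRecord(
            biomarker=row.biomarker,
            membrane=row.membrane,
            Qb=float(row.Qb),
            t=float(row.t),
            predicted=float(row.predicted),
            actual=float(row.actual),
            printed_pct_error=float(row.pct_error),
            transcription_confidence=row.transcription_confidence,
        )
        for row in df.itertuples()
    ]
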