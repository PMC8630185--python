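"""Two-level three-factor (2^3) factorial design modelling.

The prediction equations derive from replicated 2^3 designs: factor A is a
membrane property, B the blood flow rate Qb and C the treatment time t,
each at a low and a high actual level. This module estimates factor
effects from the eight corner means, fits a hierarchical regression by
greedy forward selection with single-step F-tests, converts coded (-1/+1)
coefficients to actual-unit coefficients by algebraic expansion, and
reports the standard design-of-experiments diagnostics (R^2, adjusted R^2,
adequate precision).

Terms are named Intercept, A, B, C, AB, AC, BC. The three-factor
interaction ABC is excluded from the candidate pool (sparsity-of-effects
policy); with a single replicate per corner it can instead serve as the
error-estimation term.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

MAIN_TERMS = ("A", "B", "C")
INTERACTION_TERMS = ("AB", "AC", "BC")
CANDIDATE_TERMS = MAIN_TERMS + INTERACTION_TERMS

#: relative SSE below which a fit is treated as exact (stops selection)
_EXACT_FIT_RTOL = 1e-12


class IncompleteDesignError(ValueError):
    """A 2^3 design is missing one or more corner runs."""


def _term_factors(term: str) -> tuple[int, ...]:
    return tuple("ABC".index(ch) for ch in term)


@dataclass(frozen=True)
class FactorialDesign:
    """A full 2^3 design: factor levels and replicated corner responses.

    ``runs`` maps each coded corner (levels in {-1, +1} for A, B, C) to its
    list of replicate responses in pg/mL.
    """

    factor_names: tuple[str, str, str]
    lows: tuple[float, float, float]   # actual level coded -1, per factor
    highs: tuple[float, float, float]  # actual level coded +1, per factor
    runs: Mapping[tuple[int, int, int], Sequence[float]]

    def __post_init__(self) -> None:
        corners = set(itertools.product((-1, 1), repeat=3))
        missing = corners - set(self.runs)
        if missing:
            raise IncompleteDesignError(f"missing corner runs: {sorted(missing)}")
        extra = set(self.runs) - corners
        if extra:
            raise IncompleteDesignError(f"non-corner runs present: {sorted(extra)}")
        for corner, ys in self.runs.items():
            if len(ys) < 1:
                raise IncompleteDesignError(f"corner {corner} has no replicates")
        for i in range(3):
            if self.lows[i] == self.highs[i]:
                raise ValueError(
                    f"factor {self.factor_names[i]}: low and high levels coincide "
                    f"({self.lows[i]})"
                )

    @property
    def n_obs(self) -> int:
        return sum(len(v) for v in self.runs.values())

    def corner_means(self) -> dict[tuple[int, int, int], float]:
        return {c: float(np.mean(ys)) for c, ys in self.runs.items()}

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Long format: coded design rows (n_obs, 3) and responses (n_obs,)."""
        X, y = [], []
        for corner in sorted(self.runs):
            for resp in self.runs[corner]:
                X.append(corner)
                y.append(resp)
        return np.asarray(X, dtype=float), np.asarray(y, dtype=float)

    def centers(self) -> tuple[float, float, float]:
        return tuple((lo + hi) / 2 for lo, hi in zip(self.lows, self.highs))

    def half_ranges(self) -> tuple[float, float, float]:
        return tuple((hi - lo) / 2 for lo, hi in zip(self.lows, self.highs))


def estimate_effects(d: FactorialDesign) -> dict[str, float]:
    """Classic contrast-based effect estimates from the eight corner means.

    The main effect of a factor is the mean response at its high level minus
    the mean at its low level; a two-factor interaction effect is half the
    difference between the effect of one factor at the two levels of the
    other. Both reduce to signed corner contrasts divided by 4. The
    three-factor contrast is excluded by policy. ``Intercept`` is the grand
    mean of corner means.
    """
    means = d.corner_means()
    effects: dict[str, float] = {
        "Intercept": sum(means.values()) / 8.0,
    }
    for term in CANDIDATE_TERMS:
        factors = _term_factors(term)
        contrast = 0.0
        for corner, ybar in means.items():
            sign = 1
            for f in factors:
                sign *= corner[f]
            contrast += sign * ybar
        effects[term] = contrast / 4.0
    return effects


def _design_matrix(X_coded: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(X_coded))]
    for term in terms:
        col = np.ones(len(X_coded))
        for f in _term_factors(term):
            col = col * X_coded[:, f]
        cols.append(col)
    return np.column_stack(cols)


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


@dataclass
class FactorialFit:
    """A fitted hierarchical 2^3 model in coded and actual units."""

    factor_names: tuple[str, str, str]
    selected_terms: tuple[str, ...]            # excludes Intercept
    hierarchy_forced: tuple[str, ...]
    coded_coefficients: dict[str, float]       # includes Intercept
    actual_coefficients: dict[str, float]
    R2: float
    adj_R2: float
    adequate_precision: float
    term_p_values: dict[str, float]            # selection-step p-values
    warnings: list[str] = field(default_factory=list)

    def predict_coded(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.full(len(x), self.coded_coefficients["Intercept"])
        for term in self.selected_terms:
            col = np.ones(len(x))
            for f in _term_factors(term):
                col = col * x[:, f]
            out = out + self.coded_coefficients[term] * col
        return out

    def predict_actual(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(len(X), self.actual_coefficients.get("Intercept", 0.0))
        for term, coef in self.actual_coefficients.items():
            if term == "Intercept":
                continue
            col = np.ones(len(X))
            for f in _term_factors(term):
                col = col * X[:, f]
            out = out + coef * col
        return out


def fit_forward(d: FactorialDesign, alpha: float = 0.05) -> FactorialFit:
    """Greedy forward selection by F-test, then hierarchy enforcement.

    Starting from the intercept-only model, at each step the candidate term
    whose single-step F-to-enter (judged against the saturated candidate
    model's residual mean square, which pools replicate error and lack of
    fit) has the smallest p-value is entered while p < alpha (ties broken
    in the fixed order A, B, C, AB, AC, BC). Once selection stops, any selected interaction
    pulls in its parent main effects, flagged ``hierarchy_forced``. The
    final coefficients come from least squares on the selected coded design
    matrix.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    X_coded, y = d.to_arrays()
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))
    warnings: list[str] = []
    if alpha == 1.0:
        warnings.append("alpha = 1: every candidate term enters (saturated-candidate fit)")

    # Error estimate for the entry tests: residual mean square of the
    # saturated candidate model (intercept + all six candidates). It pools
    # pure replicate error with any lack of fit, so a candidate's F-to-enter
    # is judged against noise rather than against signal still missing from
    # the current model (testing against the current residual is
    # inconsistent: strong terms mask each other and selection stalls).
    _, sse_sat = _sse(_design_matrix(X_coded, list(CANDIDATE_TERMS)), y)
    df_sat = n - (len(CANDIDATE_TERMS) + 1)
    exact = sst > 0 and (df_sat <= 0 or sse_sat <= _EXACT_FIT_RTOL * sst)
    mse_err = sse_sat / df_sat if df_sat > 0 else math.nan

    selected: list[str] = []
    p_values: dict[str, float] = {}
    _, sse_cur = _sse(_design_matrix(X_coded, selected), y)
    while True:
        remaining = [t for t in CANDIDATE_TERMS if t not in selected]
        if not remaining:
            break
        if sst > 0 and sse_cur <= _EXACT_FIT_RTOL * sst:
            break  # exact fit; nothing left to explain
        best_term, best_p = None, math.inf
        for term in remaining:
            _, sse_new = _sse(_design_matrix(X_coded, selected + [term]), y)
            delta = sse_cur - sse_new
            if delta <= _EXACT_FIT_RTOL * max(sst, 1.0):
                p = 1.0
            elif exact:
                p = 0.0  # real reduction against an exact-fit error of zero
            else:
                F = delta / mse_err
                p = float(stats.f.sf(F, 1, df_sat))
            if p < best_p:
                best_term, best_p = term, p
        if best_term is None or not (best_p < alpha or (alpha == 1.0 and best_p < math.inf)):
            break
        p_values[best_term] = best_p
        selected.append(best_term)
        _, sse_cur = _sse(_design_matrix(X_coded, selected), y)

    # hierarchy: parents of any selected interaction are force-included
    forced: list[str] = []
    for term in list(selected):
        for parent in term:
            if len(term) > 1 and parent not in selected:
                selected.append(parent)
                forced.append(parent)
    selected = [t for t in CANDIDATE_TERMS if t in selected]  # canonical order
    forced_t = tuple(t for t in selected if t in forced)

    Xd = _design_matrix(X_coded, selected)
    beta, sse = _sse(Xd, y)
    p_params = Xd.shape[1]
    df_e = n - p_params
    coded = {"Intercept": float(beta[0])}
    coded.update({t: float(b) for t, b in zip(selected, beta[1:])})

    R2 = 1.0 if sst == 0 else 1.0 - sse / sst
    if df_e > 0 and sst > 0:
        adj_R2 = 1.0 - (sse / df_e) / (sst / (n - 1))
        mse = sse / df_e
        fitted = Xd @ beta
        denom = math.sqrt(p_params * mse / n)
        adequate_precision = (
            math.inf if denom == 0 else float((fitted.max() - fitted.min()) / denom)
        )
    else:
        adj_R2 = math.nan
        adequate_precision = math.nan
        warnings.append(
            "zero residual degrees of freedom: saturated fit, "
            "adjusted R^2 and adequate precision unavailable"
        )

    fit = FactorialFit(
        factor_names=d.factor_names,
        selected_terms=tuple(selected),
        hierarchy_forced=forced_t,
        coded_coefficients=coded,
        actual_coefficients={},
        R2=R2,
        adj_R2=adj_R2,
        adequate_precision=adequate_precision,
        term_p_values=p_values,
        warnings=warnings,
    )
    fit.actual_coefficients = coded_to_actual(fit, d)
    return fit


def coded_to_actual(fit: FactorialFit, d: FactorialDesign) -> dict[str, float]:
    """Expand the coded polynomial into actual factor units.

    Substitutes x_i = (X_i - center_i)/half_range_i into every model term
    and expands the products, so the returned coefficient set evaluates
    identically to the coded model everywhere, not only at design corners.
    """
    centers = d.centers()
    halves = d.half_ranges()
    if any(h == 0 for h in halves):
        raise ValueError("degenerate factor: zero half-range")
    # x_i = a_i + b_i * X_i
    a = [-c / h for c, h in zip(centers, halves)]
    b = [1.0 / h for h in halves]

    actual: dict[frozenset, float] = {}
    terms = {"Intercept": fit.coded_coefficients["Intercept"]}
    terms.update({t: fit.coded_coefficients[t] for t in fit.selected_terms})
    for term, coef in terms.items():
        factors = () if term == "Intercept" else _term_factors(term)
        # product over i in factors of (a_i + b_i X_i): expand over subsets
        for r in range(len(factors) + 1):
            for subset in itertools.combinations(factors, r):
                weight = coef
                for f in factors:
                    weight *= b[f] if f in subset else a[f]
                key = frozenset(subset)
                actual[key] = actual.get(key, 0.0) + weight

    def name(key: frozenset) -> str:
        return "Intercept" if not key else "".join("ABC"[i] for i in sorted(key))

    return {name(k): v for k, v in sorted(actual.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))}
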