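import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdbiocompat import (
    Biomarker,
    FactorialDesign,
    PredictorFamily,
    coded_to_actual,
    estimate_effects,
    fit_forward,
    get_coefficients,
)
from hdbiocompat.factorial import (
    CANDIDATE_TERMS,
    IncompleteDesignError,
    _design_matrix,
)
from hdbiocompat.synthetic import SyntheticSpec, generate_design

CORNERS = list(itertools.product((-1, 1), repeat=3))


def make_design(responses, lows=(0, 0, 0), highs=(1, 1, 1), replicates=1):
    runs = {c: [responses[i]] * replicates for i, c in enumerate(CORNERS)}
    return FactorialDesign(("A", "B", "C"), tuple(lows), tuple(highs), runs)


def brute_force_effects(runs):
    """Independent contrast-sum oracle over the eight signed corners."""
    means = {c: float(np.mean(v)) for c, v in runs.items()}
    out = {"Intercept": sum(means.values()) / 8}
    for term, facs in [("A", (0,)), ("B", (1,)), ("C", (2,)),
                       ("AB", (0, 1)), ("AC", (0, 2)), ("BC", (1, 2))]:
        out[term] = sum(
            np.prod([c[f] for f in facs]) * m for c, m in means.items()
        ) / 4
    return out


class TestEstimateEffects:
    def test_constant_response_all_effects_zero(self):
        d = make_design([5.0] * 8)
        effects = estimate_effects(d)
        assert effects["Intercept"] == 5.0
        assert all(effects[t] == 0 for t in CANDIDATE_TERMS)

    def test_pure_main_effect(self):
        d = make_design([2 + 3 * c[0] for c in CORNERS])
        effects = estimate_effects(d)
        assert effects["A"] == pytest.approx(6.0)
        assert all(effects[t] == pytest.approx(0) for t in CANDIDATE_TERMS if t != "A")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ys=st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=8))
    def test_matches_brute_force_oracle(self, ys):
        d = make_design(ys)
        effects = estimate_effects(d)
        oracle = brute_force_effects(d.runs)
        for term, val in oracle.items():
            assert effects[term] == pytest.approx(val, rel=1e-12, abs=1e-9)

    def test_missing_corner_rejected(self):
        runs = {c: [1.0] for c in CORNERS[:-1]}
        with pytest.raises(IncompleteDesignError):
            FactorialDesign(("A", "B", "C"), (0, 0, 0), (1, 1, 1), runs)


class TestFitForward:
    def test_noise_free_truth_recovered_exactly(self):
        # truth: 10 + 2A + 3B - 1.5AB (coded), zero noise
        truth = lambda c: 10 + 2 * c[0] + 3 * c[1] - 1.5 * c[0] * c[1]
        d = make_design([truth(c) for c in CORNERS], lows=(-1, -1, -1), highs=(1, 1, 1))
        fit = fit_forward(d, alpha=0.05)
        assert set(fit.selected_terms) == {"A", "B", "AB"}
        assert fit.coded_coefficients["Intercept"] == pytest.approx(10, rel=1e-9)
        assert fit.coded_coefficients["A"] == pytest.approx(2, rel=1e-9)
        assert fit.coded_coefficients["B"] == pytest.approx(3, rel=1e-9)
        assert fit.coded_coefficients["AB"] == pytest.approx(-1.5, rel=1e-9)

    def test_coded_coefficient_equals_half_effect(self):
        rng = np.random.default_rng(42)
        ys = list(rng.normal(100, 20, 8))
        d = make_design(ys, replicates=2)
        fit = fit_forward(d, alpha=1.0)
        effects = estimate_effects(d)
        for term in fit.selected_terms:
            assert fit.coded_coefficients[term] == pytest.approx(
                effects[term] / 2, rel=1e-9, abs=1e-12
            )

    def test_hierarchy_forced_parents(self):
        # pure interaction truth: only AB carries signal
        d = make_design([5 + 4 * c[0] * c[1] for c in CORNERS], replicates=2)
        fit = fit_forward(d, alpha=0.05)
        assert "AB" in fit.selected_terms
        assert {"A", "B"} <= set(fit.selected_terms)
        assert set(fit.hierarchy_forced) == {"A", "B"}

    def test_saturated_candidate_model_zero_residuals(self):
        rng = np.random.default_rng(3)
        # any response without a three-factor component is fit exactly by
        # intercept + six candidate terms on single-replicate corners
        effects = dict(zip(CANDIDATE_TERMS, rng.normal(0, 5, 6)))
        b0 = float(rng.normal(50))
        ys = [
            b0 + sum(effects[t] * np.prod([c["ABC".index(ch)] for ch in t])
                     for t in CANDIDATE_TERMS)
            for c in CORNERS
        ]
        X = _design_matrix(np.asarray(CORNERS, float), list(CANDIDATE_TERMS))
        beta, *_ = np.linalg.lstsq(X, np.asarray(ys), rcond=None)
        assert np.allclose(X @ beta, ys, atol=1e-8)

    def test_alpha_boundary_saturated_candidates_warns(self):
        rng = np.random.default_rng(11)
        d = make_design(list(rng.normal(10, 2, 8)), replicates=2)
        fit = fit_forward(d, alpha=1.0)
        assert any("saturated-candidate" in w for w in fit.warnings)
        assert set(fit.selected_terms) == set(CANDIDATE_TERMS)

    def test_invalid_alpha_rejected(self):
        d = make_design(list(range(8)))
        with pytest.raises(ValueError, match="alpha"):
            fit_forward(d, alpha=0.0)
        with pytest.raises(ValueError, match="alpha"):
            fit_forward(d, alpha=1.5)

    def test_single_replicate_error_estimated_from_three_factor_contrast(self):
        # with one replicate per corner, the excluded ABC contrast is the
        # only error estimate left; diagnostics stay finite
        rng = np.random.default_rng(5)
        d = make_design(list(rng.normal(100, 30, 8)))
        fit = fit_forward(d, alpha=1.0)
        assert math.isfinite(fit.adj_R2)
        assert fit.R2 < 1.0

    def test_noise_free_adequate_precision_diverges(self):
        truth = lambda c: 5 + 2 * c[0] - c[1] + 0.5 * c[0] * c[2]
        d = make_design([truth(c) for c in CORNERS])
        fit = fit_forward(d, alpha=0.05)
        assert fit.R2 == pytest.approx(1.0)
        assert fit.adequate_precision > 1e6

    def test_true_terms_selected_under_noise(self):
        """Monte Carlo: with 5%-of-span Gaussian noise and 3 replicates the
        generating terms are recovered in at least 90% of repetitions."""
        cs = get_coefficients(PredictorFamily.affinity, Biomarker.C5b9)
        true_terms = {"A", "B", "C", "AB", "BC"}
        hits = 0
        reps = 200
        for seed in range(reps):
            d = generate_design(SyntheticSpec(
                truth=cs, replicates=3, noise_sd=0.05,
                noise_mode="fraction_of_span", seed=seed,
            ))
            fit = fit_forward(d, alpha=0.05)
            hits += true_terms <= set(fit.selected_terms)
        assert hits / reps >= 0.90

    def test_adequate_precision_exceeds_four_for_signal_dominated_fit(self):
        cs = get_coefficients(PredictorFamily.pore_size, Biomarker.vWF)
        d = generate_design(SyntheticSpec(
            truth=cs, replicates=3, noise_sd=0.05,
            noise_mode="fraction_of_span", seed=123,
        ))
        fit = fit_forward(d, alpha=0.05)
        assert fit.adequate_precision > 4


class TestCodedToActual:
    def test_simple_expansion(self):
        # y = 10 + 2x_A with A in [0, 30] -> y = 8 + (2/15) A
        d = make_design([10 + 2 * c[0] for c in CORNERS], lows=(0, 0, 0), highs=(30, 1, 1))
        fit = fit_forward(d, alpha=0.05)
        actual = fit.actual_coefficients
        assert actual["Intercept"] == pytest.approx(8.0, rel=1e-9)
        assert actual["A"] == pytest.approx(2 / 15, rel=1e-9)

    def test_identity_when_levels_are_unit(self):
        ys = [3 + c[0] - 2 * c[1] for c in CORNERS]
        d = make_design(ys, lows=(-1, -1, -1), highs=(1, 1, 1))
        fit = fit_forward(d, alpha=0.05)
        for term in fit.selected_terms:
            assert fit.actual_coefficients[term] == pytest.approx(
                fit.coded_coefficients[term], rel=1e-12
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        coefs=st.lists(st.floats(-100, 100), min_size=7, max_size=7),
        lows=st.lists(st.floats(-50, 40), min_size=3, max_size=3),
        spans=st.lists(st.floats(0.5, 100), min_size=3, max_size=3),
    )
    def test_actual_and_coded_forms_agree_at_random_points(self, coefs, lows, spans):
        highs = [lo + s for lo, s in zip(lows, spans)]
        truth = lambda c: coefs[0] + sum(
            coefs[1 + i] * np.prod([c["ABC".index(ch)] for ch in t])
            for i, t in enumerate(CANDIDATE_TERMS)
        )
        d = make_design([truth(c) for c in CORNERS], lows=lows, highs=highs,
                        replicates=2)
        fit = fit_forward(d, alpha=1.0)
        rng = np.random.default_rng(0)
        x_coded = rng.uniform(-2, 2, size=(100, 3))
        centers = np.asarray(d.centers())
        halves = np.asarray(d.half_ranges())
        X_actual = centers + halves * x_coded
        got_coded = fit.predict_coded(x_coded)
        got_actual = fit.predict_actual(X_actual)
        scale = max(1.0, float(np.max(np.abs(got_coded))))
        assert np.allclose(got_actual, got_coded, atol=1e-7 * scale)

    def test_parameter_recovery_closes_loop_with_shipped_equations(self):
        """Zero-noise designs generated from every one of the 40 shipped
        coefficient sets are refit to the generating terms and values."""
        from hdbiocompat.equations import coefficient_table

        term_of = {"A": "b_prop", "B": "b_Qb", "C": "b_t",
                   "AB": "b_propQb", "AC": "b_propT", "BC": "b_QbT"}
        for cs in coefficient_table().values():
            d = generate_design(SyntheticSpec(truth=cs, replicates=1, noise_sd=0))
            fit = fit_forward(d, alpha=0.05)
            actual = fit.actual_coefficients
            scale = abs(cs.intercept) or 1.0
            assert actual["Intercept"] == pytest.approx(cs.intercept, rel=1e-6), cs.equation_id
            for term, attr in term_of.items():
                true_val = getattr(cs, attr)
                got = actual.get(term, 0.0)
                if true_val != 0:
                    assert got == pytest.approx(true_val, rel=1e-6), (cs.equation_id, term)
                else:
                    assert abs(got) <= 1e-6 * scale, (cs.equation_id, term)

    def test_degenerate_factor_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            make_design(list(range(8)), lows=(0, 0, 0), highs=(0, 1, 1))
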