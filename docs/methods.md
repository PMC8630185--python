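# Methods

## Model form and assumptions

Each of the 40 prediction equations is a first-order polynomial with
two-factor interactions in three factors: one membrane property *p*, the
blood flow rate Qb and the treatment time t. There are no quadratic terms
and no three-factor interaction — the equations come from 2³ factorial
designs, which can only estimate main effects and two-factor interactions,
and the three-factor contrast was reserved by policy to avoid the sparsity
effect. Consequences worth knowing:

* predictions are linear along any ray in (Qb, t) at a fixed membrane, so
  the model extrapolates without bound — negative concentrations occur at
  long times/high flows (e.g. serpin at Qb = 500, t = 90 predicts about
  −5.7×10⁸ pg/mL). These are returned as-is with a warning, never clamped:
  the calibrated validation tables themselves contain negative predictions,
  and clamping would silently change the published arithmetic;
* membranes are characterised by equilibrium surface descriptors only; no
  kinetics, patient physiology or longitudinal dynamics are modelled.

Coefficients are stored verbatim at their printed precision in
`data/coefficients.csv` and never re-derived at runtime. Two exponent
strings in the source typography are read as negative exponents (the
IL-1α Qb·t term 7.9E−5 and the IL-6 ζ·Qb term 6.8E−5): read at face value
(10⁵) those terms would exceed the entire response by orders of magnitude
at ordinary conditions, contradicting every tabulated prediction. The
properdin intercept appears in two variants (1.12×10⁷ and 1.125×10⁷)
across families; 1.125×10⁷ is adopted everywhere because it reproduces the
tabulated properdin predictions (9.95×10⁶ and 1.87×10⁷) several-fold more
closely.

### Sign conventions for ζ and K

Both ζ and K are negative quantities, and the published per-equation
arithmetic is only self-consistent if three equations consume the
*magnitude* of the property (the C5a–ζ, C5a–K and IL-1β–ζ equations) while
the rest consume the signed value. Each coefficient set therefore carries
an explicit `prop_sign` flag. The flags are data, calibrated once against
the tabulated predictions; an audit test asserts that every stored flag
beats the alternative convention at its calibration point. For the IL-6
equations the incubation point cannot discriminate the convention (the
property enters mainly through a property×Qb interaction, which vanishes
at Qb = 0), so the audit uses the Qb = 300 condition.

The C5a affinity equation remains anomalous: under the magnitude
convention it lands ~0.1% from the cross-family value at the calibration
point, but no convention reconciles it with the other four families under
flow. It is excluded from the cross-family consistency check, as are the
IL-1α equations, which under-reproduce the incubation table by 5.5%
(CTA) and 7.4% (PAES-PVP) under their best convention.

## Membrane registry

Built-ins are the two clinical dialyzer chemistries: CTA
(Dp 0.851 nm, Ra 5.4 nm, 0 %S, ζ −38 mV) and PAES-PVP
(Dp 8.24 nm, Ra 10.4 nm, 3.83 %S, ζ −64 mV). Their affinity constants are
not printed in the main calibration source; they are fixed at the endpoints
of the stated applicability interval, K_CTA = −5.3 and K_PAES = −6.0
kcal/mol, and flagged `K_derived`. Back-solving the C5b-9 affinity equation
at the incubation condition against the tabulated predictions (1036.60 and
1302.88 pg/mL) confirms both to four significant figures. Unknown
properties are represented as NaN; consensus simply omits the affected
family with a warning.

Applicability checking is strict-interior against the expanded-model
range (0.851 < Dp < 8.24 nm, 5.4 < Ra < 10.4 nm, −68 < ζ < −34 mV,
0 < %S < 3.83, −6 < K < −5.3 kcal/mol). Range violations warn but never
block: the calibration itself evaluates boundary conditions (Qb = 0), and
the built-in membranes *are* the range endpoints, so they legitimately
produce boundary-grade warnings.

## Correction factors

Offsets are stored exactly as published. Bin boundaries follow the printed
inequalities (Qb = 300 belongs to 200 < Qb ≤ 300; upper bins printed with
strict bounds exclude 500). The material rows are matched conjunctively on
all five property intervals; because the printed rows are not mutually
exclusive in every coordinate, the contract is first-match with an
ambiguity warning when matching rows disagree.

Three data caveats, all flagged in the packaged CSVs rather than silently
resolved: the IL-6/vWF column split in the first hydrodynamic row and the
run-on IL-1β/IL-1α/IL-6 cells in the two 200–300 mL/min rows at t = 90 and
240 min are typographically ambiguous in the source (`unverified_cells`);
and the expanded-condition validation table is reproduced by the *base*
equations with zero offset despite nominally using the hydrodynamic
scheme, so the default correction mode is `none` and corrections are
strictly opt-in.

## Consensus and validation

Percent error is 100·|predicted − actual|/|actual|; the absolute value in
the denominator keeps errors finite and positive for negative predictions,
matching the published >100% error entries. Per-biomarker summaries are
unweighted means over fixture rows. The packaged fixtures transcribe the
two published validation tables (128 expanded-condition records, 42
incubation records) with a `transcription_confidence` flag; cells whose
printed error differs from recomputation by more than 0.15 percentage
points (rounded source predictions) are excluded from hard assertions.
SHA-256 checksums guard the packaged tables against corruption.

## Factorial engine

Effects use the classic contrasts (main effect = difference of corner-mean
averages; interaction = half the difference of conditional effects), which
for an orthogonal 2³ design equal twice the least-squares coded
coefficients — asserted numerically against a brute-force corner-sum
oracle.

Forward selection enters candidates {A, B, C, AB, AC, BC} greedily by
smallest p-value while p < α, ties broken in that fixed order. The entry
F-tests are judged against the residual mean square of the *saturated
candidate model*, which pools pure replicate error with lack of fit. This
is a deliberate design choice: testing against the current model's residual
makes strong terms mask each other (the untested signal inflates the error
estimate), and in the noise-free limit selection stalls entirely, which
would break the zero-noise parameter-recovery guarantee the engine is
tested by. With a single replicate per corner the excluded three-factor
contrast is the only error estimate left and the diagnostics use it; in
the exact-fit regime (residual below 10⁻¹² of total SS) remaining
candidates are judged by whether they reduce residual at all.

After selection, parents of any selected interaction are force-included
and flagged `hierarchy_forced` — hierarchy is enforced, never
discretionary. Coded→actual conversion substitutes
x = (X − center)/half-range into every term and expands the products
symbolically, so the two forms agree everywhere, not only at corners
(property-tested at random off-design points). Adequate precision is
(max fitted − min fitted)/√(p·MSE/n); it diverges for noise-free fits and
exceeds 4 for signal-dominated simulations.

## Synthetic data generator

The generator realises a known truth (typically one of the 40 shipped
coefficient sets, evaluated as a raw polynomial — sign conventions belong
to the membrane pathway, not the truth model) at the eight corners of a 2³
design and adds i.i.d. Gaussian noise, either with an absolute SD in pg/mL
or as a fraction of the noise-free corner span. Defaults reconstruct the
study conditions: the property spans the two clinical membranes (CTA low,
PAES-PVP high), Qb ∈ {0, 300} mL/min, t ∈ {0, 30} min — the incubation and
early-session conditions of the calibration data; the exact levels used in
the original designs are not published, so these are documented
reconstructions. Default replicates = 3, matching triplicate assay
measurement. Randomness is NumPy `default_rng` seeded per spec; identical
seeds give identical datasets.

What the generator does *not* emulate: patient-to-patient variation,
assay-specific (e.g. lognormal or heteroscedastic) error although
concentrations span 10⁰–10⁸ pg/mL, correlation between biomarkers, and
any Qb/t dependence of the noise. Passing recovery tests therefore show
the engine is correct, not that the clinical calibration would replicate;
the published fit statistics (R² of 76.69–99.88%) depend on the raw
patient data, which are unavailable, and are deliberately not asserted.

## Problem sizes and numerics

Test and acceptance runs use desk-scale problems: single- to triple-
replicate 2³ designs (8–24 observations), 200-repetition Monte Carlo for
the noisy term-selection rate, and 10⁴ replicates only for the noise-
variance calibration check. Least squares is `numpy.linalg.lstsq`;
F-distribution tails come from `scipy.stats`. Exact-fit detection uses a
relative 10⁻¹² threshold on SSE/SST. Regression tests against published
concentrations use 1% relative tolerance (printed-rounding absorption),
widened to 8% for the documented IL-1α anomaly only.
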