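# Methods

## The kinetic model

The culture is described macroscopically: no intracellular fluxes, only
bulk concentrations in a perfectly mixed reactor. Growth is a
multiplicative Monod law — glucose and glutamine limit, lactate and
ammonium inhibit — and death is a saturable function of the two
inhibitory metabolites. Substrate consumption couples to growth through
yield coefficients plus growth-independent maintenance; lactate
production is stoichiometrically tied to glucose consumption
(`d[LAC]/dt = -Y_lac/glc * d[GLC]/dt`, an identity the test suite
enforces everywhere); antibody production is growth-decoupled,
maximal as `mu -> 0`. All parameters and their units live in
`KineticParameters` (defaults bundled in `data/table2.yaml`):

| symbol | meaning | default | unit |
|---|---|---|---|
| mu_max | maximum growth rate | 0.039 | 1/h |
| k_d | maximum death rate | 0.004 | 1/h |
| K_glc, K_gln | Monod constants | 1.00, 0.047 | mM |
| K_Ilac, K_Iamm | growth-inhibition constants | 43.0, 6.51 | mM |
| K_Dlac, K_Damm | death-law constants | 45.8, 6.51 | mM |
| Y_X/glc, Y_X/gln | cell yields | 0.357, 0.974 | 1e9 cells/mmol |
| Y_lac/glc, Y_amm/gln | metabolite yields | 0.70, 0.67 | mmol/mmol |
| m_glc, a1, a2 | maintenance | 69.2, 3.2 (1e-12 mmol/cell/h), 2.1 mM |
| r_amm | ammonium removal | 6.3 | 1e-12 mmol/cell/h |
| Q_mAb | specific productivity | 1.51 | 1e-12 g/cell/h |

Canonical units are h, mM, 1e9 cells/L, g/L and L; the per-cell rates
are stored in the table's 1e-12-scaled units and bridged internally
(`PER_CELL_TO_BULK = 1e-3`), so the glucose uptake per unit cell
concentration is `mu/0.357 + 0.0692` mM/h. The display unit E5 cells/mL
(= 0.1e9 cells/L) is exposed through conversion helpers and used by the
offline-assay layer.

**Ammonium balance basis.** The ammonium production term divides
`(mu - mu_d)` by the *glucose* yield `Y_X/glc` in the source equations,
where a glutamine yield would be dimensionally conventional. The
default implements it exactly as written;
`KineticParameters(ammonium_yield_basis="glutamine")` switches the
denominator to `Y_X/gln` for users who read it as a typographical
artifact. Nothing else changes between the two.

**Rate-law domain.** Negative concentrations raise by default; the
integrators opt into clamping at zero because their micro-overshoots
are bounded by solver tolerance. Silent clamping elsewhere would hide
integrator defects.

## Simulation

`simulate` integrates the ODEs with scipy's adaptive LSODA at
rtol 1e-8 / atol 1e-10 (both overridable), splitting the horizon at
bolus feed times. A bolus is an instantaneous perfectly mixed jump:
every species obeys `C' = (C V + C_feed V_feed)/(V + V_feed)`, cells
are diluted (feeds are cell-free). Output rows carry both the pre- and
post-bolus state at the feed instant, so trajectory timestamps are
non-decreasing with exact duplicates at feeds — consumers either handle
the jump or collapse duplicates to the pre-event row (the evaluation
helpers do the latter).

Substrate depletion is event-detected: when glucose, glutamine or
ammonium crosses zero from above, integration stops, the state is
pinned at exactly zero, and its consumption terms are suppressed until
a feed (or net production) lifts it again. Monod factors are zero at
zero anyway; the pinning exists because maintenance terms are not.

The model tracks only viable cells, but the turbidity probe reads total
cells, so the simulator also books dead cells (`dX_d/dt = mu_d X_V`,
lysis rate defaulting to 0) and reports `X_t = X_V + X_d`.
`total_cell_track` reconstructs the same quantity from a stored
trajectory by trapezoid quadrature, as an a-posteriori alternative.

## The synthetic data layer

No measurement data are distributed, so the instrument chain is
emulated from a ground-truth trajectory. The defaults define the study
conditions and were fixed once:

* **Scenario**: 0.3e9 viable cells/L seeded at 98% viability, 30 mM
  glucose, 4 mM glutamine in 1.5 L; daily 75 mL boluses of 250 mM
  glucose / 40 mM glutamine feed from 72 h to 216 h; 240 h horizon.
  Typical of a small-scale CHO fed-batch: glutamine runs out just
  before the first feed, glucose becomes limiting late, lactate climbs
  above 40 mM and viability decays toward 0.90 by harvest.
* **Turbidity**: FAU = gain × X_t × (1 + ε), ε ~ N(0, 0.0075) — the
  probe's stated 0.75% relative error; the Gaussian shape is our
  choice. The gain (25 FAU per 1e9 cells/L) is a free fixture; no
  published value exists. An optional fouling term adds a monotone
  linear drift after a configurable onset, emulating cell accumulation
  in the probe gap.
* **Raman**: each spectrum is a linear mixture of per-analyte
  pure-component spectra (viable cells, glucose, lactate) evaluated at
  the culture state one hold-up lag (0.5 h) before the acquisition
  timestamp, plus a random order-2 polynomial baseline (sd 0.3) and
  iid noise (sd 0.02). The library is synthetic: 4–5 Gaussian peaks per
  analyte at plausible band positions (e.g. 1004 cm⁻¹ phenylalanine for
  cells, 1060/1125 cm⁻¹ ring modes for glucose) with deliberate overlap
  around 1045–1090 cm⁻¹ so that univariate regression would fail but
  the problem stays well-posed for PLS.
* **Offline assays**: two replicates per analyte per sampling time
  (every 12 h), multiplicative noise with CV 5% for hemocytometer
  counts (applied on the E5 cells/mL scale) and 2% for the
  glucose/lactate analyzer.

All generators draw from named substreams of a single root seed and are
bit-reproducible.

What this emulation does *not* capture: real Raman physics
(fluorescence, photobleaching, cosmic rays), bubbles and particles in
the turbidity gap beyond the drift term, matrix effects between
analytes, medium components outside the six model species, and any
pH/DO/temperature dependence. Passing replications therefore
demonstrate that the pipeline is correct and well-conditioned under the
stated noise model — not that these R² values would be attained on an
arbitrary real bioreactor.

## NIPALS PLS

PLS1 with mean-centering (unit-variance scaling optional); for a single
response the NIPALS weight step is closed-form, so the inner-iteration
controls (tol 1e-10, 500 iterations) only guard a future multi-response
extension. Factor count is selected at the minimum cross-validated
RMSE — leave-one-out by default, k-fold with a seeded shuffle
available — with ties broken toward fewer factors (RMSECV compared
after rounding at 1e-12 to make exact ties deterministic). Weights are
orthonormal and scores orthogonal to 1e-8; with as many factors as the
predictor rank, predictions coincide with ordinary least squares, and
coefficients match scikit-learn's PLS to 1e-6 on random problems (both
are test-suite checks; scikit-learn is not a runtime dependency).

## Calibration and parameter estimation

Turbidity calibration is OLS of offline total cell concentration on
time-matched FAU readings (nearest neighbor within 0.5 h, unmatched
samples dropped), with an optional time window to exclude fouled data.
`divergence_flag` reports times where the turbidity-implied
concentration departs from viable cells by at least 10% (threshold
configurable) — the operating criterion for when the total-cell proxy
stops being trustworthy.

`estimate_mu_max` fits log-linear growth over a user-declared
exponential-phase window; auto-detection is deliberately not the
default (a rolling-R² heuristic would silently pick different windows
on different runs). `estimate_yield_X_glc` regresses cell growth on
maintenance-corrected glucose consumption, the maintenance integral by
trapezoid quadrature; on noise-free simulated batches it recovers
0.357e9 cells/mmol to well under 1%.

The sensitivity scan re-simulates the scenario once per parameter
value, holding everything else fixed, and reduces each trajectory to
peak viable cells, glucose-depletion time (first crossing of 0.05 mM)
and final titer. For mu_max (±5%, ±10%) the orderings are strict: peak
cells increase and depletion comes earlier with faster growth. The scan
horizon must be long enough for depletion to occur at the lowest value
(340 h covers −10% under the default feeds).

## The soft sensor

`estimate_substrates` integrates the four substrate/metabolite balances
with `[X_V]` replaced by linear interpolation of the measured signal.
`mu` and `mu_d` are computed from the *estimated* concentrations
(closed loop); differentiating a noisy FAU-derived signal to obtain
`mu` directly would amplify the probe noise. Bolus feeds dilute the
estimated concentrations exactly as in the simulator — which is why the
initial-condition record includes the reactor volume. Glucose is pinned
at zero on depletion. Duplicated timestamps in a signal sampled across
a bolus are tie-broken by +1e-9 h so that integrating *up to* the feed
instant sees the pre-feed value.

Driving the estimator with a turbidity-calibrated signal imports two
error sources: calibration slope/intercept error from the noisy offline
counts, and the viable/total discrepancy, which grows as viability
falls (the test suite shows a total-cell signal degrades glucose R² on
a low-viability culture relative to a viable-cell signal).

## Numerical notes

* Self-consistency: a densely sampled (0.01 h) ground-truth signal with
  exact initials reproduces the simulated glucose and lactate to
  <1e-6 mM. The signal grid matters: a 1 h grid leaks ~1e-3 of linear
  interpolation chord error into the estimate.
* Evaluation matching collapses duplicated bolus timestamps to the
  pre-event row on both series before nearest-neighbor pairing;
  otherwise a post-feed reference value can be paired with a pre-feed
  estimate, which misstates R² badly near feeds.
* The exponential-growth closed form holds only in the
  vanishing-inoculum limit (produced lactate/ammonium feed back on mu
  in proportion to the inoculum); tests verify it at X_V(0) = 1e-5 with
  atol tightened to 1e-18.
* R² is 1 − SS_res/SS_tot throughout; the degenerate zero-variance
  reference returns 1 for a perfect fit, else 0.

## Replication design

The headline figures of merit were measured on bioreactor cultivations
that are not deposited, so `scripts/acceptance.py` and the acceptance
tests replay them as seed-ensemble replications of the synthetic
scenario (medians over 100 seeds; 1000 for the cheap turbidity fit),
never single draws: glucose R² ≥ 0.96 on the pre-feed phase, lactate
R² ≥ 0.90 on the full horizon, turbidity linearity R² ≥ 0.97, held-out
Raman-PLS R² ≥ 0.92. Ensemble sizes keep the full suite within a few
minutes on one CPU.

## Known limitations

* No lysis by default (a rate hook exists); dead cells otherwise
  accumulate indefinitely, which overstates late-culture turbidity.
* The model has no lactate-consumption phase, no temperature/pH/pO₂
  effects, and treats feed medium as the six model species only.
* PLS is single-response (PLS1); predicting several analytes means
  fitting several models.
* The soft sensor does not re-anchor to offline measurements at feed
  times; an optional re-anchoring mode is a natural extension.
* Parameter estimation here is regression-based; full Bayesian/MCMC
  calibration of the kinetic constants is out of scope.
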