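# Methods

`seedage` re-implements, as one tested pipeline, the quantitative analyses
used to characterise artificial ageing of orthodox seeds: thiol–disulphide
redox state, probit viability modelling, spike-in-referenced qRT-PCR, and
two-colour microarray differential expression.  This note records the models,
their assumptions, the defaults and why, and what the synthetic data can and
cannot show.

## Redox state

For a couple in which one disulphide oxidises two thiols (2 RSH ⇌ RSSR + 2H⁺
+ 2e⁻), the half-cell reduction potential is

E = E°′(pH) − (RT/2F)·ln([RSH]²/[RSSR]),

reported in mV, with R and F at CODATA values and E°′ corrected from its
reference pH by −(ln10·RT/F) mV per pH unit (the slope of a 2H⁺/2e⁻ couple;
−59.16 mV/pH at 25 °C).  The squared thiol term makes E depend on absolute
concentration, which is why the molarity convention matters.

**Molarity convention.** Tissue measurements arrive in µmol g⁻¹ DW; the Nernst
term needs mol L⁻¹.  The conversion divides by the tissue water volume per g
DW (`hydration_mL_per_gDW`), which is a *declared* parameter: no published
convention fixes it, and reported redox-environment magnitudes in the
literature cannot be reproduced without knowing the convention used.  A helper
derives it from fresh-weight moisture content (12% MC → 0.12/0.88 =
0.1364 mL g⁻¹ DW, the default used in the analysis scripts).  Every run logs
the value used.

**Standard potentials.** E°′ values are supplied by a config-backed registry.
The glutathione couple defaults to the widely used −240 mV (pH 7.0, 25 °C);
the three minor couples default to the same value as an explicit placeholder
and are flagged in the log until overridden.  Quantitative cross-couple
comparisons therefore require user-supplied E°′ values; the package's own
tests always pass E°′ explicitly.

**Redox environment.** Following the summed-capacity convention, the score is
Σᵢ Eᵢ·[RSHᵢ] over couples (mV·M).  The glutathione couple dominates because it
is an order of magnitude more abundant than cysteine, cysteinylglycine or
γ-glutamylcysteine.

**Zero concentrations** make E undefined and raise by default.  An optional
`detection_limit_M` floor substitutes the limit with a warning so batch
time-course runs can proceed; it is off by default because silent flooring
biases potentials towards the limit.

**Enzyme activities** (glutathione reductase, G6PDH) convert an A₃₄₀ rate via
Beer–Lambert (ε = 6.22 mM⁻¹cm⁻¹ for NADPH) to katal — mol substrate s⁻¹ —
reported as nkat g⁻¹ DW.

Replicates are summarised as mean ± SE with the n provided; missing
replicates are never imputed.

## Viability probit

Total germination is modelled as Binomial with P(germinate) = Φ(α + β·dose),
the dose being any stressor axis (a half-cell potential in mV, the redox
environment in mV·M, or days).  Fitting is iteratively reweighted least
squares (Fisher scoring) with step halving, which makes the log-likelihood
provably non-decreasing; convergence is a relative log-likelihood change
below 1e-10 within 100 iterations.  The covariance is the inverse Fisher
information at the optimum.  β is unconstrained: for redox doses viability
falls as E rises (β < 0), but the direction is left to the data.

Complete separation (all-or-nothing outcomes with non-overlapping dose
groups) and constant doses are detected up front and reported as
`converged=False` with diagnostics — never as silent estimates.  A diverging
slope (|β| > 1e6) during iteration is likewise flagged.

The dose at quantile p is (Φ⁻¹(p) − α)/β.  Its confidence zone uses the delta
method by default (simple, standard); Fieller bounds are available by config
and preferred when β is poorly determined (the delta interval degenerates
when the Wald statistic for β is small).  The confidence level is a required
config value (default 0.95) and is always echoed in the output, because the
"zone of viability loss" is meaningless without it.

## qPCR quantification

Degraded RNA makes endogenous housekeeping normalisation unreliable, so the
workflow normalises against an exogenous RNA spike added before reverse
transcription; the foreign amplicon (human PBGD) reflects only the technical
chain.

Each reaction's raw fluorescence is fitted with a four-parameter logistic
F(c) = Fb + Fmax/(1 + exp(−(c − c_half)/k)) by multistart least squares
(method-of-moments starts; additional k starts at 1/ln 2, 0.7 and 2.5
cycles).  Flat curves (rise below 5× the baseline-noise scale) raise a
no-amplification error distinct from fit non-convergence.

The cycle threshold is the fitted curve's second-derivative maximum, which
has the closed form ct = c_half − k·ln(2+√3).  The amplification efficiency
E ∈ (1, 2] defaults to the fitted exponential growth rate, **E = exp(1/k)**:
in the low-fluorescence limit the logistic grows exactly E-fold per cycle, so
on logistic-shaped data this estimator is exact.  An alternative estimator
that log-linearly refits the raw points inside the [ct, c_half] window is
exposed as `method="exp-window"` for diagnostics; over that window the
logistic's log-slope has already fallen from 0.79/k to 0.5/k, so the window
fit is biased low by design (≈1.55 for a true 2.0) and additionally fails
when the window holds fewer than three integer cycles (under two cycles at
E = 2).  It is therefore not the default.

Expression ratios are efficiency-corrected relative to the non-aged (0 d)
control: ratio = E_t^(Ct_ctrl − Ct_sample) / E_r^(Ct_ctrl − Ct_sample).  One
efficiency per gene is used — the median across that gene's reactions —
because per-well efficiency estimates are noisy (±0.03 at fluorescence noise
σ = 0.05) while the median over a gene's 15 reactions is accurate to ±0.01.
The control Ct per gene is the mean over the 0 d reactions.  Ratios are
computed per biological replicate and summarised as mean ± SE.

The stability screen regresses non-normalised expression (E^(Ct_ctrl − Ct))
on ageing days over **all replicate reactions**, not per-time means: with
only three time points the means are nearly collinear by construction and the
slope test would flag negligible drifts while missing real declines.  A gene
is "stable" when the two-sided slope p-value is ≥ 0.05.

The spike-in validity check is report-only: it lists reference amplification
in un-spiked samples, flags the absence of any spiked reference
(normalisation impossible), and — where a sample was run with and without the
spike — verifies the spike leaves target Cts unchanged within 0.5 cycles.

## Array statistics

The chain matches standard two-colour practice for spotted arrays with
replicate spots.  All statistics operate on M = log₂(aged/control) and
A = mean log₂ intensity; the generator emits M/A directly, and background
correction variants are therefore out of scope of the statistics layer.

1. **Print-tip loess.** Per print-tip block, M is detrended by a
   tricube-weighted local-linear regression of M on A (span 0.3 — common
   two-colour practice, config-exposed).  The smoother uses the ⌈span·n⌉
   nearest neighbours with tricube weights scaled by the furthest neighbour.
   Blocks under 20 spots fall back to median centering; a single under-sized
   block is a degenerate array and raises.
2. **Between-array scaling.** Each array's M values are rescaled so all
   arrays share the geometric-mean median-absolute-M; a zero scale raises.
3. **Replicate spots** are averaged to one M per probe per array before
   testing.  "Replicates" in the DE filter means biological replicate arrays;
   within-array spots are technical and correlated, and counting them would
   overstate the degrees of freedom.  (The spot-level table is retained, so
   the alternate reading can be assembled by skipping the averaging step.)
4. **Moderated t.** Per-probe variances are shrunk toward a prior:
   s²_post = (d₀s₀² + d_g s²)/(d₀ + d_g), t̃ = mean(M)/√(s²_post/n), two-sided
   p on d₀ + d_g df (normal at the d₀ = ∞ sentinel).  The prior (d₀, s₀²) is
   estimated by moment matching on z = log s²: Var(z) = ψ′(d_g/2) + ψ′(d₀/2),
   so d₀ solves the trigamma inverse by Newton iteration; s₀² comes from
   mean(z) with the digamma corrections.  When the spread of z is at or below
   the χ²_{d_g} sampling floor, d₀ = ∞ and all probes share s₀².
5. **FDR** is Benjamini–Hochberg (default level 0.05; 0.10 via flag), applied
   within each time point.
6. **DE calls** require presence in ≥2 replicate arrays, q < level, and
   |mean M| ≥ 1.0 (2-fold).  Passing the q filter but not the fold threshold
   yields `passed_filter=True, direction="none"`.
7. **Venn partitions** report the 7 exclusive regions plus the union across
   the three early time points, per direction.
8. **Clustering** of DE mean-M profiles is agglomerative with Euclidean
   distance and complete linkage (scipy), tree-cut to K = 16 by default (the
   cut criterion is a choice; no principled K is claimed).  Cluster ids are
   renumbered by first-member input order so output is deterministic for a
   given input order; equal-distance merges follow scipy's deterministic
   ordering.  Probes with missing profile values are excluded and reported.

## Synthetic data

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions:

* nine ageing time points (0, 8, 10, 12, 13, 15, 25, 31, 55 d);
* glutathione 1.9 µmol g⁻¹ DW with 11% GSSG when non-aged, half the pool and
  37% GSSG at 55 d; minor couples an order of magnitude smaller with rising
  disulphides.  Between anchors every trajectory is a normalised logistic in
  time (midpoint 28 d, rate 0.12 d⁻¹ — chosen so the pool is essentially
  stable through 15 d and near its aged state by 55 d); the anchors are the
  claim, the logistic shape is a generator convenience.  Replicates (n = 5)
  get mean-preserving lognormal noise at 10% CV;
* germination is Binomial with P = Φ(β(E − dose50)), dose50 = −185 mV and
  β = −0.25 per mV — with the redox trajectory's E(55 d) ≈ −177 mV this
  yields ≈100% germination through 15 d and ≈2% at 55 d.  Default tests use
  20 seeds × 3 replicates per time point; callers may supply explicit dose
  grids (the recovery analyses use 8 doses spanning −200…−170 mV);
* qPCR curves are logistics with k = 1/ln(E_true), a fold change φ shifting
  the midpoint by −log_E(φ) cycles, 45 cycles, Gaussian fluorescence noise
  σ = 0.05, five replicates; the spiked reference holds fold 1 while targets
  decay 1.0 → 0.5 → 0.25 over 0/25/55 d;
* arrays have 5,220 probes × 3 replicate spots × 3 arrays at 8/12/15 d; 5% of
  probes are DE with |log₂FC| ∈ {1.0, 1.5, 2.0} and random sign; per-probe
  variances are scaled-inverse-χ² (d₀ = 4, s₀² = 0.09), spot noise σ = 0.1,
  A ~ U(6, 16), and each of 16 print-tip blocks adds a sinusoidal
  intensity-dependent bias of amplitude 0.5 with a block-specific phase.

Generators are pure functions of (scenario, seed) — bit-identical output for
identical inputs, with independent deterministic sub-streams per data type —
and every generator returns its pre-noise truth table so downstream stages
have recovery oracles.

**What passing tests do not show.**  The generator draws noise from the
idealised families the estimators assume (lognormal concentrations, Gaussian
M and fluorescence, Binomial germination, inverse-χ² variances).  Real data
add dye-swap structure, spatial artefacts, spot-quality failures,
non-logistic amplification chemistry, seed-lot heterogeneity and RNA
degradation biases that are not modelled; recovery on synthetic data
demonstrates correctness of the computations, not robustness to those
violations.

## Numerical choices

* CODATA R and F throughout; potentials in mV, concentrations in mol L⁻¹.
* Probit: empirical-probit least squares start; probabilities clipped to
  [1e-12, 1−1e-12] inside the likelihood; step halving to floor 2⁻²⁷.
* Sigmoid fits: bounded Levenberg–Marquardt/TRF via `scipy.curve_fit`,
  best-of-multistart by SSE.
* Trigamma inverse: Newton with the standard curvature-corrected update,
  start 0.5 + 1/y, tolerance 1e-12.
* Loess: x-degenerate neighbourhoods fall back to the weighted mean; ties in
  neighbour selection follow `argpartition` order.
* BH adjustment delegates to `statsmodels.stats.multitest.multipletests`.
* Report JSON is sorted-key with no timestamps, so reruns are byte-identical.

## Problem sizes used in the checks

Recovery and calibration checks run at sizes chosen to make their Monte-Carlo
margins small but the runs quick: 100 seeded probit replicates at 8 × 200
seeds; 100 null array datasets of 2,000 probes; 5,000 probes for prior
recovery; 50 random instances of ≤12 profiles against the brute-force
clustering oracle; the full 5,220-probe scenario for the end-to-end run.

## Known limitations

* The minor couples' E°′ placeholder makes their absolute potentials (and
  hence their small contribution to the redox environment) nominal until the
  user supplies literature values.
* The redox-environment magnitude scales inversely with the hydration
  convention; comparisons across studies require the same convention.
* Dye-swap designs, spot-quality weights, GEO/SOFT parsing and probe
  annotation are out of scope.
* The delta-method zone can undercover when β is weakly identified (e.g.
  germination data with a single informative dose); use Fieller bounds and
  dose designs spanning the transition.
* `exp-window` efficiency estimation is provided for diagnostics only; see
  above for its bias.
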