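# Methods

This note documents the model structure, the defaults and why they were
chosen, the numerical choices, and the limits of what the test suite shows.

## Model structure and assumptions

The simulator integrates a coupled parent–metabolite whole-body system in
amounts (µmol) with time in minutes. Organs are perfusion-limited
(well-stirred): each organ's venous outflow concentration is `C_T/K_p`, so
tissue distribution is instantaneous relative to perfusion. This is a
deliberate reduction relative to platform models that resolve four
sub-compartments per organ with permeability barriers; it preserves portal
first-pass anatomy (gut wall and spleen+pancreas drain into the portal vein,
which joins the hepatic artery at the liver inlet) and whole-body mass
balance, at the cost of some fidelity in early distribution kinetics.
Blood is treated as plasma (blood:plasma ratio 1); the arterial and venous
pools are the plasma reference (K_p ≡ 1).

Metabolism in liver and gut wall is driven by the unbound intracellular
concentration `c_u = fu_plasma · C_T / K_p`, the well-stirred equilibrium
value. For felodipine the only clearance pathway is saturable CYP3A4
turnover `v = k_cat·E·c_u/(K_m + c_u)` per litre of expressing tissue, plus
passive glomerular filtration `GFR·fu` taken from the arterial pool. At
therapeutic doses `c_u ≪ K_m` everywhere (unbound fractions are 0.36% /
0.68%), so the system operates in its linear regime; the saturable form
matters for DDI and high-exposure scenarios. Dehydrofelodipine is formed
1:1 molar in the organ where the parent is metabolized and is cleared by
first-order "specific" clearances referencing the intracellular water
volume (fraction 0.6 of organ volume): a CYP3A4-mediated one that scales
with local CYP3A4 expression and is DDI-sensitive, and an unspecific
hepatic one that is not.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| K_m (CYP3A4, felodipine) | 2.81 | µmol/L | literature Michaelis constant |
| k_cat (CYP3A4, felodipine) | 250.44 | 1/min | published model estimate |
| CL-CYP3A4 / CL-hepatic (metabolite) | 35.74 / 2.76 | 1/min | published model estimates |
| fu,plasma | 0.0036 / 0.0068 | – | percent values read as fractions (>99% protein binding) |
| hepatic CYP3A4 reference | 4.32 | µmol/L liver | literature-informed stand-in for the platform expression database |
| gut CYP3A4 scale | 1.0 | – | duodenal mucosal concentration relative to liver; see calibration below |
| GFR | 120 | mL/min | 30-y male; scales with body surface area |
| liver blood flow | 1.45 (0.45 arterial + 1.0 portal) | L/min | reference-man splanchnic physiology |
| gut mucosal flow | 0.65 total | L/min | mucosal share of intestinal perfusion |
| Weibull (tablet / ER tablet) | t50 54.86 / 173.04 min, shape 1.32 / 1.30 | | published formulation estimates; t50 is the time to 50% dissolved |
| solubility (literature / ER-formulation) | 7.15 / 0.89 | mg/L | the ER value is a surrogate for reduced distal absorption and applies in all segments (a `distal-only` variant was considered and rejected as a second mechanism for the same observation) |
| CYP3A4 turnover t½ | 36 h liver, 23 h gut | | literature enzyme turnover |
| kcat_scaling | 1.0 | – | set to ~0.68 to emulate the reduced CYP3A4 activity of hypertensive populations |

**Gut CYP3A4 calibration.** The per-segment relative expression profile
(duodenum 1.0, upper jejunum 0.9, lower jejunum 0.6, ileum 0.25, caecum
0.05, colon 0.03, relative to the hepatic reference concentration) is fixed;
a single scale constant (`GUT_CYP3A4_EXPRESSION_SCALE`, default 1.0)
multiplies it. The scale was calibrated once so that a 10 mg oral solution
yields an intestinal fraction metabolized of ~53–56%, the reported extent of
gut-wall extraction for felodipine. With this calibration the total
gut-wall CYP3A4 amount is ~15% of the hepatic amount — higher than bulk
intestinal homogenate measurements suggest, which is the price of lumping
each segment's mucosa into one well-stirred compartment washed by the full
mucosal blood flow: extraction in such a compartment is
`fu·CL_int/(fu·CL_int + Q)`, so matching the observed extraction fixes the
product of expression and kcat, not the anatomical amount. The distribution
of absorption across segments, not the absolute expression, then determines
how f_m,int responds to formulation (slower-releasing forms shift absorption
distally, where expression is lower).

**Effective absorption areas** (1.2–3.0 m² per small-intestinal segment)
come from cylindrical geometry amplified for folds and villi, chosen so that
the transcellular permeability of 2.76×10⁻⁴ cm/min yields near-complete
small-intestinal absorption of dissolved felodipine — consistent with the
reported fraction absorbed >95% and with the platform convention that
permeability values are tied to their own area model.

## Dissolution and transit

The dissolution clock follows the dosage form: a single tablet-age variable
(time since administration) drives the Weibull hazard
`w'(a)/(1−w(a)) = ln2·b/t50·(a/t50)^(b−1)` applied to the remaining solid in
every segment, so a tablet that empties from the stomach keeps its release
age rather than restarting. Undissolved solid transits with luminal fluid
at the same segment rates (stomach emptying half-time 15 min, fasted).
Dissolution is clipped linearly to zero as the local dissolved
concentration approaches the applicable solubility; oral solutions are
administered pre-dissolved and are not re-precipitated. With multiple oral
doses the hazard uses the age of the most recent dose — adequate for the
once/twice-daily regimens of interest, wrong for overlapping tablets with
very different release states.

## Pharmacodynamics

Baselines are multiplicative percent-of-mean cosines because the published
amplitudes carry % units: DBP has 24-h and 12-h harmonics, HR a single 24-h
harmonic; phases are in clock hours and dosing defaults to 08:00. The drug
effect is a direct Emax model on felodipine plasma concentration (no lag, no
tolerance): subtracted from DBP (hill = 1, as no hill coefficient is
reported for the blood-pressure model), added to HR (hill = 1.40). Per-study
re-estimation of phase and mean from placebo data is exposed as
`fit_circadian` rather than hard-coded study values.

## Drug-drug interactions

Perpetrators are unbound-concentration forcing functions (constant or
piecewise-linear, optionally scaled per organ), not co-integrated PBPK
systems — the published perpetrator models live elsewhere and their full
parameterizations are not reproduced here. Competitive inhibition scales
the apparent K_m (and divides the metabolite's first-order CYP3A4 clearance)
and leaves the enzyme pool untouched; mechanism-based inactivation and
induction act on an enzyme-turnover balance whose states are integrated with
the system. Induction protocols emulating perpetrator pretreatment start
the enzyme pool at its induced steady state. When no dynamic mechanism has
nonzero exposure the enzyme states are omitted entirely, so a null
interaction reproduces the no-DDI simulation bitwise.

## Numerics

Stiff BDF integration with rtol 1e-8, atol 1e-10 µmol and a hand-built
Jacobian sparsity pattern (the 128-state system is sparse); integration
restarts at every dosing boundary so discontinuities are never straddled.
Oral doses enter as bolus amounts into the stomach state at the restart;
infusions are piecewise-constant venous inputs. Global molar mass balance
holds to ~1e-10 relative in practice (tested at 1e-6), and tightening the
tolerances tenfold moves AUC_last by <0.1%. Degenerate inputs are rejected
by validation (non-physiological demographics, non-positive Weibull
parameters, mismatched DDI parameter sets); a solver failure raises an error
carrying the failure time and state snapshot.

Bioavailability is the dose-normalized AUC_last ratio to the last common
time with no extrapolation. The ledger decomposition
`F = fa · F_gut · F_hepatic` exploits the fact that in a linear well-stirred
compartment all input streams share the same fate fractions, so per-segment
gut extraction is `met/(met + outflow)` from cumulative ledgers; the two
routes to F agree within ~0.1% and are cross-checked at 3% in the tests.

Fitting uses Latin-hypercube multi-start (default 20 starts, seeded) with
bounded trust-region least squares; concentrations contribute squared
log-residuals, effects squared plain residuals. When all free parameters
live in the PD layer the PK profile is simulated once and reused. An
optional RMS threshold stops the multi-start loop early for noiseless
self-consistency fits. A flat objective (no sensitivity to the requested
parameters) is detected and flagged with a warning.

## Synthetic data: what it does and does not emulate

Fixtures reproduce the statistical structure the evaluation assumes — sparse
clinical grids (default 0.5–24 h), multiplicative log-normal concentration
noise with CV 20% (log-sigma `sqrt(ln(1+CV²))`, unit-median multiplier),
additive Gaussian PD noise (4 mmHg / 5 bpm), LLOQ censoring at 0.1 ng/mL —
and the dose ranges of the source studies (iv 1–3 mg, oral 5–40 mg). They do
not emulate inter-individual variability, dropout, assay drift,
food effects, or study-specific sampling designs; passing recovery tests on
fixtures therefore demonstrates internal consistency of the
simulate-observe-fit loop under the assumed residual model, not performance
against real clinical data, which would require the digitized literature
profiles that are outside this package's scope.

## Problem sizes used in the automated checks

The mechanistic predictions use the defaults of the corresponding studies:
48-h horizons on a 10-min output grid for the 10 mg solution and 1 mg
infusion; parameter-recovery checks use 24-h horizons and the sparse
clinical grid; enzyme-turnover steady states are verified over ~60 turnover
half-lives; the clearance identity over a 30-day horizon where >99% of the
dose is eliminated.

## Known limitations

* Perfusion-limited distribution understates the distributional delay of a
  highly lipophilic drug; the deep adipose phase yields a long terminal
  half-life (~2 days) that truncated 48-h AUCs only partially sample — both
  routes are truncated identically, so availability ratios are insensitive.
* The partition-coefficient methods are simplified single-equation variants
  of the cited composition-based families (no erythrocyte or
  extracellular-protein terms, reduced ionization handling); K_p enters
  extraction ratios only through the unbound driving concentration, so the
  headline predictions are robust to this choice, but tissue-level
  concentration predictions are approximate.
* Cellular permeability values are carried in the compound parameter sets
  but unused (perfusion-limited organs have no permeability barrier).
* Systolic blood pressure and heart-rate tolerance are out of scope, as is
  population variability (mean individuals only).
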