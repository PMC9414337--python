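# Methods

This note documents the models, conventions and numerical choices behind
`pbpkdgi`, and what the shipped defaults do and do not claim.

## Activity-score scaling law (`pbpkdgi.scaling`)

Relative CYP2D6 turnover values (percent of the AS = 2 value) from
published metoprolol and dextromethorphan DGI models are pooled — all
finite entries including the (0, 0) anchors, 14 points in total — and
fitted jointly by OLS with the design matrix `[AS², AS]` (degree 2, no
intercept). The no-intercept constraint encodes the biology: AS = 0 means
no functional enzyme. Consequences and conventions:

* `kcat_rel(0) = 0` and `kcat_rel(2) = 1` hold exactly (the normalization
  value is the fitted polynomial at AS = 2, ≈ 102.7% with the
  integer-rounded inputs, rather than a printed rounded value — this
  reproduces more published table cells).
* R² uses the no-intercept convention (total sum of squares about zero).
* The packaged input table stores the published integer-rounded relative
  values; regenerated k_cat entries therefore carry an irreducible ~1%
  input-rounding error, and reproduction is asserted at 2% relative.
* Scores off the published grid (e.g. 1.75) are evaluated by the same
  polynomial; tables flag them via an `on_grid` column.
* Traditional "extensive metabolizer" study arms are parameterized as the
  AS = 1.25 k_cat reduced by a compound-specific fraction (0.35, 0.30,
  0.36 for paroxetine, atomoxetine, risperidone), reflecting that EM
  cohorts pool heterogeneous genotypes below AS 1.25 activity.
* Phenotype bins: poor = 0, intermediate (0, 1], normal (1, 2.25],
  ultrarapid > 2.25 — a total function on [0, ∞).

## PBPK engine (`pbpkdgi.engine`, `pbpkdgi.physiology`)

A reduced whole-body model with nine perfusion-limited compartments
(venous/arterial blood, lung, liver, gut, kidney, adipose, muscle, lumped
rest), one documented 73 kg reference adult (cardiac output 390 L/h, GFR
7.5 L/h), and a one-compartment degenerate mode used for closed-form
verification and fast fitting. Flows, volumes and enzyme reference
concentrations (CYP2D6 0.40, CYP3A4 4.32, CYP2C19 0.76 µmol/L liver) are
rounded textbook values; the analysis targets — exposure *ratios* between
activity scores — depend on the relative sizes of clearance processes,
not on anatomical detail.

Conventions that matter:

* Circulating concentrations are treated as plasma-equivalent; partition
  coefficients are tissue:plasma. The blood:plasma ratio field only
  rescales the observed venous concentration (templates use 1.0). Any
  self-consistent convention leaves DGI ratios unchanged.
* Michaelis–Menten substrate concentration `S` = unbound liver
  concentration `f_u · C_liver / Kp_liver`; enzyme amount `E` = reference
  concentration × liver volume. `k_cat` is accepted in min⁻¹ and
  converted internally (amounts µmol, time h, concentrations µmol/L;
  µg/L at the I/O boundary via the molecular weight).
* Mechanism-based inactivation adds one state per targeted enzyme:
  `dE/dt = k_deg (E0 − E) − k_inact · I_u/(K_I + I_u) · E`, with enzyme
  turnover `k_deg` defaulting to 0.03 h⁻¹ (configurable; required by the
  inactivation model but rarely reported).
* Oral dosing is an impulse into a first-order depot feeding the gut wall
  (tablets may add a lag); IV dosing is a venous bolus or zero-order
  infusion. Doses are exact-time events: integration (LSODA, rtol 1e-8,
  atol 1e-10 by default) restarts at each dose boundary, and samples at a
  dose time are post-dose.
* Cumulative elimination and metabolite formation are co-integrated, so
  mass balance (in body + eliminated = administered + formed) is auditable
  to solver precision.
* Default partition coefficients come from a coarse lipophilicity
  heuristic (`Kp = 1 + f_lipid · (10^logP)^0.6`, capped at 30); templates
  override them explicitly, and the heuristic is a fallback only.
* Virtual populations draw median-preserving log-normal factors
  (`σ² = ln(1 + CV²)`) on selected parameter paths and, optionally, a body
  weight that rescales volumes linearly and flows/GFR with BW^0.75;
  summaries are pointwise arithmetic mean ± sample SD (n − 1), SD defined
  as zero for n = 1.

## Drug templates (`pbpkdgi.drugs`)

The three templates implement the published metabolic topologies:
paroxetine (CYP2D6 + CYP3A4 + unspecific hepatic clearance + glomerular
filtration + mechanism-based auto-inhibition of CYP2D6 and CYP3A4),
atomoxetine (CYP2D6 + CYP2C19 + glomerular filtration), risperidone
(parent → 9-hydroxyrisperidone and → other metabolites via CYP2D6 and
CYP3A4 each, metabolite cleared by an unspecific hepatic process). The
CYP2D6 AS = 2 baselines are the published optimized values
(4.09, 103.82, 3.19, 1.94 min⁻¹). **All other kinetic parameters are
calibration placeholders**: the original models' full parameter tables are
not published in the main text, so K_M values, CYP3A4/CYP2C19 turnover,
unspecific clearances, fractions unbound and partition sets were chosen
once so that the documented clearance structure holds — CYP2D6 carries
~90% of atomoxetine clearance at AS = 2, paroxetine's auto-inhibition
measurably suppresses its own clearance on repeated dosing, and the
risperidone active moiety partially buffers genotype effects. Template
DGI ratios are therefore *structural* predictions (ordering, monotonicity,
compression), not reproductions of published ratio values.

`apply_activity_score` rescales every CYP2D6 k_cat from its recorded
AS = 2 baseline, leaving K_M, the reference concentration and all other
parameters untouched; it is idempotent and inverted by reapplying AS = 2.
The steady-state DGI application simulates 28 days of the template regimen
(paroxetine 40 mg qd — the equally supported 20 mg variant is a dose
override away — atomoxetine 40 mg bid, risperidone 2 mg bid) and
integrates AUC over days 24–28, warning if the last two dosing-interval
AUCs differ by more than 2%.

## Evaluation statistics (`pbpkdgi.metrics`)

MRD is implemented as 10 to the *root*-mean-square log10 error, so a
uniform 2-fold error gives exactly 2.0; printed formulas sometimes omit
the root typographically, and a `root=False` variant is provided. GMFE is
10 to the mean absolute log10 fold error over study-level AUC/C_max pairs.
Guest limits use `L = (δ + 2(R̃ − 1))/R̃` with `R̃ = max(R, 1/R)` and
δ = 1.25 (configurable), giving [0.8, 1.25] at R = 1 and a 2-fold
asymptote. Two-fold counting is boundary-inclusive. Predicted profiles are
linearly interpolated at observed timepoints before any comparison;
non-positive observations are excluded from log-scale metrics with the
count reported.

## Fitting workflow (`pbpkdgi.estimation`)

Four fixed-order stages (partition selection → absorption → CYP2D6-
independent clearance on poor-metabolizer arms → CYP2D6 k_cat on AS = 2/EM
arms), each freezing its parameters for later stages and skipping with a
report entry when its data requirement is unmet. The objective is the sum
of squared residuals on log10 concentrations across all matched,
non-censored observations (linear-scale option retained). Because
residuals pool subject-level log concentrations, log-normal
between-subject variability does not bias the recovered median parameters.
The optimizer is a seeded contracting log-multiplicative random search
(width contracted by 0.7 every 30 iterations) with a deterministic
Nelder-Mead polish in log space; it never returns a loss above its start
and is bit-reproducible per seed. Local sensitivity is one-at-a-time:
S = (ΔAUC/AUC₀)/(Δp/p₀) with a +100% perturbation on the single-dose
AUC₀₋₂₄ₕ by default (|S| > 0.5 flags sensitivity); parameters at exactly
zero are reported as skipped. Note that S = −0.5 for a clearance
perturbation is exact only when the AUC window captures essentially the
whole exposure; the tests therefore use fast-eliminating configurations.

## Synthetic studies (`pbpkdgi.synthdata`)

The generator emulates the structure of the clinical datasets used for
CYP2D6 DGI model building: arms keyed by activity score or phenotype
(EM/PM), sparse sampling grids, log-normal BSV on chosen parameters,
uniform body-weight sampling with allometric rescaling, combined
proportional + additive residual error on the linear scale, and LLOQ
censoring with flagged-but-retained BQL rows. Output is byte-identical
for identical seeds. It does **not** emulate digitization error of
literature figures, dropout, covariates beyond weight, or assay
differences between studies — so green pipeline tests demonstrate
correctness of the machinery and internal consistency, not performance on
real heterogeneous literature data. Arm summaries use the arithmetic mean
and sample SD; timepoints where all observations are censored are flagged
missing.

## Problem sizes used in the shipped checks

The test suite verifies the engine against closed forms (one-compartment
kinetics, superposition, accumulation, the Michaelis–Menten first-order
limit at peak S = K_M/1000 where the analytic AUC deviation S₀/(2K_M) is
0.05%, and the inactivation steady state), and runs the full pipeline at
deliberately moderate sizes chosen as representative rather than
exhaustive: parameter recovery on a two-arm study (AS 0 vs 2) with 100
subjects per arm, 30% BSV and 20% residual CV; steady-state DGI scans over
six activity scores at a 1 h output grid; virtual-population checks at
n = 500 in the one-compartment mode. Monte Carlo stages default to a few
hundred iterations plus polish, which recovers noise-free parameters to
well under 1%.

## Known limitations

* Placeholders, not reproductions: template DGI ratio magnitudes depend on
  unpublished parameter tables and a proprietary physiology; only their
  structure is asserted.
* P-glycoprotein transport is reduced to an optional linear clearance;
  intestinal transit/dissolution, metabolite kinetics beyond
  9-hydroxyrisperidone, allele-specific (star-allele) effects and
  pediatric/special-population scaling are out of scope.
* The perfusion-limited engine has no permeability-limited tissues; the
  engine's plasma-equivalence convention makes blood:plasma partitioning
  purely an output-scaling choice.
* Aggregated (study-mean) profiles are fitted like individual data; the
  generator produces individual-level data, so the workflow's weighting of
  real aggregated literature profiles is undefined and undocumented here.
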