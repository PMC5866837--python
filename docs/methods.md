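# Methods

## The kinetic model

The PBK model describes the fate of a parent compound in the rat with five
perfused compartments — blood, liver, fat, richly perfused and slowly
perfused tissue — plus a stomach and a small intestine split into 7
sub-compartments that carry an oral dose down the gut. All tissue exchange
is flow-limited:

    dA_T/dt = Q_T · (C_blood − C_T / P_T)

with Q_T the tissue blood flow (L/h), C_T = A_T/V_T (µM) and P_T the
tissue:blood partition coefficient. An oral dose enters the stomach and
empties first-order (rate k_s) into intestinal sub-compartment 1; lumen
contents transfer between sub-compartments at rate k_in, and material
leaving sub-compartment 7 is counted as unabsorbed. Absorption from each
sub-compartment is portal (into the liver) at rate
P_app,in vivo · SA_in · C_lumen. Hepatic metabolism is the only clearance
process:

    rate (µmol/h) = CL_liver · C_liver / P_liver

the venous-equilibration convention on the *total* liver concentration
(consistent with using total CL_int without a binding correction). The
convention is isolated in one function (`_hepatic_elimination_rate`) so a
well-stirred unbound variant can be swapped in. An IV dose is a bolus into
blood. Renal clearance, metabolite kinetics, enterohepatic recirculation
and non-oral/IV routes are out of scope.

Every process is first order, so the system is linear: blood C_max is
exactly proportional to dose, which the reverse-dosimetry search exploits
(one simulation per setting, a verified proportionality check, then
scaling; a bracketed root-finder remains as a fallback for future
non-linear variants).

### Parameter values

Physiology (adult rat, 0.25 kg default; fractions of body weight / cardiac
output): liver 0.034 / 0.25, fat 0.07 / 0.07, blood 0.074, richly perfused
0.05 / 0.51; the slowly perfused compartment takes the remainders (perfused
body fraction 0.91, flow remainder 0.17), so the sum constraints hold by
construction — also under one-at-a-time perturbation in the sensitivity
module. Cardiac output is allometric, 15·BW^0.74 L/h. S9 protein content:
87 g per kg liver.

Gut geometry is the least certain part of the parameterization and was
reconstructed from rat anatomy together with the model's own sensitivity
behaviour: per sub-compartment, lumen fluid volume V_in = 1.5 mL (≈10.5 mL
small-intestinal fluid in the fed state), absorptive surface SA_in =
16.1 cm² (smooth cylinder, r ≈ 0.18 cm × L ≈ 100 cm, no villus
amplification because Caco-2 P_app values already refer to nominal filter
area), transfer rate k_in = 4.667 h⁻¹ (≈1.5 h small-intestinal transit over
7 sub-compartments), gastric emptying 5.5 h⁻¹ (half-time ≈7.5 min, aqueous
gavage). Under this parameterization the influential parameters for oral
C_max are the hepatic ones (CL_int, S9P, VLc, QLc) and the absorption
parameters (P_app, V_in, SA_in), matching the expected behaviour of a
first-pass-limited oral exposure; k_in and the slowly perfused partition
coefficient stay below |SC| = 0.1 here.

Chemical defaults (E2 / BPA): MW 272.38 / 228.29 g/mol; log P_ow
4.01 / 3.32; P_app,Caco-2 17 / 20 ×10⁻⁶ cm/s; CL_int 175 / 392 (male S9)
and 65.5 / 431.6 (female S9) µL/min/mg protein; f_ub in serum
0.050 / 0.040, in reporter/proliferation assay medium 0.628 / 0.461 (yeast
medium is protein-free, f_ub = 1).

The Caco-2 regression is evaluated with the input in 10⁻⁶ cm/s and the
output read in 10⁻⁴ cm/s (the units the regression was published in),
then converted to cm/h; a `same-units` enum value is available for a
literal same-scale reading. Blood:plasma partitioning is assumed 1, so the
serum fraction unbound doubles as the blood free fraction.

### Partition coefficients

When not supplied explicitly, tissue:blood partition coefficients come
from a two-phase lipid/water QPPR:

    P_T = (f_lip,T · Pow^n + f_wat,T) / (f_lip,blood · Pow^n + f_wat,blood)

with compiled rat tissue compositions (blood 0.0033/0.83, liver 0.042/0.72,
fat 0.853/0.12, richly perfused 0.040/0.75, slowly perfused 0.021/0.76,
lipid/water volume fractions) and n = 1 except fat, where n = 0.7 accounts
for adipose lipid being less lipophilic than octanol. A tissue with blood's
composition partitions at exactly 1 for any log Pow, and the fat PC is
monotone in log Pow. Explicit user-supplied PCs bypass the QPPR entirely
and are the tested default wherever a reference PC set exists.

## Clearance estimation

The substrate-depletion design holds the substrate (3 µM default) well
below the lowest reported Km, so depletion is first order and
ln(C_compound/C_control) is linear in time. Replicates are pooled by
averaging ln(ratio) per time point (variance-stabilizing on the log
scale). The "linear part" is selected automatically: contiguous windows
anchored at t = 0 are scanned from longest to shortest, and the longest
window of ≥5 points with r² ≥ 0.9 is fitted; if none qualifies, all points
are used. A flat or rising series yields k = 0 with a `no_depletion` flag
rather than a negative rate. Per-time-point control normalization is
assumed done upstream (the input *is* the ratio). Michaelis–Menten
(saturable) fitting is deliberately absent — the assay design guarantees
first-order conditions, and a below-Km check (`check_substrate_below_km`)
surfaces a warning when a Km bound is available.

Whole-liver scaling: CL_liver (L/h) = CL_int ×10⁻⁶ L/µL × 60 min/h ×
(87 g/kg × liver kg × 10³ mg/g). For 175 µL/min/mg and an 8.5 g liver this
gives 7.76 L/h.

## Response curves and benchmark dose

Raw in vitro responses are normalized so the *maximum observed* response of
the compound is exactly 100% (the fitted top is kept only as a
diagnostic). The Hill model
y = bottom + (top−bottom)/(1 + (EC50/c)^slope) is fitted by least squares
with EC50 log-parameterized; starting values are bottom = min, top = max,
EC50 at the geometric mid-concentration, slope 1. Bottom and top are left
unconstrained: with curves spanning the full transition this is stable,
and it avoids biasing the EC50 when the plateaus are noisy.

BMD analysis uses the 3-parameter increasing exponential model for
continuous endpoints, y = a·exp(b·x^d) with a > 0, b ≥ 0, d ∈ [1, 4],
fitted by maximum likelihood — lognormal errors by default (standard for
positive endpoints such as uterus weight), normal errors optionally (used
for predicted curves on the percent scale, whose background can be ~0).
Internally the dose axis is rescaled to [0, 1] before optimization, making
the fit exactly equivariant under changes of dose units, and each
L-BFGS-B solution is polished with a bounded Nelder–Mead pass. The BMR is
a 10% increase over control, giving the closed form
BMD₁₀ = (ln 1.1 / b)^(1/d). Confidence bounds are profile-likelihood: the
model is reparameterized so the BMD is itself a parameter
(b = ln(1.1)/BMD^d), and the deviance is bracketed against a χ²₁ cutoff at
the 90% two-sided level (the convention yielding a one-sided 95% BMDL);
both the level and the BMR are configurable. An unbounded profile is
reported as an explicitly open bound, flat data as a no-BMD result —
values are only reported when the fit is accepted. Predicted dose–response
curves have no dose-0 group, so the pipeline anchors them with a
background row carrying the lowest predicted response (the flat bottom of
the sigmoid) before fitting.

## Sensitivity analysis

Normalized sensitivity coefficients use a one-at-a-time *forward* +5%
perturbation, SC = (C′−C)/(P′−P)·(P/C) — forward rather than central
difference for fidelity to the standard published procedure. Perturbing a
volume or flow fraction re-derives the slowly perfused remainder, so the
physiological sum constraints always hold; the screen flags |SC| > 0.1 by
default. For this all-linear model the SC of dose on C_max is exactly 1,
which serves as a self-test.

## Synthetic data

The generators draw from exactly the parametric families the estimators
assume: first-order depletion with mean-one multiplicative lognormal noise
(t = 0 forced to 1), Hill curves with additive Gaussian noise on the
percent scale, and exponential uterotrophic dose–response with lognormal
noise — positive-valued measurements get lognormal noise, normalized
percent responses additive Gaussian. Default conditions: depletion
k = 0.0875 min⁻¹ (the male-rat E2 value), CV 5%, 3 replicates on the
standard 0–45 min grid; assay curves spanning ±3 decades around the EC50
with 2% noise; uterotrophic designs of 6–7 dose groups × 5 animals with 5%
CV, using an E2-like (0–0.4 mg/kg) or BPA-like (0–800 mg/kg) dose grid.
Every generator returns its generating parameters as a manifest, enabling
recovery tests against known truth.

What the fixtures do *not* emulate: real assay artifacts (cytotoxicity at
high concentrations, solvent effects, plate effects), inter-study
variability of in vivo uterus weights, or deviations of real kinetics from
the model family (e.g. saturable metabolism). Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model assumptions, not robustness to model misspecification. The
comparison of predictions against real in vivo kinetic and uterotrophic
datasets requires those external datasets; the package instead verifies
the order-of-magnitude structure end to end — a 4-decade in vitro potency
gap between an E2-like and a BPA-like curve translates into a ≳4-decade
gap in predicted BMDL₁₀.

## Numerical choices

The ODE system is stiff when clearance is fast; it is integrated with
LSODA at rtol 10⁻⁸ / atol 10⁻¹² (atol scaled by the dose), with a
dense-output refinement of the C_max between the bracketing output grid
points. Mass balance — body + gut + metabolized + unabsorbed vs the dose —
is checked at every output time and a relative error above 10⁻⁶ fails the
simulation loudly (observed errors are ~10⁻¹⁴). Halving the tolerances
changes C_max by far less than 0.1%. AUC is trapezoidal on the output
grid (default 481 points over 24 h). A zero dose short-circuits to an
exactly-zero result.

Degenerate inputs are errors, not silent defaults: non-positive depletion
ratios, a zero buffer-chamber concentration (compound not recovered),
missing tissues in a composition table, fractions outside (0, 1],
unreachable reverse-dosimetry targets. RED ratios slightly above 1 are
clipped to 1 with a warning, since a protein-poor matrix can produce them
by measurement noise alone.

## Problem sizes

Default problem sizes were chosen so the full suite runs interactively:
481-point output grids, 13-point assay curves, 35-animal uterotrophic
designs, 200-replicate coverage checks for the profile-likelihood
interval. All are configurable upward.

## Known limitations

- The gut parameterization is a reconstruction (see above); absolute oral
  C_max predictions inherit its uncertainty, although the sensitivity
  screen shows which parameters matter.
- The QPPR ignores protein binding in tissues and blood; for highly
  protein-bound chemicals (both model compounds have f_ub ≤ 0.05 in serum)
  it will overestimate tissue:blood partitioning. Supplying measured PCs
  is preferred when available.
- C_max of the parent compound is the only internal dose metric (no AUC
  option), matching the assumption that peak concentration drives the
  uterotrophic response.
- The exponential BMD family is the single increasing 3-parameter member;
  no model averaging or covariate analysis.
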