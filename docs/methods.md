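# Methods

`qspvct` is a quantitative-systems-pharmacology (QSP) simulator of
tumor–immune dynamics in HER2-negative breast cancer under entinostat
(oral HDAC inhibitor), nivolumab (anti-PD-1) and ipilimumab
(anti-CTLA-4), together with the virtual-clinical-trial machinery used
to analyse such a model: Latin-hypercube virtual patients, RECIST
response classification, PRCC global sensitivity analysis and ROC
biomarker statistics.

## Model structure

Four compartments are represented: **central** (blood), **peripheral**
(lumped peripheral tissue), **tumor** (dynamic volume) and a lumped
**tumor-draining lymph node** (TDLN). The state vector (51 entries)
mixes cell counts (proliferating and dead cancer cells; naïve,
activated, effector and regulatory T cells; MDSCs; immature and mature
APCs), molecular amounts (tumor antigen, CCL2, Arg-I, NO, and the three
drugs in their compartments), and surface densities of the
immunological-synapse species. All rates are per day.

Tumor volume is algebraic: the summed volume of resident cells divided
by `1 − f_vol_other`, the volume fraction of vasculature, stroma and
interstitium (0.70). Diameter assumes a single spherical lesion.

### Cancer and antigen

Proliferating cancer cells grow logistically (carrying capacity in
cells) and die at a baseline rate plus Teff-mediated killing; dead
cells remain part of tumor volume until cleared (first-order, 0.05/d).
The total death flux releases antigen, which partitions between local
degradation and lymphatic transport to the TDLN, where it drives
saturable APC maturation. Antigen is one lumped species in arbitrary
units; tumor mutational burden (TMB) enters as the number of
tumor-specific T-cell clones, scaling the naïve T-cell pool available
for priming.

### T-cell priming and expansion

Naïve CD8 T cells are primed by mature APCs through kinetic
proofreading: a TCR–pMHC engagement must survive N = 4 sequential steps
(rate k_p) before antigen dissociation (rate k_off), contributing the
discrimination factor (k_p/(k_p+k_off))^N. The per-cell activation rate
multiplies antigen occupancy (half-max scaled by k_off/k_p, so weak
binders are doubly penalised) and a saturating mAPC term. Activated
cells divide through n = n₀ + w_tcr·S_tcr + w_costim·S_costim +
w_cyt·S_cyt generations (real-valued; 2ⁿ evaluated continuously) and a
fraction f_eff of daughters become effectors exported to blood. The
co-stimulatory signal is the Hill-transformed CD28 occupancy from the
TDLN synapse; the cytokine signal saturates in the activated-cell pool
(IL-2-class autocrine proxy). Regulatory T cells are primed in
parallel from their own clone pool at a fixed fraction of the Teff
priming signal.

### Trafficking, killing, exhaustion

Effectors exchange linearly between central and peripheral
compartments and enter the tumor proportionally to central count and
tumor volume (vascular-surface proxy); there is no direct
peripheral↔tumor flux. Intratumoral killing is
`k_kill · C · Teff/(total cellularity) · (1−H_PD1)(1−H_ArgI)(1−H_NO)`;
the density saturation bounds the per-cancer-cell hazard. Exhaustion
removes tumor Teff in proportion to their engagement fraction with
live cancer cells. Tumor Teff and Treg death accelerates with their
own density (crowding at 5×10⁴ and 2×10⁴ cells/µL): infiltrate density
is bounded whatever the influx, which also removes a volume–influx
positive feedback that would otherwise be unphysical.

### MDSC axis

MDSCs are recruited at a baseline density-rate (calibrated so the
chemokine-free steady-state density equals `rho_mdsc_ss`) plus a
CCL2-driven saturable term; cancer cells secrete CCL2. MDSCs secrete
Arg-I (tracked in enzymatic-activity units, mU, avoiding a molar
conversion) and NO. Both suppress killing through Hill factors; only
Arg-I drives intratumoral Treg expansion.

### Synapse contexts

All checkpoint reactions are 2-D mass-action systems on a synapse
patch (molecules/µm²), integrated as (fast) ODEs alongside the rest of
the system; complexes are states and free densities follow from
conservation totals, so receptor conservation is structural. Three
contexts exist: (1) naïve-T:APC in the TDLN — CD28 and CTLA-4 compete
for CD80/CD86, PD-L1 on the T cell sequesters CD80, and ipilimumab
binds CTLA-4 bivalently (first arm from solution, second arm at
χ·k_on from the surface); (2) Teff:cancer in the tumor — PD-1 binds
PD-L1/PD-L2 (PD-L2 fixed at 5% of PD-L1), nivolumab blocks by the same
cross-arm scheme, and H_PD1 is the Hill-transformed bound-PD-1
density, so a patient with zero PD-L1 copies has H_PD1 = 0 exactly;
(3) ipilimumab on tumor-Treg CTLA-4, whose occupancy drives
ADCC-mediated Treg depletion with a saturating transfer normalised so
that full occupancy yields exactly the maximal rate. ADCC ships
enabled (`adcc_enabled`) because its contribution in humans is
debated; it can be ablated by one flag.

A practical note on competition: when sampled PD-L1 exceeds ~10⁵
copies per cell, ligand rebinding starts to outcompete nivolumab for
free PD-1 at clinical concentrations, so the highest-PD-L1 patients
retain some suppression under therapy; over most of the sampled range,
however, 3 mg/kg q2w nivolumab saturates the blockade (see Known
limitations).

### Pharmacokinetics

Entinostat uses a dual-absorption oral model: a fraction F of each
dose enters a buccal depot by zero-order input over D₀ and is absorbed
first-order; the rest enters a GI depot after a lag T_lag. Central
drug distributes to peripheral and tumor spaces and is cleared by
parallel linear and Michaelis–Menten pathways. The constants
(F = 0.176, D₀ = 0.4 h, T_lag = 2 h, ka = 12/0.15 h⁻¹, Vc = 27.9 L,
CL = 30.2 L/h, Vmax = 2×10⁴ ng/h with Km = 50 ng/mL, k_cp = 0.08 h⁻¹,
k_pc = 0.008 h⁻¹) were calibrated by least squares to the published
plasma summaries (Cmax 15.4/30.8/46.3 ng/mL and AUC₀–₄₈
105.5/211.0/316.8 ng·h/mL at 2/4/6 mg/m², tmax 0.5 h at all doses);
the near-linear AUC ratios pin the Michaelis–Menten pathway to a small
contribution, and the slow peripheral return gives a terminal
half-life of ≈ 93 h, consistent with the long half-life reported for
entinostat. Published-per-hour constants are converted to per-day at
table load. Antibodies follow linear two-compartment disposition with
first-order tumor/TDLN exchange against an interstitial partition
coefficient (γ = 0.3 tumor, 0.5 TDLN); parameters are standard
population-PK values for nivolumab and ipilimumab.

Entinostat pharmacodynamics are Hill inhibitions of: cancer
proliferation, NO production, CCL2 production, and Arg-I *activity*
(a multiplier on effective Arg-I concentration wherever it acts). A
fifth coupling on Arg-I *production* exists but is disabled by
default, since sources disagree on whether production or activity is
the target; each coupling is independently configurable.

### Events and integration

Doses are discrete events: the integrator stops at each event time,
boluses are added to the state (IV antibodies to central; the GI
portion of an entinostat dose after T_lag), and the zero-order buccal
input is a piecewise-constant rate active on [t, t+D₀], so each
segment sees a smooth autonomous right-hand side. Each segment is
integrated on a local time origin (the RHS is autonomous), which keeps
step-size selection independent of absolute time late in a run.
Default tolerances are abstol 10⁻¹² and reltol 10⁻⁶ with LSODA; BDF is
available and agrees with LSODA on terminal diameter to better than
three significant figures. Small negative undershoots at segment
boundaries are clamped to zero; clamps larger than abstol are logged
in the event log. The right-hand side is one scalar-arithmetic kernel
compiled with numba (plain Python fallback); it calls the same
rate-law functions the unit tests exercise, so there is a single
source of truth for every flux.

## Baseline protocol and the virtual trial

Each virtual patient is a Latin-hypercube draw of 32 parameters
(growth, killing, exhaustion, TMB, PD-L1 copies, MDSC/Treg densities,
secretion rates, suppression EC50s, antigen affinity, activation
throughput, entinostat absorption/clearance, initial tumor diameter).
The patient is simulated untreated from a **single cancer cell** until
tumor volume crosses the preselected initial volume (root-finding
event detection on volume − target); the full state at crossing is the
saved baseline. Patients that never reach the target within 10
simulated years are immune-controlled and excluded from response
analysis. Under the reference table about four in five sampled
patients reach baseline, matching the scale of the protocol this
emulates (1196/1500). The identical baselined cohort is then
simulated for 400 days under each regimen (3 mg/kg nivolumab q14d;
+5 mg entinostat weekly; +1 mg/kg ipilimumab q42d × 4), so regimen
contrasts are paired.

Responses are classified by RECIST v1.1 from the weekly diameter
trajectory: CR below a 2 mm detection floor (configurable; the
criterion for a simulated continuous diameter must be chosen), PR at
≥30% shrinkage sustained to the horizon, PD at ≥20% and ≥5 mm growth
from nadir, SD otherwise. Besides baseline ("pre") and horizon
("post") observables, a week-12 ("mid", day 84) snapshot is recorded:
ipilimumab is dosed only through week 18 and clears with a ~8-day
half-life, so ADCC-driven Treg depletion is an on-treatment effect
that has washed out by day 400; week 12 is the natural biopsy
analogue for Teff:Treg contrasts.

## Statistics

* **PRCC** — rank-transform everything, residualise each parameter and
  the output on the remaining parameters, correlate residuals;
  p-values by the t approximation. No multiplicity adjustment by
  default (a Benjamini–Hochberg helper is available in `scipy` should
  users need it); invariant to monotone transforms.
* **Agresti–Coull CI** — pseudo-count-adjusted normal interval,
  clipped to [0, 1].
* **Percentile bootstrap** — resample 15 patients with replacement
  (100,000 reps) and take pure order-statistic 2.5/97.5 percentiles;
  no interpolation, because sample proportions live on a 1/15 grid and
  interpolated percentiles would fabricate unattainable values. The
  empirical quantiles converge to the exact Binomial(15, p) quantile
  function, which the tests assert.
* **Wilcoxon rank-sum** — midranks for ties; exact enumeration of all
  label assignments when n₁+n₂ ≤ 12, else normal approximation with
  continuity and tie corrections.
* **ROC** — all distinct cutoffs; orientation follows the biomarker's
  stated direction (higher-is-responder for TMB, Teff density,
  Teff:Treg; lower-is-responder for MDSC density) and is never flipped
  to force AUC ≥ 0.5; AUC equals the Mann–Whitney U statistic divided
  by n₁n₂.

## Parameter provenance and calibration

The reference table (`make_reference_table`) tags every entry:
`supplementary-table` for values with direct literature anchors,
`fitted` for the entinostat PK constants calibrated to the published
plasma summaries, and `assumed` for documented plausible defaults.
The assumed values and the 32 sampling distributions were chosen once
to reproduce the qualitative study conditions — tumors form untreated
in ~80% of draws; anti-PD-1 monotherapy produces a response rate
around 20%; adding entinostat raises it; adding ipilimumab leaves the
responder count nearly unchanged while lowering mean post-treatment
volume and sharply raising on-treatment Teff:Treg — and frozen. In a
100-patient pilot the frozen table gives reached = 0.83, ORR 0.205
(mono), 0.337 (double), 0.349 (triple), with the triple arm's median
on-treatment Teff:Treg 7.4× the double arm's.

## What the synthetic layers do and do not show

`make_synthetic_trial` plants a known logistic biomarker→response
structure (log-normal biomarkers, stated weights, tunable effect and
noise) so that the statistics layer can be validated against ground
truth without the ODE model. Passing those tests shows the estimators
are correct, not that the ODE model is. The ODE-level tests use the
reference table, whose assumed entries are documented plausible
defaults rather than a published parameterization: cohort-level *directions* (which parameters
drive outcome, which biomarkers rank highest, what each added drug
changes) are meaningful under it, while absolute response rates are
conditional on the assumed distributions and should be read as
scenario outputs, not predictions about patients.

## Problem sizes

Cohort-level tests use one shared paired trial: 320 sampled patients
(~265 evaluable) under monotherapy and double therapy, the first 150
evaluable also under triple therapy. These sizes give >99% power for
the directional response contrast at the observed effect sizes while
keeping the full suite at desk scale on a single CPU. The
single-patient checks (solver agreement, conservation, convergence)
use the reference patient at horizons of 28–150 days.

## Known limitations

* One lumped lesion; no spatial structure, no per-lesion RECIST sums.
* No toxicity, dropout or dose modification; regimens run to horizon.
* Antibody disposition is linear (no target-mediated clearance);
  entinostat tumor exchange is a single first-order pair.
* Exhaustion is irreversible; PD-1 blockade restores killing but does
  not recover exhausted cells (config switch reserved).
* Treg suppression of killing is represented only through the
  Arg-I/NO axis and engagement-fraction dilution, not as a direct
  inhibition factor.
* The macrophage axis and PD-L1 on immune cells are out of scope.
* Under 3 mg/kg q2w nivolumab the modelled tumor antibody exposure
  saturates PD-1 blockade over most of the sampled PD-L1 range, and
  the single-cell growth protocol preferentially removes low-PD-L1
  immunogenic patients before baseline. Together these make the
  cohort-level sensitivity of end tumor volume to PD-L1 copy number
  weak and sign-unstable under the reference distributions, even
  though the per-patient dose–response is monotone (high-PD-L1
  patients do worse, all else fixed). Reproducing a strong PD-L1
  sensitivity would require a different balance of tumor antibody
  exposure and synapse parameters than the documented defaults.
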