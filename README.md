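# qspvct

Quantitative-systems-pharmacology (QSP) simulation of tumor–immune
dynamics in HER2-negative breast cancer under an epigenetic modulator
(entinostat) combined with immune checkpoint inhibitors (nivolumab,
ipilimumab), plus the machinery to run *in silico* virtual clinical
trials on that model.

**Who it is for.** Modellers and pharmacometricians who want to
explore how checkpoint-inhibitor combinations behave across a
heterogeneous virtual population — which patient characteristics
(tumor mutational burden, tumor-infiltrating effector T cells,
Teff:Treg ratio, MDSC density, PD-L1 expression) drive response, and
what adding an HDAC inhibitor or an anti-CTLA-4 antibody changes.

## The model in brief

A stiff ODE system over four compartments — central, peripheral,
tumor, tumor-draining lymph node (TDLN) — couples five modules:

* **pk** — entinostat dual absorption (zero-order buccal fraction F
  over D₀ + lagged first-order GI), two-compartment disposition,
  parallel linear + Michaelis–Menten clearance; linear two-compartment
  antibody PK with tumor/TDLN exchange.
* **cancer_antigen** — logistic tumor growth under Hill inhibition by
  entinostat; dead-cell pool; antigen release ∝ death flux, lymphatic
  transport, APC maturation.
* **tcell** — kinetic-proofreading activation,
  (k_p/(k_p+k_off))^N, signal-dependent proliferation burst 2ⁿ with
  n = n₀ + Σ wᵢSᵢ, trafficking, killing
  k·C·(Teff/cellularity)·(1−H_PD1)(1−H_ArgI)(1−H_NO), exhaustion.
* **synapse** — 2-D mass-action checkpoint systems (CD28/CTLA-4 vs
  CD80/CD86 + PD-L1:CD80 in the TDLN; PD-1 vs PD-L1/2 in the tumor),
  bivalent cross-arm antibody binding, ADCC Treg depletion.
* **mdsc** — CCL2-driven recruitment; Arg-I (mU) and NO secretion
  suppressing killing; Arg-I-driven Treg expansion; entinostat PD on
  each axis.

Tumor volume is the summed cell volume over (1 − interstitial
fraction); diameter assumes a sphere. Virtual patients are Latin
hypercube draws of 32 parameters, each grown from a **single cancer
cell** until the preselected initial tumor volume is reached (patients
whose immune system wins first are excluded, as in the emulated
protocol), then treated for 400 days and classified by RECIST v1.1.

See `docs/methods.md` for the full model account, calibration notes
and limitations.

## Worked example

```python
from qspvct import (build_model, make_reference_table, preset_regimen,
                    sample_cohort, establish_baselines, run_regimen)

params, dists = make_reference_table()

# one reference patient: grow to a 3 cm tumor, then treat
system = build_model(params)
state, t0 = system.grow_to_baseline(3.0)
print(f"reached 3 cm after {t0:.0f} days of untreated growth")
sim = system.simulate(state, (0, 400), regimen=preset_regimen("nivo+enti"))
d = sim.tumor_diameter_cm()
print(f"baseline {d[0]:.2f} cm -> nadir {d.min():.2f} cm -> day 400 {d[-1]:.2f} cm")

# a small paired virtual trial
cohort = sample_cohort(dists, 100, seed=11)
establish_baselines(cohort, params)
mono = run_regimen(cohort, preset_regimen("nivo-mono"), params)
double = run_regimen(cohort, preset_regimen("nivo+enti"), params)
lo, hi = double.orr_ci()
print(f"evaluable {double.n_evaluable}/100")
print(f"ORR mono {mono.orr():.1%} vs double {double.orr():.1%} "
      f"(95% CI {lo:.1%}-{hi:.1%})")
```

prints

```
reached 3 cm after 790 days of untreated growth
baseline 3.00 cm -> nadir 0.47 cm -> day 400 0.82 cm
evaluable 83/100
ORR mono 20.5% vs double 33.7% (95% CI 24.5%-44.4%)
```

The reference patient responds to the double combination (nadir well
below −30%, partial response with late regrowth). At the cohort level
about four in five sampled patients develop a tumor; adding weekly
entinostat to nivolumab raises the objective response rate, here from
20.5% to 33.7% (Agresti–Coull 95% CI for the double arm shown).
Absolute rates are conditional on the documented reference
distributions; the paired *contrast* between regimens is the robust
output.

A command-line layer wraps the same calls:

```bash
qspvct simulate-pk --dose 2 --bsa 1.7 --hours 48 --out profile.csv
qspvct run-patient --regimen nivo+enti --days 400 --out patient/
qspvct run-trial --n 100 --seed 11 --regimen nivo+enti --out trial/
qspvct analyze --trial trial/ --prcc --roc --subgroups
qspvct fixtures --scenario default --n 500 --out fixtures/
```

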