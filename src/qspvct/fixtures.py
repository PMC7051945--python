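"""Self-contained reference inputs.

The reference parameter table carries every symbol the model needs,
with units, provenance tags, and — for the 32 virtual-patient
parameters — sampling distributions.  Entinostat PK constants are
calibrated to published plasma summaries (provenance ``fitted``);
physiological constants with literature anchors are tagged
``supplementary-table``-style values where available and ``assumed``
where they are documented plausible defaults chosen to reproduce the
qualitative trial behaviours (tumors form untreated; checkpoint
blockade shrinks a minority of them; entinostat adds benefit through
the MDSC axis).

``make_synthetic_trial`` generates a toy cohort with a planted
biomarker→response structure so the statistical layer can be tested
against known ground truth without running the ODE model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterEntry, ParameterSet
from .trial import ParameterDistributionTable

A = "assumed"
S = "supplementary-table"
F = "fitted"


def _e(name, value, unit="dimensionless", prov=A, dist=None):
    if dist is None:
        return ParameterEntry(name, value, unit, provenance=prov)
    kind, lo, hi = dist
    return ParameterEntry(name, value, unit, kind, lo, hi, prov)


def make_reference_table() -> tuple[ParameterSet, ParameterDistributionTable]:
    """The reference parameter table and its 32-parameter sampling subset."""
    entries = [
        # --- geometry & compartments ---------------------------------
        _e("d_cell_cancer", 17.0, "um", S),
        _e("d_cell_lymphocyte", 7.0, "um", A),
        _e("f_vol_other", 0.70, "dimensionless", A),
        _e("v_central", 5.0, "L", S),
        _e("v_peripheral", 60.0, "L", S),
        _e("v_ln", 5e-3, "L", A),
        # --- cancer ---------------------------------------------------
        _e("r_growth", 0.035, "1/d", S, ("loguniform", 0.02, 0.07)),
        _e("k_capacity", 1.5e10, "cell", A, ("loguniform", 5e9, 3e10)),
        _e("d_cancer", 0.008, "1/d", A, ("uniform", 0.004, 0.012)),
        _e("k_clear_dead", 0.05, "1/d", A),
        _e("pdl1_copies", 8e4, "molec/cell", S, ("loguniform", 5e3, 4e5)),
        # --- entinostat PK (calibrated to plasma summaries) -----------
        _e("ent_f_buccal", 0.176, "dimensionless", F),
        _e("ent_d0", 0.4, "h", F),
        _e("ent_tlag", 2.0, "h", F),
        _e("ent_ka_buccal", 12.0, "1/h", F, ("loguniform", 5.0, 30.0)),
        _e("ent_ka_gi", 0.15, "1/h", F, ("loguniform", 0.05, 0.5)),
        _e("ent_v_central", 27.86, "L", F),
        _e("ent_v_peripheral", 800.0, "L", F),
        _e("ent_k_cp", 0.08, "1/h", F),
        _e("ent_k_pc", 0.008, "1/h", F),
        _e("ent_k_tumor_ex", 0.1, "1/h", A),
        _e("ent_cl_linear", 30.23, "L/h", F, ("loguniform", 15.0, 60.0)),
        _e("ent_vmax_nl", 2e4, "ng/h", F, ("loguniform", 5e3, 1e5)),
        _e("ent_km_nl", 50.0, "ng/mL", F),
        # --- entinostat PD --------------------------------------------
        _e("ent_imax_prolif", 0.9, "dimensionless", S),
        _e("ent_ic50_prolif", 1.0, "ng/mL", S),
        _e("ent_n_prolif", 1.0, "dimensionless", A),
        _e("ent_imax_no", 0.95, "dimensionless", A),
        _e("ent_ic50_no", 0.5, "ng/mL", A),
        _e("ent_n_no", 1.0, "dimensionless", A),
        _e("ent_imax_ccl2", 0.95, "dimensionless", A),
        _e("ent_ic50_ccl2", 0.5, "ng/mL", A),
        _e("ent_n_ccl2", 1.0, "dimensionless", A),
        _e("ent_imax_argact", 0.9, "dimensionless", A),
        _e("ent_ic50_argact", 0.5, "ng/mL", A),
        _e("ent_n_argact", 1.0, "dimensionless", A),
        _e("ent_imax_argiprod", 0.0, "dimensionless", A),  # off by default
        _e("ent_ic50_argiprod", 0.5, "ng/mL", A),
        _e("ent_n_argiprod", 1.0, "dimensionless", A),
        # --- antibody PK ----------------------------------------------
        _e("niv_v_central", 3.63, "L", S),
        _e("niv_v_peripheral", 2.78, "L", S),
        _e("niv_k12", 0.212, "1/d", S),
        _e("niv_k21", 0.277, "1/d", S),
        _e("niv_cl", 0.228, "L/d", S),
        _e("niv_k_tumor_ex", 1.0, "1/d", A),
        _e("niv_k_ln_ex", 5.0, "1/d", A),
        _e("niv_gamma_tumor", 0.3, "dimensionless", A),
        _e("niv_gamma_ln", 0.5, "dimensionless", A),
        _e("ipi_v_central", 4.15, "L", S),
        _e("ipi_v_peripheral", 3.0, "L", S),
        _e("ipi_k12", 0.188, "1/d", S),
        _e("ipi_k21", 0.26, "1/d", S),
        _e("ipi_cl", 0.36, "L/d", S),
        _e("ipi_k_tumor_ex", 1.0, "1/d", A),
        _e("ipi_k_ln_ex", 5.0, "1/d", A),
        _e("ipi_gamma_tumor", 0.3, "dimensionless", A),
        _e("ipi_gamma_ln", 0.5, "dimensionless", A),
        # --- antigen & APC --------------------------------------------
        _e("ag_release", 1.0, "au/cell", A, ("loguniform", 0.3, 3.0)),
        _e("k_ag_transport", 0.1, "1/d", A),
        _e("k_ag_deg", 2.0, "1/d", A),
        _e("k_ag_deg_ln", 1.0, "1/d", A),
        _e("apc0", 1e5, "cell", A),
        _e("k_apc_mat", 2.0, "1/d", A),
        _e("k_ag_apc_half", 1e5, "au", A),
        _e("d_apc_imm", 0.1, "1/d", A),
        _e("d_mapc", 0.5, "1/d", A),
        # --- activation (kinetic proofreading) ------------------------
        _e("tmb_clones", 300.0, "count", S, ("loguniform", 30.0, 6000.0)),
        _e("nt0_per_clone", 200.0, "cell", A, ("loguniform", 60.0, 600.0)),
        _e("d_naive", 0.1, "1/d", A),
        _e("k_proofread", 1.0, "1/s", S),
        _e("n_proofread", 4.0, "dimensionless", S),
        _e("k_off_tcr", 1.0, "1/s", S, ("loguniform", 0.2, 5.0)),
        _e("k_ag_occ", 3e5, "au", A),
        _e("k_mapc_half", 5e3, "cell", A),
        _e("lambda_act_max", 6.0, "1/d", A, ("loguniform", 2.0, 12.0)),
        # --- proliferation burst --------------------------------------
        _e("n0_gen", 6.0, "dimensionless", S, ("uniform", 5.0, 7.0)),
        _e("w_tcr", 3.0, "dimensionless", A),
        _e("w_costim", 3.0, "dimensionless", A, ("uniform", 1.5, 4.5)),
        _e("w_cyt", 3.0, "dimensionless", A),
        _e("k_mat_t", 0.4, "1/d", A),
        _e("f_eff", 0.7, "dimensionless", A, ("uniform", 0.5, 0.9)),
        _e("k_cyt_half", 2e3, "cell", A),
        # --- Treg activation ------------------------------------------
        _e("ntreg0", 1e4, "cell", A),
        _e("lambda_act_treg", 0.3, "1/d", A),
        _e("n_gen_treg", 4.0, "dimensionless", A),
        # --- Teff trafficking / death ---------------------------------
        _e("k_te_cp", 0.8, "1/d", A),
        _e("k_te_pc", 0.4, "1/d", A),
        _e("k_te_entry", 0.02, "1/d", A, ("loguniform", 0.005, 0.08)),
        _e("v_ref_entry", 1e-3, "L", A),
        _e("d_te_central", 0.05, "1/d", A),
        _e("d_te_peripheral", 0.02, "1/d", A),
        _e("d_te_tumor", 0.15, "1/d", A, ("uniform", 0.08, 0.3)),
        _e("teff_crowd_density", 5e4, "cell/uL", A),
        # --- Treg pools -----------------------------------------------
        _e("tr_c0", 1e8, "cell", A),
        _e("d_tr_central", 0.05, "1/d", A),
        _e("k_tr_cp", 0.5, "1/d", A),
        _e("k_tr_pc", 0.2, "1/d", A),
        _e("d_tr_peripheral", 0.05, "1/d", A),
        _e("rho_treg_ss", 400.0, "cell/uL", S, ("loguniform", 100.0, 2000.0)),
        _e("d_tr_tumor", 0.1, "1/d", A),
        _e("k_treg_exp_max", 0.15, "1/d", A, ("uniform", 0.05, 0.25)),
        _e("ec50_argi_treg", 0.5, "mU", S, ("loguniform", 0.1, 2.0)),
        _e("treg_crowd_density", 2e4, "cell/uL", A),
        # --- killing / exhaustion -------------------------------------
        _e("k_kill", 12.0, "1/d", S, ("loguniform", 3.0, 60.0)),
        _e("imax_argi_kill", 0.9, "dimensionless", A),
        _e("ec50_argi_kill", 0.5, "mU", S, ("loguniform", 0.1, 2.0)),
        _e("n_argi_kill", 1.0, "dimensionless", A),
        _e("imax_no_kill", 0.9, "dimensionless", A),
        _e("ec50_no_kill", 0.5, "uM", S, ("loguniform", 0.1, 2.0)),
        _e("n_no_kill", 1.0, "dimensionless", A),
        _e("k_exhaust", 0.2, "1/d", A, ("loguniform", 0.02, 1.0)),
        # --- MDSC -----------------------------------------------------
        _e("rho_mdsc_ss", 3000.0, "cell/uL", S, ("loguniform", 500.0, 8000.0)),
        _e("d_mdsc", 0.1, "1/d", A, ("uniform", 0.05, 0.2)),
        _e("r_mdsc_max", 600.0, "cell/uL/d", A),
        _e("ec50_ccl2_rec", 1.0, "nM", S),
        _e("k_argi_sec", 5e-4, "mU*uL/cell/d", S, ("loguniform", 1e-4, 2e-3)),
        _e("d_argi", 5.0, "1/d", A),
        _e("k_no_sec", 2e-6, "nmol/cell/d", S, ("loguniform", 5e-7, 8e-6)),
        _e("d_no", 20.0, "1/d", A),
        _e("k_ccl2_sec", 2e-11, "nmol/cell/d", S, ("loguniform", 5e-12, 8e-11)),
        _e("d_ccl2", 2.0, "1/d", A),
        # --- TDLN synapse ---------------------------------------------
        _e("cd28_tot", 150.0, "molec/um^2", S),
        _e("ctla4_tot", 40.0, "molec/um^2", S),
        _e("cd80_tot", 60.0, "molec/um^2", S),
        _e("cd86_tot", 100.0, "molec/um^2", S),
        _e("pdl1t_tot", 40.0, "molec/um^2", A),
        _e("kon_2880", 200.0, "um^2/molec/d", S),
        _e("koff_2880", 1e4, "1/d", S),
        _e("kon_2886", 333.0, "um^2/molec/d", S),
        _e("koff_2886", 1e4, "1/d", S),
        _e("kon_c80", 5000.0, "um^2/molec/d", S),
        _e("koff_c80", 2000.0, "1/d", S),
        _e("kon_c86", 800.0, "um^2/molec/d", S),
        _e("koff_c86", 2000.0, "1/d", S),
        _e("kon_p80", 400.0, "um^2/molec/d", S),
        _e("koff_p80", 1e4, "1/d", S),
        _e("ipi_kon", 8.64, "1/nM/d", S),
        _e("ipi_koff", 30.0, "1/d", S),
        _e("ipi_chi", 10.0, "molec/um^2/nM", A),
        _e("ec50_costim", 90.0, "molec/um^2", A),
        _e("n_costim", 4.0, "dimensionless", A),
        # --- tumor synapse --------------------------------------------
        _e("pd1_tot", 50.0, "molec/um^2", S),
        _e("pdl1_area", 900.0, "um^2", A),
        _e("pdl2_frac", 0.05, "dimensionless", A),
        _e("kon_pdl1", 1250.0, "um^2/molec/d", S),
        _e("koff_pdl1", 1e4, "1/d", S),
        _e("kon_pdl2", 5000.0, "um^2/molec/d", S),
        _e("koff_pdl2", 1e4, "1/d", S),
        _e("niv_kon", 8.64, "1/nM/d", S),
        _e("niv_koff", 22.5, "1/d", S),
        _e("niv_chi", 50.0, "molec/um^2/nM", A),
        _e("ec50_pd1", 10.0, "molec/um^2", A),
        _e("n_pd1", 2.0, "dimensionless", A),
        # --- ADCC -----------------------------------------------------
        _e("ctla4_treg_tot", 40.0, "molec/um^2", S),
        _e("k_adcc_max", 0.3, "1/d", S, ("loguniform", 0.05, 1.0)),
        _e("k_adcc_half", 0.3, "dimensionless", A),
        _e("adcc_enabled", 1.0, "dimensionless", A),
        # --- initial immune pools -------------------------------------
        _e("te_c0", 0.0, "cell", A),
        _e("te_p0", 0.0, "cell", A),
        # --- trial-engine-only ----------------------------------------
        _e("initial_tumor_diameter", 3.0, "cm", A, ("uniform", 1.5, 4.0)),
    ]
    ps = ParameterSet(entries)
    return ps, ParameterDistributionTable.from_parameterset(ps)


# ---------------------------------------------------------------------------
# synthetic trial cohorts with planted structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Scenario for a synthetic cohort with a planted biomarker effect.

    ``effect`` scales the (log-scale, standardised) biomarker
    contributions to the latent outcome; ``noise`` is the sd of the
    additive noise.  ``effect = 0`` plants no separation at all.
    """

    scenario: str = "default"
    n: int = 500
    seed: int = 0
    effect: float = 1.0
    noise: float = 1.0


#: planted latent-outcome weights (sign convention: larger latent value
#: = larger end tumor volume = non-response)
PLANTED_WEIGHTS = {
    "tmb": -1.0,
    "teff_density": -0.7,
    "teff_treg_ratio": -0.5,
    "mdsc_density": +0.6,
}


def make_synthetic_trial(spec: FixtureSpec):
    """Cohort biomarkers + latent volume + responder labels.

    Biomarkers are log-normal; the latent outcome is the planted linear
    combination of their z-scores plus noise; responders are the
    patients whose latent outcome falls below its theoretical median.
    """
    rng = np.random.default_rng(spec.seed)
    z = {k: rng.standard_normal(spec.n) for k in PLANTED_WEIGHTS}
    latent = spec.effect * sum(w * z[k] for k, w in PLANTED_WEIGHTS.items())
    latent = latent + spec.noise * rng.standard_normal(spec.n)

    import pandas as pd

    df = pd.DataFrame(
        {
            "patient_id": np.arange(spec.n),
            "tmb": np.exp(1.5 + 0.8 * z["tmb"]),
            "teff_density": np.exp(6.0 + 1.0 * z["teff_density"]),
            "teff_treg_ratio": np.exp(-1.0 + 0.7 * z["teff_treg_ratio"]),
            "mdsc_density": np.exp(7.5 + 0.9 * z["mdsc_density"]),
            "latent_volume": latent,
            "responder": latent < 0.0,
        }
    )
    return df
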