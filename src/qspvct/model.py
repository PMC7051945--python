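"""Compartmental scaffold, ODE assembly and event-aware integration.

The model spans four compartments — central (blood), peripheral, tumor,
and a lumped tumor-draining lymph node (TDLN) — and couples five
mechanistic modules (``pk``, ``cancer_antigen``, ``tcell``, ``synapse``,
``mdsc``).  The full state vector mixes cell counts, molecular amounts
and synapse surface densities; tumor volume is an algebraic observable
recomputed from cell counts at every evaluation, and tumor diameter
follows from the spherical-tumor assumption.

Therapy is applied as discrete dose events: the integrator is stopped
at every event time, boluses are added to the state, and zero-order
buccal infusions are represented as a piecewise-constant input rate, so
each integration segment sees a smooth right-hand side.

The right-hand side is a single scalar-arithmetic kernel (numba-jitted
when available) that calls the same rate-law functions the unit tests
exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._jit import njit
from . import cancer as _cancer
from . import mdsc as _mdsc
from . import synapse as _syn
from . import tcell as _tcell
from .pk import Regimen, MW_G_PER_MOL, antibody_fluxes, entinostat_fluxes
from .params import ParameterSet

COMPARTMENTS = ("central", "peripheral", "tumor", "tdln")
MODULE_NAMES = ("pk", "cancer_antigen", "tcell", "synapse", "mdsc")


class ModelBuildError(ValueError):
    """Raised when the parameter table cannot support the requested model."""


@dataclass(frozen=True)
class CompartmentSpec:
    name: str
    volume_l: float  # tumor volume is dynamic; this is the reference/initial value

    def __post_init__(self) -> None:
        if self.name not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.name!r}")
        if self.volume_l <= 0:
            raise ValueError("compartment volume must be > 0")


# ---------------------------------------------------------------------------
# state layout
# ---------------------------------------------------------------------------

# (name, compartment) in vector order
SPECIES: list[tuple[str, str]] = [
    ("cancer_proliferating", "tumor"),
    ("cancer_dead", "tumor"),
    ("naive_t", "tdln"),
    ("activated_t", "tdln"),
    ("teff", "central"),
    ("teff", "peripheral"),
    ("teff", "tumor"),
    ("naive_treg", "tdln"),
    ("activated_treg", "tdln"),
    ("treg", "central"),
    ("treg", "peripheral"),
    ("treg", "tumor"),
    ("mdsc", "tumor"),
    ("apc_immature", "tdln"),
    ("mapc", "tdln"),
    ("antigen", "tumor"),
    ("antigen", "tdln"),
    ("ccl2", "tumor"),
    ("argI", "tumor"),
    ("no", "tumor"),
    ("entinostat", "buccal"),
    ("entinostat", "gi"),
    ("entinostat", "central"),
    ("entinostat", "peripheral"),
    ("entinostat", "tumor"),
    ("entinostat", "eliminated"),
    ("nivolumab", "central"),
    ("nivolumab", "peripheral"),
    ("nivolumab", "tumor"),
    ("nivolumab", "tdln"),
    ("nivolumab", "eliminated"),
    ("ipilimumab", "central"),
    ("ipilimumab", "peripheral"),
    ("ipilimumab", "tumor"),
    ("ipilimumab", "tdln"),
    ("ipilimumab", "eliminated"),
    ("syn_cd28_cd80", "tdln"),
    ("syn_cd28_cd86", "tdln"),
    ("syn_ctla4_cd80", "tdln"),
    ("syn_ctla4_cd86", "tdln"),
    ("syn_pdl1_cd80", "tdln"),
    ("syn_ctla4_ipi", "tdln"),
    ("syn_ctla4_ipi_ctla4", "tdln"),
    ("syn_pd1_pdl1", "tumor"),
    ("syn_pd1_pdl2", "tumor"),
    ("syn_pd1_niv", "tumor"),
    ("syn_pd1_niv_pd1", "tumor"),
    ("syn_treg_ctla4_ipi", "tumor"),
    ("syn_treg_ctla4_ipi_ctla4", "tumor"),
    ("cancer_produced_cum", "tumor"),
    ("cancer_cleared_cum", "tumor"),
]

N_STATES = len(SPECIES)
SPECIES_INDEX = {f"{name}.{comp}": i for i, (name, comp) in enumerate(SPECIES)}

# integer state indices as module globals (frozen into the jitted kernel)
for _i, (_n, _c) in enumerate(SPECIES):
    globals()[f"S_{_n.upper()}_{_c.upper()}"] = _i

# tumor-resident cell species that occupy volume
_TUMOR_CELL_IDX = [
    SPECIES_INDEX["cancer_proliferating.tumor"],
    SPECIES_INDEX["cancer_dead.tumor"],
    SPECIES_INDEX["teff.tumor"],
    SPECIES_INDEX["treg.tumor"],
    SPECIES_INDEX["mdsc.tumor"],
]

# ---------------------------------------------------------------------------
# kernel parameter vector layout
# ---------------------------------------------------------------------------

PARAM_ORDER: list[str] = [
    # geometry / compartments
    "d_cell_cancer", "d_cell_lymphocyte", "f_vol_other",
    "v_central", "v_peripheral", "v_ln",
    # cancer
    "r_growth", "k_capacity", "d_cancer", "k_clear_dead", "pdl1_copies",
    # entinostat PK (day units after conversion)
    "ent_f_buccal", "ent_d0", "ent_tlag", "ent_ka_buccal", "ent_ka_gi",
    "ent_v_central", "ent_v_peripheral", "ent_k_cp", "ent_k_pc",
    "ent_k_tumor_ex", "ent_cl_linear", "ent_vmax_nl", "ent_km_nl",
    # entinostat PD (five couplings; enable flags are ordinary parameters 0/1)
    "ent_imax_prolif", "ent_ic50_prolif", "ent_n_prolif",
    "ent_imax_no", "ent_ic50_no", "ent_n_no",
    "ent_imax_ccl2", "ent_ic50_ccl2", "ent_n_ccl2",
    "ent_imax_argact", "ent_ic50_argact", "ent_n_argact",
    "ent_imax_argiprod", "ent_ic50_argiprod", "ent_n_argiprod",
    # antibody PK
    "niv_v_central", "niv_v_peripheral", "niv_k12", "niv_k21", "niv_cl",
    "niv_k_tumor_ex", "niv_k_ln_ex", "niv_gamma_tumor", "niv_gamma_ln",
    "ipi_v_central", "ipi_v_peripheral", "ipi_k12", "ipi_k21", "ipi_cl",
    "ipi_k_tumor_ex", "ipi_k_ln_ex", "ipi_gamma_tumor", "ipi_gamma_ln",
    # antigen / APC
    "ag_release", "k_ag_transport", "k_ag_deg", "k_ag_deg_ln",
    "apc0", "k_apc_mat", "k_ag_apc_half", "d_apc_imm", "d_mapc",
    # activation (kinetic proofreading)
    "tmb_clones", "nt0_per_clone", "d_naive", "k_proofread", "n_proofread",
    "k_off_tcr", "k_ag_occ", "k_mapc_half", "lambda_act_max",
    # proliferation burst
    "n0_gen", "w_tcr", "w_costim", "w_cyt", "k_mat_t", "f_eff", "k_cyt_half",
    # treg activation
    "ntreg0", "lambda_act_treg", "n_gen_treg",
    # Teff trafficking / death
    "k_te_cp", "k_te_pc", "k_te_entry", "v_ref_entry", "d_te_central",
    "d_te_peripheral", "d_te_tumor", "teff_crowd_density",
    # Treg pools
    "tr_c0", "d_tr_central", "k_tr_cp", "k_tr_pc", "d_tr_peripheral",
    "rho_treg_ss", "d_tr_tumor", "k_treg_exp_max", "ec50_argi_treg",
    "treg_crowd_density",
    # killing / exhaustion
    "k_kill", "imax_argi_kill", "ec50_argi_kill", "n_argi_kill",
    "imax_no_kill", "ec50_no_kill", "n_no_kill", "k_exhaust",
    # MDSC
    "rho_mdsc_ss", "d_mdsc", "r_mdsc_max", "ec50_ccl2_rec",
    "k_argi_sec", "d_argi", "k_no_sec", "d_no", "k_ccl2_sec", "d_ccl2",
    # TDLN synapse
    "cd28_tot", "ctla4_tot", "cd80_tot", "cd86_tot", "pdl1t_tot",
    "kon_2880", "koff_2880", "kon_2886", "koff_2886",
    "kon_c80", "koff_c80", "kon_c86", "koff_c86", "kon_p80", "koff_p80",
    "ipi_kon", "ipi_koff", "ipi_chi", "ec50_costim", "n_costim",
    # tumor synapse
    "pd1_tot", "pdl1_area", "pdl2_frac",
    "kon_pdl1", "koff_pdl1", "kon_pdl2", "koff_pdl2",
    "niv_kon", "niv_koff", "niv_chi", "ec50_pd1", "n_pd1",
    # ADCC
    "ctla4_treg_tot", "k_adcc_max", "k_adcc_half", "adcc_enabled",
    # initial immune pools
    "te_c0", "te_p0",
]

N_PARAMS = len(PARAM_ORDER)
PARAM_INDEX = {n: i for i, n in enumerate(PARAM_ORDER)}
for _i, _n in enumerate(PARAM_ORDER):
    globals()[f"P_{_n.upper()}"] = _i

# module flag positions
F_PK, F_CANCER, F_TCELL, F_SYNAPSE, F_MDSC = range(5)


# ---------------------------------------------------------------------------
# tumor geometry
# ---------------------------------------------------------------------------

@njit
def _cell_volume_l(diameter_um: float) -> float:
    return math.pi / 6.0 * diameter_um**3 * 1e-15


@njit
def _tumor_volume_kernel(
    c_p: float, c_d: float, te: float, tr: float, md: float,
    d_cancer_um: float, d_lym_um: float, f_other: float,
) -> float:
    v = (c_p + c_d) * _cell_volume_l(d_cancer_um) + (te + tr + md) * _cell_volume_l(d_lym_um)
    return v / (1.0 - f_other)


def tumor_volume(state: Sequence[float] | Mapping[str, float], params: ParameterSet) -> float:
    """Total tumor volume in liters: cell volumes scaled by the
    interstitium/other-cell volume fraction."""
    f_other = params["f_vol_other"]
    if f_other >= 1.0:
        raise ValueError("f_vol_other must be < 1")
    if isinstance(state, Mapping):
        counts = [state.get(f"{SPECIES[i][0]}.{SPECIES[i][1]}", 0.0) for i in _TUMOR_CELL_IDX]
    else:
        y = np.asarray(state, dtype=float)
        counts = [y[i] for i in _TUMOR_CELL_IDX]
    return float(
        _tumor_volume_kernel(
            counts[0], counts[1], counts[2], counts[3], counts[4],
            params["d_cell_cancer"], params["d_cell_lymphocyte"], f_other,
        )
    )


def tumor_diameter(volume_l: float) -> float:
    """Diameter (cm) of a sphere of the given volume (liters)."""
    if volume_l < 0:
        raise ValueError("volume must be >= 0")
    volume_cm3 = volume_l * 1e3
    return (6.0 * volume_cm3 / math.pi) ** (1.0 / 3.0)


def diameter_to_volume(diameter_cm: float) -> float:
    """Volume (liters) of a sphere of the given diameter (cm)."""
    if diameter_cm < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi / 6.0 * diameter_cm**3 / 1e3


# ---------------------------------------------------------------------------
# the right-hand side kernel
# ---------------------------------------------------------------------------

@njit
def _rhs_kernel(t: float, y: np.ndarray, p: np.ndarray, ent_inf: float, flags: np.ndarray):
    """Full model right-hand side (day units).

    ``p`` follows PARAM_ORDER; ``ent_inf`` is the entinostat zero-order
    buccal input rate active on this integration segment (ng/day);
    ``flags`` gates the five modules (disabled ⇒ zero flux).
    """
    dy = np.zeros(y.shape[0])

    on_pk = flags[F_PK] != 0
    on_ca = flags[F_CANCER] != 0
    on_tc = flags[F_TCELL] != 0
    on_sy = flags[F_SYNAPSE] != 0
    on_md = flags[F_MDSC] != 0

    c_p = y[S_CANCER_PROLIFERATING_TUMOR] if y[S_CANCER_PROLIFERATING_TUMOR] > 0.0 else 0.0
    c_d = y[S_CANCER_DEAD_TUMOR] if y[S_CANCER_DEAD_TUMOR] > 0.0 else 0.0
    te_t = y[S_TEFF_TUMOR] if y[S_TEFF_TUMOR] > 0.0 else 0.0
    tr_t = y[S_TREG_TUMOR] if y[S_TREG_TUMOR] > 0.0 else 0.0
    md_t = y[S_MDSC_TUMOR] if y[S_MDSC_TUMOR] > 0.0 else 0.0

    # --- tumor geometry -------------------------------------------------
    v_min = _cell_volume_l(p[P_D_CELL_CANCER]) / (1.0 - p[P_F_VOL_OTHER])
    v_t_l = _tumor_volume_kernel(
        c_p, c_d, te_t, tr_t, md_t,
        p[P_D_CELL_CANCER], p[P_D_CELL_LYMPHOCYTE], p[P_F_VOL_OTHER],
    )
    if v_t_l < v_min:
        v_t_l = v_min
    v_t_ml = v_t_l * 1e3
    v_t_ul = v_t_l * 1e6

    # --- concentrations -------------------------------------------------
    ent_tum = y[S_ENTINOSTAT_TUMOR] / v_t_ml if y[S_ENTINOSTAT_TUMOR] > 0.0 else 0.0  # ng/mL
    niv_tum = y[S_NIVOLUMAB_TUMOR] / v_t_l if y[S_NIVOLUMAB_TUMOR] > 0.0 else 0.0     # nM
    ipi_tum = y[S_IPILIMUMAB_TUMOR] / v_t_l if y[S_IPILIMUMAB_TUMOR] > 0.0 else 0.0   # nM
    ipi_ln = y[S_IPILIMUMAB_TDLN] / p[P_V_LN] if y[S_IPILIMUMAB_TDLN] > 0.0 else 0.0  # nM
    ccl2 = y[S_CCL2_TUMOR] / v_t_l if y[S_CCL2_TUMOR] > 0.0 else 0.0                  # nM
    argi = y[S_ARGI_TUMOR] / v_t_ul if y[S_ARGI_TUMOR] > 0.0 else 0.0                 # mU
    no = y[S_NO_TUMOR] / v_t_ml if y[S_NO_TUMOR] > 0.0 else 0.0                       # µM

    # --- entinostat PD factors -----------------------------------------
    h_prolif = _mdsc.pd_hill(ent_tum, p[P_ENT_IMAX_PROLIF], p[P_ENT_IC50_PROLIF], p[P_ENT_N_PROLIF])
    h_no_pd = _mdsc.pd_hill(ent_tum, p[P_ENT_IMAX_NO], p[P_ENT_IC50_NO], p[P_ENT_N_NO])
    h_ccl2_pd = _mdsc.pd_hill(ent_tum, p[P_ENT_IMAX_CCL2], p[P_ENT_IC50_CCL2], p[P_ENT_N_CCL2])
    h_argact = _mdsc.pd_hill(ent_tum, p[P_ENT_IMAX_ARGACT], p[P_ENT_IC50_ARGACT], p[P_ENT_N_ARGACT])
    h_argiprod = _mdsc.pd_hill(
        ent_tum, p[P_ENT_IMAX_ARGIPROD], p[P_ENT_IC50_ARGIPROD], p[P_ENT_N_ARGIPROD]
    )

    # --- synapse systems ------------------------------------------------
    h_pd1 = 0.0
    s_costim = 0.0
    adcc = 0.0
    if on_sy:
        pdl1_tot = p[P_PDL1_COPIES] / p[P_PDL1_AREA]
        pdl2_tot = pdl1_tot * p[P_PDL2_FRAC]
        niv_syn = niv_tum if on_pk else 0.0
        dl1, dl2, dnab, dnab2 = _syn.pd1_synapse_fluxes(
            y[S_SYN_PD1_PDL1_TUMOR], y[S_SYN_PD1_PDL2_TUMOR], y[S_SYN_PD1_NIV_TUMOR], y[S_SYN_PD1_NIV_PD1_TUMOR],
            niv_syn, p[P_PD1_TOT], pdl1_tot, pdl2_tot,
            p[P_KON_PDL1], p[P_KOFF_PDL1], p[P_KON_PDL2], p[P_KOFF_PDL2],
            p[P_NIV_KON], p[P_NIV_KOFF], p[P_NIV_CHI],
        )
        dy[S_SYN_PD1_PDL1_TUMOR] = dl1
        dy[S_SYN_PD1_PDL2_TUMOR] = dl2
        dy[S_SYN_PD1_NIV_TUMOR] = dnab
        dy[S_SYN_PD1_NIV_PD1_TUMOR] = dnab2
        bound_pd1 = y[S_SYN_PD1_PDL1_TUMOR] + y[S_SYN_PD1_PDL2_TUMOR]
        h_pd1 = _syn.hill_signal(bound_pd1, p[P_EC50_PD1], p[P_N_PD1])

        ipi_syn = ipi_ln if on_pk else 0.0
        d1, d2, d3, d4, d5, d6, d7 = _syn.ln_synapse_fluxes(
            y[S_SYN_CD28_CD80_TDLN], y[S_SYN_CD28_CD86_TDLN], y[S_SYN_CTLA4_CD80_TDLN],
            y[S_SYN_CTLA4_CD86_TDLN], y[S_SYN_PDL1_CD80_TDLN], y[S_SYN_CTLA4_IPI_TDLN],
            y[S_SYN_CTLA4_IPI_CTLA4_TDLN], ipi_syn,
            p[P_CD28_TOT], p[P_CTLA4_TOT], p[P_CD80_TOT], p[P_CD86_TOT], p[P_PDL1T_TOT],
            p[P_KON_2880], p[P_KOFF_2880], p[P_KON_2886], p[P_KOFF_2886],
            p[P_KON_C80], p[P_KOFF_C80], p[P_KON_C86], p[P_KOFF_C86],
            p[P_KON_P80], p[P_KOFF_P80],
            p[P_IPI_KON], p[P_IPI_KOFF], p[P_IPI_CHI],
        )
        dy[S_SYN_CD28_CD80_TDLN] = d1
        dy[S_SYN_CD28_CD86_TDLN] = d2
        dy[S_SYN_CTLA4_CD80_TDLN] = d3
        dy[S_SYN_CTLA4_CD86_TDLN] = d4
        dy[S_SYN_PDL1_CD80_TDLN] = d5
        dy[S_SYN_CTLA4_IPI_TDLN] = d6
        dy[S_SYN_CTLA4_IPI_CTLA4_TDLN] = d7
        bound_cd28 = y[S_SYN_CD28_CD80_TDLN] + y[S_SYN_CD28_CD86_TDLN]
        s_costim = _syn.hill_signal(bound_cd28, p[P_EC50_COSTIM], p[P_N_COSTIM])

        ipi_t_syn = ipi_tum if on_pk else 0.0
        ct_free = (
            p[P_CTLA4_TREG_TOT]
            - y[S_SYN_TREG_CTLA4_IPI_TUMOR]
            - 2.0 * y[S_SYN_TREG_CTLA4_IPI_CTLA4_TUMOR]
        )
        if ct_free < 0.0:
            ct_free = 0.0
        da, da2 = _syn.ab_receptor_fluxes(
            y[S_SYN_TREG_CTLA4_IPI_TUMOR], y[S_SYN_TREG_CTLA4_IPI_CTLA4_TUMOR], ipi_t_syn,
            ct_free, p[P_IPI_KON], p[P_IPI_KOFF], p[P_IPI_CHI],
        )
        dy[S_SYN_TREG_CTLA4_IPI_TUMOR] = da
        dy[S_SYN_TREG_CTLA4_IPI_CTLA4_TUMOR] = da2
        if p[P_ADCC_ENABLED] != 0.0:
            occ = (
                y[S_SYN_TREG_CTLA4_IPI_TUMOR] + 2.0 * y[S_SYN_TREG_CTLA4_IPI_CTLA4_TUMOR]
            ) / p[P_CTLA4_TREG_TOT]
            if occ > 1.0:
                occ = 1.0
            adcc = _syn.adcc_depletion_rate(tr_t, occ, p[P_K_ADCC_MAX], p[P_K_ADCC_HALF])

    # --- MDSC module ----------------------------------------------------
    h_argi_kill = 0.0
    h_no_kill = 0.0
    argi_eff = 0.0
    if on_md:
        argi_eff = argi * (1.0 - h_argact)
        h_argi_kill = _mdsc.pd_hill(
            argi_eff, p[P_IMAX_ARGI_KILL], p[P_EC50_ARGI_KILL], p[P_N_ARGI_KILL]
        )
        h_no_kill = _mdsc.pd_hill(no, p[P_IMAX_NO_KILL], p[P_EC50_NO_KILL], p[P_N_NO_KILL])

        base_rate = p[P_RHO_MDSC_SS] * p[P_D_MDSC]
        rec = _mdsc.mdsc_recruitment_flux(
            ccl2, base_rate, p[P_R_MDSC_MAX], p[P_EC50_CCL2_REC], v_t_ul
        )
        dy[S_MDSC_TUMOR] = rec - p[P_D_MDSC] * md_t
        dy[S_ARGI_TUMOR] = (
            _mdsc.argI_secretion_flux(md_t, h_argiprod, p[P_K_ARGI_SEC])
            - p[P_D_ARGI] * y[S_ARGI_TUMOR]
        )
        dy[S_NO_TUMOR] = (
            _mdsc.no_secretion_flux(md_t, h_no_pd, p[P_K_NO_SEC]) - p[P_D_NO] * y[S_NO_TUMOR]
        )
        ccl2_src = _mdsc.ccl2_secretion_flux(c_p if on_ca else 0.0, h_ccl2_pd, p[P_K_CCL2_SEC])
        dy[S_CCL2_TUMOR] = ccl2_src - p[P_D_CCL2] * y[S_CCL2_TUMOR]

    # --- killing --------------------------------------------------------
    kill = 0.0
    if on_ca and on_tc:
        kill = _tcell.kill_rate(
            c_p, c_d, te_t, tr_t, md_t, h_pd1, h_argi_kill, h_no_kill, p[P_K_KILL]
        )

    # --- cancer and antigen ---------------------------------------------
    if on_ca:
        growth = _cancer.cancer_growth_flux(
            c_p, p[P_K_CAPACITY], ent_tum if on_pk else 0.0,
            p[P_R_GROWTH], p[P_ENT_IMAX_PROLIF], p[P_ENT_IC50_PROLIF], p[P_ENT_N_PROLIF],
        )
        death = p[P_D_CANCER] * c_p
        clear = p[P_K_CLEAR_DEAD] * c_d
        dy[S_CANCER_PROLIFERATING_TUMOR] = growth - death - kill
        dy[S_CANCER_DEAD_TUMOR] = death + kill - clear
        dy[S_CANCER_PRODUCED_CUM_TUMOR] = growth
        dy[S_CANCER_CLEARED_CUM_TUMOR] = clear

        rel = _cancer.antigen_release_flux(death + kill, p[P_AG_RELEASE])
        dy[S_ANTIGEN_TUMOR] = rel - (p[P_K_AG_TRANSPORT] + p[P_K_AG_DEG]) * y[S_ANTIGEN_TUMOR]
        dy[S_ANTIGEN_TDLN] = (
            p[P_K_AG_TRANSPORT] * y[S_ANTIGEN_TUMOR] - p[P_K_AG_DEG_LN] * y[S_ANTIGEN_TDLN]
        )
        mat = _cancer.apc_maturation_flux(
            y[S_ANTIGEN_TDLN], y[S_APC_IMMATURE_TDLN], p[P_K_APC_MAT], p[P_K_AG_APC_HALF]
        )
        dy[S_APC_IMMATURE_TDLN] = (
            p[P_D_APC_IMM] * (p[P_APC0] - y[S_APC_IMMATURE_TDLN]) - mat
        )
        dy[S_MAPC_TDLN] = mat - p[P_D_MAPC] * y[S_MAPC_TDLN]

    # --- T cells ----------------------------------------------------------
    if on_tc:
        ag_ln = y[S_ANTIGEN_TDLN] if on_ca else 0.0
        mapc = y[S_MAPC_TDLN] if on_ca else 0.0
        lam = _tcell.proofreading_signal(
            p[P_K_OFF_TCR], p[P_K_PROOFREAD], p[P_N_PROOFREAD],
            ag_ln, p[P_K_AG_OCC], mapc, p[P_K_MAPC_HALF], p[P_LAMBDA_ACT_MAX],
        )
        s_tcr = lam / p[P_LAMBDA_ACT_MAX] if p[P_LAMBDA_ACT_MAX] > 0.0 else 0.0
        a_t = y[S_ACTIVATED_T_TDLN] if y[S_ACTIVATED_T_TDLN] > 0.0 else 0.0
        s_cyt = a_t / (a_t + p[P_K_CYT_HALF])
        n_gen = _tcell.generations(
            s_tcr, s_costim, s_cyt, p[P_N0_GEN], p[P_W_TCR], p[P_W_COSTIM], p[P_W_CYT]
        )
        n_t = y[S_NAIVE_T_TDLN] if y[S_NAIVE_T_TDLN] > 0.0 else 0.0
        act = lam * n_t
        mat_t = p[P_K_MAT_T] * a_t
        dy[S_NAIVE_T_TDLN] = (
            p[P_D_NAIVE] * (p[P_NT0_PER_CLONE] * p[P_TMB_CLONES] - n_t)
            - act + mat_t * (1.0 - p[P_F_EFF])
        )
        dy[S_ACTIVATED_T_TDLN] = act - mat_t
        teff_out = mat_t * _tcell.burst_output(n_gen, p[P_F_EFF])

        # Treg activation mirrors Teff priming with its own clone pool
        lam_r = (
            p[P_LAMBDA_ACT_TREG] * (lam / p[P_LAMBDA_ACT_MAX])
            if p[P_LAMBDA_ACT_MAX] > 0.0 else 0.0
        )
        n_r = y[S_NAIVE_TREG_TDLN] if y[S_NAIVE_TREG_TDLN] > 0.0 else 0.0
        a_r = y[S_ACTIVATED_TREG_TDLN] if y[S_ACTIVATED_TREG_TDLN] > 0.0 else 0.0
        act_r = lam_r * n_r
        mat_r = p[P_K_MAT_T] * a_r
        dy[S_NAIVE_TREG_TDLN] = p[P_D_NAIVE] * (p[P_NTREG0] - n_r) - act_r
        dy[S_ACTIVATED_TREG_TDLN] = act_r - mat_r
        treg_out = mat_r * 2.0 ** p[P_N_GEN_TREG]

        # Teff trafficking: central ⇄ peripheral, central → tumor
        te_c = y[S_TEFF_CENTRAL] if y[S_TEFF_CENTRAL] > 0.0 else 0.0
        te_p = y[S_TEFF_PERIPHERAL] if y[S_TEFF_PERIPHERAL] > 0.0 else 0.0
        entry = p[P_K_TE_ENTRY] * te_c * (v_t_l / p[P_V_REF_ENTRY])
        dy[S_TEFF_CENTRAL] = (
            teff_out - p[P_K_TE_CP] * te_c + p[P_K_TE_PC] * te_p
            - entry - p[P_D_TE_CENTRAL] * te_c
        )
        dy[S_TEFF_PERIPHERAL] = p[P_K_TE_CP] * te_c - p[P_K_TE_PC] * te_p - p[P_D_TE_PERIPHERAL] * te_p
        engage = _tcell.engagement_fraction(c_p, c_d, te_t, tr_t, md_t)
        exh = _tcell.exhaustion_flux(te_t, engage, p[P_K_EXHAUST])
        te_dens = te_t / v_t_ul
        crowd_te = 1.0 + te_dens / p[P_TEFF_CROWD_DENSITY]
        dy[S_TEFF_TUMOR] = entry - p[P_D_TE_TUMOR] * te_t * crowd_te - exh

        # Treg pools
        tr_c = y[S_TREG_CENTRAL] if y[S_TREG_CENTRAL] > 0.0 else 0.0
        tr_p = y[S_TREG_PERIPHERAL] if y[S_TREG_PERIPHERAL] > 0.0 else 0.0
        entry_r = (
            p[P_D_TR_TUMOR] * p[P_RHO_TREG_SS] * v_t_ul * (tr_c / p[P_TR_C0])
            if p[P_TR_C0] > 0.0 else 0.0
        )
        dy[S_TREG_CENTRAL] = (
            treg_out + p[P_D_TR_CENTRAL] * p[P_TR_C0]
            - p[P_D_TR_CENTRAL] * tr_c - p[P_K_TR_CP] * tr_c + p[P_K_TR_PC] * tr_p
        )
        dy[S_TREG_PERIPHERAL] = p[P_K_TR_CP] * tr_c - p[P_K_TR_PC] * tr_p - p[P_D_TR_PERIPHERAL] * tr_p
        exp_r = _tcell.treg_expansion_flux(
            tr_t, argi_eff, p[P_K_TREG_EXP_MAX], p[P_EC50_ARGI_TREG]
        )
        crowd_tr = 1.0 + (tr_t / v_t_ul) / p[P_TREG_CROWD_DENSITY]
        dy[S_TREG_TUMOR] = entry_r + exp_r - p[P_D_TR_TUMOR] * tr_t * crowd_tr - adcc

    # --- PK --------------------------------------------------------------
    if on_pk:
        vc_ml = p[P_ENT_V_CENTRAL] * 1e3
        eb, eg, ec, ep, et, eel = entinostat_fluxes(
            y[S_ENTINOSTAT_BUCCAL], y[S_ENTINOSTAT_GI], y[S_ENTINOSTAT_CENTRAL],
            y[S_ENTINOSTAT_PERIPHERAL], y[S_ENTINOSTAT_TUMOR],
            ent_inf, v_t_ml,
            p[P_ENT_KA_BUCCAL], p[P_ENT_KA_GI], p[P_ENT_K_CP], p[P_ENT_K_PC],
            vc_ml, p[P_ENT_CL_LINEAR] * 1e3, p[P_ENT_VMAX_NL], p[P_ENT_KM_NL],
            p[P_ENT_K_TUMOR_EX],
        )
        dy[S_ENTINOSTAT_BUCCAL] = eb
        dy[S_ENTINOSTAT_GI] = eg
        dy[S_ENTINOSTAT_CENTRAL] = ec
        dy[S_ENTINOSTAT_PERIPHERAL] = ep
        dy[S_ENTINOSTAT_TUMOR] = et
        dy[S_ENTINOSTAT_ELIMINATED] = eel

        nc, npp, nt_, nl, nel = antibody_fluxes(
            y[S_NIVOLUMAB_CENTRAL], y[S_NIVOLUMAB_PERIPHERAL], y[S_NIVOLUMAB_TUMOR],
            y[S_NIVOLUMAB_TDLN],
            p[P_NIV_V_CENTRAL], v_t_l, p[P_V_LN],
            p[P_NIV_K12], p[P_NIV_K21], p[P_NIV_CL],
            p[P_NIV_K_TUMOR_EX], p[P_NIV_K_LN_EX], p[P_NIV_GAMMA_TUMOR], p[P_NIV_GAMMA_LN],
        )
        dy[S_NIVOLUMAB_CENTRAL] = nc
        dy[S_NIVOLUMAB_PERIPHERAL] = npp
        dy[S_NIVOLUMAB_TUMOR] = nt_
        dy[S_NIVOLUMAB_TDLN] = nl
        dy[S_NIVOLUMAB_ELIMINATED] = nel

        ic, ip, it, il, iel = antibody_fluxes(
            y[S_IPILIMUMAB_CENTRAL], y[S_IPILIMUMAB_PERIPHERAL], y[S_IPILIMUMAB_TUMOR],
            y[S_IPILIMUMAB_TDLN],
            p[P_IPI_V_CENTRAL], v_t_l, p[P_V_LN],
            p[P_IPI_K12], p[P_IPI_K21], p[P_IPI_CL],
            p[P_IPI_K_TUMOR_EX], p[P_IPI_K_LN_EX], p[P_IPI_GAMMA_TUMOR], p[P_IPI_GAMMA_LN],
        )
        dy[S_IPILIMUMAB_CENTRAL] = ic
        dy[S_IPILIMUMAB_PERIPHERAL] = ip
        dy[S_IPILIMUMAB_TUMOR] = it
        dy[S_IPILIMUMAB_TDLN] = il
        dy[S_IPILIMUMAB_ELIMINATED] = iel

    return dy


# ---------------------------------------------------------------------------
# model system, build, simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolverSettings:
    """Stiff-integrator settings (defaults follow the published setup)."""

    abstol: float = 1e-12
    reltol: float = 1e-6
    max_step: float = math.inf
    method: str = "LSODA"  # LSODA | BDF

    def __post_init__(self) -> None:
        if self.abstol <= 0 or self.reltol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class SimulationResult:
    """Trajectory sampled on a time grid plus the dosing/clipping event log."""

    t: np.ndarray  # days, strictly increasing
    y: np.ndarray  # (n_states, n_times)
    events: list[dict] = field(default_factory=list)
    system: "ModelSystem | None" = None

    def species(self, name: str, compartment: str) -> np.ndarray:
        return self.y[SPECIES_INDEX[f"{name}.{compartment}"]]

    def state_at(self, i: int = -1) -> np.ndarray:
        return self.y[:, i].copy()

    def tumor_volume_l(self) -> np.ndarray:
        ps = self.system.params
        return np.array([tumor_volume(self.y[:, i], ps) for i in range(self.y.shape[1])])

    def tumor_diameter_cm(self) -> np.ndarray:
        return np.array([tumor_diameter(v) for v in self.tumor_volume_l()])

    def to_long_frame(self, patient_id: str = "patient-0"):
        """Long-format trajectory table: patient_id,time_day,species,compartment,value."""
        import pandas as pd

        rows = []
        for i, (name, comp) in enumerate(SPECIES):
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patient_id,
                        "time_day": self.t,
                        "species": name,
                        "compartment": comp,
                        "value": self.y[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


class NotReached:
    """Sentinel: the tumor never reached the target volume in time."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NotReached()"

    def __bool__(self) -> bool:
        return False


NOT_REACHED = NotReached()


class ModelSystem:
    """A built model: parameter vector, module flags, RHS and observables."""

    def __init__(self, params: ParameterSet, module_flags: Iterable[str] = MODULE_NAMES):
        flags = set(module_flags)
        unknown = flags - set(MODULE_NAMES)
        if unknown:
            raise ModelBuildError(f"unknown module flag(s) {sorted(unknown)!r}")
        self.module_flags = flags
        self.params = params.in_model_units()
        missing = [n for n in PARAM_ORDER if n not in self.params]
        if missing:
            raise ModelBuildError(
                f"parameter table does not resolve symbol(s): {missing!r}"
            )
        self.p = np.array([self.params[n] for n in PARAM_ORDER], dtype=float)
        self.flag_vector = np.array(
            [1 if m in flags else 0 for m in MODULE_NAMES], dtype=np.int64
        )
        self.species_index = dict(SPECIES_INDEX)

    # -- basic surface ---------------------------------------------------
    def compartments(self) -> list[CompartmentSpec]:
        return [
            CompartmentSpec("central", self.params["v_central"]),
            CompartmentSpec("peripheral", self.params["v_peripheral"]),
            CompartmentSpec("tumor", max(self.tumor_volume(self.initial_state()), 1e-12)),
            CompartmentSpec("tdln", self.params["v_ln"]),
        ]

    def rhs(self, t: float, y: np.ndarray, ent_infusion: float = 0.0) -> np.ndarray:
        return _rhs_kernel(t, np.asarray(y, dtype=float), self.p, ent_infusion, self.flag_vector)

    def tumor_volume(self, state: np.ndarray) -> float:
        return tumor_volume(state, self.params)

    def tumor_diameter(self, state: np.ndarray) -> float:
        return tumor_diameter(self.tumor_volume(state))

    def observables(self, state: np.ndarray) -> dict:
        """Algebraic observables at one state (densities per µL of tumor)."""
        y = np.asarray(state, dtype=float)
        v_l = max(self.tumor_volume(y), 1e-12)
        v_ul = v_l * 1e6
        te = y[SPECIES_INDEX["teff.tumor"]]
        tr = y[SPECIES_INDEX["treg.tumor"]]
        md = y[SPECIES_INDEX["mdsc.tumor"]]
        return {
            "tumor_volume_l": v_l,
            "tumor_diameter_cm": tumor_diameter(v_l),
            "teff_density_per_ul": te / v_ul,
            "treg_density_per_ul": tr / v_ul,
            "teff_treg_ratio": te / tr if tr > 0 else math.inf,
            "mdsc_density_per_ul": md / v_ul,
            "tmb_clones": self.params["tmb_clones"],
            "pdl1_copies": self.params["pdl1_copies"],
        }

    # -- initial conditions ----------------------------------------------
    def initial_state(self, cancer_cells: float = 1.0) -> np.ndarray:
        """Single-cancer-cell start: immune pools at homeostatic setpoints,
        all drug amounts and complexes zero."""
        y = np.zeros(N_STATES)
        ps = self.params
        y[SPECIES_INDEX["cancer_proliferating.tumor"]] = cancer_cells
        y[SPECIES_INDEX["naive_t.tdln"]] = ps["nt0_per_clone"] * ps["tmb_clones"]
        y[SPECIES_INDEX["naive_treg.tdln"]] = ps["ntreg0"]
        y[SPECIES_INDEX["apc_immature.tdln"]] = ps["apc0"]
        y[SPECIES_INDEX["teff.central"]] = ps["te_c0"]
        y[SPECIES_INDEX["teff.peripheral"]] = ps["te_p0"]
        y[SPECIES_INDEX["treg.central"]] = ps["tr_c0"]
        denom = ps["k_tr_pc"] + ps["d_tr_peripheral"]
        y[SPECIES_INDEX["treg.peripheral"]] = (
            ps["k_tr_cp"] * ps["tr_c0"] / denom if denom > 0 else 0.0
        )
        return y

    # -- event-aware integration ------------------------------------------
    def simulate(
        self,
        state0: np.ndarray,
        t_span: tuple[float, float],
        regimen: Regimen | None = None,
        settings: SolverSettings | None = None,
        sample_every_days: float = 1.0,
        bsa_m2: float = 1.7,
        body_weight_kg: float = 70.0,
    ) -> SimulationResult:
        from scipy.integrate import solve_ivp

        settings = settings or SolverSettings()
        t0, t1 = float(t_span[0]), float(t_span[1])
        if t1 <= t0:
            raise ValueError("t_span must be positive")
        y = np.asarray(state0, dtype=float).copy()
        if (y < 0).any():
            raise ValueError("initial state must be non-negative")

        ent = None
        events: list[dict] = []
        boluses: dict[float, list[tuple[str, float]]] = {}
        infusions: list[tuple[float, float, float]] = []  # (start, end, ng/day)
        if regimen is not None and "pk" in self.module_flags:
            ps = self.params
            d0_d = ps["ent_d0"]
            tlag_d = ps["ent_tlag"]
            for t_d, drug, mg in regimen.dose_events(bsa_m2, body_weight_kg):
                if t_d >= t1:
                    continue
                if drug == "entinostat":
                    dose_ng = mg * 1e6
                    infusions.append(
                        (t_d, t_d + d0_d, ps["ent_f_buccal"] * dose_ng / d0_d)
                    )
                    boluses.setdefault(t_d + tlag_d, []).append(
                        ("entinostat.gi", (1.0 - ps["ent_f_buccal"]) * dose_ng)
                    )
                    events.append({"t": t_d, "kind": "dose", "drug": drug, "mg": mg})
                elif drug in ("nivolumab", "ipilimumab"):
                    nmol = mg * 1e-3 / MW_G_PER_MOL[drug] * 1e9
                    boluses.setdefault(t_d, []).append((f"{drug}.central", nmol))
                    events.append({"t": t_d, "kind": "dose", "drug": drug, "mg": mg})
                else:
                    raise ValueError(f"unknown drug {drug!r} in regimen")

        breaks = {t0, t1}
        breaks.update(t for t in boluses if t0 < t < t1)
        for a, b, _ in infusions:
            if t0 < a < t1:
                breaks.add(a)
            if t0 < b < t1:
                breaks.add(b)
        grid = sorted(breaks)

        ts: list[np.ndarray] = [np.array([t0])]
        ys: list[np.ndarray] = [y.copy()[:, None]]
        clip = 10.0 * settings.abstol
        for a, b in zip(grid[:-1], grid[1:]):
            for name, amount in boluses.get(a, ()):
                y[SPECIES_INDEX[name]] += amount
            inf_rate = sum(r for s, e, r in infusions if s <= a < e)
            n_pts = max(int(math.ceil((b - a) / sample_every_days)), 1)
            t_eval = np.linspace(0.0, b - a, n_pts + 1)[1:]
            # the RHS is autonomous: integrate on a local time origin so
            # step-size selection is never limited by eps(t) late in a run
            sol = solve_ivp(
                _rhs_kernel,
                (0.0, b - a),
                y,
                method=settings.method,
                t_eval=t_eval,
                rtol=settings.reltol,
                atol=settings.abstol,
                max_step=settings.max_step,
                args=(self.p, inf_rate, self.flag_vector),
            )
            sol.t = sol.t + a
            if not sol.success:
                t_arr = np.atleast_1d(np.asarray(sol.t, dtype=float))
                t_fail = float(t_arr[-1]) if t_arr.size else a
                worst = np.argsort(np.abs(self.rhs(t_fail, y)))[-3:]
                names = [f"{SPECIES[i][0]}.{SPECIES[i][1]}" for i in worst[::-1]]
                raise RuntimeError(
                    f"integration failed at t={t_fail:.3f} d "
                    f"({sol.message}); stiffest states: {names}"
                )
            y = sol.y[:, -1].copy()
            neg = y < 0
            if neg.any():
                logged = neg & (np.abs(y) >= clip)
                if logged.any():
                    events.append(
                        {
                            "t": b,
                            "kind": "clip",
                            "species": [
                                f"{SPECIES[i][0]}.{SPECIES[i][1]}"
                                for i in np.where(logged)[0]
                            ],
                        }
                    )
                y[neg] = 0.0
            ts.append(sol.t)
            ys.append(sol.y)
        t_all = np.concatenate(ts)
        y_all = np.concatenate(ys, axis=1)
        keep = np.concatenate([[True], np.diff(t_all) > 0])
        return SimulationResult(t=t_all[keep], y=y_all[:, keep], events=events, system=self)

    # -- baseline-growth protocol ------------------------------------------
    def grow_to_baseline(
        self,
        target_diameter_cm: float,
        t_max_growth_days: float = 3650.0,
        settings: SolverSettings | None = None,
    ):
        """Untreated growth from a single cancer cell until the tumor volume
        crosses the preselected target (event detection).

        Returns ``(state, t_reached_days)`` or ``(NOT_REACHED, t_max)``.
        """
        from scipy.integrate import solve_ivp

        if target_diameter_cm <= 0:
            raise ValueError("target diameter must be > 0")
        if t_max_growth_days <= 0:
            raise ValueError("t_max_growth must be > 0")
        settings = settings or SolverSettings()
        target_v = diameter_to_volume(target_diameter_cm)
        y0 = self.initial_state()
        if self.tumor_volume(y0) >= target_v:
            return y0, 0.0

        p, fv = self.p, self.flag_vector
        d_c, d_l, f_o = (
            self.params["d_cell_cancer"],
            self.params["d_cell_lymphocyte"],
            self.params["f_vol_other"],
        )

        def crossing(t, y, *args):
            v = _tumor_volume_kernel(
                max(y[0], 0.0), max(y[1], 0.0), max(y[6], 0.0),
                max(y[11], 0.0), max(y[12], 0.0), d_c, d_l, f_o,
            )
            return v - target_v

        crossing.terminal = True
        crossing.direction = 1.0

        sol = solve_ivp(
            _rhs_kernel,
            (0.0, t_max_growth_days),
            y0,
            method=settings.method,
            rtol=settings.reltol,
            atol=settings.abstol,
            events=crossing,
            args=(p, 0.0, fv),
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"baseline growth integration failed: {sol.message}")
        if sol.t_events[0].size == 0:
            return NOT_REACHED, t_max_growth_days
        t_hit = float(sol.t_events[0][0])
        state = np.maximum(sol.y_events[0][0], 0.0)
        return state, t_hit


def build_model(params: ParameterSet, module_flags: Iterable[str] = MODULE_NAMES) -> ModelSystem:
    """Assemble a :class:`ModelSystem`; unknown symbols raise
    :class:`ModelBuildError` naming them."""
    return ModelSystem(params, module_flags)
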