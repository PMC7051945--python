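"""Immunological-synapse binding systems.

All checkpoint/costimulation reactions happen on a two-dimensional
synapse patch (surface densities in molecules/µm²).  Two contexts are
maintained, as in the underlying biology:

* naïve T : mature APC in the TDLN — CD28 and CTLA-4 on the T cell
  compete for CD80/CD86 on the APC; PD-L1 on the T cell additionally
  sequesters CD80; anti-CTLA-4 antibody binds CTLA-4 from solution and
  can capture a second CTLA-4 with its other arm (cross-arm binding,
  avidity factor χ).
* Teff : cancer cell in the tumor — PD-1 binds PD-L1/PD-L2; anti-PD-1
  antibody blocks by the same two-step cross-arm scheme.

A third antibody-only context tracks anti-CTLA-4 on tumor Tregs, whose
occupancy drives ADCC-mediated Treg depletion.

Complexes are the state variables; free densities follow from the
per-receptor conservation totals, so conservation is structural.
"""

from __future__ import annotations

import numpy as np

from ._jit import njit


@njit
def ab_receptor_fluxes(
    r_ab: float,
    r_ab2: float,
    ab_nm: float,
    r_free: float,
    kon3d: float,
    koff: float,
    chi: float,
):
    """Two-step bivalent antibody binding to a surface receptor.

    First arm binds from solution (2·kon3d·C, two equivalent arms);
    the second arm captures another free receptor at surface rate χ·kon3d.
    Returns (d[R:Ab]/dt, d[R:Ab:R]/dt).
    """
    on1 = 2.0 * kon3d * ab_nm * r_free
    off1 = koff * r_ab
    on2 = chi * kon3d * r_ab * r_free
    off2 = 2.0 * koff * r_ab2
    return on1 - off1 - on2 + off2, on2 - off2


@njit
def ln_synapse_fluxes(
    cd28_80: float, cd28_86: float, ct4_80: float, ct4_86: float,
    pdl1_80: float, ct4_ab: float, ct4_ab2: float,
    ab_nm: float,
    cd28_tot: float, ctla4_tot: float, cd80_tot: float, cd86_tot: float, pdl1t_tot: float,
    kon_2880: float, koff_2880: float, kon_2886: float, koff_2886: float,
    kon_c80: float, koff_c80: float, kon_c86: float, koff_c86: float,
    kon_p80: float, koff_p80: float,
    kon_ab: float, koff_ab: float, chi_ab: float,
):
    """Mass-action fluxes for the TDLN naïve-T:APC synapse (7 complexes)."""
    f28 = cd28_tot - cd28_80 - cd28_86
    fct = ctla4_tot - ct4_80 - ct4_86 - ct4_ab - 2.0 * ct4_ab2
    f80 = cd80_tot - cd28_80 - ct4_80 - pdl1_80
    f86 = cd86_tot - cd28_86 - ct4_86
    fpd = pdl1t_tot - pdl1_80
    if f28 < 0.0:
        f28 = 0.0
    if fct < 0.0:
        fct = 0.0
    if f80 < 0.0:
        f80 = 0.0
    if f86 < 0.0:
        f86 = 0.0
    if fpd < 0.0:
        fpd = 0.0
    d2880 = kon_2880 * f28 * f80 - koff_2880 * cd28_80
    d2886 = kon_2886 * f28 * f86 - koff_2886 * cd28_86
    dc80 = kon_c80 * fct * f80 - koff_c80 * ct4_80
    dc86 = kon_c86 * fct * f86 - koff_c86 * ct4_86
    dp80 = kon_p80 * fpd * f80 - koff_p80 * pdl1_80
    dab, dab2 = ab_receptor_fluxes(ct4_ab, ct4_ab2, ab_nm, fct, kon_ab, koff_ab, chi_ab)
    return d2880, d2886, dc80, dc86, dp80, dab, dab2


@njit
def pd1_synapse_fluxes(
    pd1_l1: float, pd1_l2: float, pd1_ab: float, pd1_ab2: float,
    ab_nm: float,
    pd1_tot: float, pdl1_tot: float, pdl2_tot: float,
    kon_l1: float, koff_l1: float, kon_l2: float, koff_l2: float,
    kon_ab: float, koff_ab: float, chi_ab: float,
):
    """Mass-action fluxes for the tumor Teff:cancer synapse (4 complexes)."""
    fpd1 = pd1_tot - pd1_l1 - pd1_l2 - pd1_ab - 2.0 * pd1_ab2
    fl1 = pdl1_tot - pd1_l1
    fl2 = pdl2_tot - pd1_l2
    if fpd1 < 0.0:
        fpd1 = 0.0
    if fl1 < 0.0:
        fl1 = 0.0
    if fl2 < 0.0:
        fl2 = 0.0
    dl1 = kon_l1 * fpd1 * fl1 - koff_l1 * pd1_l1
    dl2 = kon_l2 * fpd1 * fl2 - koff_l2 * pd1_l2
    dab, dab2 = ab_receptor_fluxes(pd1_ab, pd1_ab2, ab_nm, fpd1, kon_ab, koff_ab, chi_ab)
    return dl1, dl2, dab, dab2


@njit
def hill_signal(x: float, ec50: float, n: float) -> float:
    """Hill transfer x ↦ xⁿ/(xⁿ + EC50ⁿ) mapping an occupancy to [0, 1]."""
    if x <= 0.0:
        return 0.0
    xn = x**n
    return xn / (xn + ec50**n)


@njit
def adcc_saturation(occ: float, k_half: float) -> float:
    """Saturating occupancy transfer normalised so that sat(1) = 1 exactly."""
    if occ <= 0.0:
        return 0.0
    return occ * (1.0 + k_half) / (occ + k_half)


@njit
def adcc_depletion_rate(treg: float, occupancy: float, k_max: float, k_half: float) -> float:
    """ADCC Treg depletion, cells/day: k_max·Treg·sat(occupancy)."""
    if treg <= 0.0:
        return 0.0
    return k_max * treg * adcc_saturation(occupancy, k_half)


# ---------------------------------------------------------------------------
# analytic / equilibrium helpers (testing and quasi-equilibrium mode)
# ---------------------------------------------------------------------------

def pair_equilibrium(a_tot: float, b_tot: float, kd: float) -> float:
    """Equilibrium complex density for a single A + B ⇌ AB with 2D Kd.

    Root of the quadratic AB² − (A+B+Kd)·AB + A·B = 0 lying in
    [0, min(A, B)].
    """
    s = a_tot + b_tot + kd
    disc = s * s - 4.0 * a_tot * b_tot
    return 0.5 * (s - np.sqrt(max(disc, 0.0)))


def _relax_to_equilibrium(flux_fn, n_states, t_scale=1.0):
    """Integrate a flux system long enough to reach its fixed point."""
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        return np.asarray(flux_fn(*y))

    sol = solve_ivp(
        rhs, (0.0, 2e3 * t_scale), np.zeros(n_states), method="LSODA",
        rtol=1e-10, atol=1e-12,
    )
    return sol.y[:, -1]


def ln_synapse_equilibrium(ab_nm: float, p: dict) -> dict:
    """Equilibrium complexes of the TDLN synapse at a fixed antibody level."""
    keys = ("cd28_cd80", "cd28_cd86", "ctla4_cd80", "ctla4_cd86",
            "pdl1_cd80", "ctla4_ab", "ctla4_ab_ctla4")

    def fx(*y):
        return ln_synapse_fluxes(
            *y, ab_nm,
            p["cd28_tot"], p["ctla4_tot"], p["cd80_tot"], p["cd86_tot"], p["pdl1t_tot"],
            p["kon_2880"], p["koff_2880"], p["kon_2886"], p["koff_2886"],
            p["kon_c80"], p["koff_c80"], p["kon_c86"], p["koff_c86"],
            p["kon_p80"], p["koff_p80"],
            p["kon_ab"], p["koff_ab"], p["chi_ab"],
        )

    t_scale = 1.0 / min(p["koff_2880"], p["koff_2886"], p["koff_c80"],
                        p["koff_c86"], p["koff_p80"], p["koff_ab"])
    y = _relax_to_equilibrium(fx, 7, t_scale)
    return dict(zip(keys, y))


def pd1_synapse_equilibrium(ab_nm: float, p: dict) -> dict:
    """Equilibrium complexes of the tumor PD-1 synapse at a fixed antibody level."""
    keys = ("pd1_pdl1", "pd1_pdl2", "pd1_ab", "pd1_ab_pd1")

    def fx(*y):
        return pd1_synapse_fluxes(
            *y, ab_nm,
            p["pd1_tot"], p["pdl1_tot"], p["pdl2_tot"],
            p["kon_l1"], p["koff_l1"], p["kon_l2"], p["koff_l2"],
            p["kon_ab"], p["koff_ab"], p["chi_ab"],
        )

    t_scale = 1.0 / min(p["koff_l1"], p["koff_l2"], p["koff_ab"])
    y = _relax_to_equilibrium(fx, 4, t_scale)
    return dict(zip(keys, y))


def costim_signal(bound_cd28: float, ec50: float, n: float = 1.0) -> float:
    """Co-stimulation signal in [0, 1] from total bound CD28 density."""
    return float(hill_signal(bound_cd28, ec50, n))


def pd1_inhibition(bound_pd1: float, ec50: float, n: float = 1.0) -> float:
    """PD-1-axis inhibition factor H_PD1 in [0, 1] from bound PD-1 density."""
    return float(hill_signal(bound_pd1, ec50, n))
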