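"""T-cell activation, proliferation burst, trafficking, killing, exhaustion.

Naïve tumor-specific T cells are primed in the TDLN by mature APCs.
Priming is a kinetic-proofreading chain: a T-cell receptor must hold its
antigen through N sequential steps (rate k_p each) before dissociation
(rate k_off), giving the discrimination factor (k_p/(k_p+k_off))^N.
Activated cells divide through a signal-dependent number of generations
(TCR, co-stimulatory and cytokine signals each add generations) and a
fraction of the 2ⁿ daughters differentiates into effector T cells that
traffic central → tumor.  In the tumor, Teff kill cancer cells under
multiplicative inhibition by the PD-1 axis, Arg-I and NO, and are lost
to exhaustion in proportion to their engagement with cancer cells.
"""

from __future__ import annotations

from ._jit import njit


@njit
def proofreading_factor(k_off: float, k_p: float, n_steps: float) -> float:
    """(k_p/(k_p+k_off))^N — probability of completing N steps before release."""
    if n_steps <= 0.0:
        return 1.0
    if k_p <= 0.0:
        return 0.0
    return (k_p / (k_p + k_off)) ** n_steps


@njit
def proofreading_signal(
    k_off: float,
    k_p: float,
    n_steps: float,
    antigen_ln: float,
    k_ag_occ: float,
    mapc: float,
    k_mapc_half: float,
    lambda_max: float,
) -> float:
    """Per-naïve-cell activation rate (1/day).

    λ = λ_max × occupancy(antigen) × proofreading factor × mAPC saturation.
    Occupancy uses a half-max antigen amount proportional to the TCR
    off-rate (weaker binders need more antigen), so the rate is monotone
    decreasing in k_off on both factors.
    """
    if antigen_ln <= 0.0 or mapc <= 0.0:
        return 0.0
    occ = antigen_ln / (antigen_ln + k_ag_occ * (k_off / k_p if k_p > 0.0 else 1.0))
    sat = mapc / (mapc + k_mapc_half)
    return lambda_max * occ * proofreading_factor(k_off, k_p, n_steps) * sat


@njit
def generations(
    s_tcr: float, s_costim: float, s_cyt: float, n0: float, w_tcr: float, w_co: float, w_cyt: float
) -> float:
    """Division-generation count n = n₀ + Σ weighted signals (real-valued)."""
    return n0 + w_tcr * s_tcr + w_co * s_costim + w_cyt * s_cyt


@njit
def burst_output(n_gen: float, f_eff: float) -> float:
    """Effector daughters per maturing activated cell: 2ⁿ × differentiation fraction."""
    return 2.0**n_gen * f_eff


def proliferation_burst(activation_signal, costim_signal, cytokine_signal, p):
    """Generations and per-cell Teff output for given signals in [0, 1].

    ``p`` maps ``n0_gen, w_tcr, w_costim, w_cyt, f_eff``.
    Returns ``(n_generations, teff_per_activated_cell)``.
    """
    n = generations(
        activation_signal, costim_signal, cytokine_signal,
        p["n0_gen"], p["w_tcr"], p["w_costim"], p["w_cyt"],
    )
    return n, burst_output(n, p["f_eff"])


@njit
def engagement_fraction(c_p: float, c_d: float, teff: float, treg: float, mdsc: float) -> float:
    """Fraction of tumor cellularity that is live cancer — contact probability."""
    total = c_p + c_d + teff + treg + mdsc
    if total <= 0.0:
        return 0.0
    return c_p / total


@njit
def kill_rate(
    c_p: float,
    c_d: float,
    teff: float,
    treg: float,
    mdsc: float,
    h_pd1: float,
    h_argi: float,
    h_no: float,
    k_kill: float,
) -> float:
    """Cancer-cell killing flux (cells/day).

    kill = k_kill · C · [Teff/(total cellularity)] · (1−H_PD1)(1−H_ArgI)(1−H_NO).
    The density saturation makes the per-cancer-cell hazard bounded by
    k_kill however many Teff infiltrate.
    """
    if c_p <= 0.0 or teff <= 0.0:
        return 0.0
    total = c_p + c_d + teff + treg + mdsc
    dens = teff / total
    return k_kill * c_p * dens * (1.0 - h_pd1) * (1.0 - h_argi) * (1.0 - h_no)


@njit
def exhaustion_flux(teff: float, engagement: float, k_exh: float) -> float:
    """Teff loss to exhaustion, linear in engagement with cancer cells."""
    if teff <= 0.0 or engagement <= 0.0:
        return 0.0
    return k_exh * teff * engagement


@njit
def treg_expansion_flux(
    treg: float, argi_eff: float, k_exp_max: float, ec50_argi: float
) -> float:
    """Arg-I-driven intratumoral Treg expansion, saturating in effective Arg-I."""
    if treg <= 0.0 or argi_eff <= 0.0:
        return 0.0
    return k_exp_max * treg * argi_eff / (argi_eff + ec50_argi)


def trafficking_fluxes(state, p):
    """Linear trafficking fluxes for one T-cell lineage.

    ``state`` maps ``central, peripheral, tumor``; ``p`` maps
    ``k_cp, k_pc, k_tumor_in, tumor_volume_l, v_ref_l``.  Tumor entry is
    proportional to the central pool and to tumor volume (vascular
    surface proxy); there is no direct peripheral↔tumor flux.
    Returns per-compartment net fluxes (cells/day) from exchange only —
    sources and deaths are handled by the caller.
    """
    c, per, _ = state["central"], state["peripheral"], state["tumor"]
    to_per = p["k_cp"] * c
    to_cen = p["k_pc"] * per
    entry = p["k_tumor_in"] * c * (p["tumor_volume_l"] / p["v_ref_l"])
    return {
        "central": to_cen - to_per - entry,
        "peripheral": to_per - to_cen,
        "tumor": entry,
    }
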