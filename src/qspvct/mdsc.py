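"""Myeloid-derived suppressor cell module.

MDSCs are recruited into the tumor by CCL2 secreted by cancer cells on
top of a baseline recruitment, and secrete the two suppressive
mediators: arginase I (Arg-I, tracked in enzymatic-activity units, mU)
and nitric oxide (NO).  Both suppress Teff cytotoxicity; only Arg-I
drives intratumoral Treg expansion.  Entinostat pharmacodynamics act
through Hill inhibition factors on NO production, CCL2 production,
Arg-I activity and cancer-cell proliferation (the Arg-I *production*
coupling also exists but is disabled by default).
"""

from __future__ import annotations

from ._jit import njit


@njit
def pd_hill(conc: float, imax: float, ic50: float, n: float) -> float:
    """Hill inhibition factor Imax·cⁿ/(cⁿ + IC50ⁿ), in [0, Imax]."""
    if conc <= 0.0:
        return 0.0
    cn = conc**n
    return imax * cn / (cn + ic50**n)


@njit
def mdsc_recruitment_flux(
    ccl2_conc: float, base_rate: float, max_rate: float, ec50_ccl2: float, vol_ul: float
) -> float:
    """Recruitment into the tumor, cells/day.

    ``base_rate`` and ``max_rate`` are densities-per-day (cells/µL/day);
    the flux scales with the current tumor volume in µL so that the
    chemokine-free steady-state *density* is volume-independent.
    """
    if ccl2_conc < 0.0:
        ccl2_conc = 0.0
    hill = ccl2_conc / (ccl2_conc + ec50_ccl2) if ec50_ccl2 > 0.0 else 1.0
    return (base_rate + max_rate * hill) * vol_ul


@njit
def argI_secretion_flux(mdsc: float, enti_inhibition: float, rate: float) -> float:
    """Arg-I production, mU·µL/day; ``rate`` is mU·µL/cell/day."""
    return rate * mdsc * (1.0 - enti_inhibition)


@njit
def no_secretion_flux(mdsc: float, enti_inhibition: float, rate: float) -> float:
    """NO production, nmol/day; ``rate`` is nmol/cell/day."""
    return rate * mdsc * (1.0 - enti_inhibition)


@njit
def ccl2_secretion_flux(cancer_cells: float, enti_inhibition: float, rate: float) -> float:
    """CCL2 production by cancer cells, nmol/day."""
    return rate * cancer_cells * (1.0 - enti_inhibition)


def secretion_fluxes(mdsc, cancer_cells, enti_conc, p):
    """Convenience wrapper returning the three production fluxes.

    ``p`` is a mapping with keys ``k_argi_sec, k_no_sec, k_ccl2_sec,
    imax_enti_no, ic50_enti_no, n_enti_no, imax_enti_ccl2,
    ic50_enti_ccl2, n_enti_ccl2, imax_enti_argi_prod,
    ic50_enti_argi_prod, n_enti_argi_prod`` (unused inhibitions may be
    set to Imax = 0).
    """
    h_no = pd_hill(enti_conc, p["imax_enti_no"], p["ic50_enti_no"], p["n_enti_no"])
    h_ccl2 = pd_hill(enti_conc, p["imax_enti_ccl2"], p["ic50_enti_ccl2"], p["n_enti_ccl2"])
    h_argi = pd_hill(
        enti_conc, p["imax_enti_argi_prod"], p["ic50_enti_argi_prod"], p["n_enti_argi_prod"]
    )
    return {
        "ArgI": argI_secretion_flux(mdsc, h_argi, p["k_argi_sec"]),
        "NO": no_secretion_flux(mdsc, h_no, p["k_no_sec"]),
        "CCL2": ccl2_secretion_flux(cancer_cells, h_ccl2, p["k_ccl2_sec"]),
    }
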