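"""Cancer-cell, antigen, and antigen-presenting-cell dynamics.

Proliferating cancer cells grow logistically (crowding expressed as a
cell-count carrying capacity) under Hill inhibition by entinostat.
Dying cells move to a dead-cell pool — they still occupy tumor volume —
and release tumor antigen, which partitions between local degradation
and lymphatic transport to the tumor-draining lymph node (TDLN), where
it matures antigen-presenting cells.
"""

from __future__ import annotations

from ._jit import njit
from .mdsc import pd_hill


@njit
def cancer_growth_flux(
    c: float, capacity: float, enti_conc: float, r: float, imax: float, ic50: float, n: float
) -> float:
    """Proliferation flux, cells/day: r·C·(1 − C/K)·(1 − H_enti)."""
    if c <= 0.0:
        return 0.0
    crowd = 1.0 - c / capacity
    if crowd < 0.0:
        crowd = 0.0
    return r * c * crowd * (1.0 - pd_hill(enti_conc, imax, ic50, n))


@njit
def antigen_release_flux(dying_rate: float, release_per_cell: float) -> float:
    """Antigen release, amount/day, proportional to the total death flux."""
    if dying_rate <= 0.0:
        return 0.0
    return release_per_cell * dying_rate


@njit
def apc_maturation_flux(
    antigen_ln: float, apc_immature: float, k_mat: float, k_half: float
) -> float:
    """APC maturation in the TDLN: saturating in antigen, bounded by the pool."""
    if antigen_ln <= 0.0 or apc_immature <= 0.0:
        return 0.0
    return k_mat * apc_immature * antigen_ln / (antigen_ln + k_half)
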