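"""Entinostat dual-absorption PK and antibody disposition."""

import numpy as np
import pytest
from dataclasses import replace

from scipy.integrate import solve_ivp

from qspvct.pk import (
    DoseSpec,
    Regimen,
    antibody_fluxes,
    default_entinostat_params,
    dose_to_amount,
    pk_summary,
    preset_regimen,
    simulate_pk_profile,
)


# ---------------------------------------------------------------------------
# dosing arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "spec,bsa,wt,expected",
    [
        (DoseSpec("entinostat", 2.0, "mg/m2"), 1.7, 70.0, 3.4),
        (DoseSpec("nivolumab", 3.0, "mg/kg"), 1.7, 70.0, 210.0),
        (DoseSpec("entinostat", 0.0, "mg/m2"), 1.7, 70.0, 0.0),
        (DoseSpec("entinostat", 5.0, "mg"), 1.7, 70.0, 5.0),
    ],
)
def test_dose_to_amount(spec, bsa, wt, expected):
    assert dose_to_amount(spec, bsa, wt) == pytest.approx(expected)


def test_unknown_dose_unit_rejected():
    with pytest.raises(ValueError, match="unit"):
        dose_to_amount(DoseSpec("entinostat", 1.0, "IU"))


def test_regimen_presets_expand_and_round_trip(tmp_path):
    reg = preset_regimen("triple")
    events = reg.dose_events()
    drugs = {d for _, d, _ in events}
    assert drugs == {"nivolumab", "entinostat", "ipilimumab"}
    assert sum(1 for _, d, _ in events if d == "ipilimumab") == 4
    assert reg.total_mg("nivolumab") == pytest.approx(210.0 * 29)
    for suffix in ("json", "yaml"):
        path = tmp_path / f"reg.{suffix}"
        reg.to_file(path)
        back = Regimen.from_file(path)
        assert back.dose_events() == events


# ---------------------------------------------------------------------------
# entinostat profile
# ---------------------------------------------------------------------------

def _mass_balance(params, dose_mg_m2=2.0, t_end=48.0):
    """Integrate the stand-alone subsystem and return final state + dose."""
    from qspvct.pk import entinostat_fluxes

    p = params
    dose_ng = dose_mg_m2 * 1.7 * 1e6
    vc_ml = p.V_central_l * 1e3

    def rhs(t, y, inf):
        return entinostat_fluxes(
            y[0], y[1], y[2], y[3], y[4], inf, 0.0,
            p.ka_buccal, p.ka_gi, p.k_cp, p.k_pc,
            vc_ml, p.CL_linear_l_h * 1e3, p.Vmax_nl_ng_h, p.Km_nl_ng_ml, p.k_tumor_ex,
        )

    y = np.zeros(6)
    segments = [(0.0, p.D0_h, p.F * dose_ng / p.D0_h), (p.D0_h, p.T_lag_h, 0.0),
                (p.T_lag_h, t_end, 0.0)]
    for a, b, inf in segments:
        if b <= a:
            continue
        if a == p.T_lag_h:
            y[1] += (1 - p.F) * dose_ng
        sol = solve_ivp(rhs, (a, b), y, args=(inf,), method="LSODA",
                        rtol=1e-10, atol=1e-8)
        y = sol.y[:, -1]
    return y, dose_ng


def test_mass_conservation_with_elimination_accumulator():
    y, dose = _mass_balance(default_entinostat_params())
    assert y.sum() == pytest.approx(dose, rel=1e-6)


def test_buccal_only_dose_leaves_gi_empty():
    p = replace(default_entinostat_params(), F=1.0)
    y, _ = _mass_balance(p)
    assert y[1] == 0.0


def test_zero_dose_profile_identically_zero():
    t, c = simulate_pk_profile(0.0, 1.7, default_entinostat_params(), 24.0)
    assert np.all(c == 0.0)


def test_profile_nonnegative_and_tmax_dose_invariant():
    p = default_entinostat_params()
    tmaxes = []
    for dose in (2.0, 4.0, 6.0):
        t, c = simulate_pk_profile(dose, 1.7, p, 48.0)
        assert np.all(c >= 0)
        tmaxes.append(pk_summary(t, c).tmax_h)
    assert max(tmaxes) - min(tmaxes) < 1e-9


def test_linear_clearance_gives_dose_proportionality():
    p = replace(default_entinostat_params(), Vmax_nl_ng_h=0.0)
    t2, c2 = simulate_pk_profile(2.0, 1.7, p, 48.0)
    t4, c4 = simulate_pk_profile(4.0, 1.7, p, 48.0)
    assert np.allclose(c4, 2.0 * c2, rtol=1e-6, atol=1e-9)


def test_pk_summary_on_simple_shapes():
    t = np.linspace(0.0, 10.0, 101)
    s = pk_summary(t, np.full_like(t, 3.0))
    assert (s.cmax_ng_ml, s.tmax_h) == (3.0, 0.0)
    assert s.auc_ng_h_ml == pytest.approx(30.0)
    tri = np.interp(t, [0, 1, 2], [0, 1, 0])
    assert pk_summary(t, tri).auc_ng_h_ml == pytest.approx(1.0, rel=1e-3)


# ---------------------------------------------------------------------------
# antibodies
# ---------------------------------------------------------------------------

_AB = dict(v_c_l=3.63, v_t_l=0.0, v_ln_l=0.005, k12=0.212, k21=0.277,
           cl_l_d=0.228, k_ex_t=0.0, k_ex_ln=0.0, gamma_t=0.3, gamma_ln=0.5)


def _ab_rhs(t, y, kw):
    return antibody_fluxes(y[0], y[1], y[2], y[3], kw["v_c_l"], kw["v_t_l"],
                           kw["v_ln_l"], kw["k12"], kw["k21"], kw["cl_l_d"],
                           kw["k_ex_t"], kw["k_ex_ln"], kw["gamma_t"], kw["gamma_ln"])


def test_antibody_zero_dose_stays_zero():
    fl = _ab_rhs(0.0, np.zeros(5), _AB)
    assert all(f == 0.0 for f in fl)


def test_antibody_terminal_slope_matches_slow_eigenvalue():
    kw = _AB
    ke = kw["cl_l_d"] / kw["v_c_l"]
    A = np.array([[-(kw["k12"] + ke), kw["k21"]], [kw["k12"], -kw["k21"]]])
    lam_slow = max(np.linalg.eigvals(A).real)
    y0 = np.array([1000.0, 0.0, 0.0, 0.0, 0.0])
    sol = solve_ivp(_ab_rhs, (0.0, 120.0), y0, args=(kw,), method="LSODA",
                    rtol=1e-10, atol=1e-10, t_eval=np.linspace(80, 120, 50))
    slope = np.polyfit(sol.t, np.log(sol.y[0]), 1)[0]
    assert slope == pytest.approx(lam_slow, rel=1e-3)


def test_antibody_mass_conservation_with_tissue_exchange():
    kw = dict(_AB, v_t_l=0.02, k_ex_t=1.0, k_ex_ln=5.0)
    y0 = np.array([1438.0, 0.0, 0.0, 0.0, 0.0])
    sol = solve_ivp(_ab_rhs, (0.0, 60.0), y0, args=(kw,), method="LSODA",
                    rtol=1e-10, atol=1e-10)
    assert sol.y[:, -1].sum() == pytest.approx(1438.0, rel=1e-7)


# ---------------------------------------------------------------------------
# reported plasma summaries (also covered at cohort level by acceptance)
# ---------------------------------------------------------------------------

def test_auc_ratios_imply_near_linearity():
    p = default_entinostat_params()
    aucs = {}
    for dose in (2.0, 4.0, 6.0):
        t, c = simulate_pk_profile(dose, 1.7, p, 48.0)
        aucs[dose] = pk_summary(t, c).auc_ng_h_ml
    assert aucs[4.0] / aucs[2.0] == pytest.approx(2.0, abs=0.02)
    assert aucs[6.0] / aucs[2.0] == pytest.approx(3.0, abs=0.02)
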