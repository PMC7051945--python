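"""Model assembly, event-aware integration, baseline-growth protocol."""

import numpy as np
import pytest

from qspvct import build_model, preset_regimen
from qspvct.model import (
    NOT_REACHED,
    SPECIES,
    SPECIES_INDEX,
    SolverSettings,
    diameter_to_volume,
)
from qspvct.pk import MW_G_PER_MOL, DoseSpec, Regimen


class TestRegistry:
    def test_registry_covers_all_declared_species(self, reference_system):
        expected = {
            "cancer_proliferating", "cancer_dead", "naive_t", "activated_t",
            "teff", "treg", "mdsc", "mapc", "apc_immature", "antigen",
            "ccl2", "argI", "no", "entinostat", "nivolumab", "ipilimumab",
        }
        present = {name for name, _ in SPECIES}
        assert expected <= present
        assert len(SPECIES_INDEX) == len(SPECIES)

    def test_four_compartments(self, reference_system):
        comps = {c.name for c in reference_system.compartments()}
        assert comps == {"central", "peripheral", "tumor", "tdln"}
        assert all(c.volume_l > 0 for c in reference_system.compartments())


class TestModuleGating:
    def test_pk_only_model_freezes_cancer(self, reference_params):
        system = build_model(reference_params, module_flags={"pk"})
        y0 = system.initial_state(cancer_cells=50.0)
        sim = system.simulate(y0, (0.0, 30.0))
        c = sim.species("cancer_proliferating", "tumor")
        assert np.all(c == 50.0)

    def test_rhs_deterministic(self, reference_system):
        y = reference_system.initial_state(cancer_cells=1e6)
        a = reference_system.rhs(0.0, y)
        b = reference_system.rhs(0.0, y)
        assert np.array_equal(a, b)


class TestSimulate:
    def test_no_dose_keeps_drug_species_identically_zero(self, reference_system):
        y0 = reference_system.initial_state(cancer_cells=1e6)
        sim = reference_system.simulate(y0, (0.0, 20.0))
        atol = SolverSettings().abstol
        for name in ("entinostat", "nivolumab", "ipilimumab"):
            for comp in ("central", "peripheral", "tumor"):
                assert np.all(np.abs(sim.species(name, comp)) <= atol), (name, comp)

    def test_first_order_decay_matches_closed_form(self, reference_params):
        """Decoupled species: entinostat peripheral → central at 1/day with
        everything downstream switched off gives x(1 d) = e⁻¹·x(0)."""
        over = {
            "ent_k_pc": 1.0 / 24.0,  # 1/day after unit conversion
            "ent_k_cp": 0.0, "ent_ka_buccal": 0.0, "ent_ka_gi": 0.0,
        }
        system = build_model(reference_params.with_overrides(over), module_flags={"pk"})
        y0 = system.initial_state()
        y0[SPECIES_INDEX["entinostat.peripheral"]] = 1.0
        sim = system.simulate(y0, (0.0, 1.0), sample_every_days=0.5)
        x1 = sim.species("entinostat", "peripheral")[-1]
        assert x1 == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_determinism_of_full_simulation(self, reference_system, reference_baseline):
        state, _ = reference_baseline
        reg = preset_regimen("nivo+enti", 30.0)
        a = reference_system.simulate(state, (0.0, 30.0), regimen=reg)
        b = reference_system.simulate(state, (0.0, 30.0), regimen=reg)
        assert np.array_equal(a.y, b.y) and np.array_equal(a.t, b.t)

    def test_time_grid_strictly_increasing_daily_or_finer(self, reference_system,
                                                          reference_baseline):
        state, _ = reference_baseline
        sim = reference_system.simulate(
            state, (0.0, 28.0), regimen=preset_regimen("nivo+enti", 28.0)
        )
        assert np.all(np.diff(sim.t) > 0)
        assert np.max(np.diff(sim.t)) <= 1.0 + 1e-9

    def test_trajectory_nonnegative_within_solver_tolerance(self, reference_system,
                                                            reference_baseline):
        state, _ = reference_baseline
        sim = reference_system.simulate(
            state, (0.0, 60.0), regimen=preset_regimen("triple", 60.0)
        )
        floor = -10.0 * SolverSettings().abstol
        assert sim.y.min() >= floor

    def test_dose_event_mass_conservation(self, reference_system, reference_baseline):
        """Administered nivolumab mass = Σ compartments + eliminated."""
        state, _ = reference_baseline
        reg = preset_regimen("nivo-mono", 28.0)  # doses on days 0, 14, 28
        sim = reference_system.simulate(state, (0.0, 35.0), regimen=reg)
        administered_nmol = reg.total_mg("nivolumab") * 1e-3 / MW_G_PER_MOL["nivolumab"] * 1e9
        idx = [SPECIES_INDEX[f"nivolumab.{c}"]
               for c in ("central", "peripheral", "tumor", "tdln", "eliminated")]
        total = sim.y[idx, -1].sum()
        assert total == pytest.approx(administered_nmol, rel=1e-6)

    def test_entinostat_infusion_mass_conservation(self, reference_system,
                                                   reference_baseline):
        state, _ = reference_baseline
        reg = Regimen("one-enti", [DoseSpec("entinostat", 5.0, "mg", 0.0, 7.0, 2)])
        sim = reference_system.simulate(state, (0.0, 14.0), regimen=reg)
        idx = [SPECIES_INDEX[f"entinostat.{c}"]
               for c in ("buccal", "gi", "central", "peripheral", "tumor", "eliminated")]
        total = sim.y[idx, -1].sum()
        assert total == pytest.approx(2 * 5.0 * 1e6, rel=1e-5)

    def test_tolerance_refinement_convergence(self, reference_system, reference_baseline):
        """Halving reltol moves the terminal tumor volume by ≪ the tolerance."""
        state, _ = reference_baseline
        reg = preset_regimen("nivo-mono", 60.0)
        vols = []
        for rtol in (1e-6, 5e-7):
            sim = reference_system.simulate(
                state, (0.0, 60.0), regimen=reg,
                settings=SolverSettings(reltol=rtol),
            )
            vols.append(reference_system.tumor_volume(sim.state_at(-1)))
        assert abs(vols[1] - vols[0]) / vols[0] < 10 * 1e-6

    def test_two_stiff_integrators_agree_on_terminal_diameter(
        self, reference_system, reference_baseline
    ):
        state, _ = reference_baseline
        reg = preset_regimen("nivo+enti", 84.0)
        diams = []
        for method in ("LSODA", "BDF"):
            sim = reference_system.simulate(
                state, (0.0, 84.0), regimen=reg, settings=SolverSettings(method=method)
            )
            diams.append(reference_system.tumor_diameter(sim.state_at(-1)))
        assert diams[0] == pytest.approx(diams[1], rel=5e-4)  # 3+ significant figures

    def test_negative_initial_state_rejected(self, reference_system):
        y0 = reference_system.initial_state()
        y0[0] = -1.0
        with pytest.raises(ValueError):
            reference_system.simulate(y0, (0.0, 1.0))


class TestGrowToBaseline:
    def test_target_below_single_cell_returns_immediately(self, reference_system):
        single_cell_v = reference_system.tumor_volume(reference_system.initial_state())
        d_tiny = (6 * single_cell_v * 1e3 / np.pi) ** (1 / 3) * 0.5
        state, t = reference_system.grow_to_baseline(d_tiny)
        assert t == 0.0
        assert state[SPECIES_INDEX["cancer_proliferating.tumor"]] == 1.0

    def test_killing_dominant_parameters_never_reach(self, reference_params):
        over = {"d_cancer": 0.5, "r_growth": 0.02}  # death ≫ growth
        system = build_model(reference_params.with_overrides(over))
        state, t = system.grow_to_baseline(2.0, t_max_growth_days=365.0)
        assert state is NOT_REACHED

    def test_reference_patient_reaches_target_volume(self, reference_system,
                                                     reference_baseline):
        state, t_hit = reference_baseline
        v = reference_system.tumor_volume(state)
        assert v == pytest.approx(diameter_to_volume(3.0), rel=1e-4)
        assert 0 < t_hit < 3650

    def test_invalid_arguments_rejected(self, reference_system):
        with pytest.raises(ValueError):
            reference_system.grow_to_baseline(-1.0)
        with pytest.raises(ValueError):
            reference_system.grow_to_baseline(2.0, t_max_growth_days=0.0)
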