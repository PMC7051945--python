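"""Shared fixtures: the reference table, a baselined reference patient,
and (for the cohort-level checks) a paired multi-regimen virtual trial.

Everything is generated at test time; the cohort sizes are chosen so
the whole suite runs on one CPU in well under the half-hour scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from qspvct import (
    build_model,
    establish_baselines,
    make_reference_table,
    preset_regimen,
    run_regimen,
    sample_cohort,
)


@pytest.fixture(scope="session")
def reference():
    ps, table = make_reference_table()
    return ps, table


@pytest.fixture(scope="session")
def reference_params(reference):
    return reference[0]


@pytest.fixture(scope="session")
def reference_system(reference_params):
    return build_model(reference_params)


@pytest.fixture(scope="session")
def reference_baseline(reference_system):
    """Reference patient grown from one cancer cell to a 3 cm tumor."""
    state, t_hit = reference_system.grow_to_baseline(3.0)
    assert not isinstance(state, type(None))
    return state, t_hit


# cohort sizes for the paired virtual trial used by the acceptance suite
N_SAMPLED = 320          # sampled patients (≈ 4/5 reach baseline)
N_TRIPLE = 150           # evaluable patients re-simulated under the triple regimen


@pytest.fixture(scope="session")
def paired_trial(reference):
    """One LHS cohort, baselined once, simulated under mono and double
    regimens (paired); the first N_TRIPLE evaluable patients also get
    the triple regimen for biomarker/Teff:Treg contrasts."""
    ps, table = reference
    cohort = sample_cohort(table, N_SAMPLED, seed=20260)
    establish_baselines(cohort, ps)
    mono = run_regimen(cohort, preset_regimen("nivo-mono"), ps)
    double = run_regimen(cohort, preset_regimen("nivo+enti"), ps)
    sub = [p for p in cohort if p.evaluable][:N_TRIPLE]
    triple = run_regimen(sub, preset_regimen("triple"), ps)
    return {
        "params": ps,
        "cohort": cohort,
        "mono": mono,
        "double": double,
        "triple": triple,
        "triple_ids": {p.patient_id for p in sub},
    }
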