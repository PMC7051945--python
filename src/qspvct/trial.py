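"""Virtual clinical trial engine.

Virtual patients are parameter sets drawn by Latin hypercube sampling
(one stratum per patient per parameter) from the distribution table,
plus a preselected initial tumor diameter.  Each patient is grown from
a single cancer cell until the tumor reaches the preselected volume;
patients whose immune systems control the tumor first never reach it
and are excluded from response analysis, mirroring the trial protocol.
The same baselined cohort is then simulated under each regimen and
responses are classified by RECIST v1.1 from the weekly diameter
trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ModelSystem,
    NOT_REACHED,
    SolverSettings,
    build_model,
    tumor_diameter,
)
from .params import ParameterEntry, ParameterSet
from .pk import Regimen
from .stats import agresti_coull_ci

#: table entries consumed by the trial engine rather than the ODE kernel
SPECIAL_SAMPLED = ("initial_tumor_diameter",)


@dataclass(frozen=True)
class ParameterDistribution:
    name: str
    kind: str  # uniform | loguniform | normal (truncated at 0)
    low: float  # mean when kind == "normal"
    high: float  # sd when kind == "normal"
    integer: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "loguniform", "normal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError(f"bounds must be finite for {self.name}")
        if self.kind in ("uniform", "loguniform") and not self.low < self.high:
            raise ValueError(f"require low < high for {self.name}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform of uniform(0,1) strata to the target law."""
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        if self.kind == "uniform":
            x = self.low + u * (self.high - self.low)
        elif self.kind == "loguniform":
            x = np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low)))
        else:  # normal truncated at 0
            from scipy.stats import truncnorm

            mean, sd = self.low, self.high
            a = (0.0 - mean) / sd
            x = truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)
        if self.integer:
            x = np.maximum(np.rint(x), 0.0)
        return x


class ParameterDistributionTable:
    """Sampling distributions for the virtual-patient parameters."""

    def __init__(self, distributions: list[ParameterDistribution]):
        if not distributions:
            raise ValueError("distribution table is empty")
        names = [d.name for d in distributions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter in distribution table")
        self.distributions = list(distributions)

    def __len__(self) -> int:
        return len(self.distributions)

    def names(self) -> list[str]:
        return [d.name for d in self.distributions]

    @classmethod
    def from_parameterset(cls, ps: ParameterSet) -> "ParameterDistributionTable":
        """Collect every entry of the table that carries a distribution."""
        dists = [
            ParameterDistribution(
                name=e.name,
                kind=e.dist_kind,
                low=e.dist_low,
                high=e.dist_high,
                integer=(e.unit == "count"),
            )
            for e in ps.sampled_entries()
        ]
        return cls(dists)


@dataclass
class VirtualPatient:
    """One sampled patient: overrides + preselected diameter + baseline."""

    patient_id: int
    overrides: dict[str, float]
    initial_diameter_cm: float
    baseline_state: np.ndarray | None = None
    reached_baseline: bool = False
    t_reached_days: float | None = None

    @property
    def evaluable(self) -> bool:
        return self.reached_baseline and self.baseline_state is not None


def sample_cohort(
    table: ParameterDistributionTable,
    n: int,
    seed: int | np.random.Generator = 0,
    default_diameter_cm: float = 3.0,
) -> list[VirtualPatient]:
    """Latin hypercube cohort: each parameter's n draws occupy distinct
    equal-probability strata; reproducible under the seed."""
    from scipy.stats import qmc

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(table), rng=rng)
    U = sampler.random(n)
    cols = {
        d.name: d.ppf(U[:, j]) for j, d in enumerate(table.distributions)
    }
    patients = []
    for i in range(n):
        overrides = {k: float(v[i]) for k, v in cols.items() if k not in SPECIAL_SAMPLED}
        diam = float(cols["initial_tumor_diameter"][i]) if "initial_tumor_diameter" in cols else default_diameter_cm
        patients.append(
            VirtualPatient(patient_id=i, overrides=overrides, initial_diameter_cm=diam)
        )
    return patients


def patient_system(
    base_params: ParameterSet, patient: VirtualPatient, module_flags=None
) -> ModelSystem:
    ps = base_params.with_overrides(patient.overrides)
    if module_flags is None:
        return build_model(ps)
    return build_model(ps, module_flags)


def establish_baselines(
    cohort: list[VirtualPatient],
    base_params: ParameterSet,
    t_max_growth_days: float = 3650.0,
    settings: SolverSettings | None = None,
) -> list[VirtualPatient]:
    """Grow every patient from a single cancer cell to the preselected
    volume; flag those that never reach it (immune control)."""
    for pt in cohort:
        system = patient_system(base_params, pt)
        state, t = system.grow_to_baseline(
            pt.initial_diameter_cm, t_max_growth_days, settings
        )
        if state is NOT_REACHED:
            pt.reached_baseline = False
            pt.baseline_state = None
            pt.t_reached_days = None
        else:
            pt.reached_baseline = True
            pt.baseline_state = state
            pt.t_reached_days = t
    return cohort


# ---------------------------------------------------------------------------
# RECIST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RECISTRecord:
    baseline_mm: float
    nadir_mm: float
    final_mm: float
    pct_change_from_baseline: float
    category: str  # CR | PR | SD | PD


def classify_recist(diam_trajectory_cm, detection_floor_mm: float = 2.0) -> RECISTRecord:
    """RECIST v1.1 from a (baseline-first) diameter trajectory.

    CR: final diameter below the detection floor.  PR: ≥30% decrease
    from baseline sustained to the classification time (horizon).
    PD: ≥20% increase from the nadir with ≥5 mm absolute increase.
    SD otherwise.
    """
    d = np.asarray(diam_trajectory_cm, dtype=float) * 10.0  # mm
    if d.size == 0:
        raise ValueError("empty diameter trajectory")
    baseline = d[0]
    if baseline <= 0:
        raise ValueError("baseline diameter must be > 0")
    nadir = float(d.min())
    final = float(d[-1])
    pct = (final - baseline) / baseline * 100.0

    if final < detection_floor_mm:
        cat = "CR"
    elif final <= 0.7 * baseline:
        cat = "PR"
    elif final >= 1.2 * nadir and (final - nadir) >= 5.0:
        cat = "PD"
    else:
        cat = "SD"
    return RECISTRecord(
        baseline_mm=float(baseline),
        nadir_mm=nadir,
        final_mm=final,
        pct_change_from_baseline=float(pct),
        category=cat,
    )


# ---------------------------------------------------------------------------
# trial result
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    regimen_name: str
    records: list[dict] = field(default_factory=list)  # one per evaluable patient
    trajectories: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def n_evaluable(self) -> int:
        return len(self.records)

    @property
    def n_responders(self) -> int:
        return sum(1 for r in self.records if r["category"] in ("CR", "PR"))

    def orr(self) -> float:
        return self.n_responders / self.n_evaluable if self.records else float("nan")

    def orr_ci(self, level: float = 0.95) -> tuple[float, float]:
        return agresti_coull_ci(self.n_responders, self.n_evaluable, level)

    def category_counts(self) -> dict[str, int]:
        out = {"CR": 0, "PR": 0, "SD": 0, "PD": 0}
        for r in self.records:
            out[r["category"]] += 1
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def waterfall_frame(self):
        df = self.to_frame()
        return df[["patient_id", "pct_change_from_baseline", "category"]].sort_values(
            "pct_change_from_baseline", ascending=False
        )

    def spider_frame(self):
        import pandas as pd

        rows = []
        for pid, (t, d) in self.trajectories.items():
            base = d[0]
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "time_day": t,
                        "diameter_cm": d,
                        "pct_change": (d - base) / base * 100.0,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_regimen(
    cohort: list[VirtualPatient],
    regimen: Regimen,
    base_params: ParameterSet,
    horizon_days: float = 400.0,
    settings: SolverSettings | None = None,
    detection_floor_mm: float = 2.0,
    sample_every_days: float = 7.0,
) -> TrialResult:
    """Simulate every baselined patient under one regimen.

    The same cohort object (ids, overrides, saved baseline states) can
    be passed to several regimens, so between-regimen contrasts are
    paired.  Patients that never reached baseline are skipped and never
    enter response denominators.
    """
    result = TrialResult(regimen_name=regimen.name)
    for pt in cohort:
        if not pt.evaluable:
            continue
        system = patient_system(base_params, pt)
        sim = system.simulate(
            pt.baseline_state,
            (0.0, horizon_days),
            regimen=regimen,
            settings=settings,
            sample_every_days=sample_every_days,
        )
        diam = sim.tumor_diameter_cm()
        rec = classify_recist(diam, detection_floor_mm)
        pre = system.observables(pt.baseline_state)
        post = system.observables(sim.state_at(-1))
        # on-treatment snapshot (week 12 biopsy analogue) for immune contrasts
        i_mid = int(np.searchsorted(sim.t, min(84.0, sim.t[-1])))
        mid = system.observables(sim.state_at(min(i_mid, sim.t.size - 1)))
        row = {
            "patient_id": pt.patient_id,
            "regimen": regimen.name,
            "baseline_mm": rec.baseline_mm,
            "nadir_mm": rec.nadir_mm,
            "final_mm": rec.final_mm,
            "pct_change_from_baseline": rec.pct_change_from_baseline,
            "category": rec.category,
            "responder": rec.category in ("CR", "PR"),
        }
        for k, v in pre.items():
            row[f"pre_{k}"] = v
        for k, v in post.items():
            row[f"post_{k}"] = v
        for k, v in mid.items():
            row[f"mid_{k}"] = v
        for k, v in pt.overrides.items():
            row[f"param_{k}"] = v
        row["param_initial_tumor_diameter"] = pt.initial_diameter_cm
        result.records.append(row)
        result.trajectories[pt.patient_id] = (sim.t, diam)
    return result


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

def subgroup_split(result: TrialResult, biomarker: str, mode: str = "median"):
    """Split the cohort on a pre-treatment observable.

    ``median``: two groups (≤ median / > median) with per-group ORR and
    Agresti–Coull CI.  ``sextile``: six equal groups ordered ascending
    (stable tie-break by patient id) with per-group response counts.
    """
    import pandas as pd
    import warnings

    df = result.to_frame()
    col = biomarker if biomarker in df.columns else f"pre_{biomarker}"
    if col not in df.columns:
        raise KeyError(f"biomarker {biomarker!r} not among pre-treatment observables")
    df = df.sort_values([col, "patient_id"], kind="stable").reset_index(drop=True)

    if mode == "median":
        med = df[col].median()
        hi_mask = df[col] > med
        if hi_mask.sum() == 0 or hi_mask.sum() == len(df):
            warnings.warn(
                f"degenerate median split on {biomarker!r}: ties broken by patient order"
            )
            half = len(df) // 2
            hi_mask = pd.Series(np.arange(len(df)) >= half, index=df.index)
        rows = []
        for name, g in (("low", df[~hi_mask]), ("high", df[hi_mask])):
            x = int(g["responder"].sum())
            n = len(g)
            lo, hi = agresti_coull_ci(x, n) if n else (float("nan"),) * 2
            rows.append(
                {"group": name, "n": n, "responders": x,
                 "orr": x / n if n else float("nan"), "ci_low": lo, "ci_high": hi}
            )
        return pd.DataFrame(rows)

    if mode == "sextile":
        n = len(df)
        bounds = [round(i * n / 6) for i in range(7)]
        rows = []
        for i in range(6):
            g = df.iloc[bounds[i]:bounds[i + 1]]
            counts = g["category"].value_counts().to_dict()
            rows.append(
                {
                    "sextile": i + 1,
                    "n": len(g),
                    "median_value": g[col].median(),
                    "responders": int(g["responder"].sum()),
                    **{c: int(counts.get(c, 0)) for c in ("CR", "PR", "SD", "PD")},
                }
            )
        return pd.DataFrame(rows)

    raise ValueError(f"unknown subgroup mode {mode!r}")
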