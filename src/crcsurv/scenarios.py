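"""Packaged trial fixtures, scenario I/O, synthetic scenarios and exports.

The two packaged fixtures reproduce the arms of the Pietra et al. randomized
follow-up trial used to fit and check the model: an *intensive* arm
(3-monthly visits for two years, then 6-monthly, with annual imaging) used
for calibration, and a *minimal* arm (6-monthly visits for a year, then
annual) used for validation.  All printed trial quantities (test
characteristics, schedules, recurrence rates, metastasis distributions,
outcome targets, calibrated parameter values and their starting ranges) are
carried here verbatim.

The split of recurrences between local-only and metastatic disease is not
printed directly; it is derived from the printed counts: the metastasis
distributions are exact fractions over 15 (intensive) and 21 (minimal)
metastatic patients, and the recurrence rates imply 41 and 42 recurrers,
giving local-only shares of 26/41 and 21/42.  The locoregional :
anastomotic-only split within the local share is assumed 2 : 1.  Both are
exposed as ordinary scenario inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .progression import (
    CohortScenario,
    ConfigurationError,
    DiseaseProgressionParams,
    LifeExpectancies,
    LocalStatus,
    MetStatus,
    RecurrenceSite,
    WEEKS_PER_CYCLE,
    sample_detectability_time,
    symptom_onset_time,
    unresectability_time,
)
from .surveillance import (
    Modality,
    ScheduleSegment,
    SurveillanceSchedule,
    TestCharacteristics,
    build_schedule,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Parameter fixtures
# ---------------------------------------------------------------------------

#: Final calibrated disease-progression / background-mortality parameters.
CALIBRATED_PARAMS = DiseaseProgressionParams(
    r_d=0.092,       # per-cycle detectability hazard
    x_ds=17.0,       # weeks
    x_du=6.0,        # weeks
    r_s=0.07,        # per cycle
    r_u=0.11,        # per cycle
    sigma_ds=11.0,   # weeks
    m=0.016,         # five-year cumulative non-CRC mortality (intensive arm)
)

#: Starting ranges for the first calibration round (9 months = 39 weeks,
#: 6 months = 26 weeks at 13 weeks per cycle).
CALIBRATION_STARTING_RANGES: dict[str, tuple[float, float]] = {
    "r_d": (0.05, 0.12),
    "x_ds": (1.0, 39.0),
    "x_du": (1.0, 39.0),
    "r_s": (-0.025, 0.15),
    "r_u": (0.0, 0.15),
    "sigma_ds": (1.0, 26.0),
    "m": (0.01, 0.20),
}

#: Validation-arm background mortality: intensive-arm 1.6% plus the 14.0
#: percentage-point adjustment attributed to between-arm mortality imbalance.
VALIDATION_BACKGROUND_MORTALITY = 0.016 + 0.140


def default_tests() -> list[TestCharacteristics]:
    """Published sensitivity/specificity of the seven surveillance modalities."""
    values = {
        Modality.CEA: (0.64, 0.90),
        Modality.CHEST_XRAY: (0.76, 0.95),
        Modality.CT_HEPATIC: (0.83, 0.93),
        Modality.CT_OTHER_ABDOMINAL: (0.46, 0.98),
        Modality.HEPATIC_ULTRASOUND: (0.62, 0.85),
        Modality.COLONOSCOPY: (0.95, 1.00),
        Modality.CLINICAL_EXAM: (0.42, 0.95),
    }
    return [
        TestCharacteristics(modality=m, sensitivity=se, specificity=sp)
        for m, (se, sp) in values.items()
    ]


#: Plausible ranges for one-way sensitivity analysis (sensitivities,
#: specificities and life expectancies).
SENSITIVITY_RANGES: dict[str, tuple[float, float]] = {
    "tests.cea.sensitivity": (0.49, 0.79),
    "tests.cea.specificity": (0.75, 1.00),
    "tests.chest_xray.sensitivity": (0.61, 0.91),
    "tests.chest_xray.specificity": (0.80, 1.00),
    "tests.ct_hepatic.sensitivity": (0.68, 0.98),
    "tests.ct_hepatic.specificity": (0.78, 1.00),
    "tests.ct_other_abdominal.sensitivity": (0.31, 0.61),
    "tests.ct_other_abdominal.specificity": (0.83, 1.00),
    "tests.hepatic_ultrasound.sensitivity": (0.47, 0.77),
    "tests.hepatic_ultrasound.specificity": (0.70, 1.00),
    "tests.colonoscopy.sensitivity": (0.80, 1.00),
    "tests.colonoscopy.specificity": (0.85, 1.00),
    "tests.clinical_exam.sensitivity": (0.27, 0.57),
    "tests.clinical_exam.specificity": (0.70, 1.00),
    "life_expectancies.post_salvage_months": (15.0, 27.0),
    "life_expectancies.post_unresectable_months": (4.0, 12.0),
}

# ---------------------------------------------------------------------------
# Surveillance schedule fixtures
# ---------------------------------------------------------------------------

_ALL_MODALITIES = (
    Modality.CLINICAL_EXAM,
    Modality.CEA,
    Modality.HEPATIC_ULTRASOUND,
    Modality.CT_HEPATIC,
    Modality.CT_OTHER_ABDOMINAL,
    Modality.CHEST_XRAY,
    Modality.COLONOSCOPY,
)

# "Every 3 months for 2 years; every 6 months thereafter" -> cycles 1-8 then
# 10, 12, ..., 20; "every 12 months" -> cycles 4, 8, ..., 20.  A scheduled
# abdominal/pelvic CT administers its hepatic and other-abdominal components
# at the same visit.
_Q3_2Y_THEN_Q6 = (ScheduleSegment(3, 0, 24), ScheduleSegment(6, 24, 60))
_Q6_1Y_THEN_Q12 = (ScheduleSegment(6, 0, 12), ScheduleSegment(12, 12, 60))
_ANNUAL = (ScheduleSegment(12, 0, 60),)


def intensive_schedule(horizon_cycles: int = 20) -> SurveillanceSchedule:
    return build_schedule(
        {
            Modality.CLINICAL_EXAM: _Q3_2Y_THEN_Q6,
            Modality.CEA: _Q3_2Y_THEN_Q6,
            Modality.HEPATIC_ULTRASOUND: _Q3_2Y_THEN_Q6,
            Modality.CT_HEPATIC: _ANNUAL,
            Modality.CT_OTHER_ABDOMINAL: _ANNUAL,
            Modality.CHEST_XRAY: _ANNUAL,
            Modality.COLONOSCOPY: _ANNUAL,
        },
        horizon_cycles=horizon_cycles,
        modalities=_ALL_MODALITIES,
    )


def minimal_schedule(horizon_cycles: int = 20) -> SurveillanceSchedule:
    return build_schedule(
        {
            Modality.CLINICAL_EXAM: _Q6_1Y_THEN_Q12,
            Modality.CEA: _Q6_1Y_THEN_Q12,
            Modality.HEPATIC_ULTRASOUND: _Q6_1Y_THEN_Q12,
            Modality.CT_HEPATIC: (),  # no CT in the minimal arm
            Modality.CT_OTHER_ABDOMINAL: (),
            Modality.CHEST_XRAY: _ANNUAL,
            Modality.COLONOSCOPY: _ANNUAL,
        },
        horizon_cycles=horizon_cycles,
        modalities=_ALL_MODALITIES,
    )


# ---------------------------------------------------------------------------
# Recurrence-site distributions
# ---------------------------------------------------------------------------

_SITE_LOCOREGIONAL = RecurrenceSite(local_status=LocalStatus.LOCOREGIONAL)
_SITE_ANASTOMOTIC = RecurrenceSite(local_status=LocalStatus.ANASTOMOTIC_ONLY)
_SITE_LIVER = RecurrenceSite(met_status=MetStatus.LIVER)
_SITE_LUNG = RecurrenceSite(met_status=MetStatus.LUNG)
_SITE_MULTI = RecurrenceSite(met_status=MetStatus.MULTIPLE_OTHER)


def site_distribution(
    local_share: float, met_split: tuple[float, float, float]
) -> dict[RecurrenceSite, float]:
    """Build a recurrence-site distribution from the local-only share and the
    liver/lung/multiple-other split among metastatic patients.  Local-only
    disease is split 2:1 between locoregional and anastomotic-only."""
    liver, lung, other = met_split
    total = liver + lung + other
    if total <= 0 or abs(total - 1.0) > 1e-6:
        raise ConfigurationError("metastatic split must sum to 1")
    met_share = 1.0 - local_share
    return {
        _SITE_LOCOREGIONAL: local_share * 2.0 / 3.0,
        _SITE_ANASTOMOTIC: local_share * 1.0 / 3.0,
        _SITE_LIVER: met_share * liver,
        _SITE_LUNG: met_share * lung,
        _SITE_MULTI: met_share * other,
    }


#: Metastasis distributions among metastatic patients, as printed:
#: intensive 26.7% / 0.0% / 73.3% (= 4/15, 0/15, 11/15) and minimal
#: 14.2% / 4.8% / 81.0% (= 3/21, 1/21, 17/21).
INTENSIVE_MET_SPLIT = (4 / 15, 0 / 15, 11 / 15)
MINIMAL_MET_SPLIT = (3 / 21, 1 / 21, 17 / 21)

#: Local-only shares derived from the printed counts (see module docstring).
INTENSIVE_LOCAL_SHARE = 26 / 41
MINIMAL_LOCAL_SHARE = 21 / 42

#: Observed outcome targets (percentage points).
INTENSIVE_TARGETS = {
    "dfs5": 68.0,
    "os1": 97.0,
    "os2": 90.0,
    "os3": 84.0,
    "os4": 76.0,
    "os5": 73.0,
    "salvage": 20.0,
}
MINIMAL_TARGETS = {
    "dfs5": 53.0,
    "os1": 98.0,
    "os2": 89.0,
    "os3": 74.0,
    "os4": 65.0,
    "os5": 58.0,
    "salvage": 6.0,
}


def pietra_intensive(n_patients: int = 10_000) -> CohortScenario:
    return CohortScenario(
        n_patients=n_patients,
        p_recur=0.394,
        site_distribution=site_distribution(INTENSIVE_LOCAL_SHARE, INTENSIVE_MET_SPLIT),
        progression=CALIBRATED_PARAMS,
        tests=default_tests(),
        schedule=intensive_schedule(),
        life_expectancies=LifeExpectancies(),
        name="pietra_intensive",
    )


def pietra_minimal(n_patients: int = 10_000) -> CohortScenario:
    return CohortScenario(
        n_patients=n_patients,
        p_recur=0.404,
        site_distribution=site_distribution(MINIMAL_LOCAL_SHARE, MINIMAL_MET_SPLIT),
        progression=CALIBRATED_PARAMS.replace(m=VALIDATION_BACKGROUND_MORTALITY),
        tests=default_tests(),
        schedule=minimal_schedule(),
        life_expectancies=LifeExpectancies(),
        name="pietra_minimal",
    )


_FIXTURES = {
    "pietra_intensive": (pietra_intensive, INTENSIVE_TARGETS),
    "pietra_minimal": (pietra_minimal, MINIMAL_TARGETS),
}


def load_fixture(
    name: str, n_patients: int = 10_000
) -> tuple[CohortScenario, dict[str, float]]:
    """Return a packaged scenario and its observed outcome targets."""
    try:
        builder, targets = _FIXTURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return builder(n_patients=n_patients), dict(targets)


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def default_sweep_table(seed: int = 0) -> list["SweepSpec"]:
    """One-way sweep specs for every non-calibrated parameter."""
    from .sensitivity import SweepSpec

    return [
        SweepSpec(parameter=path, low=lo, high=hi, seed=seed)
        for path, (lo, hi) in SENSITIVITY_RANGES.items()
    ]


# ---------------------------------------------------------------------------
# Scenario serialization (YAML / JSON, explicit unit suffixes)
# ---------------------------------------------------------------------------

def scenario_to_dict(scenario: CohortScenario) -> dict:
    return {
        "name": scenario.name,
        "n_patients": scenario.n_patients,
        "p_recur": scenario.p_recur,
        "horizon_cycles": scenario.horizon_cycles,
        "site_distribution": [
            {
                "local": site.local_status.value,
                "met": site.met_status.value,
                "p": float(p),
            }
            for site, p in scenario.site_distribution.items()
        ],
        "progression": {
            "r_d_per_cycle": scenario.progression.r_d,
            "x_du_weeks": scenario.progression.x_du,
            "r_u_per_cycle": scenario.progression.r_u,
            "x_ds_weeks": scenario.progression.x_ds,
            "r_s_per_cycle": scenario.progression.r_s,
            "sigma_ds_weeks": scenario.progression.sigma_ds,
            "m_5yr": scenario.progression.m,
        },
        "tests": [
            {
                "modality": t.modality.value,
                "sensitivity": t.sensitivity,
                "specificity": t.specificity,
                "detectable_targets": sorted(t.detectable_targets),
            }
            for t in scenario.tests
        ],
        "schedule": {
            "modalities": [m.value for m in scenario.schedule.modalities],
            "matrix": scenario.schedule.matrix.tolist(),
        }
        if scenario.schedule is not None
        else None,
        "life_expectancies": {
            "no_recurrence_years": scenario.life_expectancies.no_recurrence_years,
            "post_salvage_months": scenario.life_expectancies.post_salvage_months,
            "post_unresectable_months": scenario.life_expectancies.post_unresectable_months,
        },
    }


def scenario_from_dict(data: Mapping) -> CohortScenario:
    dist = {}
    for entry in data.get("site_distribution", []):
        site = RecurrenceSite(
            local_status=LocalStatus(entry.get("local", "none")),
            met_status=MetStatus(entry.get("met", "none")),
        )
        dist[site] = float(entry["p"])
    prog = data["progression"]
    progression = DiseaseProgressionParams(
        r_d=float(prog["r_d_per_cycle"]),
        x_du=float(prog["x_du_weeks"]),
        r_u=float(prog["r_u_per_cycle"]),
        x_ds=float(prog["x_ds_weeks"]),
        r_s=float(prog["r_s_per_cycle"]),
        sigma_ds=float(prog["sigma_ds_weeks"]),
        m=float(prog["m_5yr"]),
    )
    tests = [
        TestCharacteristics(
            modality=Modality(t["modality"]),
            sensitivity=float(t["sensitivity"]),
            specificity=float(t["specificity"]),
            detectable_targets=frozenset(t.get("detectable_targets") or ()),
        )
        for t in data.get("tests", [])
    ]
    schedule = None
    sched = data.get("schedule")
    if sched is not None:
        if "matrix" in sched:
            schedule = SurveillanceSchedule(
                modalities=tuple(Modality(m) for m in sched["modalities"]),
                matrix=np.asarray(sched["matrix"]),
            )
        else:  # visit-rule shorthand: {modality: [[interval, start, end], ...]}
            rules = {
                Modality(m): [ScheduleSegment(*seg) for seg in segs]
                for m, segs in sched["rules"].items()
            }
            schedule = build_schedule(
                rules, horizon_cycles=int(data.get("horizon_cycles", 20))
            )
    le = data.get("life_expectancies", {})
    return CohortScenario(
        n_patients=int(data["n_patients"]),
        p_recur=float(data["p_recur"]),
        site_distribution=dist,
        progression=progression,
        tests=tests,
        schedule=schedule,
        life_expectancies=LifeExpectancies(
            no_recurrence_years=float(le.get("no_recurrence_years", 20.7)),
            post_salvage_months=float(le.get("post_salvage_months", 21.0)),
            post_unresectable_months=float(le.get("post_unresectable_months", 8.0)),
        ),
        horizon_cycles=int(data.get("horizon_cycles", 20)),
        name=str(data.get("name", "scenario")),
    )


def save_scenario(scenario: CohortScenario, path) -> None:
    path = Path(path)
    data = scenario_to_dict(scenario)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_scenario(path) -> CohortScenario:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scenario_from_dict(data)


# ---------------------------------------------------------------------------
# Synthetic scenario generation (for property-based testing)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenarioSpec:
    """Ranges from which a random but valid scenario is drawn."""

    n_patients: tuple[int, int] = (50, 500)
    p_recur: tuple[float, float] = (0.0, 1.0)
    r_d: tuple[float, float] = (0.02, 0.3)
    x_du: tuple[float, float] = (1.0, 39.0)
    r_u: tuple[float, float] = (0.0, 0.15)
    x_ds: tuple[float, float] = (1.0, 39.0)
    r_s: tuple[float, float] = (-0.025, 0.15)
    sigma_ds: tuple[float, float] = (0.0, 26.0)
    m: tuple[float, float] = (0.0, 0.3)
    schedule_density: tuple[float, float] = (0.0, 1.0)
    horizon_cycles: int = 20

    def __post_init__(self) -> None:
        for name in (
            "p_recur", "r_d", "x_du", "r_u", "x_ds", "r_s", "sigma_ds", "m",
            "schedule_density",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigurationError(f"empty range for {name}")
        if not (0 <= self.p_recur[0] and self.p_recur[1] <= 1):
            raise ConfigurationError("p_recur range must lie within [0, 1]")
        if self.r_d[0] <= 0:
            raise ConfigurationError("r_d range must be positive")


def generate_synthetic_scenario(
    spec: SyntheticScenarioSpec, seed: int
) -> CohortScenario:
    """Draw a random scenario satisfying all invariants; deterministic in seed."""
    rng = np.random.default_rng(seed)

    def draw(lo_hi: tuple[float, float]) -> float:
        lo, hi = lo_hi
        return float(lo if lo == hi else rng.uniform(lo, hi))

    n = int(rng.integers(spec.n_patients[0], spec.n_patients[1] + 1))
    weights = rng.dirichlet(np.ones(5))
    dist = dict(
        zip(
            (_SITE_LOCOREGIONAL, _SITE_ANASTOMOTIC, _SITE_LIVER, _SITE_LUNG, _SITE_MULTI),
            (weights / weights.sum()).tolist(),
        )
    )
    density = draw(spec.schedule_density)
    tests = default_tests()
    matrix = (
        rng.uniform(size=(spec.horizon_cycles, len(_ALL_MODALITIES))) < density
    ).astype(np.int8)
    schedule = SurveillanceSchedule(modalities=_ALL_MODALITIES, matrix=matrix)
    return CohortScenario(
        n_patients=n,
        p_recur=draw(spec.p_recur),
        site_distribution=dist,
        progression=DiseaseProgressionParams(
            r_d=draw(spec.r_d),
            x_du=max(draw(spec.x_du), 1e-6),
            r_u=draw(spec.r_u),
            x_ds=max(draw(spec.x_ds), 1e-6),
            r_s=draw(spec.r_s),
            sigma_ds=draw(spec.sigma_ds),
            m=draw(spec.m),
        ),
        tests=tests,
        schedule=schedule,
        life_expectancies=LifeExpectancies(),
        horizon_cycles=spec.horizon_cycles,
        name=f"synthetic_{seed}",
    )


# ---------------------------------------------------------------------------
# Per-patient progression scatter export
# ---------------------------------------------------------------------------

def export_progression_scatter(
    params: DiseaseProgressionParams, n: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Sample ``n`` recurring patients and tabulate their D/U/S milestones,
    ranked from earliest- to latest-recurring (ascending D)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        D = sample_detectability_time(params.r_d, rng)
        U = unresectability_time(D, params)
        S, eps = symptom_onset_time(D, params, rng)
        rows.append((D, U, S, eps))
    rows.sort(key=lambda r: r[0])
    df = pd.DataFrame(rows, columns=["D_cycles", "U_cycles", "S_cycles", "eps_cycles"])
    df.insert(0, "rank", np.arange(1, n + 1))
    for col in ("D", "U", "S"):
        df[f"{col}_weeks"] = df[f"{col}_cycles"] * WEEKS_PER_CYCLE
    return df
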