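"""Five-state Markov loop combining latent progression, surveillance and death.

Each patient starts in *no known recurrence* and is stepped through 3-month
cycles up to the 5-year horizon (20 cycles).  Within a cycle events resolve in
a fixed order:

1. **Symptomatic interval detection** — if the patient is undiagnosed and the
   symptom-onset time S falls within the cycle (previous boundary, boundary],
   recurrence is diagnosed at the continuous time S.
2. **Scheduled surveillance** at the cycle boundary (only if still
   undiagnosed): any positive test triggers a full workup which diagnoses the
   recurrence iff it is truly detectable (boundary time >= D).
3. **Background mortality** — a per-cycle draw calibrated so the five-year
   cumulative probability equals the scenario's ``m``.

On diagnosis the patient moves to *recurrence curatively treated* (salvage)
when the diagnosing cycle begins before the continuous unresectability time U
at an operable site, otherwise to *recurrence palliatively treated*; a life
expectancy is assigned and cancer
death occurs deterministically at diagnosis time + life expectancy if within
the horizon.  Background mortality competes in every living state; the first
death wins.  Curatively treated patients remain under the schedule but no
second recurrence exists to find.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .progression import (
    CohortProfiles,
    CohortScenario,
    ConfigurationError,
    LUNG_OPERABLE_FACTOR,
    MetStatus,
    RecurrenceProfile,
    generate_cohort_profiles,
    salvage_eligible,
)
from .surveillance import run_surveillance_cycle

logger = logging.getLogger(__name__)

# Markov states
STATE_NO_KNOWN_RECURRENCE = "no_known_recurrence"
STATE_RECURRENCE_CURATIVE = "recurrence_curative"
STATE_RECURRENCE_PALLIATIVE = "recurrence_palliative"
STATE_DEAD_CANCER = "dead_cancer"
STATE_DEAD_OTHER = "dead_other"

MODE_SURVEILLANCE = "surveillance"
MODE_SYMPTOMATIC = "symptomatic"


@dataclass
class PatientOutcome:
    """Realized trajectory of one simulated patient (times in cycles)."""

    state_path: list[str]
    dx_time: Optional[float] = None
    dx_mode: Optional[str] = None
    salvage: bool = False
    death_time: Optional[float] = None
    death_cause: Optional[str] = None
    profile: Optional[RecurrenceProfile] = None

    @property
    def diagnosed(self) -> bool:
        return self.dx_time is not None

    def alive_at(self, t: float) -> bool:
        """Alive strictly after the events of time ``t`` (deaths at exactly
        ``t`` count as dead)."""
        return self.death_time is None or self.death_time > t


@dataclass
class OutcomeSummary:
    """Cohort-level outcome targets, as proportions in [0, 1]."""

    dfs5: float
    os: tuple[float, float, float, float, float]  # years 1..5
    salvage_prop: float
    dx_mode_split: dict = field(default_factory=dict)
    n_patients: int = 0

    TARGET_NAMES = ("dfs5", "os1", "os2", "os3", "os4", "os5", "salvage")

    def as_percent_targets(self) -> dict[str, float]:
        """The seven calibration/validation targets on the 0-100 scale."""
        out = {"dfs5": 100.0 * self.dfs5}
        for k in range(1, 6):
            out[f"os{k}"] = 100.0 * self.os[k - 1]
        out["salvage"] = 100.0 * self.salvage_prop
        return out


def per_cycle_mortality(cum_5yr: float, horizon_cycles: int = 20) -> float:
    """Per-cycle background death probability p with (1-p)^20 = 1 - cum_5yr."""
    if not (0.0 <= cum_5yr < 1.0):
        raise ConfigurationError(f"cumulative mortality must lie in [0, 1), got {cum_5yr}")
    return 1.0 - (1.0 - cum_5yr) ** (1.0 / horizon_cycles)


def _assign_life_expectancy_cycles(scenario: CohortScenario, salvage: bool) -> float:
    le = scenario.life_expectancies
    return le.post_salvage_cycles if salvage else le.post_unresectable_cycles


def simulate_patient(
    profile: RecurrenceProfile,
    scenario: CohortScenario,
    rng: np.random.Generator,
) -> PatientOutcome:
    """Step one patient through the surveillance/re-treatment submodel.

    This is the scalar reference implementation of the cycle loop; cohort runs
    use the vectorized engine in :func:`run_scenario`, which implements the
    same event ordering.
    """
    horizon = scenario.horizon_cycles
    p_bg = per_cycle_mortality(scenario.progression.m, horizon)
    states: list[str] = []
    dx_time: Optional[float] = None
    dx_mode: Optional[str] = None
    salvage = False
    death_time: Optional[float] = None
    death_cause: Optional[str] = None
    cancer_death_time: Optional[float] = None
    state = STATE_NO_KNOWN_RECURRENCE

    for cycle in range(1, horizon + 1):
        boundary = float(cycle)
        # (1) symptomatic interval detection
        if (
            dx_time is None
            and profile.will_recur
            and profile.S is not None
            and boundary - 1.0 < profile.S <= boundary
        ):
            dx_time, dx_mode = profile.S, MODE_SYMPTOMATIC
        # (2) scheduled surveillance at the boundary
        if dx_time is None and scenario.schedule is not None:
            result = run_surveillance_cycle(
                profile, cycle, scenario.schedule, scenario.tests, rng
            )
            if result.diagnosis is not None:
                dx_time, dx_mode = result.diagnosis.time, MODE_SURVEILLANCE
        # re-treatment decision at diagnosis: resectability is judged at cycle
        # level, using the diagnosing cycle's start time against continuous U
        if dx_time is not None and cancer_death_time is None:
            salvage = salvage_eligible(
                profile.site, float(cycle - 1), profile.U, rng
            )
            cancer_death_time = dx_time + _assign_life_expectancy_cycles(
                scenario, salvage
            )
            state = (
                STATE_RECURRENCE_CURATIVE if salvage else STATE_RECURRENCE_PALLIATIVE
            )
        # deterministic cancer death within this cycle?
        if (
            cancer_death_time is not None
            and death_time is None
            and cancer_death_time <= boundary
        ):
            death_time, death_cause = cancer_death_time, STATE_DEAD_CANCER
        # (3) background-mortality draw (skipped if already dead this cycle)
        if death_time is None:
            if rng.uniform() < p_bg:
                death_time, death_cause = boundary, STATE_DEAD_OTHER
        if death_time is not None:
            states.append(death_cause)
            states.extend([death_cause] * (horizon - cycle))
            break
        states.append(state)

    return PatientOutcome(
        state_path=states,
        dx_time=dx_time,
        dx_mode=dx_mode,
        salvage=salvage,
        death_time=death_time,
        death_cause=death_cause,
        profile=profile,
    )


# ---------------------------------------------------------------------------
# Vectorized cohort engine
# ---------------------------------------------------------------------------

@dataclass
class CohortArrays:
    """Structure-of-arrays simulation result for a whole cohort."""

    profiles: CohortProfiles
    dx_time: np.ndarray  # nan = never diagnosed
    dx_surveillance: np.ndarray  # bool: diagnosed via surveillance
    salvage: np.ndarray  # bool
    death_time: np.ndarray  # nan = alive at horizon
    death_cancer: np.ndarray  # bool: death cause is cancer


def _simulate_cohort(
    scenario: CohortScenario, seed_sequence: np.random.SeedSequence
) -> CohortArrays:
    """Run the whole cohort through the cycle loop using array operations.

    Randomness comes from named child streams of ``seed_sequence`` (profiles,
    test results, lung-operability draw, background mortality).  All random
    draws are indexed by patient, cycle and test position rather than consumed
    conditionally, which makes runs with a common seed usable as common random
    numbers across scenario variants.
    """
    n = scenario.n_patients
    horizon = scenario.horizon_cycles
    ss_profiles, ss_tests, ss_lung, ss_mort = seed_sequence.spawn(4)
    profiles = generate_cohort_profiles(scenario, ss_profiles)

    tests = list(scenario.tests)
    n_tests = len(tests)
    u_tests = np.random.default_rng(ss_tests).uniform(size=(n, horizon, n_tests))
    u_lung = np.random.default_rng(ss_lung).uniform(size=n)
    u_mort = np.random.default_rng(ss_mort).uniform(size=(n, horizon))

    boundaries = np.arange(1, horizon + 1, dtype=float)  # (horizon,)
    D = profiles.D  # nan for non-recurrers
    with np.errstate(invalid="ignore"):
        detectable = profiles.will_recur[:, None] & (
            D[:, None] <= boundaries[None, :]
        )  # (n, horizon)

    # --- surveillance: first cycle whose workup yields a true diagnosis ----
    if n_tests and scenario.schedule is not None:
        sched = np.zeros((horizon, n_tests), dtype=bool)
        for j, test in enumerate(tests):
            col = scenario.schedule.column(test.modality)
            sched[: len(col), j] = col.astype(bool)[:horizon]
        # does the modality reach the patient's site?
        site_match = np.zeros((n, n_tests), dtype=bool)
        for s_idx, site in enumerate(profiles.sites):
            members = profiles.site_index == s_idx
            if not members.any():
                continue
            for j, test in enumerate(tests):
                if site.components & test.detectable_targets:
                    site_match[members, j] = True
        sens = np.array([t.sensitivity for t in tests])
        fp = 1.0 - np.array([t.specificity for t in tests])
        true_channel = detectable[:, :, None] & site_match[:, None, :]
        p_pos = np.where(true_channel, sens[None, None, :], fp[None, None, :])
        positive = (u_tests < p_pos) & sched[None, :, :]
        any_positive = positive.any(axis=2)  # (n, horizon)
        workup_dx = any_positive & detectable
        has_surv = workup_dx.any(axis=1)
        first_idx = workup_dx.argmax(axis=1)
        c_surv = np.where(has_surv, boundaries[first_idx], np.inf)
    else:
        c_surv = np.full(n, np.inf)

    # --- symptomatic interval detection ------------------------------------
    S = profiles.S
    with np.errstate(invalid="ignore"):
        sympt_ok = profiles.will_recur & (S <= horizon)
    c_sympt_cycle = np.where(sympt_ok, np.ceil(np.where(sympt_ok, S, 1.0)), np.inf)
    c_sympt_cycle = np.where(
        sympt_ok & (c_sympt_cycle < 1.0), 1.0, c_sympt_cycle
    )  # S > 0 always, but guard exact zeros

    # symptoms resolve before the boundary tests of the same cycle
    symptomatic_first = c_sympt_cycle <= c_surv
    dx_time_candidate = np.where(symptomatic_first, S, c_surv)
    dx_cycle_candidate = np.where(symptomatic_first, c_sympt_cycle, c_surv)
    has_dx_candidate = np.isfinite(dx_cycle_candidate)

    # --- background mortality ----------------------------------------------
    p_bg = per_cycle_mortality(scenario.progression.m, horizon)
    bg_hit = u_mort < p_bg
    has_bg = bg_hit.any(axis=1)
    bg_cycle = np.where(has_bg, boundaries[bg_hit.argmax(axis=1)], np.inf)

    # diagnosis happens only if its cycle's detection step precedes background
    # death (within a cycle: symptoms/tests before the mortality draw)
    diagnosed = has_dx_candidate & (dx_cycle_candidate <= bg_cycle)
    dx_time = np.where(diagnosed, dx_time_candidate, np.nan)
    dx_surveillance = diagnosed & ~symptomatic_first

    # --- salvage eligibility ------------------------------------------------
    # The curative-vs-palliative decision is made at cycle level: a recurrence
    # diagnosed during a cycle is still resectable when that cycle *begins*
    # before U (continuous U is compared against the diagnosing cycle, not
    # against the exact within-cycle diagnosis time).
    met_index = np.full(n, -1, dtype=np.int64)
    for s_idx, site in enumerate(profiles.sites):
        met_index[profiles.site_index == s_idx] = {
            MetStatus.NONE: 0,
            MetStatus.LIVER: 1,
            MetStatus.LUNG: 2,
            MetStatus.MULTIPLE_OTHER: 3,
        }[site.met_status]
    with np.errstate(invalid="ignore"):
        dx_cycle_start = np.ceil(dx_time) - 1.0
        before_U = diagnosed & (dx_cycle_start < profiles.U)
    operable = np.select(
        [met_index == 0, met_index == 1, met_index == 2],
        [True, True, u_lung < LUNG_OPERABLE_FACTOR],
        default=False,
    )
    salvage = before_U & operable

    # --- death resolution ----------------------------------------------------
    le_salvage = scenario.life_expectancies.post_salvage_cycles
    le_palliative = scenario.life_expectancies.post_unresectable_cycles
    cancer_death = np.where(
        diagnosed, dx_time + np.where(salvage, le_salvage, le_palliative), np.inf
    )
    cancer_death = np.where(cancer_death <= horizon, cancer_death, np.inf)
    # cancer death at t <= boundary resolves before that boundary's mortality
    # draw, so ties go to cancer
    death_time = np.minimum(cancer_death, bg_cycle)
    death_cancer = cancer_death <= bg_cycle
    dead = np.isfinite(death_time)
    death_time = np.where(dead, death_time, np.nan)
    death_cancer = dead & death_cancer

    return CohortArrays(
        profiles=profiles,
        dx_time=dx_time,
        dx_surveillance=dx_surveillance,
        salvage=salvage,
        death_time=death_time,
        death_cancer=death_cancer,
    )


def _summary_from_arrays(arrays: CohortArrays, horizon: int) -> OutcomeSummary:
    n = len(arrays.profiles)
    dead = ~np.isnan(arrays.death_time)
    death_time = np.where(dead, arrays.death_time, np.inf)
    diagnosed = ~np.isnan(arrays.dx_time)
    os = tuple(
        float(np.mean(death_time > 4.0 * k)) for k in range(1, (horizon // 4) + 1)
    )
    dfs = float(np.mean(~diagnosed & (death_time > horizon)))
    n_dx = int(diagnosed.sum())
    split = {
        MODE_SURVEILLANCE: float(arrays.dx_surveillance.sum() / n_dx) if n_dx else 0.0,
        MODE_SYMPTOMATIC: float(
            (diagnosed & ~arrays.dx_surveillance).sum() / n_dx
        )
        if n_dx
        else 0.0,
    }
    return OutcomeSummary(
        dfs5=dfs,
        os=os,  # type: ignore[arg-type]
        salvage_prop=float(arrays.salvage.mean()),
        dx_mode_split=split,
        n_patients=n,
    )


def _outcomes_from_arrays(
    arrays: CohortArrays, scenario: CohortScenario
) -> list[PatientOutcome]:
    horizon = scenario.horizon_cycles
    outcomes: list[PatientOutcome] = []
    for i in range(len(arrays.profiles)):
        dx_t = arrays.dx_time[i]
        diagnosed = not math.isnan(dx_t)
        death_t = arrays.death_time[i]
        dead = not math.isnan(death_t)
        salvage = bool(arrays.salvage[i])
        dx_mode = (
            (MODE_SURVEILLANCE if arrays.dx_surveillance[i] else MODE_SYMPTOMATIC)
            if diagnosed
            else None
        )
        death_cause = (
            (STATE_DEAD_CANCER if arrays.death_cancer[i] else STATE_DEAD_OTHER)
            if dead
            else None
        )
        path = []
        for cycle in range(1, horizon + 1):
            if dead and death_t <= cycle:
                path.append(death_cause)
            elif diagnosed and dx_t <= cycle:
                path.append(
                    STATE_RECURRENCE_CURATIVE if salvage else STATE_RECURRENCE_PALLIATIVE
                )
            else:
                path.append(STATE_NO_KNOWN_RECURRENCE)
        outcomes.append(
            PatientOutcome(
                state_path=path,
                dx_time=float(dx_t) if diagnosed else None,
                dx_mode=dx_mode,
                salvage=salvage,
                death_time=float(death_t) if dead else None,
                death_cause=death_cause,
                profile=arrays.profiles.profile(i),
            )
        )
    return outcomes


def summarize_cohort(
    outcomes: Sequence[PatientOutcome], horizon: int = 20
) -> OutcomeSummary:
    """Cohort targets from realized trajectories.

    OS at year k is evaluated at exactly cycle 4k after that cycle's events;
    DFS counts a patient as event-free when neither a recurrence diagnosis nor
    death from any cause occurred by the horizon.
    """
    if not outcomes:
        raise ConfigurationError("cannot summarize an empty cohort")
    n = len(outcomes)
    os = tuple(
        sum(o.alive_at(4.0 * k) for o in outcomes) / n
        for k in range(1, (horizon // 4) + 1)
    )
    dfs = (
        sum(
            (not o.diagnosed) and (o.death_time is None or o.death_time > horizon)
            for o in outcomes
        )
        / n
    )
    n_dx = sum(o.diagnosed for o in outcomes)
    split = {
        MODE_SURVEILLANCE: (
            sum(o.dx_mode == MODE_SURVEILLANCE for o in outcomes) / n_dx if n_dx else 0.0
        ),
        MODE_SYMPTOMATIC: (
            sum(o.dx_mode == MODE_SYMPTOMATIC for o in outcomes) / n_dx if n_dx else 0.0
        ),
    }
    return OutcomeSummary(
        dfs5=dfs,
        os=os,  # type: ignore[arg-type]
        salvage_prop=sum(o.salvage for o in outcomes) / n,
        dx_mode_split=split,
        n_patients=n,
    )


def run_scenario_summary(scenario: CohortScenario, seed: int) -> OutcomeSummary:
    """Fast path: cohort summary only, without materializing trajectories."""
    arrays = _simulate_cohort(scenario, np.random.SeedSequence(seed))
    return _summary_from_arrays(arrays, scenario.horizon_cycles)


def run_scenario(
    scenario: CohortScenario, seed: int
) -> tuple[OutcomeSummary, list[PatientOutcome]]:
    """Simulate the full cohort; deterministic given (scenario, seed).

    Per-patient randomness is indexed by patient position within named
    streams derived from the master seed, so enlarging the cohort appends
    patients without changing earlier ones.
    """
    logger.info(
        "run_scenario: name=%s n=%d seed=%d", scenario.name, scenario.n_patients, seed
    )
    arrays = _simulate_cohort(scenario, np.random.SeedSequence(seed))
    outcomes = _outcomes_from_arrays(arrays, scenario)
    summary = summarize_cohort(outcomes, scenario.horizon_cycles)
    return summary, outcomes
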