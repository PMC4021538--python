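"""Latent disease-progression timelines for recurrent colorectal cancer.

Each simulated patient who will recur is assigned, at time of curative
resection, a continuous-time timeline of three clinically meaningful
milestones:

``D``
    earliest time at which the recurrence is detectable by surveillance
    testing, drawn from an exponential distribution with per-cycle hazard
    ``r_d`` (so recurrence incidence declines with time since surgery);
``U``
    time at which the recurrence is no longer amenable to curative salvage
    surgery, ``U = D + x_du * (1 + r_u * D)``;
``S``
    time of symptom onset, ``S = D + x_ds * (1 + r_s * D) + eps`` with
    ``eps ~ Normal(0, sigma_ds)``, which can pull symptoms before or after
    the point of unresectability.

All internal times are measured in continuous 3-month cycles (1 cycle =
13 weeks, 1 year = 4 cycles); the window parameters ``x_du``, ``x_ds`` and
``sigma_ds`` are specified in weeks, as they are usually reported, and
converted on use.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Canonical time conversions: the Markov surveillance loop steps in 3-month
# cycles, so everything is expressed in (fractional) cycles internally.
WEEKS_PER_CYCLE = 13.0
CYCLES_PER_YEAR = 4.0
MONTHS_PER_CYCLE = 3.0

DEFAULT_HORIZON_CYCLES = 20  # five years of quarterly cycles


def weeks_to_cycles(weeks: float) -> float:
    return weeks / WEEKS_PER_CYCLE


def months_to_cycles(months: float) -> float:
    return months / MONTHS_PER_CYCLE


def years_to_cycles(years: float) -> float:
    return years * CYCLES_PER_YEAR


class ConfigurationError(ValueError):
    """Raised when a scenario or parameter set violates its invariants."""


class LocalStatus(str, enum.Enum):
    NONE = "none"
    LOCOREGIONAL = "locoregional"
    ANASTOMOTIC_ONLY = "anastomotic_only"
    INTRALUMINAL_METACHRONOUS = "intraluminal_metachronous"


class MetStatus(str, enum.Enum):
    NONE = "none"
    LIVER = "liver"
    LUNG = "lung"
    MULTIPLE_OTHER = "multiple_other"


@dataclass(frozen=True)
class RecurrenceSite:
    """Anatomic description of a recurrence: local tumor status + metastasis status."""

    local_status: LocalStatus = LocalStatus.NONE
    met_status: MetStatus = MetStatus.NONE

    def __post_init__(self) -> None:
        if self.local_status is LocalStatus.NONE and self.met_status is MetStatus.NONE:
            raise ConfigurationError(
                "a recurrence site must have a local and/or metastatic component"
            )

    @property
    def components(self) -> frozenset[str]:
        """Site components (enum values) usable for test-target matching."""
        out = set()
        if self.local_status is not LocalStatus.NONE:
            out.add(self.local_status.value)
        if self.met_status is not MetStatus.NONE:
            out.add(self.met_status.value)
        return frozenset(out)


@dataclass(frozen=True)
class DiseaseProgressionParams:
    """The seven calibrated natural-history / background-mortality parameters.

    Parameters
    ----------
    r_d : float
        Per-cycle hazard at which recurrences become detectable.
    x_du : float
        Baseline (D = 0) window between detectability and unresectability, weeks.
    r_u : float
        Per-cycle rate of growth of the resectability window with D.
    x_ds : float
        Baseline (D = 0) presymptomatic window, weeks.
    r_s : float
        Per-cycle rate of growth of the presymptomatic window with D
        (may be slightly negative).
    sigma_ds : float
        Standard deviation of the normal error on symptom onset, weeks.
    m : float
        Five-year cumulative probability of death from non-CRC causes.
    """

    r_d: float
    x_du: float
    r_u: float
    x_ds: float
    r_s: float
    sigma_ds: float
    m: float

    def __post_init__(self) -> None:
        if not self.r_d > 0:
            raise ConfigurationError(f"r_d must be > 0, got {self.r_d}")
        if not self.x_du > 0:
            raise ConfigurationError(f"x_du must be > 0, got {self.x_du}")
        if not self.x_ds > 0:
            raise ConfigurationError(f"x_ds must be > 0, got {self.x_ds}")
        if self.sigma_ds < 0:
            raise ConfigurationError(f"sigma_ds must be >= 0, got {self.sigma_ds}")
        if self.r_u < 0:
            raise ConfigurationError(f"r_u must be >= 0, got {self.r_u}")
        if not (0 <= self.m < 1):
            raise ConfigurationError(f"m must lie in [0, 1), got {self.m}")

    PARAM_NAMES = ("r_d", "x_du", "r_u", "x_ds", "r_s", "sigma_ds", "m")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.PARAM_NAMES}

    def replace(self, **kwargs: float) -> "DiseaseProgressionParams":
        d = self.as_dict()
        d.update(kwargs)
        return DiseaseProgressionParams(**d)


@dataclass(frozen=True)
class RecurrenceProfile:
    """One patient's latent recurrence timeline (times in cycles)."""

    will_recur: bool
    site: Optional[RecurrenceSite] = None
    D: Optional[float] = None
    U: Optional[float] = None
    S: Optional[float] = None
    eps_ds: Optional[float] = None
    clipped: bool = False  # True when the symptom-onset error pushed S below D

    def __post_init__(self) -> None:
        if self.will_recur:
            if self.site is None or self.D is None or self.U is None or self.S is None:
                raise ConfigurationError("recurring patient requires site and D/U/S")
            if not (self.D < self.U):
                raise ConfigurationError("D < U must hold")
            if self.S < self.D:
                raise ConfigurationError("S >= D must hold (after clipping)")
            if self.D <= 0:
                raise ConfigurationError("times must be positive")


@dataclass(frozen=True)
class LifeExpectancies:
    """Assigned life expectancies by state at diagnosis (input units as named)."""

    no_recurrence_years: float = 20.7
    post_salvage_months: float = 21.0
    post_unresectable_months: float = 8.0

    @property
    def post_salvage_cycles(self) -> float:
        return months_to_cycles(self.post_salvage_months)

    @property
    def post_unresectable_cycles(self) -> float:
        return months_to_cycles(self.post_unresectable_months)


@dataclass
class CohortScenario:
    """Everything needed to simulate one cohort under one surveillance strategy."""

    n_patients: int
    p_recur: float
    site_distribution: Mapping[RecurrenceSite, float]
    progression: DiseaseProgressionParams
    tests: Sequence["TestCharacteristics"] = field(default_factory=list)
    schedule: Optional["SurveillanceSchedule"] = None
    life_expectancies: LifeExpectancies = field(default_factory=LifeExpectancies)
    horizon_cycles: int = DEFAULT_HORIZON_CYCLES
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not (0.0 <= self.p_recur <= 1.0):
            raise ConfigurationError(f"p_recur must lie in [0, 1], got {self.p_recur}")
        if self.horizon_cycles < 1:
            raise ConfigurationError("horizon_cycles must be >= 1")
        total = float(sum(self.site_distribution.values()))
        if self.site_distribution and abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"site_distribution must sum to 1 (got {total:.6g})"
            )
        if self.p_recur > 0 and not self.site_distribution:
            raise ConfigurationError("site_distribution required when p_recur > 0")

    def sites_and_probs(self) -> tuple[list[RecurrenceSite], np.ndarray]:
        sites = list(self.site_distribution.keys())
        probs = np.asarray([self.site_distribution[s] for s in sites], dtype=float)
        return sites, probs


# ---------------------------------------------------------------------------
# Milestone formulas
# ---------------------------------------------------------------------------

def sample_detectability_time(r_d: float, rng: np.random.Generator) -> float:
    """Draw the earliest-detectability time D (cycles) ~ Exponential(r_d)."""
    if r_d <= 0:
        raise ConfigurationError(f"r_d must be > 0, got {r_d}")
    return float(rng.exponential(scale=1.0 / r_d))


def unresectability_time(D: float, params: DiseaseProgressionParams) -> float:
    """U = D + x_du * (1 + r_u * D), with the baseline window converted to cycles."""
    if D < 0:
        raise ConfigurationError("D must be >= 0")
    x_du_cycles = weeks_to_cycles(params.x_du)
    return D + x_du_cycles * (1.0 + params.r_u * D)


def symptom_onset_time(
    D: float, params: DiseaseProgressionParams, rng: np.random.Generator
) -> tuple[float, float]:
    """S = D + x_ds * (1 + r_s * D) + eps, eps ~ N(0, sigma_ds), clipped so S >= D.

    Returns ``(S, eps)`` with the *unclipped* error draw, so callers can log
    how often clipping fired.
    """
    if D < 0:
        raise ConfigurationError("D must be >= 0")
    x_ds_cycles = weeks_to_cycles(params.x_ds)
    sigma_cycles = weeks_to_cycles(params.sigma_ds)
    eps = float(rng.normal(0.0, sigma_cycles)) if sigma_cycles > 0 else 0.0
    S = D + x_ds_cycles * (1.0 + params.r_s * D) + eps
    return max(S, D), eps


# Operability by metastasis status.  Multiple/other-organ metastases are never
# operable; lung metastases are half as likely as liver metastases to be
# operable; liver metastases and local-only recurrences are operable whenever
# diagnosis precedes U.
LUNG_OPERABLE_FACTOR = 0.5


def salvage_eligible(
    site: RecurrenceSite, t_dx: float, U: float, rng: np.random.Generator
) -> bool:
    """Is a recurrence diagnosed at ``t_dx`` still curable by salvage surgery?"""
    if t_dx < 0:
        raise ConfigurationError("t_dx must be >= 0")
    if t_dx >= U:
        return False
    if site.met_status is MetStatus.MULTIPLE_OTHER:
        return False
    if site.met_status is MetStatus.LUNG:
        return bool(rng.uniform() < LUNG_OPERABLE_FACTOR)
    # liver metastases or local-only disease
    return True


def assign_recurrence(
    scenario: CohortScenario, rng: np.random.Generator
) -> RecurrenceProfile:
    """Draw one patient's latent recurrence profile.

    Draw order (uniform recurrence flag, uniform site, exponential D, normal
    eps) is part of the reproducibility contract.
    """
    u = rng.uniform()
    if u >= scenario.p_recur:
        return RecurrenceProfile(will_recur=False)
    sites, probs = scenario.sites_and_probs()
    idx = int(np.searchsorted(np.cumsum(probs), rng.uniform(), side="right"))
    idx = min(idx, len(sites) - 1)
    site = sites[idx]
    params = scenario.progression
    D = sample_detectability_time(params.r_d, rng)
    U = unresectability_time(D, params)
    S, eps = symptom_onset_time(D, params, rng)
    clipped = S == D and eps < 0
    if clipped:
        logger.debug("symptom-onset clipped to D=%.4f (eps=%.4f)", D, eps)
    return RecurrenceProfile(
        will_recur=True, site=site, D=D, U=U, S=S, eps_ds=eps, clipped=clipped
    )


# ---------------------------------------------------------------------------
# Vectorized cohort profile generation (used by the simulator engine)
# ---------------------------------------------------------------------------

@dataclass
class CohortProfiles:
    """Structure-of-arrays form of per-patient latent timelines."""

    will_recur: np.ndarray  # bool (n,)
    site_index: np.ndarray  # int (n,), -1 for non-recurrers
    sites: list  # list[RecurrenceSite], index space for site_index
    D: np.ndarray  # float (n,), nan for non-recurrers
    U: np.ndarray
    S: np.ndarray
    eps_ds: np.ndarray

    def __len__(self) -> int:
        return len(self.will_recur)

    def profile(self, i: int) -> RecurrenceProfile:
        if not self.will_recur[i]:
            return RecurrenceProfile(will_recur=False)
        return RecurrenceProfile(
            will_recur=True,
            site=self.sites[self.site_index[i]],
            D=float(self.D[i]),
            U=float(self.U[i]),
            S=float(self.S[i]),
            eps_ds=float(self.eps_ds[i]),
            clipped=bool(self.S[i] == self.D[i] and self.eps_ds[i] < 0),
        )


def generate_cohort_profiles(
    scenario: CohortScenario, seed_sequence: np.random.SeedSequence
) -> CohortProfiles:
    """Generate all patients' latent timelines from dedicated random streams.

    Each latent variable draws from its own child stream of ``seed_sequence``
    and patient *i* always reads the *i*-th element, so enlarging the cohort
    appends patients without reshuffling existing ones.
    """
    n = scenario.n_patients
    params = scenario.progression
    ss_recur, ss_site, ss_d, ss_eps = seed_sequence.spawn(4)
    u_recur = np.random.default_rng(ss_recur).uniform(size=n)
    u_site = np.random.default_rng(ss_site).uniform(size=n)
    D_all = np.random.default_rng(ss_d).exponential(scale=1.0 / params.r_d, size=n)
    sigma_cycles = weeks_to_cycles(params.sigma_ds)
    eps_all = np.random.default_rng(ss_eps).normal(0.0, 1.0, size=n) * sigma_cycles

    will_recur = u_recur < scenario.p_recur
    if scenario.site_distribution:
        sites, probs = scenario.sites_and_probs()
        site_index = np.searchsorted(np.cumsum(probs), u_site, side="right")
        site_index = np.minimum(site_index, len(sites) - 1).astype(np.int64)
    else:
        sites, site_index = [], np.zeros(n, dtype=np.int64)
    site_index = np.where(will_recur, site_index, -1)

    D = np.where(will_recur, D_all, np.nan)
    x_du_c = weeks_to_cycles(params.x_du)
    x_ds_c = weeks_to_cycles(params.x_ds)
    U = D + x_du_c * (1.0 + params.r_u * D)
    S_raw = D + x_ds_c * (1.0 + params.r_s * D) + np.where(will_recur, eps_all, np.nan)
    S = np.fmax(S_raw, D)
    return CohortProfiles(
        will_recur=will_recur,
        site_index=site_index,
        sites=sites,
        D=D,
        U=U,
        S=S,
        eps_ds=np.where(will_recur, eps_all, np.nan),
    )
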