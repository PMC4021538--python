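"""Surveillance schedules, test characteristics and per-cycle test resolution.

A surveillance strategy is a binary matrix with one row per 3-month cycle and
one column per testing modality.  At each scheduled visit every indicated test
is administered independently; a test returns positive with probability equal
to its sensitivity when the patient harbours a recurrence that is both
detectable (current time >= D) and within the modality's anatomic reach, and
with probability 1 - specificity otherwise (the false-positive channel).  Any
positive result triggers a single full diagnostic workup within the cycle,
modelled with combined sensitivity and specificity of 100%: the workup records
a diagnosis if and only if the patient actually has a detectable recurrence
anywhere, so a false positive on one modality can still surface a true
recurrence at another site, while patients without detectable disease are
always correctly ruled out.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .progression import (
    ConfigurationError,
    LocalStatus,
    MetStatus,
    MONTHS_PER_CYCLE,
    RecurrenceProfile,
)


class Modality(str, enum.Enum):
    CEA = "cea"
    CHEST_XRAY = "chest_xray"
    CT_HEPATIC = "ct_hepatic"
    CT_OTHER_ABDOMINAL = "ct_other_abdominal"
    HEPATIC_ULTRASOUND = "hepatic_ultrasound"
    COLONOSCOPY = "colonoscopy"
    CLINICAL_EXAM = "clinical_exam"


_ANY_SITE = frozenset(
    {
        LocalStatus.LOCOREGIONAL.value,
        LocalStatus.ANASTOMOTIC_ONLY.value,
        LocalStatus.INTRALUMINAL_METACHRONOUS.value,
        MetStatus.LIVER.value,
        MetStatus.LUNG.value,
        MetStatus.MULTIPLE_OTHER.value,
    }
)

# Which recurrence-site components each modality can truly detect.  CEA and
# the clinical interview/exam are site-agnostic; imaging is anatomically
# targeted (a scheduled abdominal/pelvic CT is modelled as its hepatic and
# other-abdominal components administered at the same visit).
DEFAULT_DETECTABLE_TARGETS: dict[Modality, frozenset[str]] = {
    Modality.CEA: _ANY_SITE,
    Modality.CLINICAL_EXAM: _ANY_SITE,
    Modality.CHEST_XRAY: frozenset({MetStatus.LUNG.value}),
    Modality.CT_HEPATIC: frozenset({MetStatus.LIVER.value}),
    Modality.CT_OTHER_ABDOMINAL: frozenset(
        {LocalStatus.LOCOREGIONAL.value, MetStatus.MULTIPLE_OTHER.value}
    ),
    Modality.HEPATIC_ULTRASOUND: frozenset({MetStatus.LIVER.value}),
    Modality.COLONOSCOPY: frozenset(
        {
            LocalStatus.ANASTOMOTIC_ONLY.value,
            LocalStatus.INTRALUMINAL_METACHRONOUS.value,
        }
    ),
}


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity/specificity of one surveillance modality."""

    modality: Modality
    sensitivity: float
    specificity: float
    detectable_targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ConfigurationError("sensitivity must lie in [0, 1]")
        if not (0.0 <= self.specificity <= 1.0):
            raise ConfigurationError("specificity must lie in [0, 1]")
        if not self.detectable_targets:
            object.__setattr__(
                self,
                "detectable_targets",
                DEFAULT_DETECTABLE_TARGETS[self.modality],
            )

    def can_detect(self, profile: RecurrenceProfile) -> bool:
        if not profile.will_recur or profile.site is None:
            return False
        return bool(profile.site.components & self.detectable_targets)

    def replace(self, **kwargs) -> "TestCharacteristics":
        d = {
            "modality": self.modality,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "detectable_targets": self.detectable_targets,
        }
        d.update(kwargs)
        return TestCharacteristics(**d)


@dataclass
class SurveillanceSchedule:
    """Binary cycle x modality matrix; entry 1 means the test is given that cycle.

    Row ``c`` (0-based index ``c - 1``) corresponds to the visit at the end of
    month ``3 * c`` since surgery, for cycles 1..horizon.
    """

    modalities: tuple[Modality, ...]
    matrix: np.ndarray  # (horizon, n_modalities) of {0, 1}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.modalities):
            raise ConfigurationError("schedule matrix shape mismatch")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ConfigurationError("schedule entries must be 0 or 1")

    @property
    def horizon_cycles(self) -> int:
        return self.matrix.shape[0]

    def scheduled(self, cycle: int) -> list[Modality]:
        """Modalities administered at the given 1-based cycle."""
        if not (1 <= cycle <= self.horizon_cycles):
            return []
        row = self.matrix[cycle - 1]
        return [m for m, flag in zip(self.modalities, row) if flag]

    def column(self, modality: Modality) -> np.ndarray:
        return self.matrix[:, self.modalities.index(modality)]

    def is_superset_of(self, other: "SurveillanceSchedule") -> bool:
        """True when this schedule tests a superset of `other` in every cycle."""
        if self.modalities != other.modalities:
            raise ConfigurationError("schedules must share a modality axis")
        return bool((self.matrix >= other.matrix).all())

    # -- CSV round-trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[m.value for m in self.modalities])
        df.insert(0, "cycle", np.arange(1, self.horizon_cycles + 1))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveillanceSchedule":
        cols = [c for c in df.columns if c != "cycle"]
        modalities = tuple(Modality(c) for c in cols)
        return cls(modalities=modalities, matrix=df[cols].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "SurveillanceSchedule":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class ScheduleSegment:
    """Visits every `interval_months` within (start_month, end_month]."""

    interval_months: float
    start_month: float
    end_month: float


@dataclass(frozen=True)
class Diagnosis:
    time: float  # cycles
    mode: str  # "surveillance" | "symptomatic"


@dataclass
class CycleResult:
    tests_administered: list[Modality]
    any_positive: bool
    diagnosis: Optional[Diagnosis] = None

    def __post_init__(self) -> None:
        if self.diagnosis is not None and self.diagnosis.mode == "surveillance":
            assert self.any_positive, "surveillance diagnosis requires a positive test"


def build_schedule(
    pattern: Mapping[Modality, Sequence[ScheduleSegment | tuple]],
    horizon_cycles: int = 20,
    modalities: Optional[Sequence[Modality]] = None,
) -> SurveillanceSchedule:
    """Expand per-modality visit rules into an exact binary schedule matrix.

    Each rule segment ``(interval_months, start_month, end_month)`` places
    visits at months ``start + k * interval`` for ``k >= 1`` up to and
    including ``end_month`` (months are anchored to surgery; there is no
    cycle-0 visit).  Intervals must be multiples of 3 months, the cycle
    granularity.
    """
    if modalities is None:
        modalities = sorted(pattern.keys(), key=lambda m: m.value)
    matrix = np.zeros((horizon_cycles, len(modalities)), dtype=np.int8)
    for j, modality in enumerate(modalities):
        for seg in pattern.get(modality, ()):
            if not isinstance(seg, ScheduleSegment):
                seg = ScheduleSegment(*seg)
            if seg.interval_months <= 0 or seg.interval_months % MONTHS_PER_CYCLE != 0:
                raise ConfigurationError(
                    f"visit interval must be a positive multiple of 3 months, "
                    f"got {seg.interval_months} for {modality.value}"
                )
            month = seg.start_month + seg.interval_months
            while month <= seg.end_month + 1e-9:
                cycle = int(round(month / MONTHS_PER_CYCLE))
                if 1 <= cycle <= horizon_cycles:
                    matrix[cycle - 1, j] = 1
                month += seg.interval_months
    return SurveillanceSchedule(modalities=tuple(modalities), matrix=matrix)


def administer_test(
    test: TestCharacteristics,
    profile: RecurrenceProfile,
    t: float,
    rng: np.random.Generator,
) -> bool:
    """Resolve one test at time ``t`` (cycles): True = positive result."""
    detectable = profile.will_recur and profile.D is not None and t >= profile.D
    if detectable and test.can_detect(profile):
        return bool(rng.uniform() < test.sensitivity)
    return bool(rng.uniform() < 1.0 - test.specificity)


def run_surveillance_cycle(
    profile: RecurrenceProfile,
    cycle: int,
    schedule: SurveillanceSchedule,
    tests: Sequence[TestCharacteristics],
    rng: np.random.Generator,
) -> CycleResult:
    """Administer the cycle's scheduled tests and resolve any positive workup.

    Diagnosis is recorded at the cycle boundary (time = ``cycle``) if and only
    if some test fired and the patient has a detectable recurrence; a false
    positive in a disease-free (or not-yet-detectable) patient is worked up
    and correctly ruled out, with no lasting effect.
    """
    by_modality = {t.modality: t for t in tests}
    scheduled = [m for m in schedule.scheduled(cycle) if m in by_modality]
    t_boundary = float(cycle)
    any_positive = False
    for modality in scheduled:
        positive = administer_test(by_modality[modality], profile, t_boundary, rng)
        any_positive = any_positive or positive
    diagnosis = None
    if any_positive:
        truly_detectable = (
            profile.will_recur and profile.D is not None and t_boundary >= profile.D
        )
        if truly_detectable:
            diagnosis = Diagnosis(time=t_boundary, mode="surveillance")
    return CycleResult(
        tests_administered=scheduled, any_positive=any_positive, diagnosis=diagnosis
    )
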