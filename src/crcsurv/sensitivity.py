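"""One-way deterministic sensitivity analysis with common random numbers.

Each non-calibrated parameter (a test's sensitivity or specificity, or a
life expectancy) is swept to the low and high end of its plausible range
while everything else, including the random seed, is held fixed; outcome
differences therefore reflect the parameter change alone.  Reported changes
are relative (percent of the baseline value), e.g. +7.9 means the outcome
rose to 1.079x its base-case value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .progression import CohortScenario, ConfigurationError, LifeExpectancies
from .simulator import OutcomeSummary, run_scenario_summary
from .surveillance import Modality

logger = logging.getLogger(__name__)

DEFAULT_OUTCOMES = ("salvage", "os5")


def _get_outcome(summary: OutcomeSummary, name: str) -> float:
    return summary.as_percent_targets()[name]


def resolve_parameter(scenario: CohortScenario, path: str) -> float:
    """Read a scalar scenario parameter addressed by a dotted path.

    Supported paths: ``tests.<modality>.sensitivity`` /
    ``tests.<modality>.specificity`` and
    ``life_expectancies.<field>`` (e.g. ``post_salvage_months``).
    """
    parts = path.split(".")
    try:
        if parts[0] == "tests" and len(parts) == 3:
            modality = Modality(parts[1])
            for test in scenario.tests:
                if test.modality is modality:
                    return float(getattr(test, parts[2]))
            raise KeyError(parts[1])
        if parts[0] == "life_expectancies" and len(parts) == 2:
            return float(getattr(scenario.life_expectancies, parts[1]))
    except (ValueError, AttributeError, KeyError) as exc:
        raise ConfigurationError(f"cannot resolve parameter path {path!r}") from exc
    raise ConfigurationError(f"cannot resolve parameter path {path!r}")


def set_parameter(scenario: CohortScenario, path: str, value: float) -> CohortScenario:
    """Return a copy of the scenario with the addressed parameter replaced."""
    resolve_parameter(scenario, path)  # validates the path
    parts = path.split(".")
    if parts[0] == "tests":
        modality = Modality(parts[1])
        tests = [
            t.replace(**{parts[2]: value}) if t.modality is modality else t
            for t in scenario.tests
        ]
        return replace(scenario, tests=tests)
    le = scenario.life_expectancies
    fields = {
        "no_recurrence_years": le.no_recurrence_years,
        "post_salvage_months": le.post_salvage_months,
        "post_unresectable_months": le.post_unresectable_months,
    }
    fields[parts[1]] = value
    return replace(scenario, life_expectancies=LifeExpectancies(**fields))


@dataclass(frozen=True)
class SweepSpec:
    parameter: str  # dotted path into the scenario
    low: float
    high: float
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ConfigurationError("sweep requires low <= high")


@dataclass
class SweepResult:
    spec: SweepSpec
    baseline_value: float
    baseline: dict[str, float]
    at_low: dict[str, float]
    at_high: dict[str, float]
    relative_change_low: dict[str, float]  # percent of baseline
    relative_change_high: dict[str, float]

    def max_abs_relative_change(self, outcome: Optional[str] = None) -> float:
        outcome = outcome or self.spec.outcomes[0]
        return max(
            abs(self.relative_change_low[outcome]),
            abs(self.relative_change_high[outcome]),
        )


def one_way_sweep(spec: SweepSpec, scenario: CohortScenario) -> SweepResult:
    """Run baseline / low / high with one shared seed and compare outcomes."""
    baseline_value = resolve_parameter(scenario, spec.parameter)
    if not (spec.low <= baseline_value <= spec.high):
        raise ConfigurationError(
            f"baseline value {baseline_value} of {spec.parameter!r} lies outside "
            f"the sweep range [{spec.low}, {spec.high}]"
        )
    summaries = {}
    for label, value in (
        ("baseline", baseline_value),
        ("low", spec.low),
        ("high", spec.high),
    ):
        varied = set_parameter(scenario, spec.parameter, value)
        summaries[label] = run_scenario_summary(varied, spec.seed)

    def grab(label: str) -> dict[str, float]:
        return {o: _get_outcome(summaries[label], o) for o in spec.outcomes}

    base = grab("baseline")

    def rel(values: dict[str, float]) -> dict[str, float]:
        return {
            o: (100.0 * (values[o] - base[o]) / base[o]) if base[o] != 0 else 0.0
            for o in spec.outcomes
        }

    low, high = grab("low"), grab("high")
    return SweepResult(
        spec=spec,
        baseline_value=baseline_value,
        baseline=base,
        at_low=low,
        at_high=high,
        relative_change_low=rel(low),
        relative_change_high=rel(high),
    )


def sweep_all(
    table: Sequence[SweepSpec], scenario: CohortScenario
) -> tuple[list[SweepResult], pd.DataFrame]:
    """Sweep every parameter and rank by impact on the primary outcome.

    Ranking is by maximum absolute relative change of each spec's first
    outcome; equal-impact parameters keep their input order (stable sort).
    """
    if not table:
        raise ConfigurationError("sweep table must be non-empty")
    results = [one_way_sweep(spec, scenario) for spec in table]
    order = sorted(
        range(len(results)),
        key=lambda i: -results[i].max_abs_relative_change(),
    )
    ranked = [results[i] for i in order]
    rows = []
    for res in ranked:
        for outcome in res.spec.outcomes:
            rows.append(
                {
                    "parameter": res.spec.parameter,
                    "low": res.spec.low,
                    "high": res.spec.high,
                    "outcome": outcome,
                    "baseline": res.baseline[outcome],
                    "at_low": res.at_low[outcome],
                    "at_high": res.at_high[outcome],
                    "relative_change_low": res.relative_change_low[outcome],
                    "relative_change_high": res.relative_change_high[outcome],
                }
            )
    return ranked, pd.DataFrame(rows)
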