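"""Iterative grid-search calibration of the seven disease-progression parameters.

The natural-history parameters (r_d, x_du, r_u, x_ds, r_s, sigma_ds) and the
background-mortality parameter m cannot be observed directly, so they are
estimated by matching simulated cohort outcomes to seven observed targets
(DFS5, OS1..OS5, salvage proportion) from a trial arm with a known
surveillance schedule:

1. each parameter range is divided into evenly spaced values and every
   combination is simulated;
2. candidates are filtered sequentially, one target at a time in a fixed
   priority order (DFS5, OS5, OS4, OS3, salvage, OS2, OS1 by default),
   dropping sets that deviate by more than 1 percentage point (2 pp as a
   fallback when the 1-pp band empties the step);
3. ranges are narrowed around the survivors and the loop repeats until the
   round's best unweighted sum-of-squared-differences fit stops improving.

The final parameter set is the terminal survivor closest to the midpoints of
the final per-parameter ranges.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .progression import CohortScenario, ConfigurationError, DiseaseProgressionParams
from .simulator import OutcomeSummary, run_scenario_summary

logger = logging.getLogger(__name__)

PARAM_NAMES = DiseaseProgressionParams.PARAM_NAMES
TARGET_NAMES = OutcomeSummary.TARGET_NAMES
DEFAULT_PRIORITY = ("dfs5", "os5", "os4", "os3", "salvage", "os2", "os1")

TERMINATION_NO_IMPROVEMENT = "no_improvement"
TERMINATION_BUDGET = "budget"
TERMINATION_SINGLE_CANDIDATE = "single_candidate"


@dataclass
class CalibrationSpec:
    """Configuration of one calibration exercise.

    ``ranges`` maps each of the seven parameter names to an inclusive
    interval; ``targets`` holds the observed outcome values in percentage
    points (0-100 scale).
    """

    ranges: Mapping[str, tuple[float, float]]
    targets: Mapping[str, float]
    points_per_param: int | Mapping[str, int] = 3
    priority: Sequence[str] = DEFAULT_PRIORITY
    tol_primary: float = 1.0
    tol_fallback: float = 2.0
    n_patients: int = 2_000
    max_rounds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.ranges)
        if missing:
            raise ConfigurationError(f"ranges missing parameters: {sorted(missing)}")
        if sorted(self.priority) != sorted(TARGET_NAMES):
            raise ConfigurationError(
                "priority must be a permutation of the seven targets"
            )
        for name, (lo, hi) in self.ranges.items():
            if hi < lo:
                raise ConfigurationError(f"empty range for {name}: ({lo}, {hi})")

    def points_for(self, name: str) -> int:
        if isinstance(self.points_per_param, Mapping):
            return int(self.points_per_param[name])
        return int(self.points_per_param)


@dataclass
class RoundResult:
    round_index: int
    ranges: dict[str, tuple[float, float]]
    table: pd.DataFrame  # one row per candidate: params, predictions, fit, survived
    best_fit: float
    n_survivors: int
    flagged_steps: list[str] = field(default_factory=list)


@dataclass
class CalibrationResult:
    rounds: list[RoundResult]
    final_params: DiseaseProgressionParams
    final_ranges: dict[str, tuple[float, float]]
    termination_reason: str

    @property
    def best_fit_per_round(self) -> list[float]:
        return [r.best_fit for r in self.rounds]


def build_grid(
    ranges: Mapping[str, tuple[float, float]],
    points_per_param: int | Mapping[str, int],
) -> list[DiseaseProgressionParams]:
    """Cartesian product of evenly spaced values over each parameter range.

    A width-zero range contributes a single value.  Values are generated with
    endpoints included.
    """
    axes: list[np.ndarray] = []
    for name in PARAM_NAMES:
        lo, hi = ranges[name]
        k = (
            points_per_param.get(name, 3)
            if isinstance(points_per_param, Mapping)
            else points_per_param
        )
        if k < 2 and lo != hi:
            raise ConfigurationError("points_per_param must be >= 2")
        axes.append(np.array([lo]) if lo == hi else np.linspace(lo, hi, k))
    return [
        DiseaseProgressionParams(**dict(zip(PARAM_NAMES, combo)))
        for combo in itertools.product(*axes)
    ]


def grid_steps(
    ranges: Mapping[str, tuple[float, float]],
    points_per_param: int | Mapping[str, int],
) -> dict[str, float]:
    steps = {}
    for name in PARAM_NAMES:
        lo, hi = ranges[name]
        k = (
            points_per_param.get(name, 3)
            if isinstance(points_per_param, Mapping)
            else points_per_param
        )
        steps[name] = 0.0 if hi == lo else (hi - lo) / (k - 1)
    return steps


def goodness_of_fit(
    predicted: Mapping[str, float], observed: Mapping[str, float]
) -> float:
    """Unweighted sum of squared differences over the seven targets (pp scale)."""
    if set(predicted) < set(TARGET_NAMES) or set(observed) < set(TARGET_NAMES):
        raise ConfigurationError("predicted and observed must cover all seven targets")
    return float(
        sum((predicted[t] - observed[t]) ** 2 for t in TARGET_NAMES)
    )


def sequential_filter(
    candidates: Sequence[tuple[DiseaseProgressionParams, Mapping[str, float]]],
    observed: Mapping[str, float],
    spec: CalibrationSpec,
) -> tuple[list[tuple[DiseaseProgressionParams, Mapping[str, float]]], list[str]]:
    """Filter candidates target-by-target in priority order.

    At each step candidates deviating by more than ``tol_primary`` percentage
    points are dropped; if the step would eliminate everyone, it is retried at
    ``tol_fallback``, and if even that eliminates everyone the step passes all
    candidates through unchanged and is flagged.
    Returns (survivors, flagged_steps).
    """
    survivors = list(candidates)
    flagged: list[str] = []
    for target in spec.priority:
        obs = observed[target]
        primary = [
            c for c in survivors if abs(c[1][target] - obs) <= spec.tol_primary
        ]
        if primary:
            survivors = primary
            continue
        fallback = [
            c for c in survivors if abs(c[1][target] - obs) <= spec.tol_fallback
        ]
        if fallback:
            survivors = fallback
        else:
            flagged.append(target)
            logger.warning(
                "calibration step %r eliminated all candidates even at the "
                "fallback tolerance; passing all through",
                target,
            )
    return survivors, flagged


def narrow_ranges(
    survivors: Sequence[DiseaseProgressionParams],
    previous_ranges: Mapping[str, tuple[float, float]],
    previous_steps: Mapping[str, float],
    original_ranges: Mapping[str, tuple[float, float]],
) -> dict[str, tuple[float, float]]:
    """New per-parameter range = survivor [min, max] padded by one previous
    grid step each side, clipped to the original starting range."""
    if not survivors:
        raise ConfigurationError("narrow_ranges requires at least one survivor")
    out = {}
    for name in PARAM_NAMES:
        values = [getattr(p, name) for p in survivors]
        step = previous_steps[name]
        lo = min(values) - step
        hi = max(values) + step
        o_lo, o_hi = original_ranges[name]
        out[name] = (max(lo, o_lo), min(hi, o_hi))
    return out


def _sub_seed(master: int, round_index: int, set_index: int) -> int:
    ss = np.random.SeedSequence(entropy=(int(master), int(round_index), int(set_index)))
    return int(ss.generate_state(1)[0] % (2**31))


def evaluate_grid(
    grid: Sequence[DiseaseProgressionParams],
    scenario_template: CohortScenario,
    n_patients: int,
    master_seed: int,
    round_index: int = 0,
) -> list[tuple[DiseaseProgressionParams, dict[str, float]]]:
    """Simulate every candidate parameter set and collect predicted targets.

    Each candidate runs with a sub-seed derived from (master seed, round,
    candidate index) so the exercise is reproducible end to end.
    """
    results = []
    for idx, params in enumerate(grid):
        scenario = replace(
            scenario_template, progression=params, n_patients=n_patients
        )
        summary = run_scenario_summary(scenario, _sub_seed(master_seed, round_index, idx))
        results.append((params, summary.as_percent_targets()))
    return results


def _round_table(
    evaluated: Sequence[tuple[DiseaseProgressionParams, Mapping[str, float]]],
    survivors: Sequence[tuple[DiseaseProgressionParams, Mapping[str, float]]],
    observed: Mapping[str, float],
) -> pd.DataFrame:
    surviving_params = {tuple(p.as_dict().values()) for p, _ in survivors}
    rows = []
    for params, predicted in evaluated:
        row = params.as_dict()
        row.update({f"pred_{t}": predicted[t] for t in TARGET_NAMES})
        row["fit"] = goodness_of_fit(predicted, observed)
        row["survived"] = tuple(params.as_dict().values()) in surviving_params
        rows.append(row)
    return pd.DataFrame(rows)


def _closest_to_midpoints(
    survivors: Sequence[tuple[DiseaseProgressionParams, Mapping[str, float]]],
    final_ranges: Mapping[str, tuple[float, float]],
) -> DiseaseProgressionParams:
    """Pick the survivor closest to the per-parameter midpoints of the final
    ranges (normalized by range width; ties resolved parameter-by-parameter,
    then by goodness-of-fit row order)."""

    def key(item):
        params, _ = item
        dists = []
        total = 0.0
        for name in PARAM_NAMES:
            lo, hi = final_ranges[name]
            width = hi - lo
            mid = 0.5 * (lo + hi)
            d = abs(getattr(params, name) - mid) / width if width > 0 else 0.0
            dists.append(d)
            total += d
        return (total, tuple(dists))

    return min(survivors, key=key)[0]


def calibrate(
    spec: CalibrationSpec, scenario_template: CohortScenario
) -> CalibrationResult:
    """Run rounds of grid search / filter / narrow until fit stops improving.

    Termination: the first round whose minimum goodness-of-fit fails to
    improve on the previous round's ends the search, and the previous round's
    survivors define the final ranges; hitting ``max_rounds`` returns the
    best so far with ``termination_reason = "budget"``.
    """
    original_ranges = {k: tuple(v) for k, v in spec.ranges.items()}
    current_ranges = dict(original_ranges)
    rounds: list[RoundResult] = []
    best_prev_fit = np.inf
    prev_survivors: Optional[list] = None
    prev_ranges = current_ranges
    termination = TERMINATION_BUDGET

    for round_index in range(spec.max_rounds):
        grid = build_grid(current_ranges, spec.points_per_param)
        steps = grid_steps(current_ranges, spec.points_per_param)
        evaluated = evaluate_grid(
            grid, scenario_template, spec.n_patients, spec.seed, round_index
        )
        survivors, flagged = sequential_filter(evaluated, spec.targets, spec)
        if not survivors:
            survivors = list(evaluated)
        best_fit = min(goodness_of_fit(pred, spec.targets) for _, pred in survivors)
        rounds.append(
            RoundResult(
                round_index=round_index,
                ranges=dict(current_ranges),
                table=_round_table(evaluated, survivors, spec.targets),
                best_fit=best_fit,
                n_survivors=len(survivors),
                flagged_steps=flagged,
            )
        )
        logger.info(
            "calibration round %d: %d candidates, %d survivors, best fit %.3f",
            round_index,
            len(grid),
            len(survivors),
            best_fit,
        )
        if best_fit >= best_prev_fit:
            termination = TERMINATION_NO_IMPROVEMENT
            break
        best_prev_fit = best_fit
        prev_survivors = survivors
        prev_ranges = dict(current_ranges)
        if len(grid) == 1:
            termination = TERMINATION_SINGLE_CANDIDATE
            break
        current_ranges = narrow_ranges(
            [p for p, _ in survivors], current_ranges, steps, original_ranges
        )

    if prev_survivors is None:
        # first round failed to improve on "infinity" cannot happen, but a
        # single-round budget lands here: use the only round's survivors
        prev_survivors = survivors
        prev_ranges = rounds[-1].ranges

    final_steps = grid_steps(prev_ranges, spec.points_per_param)
    final_ranges = narrow_ranges(
        [p for p, _ in prev_survivors], prev_ranges, final_steps, original_ranges
    )
    final_params = _closest_to_midpoints(prev_survivors, final_ranges)
    return CalibrationResult(
        rounds=rounds,
        final_params=final_params,
        final_ranges=final_ranges,
        termination_reason=termination,
    )
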