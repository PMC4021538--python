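"""Markov cycle loop: event ordering, mortality, oracles, cohort summaries."""

import math

import numpy as np
import pytest

from crcsurv import (
    ConfigurationError,
    Modality,
    PatientOutcome,
    RecurrenceProfile,
    RecurrenceSite,
    per_cycle_mortality,
    run_scenario,
    run_scenario_summary,
    simulate_patient,
    summarize_cohort,
)
from crcsurv.progression import LocalStatus, MetStatus, generate_cohort_profiles
from crcsurv.scenarios import generate_synthetic_scenario, SyntheticScenarioSpec
from crcsurv.simulator import (
    MODE_SURVEILLANCE,
    MODE_SYMPTOMATIC,
    STATE_DEAD_CANCER,
    STATE_DEAD_OTHER,
    _simulate_cohort,
)
from conftest import every_cycle_schedule, make_scenario, perfect_test

LOCAL = RecurrenceSite(local_status=LocalStatus.LOCOREGIONAL)
LIVER = RecurrenceSite(met_status=MetStatus.LIVER)


def profile(site=LIVER, D=2.5, U=40.0, S=3.1):
    return RecurrenceProfile(will_recur=True, site=site, D=D, U=U, S=S, eps_ds=0.0)


class TestPerCycleMortality:
    def test_zero(self):
        assert per_cycle_mortality(0.0) == 0.0

    def test_intensive_arm_value(self):
        assert per_cycle_mortality(0.016) == pytest.approx(8.063e-4, rel=1e-3)

    def test_validation_arm_value(self):
        assert per_cycle_mortality(0.156) == pytest.approx(8.44e-3, rel=1e-2)

    def test_compounds_back_to_cumulative(self):
        p = per_cycle_mortality(0.37)
        assert 1 - (1 - p) ** 20 == pytest.approx(0.37)

    def test_invalid(self):
        with pytest.raises(ConfigurationError):
            per_cycle_mortality(1.0)


class TestSimulatePatient:
    def test_non_recurrer_stays_disease_free(self, rng, calibrated_params):
        scenario = make_scenario(progression=calibrated_params.replace(m=0.0))
        out = simulate_patient(RecurrenceProfile(will_recur=False), scenario, rng)
        assert not out.diagnosed and out.death_time is None
        assert all(s == "no_known_recurrence" for s in out.state_path)

    def test_symptomatic_salvage_then_cancer_death(self, rng, calibrated_params):
        # liver recurrence declares itself at S=3.1 (< U), is salvaged, and
        # cancer death follows 21 months (7 cycles) later at t = 10.1
        scenario = make_scenario(progression=calibrated_params.replace(m=0.0))
        out = simulate_patient(profile(), scenario, rng)
        assert out.dx_mode == MODE_SYMPTOMATIC
        assert out.dx_time == pytest.approx(3.1)
        assert out.salvage
        assert out.death_time == pytest.approx(10.1)
        assert out.death_cause == STATE_DEAD_CANCER

    def test_late_diagnosis_is_palliative(self, rng, calibrated_params):
        # diagnosed well after U: palliative, death 8 months (8/3 cycles) later
        scenario = make_scenario(progression=calibrated_params.replace(m=0.0))
        out = simulate_patient(profile(U=3.0, S=9.5), scenario, rng)
        assert not out.salvage
        assert out.death_time == pytest.approx(9.5 + 8 / 3)

    def test_salvage_decision_is_cycle_level(self, rng, calibrated_params):
        # U falls inside the diagnosing cycle: the cycle begins before U, so
        # re-treatment is still curative even though S > U
        scenario = make_scenario(progression=calibrated_params.replace(m=0.0))
        out = simulate_patient(profile(U=3.2, S=3.6), scenario, rng)
        assert out.dx_time == pytest.approx(3.6)
        assert out.salvage

    def test_symptoms_beat_surveillance_within_cycle(self, rng, calibrated_params):
        # D = 3.2 and S = 3.4 both lie in cycle 4; the cycle-4 visit would
        # also detect, but interval symptoms resolve first
        scenario = make_scenario(
            progression=calibrated_params.replace(m=0.0),
            tests=[perfect_test()],
            schedule=every_cycle_schedule([Modality.CEA]),
        )
        out = simulate_patient(profile(D=3.2, S=3.4), scenario, rng)
        assert out.dx_mode == MODE_SYMPTOMATIC and out.dx_time == pytest.approx(3.4)

    def test_surveillance_detection_at_boundary(self, rng, calibrated_params):
        scenario = make_scenario(
            progression=calibrated_params.replace(m=0.0),
            tests=[perfect_test()],
            schedule=every_cycle_schedule([Modality.CEA]),
        )
        out = simulate_patient(profile(D=2.5, S=15.0), scenario, rng)
        assert out.dx_mode == MODE_SURVEILLANCE and out.dx_time == 3.0


class TestSummarizeCohort:
    def test_all_alive_none_diagnosed(self):
        outs = [PatientOutcome(state_path=["no_known_recurrence"] * 20)] * 10
        s = summarize_cohort(outs)
        assert s.dfs5 == 1.0 and s.os == (1.0,) * 5 and s.salvage_prop == 0.0

    def test_hand_counted_mixture(self):
        # 10 patients: 2 diagnosed (1 salvaged) and alive at 5y, 1 dead of
        # other causes at cycle 10 -> DFS5 70%, OS5 90%, salvage 10%
        alive = PatientOutcome(state_path=["no_known_recurrence"] * 20)
        dx_salvage = PatientOutcome(
            state_path=[], dx_time=6.0, dx_mode=MODE_SURVEILLANCE, salvage=True
        )
        dx_palliative = PatientOutcome(
            state_path=[], dx_time=8.0, dx_mode=MODE_SYMPTOMATIC, salvage=False
        )
        dead_other = PatientOutcome(
            state_path=[], death_time=10.0, death_cause=STATE_DEAD_OTHER
        )
        s = summarize_cohort([alive] * 7 + [dx_salvage, dx_palliative, dead_other])
        assert s.dfs5 == pytest.approx(0.7)
        assert s.os[4] == pytest.approx(0.9)
        assert s.salvage_prop == pytest.approx(0.1)

    def test_cancer_death_counts_once_for_dfs_and_os(self):
        # diagnosis at cycle 10 is the DFS event; death at 19 is the OS event
        o = PatientOutcome(
            state_path=[],
            dx_time=10.0,
            dx_mode=MODE_SURVEILLANCE,
            death_time=19.0,
            death_cause=STATE_DEAD_CANCER,
        )
        s = summarize_cohort([o])
        assert s.dfs5 == 0.0
        assert s.os == (1.0, 1.0, 1.0, 1.0, 0.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize_cohort([])


class TestRunScenario:
    def test_bitwise_reproducible(self, calibrated_params):
        scenario = make_scenario(
            n_patients=500,
            progression=calibrated_params,
            tests=[perfect_test()],
            schedule=every_cycle_schedule([Modality.CEA]),
        )
        s1, o1 = run_scenario(scenario, seed=42)
        s2, o2 = run_scenario(scenario, seed=42)
        assert s1 == s2
        assert all(a == b for a, b in zip(o1, o2))

    def test_no_recurrence_no_mortality(self, calibrated_params):
        scenario = make_scenario(
            n_patients=300, p_recur=0.0, progression=calibrated_params.replace(m=0.0)
        )
        s = run_scenario_summary(scenario, seed=3)
        assert s.dfs5 == 1.0 and s.os == (1.0,) * 5

    def test_summary_matches_outcome_materialization(self, calibrated_params):
        from crcsurv.scenarios import default_tests, intensive_schedule

        scenario = make_scenario(
            n_patients=2_000,
            progression=calibrated_params,
            tests=default_tests(),
            schedule=intensive_schedule(),
        )
        summary, outcomes = run_scenario(scenario, seed=9)
        fast = run_scenario_summary(scenario, seed=9)
        assert summary.as_percent_targets() == fast.as_percent_targets()

    def test_monotone_survival_invariants(self):
        spec = SyntheticScenarioSpec()
        for seed in range(6):
            scenario = generate_synthetic_scenario(spec, seed)
            s = run_scenario_summary(scenario, seed=100 + seed)
            assert s.dfs5 <= s.os[4] + 1e-12
            assert all(s.os[i] >= s.os[i + 1] for i in range(4))
            assert s.salvage_prop <= 1.0

    def test_superset_schedule_diagnoses_no_later(self, calibrated_params):
        # coupled draws: adding tests can only move surveillance detection earlier
        from crcsurv.scenarios import default_tests

        tests = default_tests()
        full = every_cycle_schedule([t.modality for t in tests])
        sparse_matrix = full.matrix.copy()
        sparse_matrix[::2] = 0
        sparse_matrix[:, :3] = 0
        sparse = type(full)(modalities=full.modalities, matrix=sparse_matrix)
        base = make_scenario(
            n_patients=3_000, progression=calibrated_params, tests=tests, schedule=full
        )
        a = _simulate_cohort(base, np.random.SeedSequence(7))
        base.schedule = sparse
        b = _simulate_cohort(base, np.random.SeedSequence(7))
        ta = np.where(np.isnan(a.dx_time), np.inf, a.dx_time)
        tb = np.where(np.isnan(b.dx_time), np.inf, b.dx_time)
        assert (ta <= tb + 1e-12).all()

    def test_salvage_monotone_in_sensitivity(self, calibrated_params):
        from crcsurv.scenarios import default_tests

        tests = default_tests()
        schedule = every_cycle_schedule([t.modality for t in tests])
        props = []
        for scale in (1.0, 0.5, 0.0):
            scaled = [t.replace(sensitivity=t.sensitivity * scale) for t in tests]
            scenario = make_scenario(
                n_patients=5_000,
                progression=calibrated_params,
                tests=scaled,
                schedule=schedule,
            )
            props.append(run_scenario_summary(scenario, seed=31).salvage_prop)
        assert props[0] >= props[1] >= props[2]


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_diagnosis_time(profile, schedule, tests, horizon):
    """Event enumeration: earliest of symptomatic onset and the first
    scheduled visit at which some administered test can truly see the
    (detectable) recurrence.  Valid for perfect tests and no mortality."""
    if not profile.will_recur:
        return None
    candidates = []
    if profile.S <= horizon:
        candidates.append((profile.S, MODE_SYMPTOMATIC))
    for cycle in range(1, horizon + 1):
        t = float(cycle)
        if t < profile.D:
            continue
        for test in tests:
            scheduled = schedule.column(test.modality)[cycle - 1]
            if scheduled and (profile.site.components & test.detectable_targets):
                candidates.append((t, MODE_SURVEILLANCE))
                break
        else:
            continue
        break
    if not candidates:
        return None
    # symptoms within a cycle resolve before that cycle's boundary visit
    return min(candidates, key=lambda c: (math.ceil(c[0]), c[1] == MODE_SURVEILLANCE))


class TestOracleEquivalence:
    def test_diagnosis_times_match_event_enumeration(self, calibrated_params):
        from crcsurv.scenarios import default_tests, intensive_schedule

        tests = [
            t.replace(sensitivity=1.0, specificity=1.0) for t in default_tests()
        ]
        scenario = make_scenario(
            n_patients=1_000,
            p_recur=0.7,
            progression=calibrated_params.replace(m=0.0),
            tests=tests,
            schedule=intensive_schedule(),
        )
        arrays = _simulate_cohort(scenario, np.random.SeedSequence(17))
        for i in range(len(arrays.profiles)):
            prof = arrays.profiles.profile(i)
            expected = brute_force_diagnosis_time(
                prof, scenario.schedule, tests, scenario.horizon_cycles
            )
            got = arrays.dx_time[i]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == expected[0]
                mode = (
                    MODE_SURVEILLANCE if arrays.dx_surveillance[i] else MODE_SYMPTOMATIC
                )
                assert mode == expected[1]

    def test_no_surveillance_salvage_matches_integration(self, calibrated_params):
        # with no testing at all, salvage can only come from symptomatic
        # presentation while the diagnosing cycle still begins before U;
        # integrate the exponential-D, Normal-eps model directly
        from scipy import stats

        params = calibrated_params.replace(m=0.0)
        site_dist = {LOCAL: 0.55, LIVER: 0.20, RecurrenceSite(met_status=MetStatus.MULTIPLE_OTHER): 0.25}
        scenario = make_scenario(
            n_patients=150_000,
            p_recur=0.5,
            progression=params,
            site_dist=site_dist,
            tests=[],
            schedule=None,
        )
        horizon = scenario.horizon_cycles
        w_du = params.x_du / 13.0
        w_ds = params.x_ds / 13.0
        sigma = params.sigma_ds / 13.0

        # P(symptomatic diagnosis counted curative | D = d): the diagnosing
        # cycle of S is ceil(S); its start must precede U, i.e. S <= s_max
        # with s_max = U if U + 1 is integral else ceil(U + 1) - 1; clipping
        # of S at D never removes eligible mass because D < U <= s_max.
        def p_salvage_given_d(d):
            U = d + w_du * (1 + params.r_u * d)
            s_max = U if float(U + 1).is_integer() else math.ceil(U + 1) - 1
            bound = min(s_max, horizon)
            mu = d + w_ds * (1 + params.r_s * d)
            return stats.norm.cdf((bound - mu) / sigma)

        d_grid = np.linspace(0, horizon, 40_001)
        dens = params.r_d * np.exp(-params.r_d * d_grid)
        p_sym = np.array([p_salvage_given_d(d) for d in d_grid])
        p_event = float(np.trapezoid(dens * p_sym, d_grid))
        operable_share = 0.55 + 0.20  # local-only and liver operable, rest not
        expected = scenario.p_recur * operable_share * p_event

        s = run_scenario_summary(scenario, seed=23)
        n = scenario.n_patients
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(s.salvage_prop - expected) < 3 * se

    def test_scalar_and_vectorized_paths_agree_deterministically(self, calibrated_params):
        # with perfect tests and no mortality both implementations are
        # deterministic and must produce identical outcomes patient by patient
        from crcsurv.scenarios import intensive_schedule

        tests = [perfect_test(Modality.CEA), perfect_test(Modality.CLINICAL_EXAM)]
        scenario = make_scenario(
            n_patients=400,
            p_recur=0.8,
            progression=calibrated_params.replace(m=0.0),
            site_dist={LOCAL: 0.6, LIVER: 0.4},
            tests=tests,
            schedule=intensive_schedule(),
        )
        arrays = _simulate_cohort(scenario, np.random.SeedSequence(29))
        rng = np.random.default_rng(0)  # irrelevant: no stochastic branches
        for i in range(len(arrays.profiles)):
            prof = arrays.profiles.profile(i)
            out = simulate_patient(prof, scenario, rng)
            if out.dx_time is None:
                assert np.isnan(arrays.dx_time[i])
            else:
                assert arrays.dx_time[i] == out.dx_time
                assert bool(arrays.salvage[i]) == out.salvage
            vec_death = arrays.death_time[i]
            if out.death_time is None:
                assert np.isnan(vec_death)
            else:
                assert vec_death == pytest.approx(out.death_time)

    def test_scalar_and_vectorized_paths_agree_statistically(self, calibrated_params):
        # full stochastic machinery: the two paths share event logic but not
        # random streams, so cohort summaries must agree within Monte-Carlo
        # error
        from crcsurv.scenarios import default_tests, intensive_schedule

        scenario = make_scenario(
            n_patients=4_000,
            progression=calibrated_params,
            tests=default_tests(),
            schedule=intensive_schedule(),
        )
        vec = run_scenario_summary(scenario, seed=13)
        rng = np.random.default_rng(13)
        profiles = generate_cohort_profiles(scenario, np.random.SeedSequence(77))
        outs = [
            simulate_patient(profiles.profile(i), scenario, rng)
            for i in range(len(profiles))
        ]
        scalar = summarize_cohort(outs, scenario.horizon_cycles)
        n = scenario.n_patients
        for key, v_vec in vec.as_percent_targets().items():
            v_sca = scalar.as_percent_targets()[key]
            p = max(min(v_vec / 100.0, 0.99), 0.01)
            se_pp = 100.0 * math.sqrt(2 * p * (1 - p) / n)
            assert abs(v_vec - v_sca) < 4 * se_pp, key
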