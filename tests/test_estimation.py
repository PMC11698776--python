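import numpy as np
import pytest

from seromarkov import (
    IllPosedPartitionError,
    IncidenceSchedule,
    KineticsModel,
    MeasurementDensity,
    Partition,
    default_partition,
    estimate_recursive,
    estimate_transition_matrix,
    prevalence,
    qhat,
    run_noiseless,
    sinusoidal_scenario,
)
from seromarkov.estimation import _design_masses
from seromarkov.experiments import exact_qhat_series
from seromarkov.sampler import sample_measurements, substream


class TestQhat:
    def test_all_below_first_cut(self, part):
        np.testing.assert_array_equal(
            qhat(np.full(10, part.c1 / 2), part), [1.0, 0.0, 0.0]
        )

    def test_boundary_belongs_to_right_interval(self, part):
        np.testing.assert_array_equal(qhat(np.array([part.c1]), part), [0, 1, 0])
        np.testing.assert_array_equal(qhat(np.array([part.c2]), part), [0, 0, 1])

    def test_empty_sample_set_rejected(self, part):
        with pytest.raises(ValueError):
            qhat(np.array([]), part)

    def test_fractions_sum_to_one(self, part):
        rng = np.random.default_rng(2)
        frac = qhat(rng.uniform(0, part.r_max, 999), part)
        assert frac.sum() == 1.0

    def test_unbiased_for_subdomain_masses(self, kin, sched, part):
        # mean of the Monte Carlo fractions over replicates matches the
        # exact mixture masses to within Monte Carlo error
        n, reps, T = 2_000, 500, 3
        masses = MeasurementDensity(kin, sched).subdomain_masses(part, T)
        acc = np.zeros(3)
        for k in range(reps):
            r, _, _ = sample_measurements(kin, sched, T, n, substream(21, k, T))
            acc += qhat(r, part)
        mean = acc / reps
        se = np.sqrt(masses * (1 - masses) / n) / np.sqrt(reps)
        assert np.all(np.abs(mean - masses) < 4 * se)


class TestNoiselessRecovery:
    def test_both_schemes_invert_the_forward_model_exactly(self, kin, sched, part):
        results = run_noiseless(kin, sched, part)
        for res in results.values():
            t_max = sched.t_max
            np.testing.assert_allclose(
                res.f_infected, sched.f_infected[:t_max], atol=1e-10
            )
            np.testing.assert_allclose(
                res.f_vaccinated, sched.f_vaccinated[:t_max], atol=1e-10
            )

    def test_single_step_matches_direct_closed_form(self, kin, sched, part):
        # with only step-1 data the recursion reduces to one 2x2 solve
        q = exact_qhat_series(kin, sched, part)[:2]
        res = estimate_recursive(q, kin, part)
        n_mass, r_mass, w_mass = _design_masses(kin, part, 1)
        M1 = np.array([[r_mass[1, 0], w_mass[1, 0]], [r_mass[1, 1], w_mass[1, 1]]])
        n2 = n_mass[:2]
        f0 = np.linalg.solve(M1 - np.outer(n2, [1, 1]), q[1, :2] - n2)
        np.testing.assert_allclose([res.f_infected[0], res.f_vaccinated[0]], f0,
                                   atol=1e-13)

    def test_transition_matrix_naive_estimates_consistent(self, kin, sched, part):
        res = estimate_transition_matrix(
            exact_qhat_series(kin, sched, part), kin, part
        )
        prev = prevalence(sched)
        np.testing.assert_allclose(res.q_naive, prev.q_naive[: sched.t_max],
                                   atol=1e-10)


def _sampled_qhat(kin, sched, part, n, seed, dataset=0):
    rows = np.zeros((sched.t_max + 1, 3))
    for T in range(1, sched.t_max + 1):
        r, _, _ = sample_measurements(kin, sched, T, n, substream(seed, dataset, T))
        rows[T] = qhat(r, part)
    return rows


class TestOnSampledData:
    def test_no_vaccination_scenario_estimates_near_zero(self, kin, part):
        sched = sinusoidal_scenario(10)
        sched = IncidenceSchedule(sched.f_infected, np.zeros(11), dt_days=21)
        rows = _sampled_qhat(kin, sched, part, 100_000, seed=31)
        res = estimate_transition_matrix(rows, kin, part)
        assert np.max(np.abs(res.f_vaccinated)) < 5e-3

    def test_accumulation_identity_links_new_and_previous_entries(
        self, kin, sched, part
    ):
        rows = _sampled_qhat(kin, sched, part, 1_000, seed=32)
        res = estimate_transition_matrix(rows, kin, part)
        np.testing.assert_allclose(
            res.h_prev_infected,
            np.concatenate([[0.0], np.cumsum(res.h_new_infected)[:-1]]),
            atol=0,
        )

    def test_schemes_agree_on_identical_data(self, kin, sched, part):
        # the 2x2 recursion and the 3x3 per-step solves are algebraically
        # the same estimator; on shared data they match to rounding
        for d in range(20):
            rows = _sampled_qhat(kin, sched, part, 1_000, seed=33, dataset=d)
            a = estimate_recursive(rows, kin, part)
            b = estimate_transition_matrix(rows, kin, part)
            assert np.linalg.norm(a.q_infected - b.q_infected) < 1.5e-14
            assert np.linalg.norm(a.q_vaccinated - b.q_vaccinated) < 1.5e-14

    def test_negative_estimates_preserved_raw_and_clipped_on_demand(
        self, kin, sched, part
    ):
        # hunt a small-sample replicate with an infeasible negative estimate
        for d in range(50):
            rows = _sampled_qhat(kin, sched, part, 100, seed=34, dataset=d)
            res = estimate_recursive(rows, kin, part)
            if np.any(res.q_infected < 0) or np.any(res.q_vaccinated < 0):
                clipped = estimate_recursive(rows, kin, part, clip=True)
                assert np.all(clipped.q_infected >= 0)
                assert np.all(clipped.q_vaccinated >= 0)
                total = clipped.q_infected + clipped.q_vaccinated + clipped.q_naive
                np.testing.assert_allclose(total, 1.0, atol=1e-12)
                return
        pytest.fail("no replicate produced a negative estimate at n=100")


class TestPartitionSelection:
    def test_cuts_bracket_the_lag_one_modes(self, kin, sched, part):
        naive_mode = kin.naive_mode()
        infected_mode = (kin.shape_at(kin.dt_days, "infected") - 1) * kin.beta_n
        vacc_mode = (kin.shape_at(kin.dt_days, "vaccinated") - 1) * kin.beta_n
        assert naive_mode < part.c1 < infected_mode
        assert part.c1 < part.c2
        assert infected_mode < part.c2 < vacc_mode

    def test_design_is_well_conditioned(self, kin, sched, part):
        res = estimate_transition_matrix(exact_qhat_series(kin, sched, part), kin, part)
        assert res.condition_number < 1e6

    def test_identical_event_kinetics_trigger_tertile_fallback(self, sched):
        kin = KineticsModel.from_preset(
            "sars2", theta1_v=1.56, theta2_v=5.1e-4
        )  # vaccinated == infected kinetics: no I/V crossing exists
        part = default_partition(kin, sched)
        dens = MeasurementDensity(kin, sched)
        masses = dens.subdomain_masses(part, 1)
        np.testing.assert_allclose(masses, 1 / 3, atol=1e-8)

    def test_tail_partition_is_rejected_as_ill_posed(self, kin, sched):
        bad = Partition(25.0, 28.0, kin.r_max)
        with pytest.raises(IllPosedPartitionError):
            estimate_recursive(exact_qhat_series(kin, sched, bad), kin, bad)

    def test_invalid_cut_points_rejected(self):
        with pytest.raises(ValueError):
            Partition(5.0, 5.0, 30.0)
        with pytest.raises(ValueError):
            Partition(-1.0, 5.0, 30.0)


def test_qhat_series_shape_validated(kin, part):
    with pytest.raises(ValueError):
        estimate_recursive(np.zeros((3, 2)), kin, part)
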