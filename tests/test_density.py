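import numpy as np
import pytest
from scipy import integrate

from seromarkov import (
    INFECTED,
    VACCINATED,
    MeasurementDensity,
    Partition,
    sample_population,
)
from conftest import random_schedule


@pytest.fixture(scope="module")
def conv(kin, sched):
    return MeasurementDensity(kin, sched, "convolution")


@pytest.fixture(scope="module")
def mkv(kin, sched):
    return MeasurementDensity(kin, sched, "markov")


class TestTotalDensity:
    def test_emergence_distribution_is_naive(self, kin, conv, mkv):
        r = np.linspace(0.0, kin.r_max, 300)
        n = kin.pdf(r)
        assert np.max(np.abs(conv.total(r, 0) - n)) < 1e-14
        assert np.max(np.abs(mkv.total(r, 0) - n)) < 1e-14

    @pytest.mark.parametrize("T", [1, 4, 10])
    def test_normalization(self, kin, conv, T):
        total, _ = integrate.quad(lambda r: conv.total(r, T), 0, kin.r_max, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_frameworks_agree_pointwise(self, kin, conv, mkv):
        rng = np.random.default_rng(5)
        for _ in range(50):
            r = float(rng.uniform(0, kin.r_max))
            T = int(rng.integers(0, 11))
            assert conv.total(r, T) == pytest.approx(mkv.total(r, T), abs=1e-12)


class TestClassConditional:
    def test_collapses_to_naive_at_emergence(self, kin, conv):
        r = np.linspace(0.0, kin.r_max, 200)
        n = kin.pdf(r)
        for klass in (INFECTED, VACCINATED):
            assert np.max(np.abs(conv.class_conditional(r, 0, klass) - n)) < 1e-14

    @pytest.mark.parametrize("klass", [INFECTED, VACCINATED])
    def test_normalization(self, kin, conv, klass):
        total, _ = integrate.quad(
            lambda r: conv.class_conditional(r, 6, klass), 0, kin.r_max, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_frameworks_agree_pointwise(self, kin, conv, mkv):
        rng = np.random.default_rng(6)
        for _ in range(50):
            r = float(rng.uniform(0, kin.r_max))
            T = int(rng.integers(0, 11))
            klass = INFECTED if rng.random() < 0.5 else VACCINATED
            assert conv.class_conditional(r, T, klass) == pytest.approx(
                mkv.class_conditional(r, T, klass), abs=1e-12
            )

    def test_zero_prevalence_is_undefined(self, kin):
        schedule = random_schedule(np.random.default_rng(1), t_max=4)
        schedule = type(schedule)(
            np.zeros_like(schedule.f_infected), schedule.f_vaccinated
        )
        dens = MeasurementDensity(kin, schedule)
        with pytest.raises(ZeroDivisionError):
            dens.class_conditional(3.0, 2, INFECTED)


class TestFrameworkEquivalenceOnRandomSchedules:
    def test_dense_grid(self, kin):
        rng = np.random.default_rng(17)
        r = np.linspace(0.0, kin.r_max, 101)
        for _ in range(10):
            schedule = random_schedule(rng)
            a = MeasurementDensity(kin, schedule, "convolution")
            b = MeasurementDensity(kin, schedule, "markov")
            for T in range(schedule.t_max + 1):
                assert np.max(np.abs(a.total(r, T) - b.total(r, T))) < 1e-12


class TestSubdomainMasses:
    def test_sum_to_one_and_start_naive(self, kin, conv, part):
        naive = np.array([kin.subdomain_mass(iv) for iv in part.intervals])
        np.testing.assert_allclose(conv.subdomain_masses(part, 0), naive, atol=1e-14)
        for T in range(11):
            masses = conv.subdomain_masses(part, T)
            assert masses.sum() == pytest.approx(1.0, abs=1e-10)

    def test_weight_bookkeeping(self, sched, conv):
        # mixture weights of Q(.,T): naive share + all event incidences = 1
        for T in range(1, 11):
            w = (
                conv._naive_weight(T)
                + conv._event_weights(T - 1, INFECTED).sum()
                + conv._event_weights(T - 1, VACCINATED).sum()
            )
            assert w == pytest.approx(1.0, abs=1e-12)

    def test_matches_monte_carlo_frequencies(self, kin, sched, conv, part):
        n = 1_000_000
        T = 5
        frame = sample_population(kin, sched, T, n, seed=99, labeled=False)
        r = frame["measurement"].to_numpy()
        counts = np.bincount(part.assign(r), minlength=3)
        masses = conv.subdomain_masses(part, T)
        se = np.sqrt(masses * (1 - masses) / n)
        assert np.all(np.abs(counts / n - masses) < 4 * se)

    def test_bad_partitions_rejected(self, conv, kin):
        with pytest.raises(ValueError):
            conv.subdomain_masses(((0, 3), (4, 8), (8, kin.r_max)), 1)  # gap
        with pytest.raises(ValueError):
            conv.subdomain_masses(((0, 5), (3, 8), (8, kin.r_max)), 1)  # overlap
        with pytest.raises(ValueError):
            conv.subdomain_masses(((0, 5), (5, 8), (8, kin.r_max - 1)), 1)  # short


def test_unknown_framework_rejected(kin, sched):
    with pytest.raises(ValueError):
        MeasurementDensity(kin, sched, framework="bayes")


def test_grid_frame_export(conv):
    frame = conv.grid_frame(3, n_points=64)
    assert list(frame.columns) == ["r", "density"]
    assert len(frame) == 64
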