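"""Plateau, tcrit estimation, saturation diagnostics, revisitation."""

import itertools
import math

import numpy as np
import pytest

from polyspace import (
    CrossingNotReachedError,
    DivergenceTrajectory,
    MutationModel,
    NotSaturatedError,
    PolymorphismProfile,
    SimulationConfig,
    blind_permutation_log_probability,
    critical_times,
    effective_space,
    estimate_plateau,
    evolve,
    find_tcrit,
    revisitation_probability,
    stationary_match_probability,
    steady_state_distribution,
    time_divergence_correlation,
)
from polyspace.critical_time import StationarityError
from polyspace.exhaustion import TimeScale
from polyspace.space_math import SemantideSpec


def analytic_trajectory(d_inf, rate, horizon, n_points=400, digest="analytic"):
    t = np.linspace(0, horizon, n_points)
    d = d_inf * (1 - np.exp(-rate * t))
    return DivergenceTrajectory(
        generations=t,
        mean_divergence=d,
        sd_divergence=np.zeros_like(d),
        population_sizes=np.ones_like(d, dtype=int),
        config_digest=digest,
    )


class TestPlateau:
    def test_constructed_asymptote_recovered(self):
        traj = analytic_trajectory(0.6, 1 / 100, 2000)
        d_inf, _ = estimate_plateau(traj)
        assert d_inf == pytest.approx(0.6, rel=0.01)

    def test_constant_trajectory_is_its_own_plateau(self):
        traj = analytic_trajectory(0.3, 1e9, 1000)  # instantly saturated
        d_inf, _ = estimate_plateau(traj)
        assert d_inf == pytest.approx(0.3, rel=1e-9)

    def test_linear_ramp_is_not_saturated(self):
        t = np.arange(0, 1000, 10.0)
        traj = DivergenceTrajectory(
            generations=t,
            mean_divergence=0.0005 * t,
            sd_divergence=np.zeros_like(t),
            population_sizes=np.ones_like(t, dtype=int),
        )
        with pytest.raises(NotSaturatedError):
            estimate_plateau(traj)

    def test_zero_divergence_is_not_saturated(self):
        t = np.arange(0, 100, 1.0)
        traj = DivergenceTrajectory(
            generations=t,
            mean_divergence=np.zeros_like(t),
            sd_divergence=np.zeros_like(t),
            population_sizes=np.ones_like(t, dtype=int),
        )
        with pytest.raises(NotSaturatedError):
            estimate_plateau(traj)


class TestTcrit:
    @pytest.mark.parametrize("rate", [1e-3, 1e-2, 1e-1])
    def test_crossings_match_the_closed_form(self, rate):
        """For D(t) = D_inf (1 - e^(-rt)): tcrit50 = ln2/r, tcrit90 = ln10/r."""
        traj = analytic_trajectory(0.5, rate, 12 / rate, n_points=3000)
        d_inf, _ = estimate_plateau(traj)
        assert find_tcrit(traj, d_inf, 0.5) == pytest.approx(math.log(2) / rate, rel=0.02)
        assert find_tcrit(traj, d_inf, 0.9) == pytest.approx(math.log(10) / rate, rel=0.02)

    def test_tcrit50_precedes_tcrit90(self):
        traj = analytic_trajectory(0.4, 0.01, 1200)
        crit = critical_times(traj)
        assert 0 < crit.tcrit50 < crit.tcrit90

    def test_year_conversion_is_opt_in(self):
        traj = analytic_trajectory(0.4, 0.01, 1200)
        bare = critical_times(traj)
        assert bare.tcrit50_years is None
        timed = critical_times(traj, timescale=TimeScale(generation_time_minutes=20))
        assert timed.tcrit50_years == pytest.approx(
            timed.tcrit50 * 20 / 525_960, rel=1e-12
        )

    def test_unreachable_crossing_raises(self):
        t = np.arange(0, 100, 1.0)
        traj = DivergenceTrajectory(
            generations=t,
            mean_divergence=np.zeros_like(t),
            sd_divergence=np.zeros_like(t),
            population_sizes=np.ones_like(t, dtype=int),
        )
        with pytest.raises(CrossingNotReachedError):
            find_tcrit(traj, 0.6, 0.5)


class TestSteadyStateDistribution:
    def test_identical_copies_give_a_point_mass_at_zero(self):
        pop = np.zeros((50, 10), dtype=np.uint8)
        dist = steady_state_distribution({1000: pop}, "A" * 10, tcrit90=500.0)
        masses = dist.masses
        assert masses[0] == pytest.approx(1.0)
        assert np.all(masses[1:] == 0)
        assert masses.sum() == pytest.approx(1.0, rel=1e-9)

    def test_pre_tcrit90_snapshots_rejected(self):
        pop = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError, match="not past tcrit90"):
            steady_state_distribution({100: pop, 1000: pop}, "A" * 10, tcrit90=500.0)

    def test_drifted_snapshots_fail_the_stationarity_check(self):
        near = np.zeros((50, 10), dtype=np.uint8)
        far = np.full((50, 10), 3, dtype=np.uint8)  # all sites diverged
        with pytest.raises(StationarityError):
            steady_state_distribution(
                {600: near, 1200: far}, "A" * 10, tcrit90=500.0, tv_tolerance=0.1
            )


class TestTimeDivergenceCorrelation:
    @staticmethod
    def _linear_ensemble(n=25, slope=1e-4):
        t = np.arange(0, 2000, 50.0)
        rng = np.random.default_rng(1)
        out = []
        for _ in range(n):
            out.append(
                DivergenceTrajectory(
                    generations=t,
                    mean_divergence=slope * t + rng.normal(0, 1e-6, t.size),
                    sd_divergence=np.zeros_like(t),
                    population_sizes=np.ones_like(t, dtype=int),
                )
            )
        return out

    def test_clocklike_trajectories_correlate_fully_in_every_window(self):
        curve = time_divergence_correlation(
            self._linear_ensemble(), window_edges=[0, 500, 1000, 1500, 2000]
        )
        assert (curve["correlation"].dropna() > 0.99).all()

    def test_a_single_replicate_is_rejected(self):
        with pytest.raises(ValueError, match="20 replicate"):
            time_divergence_correlation(self._linear_ensemble(n=1), [0, 1000])

    def test_correlation_collapses_past_saturation(self):
        """Within post-tcrit90 windows, divergence no longer predicts time."""
        L = 40
        prof = PolymorphismProfile.free(L)
        model = MutationModel(mu=5e-3, kappa=1.0)
        base = SimulationConfig(
            ancestor="A" * L, profile=prof, model=model,
            generations=2000, population_size=30, seed=100, record_every=25,
        )
        trajs = []
        for i in range(20):
            cfg = SimulationConfig(
                ancestor=base.ancestor, profile=prof, model=model,
                generations=base.generations, population_size=base.population_size,
                seed=base.seed + i, record_every=base.record_every,
            )
            trajs.append(evolve(cfg).trajectory)
        # tcrit90 for JC at mu=5e-3 is ln10 / (4mu/3) ~ 345 generations
        curve = time_divergence_correlation(trajs, window_edges=[0, 200, 1000, 2000])
        early = curve["correlation"].iloc[0]
        late = curve["correlation"].iloc[-1]
        assert early > 0.8
        assert abs(late) < 0.2


class TestRevisitation:
    @staticmethod
    def _config(L, seed=0, generations=80, mu=0.3):
        prof = PolymorphismProfile.free(L)
        return SimulationConfig(
            ancestor="A" * L, profile=prof,
            model=MutationModel(mu=mu, kappa=1.0),
            generations=generations, population_size=1, seed=seed,
        )

    def test_threshold_one_is_certain(self):
        est = revisitation_probability(
            self._config(4), self._config(4), threshold=1.0, n_pairs=10
        )
        assert est.probability == 1.0

    def test_single_free_site_meets_a_quarter_of_the_time(self):
        est = revisitation_probability(
            self._config(1), self._config(1), threshold=0.0, n_pairs=4000, seed=3
        )
        assert abs(est.probability - 0.25) < 3 * est.se

    def test_mismatched_profiles_rejected(self):
        with pytest.raises(ValueError, match="share the polymorphism profile"):
            revisitation_probability(
                self._config(3), self._config(4), threshold=0.0, n_pairs=10
            )

    def test_exact_poisson_binomial_matches_brute_force_enumeration(self):
        """Independent oracle: enumerate every pair of stationary sequences
        of a 3-site gene with mixed constraints and sum their probabilities."""
        allowed = np.array([[1, 0, 1, 0], [1, 1, 1, 0], [1, 0, 0, 0]], dtype=bool)
        prof = PolymorphismProfile(
            allowed=allowed, frequencies=allowed / allowed.sum(axis=1, keepdims=True)
        )
        model = MutationModel(mu=0.1, kappa=4.0)
        sets = [np.flatnonzero(a) for a in allowed]
        probs = [1.0 / len(s) for s in sets]  # stationary is uniform on allowed
        for threshold in (0.0, 1 / 3, 2 / 3):
            brute = 0.0
            for x in itertools.product(*sets):
                for y in itertools.product(*sets):
                    p = np.prod([pi**2 for pi in probs])
                    if np.mean(np.array(x) != np.array(y)) <= threshold + 1e-12:
                        brute += p
            assert stationary_match_probability(prof, model, threshold) == pytest.approx(
                brute, rel=1e-10
            )

    def test_meeting_probability_is_floored_by_blind_permutation(self):
        """At stationarity, P(identical) for the effective space can never
        drop below the blind-permutation probability of that space."""
        prof = PolymorphismProfile.free(4)
        model = MutationModel(mu=0.1, kappa=1.0)
        exact = stationary_match_probability(prof, model, threshold=0.0)
        eff = effective_space(prof, model)
        floor = 10 ** (-eff.le * math.log10(eff.ke))
        assert exact >= floor - 1e-12
        assert floor == pytest.approx(
            10 ** blind_permutation_log_probability(SemantideSpec.dna(4))
        )
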