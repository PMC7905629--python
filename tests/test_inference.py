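"""FFBS exactness, conjugate updates, sampler determinism, diagnostics."""

import itertools

import numpy as np
import pytest

from telemark.inference import (
    MCMCConfig,
    count_transitions,
    dic,
    ffbs_all,
    ffbs_draw,
    gelman_rubin,
    gibbs_update,
    gibbs_update_from_paths,
    param_names,
    params_to_vector,
    run_mcmc,
    summarize,
    vector_to_params,
)
from telemark.priors import build_prior_spec
from telemark.states import ALLOWED_TRANSITIONS, SPAWN, feasible_states

from tests.test_model import make_obs, random_params


def enumerate_paths(obs, params, season_of, i=0):
    """Exact conditional path distribution by exhaustive enumeration."""
    occasions = list(obs.active_occasions(i))
    supports = [feasible_states(int(obs.codes[i, j])) for j in occasions]
    Tm = [params.transition_matrix(0, int(season_of[j])) for j in range(obs.f + 1)]
    paths, probs = [], []
    for path in itertools.product(*supports):
        p, prev = 1.0, SPAWN
        for j, state in zip(occasions, path):
            p *= Tm[j - 1][prev - 1, state - 1]
            prev = state
        if p > 0:
            paths.append(path)
            probs.append(p)
    probs = np.array(probs)
    return paths, probs / probs.sum()


class TestFFBS:
    def test_fully_observed_path_is_deterministic(self, rng):
        params = random_params(rng)
        obs = make_obs([[2, 2, 2, 2]])
        season = np.zeros(5, dtype=int)
        Z = ffbs_draw(obs, params, season, np.zeros(1, dtype=int), rng)
        np.testing.assert_array_equal(Z[0, 1:], [2, 2, 2, 2])
        assert Z[0, 0] == SPAWN

    def test_forced_middle_state(self, rng):
        # X = (2, 1, 2): the middle state must be 4 (only member of {1,4,8}
        # from which the spawning grounds are reachable)
        params = random_params(rng)
        obs = make_obs([[2, 1, 2]])
        season = np.zeros(4, dtype=int)
        for _ in range(20):
            Z = ffbs_draw(obs, params, season, np.zeros(1, dtype=int), rng)
            np.testing.assert_array_equal(Z[0, 1:], [2, 4, 2])

    def test_empirical_path_frequencies_match_enumeration(self, rng):
        params = random_params(rng)
        obs = make_obs([[1, 4, 1, 1]])
        season = np.zeros(5, dtype=int)
        paths, probs = enumerate_paths(obs, params, season)
        n = 10_000
        freq = {p: 0 for p in paths}
        for _ in range(n):
            Z = ffbs_draw(obs, params, season, np.zeros(1, dtype=int), rng)
            freq[tuple(int(z) for z in Z[0, 1:])] += 1
        for path, prob in zip(paths, probs):
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(freq[path] / n - prob) <= 3 * se + 1e-9, path

    def test_paths_respect_structural_zeros(self, rng):
        params = random_params(rng)
        obs = make_obs([[1, 1, 1, 4, 1, 1]])
        season = np.zeros(7, dtype=int)
        for _ in range(50):
            Z = ffbs_draw(obs, params, season, np.zeros(1, dtype=int), rng)
            states = Z[0][Z[0] > 0]
            for a, b in zip(states, states[1:]):
                assert b in ALLOWED_TRANSITIONS[a]


class TestConjugateUpdate:
    def test_dirichlet_posterior_parameters(self, rng):
        spec = build_prior_spec(1, 1)
        # paths: 10 stays at spawn, 0 departures, from a fish observed 11 weeks
        Z = np.full((1, 12), 2, dtype=np.int64)
        season = np.zeros(12, dtype=int)
        draws = np.array(
            [
                gibbs_update_from_paths(Z, np.zeros(1, dtype=int), season, spec, rng)
                .psi[(2, 0, 0)][0]
                for _ in range(4000)
            ]
        )
        # posterior is Dirichlet(2+11, 2): check mean within 3 MC standard errors
        a, b = 2 + 11, 2
        mean = a / (a + b)
        sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        assert abs(draws.mean() - mean) <= 3 * sd / np.sqrt(len(draws))

    def test_beta_posterior_parameters(self, rng):
        spec = build_prior_spec(1, 1)
        counts = np.zeros((1, 1, 8, 8), dtype=np.int64)
        counts[0, 0, 3, 0] = 10            # 10 deaths from the sound
        counts[0, 0, 3, 3] = 30            # 30 survivals (stays)
        draws = np.array(
            [gibbs_update(counts, spec, rng).surv[(4, 0, 0)] for _ in range(4000)]
        )
        a, b = 2 + 30, 2 + 10
        mean, var = a / (a + b), a * b / ((a + b) ** 2 * (a + b + 1))
        assert abs(draws.mean() - mean) <= 3 * np.sqrt(var / len(draws))
        assert abs(draws.var() - var) <= 3 * var * np.sqrt(2 / len(draws))

    def test_zero_counts_reproduce_prior(self, rng):
        spec = build_prior_spec(1, 1)
        counts = np.zeros((1, 1, 8, 8), dtype=np.int64)
        draws = np.array(
            [gibbs_update(counts, spec, rng).psi[(8, 0, 0)] for _ in range(4000)]
        )
        np.testing.assert_allclose(draws.mean(axis=0), 0.25, atol=0.02)

    def test_count_transitions_bins_by_season_of_origin(self):
        Z = np.array([[1, 1, 2, 3]]) - 1  # states 2 at j=2 -> 3... (0-based input)
        Z = np.array([[-1, 1, 1, 3]])     # spawn at 1,2 then sound at 3 (0-based)
        season = np.array([0, 0, 0, 1])
        counts = count_transitions(Z, np.zeros(1, dtype=int), season, 1, 2)
        assert counts[0, 0, 1, 1] == 1  # 2->2 binned to season of occasion 1
        assert counts[0, 0, 1, 3] == 1  # 2->4 from occasion 2 (season 0)
        assert counts.sum() == 2


class TestSampler:
    def _setup(self, rng, n_fish=8, f=6):
        params = random_params(rng)
        rows = []
        for _ in range(n_fish):
            # codes in {1, 2} keep every consecutive pair feasible
            rows.append([int(x) for x in rng.choice([1, 1, 1, 2], size=f)])
        obs = make_obs(rows)
        season = np.zeros(f + 1, dtype=int)
        spec = build_prior_spec(1, 1)
        return obs, season, spec

    def test_identical_seeds_give_identical_draws(self, rng):
        obs, season, spec = self._setup(rng)
        cfg = MCMCConfig(n_chains=2, n_iterations=60, burn_in=20, thin=2, seed=7)
        classes = np.zeros(obs.n_fish, dtype=int)
        a = run_mcmc(obs, spec, classes, season, cfg)
        b = run_mcmc(obs, spec, classes, season, cfg)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_draw_count_and_simplex_validity(self, rng):
        obs, season, spec = self._setup(rng)
        cfg = MCMCConfig(n_chains=2, n_iterations=55, burn_in=15, thin=4, seed=3)
        out = run_mcmc(obs, spec, np.zeros(obs.n_fish, dtype=int), season, cfg)
        assert out.n_draws == (55 - 15) // 4
        params = vector_to_params(out.values[0, -1], 1, 1)
        params.validate()

    def test_empty_fish_set_recovers_prior_means(self):
        spec = build_prior_spec(1, 2)
        spec.dirichlet[(5, 0, 0)] = np.array([3.0, 5.0, 2.0])
        from telemark.discretize import ObservationMatrix

        obs = ObservationMatrix(
            tag_ids=[],
            codes=np.zeros((0, 5), dtype=np.int8),
            release_occasion=np.zeros(0, dtype=np.int64),
            last_occasion=np.zeros(0, dtype=np.int64),
            f=4,
        )
        season = np.array([0, 0, 0, 1, 1])
        cfg = MCMCConfig(n_chains=2, n_iterations=3000, burn_in=500, thin=1, seed=11)
        out = run_mcmc(obs, spec, np.zeros(0, dtype=int), season, cfg)
        pooled = out.pooled()
        n = pooled.shape[0]
        alpha = spec.dirichlet[(5, 0, 0)]
        mean = alpha[0] / alpha.sum()
        sd = np.sqrt(mean * (1 - mean) / (alpha.sum() + 1))
        got = pooled[:, out.names.index("psi[5->4|y0,k0]")].mean()
        assert abs(got - mean) <= 3 * sd / np.sqrt(n)
        got_s = pooled[:, out.names.index("S[4|y0,k1]")].mean()
        sd_s = np.sqrt(0.25 / 5)  # Beta(2,2) sd
        assert abs(got_s - 0.5) <= 3 * sd_s / np.sqrt(n)


class TestCovariateContrast:
    def test_true_logit_gap_detected_in_majority_of_replicates(self):
        """Two-class data with a real logit gap in spawn-ground departure:
        the posterior beta_1 interval excludes 0 in most replicates."""
        from telemark.discretize import build_grid
        from telemark.pipeline import fit_pipeline
        from telemark.simulate import (
            SimulationScenario,
            default_true_params,
            simulate_dataset,
        )

        grid = build_grid(end="2017-09-30", season_starts=[("S", "2017-04-01")])
        params = default_true_params(n_classes=2, n_seasons=1)
        # logit gap ~1.0 on the spawn departure probability
        params.psi[(2, 0, 0)] = np.array([0.80, 0.20])
        params.psi[(2, 1, 0)] = np.array([0.60, 0.40])
        hits = 0
        for rep in range(3):
            scen = SimulationScenario(
                cohort_sizes=(200,), release_occasions=(1,), short_tag_counts=(0,)
            )
            data = simulate_dataset(scen, grid, params=params, seed=300 + rep)
            res = fit_pipeline(
                data.detections, data.registry, data.deployments, grid,
                covariate="weight",
                n_chains=2, n_iterations=500, burn_in=150, thin=2, seed=400 + rep,
            )
            row = res.estimator.summary_.contrasts.loc["psi[2->4|k0]"]
            hits += bool(row.significant and row.beta1_median > 0)
        assert hits >= 2


class TestDiagnostics:
    def test_constant_chains_report_one_with_warning(self):
        vals = np.ones((2, 50))
        with pytest.warns(RuntimeWarning):
            assert gelman_rubin(vals) == 1.0

    def test_same_distribution_chains_near_one(self, rng):
        vals = rng.normal(size=(4, 1000))
        assert gelman_rubin(vals) < 1.05

    def test_separated_chains_flagged(self, rng):
        vals = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(vals) > 1.1

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 100)))

    def test_degenerate_posterior_has_zero_pd(self, rng):
        obs = make_obs([[1, 2]])
        season = np.zeros(3, dtype=int)
        spec = build_prior_spec(1, 1)
        cfg = MCMCConfig(n_chains=2, n_iterations=40, burn_in=10, thin=1, seed=5)
        out = run_mcmc(obs, spec, np.zeros(1, dtype=int), season, cfg)
        out.values[:] = out.values[0, 0]       # collapse to a single draw
        out.deviance[:] = out.deviance[0, 0]
        d = dic(out, obs, season, np.zeros(1, dtype=int))
        assert d["pd"] == pytest.approx(0.0, abs=1e-8)
        assert d["dic"] == pytest.approx(d["mean_deviance"], abs=1e-8)


class TestSummaries:
    def test_median_and_interval(self, rng):
        obs = make_obs([[1, 1]])
        season = np.zeros(3, dtype=int)
        spec = build_prior_spec(1, 1)
        cfg = MCMCConfig(n_chains=2, n_iterations=200, burn_in=50, thin=1, seed=2)
        out = run_mcmc(obs, spec, np.zeros(1, dtype=int), season, cfg)
        s = summarize(out)
        assert ((s.table["lo5"] <= s.table["median"]) & (s.table["median"] <= s.table["hi95"])).all()

    def test_contrasts_present_for_two_class_fits(self, rng):
        obs = make_obs([[1, 1], [2, 1]])
        season = np.zeros(3, dtype=int)
        spec = build_prior_spec(2, 1)
        cfg = MCMCConfig(n_chains=2, n_iterations=100, burn_in=20, thin=1, seed=2)
        out = run_mcmc(obs, spec, np.array([0, 1]), season, cfg)
        s = summarize(out)
        assert s.contrasts is not None
        assert "psi[5->4|k0]" in s.contrasts.index

    def test_posterior_csv_round_trip(self, tmp_path, rng):
        obs = make_obs([[1, 2]])
        season = np.zeros(3, dtype=int)
        spec = build_prior_spec(1, 1)
        cfg = MCMCConfig(n_chains=2, n_iterations=40, burn_in=10, thin=2, seed=9)
        out = run_mcmc(obs, spec, np.zeros(1, dtype=int), season, cfg)
        p = tmp_path / "post.csv"
        out.to_csv(p)
        from telemark.inference import PosteriorDraws

        back = PosteriorDraws.from_csv(p)
        assert set(back.names) == set(out.names)
        for name in out.names:
            np.testing.assert_allclose(back.column(name), out.column(name))
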