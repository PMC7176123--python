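"""Oracle checks for the joint spatial model: likelihood, CAR conditionals,
conjugate updates, recentering, and small posterior-correctness studies."""

import math

import numpy as np
import pytest

from cvdmap import model as mdl
from cvdmap.spatial_graph import AdjacencyGraph, lattice_graph


def make_spec(rng, J=4, K=2, n=20, p=2, graph=None, spatial=True, missing=0.0):
    graph = graph or lattice_graph(2, J // 2)
    Y = (rng.random((n, K)) < 0.4).astype(float)
    if missing:
        Y[rng.random((n, K)) < missing] = np.nan
    X = rng.standard_normal((n, p))
    area = rng.integers(0, graph.n_areas, size=n)
    return mdl.ModelSpec(Y=Y, X=X, area=area, graph=graph, spatial=spatial)


def random_state(rng, spec):
    K, J, p = spec.K, spec.J, spec.p
    A = rng.standard_normal((K, K)) * 0.3
    B = rng.standard_normal((K, K)) * 0.3
    return mdl.ModelState(
        alpha=rng.standard_normal(K),
        beta=rng.standard_normal((p, K)),
        S=rng.standard_normal((J, K)),
        V=rng.standard_normal((J, K)),
        Sigma_s=A @ A.T + np.eye(K),
        Sigma_v=B @ B.T + np.eye(K),
    )


class TestLinearPredictor:
    def test_all_zero_gives_half(self, rng):
        spec = make_spec(rng)
        state = mdl.initial_state(spec)
        state.alpha[:] = 0
        eta = mdl.linear_predictor(state, spec)
        np.testing.assert_allclose(1 / (1 + np.exp(-eta)), 0.5)

    def test_intercept_log3_gives_three_quarters(self, rng):
        spec = make_spec(rng)
        state = mdl.initial_state(spec)
        state.alpha[:] = math.log(3.0)
        pi = 1 / (1 + np.exp(-mdl.linear_predictor(state, spec)))
        np.testing.assert_allclose(pi, 0.75, atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        spec = make_spec(rng, n=15, p=3)
        state = random_state(rng, spec)
        eta = mdl.linear_predictor(state, spec)
        for i in range(spec.n):
            for k in range(spec.K):
                j = spec.area[i]
                expect = (
                    state.alpha[k]
                    + sum(state.beta[r, k] * spec.X[i, r] for r in range(spec.p))
                    + state.S[j, k]
                    + state.V[j, k]
                )
                assert abs(eta[i, k] - expect) < 1e-12

    def test_dimension_mismatch(self, rng):
        spec = make_spec(rng)
        state = mdl.initial_state(spec)
        state.beta = np.zeros((7, spec.K))
        with pytest.raises(mdl.ModelError):
            mdl.linear_predictor(state, spec)


class TestLogLikelihood:
    def test_all_half_is_n_log_half(self, rng):
        spec = make_spec(rng, n=25)
        state = mdl.initial_state(spec)
        state.alpha[:] = 0
        n_cells = int((~np.isnan(spec.Y)).sum())
        assert mdl.log_likelihood(state, spec) == pytest.approx(n_cells * math.log(0.5))

    def test_matches_per_cell_oracle(self, rng):
        spec = make_spec(rng, n=5, K=2, missing=0.2)
        state = random_state(rng, spec)
        eta = mdl.linear_predictor(state, spec)
        expect = 0.0
        for i in range(5):
            for k in range(2):
                y = spec.Y[i, k]
                if np.isnan(y):
                    continue
                pi = 1 / (1 + math.exp(-eta[i, k]))
                expect += y * math.log(pi) + (1 - y) * math.log(1 - pi)
        assert abs(mdl.log_likelihood(state, spec) - expect) < 1e-10

    def test_monotone_in_eta_for_positive_cell(self, rng):
        spec = make_spec(rng, n=1, K=1, p=0)
        spec.Y[0, 0] = 1.0
        state = mdl.initial_state(spec)
        lls = []
        for a in (-1.0, 0.0, 1.0, 2.0):
            state.alpha[:] = a
            lls.append(mdl.log_likelihood(state, spec))
        assert lls == sorted(lls)

    def test_stable_at_extreme_eta(self, rng):
        spec = make_spec(rng, n=4, K=1)
        state = mdl.initial_state(spec)
        state.alpha[:] = 500.0
        assert np.isfinite(mdl.log_likelihood(state, spec))


class TestMicarConditional:
    def test_zero_neighbours_zero_mean(self, path3_graph=None):
        g = lattice_graph(1, 3)
        S = np.zeros((3, 2))
        mean, cov = mdl.micar_conditional(S, 1, g, np.eye(2))
        np.testing.assert_array_equal(mean, 0.0)
        np.testing.assert_allclose(cov, np.eye(2) / 2)

    def test_univariate_specialisation(self, rng):
        g = lattice_graph(2, 2)
        S = rng.standard_normal((4, 1))
        sigma2 = 0.7
        mean, cov = mdl.micar_conditional(S, 0, g, np.array([[sigma2]]))
        nbrs = g.neighbours[0]
        assert mean[0] == pytest.approx(S[nbrs, 0].mean())
        assert cov[0, 0] == pytest.approx(sigma2 / len(nbrs))

    def test_island_raises(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = AdjacencyGraph(n_areas=2, neighbours=[[], []])
        with pytest.raises(mdl.ModelError, match="island"):
            mdl.micar_conditional(np.zeros((2, 1)), 0, g, np.eye(1))

    @pytest.mark.parametrize("J,K", [(4, 2), (5, 3), (6, 1)])
    def test_matches_dense_kron_conditioning_oracle(self, J, K, rng):
        """Full conditional equals block conditioning of N(0, (Q ⊗ Σ⁻¹)⁻)."""
        g = lattice_graph(2, J // 2) if J % 2 == 0 else lattice_graph(1, J)
        S = rng.standard_normal((g.n_areas, K))
        A = rng.standard_normal((K, K)) * 0.4
        Sigma = A @ A.T + np.eye(K)
        from cvdmap.spatial_graph import icar_structure

        Q = icar_structure(g).Q
        P = np.kron(Q, np.linalg.inv(Sigma))  # vec ordering: rows of S stacked
        for j in range(g.n_areas):
            if not g.neighbours[j]:
                continue
            idx = slice(j * K, (j + 1) * K)
            rest = [r for r in range(g.n_areas * K) if not (j * K <= r < (j + 1) * K)]
            Pjj = P[idx, idx]
            Pjr = P[idx, :][:, rest]
            s_rest = np.delete(S.reshape(-1), np.arange(j * K, (j + 1) * K))
            mean_oracle = -np.linalg.solve(Pjj, Pjr @ s_rest)
            cov_oracle = np.linalg.inv(Pjj)
            mean, cov = mdl.micar_conditional(S, j, g, Sigma)
            np.testing.assert_allclose(mean, mean_oracle, atol=1e-10)
            np.testing.assert_allclose(cov, cov_oracle, atol=1e-10)


class TestUpdatePrecision:
    def test_zero_effects_conjugate_null(self, rng, grid33):
        from cvdmap.spatial_graph import icar_structure

        ic = icar_structure(grid33)
        K = 2
        draws = np.array(
            [
                mdl.update_precision(
                    np.zeros((9, K)), K, np.eye(K), "structured", rng, icar=ic
                )
                for _ in range(4000)
            ]
        )
        df_star = K + ic.rank
        np.testing.assert_allclose(draws.mean(axis=0), df_star * np.eye(K), atol=0.3)

    def test_structured_crossprod_is_edge_differences(self, rng, grid33):
        from cvdmap.spatial_graph import icar_structure

        ic = icar_structure(grid33)
        S = rng.standard_normal((9, 2))
        direct = sum(
            np.outer(S[a] - S[b], S[a] - S[b]) for a, b in grid33.edges()
        )
        np.testing.assert_allclose(S.T @ ic.Q @ S, direct, atol=1e-10)

    def test_k1_reduces_to_gamma(self, rng):
        """Scalar Wishart draws follow Gamma(df/2, 2*scale)."""
        from scipy import stats

        g = lattice_graph(1, 4)
        from cvdmap.spatial_graph import icar_structure

        ic = icar_structure(g)
        V = rng.standard_normal((4, 1))
        draws = np.array(
            [
                mdl.update_precision(V, 1.0, np.eye(1), "unstructured", rng)
                for _ in range(3000)
            ]
        ).ravel()
        df_star = 1.0 + 4
        scale_star = 1.0 / (1.0 + float((V.T @ V).item()))
        ks = stats.kstest(draws, stats.gamma(a=df_star / 2, scale=2 * scale_star).cdf)
        assert ks.pvalue > 0.01

    def test_unknown_kind(self, rng):
        with pytest.raises(mdl.ModelError):
            mdl.update_precision(np.zeros((3, 1)), 1, np.eye(1), "magic", rng)


class TestRecenter:
    def test_already_centred_unchanged(self, rng):
        spec = make_spec(rng)
        state = random_state(rng, spec)
        state.S -= state.S.mean(axis=0)
        before = state.S.copy()
        mdl.recenter(state, spec)
        np.testing.assert_allclose(state.S, before, atol=1e-12)

    def test_constant_column_moves_to_alpha(self, rng):
        spec = make_spec(rng)
        state = random_state(rng, spec)
        state.S[:] = 0.0
        state.S[:, 0] = 3.0
        a0 = state.alpha[0]
        mdl.recenter(state, spec)
        np.testing.assert_allclose(state.S[:, 0], 0.0, atol=1e-12)
        assert state.alpha[0] == pytest.approx(a0 + 3.0)

    def test_linear_predictor_invariant(self, rng):
        spec = make_spec(rng)
        state = random_state(rng, spec)
        eta0 = mdl.linear_predictor(state, spec)
        mdl.recenter(state, spec)
        np.testing.assert_allclose(mdl.linear_predictor(state, spec), eta0, atol=1e-12)
        assert abs(state.S.sum(axis=0)).max() < 1e-10

    def test_islands_stay_zero(self, rng):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = AdjacencyGraph(n_areas=3, neighbours=[[1], [0], []])
        spec = mdl.ModelSpec(
            Y=np.ones((4, 1)), X=np.empty((4, 0)),
            area=np.array([0, 1, 1, 0]), graph=g,
        )
        state = mdl.initial_state(spec)
        state.S[:, 0] = [1.0, 2.0, 0.0]
        mdl.recenter(state, spec)
        assert state.S[2, 0] == 0.0
        assert abs(state.S[:2, 0].sum()) < 1e-12


class TestMcmc:
    def test_fixed_seed_bit_identical(self, rng):
        spec = make_spec(rng, n=50)
        s1 = mdl.initial_state(spec)
        s2 = mdl.initial_state(spec)
        r1, r2 = np.random.default_rng(4), np.random.default_rng(4)
        for _ in range(5):
            mdl.mcmc_step(s1, spec, r1)
            mdl.mcmc_step(s2, spec, r2)
        np.testing.assert_array_equal(s1.alpha, s2.alpha)
        np.testing.assert_array_equal(s1.S, s2.S)
        np.testing.assert_array_equal(s1.Sigma_v, s2.Sigma_v)

    def test_empty_district_v_follows_prior(self):
        """In districts with no data, V draws satisfy E[V Vᵀ] = E[Σ_v]."""
        rng = np.random.default_rng(100)
        g = lattice_graph(4, 4)
        n = 60
        Y = (rng.random((n, 2)) < 0.4).astype(float)
        area = np.zeros(n, dtype=int)  # everyone in district 1
        spec = mdl.ModelSpec(Y=Y, X=np.empty((n, 0)), area=area, graph=g)
        state = mdl.initial_state(spec)
        vv = []
        sig = []
        for it in range(3000):
            mdl.mcmc_step(state, spec, rng)
            if it > 200:
                vv.append(np.einsum("jk,jl->kl", state.V[1:], state.V[1:]) / 15)
                sig.append(state.Sigma_v)
        vv, sig = np.mean(vv, axis=0), np.mean(sig, axis=0)
        np.testing.assert_allclose(vv, sig, rtol=0.15, atol=0.02)

    def test_intercept_only_nonspatial_recovers_prevalence(self):
        """Posterior median of logistic(α) within ±0.03 of the true 0.3."""
        rng = np.random.default_rng(17)
        g = lattice_graph(1, 2)
        n = 2000
        Y = (rng.random((n, 1)) < 0.3).astype(float)
        spec = mdl.ModelSpec(
            Y=Y, X=np.empty((n, 0)), area=np.zeros(n, dtype=int),
            graph=g, spatial=False,
        )
        cfg = mdl.McmcConfig(chains=2, iterations=800, burnin=300, thin=1, seed=2)
        samples = mdl.run_mcmc(spec, cfg)
        med = np.median(1 / (1 + np.exp(-samples.pooled("alpha")[:, 0])))
        assert abs(med - 0.3) < 0.03

    def test_nonspatial_alpha_posterior_matches_quadrature(self):
        """K=1, no covariates: MCMC α posterior equals the 1-D quadrature posterior."""
        rng = np.random.default_rng(23)
        n, p_true = 400, 0.35
        y = (rng.random(n) < p_true).astype(float)
        g = lattice_graph(1, 2)
        spec = mdl.ModelSpec(
            Y=y[:, None], X=np.empty((n, 0)), area=np.zeros(n, dtype=int),
            graph=g, spatial=False,
        )
        cfg = mdl.McmcConfig(chains=2, iterations=4000, burnin=500, thin=1, seed=8)
        samples = mdl.run_mcmc(spec, cfg)
        draws = samples.pooled("alpha")[:, 0]
        # dense numerical integration of the flat-prior logistic posterior
        grid = np.linspace(-3, 3, 20001)
        s = y.sum()
        loglik = s * grid - n * np.logaddexp(0.0, grid)
        w = np.exp(loglik - loglik.max())
        w /= np.trapezoid(w, grid)
        mean_q = np.trapezoid(grid * w, grid)
        var_q = np.trapezoid((grid - mean_q) ** 2 * w, grid)
        se = np.sqrt(var_q / samples.ess["alpha[disease_1]"])
        assert abs(draws.mean() - mean_q) < 5 * se + 0.005
        assert abs(draws.std() - np.sqrt(var_q)) < 0.15 * np.sqrt(var_q)

    def test_metropolis_cross_check(self):
        """Adaptive RW Metropolis and PG Gibbs target the same posterior."""
        rng = np.random.default_rng(31)
        g = lattice_graph(2, 2)
        n = 300
        area = rng.integers(0, 4, n)
        Y = (rng.random((n, 1)) < 0.4).astype(float)
        spec = mdl.ModelSpec(Y=Y, X=np.empty((n, 0)), area=area, graph=g)
        pg = mdl.run_mcmc(spec, mdl.McmcConfig(
            chains=1, iterations=3000, burnin=1000, thin=1, seed=5))
        met = mdl.run_mcmc(spec, mdl.McmcConfig(
            chains=1, iterations=6000, burnin=3000, thin=1, seed=6,
            sampler="metropolis"))
        a_pg = pg.pooled("alpha")[:, 0]
        a_met = met.pooled("alpha")[:, 0]
        assert abs(a_pg.mean() - a_met.mean()) < 0.1
        assert abs(a_pg.std() - a_met.std()) < 0.08

    def test_burnin_must_be_smaller(self):
        with pytest.raises(mdl.ModelError):
            mdl.McmcConfig(iterations=100, burnin=100)


class TestDesign:
    def test_recode_collapses_levels(self):
        import pandas as pd

        frame = pd.DataFrame({"smoking": ["never", "ex_smoker", "current", "never"]})
        X3, info3 = mdl.build_design(frame, ["smoking"], references={"smoking": "never"})
        X2, info2 = mdl.build_design(
            frame, ["smoking"], references={"smoking": "never"},
            recode={"smoking": {"ex_smoker": "ever", "current": "ever"}},
        )
        assert info3.names == ["smoking=current", "smoking=ex_smoker"]
        assert info2.names == ["smoking=ever"]
        np.testing.assert_array_equal(X2[:, 0], [0, 1, 1, 0])

    def test_numeric_column_passes_through(self, rng):
        import pandas as pd

        frame = pd.DataFrame({"age": rng.uniform(15, 80, 10)})
        X, info = mdl.build_design(frame, ["age"])
        np.testing.assert_array_equal(X[:, 0], frame["age"])
        assert info.terms["age"] == ["age"]

    def test_unknown_reference_rejected(self):
        import pandas as pd

        frame = pd.DataFrame({"sex": ["male", "female"]})
        with pytest.raises(mdl.ModelError):
            mdl.build_design(frame, ["sex"], references={"sex": "other"})


class TestSummaries:
    def _tiny_samples(self, spec, beta_vals):
        C, T = 1, 41  # odd draw count: the sample median is an order statistic
        return mdl.PosteriorSamples(
            alpha=np.zeros((C, T, spec.K)),
            beta=np.broadcast_to(beta_vals, (C, T, spec.p, spec.K)).copy(),
            S=np.zeros((C, T, spec.J, spec.K)),
            V=np.zeros((C, T, spec.J, spec.K)),
            Sigma_s=np.broadcast_to(np.eye(spec.K), (C, T, spec.K, spec.K)).copy(),
            Sigma_v=np.broadcast_to(np.eye(spec.K), (C, T, spec.K, spec.K)).copy(),
            config=mdl.McmcConfig(chains=1, iterations=2, burnin=1, thin=1),
        )

    def test_zero_beta_gives_unit_or(self, rng):
        spec = make_spec(rng, p=2)
        samples = self._tiny_samples(spec, np.zeros((spec.p, spec.K)))
        t = mdl.posterior_or_table(samples, spec)
        np.testing.assert_allclose(t["or_median"], 1.0)
        np.testing.assert_allclose(t["or_low"], 1.0)

    def test_constant_log2_beta(self, rng):
        spec = make_spec(rng, p=1)
        samples = self._tiny_samples(spec, np.full((1, spec.K), math.log(2.0)))
        t = mdl.posterior_or_table(samples, spec)
        np.testing.assert_allclose(t["or_median"], 2.0, rtol=1e-12)

    def test_reference_levels_reported_as_one(self, rng):
        import pandas as pd

        frame = pd.DataFrame({"grp": ["a", "b", "c", "a"] * 5})
        X, info = mdl.build_design(frame, ["grp"], references={"grp": "a"})
        spec = mdl.ModelSpec(
            Y=(np.arange(20) % 2).astype(float)[:, None], X=X,
            area=np.zeros(20, dtype=int), graph=lattice_graph(1, 2),
            design_info=info,
        )
        samples = self._tiny_samples(spec, np.zeros((2, 1)))
        t = mdl.posterior_or_table(samples, spec)
        ref = t[t["reference"]]
        assert list(ref["level"]) == ["a"]

    def test_spatial_odds_unit_when_effects_zero(self, rng):
        spec = make_spec(rng)
        samples = self._tiny_samples(spec, np.zeros((spec.p, spec.K)))
        so = mdl.spatial_odds(samples, spec)
        np.testing.assert_allclose(so["odds_median"], 1.0)

    def test_median_commutes_with_exp(self, rng):
        spec = make_spec(rng, J=4, K=1)
        samples = self._tiny_samples(spec, np.zeros((spec.p, spec.K)))
        samples.S = rng.standard_normal(samples.S.shape)
        so = mdl.spatial_odds(samples, spec)
        U = samples.pooled("S") + samples.pooled("V")
        for j in range(spec.J):
            assert so.loc[so["district"] == j + 1, "odds_median"].iloc[0] == pytest.approx(
                np.exp(np.median(U[:, j, 0])), rel=1e-9
            )
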