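"""Gibbs sampler correctness: conditionals, objective, chains, imputation."""

import numpy as np
import pytest

from tphpmf.engine import (
    EngineConfig,
    LatentState,
    LevelData,
    LevelMaps,
    build_levels,
    conditional_update_s,
    conditional_update_t,
    gibbs_sweep,
    impute,
    init_state,
    objective,
    run_chain,
)
from tphpmf.hierarchy import TaxonDistanceMatrix, build_hierarchy
from tphpmf.preprocessing import CountMatrix


def _single_level(Y, obs):
    data = [LevelData(np.where(obs, Y, 0.0), obs, [f"t{j}" for j in range(Y.shape[1])])]
    maps = LevelMaps(parents=[None], children=[None])
    return data, maps


def _three_level_chain(n=2, sizes=(2, 3, 4), obs_frac=0.0, seed=0):
    """Small 3-level setup with random parent maps and optional data."""
    rng = np.random.default_rng(seed)
    data, parents, children = [], [None], []
    for li, m in enumerate(sizes):
        Y = rng.normal(2, 1, (n, m))
        obs = rng.random((n, m)) < obs_frac
        data.append(LevelData(np.where(obs, Y, 0.0), obs, [f"c{li}_{j}" for j in range(m)]))
        if li > 0:
            parents.append(rng.integers(0, sizes[li - 1], m))
    for li in range(len(sizes) - 1):
        children.append(
            [np.flatnonzero(parents[li + 1] == c) for c in range(sizes[li])]
        )
    children.append(None)
    return data, LevelMaps(parents=parents, children=children)


class TestInitState:
    def test_deterministic_given_seed(self):
        data, _ = _three_level_chain()
        cfg = EngineConfig(latent_dim=3, n_samples=2, burn_in=0, seed=9)
        a, b = init_state(cfg, data), init_state(cfg, data)
        for x, y in zip(a.S_levels + a.T_levels, b.S_levels + b.T_levels):
            np.testing.assert_array_equal(x, y)

    def test_shapes_and_prior_scale(self):
        data, _ = _three_level_chain(n=1, sizes=(1, 1, 1))
        cfg = EngineConfig(latent_dim=1, sigma_s2=4.0, n_samples=2, burn_in=0, seed=0)
        st = init_state(cfg, data)
        assert all(s.shape == (1, 1) for s in st.S_levels)
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 2.0, 10000)
        st_many = [init_state(cfg, data, rng=np.random.default_rng(i)) for i in range(200)]
        sds = np.std([s.S_levels[0][0, 0] for s in st_many])
        assert sds < 3 * 2.0 and np.isfinite(sds)
        assert np.isfinite(draws).all()


class TestConditionals:
    def test_prior_reduction_no_data(self):
        cfg = EngineConfig(latent_dim=2, sigma_t2=2.5, n_samples=2, burn_in=0, seed=0)
        data, maps = _single_level(np.zeros((3, 3)), np.zeros((3, 3), bool))
        st = init_state(cfg, data)
        mean = conditional_update_t(0, 0, st, data, maps, cfg, rng=None)
        np.testing.assert_allclose(mean, 0.0)
        rng = np.random.default_rng(1)
        draws = np.array(
            [conditional_update_t(0, 0, st, data, maps, cfg, rng) for _ in range(10000)]
        )
        np.testing.assert_allclose(draws.mean(axis=0), 0.0, atol=0.1)
        np.testing.assert_allclose(draws.var(axis=0), 2.5, rtol=0.1)

    def test_one_observation_closed_form(self):
        # D=1, y with s=1, sigma2=sigma_t2=1 -> mean y/2, variance 1/2
        cfg = EngineConfig(latent_dim=1, n_samples=2, burn_in=0, seed=0)
        y = 1.7
        data, maps = _single_level(np.array([[y]]), np.array([[True]]))
        st = LatentState([np.array([[1.0]])], [np.array([[0.0]])])
        mean = conditional_update_t(0, 0, st, data, maps, cfg, rng=None)
        np.testing.assert_allclose(mean, y / 2)
        rng = np.random.default_rng(2)
        draws = np.array(
            [conditional_update_t(0, 0, st, data, maps, cfg, rng)[0] for _ in range(20000)]
        )
        np.testing.assert_allclose(draws.var(), 0.5, rtol=0.05)

    def test_interior_s_chain_mean(self):
        # no data: interior s conditional mean is the average of its
        # neighbours with variance sigma_s2/2
        cfg = EngineConfig(latent_dim=1, sigma_s2=1.0, n_samples=2, burn_in=0, seed=0)
        data, maps = _three_level_chain(n=1, sizes=(1, 1, 1))
        st = LatentState(
            [np.array([[2.0]]), np.array([[0.0]]), np.array([[4.0]])],
            [np.zeros((1, 1)) for _ in range(3)],
        )
        mean = conditional_update_s(0, 1, st, data, maps, cfg, rng=None)
        np.testing.assert_allclose(mean, 3.0)

    @pytest.mark.parametrize("kind", ["t", "s"])
    def test_stationary_mean_zeroes_objective_gradient(self, kind):
        """The conditional mean must be the stationary (ridge) point of the
        per-level objective E^h: its finite-difference gradient vanishes."""
        cfg = EngineConfig(
            latent_dim=3, sigma2=0.7, sigma_s2=1.3, sigma_t2=0.9,
            n_samples=2, burn_in=0, seed=4,
        )
        data, maps = _three_level_chain(n=4, sizes=(2, 3, 5), obs_frac=0.8, seed=4)
        st = init_state(cfg, data)
        for h in range(3):
            if kind == "t":
                idx = 1 % data[h].values.shape[1]
                mean = conditional_update_t(idx, h, st, data, maps, cfg, rng=None)
                st.T_levels[h][idx] = mean
                block = ("T", h, idx)
            else:
                idx = 2
                mean = conditional_update_s(idx, h, st, data, maps, cfg, rng=None)
                st.S_levels[h][idx] = mean
                block = ("S", h, idx)
            grad = _fd_gradient(st, block, data, maps, cfg)
            np.testing.assert_allclose(grad, 0.0, atol=1e-5)

    def test_lambda_to_zero_recovers_plain_pmf_conditional(self):
        # huge prior variance removes the ridge: conditional mean tends to
        # the least-squares solution
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 1, (6, 4))
        obs = np.ones((6, 4), bool)
        data, maps = _single_level(Y, obs)
        cfg = EngineConfig(
            latent_dim=2, sigma2=1.0, sigma_t2=1e10, sigma_s2=1e10,
            n_samples=2, burn_in=0, seed=0,
        )
        st = init_state(EngineConfig(latent_dim=2, n_samples=2, burn_in=0, seed=3), data)
        S = st.S_levels[0]
        mean = conditional_update_t(1, 0, st, data, maps, cfg, rng=None)
        lsq, *_ = np.linalg.lstsq(S, Y[:, 1], rcond=None)
        np.testing.assert_allclose(mean, lsq, atol=1e-6)


def _fd_gradient(state, block, data, maps, cfg, eps=1e-6):
    kind, h, idx = block
    arr = state.T_levels[h] if kind == "T" else state.S_levels[h]
    grad = np.zeros(arr.shape[1])
    for d in range(arr.shape[1]):
        orig = arr[idx, d]
        arr[idx, d] = orig + eps
        up = objective(state, data, maps, cfg)[h]
        arr[idx, d] = orig - eps
        dn = objective(state, data, maps, cfg)[h]
        arr[idx, d] = orig
        grad[d] = (up - dn) / (2 * eps)
    return grad


class TestObjective:
    def test_all_zero_state_no_data(self):
        data, maps = _single_level(np.zeros((2, 2)), np.zeros((2, 2), bool))
        cfg = EngineConfig(latent_dim=2, n_samples=2, burn_in=0, seed=0)
        st = LatentState([np.zeros((2, 2))], [np.zeros((2, 2))])
        np.testing.assert_allclose(objective(st, data, maps, cfg), 0.0)

    def test_single_observation_squared(self):
        y = 2.3
        data, maps = _single_level(np.array([[y]]), np.array([[True]]))
        cfg = EngineConfig(latent_dim=1, n_samples=2, burn_in=0, seed=0)
        st = LatentState([np.zeros((1, 1))], [np.zeros((1, 1))])
        np.testing.assert_allclose(objective(st, data, maps, cfg), [y**2])


class TestChain:
    def test_retained_count_arithmetic(self):
        data, maps = _single_level(np.ones((2, 2)), np.ones((2, 2), bool))
        cfg = EngineConfig(
            latent_dim=1, n_samples=10, burn_in=4, thin=2, seed=0
        )
        chain = run_chain(data, maps, cfg)
        assert len(chain.retained_states) == 3 == cfg.n_retained

    @pytest.mark.parametrize(
        "n_samples,burn_in,thin", [(7, 2, 1), (20, 5, 3), (15, 0, 4)]
    )
    def test_retained_count_formula(self, n_samples, burn_in, thin):
        data, maps = _single_level(np.ones((2, 2)), np.ones((2, 2), bool))
        cfg = EngineConfig(
            latent_dim=1, n_samples=n_samples, burn_in=burn_in, thin=thin, seed=0
        )
        chain = run_chain(data, maps, cfg)
        assert len(chain.retained_states) == (n_samples - burn_in) // thin

    def test_sweep_deterministic_given_seed(self):
        data, maps = _three_level_chain(n=3, sizes=(2, 3, 4), obs_frac=0.7, seed=1)
        cfg = EngineConfig(latent_dim=2, n_samples=2, burn_in=0, seed=5)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            st = init_state(cfg, data, rng)
            gibbs_sweep(st, data, maps, cfg, rng)
            out.append(st)
        for a, b in zip(out[0].T_levels, out[1].T_levels):
            np.testing.assert_array_equal(a, b)

    def test_prior_sampling_no_data(self):
        """With no observations the chain targets the hierarchical prior:
        marginal variance at depth h is h * sigma^2 for the sample chain."""
        data, maps = _three_level_chain(n=1, sizes=(1, 1, 1), obs_frac=0.0, seed=0)
        cfg = EngineConfig(
            latent_dim=1, sigma_s2=1.0, sigma_t2=1.0,
            n_samples=5000, burn_in=500, thin=1, seed=17,
        )
        chain = run_chain(data, maps, cfg)
        for h, expected in enumerate([1.0, 2.0, 3.0]):
            draws = np.array([st.S_levels[h][0, 0] for st in chain.retained_states])
            assert abs(draws.mean()) < 0.15
            np.testing.assert_allclose(draws.var(), expected, rtol=0.25)

    def test_two_seeds_agree_on_posterior_mean(self):
        rng = np.random.default_rng(12)
        S = rng.normal(0, 1, (8, 2))
        T = rng.normal(0, 1, (10, 2))
        Y = S @ T.T + 0.1 * rng.normal(size=(8, 10))
        obs = rng.random((8, 10)) < 0.7
        data, maps = _single_level(Y, obs)
        means = []
        for seed in (1, 2):
            cfg = EngineConfig(
                latent_dim=2, sigma2=0.25, n_samples=800, burn_in=200, thin=1, seed=seed
            )
            chain = run_chain(data, maps, cfg)
            vals = np.array(
                [st.S_levels[0][0] @ st.T_levels[0][0] for st in chain.retained_states]
            )
            nb = 40
            bm = vals[: len(vals) // nb * nb].reshape(nb, -1).mean(axis=1)
            means.append((vals.mean(), bm.std(ddof=1) / np.sqrt(nb)))
        (m1, se1), (m2, se2) = means
        assert abs(m1 - m2) < 3 * np.hypot(se1, se2) + 1e-12


class _PlainPMFGibbs:
    """Independent single-level PMF Gibbs sampler (test oracle).

    Written from the model directly: s_n ~ N(0, ss2 I), t_m ~ N(0, st2 I),
    y_nm ~ N(s_n' t_m, s2) on observed entries; standard normal-normal
    conjugate updates, no shared code with the engine.
    """

    def __init__(self, Y, obs, d, s2, ss2, st2, seed):
        self.Y, self.obs, self.d = Y, obs, d
        self.s2, self.ss2, self.st2 = s2, ss2, st2
        self.rng = np.random.default_rng(seed)
        n, m = Y.shape
        self.S = self.rng.normal(0, np.sqrt(ss2), (n, d))
        self.T = self.rng.normal(0, np.sqrt(st2), (m, d))

    def _draw(self, A, y, prior_var):
        prec = A.T @ A / self.s2 + np.eye(self.d) / prior_var
        cov = np.linalg.inv(prec)
        mean = cov @ (A.T @ y / self.s2)
        return self.rng.multivariate_normal(mean, cov)

    def sweep(self):
        n, m = self.Y.shape
        for mm in range(m):
            r = np.flatnonzero(self.obs[:, mm])
            self.T[mm] = self._draw(self.S[r], self.Y[r, mm], self.st2)
        for nn in range(n):
            c = np.flatnonzero(self.obs[nn])
            self.S[nn] = self._draw(self.T[c], self.Y[nn, c], self.ss2)

    def posterior_mean(self, entries, n_samples, burn_in):
        acc = np.zeros(len(entries))
        kept = 0
        for i in range(n_samples):
            self.sweep()
            if i >= burn_in:
                acc += np.array([self.S[n] @ self.T[m] for n, m in entries])
                kept += 1
        return acc / kept


class TestPlainPMFEquivalence:
    def test_single_level_engine_matches_independent_oracle(self):
        rng = np.random.default_rng(21)
        S = rng.normal(0, 1, (6, 2))
        T = rng.normal(0, 1, (8, 2))
        Y = S @ T.T + 0.2 * rng.normal(size=(6, 8))
        obs = rng.random((6, 8)) < 0.75
        obs[0, 0] = False
        entries = [(0, 0), (1, 2)]
        obs[1, 2] = False
        data, maps = _single_level(Y, obs)
        cfg = EngineConfig(
            latent_dim=2, sigma2=0.25, sigma_s2=1.0, sigma_t2=1.0,
            n_samples=1500, burn_in=300, thin=1, seed=3,
        )
        chain = run_chain(data, maps, cfg)
        vals = np.array(
            [
                [st.S_levels[0][n] @ st.T_levels[0][m] for n, m in entries]
                for st in chain.retained_states
            ]
        )
        engine_mean = vals.mean(axis=0)
        nb = 40
        bm = vals[: len(vals) // nb * nb].reshape(nb, -1, 2).mean(axis=1)
        engine_se = bm.std(axis=0, ddof=1) / np.sqrt(nb)

        oracle = _PlainPMFGibbs(Y, obs, 2, 0.25, 1.0, 1.0, seed=7)
        oracle_runs = np.array(
            [
                _PlainPMFGibbs(Y, obs, 2, 0.25, 1.0, 1.0, seed=7 + k).posterior_mean(
                    entries, 700, 200
                )
                for k in range(3)
            ]
        )
        oracle_mean = oracle_runs.mean(axis=0)
        oracle_se = oracle_runs.std(axis=0, ddof=1) / np.sqrt(3)
        tol = 3 * np.sqrt(engine_se**2 + oracle_se**2) + 0.02
        assert np.all(np.abs(engine_mean - oracle_mean) < tol)


class TestImpute:
    def test_single_state_inner_product(self):
        data, maps = _single_level(np.ones((2, 2)), np.ones((2, 2), bool))
        from tphpmf.preprocessing import LogMatrix

        lm = LogMatrix(np.full((2, 2), 1.0), ["s0", "s1"], ["t0", "t1"])
        cfg = EngineConfig(latent_dim=1, n_samples=2, burn_in=1, thin=1, seed=0)
        chain = run_chain(data, maps, cfg)
        assert len(chain.retained_states) == 1
        st = chain.retained_states[0]
        flags = np.array([[True, False], [False, False]])
        res = impute(chain, flags, lm)
        expected = max(float(st.S_levels[0][0] @ st.T_levels[0][0]), lm.zero_value)
        np.testing.assert_allclose(res.imputed.values[0, 0], expected)

    def test_no_flags_identity(self):
        from tphpmf.preprocessing import LogMatrix

        data, maps = _single_level(np.ones((2, 2)), np.ones((2, 2), bool))
        lm = LogMatrix(np.full((2, 2), 1.0), ["s0", "s1"], ["t0", "t1"])
        cfg = EngineConfig(latent_dim=1, n_samples=4, burn_in=1, thin=1, seed=0)
        chain = run_chain(data, maps, cfg)
        res = impute(chain, np.zeros((2, 2), bool), lm)
        np.testing.assert_array_equal(res.imputed.values, lm.values)

    def test_low_rank_recovery_beats_zero_fill(self):
        rng = np.random.default_rng(31)
        D_true, N, M = 3, 40, 60
        S = rng.normal(0, 1, (N, D_true))
        T = rng.normal(0, 1, (M, D_true))
        Y = 3.0 + (S @ T.T) / np.sqrt(D_true) + 0.1 * rng.normal(size=(N, M))
        flags = rng.random((N, M)) < 0.7
        from tphpmf.preprocessing import LogMatrix

        lm = LogMatrix(np.where(flags, np.log10(1.01), Y), [f"s{i}" for i in range(N)],
                       [f"t{j}" for j in range(M)], missing_mask=flags)
        data = [LevelData(lm.values, ~flags, lm.taxon_ids)]
        maps = LevelMaps(parents=[None], children=[None])
        cfg = EngineConfig(latent_dim=5, n_samples=120, burn_in=40, thin=2, seed=9)
        chain = run_chain(data, maps, cfg)
        res = impute(chain, flags, lm)
        mse_imp = np.mean((res.imputed.values[flags] - Y[flags]) ** 2)
        mse_zero = np.mean((np.log10(1.01) - Y[flags]) ** 2)
        assert mse_imp < mse_zero / 2

    def test_monotone_information(self):
        """MSE does not get worse (beyond noise) as more data is observed."""
        rng = np.random.default_rng(41)
        N, M, D_true = 30, 40, 2
        S = rng.normal(0, 1, (N, D_true))
        T = rng.normal(0, 1, (M, D_true))
        Y = 2.5 + (S @ T.T) / np.sqrt(D_true) + 0.1 * rng.normal(size=(N, M))
        from tphpmf.preprocessing import LogMatrix

        mses = []
        for frac_obs in (0.3, 0.6, 0.9):
            flags = rng.random((N, M)) > frac_obs
            lm = LogMatrix(np.where(flags, np.log10(1.01), Y),
                           [f"s{i}" for i in range(N)], [f"t{j}" for j in range(M)],
                           missing_mask=flags)
            data = [LevelData(lm.values, ~flags, lm.taxon_ids)]
            maps = LevelMaps(parents=[None], children=[None])
            cfg = EngineConfig(latent_dim=4, n_samples=100, burn_in=30, thin=2, seed=2)
            chain = run_chain(data, maps, cfg)
            res = impute(chain, flags, lm)
            mses.append(float(np.mean((res.imputed.values[flags] - Y[flags]) ** 2)))
        assert mses[2] < mses[0] * 1.2

    def test_empty_chain_rejected(self):
        from tphpmf.preprocessing import LogMatrix

        lm = LogMatrix(np.ones((1, 1)), ["s0"], ["t0"])
        cfg = EngineConfig(latent_dim=1, n_samples=2, burn_in=1, thin=1, seed=0)
        from tphpmf.engine import GibbsChain

        with pytest.raises(ValueError, match="empty chain"):
            impute(GibbsChain([], cfg), np.ones((1, 1), bool), lm)


class TestBuildLevels:
    def test_four_layers_with_hierarchy(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((6, 2))
        Dm = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dm = TaxonDistanceMatrix(Dm, [f"t{j}" for j in range(6)])
        from tphpmf.hierarchy import default_cut_heights

        h = build_hierarchy(dm, default_cut_heights(dm))
        counts = CountMatrix(
            rng.gamma(2, 100, (4, 6)), [f"s{i}" for i in range(4)],
            [f"t{j}" for j in range(6)],
        )
        flags = np.zeros((4, 6), bool)
        data, maps = build_levels(counts, flags, h, 1.01)
        assert len(data) == 4  # F, G, S, taxa
        assert maps.parents[0] is None and maps.children[-1] is None
        # every parent index valid; children consistent with parents
        for lvl in range(1, 4):
            p = maps.parents[lvl]
            assert p.max() < data[lvl - 1].values.shape[1]
            for c, kids in enumerate(maps.children[lvl - 1]):
                assert all(p[k] == c for k in kids)

    def test_no_hierarchy_single_level(self):
        counts = CountMatrix(np.ones((2, 3)), ["a", "b"], ["x", "y", "z"])
        data, maps = build_levels(counts, np.zeros((2, 3), bool), None, 1.01)
        assert len(data) == 1 and maps.parents == [None]
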