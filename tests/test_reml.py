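import numpy as np
import pytest

from gxp import lowrank as lr
from gxp.grm import compute_grm
from gxp.mixedmodel import fit_bivariate_greml, fit_greml, fit_rnm
from gxp.reml import reml_loglik_dense
from gxp.synthpop import TruthModel, simulate_genotypes, simulate_phenotype


@pytest.fixture(scope="module")
def small_problem():
    G = simulate_genotypes((60, 60), 150, fst=0.02, seed=201)
    ph = simulate_phenotype(G, TruthModel(h2=0.5, fst=0.02), seed=202)
    return G, compute_grm(G), ph


class TestLoglikAgainstBruteForce:
    """The production solvers must reproduce the dense-oracle restricted
    log-likelihood (explicit inverse, determinants, fixed-effect projection)."""

    def test_baseline_spectral_vs_oracle(self, small_problem):
        G, A, ph = small_problem
        fit = fit_greml(ph.y, A, method="spectral")
        n = G.n
        V = A.values * fit.theta[0] + np.eye(n) * fit.theta[1]
        oracle = reml_loglik_dense(ph.y, np.ones((n, 1)), V)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_gxp_dense_vs_oracle(self, small_problem, rng):
        G, A, ph = small_problem
        c = rng.standard_normal(G.n)
        c = (c - c.mean()) / c.std()
        fit = fit_rnm(ph.y, A, c, mode="gxp")
        n = G.n
        Av = A.values
        V = (fit.theta[0] * Av
             + fit.theta[1] * Av * np.outer(c, c)
             + fit.theta[2] * Av * (c[:, None] + c[None, :])
             + fit.theta[3] * np.eye(n))
        oracle = reml_loglik_dense(ph.y, np.ones((n, 1)), V)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_bivariate_vs_oracle(self, small_problem):
        G, A, ph = small_problem
        idx1 = np.arange(60)
        idx2 = np.arange(60, 120)
        fit = fit_bivariate_greml(ph.y[idx1], ph.y[idx2], A, idx1, idx2)
        Av = A.values
        n = 120
        d1 = np.concatenate([np.ones(60), np.zeros(60)])
        d2 = 1 - d1
        V = (fit.theta[0] * Av * np.outer(d1, d1)
             + fit.theta[1] * Av * np.outer(d2, d2)
             + fit.theta[2] * Av * (np.outer(d1, d2) + np.outer(d2, d1))
             + fit.theta[3] * np.diag(d1) + fit.theta[4] * np.diag(d2))
        X = np.column_stack([d1, d2])
        oracle = reml_loglik_dense(ph.y, X, V)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)


@pytest.fixture(scope="module")
def wide_problem():
    G = simulate_genotypes((100, 100), 50, fst=0.02, seed=211)
    ph = simulate_phenotype(G, TruthModel(h2=0.5, fst=0.02), seed=212)
    return G, compute_grm(G), ph, lr.standardized_genotypes(G)


class TestReducedBasisEquivalence:
    """The reduced-basis (low-rank) path is an exact reformulation: its
    restricted log-likelihoods and estimates match the dense path."""

    def test_baseline(self, wide_problem):
        G, A, ph, Gs = wide_problem
        dense = fit_greml(ph.y, A, method="dense")
        red = lr.fit_greml_lowrank(ph.y, Gs)
        assert red.loglik == pytest.approx(dense.loglik, abs=1e-6)
        np.testing.assert_allclose(red.theta, dense.theta, atol=1e-4)

    def test_gxp(self, wide_problem, rng):
        G, A, ph, Gs = wide_problem
        c = rng.standard_normal(G.n)
        c = (c - c.mean()) / c.std()
        dense = fit_rnm(ph.y, A, c, mode="gxp")
        red = lr.fit_gxp_lowrank(ph.y, Gs, c)
        assert red.loglik == pytest.approx(dense.loglik, abs=1e-6)

    def test_bivariate_and_constrained(self, wide_problem):
        G, A, ph, Gs = wide_problem
        idx1 = np.arange(100)
        idx2 = np.arange(100, 200)
        for kw in (dict(), dict(constrain_rg_one=True)):
            dense = fit_bivariate_greml(ph.y[idx1], ph.y[idx2], A, idx1, idx2,
                                        **kw)
            red = lr.fit_bivariate_lowrank(ph.y[idx1], ph.y[idx2],
                                           Gs[idx1], Gs[idx2], **kw)
            assert red.loglik == pytest.approx(dense.loglik, abs=1e-5)

    def test_same_sample_spectral_vs_reduced(self, wide_problem):
        # the public same_sample fit uses the 2x2 spectral path; it must
        # agree with the reduced-basis formulation (itself dense-exact)
        G, A, ph, Gs = wide_problem
        ph2 = simulate_phenotype(G, TruthModel(h2=0.3, fst=0.02), seed=219)
        spect = fit_bivariate_greml(ph.y, ph2.y, A, layout="same_sample")
        red = lr.fit_bivariate_samesample_lowrank(ph.y, ph2.y, Gs)
        assert spect.loglik == pytest.approx(red.loglik, abs=1e-5)
        assert spect.rg == pytest.approx(red.rg, abs=1e-3)

    def test_top_pcs_match_grm_eigenvectors(self, wide_problem):
        G, A, ph, Gs = wide_problem
        from gxp.ancestry import compute_pcs
        full = compute_pcs(A, k=2)
        w, scores = lr.top_pcs_lowrank(Gs, k=2)
        np.testing.assert_allclose(w, full.eigenvalues, atol=1e-8)
        np.testing.assert_allclose(np.abs(scores), np.abs(full.scores),
                                   atol=1e-6)


class TestEngineInvariants:
    def test_loglik_trajectory_monotone(self, small_problem, rng):
        G, A, ph = small_problem
        c = rng.standard_normal(G.n)
        fit = fit_rnm(ph.y, A, c, mode="full")
        # history recorded by the engine must be non-decreasing
        from gxp.reml import LinearStructure, ai_reml
        Av = A.values
        n = G.n
        mats = [Av, Av * np.outer(c, c), Av * (c[:, None] + c[None, :]),
                np.eye(n), np.diag(c ** 2), 2 * np.diag(c)]
        vy = float(np.var(ph.y, ddof=1))
        raw = ai_reml(ph.y, np.ones((n, 1)), LinearStructure(mats),
                      [vy / 2, 0, 0, vy / 2, 0, 0])
        diffs = np.diff(raw.history)
        assert np.all(diffs >= -1e-9)

    def test_constant_covariate_collapses_to_baseline(self, small_problem):
        G, A, ph = small_problem
        base = fit_greml(ph.y, A)
        gxp = fit_rnm(ph.y, A, np.full(G.n, 2.0), mode="gxp",
                      allow_degenerate_covariate=True)
        assert gxp.loglik == pytest.approx(base.loglik, abs=1e-4)

    def test_covariate_sign_flip_symmetry(self, small_problem, rng):
        G, A, ph = small_problem
        c = rng.standard_normal(G.n)
        c = (c - c.mean()) / c.std()
        f_pos = fit_rnm(ph.y, A, c, mode="gxp")
        f_neg = fit_rnm(ph.y, A, -c, mode="gxp")
        assert f_neg.loglik == pytest.approx(f_pos.loglik, abs=1e-4)
        assert f_neg.components.var_g1 == pytest.approx(
            f_pos.components.var_g1, abs=1e-4)
        assert f_neg.components.cov_g01 == pytest.approx(
            -f_pos.components.cov_g01, abs=1e-4)

    def test_reml_solution_beats_null_point(self, small_problem):
        G, A, ph = small_problem
        fit = fit_greml(ph.y, A)
        n = G.n
        V0 = np.eye(n) * float(np.var(ph.y, ddof=1))
        ll0 = reml_loglik_dense(ph.y, np.ones((n, 1)), V0)
        assert fit.loglik >= ll0 - 1e-9
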