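import numpy as np
import pytest

from gxp.synthpop import (SelectionScenario, TruthModel, apply_selection,
                          hudson_fst, simulate_genotypes, simulate_phenotype)


class TestSimulateGenotypes:
    def test_seeded_runs_are_identical(self):
        a = simulate_genotypes((50, 50), 200, fst=0.01, seed=1)
        b = simulate_genotypes((50, 50), 200, fst=0.01, seed=1)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_dosage_domain_and_freq(self, cohort):
        G, _, _ = cohort
        assert np.all(np.isin(G.dosages, (0.0, 1.0, 2.0)))
        np.testing.assert_allclose(G.allele_freq, G.compute_freq(), atol=1e-12)

    def test_fst_recovered_by_hudson_estimator(self):
        G = simulate_genotypes((200, 200), 5000, fst=0.01, seed=7)
        # ratio-of-averages estimator with a delta-method Monte Carlo SE
        fst_hat = hudson_fst(G)
        pops = G.sample_meta["pop"].to_numpy()
        d1 = G.dosages[pops == "POP1"]
        d2 = G.dosages[pops == "POP2"]
        n1, n2 = d1.shape[0] * 2, d2.shape[0] * 2
        p1 = d1.mean(axis=0) / 2
        p2 = d2.mean(axis=0) / 2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        resid = num - fst_hat * den
        se = np.std(resid, ddof=1) / np.sqrt(len(resid)) / den.mean()
        assert abs(fst_hat - 0.01) < 3 * se

    def test_no_differentiation_limit(self):
        G = simulate_genotypes((300, 300), 2000, fst=1e-6, seed=3)
        pops = G.sample_meta["pop"].to_numpy()
        p1 = G.dosages[pops == "POP1"].mean(axis=0) / 2
        p2 = G.dosages[pops == "POP2"].mean(axis=0) / 2
        diff = p1 - p2
        assert abs(diff.mean()) < 3 * diff.std(ddof=1) / np.sqrt(len(diff))

    @pytest.mark.parametrize("kwargs", [
        dict(n_per_pop=(1, 50), L=10, fst=0.01),
        dict(n_per_pop=(50, 50), L=0, fst=0.01),
        dict(n_per_pop=(50, 50), L=10, fst=0.6),
        dict(n_per_pop=(50, 50), L=10, fst=0.01, maf_range=(0.0, 0.5)),
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            simulate_genotypes(seed=1, **kwargs)


class TestSimulatePhenotype:
    def test_heritability_of_latents(self):
        # the realized genetic variance fluctuates with the effect draw
        # (SD ~ h2*sqrt(2/L)), so average the ratio over a few draws
        G = simulate_genotypes((1000, 1000), 1000, fst=0.01, seed=11)
        ratios = []
        for seed in (12, 13, 14):
            ph = simulate_phenotype(G, TruthModel(h2=0.5), seed=seed)
            ratios.append(np.var(ph.g0) / np.var(ph.y))
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.05)

    def test_latents_reconstruct_y(self, cohort, rng):
        G, truth, _ = cohort
        c = rng.standard_normal(G.n)
        t = TruthModel(h2=0.4, var_g1_frac=0.3, var_e1_frac=0.2, fst=0.02)
        ph = simulate_phenotype(G, t, c=c, seed=55)
        np.testing.assert_allclose(ph.y, ph.mu + ph.g0 + c * ph.g1 + ph.e,
                                   atol=1e-12)

    def test_null_architecture(self, cohort):
        G, _, _ = cohort
        ph = simulate_phenotype(G, TruthModel(h2=0.0, fst=0.02), seed=13)
        assert np.all(ph.g0 == 0) and np.all(ph.beta0 == 0)

    def test_interaction_variance_fraction(self, rng):
        G = simulate_genotypes((1000, 1000), 500, fst=0.01, seed=21)
        c = rng.standard_normal(G.n)
        ph = simulate_phenotype(G, TruthModel(h2=0.5, var_g1_frac=0.3),
                                c=c, seed=22)
        # var of the g1 latents ~ 0.3 * sigma_g^2 = 0.15
        assert np.var(ph.g1) == pytest.approx(0.15, abs=0.03)

    def test_n_causal_exceeds_L(self, cohort):
        G, _, _ = cohort
        with pytest.raises(ValueError, match="n_causal"):
            simulate_phenotype(G, TruthModel(h2=0.5, n_causal=10_000, fst=0.02),
                               seed=1)

    def test_exp_transform_is_monotone_in_latent(self, cohort):
        G, _, _ = cohort
        t = TruthModel(h2=0.3, transform="exp", transform_scale=0.5, fst=0.02)
        ph = simulate_phenotype(G, t, seed=77)
        order_lat = np.argsort(ph.y_latent)
        order_obs = np.argsort(ph.y)
        np.testing.assert_array_equal(order_lat, order_obs)


class TestApplySelection:
    def test_or_one_is_random_sampling(self, rng):
        y = rng.standard_normal(4000)
        pops = np.repeat(["POP1", "POP2"], 2000)
        scen = SelectionScenario(or_y={"POP1": 1.0, "POP2": 1.0})
        sel = apply_selection(y, pops, scen, seed=4)
        se = y.std() / np.sqrt(sel.size)
        assert abs(y[sel].mean() - y.mean()) < 3 * se

    def test_differential_or_raises_selected_mean(self):
        rng = np.random.default_rng(5)
        diffs = []
        for rep in range(50):
            y = rng.standard_normal(1000)
            pops = np.repeat(["POP1", "POP2"], 500)
            scen = SelectionScenario(or_y={"POP1": 1.0, "POP2": 2.0})
            sel = apply_selection(y, pops, scen, seed=100 + rep)
            ys, ps = y[sel], pops[sel]
            diffs.append(ys[ps == "POP2"].mean() - ys[ps == "POP1"].mean())
        assert np.mean(diffs) > 0

    def test_participation_rate_calibration(self, rng):
        y = rng.standard_normal(4000)
        pops = np.repeat(["POP1", "POP2"], 2000)
        scen = SelectionScenario(or_y={"POP1": 2.0, "POP2": 3.0},
                                 participation_rate=0.5)
        sel = apply_selection(y, pops, scen, seed=6)
        assert sel.size / 4000 == pytest.approx(0.5, abs=0.03)

    def test_seeded_determinism(self, rng):
        y = rng.standard_normal(500)
        pops = np.repeat(["POP1", "POP2"], 250)
        scen = SelectionScenario(or_y={"POP1": 1.0, "POP2": 2.0})
        a = apply_selection(y, pops, scen, seed=9)
        b = apply_selection(y, pops, scen, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_invalid_odds_ratio(self):
        with pytest.raises(ValueError, match="odds ratio"):
            SelectionScenario(or_y={"POP1": 0.0, "POP2": 1.0})

    def test_missing_population_label(self, rng):
        y = rng.standard_normal(100)
        pops = np.repeat(["POP1", "POPX"], 50)
        scen = SelectionScenario(or_y={"POP1": 1.0, "POP2": 1.0})
        with pytest.raises(ValueError, match="POPX"):
            apply_selection(y, pops, scen, seed=1)
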