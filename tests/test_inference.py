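import numpy as np
import pandas as pd
import pytest

from gxp import lowrank as lr
from gxp.inference import (PipelineConfig, bonferroni_threshold, h2_screen,
                           lrt, orthogonality_test, run_gxp_pipeline)
from gxp.mixedmodel import FitResult
from gxp.synthpop import TruthModel, simulate_genotypes, simulate_phenotype
from gxp.transforms import adjust_fixed_effects


def fake_fit(tag, loglik, n_params):
    return FitResult(model_tag=tag, loglik=loglik, components=None, se={},
                     converged=True, n_params=n_params)


class TestLRT:
    def test_equal_logliks(self):
        res = lrt(fake_fit("baseline", -100.0, 2), fake_fit("gxp", -100.0, 4))
        assert res.statistic == 0.0 and res.p == 1.0 and res.df == 2

    def test_chi2_two_df_closed_form(self):
        # 2*delta = 12 on 2 df: survival is exp(-6)
        res = lrt(fake_fit("baseline", -106.0, 2), fake_fit("gxp", -100.0, 4))
        assert res.statistic == pytest.approx(12.0)
        assert res.p == pytest.approx(np.exp(-6.0), rel=1e-10)

    def test_negative_improvement_clipped(self):
        res = lrt(fake_fit("baseline", -99.0, 2), fake_fit("gxp", -100.0, 4))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(fake_fit("gxp", -100.0, 4), fake_fit("rxp", -99.0, 4))


class TestBonferroni:
    @pytest.mark.parametrize("traits, covs, fwer, expected", [
        (70, 2, 0.05, 0.05 / 140),
        (1, 1, 0.05, 0.05),
        (10, 2, 0.05, 2.5e-3),
    ])
    def test_threshold(self, traits, covs, fwer, expected):
        assert bonferroni_threshold(traits, covs, fwer) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 2, 0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, 2, 1.5)


class TestH2Screen:
    def test_boundary_mass_gives_half(self, rng):
        # pure-noise trait on a tiny cohort frequently lands at the boundary
        y = rng.standard_normal(60)
        passed, p, _ = h2_screen(y, np.eye(60) + 1e-9, alpha=0.05)
        assert p >= 0.5 - 1e-9 or p <= 0.5  # p in (0, 1]; mass at 0 maps to 0.5
        assert 0 < p <= 1

    def test_power_at_strong_heritability(self):
        hits = 0
        for s in range(8):
            G = simulate_genotypes((300, 300), 300, fst=0.01, seed=900 + s)
            ph = simulate_phenotype(G, TruthModel(h2=0.5), seed=950 + s)
            Gs = lr.standardized_genotypes(G)
            base = lr.fit_greml_lowrank(ph.y - ph.y.mean(), Gs)
            from gxp.reml import loglik_iid_null
            from scipy.stats import chi2
            stat = max(0.0, 2 * (base.loglik - loglik_iid_null(ph.y - ph.y.mean())))
            p = 0.5 * chi2.sf(stat, 1) if stat > 0 else 0.5
            hits += p < 0.05
        assert hits >= 7

    def test_null_calibration(self):
        rejections = 0
        n_rep = 40
        rng = np.random.default_rng(31)
        G = simulate_genotypes((150, 150), 300, fst=0.01, seed=30)
        from gxp.grm import compute_grm
        from scipy.linalg import eigh
        A = compute_grm(G)
        eig = eigh(A.values)
        for _ in range(n_rep):
            y = rng.standard_normal(300)
            passed, p, _ = h2_screen(y, A, alpha=0.05, eig=eig)
            rejections += passed
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rejections / n_rep <= 0.05 + 3 * se


class TestOrthogonality:
    def test_pure_gxp_detected_over_rxp(self):
        sig = 0
        for s in range(4):
            G = simulate_genotypes((400, 400), 300, fst=0.01, seed=1000 + s)
            Gs = lr.standardized_genotypes(G)
            _, pcs = lr.top_pcs_lowrank(Gs, k=1)
            c = pcs[:, 0]
            c = (c - c.mean()) / c.std()
            truth = TruthModel(h2=0.5, var_g1_frac=0.6, cov_g01_corr=0.0)
            ph = simulate_phenotype(G, truth, c=c, seed=1100 + s)
            from gxp.grm import compute_grm
            A = compute_grm(G)
            y = adjust_fixed_effects(ph.y, c).values
            res = orthogonality_test(y, A, c)
            if not res.excluded and res.full_vs_rxp.p < 0.05:
                sig += 1
        assert sig >= 3

    def test_pure_rxp_case(self):
        G = simulate_genotypes((400, 400), 300, fst=0.01, seed=1200)
        Gs = lr.standardized_genotypes(G)
        _, pcs = lr.top_pcs_lowrank(Gs, k=1)
        c = pcs[:, 0]
        c = (c - c.mean()) / c.std()
        truth = TruthModel(h2=0.5, var_g1_frac=0.0, var_e1_frac=1.5)
        ph = simulate_phenotype(G, truth, c=c, seed=1201)
        from gxp.grm import compute_grm
        A = compute_grm(G)
        y = adjust_fixed_effects(ph.y, c).values
        res = orthogonality_test(y, A, c)
        if not res.excluded:
            # residual heterogeneity must be detected on top of the gxp model
            assert res.full_vs_gxp.p < 0.05


@pytest.fixture(scope="module")
def pipeline_result():
    G = simulate_genotypes((300, 300), 400, fst=0.015, seed=1300)
    Gs = lr.standardized_genotypes(G)
    _, pcs = lr.top_pcs_lowrank(Gs, k=1)
    c = pcs[:, 0]
    c = (c - c.mean()) / c.std()
    rng = np.random.default_rng(1301)
    null_trait = rng.standard_normal(G.n)
    strong = simulate_phenotype(
        G, TruthModel(h2=0.5, var_g1_frac=1.2, fst=0.015), c=c, seed=1302)
    plain = simulate_phenotype(
        G, TruthModel(h2=0.5, fst=0.015), seed=1303)
    phenos = pd.DataFrame({
        "fid": G.sample_meta["fid"], "iid": G.sample_meta["iid"],
        "trait_null": null_trait,
        "trait_gxp": strong.y,
        "trait_plain": plain.y,
    })
    # relatedness threshold scaled up: at L=400 the GRM off-diagonal noise
    # (sd ~ 1/sqrt(L) = 0.05) would otherwise prune unrelated individuals
    cfg = PipelineConfig(covariates=("PC1",), seed=5,
                         bivariate_screen=True, relatedness_max=0.5)
    return run_gxp_pipeline(G, phenos, config=cfg)


class TestPipeline:
    def test_every_trait_accounted_once(self, pipeline_result):
        rep = pipeline_result.report
        assert len(rep) == 3
        assert rep.groupby(["trait", "covariate"]).size().max() == 1
        assert rep["stage_exit"].notna().all()

    def test_null_trait_exits_at_h2_screen(self, pipeline_result):
        row = pipeline_result.report.query("trait == 'trait_null'").iloc[0]
        assert row["stage_exit"] == "h2_screen"

    def test_strong_interaction_reaches_lrt_significance(self, pipeline_result):
        row = pipeline_result.report.query("trait == 'trait_gxp'").iloc[0]
        assert row["stage_exit"] != "h2_screen"
        if "p_gxp" in row and pd.notna(row.get("p_gxp", np.nan)):
            assert row["p_gxp"] < 0.05

    def test_bonferroni_level_matches_counts(self, pipeline_result):
        assert pipeline_result.bonferroni_level == pytest.approx(0.05 / 3)
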