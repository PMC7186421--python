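"""Likelihood-ratio testing, multiple-testing correction, the orthogonality
test between genotype- and residual-covariate interaction, and the staged
G x P screening pipeline.

The pipeline mirrors the analysis workflow: QC -> GRM -> relatedness pruning
-> ancestry PCs and partition -> confounder adjustment -> heritability screen
-> phenotype-vs-PC bivariate screen -> G x P reaction-norm fit per covariate
-> validity filter -> LRT against the baseline with Bonferroni correction ->
rank-INT robustness re-fit -> orthogonality test for the survivors.  Every
trait/covariate combination exits at exactly one stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from . import grm as grm_mod
from .ancestry import compute_pcs
from .mixedmodel import (FitResult, check_validity, fit_bivariate_greml,
                         fit_greml, fit_rnm, snp_heritability)
from .reml import loglik_iid_null
from .transforms import adjust_fixed_effects, rank_int

__all__ = ["LRTResult", "lrt", "h2_screen", "bonferroni_threshold",
           "orthogonality_test", "rg_heterogeneity_lrt",
           "PipelineConfig", "run_gxp_pipeline"]

# null -> alt pairs that form nested model comparisons
_NESTED = {
    ("baseline", "gxp"), ("baseline", "rxp"), ("baseline", "full"),
    ("gxp", "full"), ("rxp", "full"),
    ("bivariate_rg1", "bivariate"),
}


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float
    comparison: tuple


def lrt(null_fit: FitResult, alt_fit: FitResult) -> LRTResult:
    """Likelihood-ratio test of two nested REML fits.

    statistic = max(0, 2 * (loglik_alt - loglik_null)); df is the parameter
    difference; p from the upper tail of chi-square(df).  Numerically
    negative improvements are clipped to 0 (p = 1).
    """
    pair = (null_fit.model_tag, alt_fit.model_tag)
    if pair not in _NESTED:
        raise ValueError(f"models {pair} are not a recognised nested pair")
    df = alt_fit.n_params - null_fit.n_params
    if df <= 0:
        raise ValueError("alternative must have more parameters than the null")
    stat = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=stat, df=df, p=p, comparison=pair)


def h2_screen(y, A, alpha: float = 0.05, eig=None):
    """Boundary LRT of sigma_g^2 = 0 against the baseline GREML model.

    The null places the parameter on the boundary, so p comes from the
    50:50 mixture chi2_0 : chi2_1 — p = 0.5 * P(chi2_1 > stat), which equals
    0.5 at statistic 0 (the point mass).  The alternative is the constrained
    sigma_g^2 >= 0 model: when the unconstrained estimate is negative, the
    constrained optimum sits at the boundary and the statistic is 0 (an
    unconstrained negative estimate must not count as evidence of
    heritability).  Returns (passed, p, baseline_fit).
    """
    fit = fit_greml(y, A, eig=eig)
    ll0 = loglik_iid_null(y)
    if fit.components.var_g0 <= 0:
        stat = 0.0
    else:
        stat = max(0.0, 2.0 * (fit.loglik - ll0))
    p = 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 0.5
    return p < alpha, p, fit


def bonferroni_threshold(n_traits: int, n_covariates: int,
                         fwer: float = 0.05) -> float:
    """Family-wise corrected per-test level: fwer / (n_traits * n_covariates)."""
    if n_traits < 1 or n_covariates < 1:
        raise ValueError("counts must be >= 1")
    if not 0.0 < fwer < 1.0:
        raise ValueError("fwer must be in (0, 1)")
    return fwer / (n_traits * n_covariates)


@dataclass
class OrthogonalityResult:
    full_vs_rxp: LRTResult | None    # significant => G x P orthogonal to R x P
    full_vs_gxp: LRTResult | None
    excluded: bool = False
    reason: str = ""
    fits: dict = field(default_factory=dict)


def orthogonality_test(y, A, c) -> OrthogonalityResult:
    """Fit gxp, rxp and full models; LRT the full model against each nested one.

    A significant full-vs-rxp test shows the genotype-covariate interaction
    survives after residual heterogeneity is modelled (orthogonality), and
    vice versa.  Fits outside the valid parameter space mark the result
    excluded.
    """
    fits = {m: fit_rnm(y, A, c, mode=m) for m in ("gxp", "rxp", "full")}
    for m in ("gxp", "full"):
        chk = check_validity(fits[m].components)
        if not chk.valid:
            return OrthogonalityResult(None, None, excluded=True,
                                       reason=f"{m} fit invalid "
                                              f"(criteria {chk.violated})",
                                       fits=fits)
    if not all(f.converged for f in fits.values()):
        bad = [m for m, f in fits.items() if not f.converged]
        return OrthogonalityResult(None, None, excluded=True,
                                   reason=f"non-convergence: {bad}", fits=fits)
    return OrthogonalityResult(
        full_vs_rxp=lrt(fits["rxp"], fits["full"]),
        full_vs_gxp=lrt(fits["gxp"], fits["full"]),
        fits=fits,
    )


def rg_heterogeneity_lrt(free_fit: FitResult, rg1_fit: FitResult) -> LRTResult:
    """LRT of cross-population genetic heterogeneity: free r_g vs r_g = 1 (1 df)."""
    stat = max(0.0, 2.0 * (free_fit.loglik - rg1_fit.loglik))
    p = float(chi2.sf(stat, 1)) if stat > 0 else 1.0
    return LRTResult(statistic=stat, df=1,
                     p=p, comparison=("bivariate_rg1", "bivariate"))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    covariates: tuple = ("PC1", "PC2")
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4
    drop_ambiguous: bool = True
    relatedness_max: float = 0.05
    n_pcs: int = 2
    adjust_pcs: bool = True          # include computed PCs as fixed confounders
    h2_alpha: float = 0.05
    fwer: float = 0.05
    int_refit: bool = True
    orthogonality: bool = True
    bivariate_screen: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    report: pd.DataFrame
    counts: dict
    bonferroni_level: float


def run_gxp_pipeline(G, phenotypes: pd.DataFrame, confounders=None,
                     config: PipelineConfig | None = None) -> PipelineResult:
    """Staged genotype-by-population interaction screen over many traits.

    ``phenotypes`` is FID/IID-keyed (columns fid, iid, then trait columns),
    row-aligned with ``G``.  The report has one row per trait x covariate
    with the exit stage and the statistics computed up to that point.
    """
    cfg = config or PipelineConfig()

    Gq, qc_report = grm_mod.qc_filter(
        G, maf_min=cfg.maf_min, call_rate_min=cfg.call_rate_min,
        hwe_p_min=cfg.hwe_p_min, drop_ambiguous=cfg.drop_ambiguous)
    A = grm_mod.compute_grm(Gq)
    keep = grm_mod.prune_related(A, threshold=cfg.relatedness_max, seed=cfg.seed)
    A = A.subset(keep)

    w, U = linalg.eigh(A.values)
    pcs_raw = compute_pcs(A, k=cfg.n_pcs,
                          precomputed_eig=(w[-cfg.n_pcs:], U[:, -cfg.n_pcs:]))
    pc_cols = {f"PC{j + 1}":
               (pcs_raw.scores[:, j] - pcs_raw.scores[:, j].mean())
               / pcs_raw.scores[:, j].std()
               for j in range(cfg.n_pcs)}

    trait_cols = [c for c in phenotypes.columns if c not in ("fid", "iid")]
    n_tests = len(trait_cols) * len(cfg.covariates)
    bonf = bonferroni_threshold(len(trait_cols), len(cfg.covariates), cfg.fwer)

    conf_design = None
    if confounders is not None:
        conf = confounders.drop(columns=[c for c in ("fid", "iid")
                                         if c in confounders.columns])
        conf_design = conf.iloc[keep].reset_index(drop=True)
    pc_design = pd.DataFrame(pc_cols) if cfg.adjust_pcs else None

    rows = []
    counts = {"n_snps_qc": qc_report.n_passed,
              "n_samples": A.n,
              "n_traits": len(trait_cols),
              "bonferroni_level": bonf}

    for trait in trait_cols:
        y_raw = phenotypes[trait].to_numpy(dtype=float)[keep]
        design_parts = []
        if conf_design is not None:
            design_parts.append(conf_design)
        if pc_design is not None:
            design_parts.append(pc_design)
        Xc = pd.concat(design_parts, axis=1) if design_parts else None
        y = adjust_fixed_effects(y_raw, Xc).values

        passed, p_h2, base_fit = h2_screen(y, A, alpha=cfg.h2_alpha, eig=(w, U))
        h2, h2_se = snp_heritability(base_fit)
        base_row = {"trait": trait, "h2": h2, "h2_se": h2_se, "p_h2": p_h2}
        if not passed:
            for cov in cfg.covariates:
                rows.append({**base_row, "covariate": cov,
                             "stage_exit": "h2_screen"})
            continue

        for cov in cfg.covariates:
            c = pc_cols[cov]
            row = {**base_row, "covariate": cov}

            if cfg.bivariate_screen:
                biv = fit_bivariate_greml(y, c, A, layout="same_sample",
                                          eig=(w, U))
                cg, ce = biv.components.cov_g12, biv.components.cov_e12
                cg_se = biv.se["cov_g12"]
                ce_se = biv.se["cov_e12"]
                row.update(yc_cov_g=cg, yc_cov_g_se=cg_se,
                           yc_cov_e=ce, yc_cov_e_se=ce_se)
                if abs(cg) >= 2 * cg_se or abs(ce) >= 2 * ce_se:
                    row["stage_exit"] = "bivariate_screen"
                    rows.append(row)
                    continue

            gxp_fit = fit_rnm(y, A, c, mode="gxp")
            comp = gxp_fit.components
            row.update(var_g0=comp.var_g0, var_g1=comp.var_g1,
                       cov_g01=comp.cov_g01, var_e0=comp.var_e0)
            chk = check_validity(comp)
            if not chk.valid:
                row["stage_exit"] = "validity"
                row["violated"] = ",".join(map(str, chk.violated))
                rows.append(row)
                continue

            test = lrt(base_fit, gxp_fit)
            row["p_gxp"] = test.p
            if test.p >= bonf:
                row["stage_exit"] = "lrt"
                rows.append(row)
                continue

            if cfg.int_refit:
                # INT the raw trait, then re-apply the confounder adjustment
                y_int = adjust_fixed_effects(rank_int(y_raw).values, Xc).values
                _, _, base_int = h2_screen(y_int, A, eig=(w, U))
                gxp_int = fit_rnm(y_int, A, c, mode="gxp")
                p_int = lrt(base_int, gxp_int).p
                row["p_gxp_int"] = p_int
                if p_int >= bonf:
                    row["stage_exit"] = "int_refit"
                    rows.append(row)
                    continue
                y_final = y_int
            else:
                y_final = y

            if cfg.orthogonality:
                orth = orthogonality_test(y_final, A, c)
                if orth.excluded:
                    row["stage_exit"] = "orthogonality_excluded"
                    row["violated"] = orth.reason
                    rows.append(row)
                    continue
                row["p_full_vs_rxp"] = orth.full_vs_rxp.p
                row["p_full_vs_gxp"] = orth.full_vs_gxp.p

            row["stage_exit"] = "significant"
            rows.append(row)

    report = pd.DataFrame(rows)
    stage_counts = report["stage_exit"].value_counts().to_dict()
    counts["stage_exits"] = stage_counts
    assert len(report) == n_tests, "pipeline must account for every trait/covariate"
    return PipelineResult(report=report, counts=counts, bonferroni_level=bonf)
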