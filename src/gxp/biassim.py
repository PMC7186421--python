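"""Participation-selection and collider-bias simulation studies.

Each study repeatedly simulates a two-population cohort under a
genotype-by-population null (no genotype-covariate interaction, true
cross-population genetic correlation 1), applies logistic participation
selection with per-population odds ratios, recomputes the GRM and ancestry
PC1 on the selected sample, and measures

* the type-I error of the G x P reaction-norm LRT (PC1 covariate), and
* the distribution of the bivariate-GREML cross-population genetic
  correlation and the type-I error of its r_g = 1 LRT.

The collider study adds a second, genetically and residually independent
trait Z to the participation logit and additionally estimates the
(collider-biased) Y-Z genetic correlation in the selected sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import qc_filter
from .inference import lrt, rg_heterogeneity_lrt
from .lowrank import (fit_bivariate_lowrank, fit_bivariate_samesample_lowrank,
                      fit_greml_lowrank, fit_gxp_lowrank,
                      standardized_genotypes, top_pcs_lowrank)
from .synthpop import (SelectionScenario, TruthModel, apply_selection,
                       simulate_genotypes, simulate_phenotype)
from .transforms import adjust_fixed_effects

__all__ = ["SimulationReport", "run_selection_study", "run_collider_study",
           "type1_error", "report_table"]


@dataclass
class SimulationReport:
    scenario: SelectionScenario
    n_reps: int
    type1_rnm: float
    type1_bivgreml: float
    rg_mean: float
    rg_se: float
    rg_yz_mean: float | None = None
    rg_yz_se: float | None = None
    n_mean: float = 0.0          # mean selected sample size
    p_rnm: np.ndarray | None = None
    p_biv: np.ndarray | None = None
    rg_values: np.ndarray | None = None
    rg_yz_values: np.ndarray | None = None


def type1_error(p_values, alpha: float = 0.05) -> float:
    """Fraction of p-values below alpha."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.mean(p < alpha))


def _replicate(G, traits, scenario, rep_seed, estimate_yz=False):
    """One replicate: select, rebuild GRM basis + PC1, fit all models.

    All fits run through the exact reduced-basis REML path, which scales to
    biobank-size selected samples (the regime where differential selection
    visibly inflates the reaction-norm test).
    """
    pops = G.sample_meta["pop"].to_numpy()
    sel = apply_selection(traits, pops, scenario, seed=rep_seed)
    Gsel = G.subset(samples=sel)
    Gsel, _ = qc_filter(Gsel, maf_min=0.01, call_rate_min=0.0, hwe_p_min=0.0,
                        drop_ambiguous=False)
    Gs = standardized_genotypes(Gsel)
    _, pcs = top_pcs_lowrank(Gs, k=1)
    pc1 = pcs[:, 0]
    pc1 = (pc1 - pc1.mean()) / pc1.std()

    pops_sel = pops[sel]
    labels = pd.unique(G.sample_meta["pop"])
    idx1 = np.flatnonzero(pops_sel == labels[0])
    idx2 = np.flatnonzero(pops_sel == labels[1])

    y = adjust_fixed_effects(traits[0][sel], pc1).values

    base = fit_greml_lowrank(y, Gs)
    gxp = fit_gxp_lowrank(y, Gs, pc1)
    p_rnm = lrt(base, gxp).p

    biv = fit_bivariate_lowrank(y[idx1], y[idx2], Gs[idx1], Gs[idx2])
    biv1 = fit_bivariate_lowrank(y[idx1], y[idx2], Gs[idx1], Gs[idx2],
                                 constrain_rg_one=True)
    p_biv = rg_heterogeneity_lrt(biv, biv1).p
    rg = biv.rg if biv.rg is not None else np.nan

    out = {"p_rnm": p_rnm, "p_biv": p_biv, "rg": rg, "n_sel": sel.size}
    if estimate_yz:
        z = adjust_fixed_effects(traits[1][sel], pc1).values
        yz = fit_bivariate_samesample_lowrank(y, z, Gs)
        out["rg_yz"] = yz.rg if yz.rg is not None else np.nan
    return out


def _aggregate(scenario, results, alpha, with_yz):
    rg = np.array([r["rg"] for r in results])
    ok = np.isfinite(rg)
    rep = SimulationReport(
        scenario=scenario,
        n_reps=len(results),
        type1_rnm=type1_error([r["p_rnm"] for r in results], alpha),
        type1_bivgreml=type1_error([r["p_biv"] for r in results], alpha),
        rg_mean=float(np.mean(rg[ok])),
        rg_se=float(np.std(rg[ok], ddof=1) / np.sqrt(ok.sum())) if ok.sum() > 1 else 0.0,
        n_mean=float(np.mean([r["n_sel"] for r in results])),
        p_rnm=np.array([r["p_rnm"] for r in results]),
        p_biv=np.array([r["p_biv"] for r in results]),
        rg_values=rg,
    )
    if with_yz:
        yz = np.array([r["rg_yz"] for r in results])
        okz = np.isfinite(yz)
        rep.rg_yz_values = yz
        rep.rg_yz_mean = float(np.mean(yz[okz]))
        rep.rg_yz_se = (float(np.std(yz[okz], ddof=1) / np.sqrt(okz.sum()))
                        if okz.sum() > 1 else 0.0)
    return rep


def run_selection_study(scenarios, truth: TruthModel | None = None,
                        n_reps: int = 100, seed: int = 0,
                        n_per_pop: int = 1000, n_snps: int = 2000,
                        alpha: float = 0.05):
    """Single-trait selection-bias study (one report per scenario).

    ``truth`` must be a G x P null (var_g1_frac = 0, rg_cross = 1) so every
    reaction-norm rejection is a type-I error.  A master seed spawns
    independent per-replicate substreams; scenarios share replicate cohorts
    (only the selection differs), mirroring a paired design.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    truth = truth or TruthModel(h2=0.5, var_g1_frac=0.0, rg_cross=1.0)
    if truth.var_g1_frac != 0:
        raise ValueError("selection study requires a G x P-null truth")
    scenarios = list(scenarios)

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_reps)]

    per_scenario = [[] for _ in scenarios]
    for r, rs in enumerate(rep_seeds):
        G = simulate_genotypes((n_per_pop, n_per_pop), n_snps, fst=truth.fst,
                               seed=rs)
        ph = simulate_phenotype(G, truth, seed=rs + 1)
        for s_i, scen in enumerate(scenarios):
            res = _replicate(G, [ph.y], scen, rep_seed=rs + 2 + s_i)
            per_scenario[s_i].append(res)

    return [_aggregate(scen, res, alpha, with_yz=False)
            for scen, res in zip(scenarios, per_scenario)]


def run_collider_study(scenarios, truth: TruthModel | None = None,
                       n_reps: int = 100, seed: int = 0,
                       n_per_pop: int = 1000, n_snps: int = 2000,
                       alpha: float = 0.05):
    """Two-trait collider-bias study.

    Y and Z are simulated with zero genetic and zero residual correlation;
    both enter the participation logit.  Reports add the Y-Z genetic
    correlation estimated on the selected combined sample, whose deviation
    from 0 is pure collider bias.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    truth = truth or TruthModel(h2=0.5, var_g1_frac=0.0, rg_cross=1.0)
    if truth.var_g1_frac != 0:
        raise ValueError("collider study requires a G x P-null truth")
    scenarios = list(scenarios)
    for scen in scenarios:
        if scen.or_z is None:
            raise ValueError("collider scenarios need odds ratios for both traits")

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_reps)]

    per_scenario = [[] for _ in scenarios]
    for r, rs in enumerate(rep_seeds):
        G = simulate_genotypes((n_per_pop, n_per_pop), n_snps, fst=truth.fst,
                               seed=rs)
        ph_y = simulate_phenotype(G, truth, seed=rs + 1)
        ph_z = simulate_phenotype(G, truth, seed=rs + 20_000_001)
        for s_i, scen in enumerate(scenarios):
            res = _replicate(G, [ph_y.y, ph_z.y], scen,
                             rep_seed=rs + 2 + s_i, estimate_yz=True)
            per_scenario[s_i].append(res)

    return [_aggregate(scen, res, alpha, with_yz=True)
            for scen, res in zip(scenarios, per_scenario)]


def report_table(reports) -> pd.DataFrame:
    """Tabulate simulation reports in the published table layout."""
    rows = []
    for rep in reports:
        scen = rep.scenario
        label = ", ".join(f"OR_{pop},Y={v:g}" for pop, v in scen.or_y.items())
        if scen.or_z is not None:
            label += "; " + ", ".join(f"OR_{pop},Z={v:g}"
                                      for pop, v in scen.or_z.items())
        row = {
            "scenario": label,
            "type1_rnm": rep.type1_rnm,
            "type1_bivgreml": rep.type1_bivgreml,
            "rg_mean": rep.rg_mean,
            "rg_se": rep.rg_se,
        }
        if rep.rg_yz_mean is not None:
            row["rg_yz_mean"] = rep.rg_yz_mean
            row["rg_yz_se"] = rep.rg_yz_se
        rows.append(row)
    return pd.DataFrame(rows)
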