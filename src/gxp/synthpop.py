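"""Two-population synthetic cohorts with controllable genotype-by-population
interaction, residual heterogeneity, and biased participation.

The generator emulates the statistical structure of a biobank extract with two
white-European-like subpopulations: allele frequencies differentiated under a
Balding-Nichols model (small FST, visible on the leading ancestry PCs),
polygenic phenotypes whose SNP effects may be modulated linearly by a
continuous covariate (g0 + g1*c truth), optional residual heterogeneity along
the same covariate, and logistic participation selection with per-population,
per-trait odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "GenotypeMatrix",
    "TruthModel",
    "SelectionScenario",
    "PhenotypeDraw",
    "simulate_genotypes",
    "simulate_phenotype",
    "apply_selection",
    "hudson_fst",
]

MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """n x L dosage matrix (counts of the reference allele) plus metadata.

    ``dosages`` holds values in {0, 1, 2} with NaN marking missing calls.
    ``variant_meta`` has columns (id, chrom, pos, a1, a2); ``sample_meta``
    has (fid, iid, pop).  ``allele_freq`` caches the reference-allele
    frequency p_l of each SNP.
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    allele_freq: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (n x L) array")
        n, L = self.dosages.shape
        if n < 2 or L < 1:
            raise ValueError(f"need n >= 2 and L >= 1, got n={n}, L={L}")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValueError("non-missing dosages must lie in {0, 1, 2}")
        if len(self.variant_meta) != L:
            raise ValueError("variant_meta length does not match L")
        if len(self.sample_meta) != n:
            raise ValueError("sample_meta length does not match n")
        if self.allele_freq is None:
            self.allele_freq = self.compute_freq()
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def compute_freq(self) -> np.ndarray:
        """Reference-allele frequency per SNP from the non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        d = self.dosages
        sm = self.sample_meta
        vm = self.variant_meta
        if samples is not None:
            d = d[samples]
            sm = sm.iloc[samples].reset_index(drop=True)
        if snps is not None:
            d = d[:, snps]
            vm = vm.iloc[snps].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), vm, sm)


@dataclass
class TruthModel:
    """Generative truth for a polygenic phenotype with optional interaction.

    Total phenotypic variance is 1 at covariate value 0: the main genetic
    variance is ``h2`` and the baseline residual variance 1 - h2.  The
    covariate-modulated genetic variance is ``var_g1_frac * h2`` and the
    residual-heterogeneity variance ``var_e1_frac * (1 - h2)``.
    """

    h2: float = 0.5
    n_causal: int | None = None          # None -> all SNPs causal
    var_g1_frac: float = 0.0
    cov_g01_corr: float = 0.0
    var_e1_frac: float = 0.0
    fst: float = 0.01
    rg_cross: float = 1.0                # cross-population genetic correlation
    resid_dist: str = "normal"           # "normal" | "chi2" (skewed)
    resid_df: int = 4
    beta_c: float = 0.0                  # fixed (mean) effect of the covariate
    transform: str | None = None         # None | "exp": monotone output skew
    transform_scale: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        if self.var_g1_frac < 0:
            raise ValueError("var_g1_frac must be >= 0")
        if not -1.0 <= self.cov_g01_corr <= 1.0:
            raise ValueError("cov_g01_corr must be in [-1, 1]")
        if self.var_e1_frac < 0:
            raise ValueError("var_e1_frac must be >= 0")
        if not 0.0 < self.fst < 0.5:
            raise ValueError("fst must be in (0, 0.5)")
        if self.resid_dist not in ("normal", "chi2"):
            raise ValueError("resid_dist must be 'normal' or 'chi2'")
        if self.transform not in (None, "exp"):
            raise ValueError("transform must be None or 'exp'")


@dataclass
class SelectionScenario:
    """Per-population, per-trait participation odds ratios.

    ``or_y[pop]`` is the odds ratio of participation per SD of trait Y in
    population ``pop``; ``or_z`` optionally adds a second trait to the
    participation logit (the collider setting).
    """

    or_y: dict
    or_z: dict | None = None
    participation_rate: float = 0.5

    def __post_init__(self):
        for d in (self.or_y, self.or_z or {}):
            for pop, v in d.items():
                if v <= 0:
                    raise ValueError(f"odds ratio for {pop} must be > 0, got {v}")
        if not 0.0 < self.participation_rate <= 1.0:
            raise ValueError("participation_rate must be in (0, 1]")


@dataclass
class PhenotypeDraw:
    """Phenotype plus its latent components.

    The latent trait decomposes exactly: y_latent = mu + g0 + c*g1 + e.
    ``y`` equals ``y_latent`` unless the truth model applies a monotone
    output transform (skewed observation scale).
    """

    y: np.ndarray
    y_latent: np.ndarray
    g0: np.ndarray
    g1: np.ndarray
    e: np.ndarray
    mu: np.ndarray           # fixed-effect part (beta_c * c)
    beta0: np.ndarray        # per-SNP main effects (0 for non-causal SNPs)
    beta1: np.ndarray        # per-SNP interaction effects
    causal_idx: np.ndarray


def simulate_genotypes(n_per_pop, L, fst=0.01, maf_range=(0.05, 0.5), seed=0,
                       pop_names=("POP1", "POP2")) -> GenotypeMatrix:
    """Draw unlinked biallelic genotypes for two populations.

    Ancestral frequencies are uniform on ``maf_range``; each population's
    frequency is Balding-Nichols: Beta(p(1-F)/F, (1-p)(1-F)/F) with F = fst.
    Dosages are Binomial(2, p_pop).  Deterministic given ``seed``.
    """
    n1, n2 = int(n_per_pop[0]), int(n_per_pop[1])
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs at least 2 individuals")
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0.0 < fst < 0.5:
        raise ValueError("fst must be in (0, 0.5)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")

    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(lo, hi, size=L)
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    p_pops = np.stack([rng.beta(a, b), rng.beta(a, b)])        # 2 x L
    p_pops = np.clip(p_pops, 1e-6, 1.0 - 1e-6)

    dos = np.empty((n1 + n2, L))
    dos[:n1] = rng.binomial(2, p_pops[0], size=(n1, L))
    dos[n1:] = rng.binomial(2, p_pops[1], size=(n2, L))

    variant_meta = pd.DataFrame({
        "id": [f"snp{l + 1}" for l in range(L)],
        "chrom": np.ones(L, dtype=int),
        "pos": np.arange(1, L + 1) * 1000,
        "a1": "A",
        "a2": "G",
    })
    pops = [pop_names[0]] * n1 + [pop_names[1]] * n2
    sample_meta = pd.DataFrame({
        "fid": [f"F{i + 1}" for i in range(n1 + n2)],
        "iid": [f"I{i + 1}" for i in range(n1 + n2)],
        "pop": pops,
    })
    return GenotypeMatrix(dos, variant_meta, sample_meta)


def hudson_fst(G: GenotypeMatrix) -> float:
    """Hudson's FST estimator (ratio of averages) between the two populations."""
    pops = G.sample_meta["pop"].to_numpy()
    labels = pd.unique(pops)
    if len(labels) != 2:
        raise ValueError("hudson_fst needs exactly two populations")
    num = den = 0.0
    for lab1, lab2 in [(labels[0], labels[1])]:
        d1 = G.dosages[pops == lab1]
        d2 = G.dosages[pops == lab2]
        n1 = d1.shape[0] * 2
        n2 = d2.shape[0] * 2
        p1 = np.nanmean(d1, axis=0) / 2.0
        p2 = np.nanmean(d2, axis=0) / 2.0
        num_l = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den_l = p1 * (1 - p2) + p2 * (1 - p1)
        num += np.nansum(num_l)
        den += np.nansum(den_l)
    return float(num / den)


def _standardize_dosages(G: GenotypeMatrix) -> np.ndarray:
    """Center and scale dosages by the overall sample frequency (mean-imputed)."""
    d = G.dosages.copy()
    p = np.nanmean(d, axis=0) / 2.0
    inds = np.where(np.isnan(d))
    if inds[0].size:
        d[inds] = np.take(2.0 * p, inds[1])
    denom = np.sqrt(2.0 * p * (1.0 - p))
    if np.any(denom == 0):
        raise ValueError("monomorphic SNP encountered while standardizing")
    return (d - 2.0 * p) / denom


def simulate_phenotype(G: GenotypeMatrix, truth: TruthModel, c=None, seed=0,
                       shared_beta: tuple | None = None) -> PhenotypeDraw:
    """Draw a polygenic phenotype y = g0 + c*g1 + e from the generative truth.

    Per-SNP main and interaction effects (beta0, beta1) are bivariate normal
    with correlation ``truth.cov_g01_corr``; individual genetic values use
    sample-standardized dosages.  Residual variance is
    (1-h2)(1 + c^2 * var_e1_frac); with ``resid_dist='chi2'`` the residual is
    a standardized (right-skewed) chi-square draw instead of a Gaussian.

    ``truth.rg_cross`` < 1 draws partially independent effect vectors per
    population.  ``shared_beta`` lets a caller reuse effect vectors across
    calls (e.g., to build two traits that share no effects by passing fresh
    seeds instead).
    """
    n, L = G.dosages.shape
    m = L if truth.n_causal is None else int(truth.n_causal)
    if m > L:
        raise ValueError(f"n_causal={m} exceeds L={L}")
    if c is None:
        c = np.zeros(n)
    c = np.asarray(c, dtype=float)
    if c.shape[0] != n:
        raise ValueError("covariate length must match sample size")

    rng = np.random.default_rng(seed)
    causal = (np.sort(rng.choice(L, size=m, replace=False))
              if m < L else np.arange(L))

    sg0 = truth.h2
    sg1 = truth.var_g1_frac * truth.h2
    se0 = 1.0 - truth.h2
    se1 = truth.var_e1_frac * se0

    if shared_beta is not None:
        beta0, beta1 = shared_beta
    else:
        rho = truth.cov_g01_corr
        z = rng.standard_normal((m, 2))
        b0 = z[:, 0]
        b1 = rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho ** 2)) * z[:, 1]
        beta0 = np.zeros(L)
        beta1 = np.zeros(L)
        beta0[causal] = b0 * np.sqrt(sg0 / m)
        beta1[causal] = b1 * np.sqrt(sg1 / m) if sg1 > 0 else 0.0

    W = _standardize_dosages(G)
    pops = G.sample_meta["pop"].to_numpy()
    labels = pd.unique(pops)
    if truth.rg_cross < 1.0 and len(labels) == 2:
        # population-specific main effects with correlation rg_cross
        r = truth.rg_cross
        extra = rng.standard_normal(L) * np.sqrt(sg0 / m)
        extra[np.setdiff1d(np.arange(L), causal)] = 0.0
        beta0_b = r * beta0 + np.sqrt(max(0.0, 1 - r ** 2)) * extra
        g0 = np.where(pops == labels[0], W @ beta0, W @ beta0_b)
    else:
        g0 = W @ beta0
    g1 = W @ beta1

    sd_e = np.sqrt(se0 + c ** 2 * se1)
    if truth.resid_dist == "chi2":
        df = truth.resid_df
        raw = rng.chisquare(df, size=n)
        eps = (raw - df) / np.sqrt(2.0 * df)
    else:
        eps = rng.standard_normal(n)
    e = sd_e * eps

    mu = truth.beta_c * c
    y_lat = mu + g0 + c * g1 + e
    if truth.transform == "exp":
        y = np.exp(truth.transform_scale * y_lat)
    else:
        y = y_lat
    return PhenotypeDraw(y=y, y_latent=y_lat, g0=g0, g1=g1, e=e, mu=mu,
                         beta0=beta0, beta1=beta1, causal_idx=causal)


def apply_selection(traits, pop_labels, scenario: SelectionScenario, seed=0,
                    return_probs=False):
    """Select study participants with phenotype-dependent probability.

    The participation probability of individual i in population pop is
    logistic(alpha_pop + ln(OR_pop,Y) y_i [+ ln(OR_pop,Z) z_i]) with each
    trait standardized to unit SD, and alpha_pop calibrated by bisection so
    the expected selected fraction per population equals
    ``scenario.participation_rate``.  Returns the sorted indices of selected
    individuals.
    """
    if isinstance(traits, np.ndarray) and traits.ndim == 1:
        traits = [traits]
    traits = [np.asarray(t, dtype=float) for t in traits]
    n = traits[0].shape[0]
    pop_labels = np.asarray(pop_labels)
    if pop_labels.shape[0] != n:
        raise ValueError("pop_labels must cover all individuals")
    ors = [scenario.or_y] + ([scenario.or_z] if scenario.or_z is not None else [])
    if len(ors) != len(traits):
        raise ValueError("number of traits must match the scenario's odds-ratio maps")

    zs = [(t - t.mean()) / t.std() for t in traits]
    rng = np.random.default_rng(seed)
    rate = scenario.participation_rate
    prob = np.empty(n)
    for pop in pd.unique(pop_labels):
        mask = pop_labels == pop
        lin = np.zeros(mask.sum())
        for z, ormap in zip(zs, ors):
            if pop not in ormap:
                raise ValueError(f"no odds ratio given for population {pop!r}")
            lin += np.log(ormap[pop]) * z[mask]

        if rate >= 1.0:
            prob[mask] = 1.0
            continue

        def frac(alpha, lin=lin):
            return float(np.mean(expit(alpha + lin))) - rate

        alpha = brentq(frac, -50.0, 50.0)
        prob[mask] = expit(alpha + lin)

    selected = np.flatnonzero(rng.uniform(size=n) < prob)
    if selected.size == 0:
        raise RuntimeError("selection produced an empty sample")
    if return_probs:
        return selected, prob
    return selected
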