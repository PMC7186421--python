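"""Genotype QC, genomic relationship matrix construction and relatedness pruning.

The GRM follows the GCTA convention: A_ij = (1/L) sum_l (x_il - 2 p_l)
(x_jl - 2 p_l) / (2 p_l (1 - p_l)), with p_l the sample reference-allele
frequency and the denominator the Hardy-Weinberg expectation of var(x_l).
Missing dosages are mean-imputed per SNP before centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .synthpop import GenotypeMatrix

__all__ = ["GRMatrix", "QCReport", "qc_filter", "compute_grm", "prune_related"]

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GRMatrix:
    """Symmetric n x n genomic relationship matrix with sample identifiers."""

    values: np.ndarray
    n_snps_used: int
    sample_ids: pd.DataFrame      # columns fid, iid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GRM must be square")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must match GRM dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, idx) -> "GRMatrix":
        idx = np.asarray(idx)
        return GRMatrix(self.values[np.ix_(idx, idx)], self.n_snps_used,
                        self.sample_ids.iloc[idx].reset_index(drop=True))


@dataclass
class QCReport:
    n_input: int
    removed_call_rate: int = 0
    removed_hwe: int = 0
    removed_maf: int = 0
    removed_ambiguous: int = 0

    @property
    def n_passed(self) -> int:
        return (self.n_input - self.removed_call_rate - self.removed_hwe
                - self.removed_maf - self.removed_ambiguous)


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """1-df chi-square goodness-of-fit p-value for HWE per SNP.

    Observed genotype counts (n0, n1, n2) are compared with the HWE
    expectation at the sample allele frequency.
    """
    d = dosages
    n_obs = np.sum(~np.isnan(d), axis=0).astype(float)
    n2 = np.nansum(d == 2, axis=0).astype(float)
    n1 = np.nansum(d == 1, axis=0).astype(float)
    n0 = n_obs - n1 - n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n_obs)
        poly = (n_obs > 0) & (p > 0) & (p < 1)
        e0 = n_obs * (1 - p) ** 2
        e1 = n_obs * 2 * p * (1 - p)
        e2 = n_obs * p ** 2
        stat = ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2)
    p_out = np.ones(d.shape[1])
    p_out[poly] = chi2.sf(stat[poly], df=1)
    return p_out


def qc_filter(G: GenotypeMatrix, maf_min: float = 0.01,
              call_rate_min: float = 0.95, hwe_p_min: float = 1e-4,
              drop_ambiguous: bool = True):
    """Apply SNP quality-control filters in order: call rate, HWE, MAF, ambiguity.

    Returns the filtered :class:`GenotypeMatrix` and a :class:`QCReport` with
    the count removed by each filter (applied sequentially, so each SNP is
    counted against the first filter it fails).
    """
    for name, v in (("maf_min", maf_min), ("call_rate_min", call_rate_min),
                    ("hwe_p_min", hwe_p_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    d = G.dosages
    n, L = d.shape
    keep = np.ones(L, dtype=bool)
    report = QCReport(n_input=L)

    call_rate = 1.0 - np.mean(np.isnan(d), axis=0)
    fail = keep & (call_rate < call_rate_min)
    report.removed_call_rate = int(fail.sum())
    keep &= ~fail

    hwe_p = hwe_pvalues(d)
    fail = keep & (hwe_p < hwe_p_min)
    report.removed_hwe = int(fail.sum())
    keep &= ~fail

    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    fail = keep & (maf < maf_min)
    report.removed_maf = int(fail.sum())
    keep &= ~fail

    if drop_ambiguous:
        pairs = list(zip(G.variant_meta["a1"].astype(str),
                         G.variant_meta["a2"].astype(str)))
        amb = np.array([pr in AMBIGUOUS_PAIRS for pr in pairs])
        fail = keep & amb
        report.removed_ambiguous = int(fail.sum())
        keep &= ~fail

    if not keep.any():
        raise RuntimeError("all SNPs removed by QC filters")
    return G.subset(snps=np.flatnonzero(keep)), report


def compute_grm(G: GenotypeMatrix) -> GRMatrix:
    """GCTA-style GRM from mean-imputed, frequency-standardized dosages."""
    d = G.dosages.copy()
    p = np.nanmean(d, axis=0) / 2.0
    mono = np.flatnonzero((p <= 0) | (p >= 1))
    if mono.size:
        names = G.variant_meta["id"].iloc[mono[:5]].tolist()
        raise ValueError(f"monomorphic SNP(s) present (e.g. {names}); "
                         "filter them before computing the GRM")
    inds = np.where(np.isnan(d))
    if inds[0].size:
        d[inds] = np.take(2.0 * p, inds[1])
    W = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    L = d.shape[1]
    A = (W @ W.T) / L
    A = 0.5 * (A + A.T)
    ids = G.sample_meta[["fid", "iid"]].reset_index(drop=True)
    return GRMatrix(A, L, ids)


def prune_related(A: GRMatrix, threshold: float = 0.05, seed: int = 0) -> np.ndarray:
    """Greedy relatedness pruning: drop one random member of each close pair.

    While any off-diagonal relationship exceeds ``threshold``, one member of
    a violating pair is removed, chosen uniformly at random (seeded).
    Returns the sorted indices of the retained individuals, among which all
    off-diagonal entries are <= threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rng = np.random.default_rng(seed)
    vals = A.values
    n = vals.shape[0]
    active = np.ones(n, dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    viol = vals[iu, ju] > threshold
    order = np.argsort(-vals[iu, ju][viol])     # worst pairs first
    pairs = list(zip(iu[viol][order], ju[viol][order]))
    for i, j in pairs:
        if active[i] and active[j]:
            drop = i if rng.random() < 0.5 else j
            active[drop] = False
    retained = np.flatnonzero(active)
    if retained.size < 2:
        raise RuntimeError("relatedness pruning left fewer than 2 individuals")
    sub = vals[np.ix_(retained, retained)]
    np.fill_diagonal(sub, 0.0)
    assert sub.max(initial=0.0) <= threshold + 1e-12
    return retained
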