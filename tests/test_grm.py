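import numpy as np
import pandas as pd
import pytest

from gxp.grm import compute_grm, prune_related, qc_filter
from gxp.synthpop import GenotypeMatrix, simulate_genotypes


def make_genotypes(dosages, a1="A", a2="G"):
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    vm = pd.DataFrame({"id": [f"s{l}" for l in range(L)],
                       "chrom": 1, "pos": np.arange(L) + 1,
                       "a1": a1, "a2": a2})
    sm = pd.DataFrame({"fid": [f"F{i}" for i in range(n)],
                       "iid": [f"I{i}" for i in range(n)],
                       "pop": "POP1"})
    return GenotypeMatrix(dosages, vm, sm)


def grm_bruteforce(dosages):
    """Double-loop oracle for the GRM entry formula."""
    d = np.asarray(dosages, dtype=float)
    n, L = d.shape
    p = d.mean(axis=0) / 2
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for l in range(L):
                s += ((d[i, l] - 2 * p[l]) * (d[j, l] - 2 * p[l])
                      / (2 * p[l] * (1 - p[l])))
            A[i, j] = s / L
    return A


class TestQCFilter:
    def test_low_maf_removed(self):
        col = np.zeros((100, 2))
        col[0, 0] = 1.0          # MAF 0.005 at SNP 0
        col[:50, 1] = 1.0        # MAF 0.25 at SNP 1
        G = make_genotypes(col)
        Gq, rep = qc_filter(G, maf_min=0.01, hwe_p_min=0.0)
        assert rep.removed_maf == 1 and Gq.n_snps == 1
        assert Gq.variant_meta["id"].tolist() == ["s1"]

    def test_hwe_outlier_removed(self):
        # genotype counts (30, 0, 30): expected (15, 30, 15), chi2 = 60
        bad = np.repeat([0.0, 2.0], 30)
        ok = np.tile([0.0, 1.0, 1.0, 2.0], 15)
        G = make_genotypes(np.column_stack([bad, ok]))
        Gq, rep = qc_filter(G, hwe_p_min=1e-4, maf_min=0.0)
        assert rep.removed_hwe == 1
        assert Gq.variant_meta["id"].tolist() == ["s1"]

    def test_ambiguous_alleles_removed(self):
        d = np.tile([0.0, 1.0, 1.0, 2.0], (1, 1)).T @ np.ones((1, 2))
        d = np.column_stack([np.tile([0, 1, 1, 2], 25)] * 2).astype(float)
        G = make_genotypes(d)
        G.variant_meta.loc[0, ["a1", "a2"]] = ["A", "T"]
        Gq, rep = qc_filter(G, drop_ambiguous=True)
        assert rep.removed_ambiguous == 1
        assert Gq.variant_meta["id"].tolist() == ["s1"]

    def test_call_rate_filter(self):
        d = np.column_stack([np.tile([0, 1, 1, 2], 25)] * 2).astype(float)
        d[:10, 0] = np.nan       # call rate 0.9
        G = make_genotypes(d)
        Gq, rep = qc_filter(G, call_rate_min=0.95)
        assert rep.removed_call_rate == 1 and Gq.n_snps == 1

    def test_all_removed_raises(self):
        d = np.zeros((50, 2))
        d[0] = 1.0
        G = make_genotypes(d)
        with pytest.raises(RuntimeError, match="all SNPs removed"):
            qc_filter(G, maf_min=0.05)


class TestComputeGRM:
    def test_hand_computed_entry(self):
        G = make_genotypes(np.array([[0.0], [1.0], [1.0], [2.0]]))
        A = compute_grm(G)
        # p = 0.5, denominator 0.5: A_14 = (0-1)(2-1)/0.5 = -2
        assert A.values[0, 3] == pytest.approx(-2.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        d = rng.integers(0, 3, size=(10, 20)).astype(float)
        while np.any((d.mean(axis=0) == 0) | (d.mean(axis=0) == 2)):
            d = rng.integers(0, 3, size=(10, 20)).astype(float)
        A = compute_grm(make_genotypes(d))
        np.testing.assert_allclose(A.values, grm_bruteforce(d), atol=1e-10)

    def test_identical_rows_give_equal_diagonal_and_offdiagonal(self, rng):
        d = rng.integers(0, 3, size=(8, 30)).astype(float)
        d[1] = d[0]
        A = compute_grm(make_genotypes(d)).values
        assert A[0, 1] == pytest.approx(A[0, 0], abs=1e-12)

    def test_diagonal_mean_near_one(self):
        G = simulate_genotypes((60, 60), 5000, fst=0.005, seed=31)
        A = compute_grm(G)
        assert 0.95 <= np.diag(A.values).mean() <= 1.05

    def test_psd_and_symmetric(self, cohort_grm):
        A = cohort_grm.values
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert np.linalg.eigvalsh(A).min() >= -1e-8

    def test_allele_flip_invariance(self, rng):
        d = rng.integers(0, 3, size=(20, 40)).astype(float)
        while np.any((d.mean(axis=0) == 0) | (d.mean(axis=0) == 2)):
            d = rng.integers(0, 3, size=(20, 40)).astype(float)
        A1 = compute_grm(make_genotypes(d)).values
        flip = rng.random(40) < 0.5
        d2 = d.copy()
        d2[:, flip] = 2.0 - d2[:, flip]
        A2 = compute_grm(make_genotypes(d2)).values
        np.testing.assert_allclose(A1, A2, atol=1e-10)

    def test_missing_mean_imputed(self):
        d = np.tile([0.0, 1.0, 1.0, 2.0], (6, 1)).T @ np.ones((6, 3))
        d = np.tile(np.array([[0.0], [1.0], [1.0], [2.0]]), (1, 3))
        d[0, 0] = np.nan
        A = compute_grm(make_genotypes(d))
        assert np.all(np.isfinite(A.values))

    def test_monomorphic_raises_with_name(self):
        d = np.column_stack([np.zeros(6), np.tile([0.0, 1.0, 2.0], 2)])
        with pytest.raises(ValueError, match="s0"):
            compute_grm(make_genotypes(d))


class TestPruneRelated:
    def _grm_with_pair(self, value):
        from gxp.grm import GRMatrix
        A = np.eye(6) * 1.0
        A[0, 1] = A[1, 0] = value
        ids = pd.DataFrame({"fid": list("ABCDEF"), "iid": list("ABCDEF")})
        return GRMatrix(A, 100, ids)

    def test_single_violating_pair(self):
        A = self._grm_with_pair(0.9)
        kept = prune_related(A, threshold=0.05, seed=1)
        assert len(kept) == 5
        assert len({0, 1} & set(kept)) == 1

    def test_no_violations_no_removals(self):
        A = self._grm_with_pair(0.04)
        kept = prune_related(A, threshold=0.05, seed=1)
        assert len(kept) == 6

    def test_seeded_determinism(self):
        A = self._grm_with_pair(0.9)
        a = prune_related(A, threshold=0.05, seed=3)
        b = prune_related(A, threshold=0.05, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_retained_set_clean(self, rng):
        from gxp.grm import GRMatrix
        n = 30
        M = rng.normal(0, 0.05, size=(n, n))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 1.0)
        ids = pd.DataFrame({"fid": [str(i) for i in range(n)],
                            "iid": [str(i) for i in range(n)]})
        kept = prune_related(GRMatrix(A, 10, ids), threshold=0.05, seed=2)
        sub = A[np.ix_(kept, kept)].copy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.05
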