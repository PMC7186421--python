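"""Simulate the working two-population cohort.

Draws 500 + 500 individuals at 3,000 unlinked SNPs (Balding-Nichols FST
0.01) with three phenotypes on the same genotypes.  The panel size trades
off two desk-scale constraints: GREML precision improves with fewer SNPs
(SE(h2) ~ sqrt(2L)/n) while relatedness estimates get noisier
(sd ~ 1/sqrt(L)), which the downstream pruning threshold accounts for.
Phenotypes:

* ``y_plain``   - polygenic, h2 = 0.5, no interaction
* ``y_gxp``     - h2 = 0.5 with genotype-covariate interaction along PC1
                  (interaction variance 60% of the genetic variance)
* ``y_null``    - pure noise (h2 = 0)

Writes a PLINK .bed/.bim/.fam triplet and a phenotype TSV under
results/cohort/.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from gxp import lowrank as lr
from gxp.plink import write_pheno_table, write_plink
from gxp.synthpop import TruthModel, simulate_genotypes, simulate_phenotype

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "cohort"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20240601

G = simulate_genotypes((500, 500), 3000, fst=0.01, seed=SEED)
Gs = lr.standardized_genotypes(G)
eigvals, pcs = lr.top_pcs_lowrank(Gs, k=2)
pc1 = (pcs[:, 0] - pcs[:, 0].mean()) / pcs[:, 0].std()

plain = simulate_phenotype(G, TruthModel(h2=0.5), seed=SEED + 1)
gxp = simulate_phenotype(G, TruthModel(h2=0.5, var_g1_frac=0.6), c=pc1,
                         seed=SEED + 2)
null = np.random.default_rng(SEED + 3).standard_normal(G.n)

table = G.sample_meta[["fid", "iid", "pop"]].copy()
table["y_plain"] = plain.y
table["y_gxp"] = gxp.y
table["y_null"] = null
table["PC1"] = pcs[:, 0]
table["PC2"] = pcs[:, 1]

write_plink(G, str(OUT / "cohort"))
write_pheno_table(table, str(OUT / "cohort.pheno.tsv"))

print(f"cohort: n={G.n}, L={G.n_snps}, top eigenvalues "
      f"{eigvals[0]:.2f}, {eigvals[1]:.2f}")
print(f"wrote {OUT}/cohort.bed/.bim/.fam and cohort.pheno.tsv")
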