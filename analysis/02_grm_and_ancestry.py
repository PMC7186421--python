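"""QC the simulated cohort, build the GRM, prune relatives, derive ancestry
PCs and the rectangle-based population partition.

Reads results/cohort/ (run 01 first); writes the GCTA GRM triplet, PC
scores and the POP1/POP2/POP3 partition under results/ancestry/.
"""

import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from gxp.ancestry import compute_pcs, rectangle_partition
from gxp.grm import compute_grm, prune_related, qc_filter
from gxp.plink import read_pheno_table, read_plink, write_grm_gcta, \
    write_pheno_table

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "ancestry"
OUT.mkdir(parents=True, exist_ok=True)

G = read_plink(str(ROOT / "cohort" / "cohort"))
pheno = read_pheno_table(str(ROOT / "cohort" / "cohort.pheno.tsv"))
G.sample_meta["pop"] = pheno["pop"].to_numpy()

Gq, qc = qc_filter(G, maf_min=0.01, call_rate_min=0.95, hwe_p_min=1e-4)
print(f"QC: {qc.n_input} SNPs in -> {qc.n_passed} retained "
      f"(call rate {qc.removed_call_rate}, HWE {qc.removed_hwe}, "
      f"MAF {qc.removed_maf}, ambiguous {qc.removed_ambiguous})")

A = compute_grm(Gq)
# the published > 0.05 rule presumes a biobank-size panel where GRM noise
# is negligible; at L = 3,000 the off-diagonal noise sd is ~ 1/sqrt(L), so
# the threshold carries a noise guard to avoid pruning unrelated pairs
threshold = 0.05 + 5.5 / np.sqrt(A.n_snps_used)
kept = prune_related(A, threshold=threshold, seed=1)
print(f"relatedness pruning at {threshold:.3f}: "
      f"{A.n} -> {len(kept)} individuals")
A = A.subset(kept)
write_grm_gcta(A, str(OUT / "cohort"))

pcs = compute_pcs(A, k=2)
scores = pcs.to_frame(A.sample_ids)
write_pheno_table(scores, str(OUT / "cohort.pcs.tsv"))

ref = np.where(Gq.sample_meta["pop"].to_numpy()[kept] == "POP1", "REF", "OTHER")
part = rectangle_partition(pcs, ref)
out = A.sample_ids.copy()
out["POP"] = part.labels
write_pheno_table(out, str(OUT / "cohort.partition.tsv"))

lab = Gq.sample_meta["pop"].to_numpy()[kept]
r = np.corrcoef(pcs.scores[:, 0], (lab == "POP2").astype(float))[0, 1]
counts = {p: int((part.labels == p).sum()) for p in ("POP1", "POP2", "POP3")}
print(f"PC1 separates the simulated populations: |r(PC1, pop)| = {abs(r):.3f}")
print(f"rectangle partition sizes: {counts}")
print(f"wrote GRM triplet, PC scores and partition under {OUT}")
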