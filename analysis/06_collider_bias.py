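"""Collider-bias study (reduced scale).

Two genetically and residually independent traits Y and Z both influence
participation; analyses on the selected sample then measure (i) the
cross-population genetic correlation of Y (robust, stays near 1), (ii) the
bivariate-GREML heterogeneity test for Y (near nominal size), and (iii)
the estimated Y-Z genetic correlation in the selected sample, which is
biased negative purely by the collider.

Writes results/collider_bias.tsv (3 scenarios x 20 replicates,
n = 2,500 per population pre-selection).
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from gxp.biassim import report_table, run_collider_study
from gxp.synthpop import SelectionScenario, TruthModel

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
TRUTH = TruthModel(h2=0.5, var_g1_frac=0.0, fst=0.01, rg_cross=1.0)

scenarios = [
    SelectionScenario(or_y={"POP1": 2.0, "POP2": 3.0},
                      or_z={"POP1": 2.0, "POP2": 2.0}),
    SelectionScenario(or_y={"POP1": 2.0, "POP2": 3.0},
                      or_z={"POP1": 2.0, "POP2": 3.0}),
    SelectionScenario(or_y={"POP1": 2.0, "POP2": 3.0},
                      or_z={"POP1": 3.0, "POP2": 3.0}),
]
reports = run_collider_study(scenarios, truth=TRUTH, n_reps=20, seed=61,
                             n_per_pop=2500, n_snps=300)
table = report_table(reports)
table.to_csv(ROOT / "collider_bias.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print("\nacross-population rg of Y stays ~1 and its heterogeneity test near")
print("nominal, while the Y-Z genetic correlation in the selected sample is")
print("biased negative although the traits share nothing.")
print(f"wrote {ROOT / 'collider_bias.tsv'}")
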