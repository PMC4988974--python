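"""Quantify module preservation between the two species.

Reference-module definitions are mapped onto the test dataset; density and
connectivity statistics are compared against a permutation null of
same-size random gene sets, giving the Z-summary score (< 2 not preserved,
2-10 moderate, > 10 strong). A random "gold" module serves as control.
"""

import pandas as pd

import conetdiff as cd
from conetdiff.modules import ModulePartition
from conetdiff.simulate import demo_config, generate_paired_datasets

a, b, map_a, map_b, truth = generate_paired_datasets(
    demo_config(seed=1, duplicate_rate=0.0))
ha, hb = cd.harmonize_orthologs(a, b, map_a, map_b)

names = {0: "turquoise", 1: "blue", 2: "brown", 3: "yellow"}
tm = truth.true_module_of["a"]
part = ModulePartition(pd.Series(
    [names.get(tm.get(g, -1), "grey") for g in ha.gene_ids], index=ha.gene_ids))

rep = cd.z_summary(ha, hb, part, n_perm=100, gold_size=30, seed=1)
print(rep.table[["size", "z_density", "z_connectivity", "z_summary", "category"]]
      .round(2))
print("# 'yellow' was generated as independent noise in species B and is"
      " correctly called not_preserved;\n# the other planted modules share"
      " structure across species and score far above the gold control")

ov = cd.overlap_table(part, part)
print("\ncross-tabulation diagonal (identical partitions):",
      {m: int(ov.counts.loc[m, m]) for m in ov.counts.index})
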