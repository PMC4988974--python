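"""Screen for differentially expressed orthologs between the two species.

Runs the pooled-variance t-test with the bottom-30%-variance pre-filter and
Benjamini-Hochberg FDR control, then shows the calibration of the test on
data with known planted shifts.
"""

import conetdiff as cd
from conetdiff.simulate import (demo_config, generate_de_benchmark,
                                generate_paired_datasets)

a, b, map_a, map_b, _ = generate_paired_datasets(demo_config(seed=1))
ha, hb = cd.harmonize_orthologs(a, b, map_a, map_b)

deg = cd.identify_degs(ha, hb, variance_percentile=30, alpha=0.05)
n_sig = int(deg["significant"].sum())
print(f"{len(deg)} orthologs tested after the variance filter; "
      f"{n_sig} significant at q <= 0.05")
print(deg.sort_values("q_value").head(3)[["mean_a", "mean_b", "t_stat", "q_value"]])
print("# t < 0 means higher expression in species B")

# calibration against known truth: 50 of 500 genes carry a 5-sigma shift
a2, b2, shifted = generate_de_benchmark(n_genes=500, n_shifted=50, seed=2)
table = cd.identify_degs(a2, b2, variance_percentile=0)
sens = table.loc[shifted, "significant"].mean()
fpr = table.loc[~table.index.isin(shifted), "significant"].mean()
print(f"planted-shift benchmark: sensitivity {sens:.2f}, false-positive rate "
      f"{fpr:.3f} (the screen finds real shifts without flooding nulls)")
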