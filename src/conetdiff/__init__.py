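"""conetdiff: comparative differential co-expression network analysis.

A desk-scale pipeline for comparing co-expression architecture between two
related transcriptomes over shared orthologs: DEG screening (pooled-variance
t-test + BH FDR), signed soft-threshold networks and topological overlap,
module detection with a deepsplit-controlled tree cut, permutation
Z-summary module preservation, targeted-attack robustness (R/V indices and
the composite V_max), divergent-hub detection by normalized intramodular
connectivity, and gene-metabolite bipartite network comparison.
"""

from importlib.resources import files as _files

import pandas as _pd

from .data import (ExpressionDataset, OrthologMap, load_expression,
                   load_ortholog_map, write_expression, write_ortholog_map)
from .simulate import (GroundTruth, ModuleSpec, SyntheticConfig,
                       generate_de_benchmark, generate_metabolome,
                       generate_paired_datasets)
from .preprocess import (ComparabilityResult, comparability_check,
                         harmonize_orthologs, pca_overview, qc_filter)
from .diffexpr import bh_adjust, deg_statistics, identify_degs
from .network import (SoftThresholdReport, TOMMatrix, correlation_matrix,
                      pick_soft_threshold, signed_adjacency, tom_similarity)
from .modules import (COLOR_PALETTE, ModuleEigengenes, ModulePartition,
                      detect_modules, enrich_hypergeometric,
                      module_eigengenes, tissue_specificity)
from .preservation import (OverlapTable, PreservationReport, categorize,
                           kme_correlations, overlap_table, z_summary)
from .robustness import (STRATEGIES, AttackTrajectory, RobustnessReport,
                         attack_trajectory, binarize, binarize_percentile,
                         centralities, robustness_indices)
from .divergence import (flag_divergent, intramodular_connectivity,
                         shared_hub_table)
from .metabolites import (GeneMetaboliteNetwork, MetaboliteCorrelationTable,
                          build_metabolite_network, compare_complexity)
from .pipeline import PipelineConfig, run_pipeline

__version__ = "0.1.0"


def reference_hub_table() -> _pd.DataFrame:
    """Published reference table of normalized intramodular connectivities.

    Seventeen orthologs shared between the root-expressed module of
    *R. serpentina* and the matched aerial-expressed module of *C. roseus*,
    with each gene's K_i in both species. Serves as the worked example for
    divergent-hub flagging: at the default |delta| >= 0.2 exactly three
    genes are flagged.
    """
    path = _files("conetdiff") / "data" / "shared_hub_connectivity.tsv"
    t = _pd.read_csv(path, sep="\t").set_index("ortholog_id")
    t["delta"] = t["K_i_a"] - t["K_i_b"]
    return t
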