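"""Build the pathogenic co-abundance network and find its constellations.

Taxa significant (p < 0.001) against all nine factors are thresholded to
roughly twenty species; pairs correlated at r >= 0.6 are connected, and
maximal cliques of four or more taxa are the "constellations" — tightly
co-varying pathogen groups that update the classical red/orange complexes.
"""

import pandas as pd

from periomics import CohortConfig, generate_cohort, prevalence_filter, screen
from periomics.networks import build_network, select_commensal, select_pathogenic
from periomics.pipeline import condition_level_factors
from periomics.rmcorr import NINE_FACTORS, rmcorr_matrix

cohort = generate_cohort(CohortConfig(seed=7))
taxa = prevalence_filter(cohort.abundance, 0.10).to_biomass().absolute.T
cells = pd.MultiIndex.from_frame(
    cohort.metadata[["subject_id", "condition", "visit_month"]]
)
factors = condition_level_factors(cohort.biomarkers, NINE_FACTORS, index=cells)
factors.index = taxa.index
subjects = cohort.metadata["subject_id"].to_numpy()

sc = screen(taxa, factors, subjects)
pathogenic, threshold = select_pathogenic(sc)
print(f"{len(pathogenic)} pathogenic taxa selected (min-r threshold {threshold:.2f})")

tt_r, _ = rmcorr_matrix(taxa[pathogenic], subjects)
net = build_network(tt_r, edge_threshold=0.6, screen=sc, include_factors=True)
print(f"network: {net.graph.number_of_nodes()} nodes, {net.graph.number_of_edges()} edges")
print("\nconstellations (maximal cliques of >= 4 taxa):")
for clique in net.constellations:
    print("  " + ", ".join(clique))
# Two groups emerge: the red constellation around P. endodontalis,
# T. forsythia, T. denticola and F. alocis, and the pink one around
# F. nucleatum, TM7, D. invisus and T. socranskii.  P. gingivalis sits just
# outside both cliques.

commensal = select_commensal(sc)
print(f"\n{len(commensal)} taxa uncorrelated with the nine factors, e.g.: "
      + ", ".join(sorted(commensal)[:5]))
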