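"""Microbial biomass and alpha diversity from a profiler-style table.

Relative abundances only say what fraction of the community a species is;
multiplying by each sample's microbial DNA (total DNA x microbial read
fraction) converts them to absolute biomass in ng, which is what tracks
disease severity.
"""

import pandas as pd

from periomics import CohortConfig, generate_cohort, prevalence_filter

cohort = generate_cohort(CohortConfig(seed=7))
ab = cohort.abundance

summary = pd.DataFrame(
    {
        "microbial_dna_ng": ab.microbial_dna(),
        "shannon": ab.shannon(),
        "observed_species": ab.observed(),
    }
).join(cohort.metadata[["condition", "visit_month"]])

base = summary.query("visit_month == 0")
print("baseline means by site condition:")
print(base.groupby("condition").mean(numeric_only=True).round(2).to_string())
# Microbial DNA, Shannon diversity and species counts all rise from healthy
# through gingivitis to periodontitis sites: a bigger, more complex biofilm.

kept = prevalence_filter(ab, 0.10)
print(f"\nspecies present in >= 10% of samples: {len(kept.species)} of {len(ab.species)}")

biomass = kept.to_biomass().absolute
pg = biomass.loc["Porphyromonas_gingivalis"].to_frame("ng").join(cohort.metadata)
print("\nP. gingivalis biomass (ng) at baseline:")
print(pg.query("visit_month == 0").groupby("condition")["ng"].mean().round(3).to_string())
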