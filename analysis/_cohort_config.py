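"""Shared configuration for the worked mitochondrial-cohort analysis.

A 44-genome mitochondrial cohort (the sampled-genome count of the study
system) carrying the degeneration-rich 15-family roster, with moderate
within-family divergence so annotation, occurrence and tree-building all
have realistic signal and noise.
"""

from intronscape.simulate import SimConfig, demo_families

COHORT_DIR = "results/cohort_mt"

CONFIG = SimConfig(
    n_species=44,
    organelle="mt",
    seed=11,
    subst_rate_rna=0.04,
    subst_rate_orf=0.06,
    families=demo_families(rich=True),
    family_divergence=0.2,
    scaffold_extra=1800,
)
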