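"""Simulate a synthetic allohexaploid GBS panel with planted truth.

The generator draws a structured panel (Balding–Nichols subpopulation
frequencies, Markovian haplotype copying for distance-decaying LD), plants
hemizygous markers on subgenome D, derives dominant PAV markers, and emits
an accompanying BLAST-style hit table and year/yield phenotypes.
"""

import hexapop as hp

config = hp.SimConfig(
    n_accessions=120,
    n_subpops=3,
    fst=0.15,
    subgenome_sizes={
        "A": hp.SubgenomeSpec(n_chromosomes=2, chromosome_length=2e8, n_markers=60),
        "B": hp.SubgenomeSpec(2, 2e8, 70),
        "D": hp.SubgenomeSpec(2, 2e8, 35),  # the subgenome-D marker deficit
    },
    ld_decay_bp=5e6,
    hemizygous_fraction=0.2,
    seed=7,
)
panel = hp.simulate_panel(config)

print(panel.snp)
print(panel.pav)
print(f"planted hemizygous markers : {len(panel.truth.hemizygous_ids)}")
print(f"hit-table rows             : {len(panel.hits)}")
print(panel.phenotypes.head())

# Every downstream stage can be validated against panel.truth: subpopulation
# labels, per-subpopulation allele frequencies, the planted LD scale and the
# list of hemizygous markers.
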