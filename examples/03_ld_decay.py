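"""Structure-corrected LD, the unlinked null and the decay distance.

LD between two markers is the squared partial correlation of their dosage
codes given principal-coordinate covariates. The decay distance is where a
12-effective-df smoothing spline of LD on physical distance drops to the
95th percentile of LD among random cross-chromosome pairs.
"""

import hexapop as hp

config = hp.SimConfig(
    n_accessions=200, n_subpops=1, fst=0.0,
    subgenome_sizes={"A": hp.SubgenomeSpec(1, 1e8, 150),
                     "B": hp.SubgenomeSpec(1, 1e8, 150),
                     "D": hp.SubgenomeSpec(1, 1e8, 150)},
    ld_decay_bp=5e6,  # the planted decay scale we will try to recover
    hemizygous_fraction=0.0, pav_fraction=0.0, missing_rate=0.02, seed=1,
)
panel = hp.simulate_genotypes(config)
info = panel.marker_info.assign(max_score=99.0, n_best_hits=1,
                                n_hit_positions=1, n_subgenomes_hit=1)

kinship = hp.dice_kinship(panel.snp)
pcs = hp.pcoa(kinship, n_axes=3).coordinates.to_numpy()

table = hp.pairwise_ld(panel.snp, info, max_distance=2e7, pcs=pcs,
                       max_pairs=6000, seed=1)
null = hp.unlinked_null(panel.snp, info, n_pairs=5000, pcs=pcs, seed=1)
model = hp.fit_decay(table, null.q95)

print(f"pairs used                : {len(table)}")
print(f"unlinked null q95         : {null.q95:.4f}")
print(f"decay distance            : {model.decay_distance / 1e6:.2f} Mb "
      f"(planted scale {config.ld_decay_bp / 1e6:.0f} Mb)")
print(f"spline effective df       : {model.spline.edf:.1f}")
# Expected LD exceeds the unlinked background out to a few Mb: markers within
# that span are redundant for association scans, markers beyond it are not.
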