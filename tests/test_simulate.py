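"""Generator behavior: determinism, planted frequencies/LD/structure,
hemizygosity and dominant recoding, hit-table and phenotype properties."""

import numpy as np
import pandas as pd
import pytest

import hexapop as hp
from conftest import small_sizes


def _cfg(**kw):
    base = dict(
        n_accessions=80, n_subpops=2, fst=0.2, subgenome_sizes=small_sizes(),
        ld_decay_bp=5e6, missing_rate=0.05, seed=5,
    )
    base.update(kw)
    return hp.SimConfig(**base)


def test_identical_config_reproduces_bitwise():
    a = hp.simulate_panel(_cfg())
    b = hp.simulate_panel(_cfg())
    assert np.array_equal(a.snp.calls, b.snp.calls)
    assert np.array_equal(a.pav.calls, b.pav.calls)
    assert a.snp.marker_ids == b.snp.marker_ids
    pd.testing.assert_frame_equal(a.hits, b.hits)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    assert a.truth.hemizygous_ids == b.truth.hemizygous_ids


def test_different_seeds_differ():
    a = hp.simulate_panel(_cfg(seed=1))
    b = hp.simulate_panel(_cfg(seed=2))
    assert not np.array_equal(a.snp.calls, b.snp.calls)


def test_planted_frequencies_recovered_within_3_binomial_sd():
    cfg = _cfg(fst=0.0, n_accessions=200, missing_rate=0.0, hemizygous_fraction=0.0,
               pav_fraction=0.0, inbreeding=0.0)
    panel = hp.simulate_genotypes(cfg)
    p_hat, _ = hp.allele_frequencies(panel.snp.calls)
    p_true = panel.truth.ancestral_freqs.loc[panel.snp.marker_ids].to_numpy()
    n_alleles = 2 * cfg.n_accessions
    sd = np.sqrt(p_true * (1 - p_true) / n_alleles)
    frac_outside = np.mean(np.abs(p_hat - p_true) > 3 * sd)
    assert frac_outside < 0.05  # ~0.3% expected under normality; 5% is generous


def test_no_structure_no_ld_gives_independent_markers():
    cfg = _cfg(fst=0.0, ld_decay_bp=0.0, missing_rate=0.0, hemizygous_fraction=0.0,
               pav_fraction=0.0, n_accessions=150)
    panel = hp.simulate_genotypes(cfg)
    X = panel.snp.calls.astype(float)
    R = np.corrcoef(X.T)
    off = np.abs(R[np.triu_indices(R.shape[0], k=1)])
    assert np.nanmean(off) < 0.08  # |r| ~ 1/sqrt(n) for independent columns


def test_subpopulation_structure_separates_kinship():
    panel = hp.simulate_genotypes(_cfg(fst=0.3, n_accessions=100))
    K = hp.dice_kinship(panel.snp).to_numpy()
    lab = panel.truth.subpop_labels.to_numpy()
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(len(lab), k=1)
    within = K[iu][same[iu]].mean()
    cross = K[iu][~same[iu]].mean()
    assert cross < within


def test_binned_ld_decays_with_distance():
    cfg = _cfg(ld_decay_bp=5e6, fst=0.0, n_accessions=150, missing_rate=0.0,
               hemizygous_fraction=0.0, pav_fraction=0.0)
    panel = hp.simulate_genotypes(cfg)
    info = panel.marker_info
    gm = panel.snp
    pos = info.loc[gm.marker_ids, "position"].to_numpy(float)
    chrom = info.loc[gm.marker_ids, "chromosome"].to_numpy()
    X = gm.calls.astype(float)
    near, far = [], []
    for c in np.unique(chrom):
        cols = np.nonzero(chrom == c)[0]
        for ai in range(len(cols)):
            for bi in range(ai + 1, len(cols)):
                d = abs(pos[cols[bi]] - pos[cols[ai]])
                r = np.corrcoef(X[:, cols[ai]], X[:, cols[bi]])[0, 1] ** 2
                if d < 1e6:
                    near.append(r)
                elif d > 1.5e7:
                    far.append(r)
    assert np.mean(near) > np.mean(far)


def test_hemizygous_markers_called_heterozygous():
    cfg = _cfg(hemizygous_fraction=0.2, het_call_prob=0.95, missing_rate=0.0,
               pav_fraction=0.0)
    panel = hp.simulate_genotypes(cfg)
    gm = panel.snp
    het = hp.heterozygosity(gm.calls)
    hemi = np.isin(gm.marker_ids, panel.truth.hemizygous_ids)
    assert hemi.sum() > 0
    assert het[hemi].mean() > 0.9
    assert het[~hemi].mean() < 0.2  # default inbreeding keeps true het low


def test_pav_dominant_recoding_matches_underlying_dosage():
    cfg = _cfg(missing_rate=0.0, pav_fraction=0.5, hemizygous_fraction=0.0,
               n_accessions=30)
    panel = hp.simulate_genotypes(cfg)
    # regenerate without the PAV split: same streams => same dosages
    full = hp.simulate_genotypes(
        hp.SimConfig(**{**cfg.__dict__, "pav_fraction": 0.0})
    )
    dosage = {m: full.snp.calls[:, j] for j, m in enumerate(full.snp.marker_ids)}
    for j, m in enumerate(panel.pav.marker_ids):
        expected = (dosage[m] >= 1).astype(np.int8)
        assert np.array_equal(panel.pav.calls[:, j], expected)


def test_hit_table_single_hit_when_rates_zero(small_panel):
    hits = hp.simulate_hit_table(small_panel.marker_info, small_panel.truth,
                                 multi_hit_rate=0.0, tie_rate=0.0,
                                 hemi_alt_subgenome_prob=0.0, seed=3)
    assert (hits.groupby("marker_id").size() == 1).all()
    # best hits sit at the true positions
    merged = hits.set_index("marker_id").join(small_panel.marker_info, rsuffix="_true")
    assert (merged["position"] == merged["position_true"]).all()


def test_hit_table_multi_hit_rate_binomial(small_panel):
    hits = hp.simulate_hit_table(small_panel.marker_info, small_panel.truth,
                                 multi_hit_rate=0.3, tie_rate=0.0,
                                 hemi_alt_subgenome_prob=0.0, seed=3)
    n = len(small_panel.marker_info)
    n_multi = (hits.groupby("marker_id").size() >= 2).sum()
    sd = np.sqrt(n * 0.3 * 0.7)
    assert abs(n_multi - 0.3 * n) < 4 * sd


def test_hemizygous_markers_hit_multiple_subgenomes(structured_panel):
    hits = structured_panel.hits
    info = hp.derive_marker_info(
        hits[hits["marker_id"].isin(set(structured_panel.snp.marker_ids))],
        structured_panel.snp,
    )
    hemi = info.index.isin(structured_panel.truth.hemizygous_ids)
    multi = (info["n_subgenomes_hit"] >= 2).to_numpy()
    assert multi[hemi].mean() > multi[~hemi].mean()


def test_hit_table_rejects_bad_rates(small_panel):
    with pytest.raises(ValueError):
        hp.simulate_hit_table(small_panel.marker_info, small_panel.truth, multi_hit_rate=-0.1)


def test_phenotype_unknown_effect_marker_rejected(small_panel):
    cfg = _cfg(phenotype_effects=[("nonexistent", 10.0)])
    with pytest.raises(ValueError, match="unknown marker"):
        hp.simulate_phenotypes(small_panel.snp, small_panel.truth, cfg)


def test_zero_effects_leave_year_uncorrelated(small_panel):
    cfg = _cfg(phenotype_effects=[], year_noise_sd=4.0)
    pheno = hp.simulate_phenotypes(small_panel.snp, small_panel.truth, cfg)
    year = pheno["year"].astype(float).to_numpy()
    X = small_panel.snp.calls.astype(float)
    X[X == -1] = np.nan
    rs = []
    for j in range(0, X.shape[1], 5):
        ok = np.isfinite(X[:, j])
        if ok.sum() > 10 and np.nanstd(X[ok, j]) > 0:
            rs.append(abs(np.corrcoef(X[ok, j], year[ok])[0, 1]))
    assert np.mean(rs) < 0.15


def test_config_validation_errors():
    with pytest.raises(ValueError, match="fst"):
        hp.SimConfig(fst=1.5).validate()
    with pytest.raises(ValueError, match="missing_rate"):
        hp.SimConfig(missing_rate=-0.1).validate()
    with pytest.raises(ValueError, match="subgenome-D"):
        hp.SimConfig(
            subgenome_sizes={"A": hp.SubgenomeSpec(2, 1e8, 10)},
            hemizygous_fraction=0.5,
        ).validate()
    with pytest.raises(ValueError, match=">= 2 markers"):
        hp.SimConfig(subgenome_sizes={"A": hp.SubgenomeSpec(2, 1e8, 1)}).validate()
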