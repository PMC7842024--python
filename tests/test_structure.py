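"""Kinship, ordination, bootstrap grouping, distribution comparisons and
the association scan."""

import numpy as np
import pandas as pd
import pytest

import hexapop as hp
from hexapop.structure import band_matrix, chi_square_binned, dice_from_bands
from conftest import brute_bh, brute_dice, small_sizes


def _snp_gm(calls):
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_mark = calls.shape
    return hp.GenotypeMatrix(
        [f"k{i}" for i in range(n_acc)], [f"m{j}" for j in range(n_mark)],
        calls, "snp",
        ref_alleles=np.array(["A"] * n_mark), alt_alleles=np.array(["G"] * n_mark),
    )


# -- Dice kinship -----------------------------------------------------------

def test_dice_hand_example():
    # band vectors [1,1,0] vs [1,0,1] -> 2*1/(2+2) = 0.5
    bands = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
    K = dice_from_bands(bands)
    assert K[0, 1] == pytest.approx(0.5)


def test_dice_identical_and_disjoint():
    bands = np.array([[1.0, 0.0, 1.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    K = dice_from_bands(bands)
    assert K[0, 1] == pytest.approx(1.0)
    assert K[0, 2] == pytest.approx(0.0)
    assert np.allclose(np.diag(K), 1.0)


def test_dice_matches_setbased_oracle_with_missing():
    rng = np.random.default_rng(21)
    for _ in range(5):
        calls = rng.integers(-1, 3, size=(6, 20)).astype(np.int8)
        gm = _snp_gm(calls)
        K = hp.dice_kinship(gm).to_numpy()
        for i in range(6):
            for j in range(i + 1, 6):
                expected = brute_dice(calls[i], calls[j], "snp")
                if np.isnan(expected):
                    assert np.isnan(K[i, j])
                else:
                    assert K[i, j] == pytest.approx(expected, abs=1e-12)


def test_dice_heterozygote_carries_both_bands():
    # acc0 het (both bands), acc1 hom ref, acc2 hom alt
    K = hp.dice_kinship(_snp_gm([[1], [0], [2]])).to_numpy()
    assert K[0, 1] == pytest.approx(2 * 1 / (2 + 1))
    assert K[0, 2] == pytest.approx(2 * 1 / (2 + 1))
    assert K[1, 2] == pytest.approx(0.0)


def test_dice_pools_snp_and_pav(small_panel):
    K = hp.dice_kinship(small_panel.snp, small_panel.pav)
    arr = K.to_numpy()
    assert np.allclose(arr, arr.T)
    vals = arr[np.isfinite(arr)]
    assert vals.min() >= 0.0 and vals.max() <= 1.0


# -- PCoA -------------------------------------------------------------------

def test_pcoa_constant_similarity_gives_zero_coordinates():
    K = pd.DataFrame(np.ones((5, 5)))
    res = hp.pcoa(K)
    assert res.coordinates.shape[1] == 0


def test_pcoa_spectral_identities():
    rng = np.random.default_rng(22)
    X = rng.normal(size=(12, 30))
    R = np.corrcoef(X)
    S = (R + 1.0) / 2.0  # unit-diagonal PSD similarity
    res = hp.pcoa(pd.DataFrame(S))
    n = S.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ S @ J
    assert res.eigenvalues.sum() == pytest.approx(np.trace(G), abs=1e-8)
    # squared coordinate distances reproduce the Gower-transformed dissimilarity
    C = res.coordinates.to_numpy()
    for i in range(n):
        for j in range(n):
            d2 = np.sum((C[i] - C[j]) ** 2)
            assert d2 == pytest.approx(G[i, i] + G[j, j] - 2 * G[i, j], abs=1e-8)


def test_pcoa_eigenvalues_match_skbio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(23)
    X = rng.normal(size=(10, 40))
    S = (np.corrcoef(X) + 1.0) / 2.0
    res = hp.pcoa(pd.DataFrame(S))
    D = np.sqrt(np.clip(2.0 * (1.0 - S), 0, None))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
    got = np.sort(res.eigenvalues[res.eigenvalues > 1e-10])[::-1]
    exp = np.sort(ref.eigvals.to_numpy()[ref.eigvals.to_numpy() > 1e-10])[::-1]
    # our Gower form centers S itself; skbio centers -D^2/2 = S - const: same spectrum
    assert np.allclose(got, exp[: len(got)], atol=1e-8)


def test_pcoa_first_axis_separates_planted_subpops(structured_panel):
    K = hp.dice_kinship(structured_panel.snp)
    res = hp.pcoa(K)
    pco1 = res.coordinates["PCO1"].to_numpy()
    labels = structured_panel.truth.subpop_labels.to_numpy()
    pred = (pco1 > 0).astype(int)
    acc = max((pred == labels).mean(), (pred != labels).mean())
    assert acc > 0.95


def test_pcoa_rejects_asymmetry():
    M = np.eye(4)
    M[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        hp.pcoa(pd.DataFrame(M))


# -- bootstrap-stable groups ------------------------------------------------

def test_stable_groups_planted_clusters(structured_panel):
    grp = hp.stable_groups(structured_panel.snp, n_bootstrap=30, n_groups=2, seed=4)
    assert grp.n_stable == 2
    assert (grp.stability["mean_co_clustering"] > 0.9).all()
    # groups reproduce the planted subpopulations
    labels = structured_panel.truth.subpop_labels
    tab = pd.crosstab(grp.labels, labels)
    assert (tab.max(axis=1) / tab.sum(axis=1) > 0.95).all()


def test_stable_groups_deterministic_and_order_invariant(structured_panel):
    a = hp.stable_groups(structured_panel.snp, n_bootstrap=15, n_groups=2, seed=4)
    b = hp.stable_groups(structured_panel.snp, n_bootstrap=15, n_groups=2, seed=4)
    pd.testing.assert_series_equal(a.labels, b.labels)
    # permuted accession order: same grouping structure (modulo group ids)
    rng = np.random.default_rng(0)
    perm = rng.permutation(structured_panel.snp.n_accessions)
    gmp = structured_panel.snp.subset_accessions(perm)
    c = hp.stable_groups(gmp, n_bootstrap=15, n_groups=2, seed=4)
    joined = pd.concat([a.labels.rename("orig"), c.labels.rename("perm")], axis=1)
    tab = pd.crosstab(joined["orig"], joined["perm"])
    assert (tab > 0).sum().sum() == len(tab)  # one-to-one label correspondence


def test_stable_groups_parameter_validation(small_panel):
    with pytest.raises(ValueError):
        hp.stable_groups(small_panel.snp, n_bootstrap=0, n_groups=2)
    with pytest.raises(ValueError):
        hp.stable_groups(small_panel.snp, n_bootstrap=5, n_groups=1)


# -- distribution comparisons -----------------------------------------------

def test_chi_square_sample_against_itself_is_one():
    rng = np.random.default_rng(24)
    s = rng.beta(5, 2, size=400)
    res = hp.compare_kinship_distributions(s, s, test="chi_square")
    assert res.p_value == 1.0


def test_mann_whitney_detects_small_shift():
    rng = np.random.default_rng(25)
    a = np.clip(rng.normal(0.7, 0.05, size=500), 0, 1)
    b = np.clip(rng.normal(0.75, 0.05, size=500), 0, 1)
    res = hp.compare_kinship_distributions(a, b, test="mann_whitney")
    assert res.p_value < 0.01


def test_degenerate_binning_reported_not_raised():
    a = np.full(50, 0.55)
    b = np.full(60, 0.552)
    res = hp.compare_kinship_distributions(a, b, test="chi_square")
    assert res.note.startswith("skipped") or res.p_value == 1.0


def test_bin_merging_keeps_expected_counts():
    rng = np.random.default_rng(26)
    a = rng.beta(8, 2, size=80)
    b = rng.beta(2, 8, size=80)
    res = chi_square_binned(a, b, bins=10)
    assert np.isfinite(res.p_value)


# -- BH adjustment and the year scan ----------------------------------------

def test_bh_matches_bruteforce_on_random_vectors():
    rng = np.random.default_rng(27)
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(hp.bh_adjust(p), brute_bh(p), atol=1e-12)


def test_bh_hand_example():
    assert np.allclose(hp.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_year_scan_finds_planted_effect():
    cfg = hp.SimConfig(
        n_accessions=300, n_subpops=2, fst=0.1, subgenome_sizes=small_sizes(),
        ld_decay_bp=0.0, hemizygous_fraction=0.0, pav_fraction=0.0,
        missing_rate=0.02, year_noise_sd=2.0, seed=31,
    )
    panel = hp.simulate_panel(cfg)
    p, q = hp.allele_frequencies(panel.snp.calls)
    marker = panel.snp.marker_ids[int(np.argmax(np.minimum(p, q) > 0.3))]
    cfg.phenotype_effects = [(marker, 10.0)]
    pheno = hp.simulate_phenotypes(panel.snp, panel.truth, cfg)
    scan = hp.year_scan(panel.snp, pheno["year"].dropna())
    tested = scan["p_adj"].dropna()
    assert tested.idxmin() == marker
    assert tested.min() < 0.05


def test_year_scan_rejects_constant_response(small_panel):
    years = pd.Series(2000, index=small_panel.snp.accession_ids)
    with pytest.raises(ValueError, match="constant"):
        hp.year_scan(small_panel.snp, years)


def test_year_scan_skips_low_mvf_markers(small_panel):
    years = pd.Series(
        np.random.default_rng(1).integers(1990, 2020, size=small_panel.snp.n_accessions),
        index=small_panel.snp.accession_ids,
    )
    scan = hp.year_scan(small_panel.snp, years, mvf_min=0.4)
    assert (scan["skipped"] == "mvf_below_floor").any()
    assert scan.loc[scan["skipped"] == "mvf_below_floor", "p_raw"].isna().all()
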