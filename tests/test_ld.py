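"""Linkage disequilibrium: partial-correlation r2, unlinked null, decay
spline and UPGMA marker blocks."""

import numpy as np
import pandas as pd
import pytest

import hexapop as hp
from hexapop.ld import PSpline, ld_matrix
from conftest import brute_upgma_partition, small_sizes


def test_r2_without_covariates_is_squared_pearson():
    rng = np.random.default_rng(0)
    for _ in range(50):
        x = rng.integers(0, 3, size=80).astype(float)
        y = rng.integers(0, 3, size=80).astype(float)
        r2, n = hp.structure_corrected_r2(x, y, pcs=None, min_complete=2)
        assert n == 80
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 == pytest.approx(expected, abs=1e-10)


def test_r2_is_symmetric():
    rng = np.random.default_rng(1)
    pcs = rng.normal(size=(60, 3))
    for _ in range(20):
        x = rng.integers(0, 3, size=60).astype(float)
        y = rng.integers(0, 3, size=60).astype(float)
        a, _ = hp.structure_corrected_r2(x, y, pcs, min_complete=2)
        b, _ = hp.structure_corrected_r2(y, x, pcs, min_complete=2)
        assert a == pytest.approx(b, abs=1e-10)


def test_r2_self_is_one_and_covariate_absorbs():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 3, size=50).astype(float)
    assert hp.structure_corrected_r2(x, x, min_complete=2)[0] == pytest.approx(1.0)
    pc = rng.normal(size=50)
    y = pc.copy()  # response equal to the covariate
    r2, _ = hp.structure_corrected_r2(x, y, pcs=pc, min_complete=2)
    assert np.isnan(r2)  # zero residual variance after projection -> undefined


def test_shared_confounder_correction_reduces_r2():
    rng = np.random.default_rng(3)
    conf = rng.normal(size=200)
    x = conf + 0.3 * rng.normal(size=200)
    y = conf + 0.3 * rng.normal(size=200)
    raw, _ = hp.structure_corrected_r2(x, y, min_complete=2)
    corrected, _ = hp.structure_corrected_r2(x, y, pcs=conf, min_complete=2)
    assert corrected < raw


def test_r2_pairwise_complete_and_minimum():
    x = np.array([0, 1, 2, -1, 0, 1, 2, 0, 1, 2], dtype=float)
    y = np.array([0, 1, 2, 0, -1, 1, 2, 0, 1, 2], dtype=float)
    r2, n = hp.structure_corrected_r2(x, y, min_complete=2)
    assert n == 8
    assert r2 == pytest.approx(1.0)
    r2, n = hp.structure_corrected_r2(x, y, min_complete=30)
    assert np.isnan(r2)


def test_pairwise_ld_table_rules():
    calls = np.tile(np.array([[0], [1], [2], [0], [2], [1], [0], [2]], dtype=np.int8), (1, 3))
    gm = hp.GenotypeMatrix(
        [f"k{i}" for i in range(8)], ["m0", "m1", "m2"], calls, "snp",
        ref_alleles=np.array(["A"] * 3), alt_alleles=np.array(["G"] * 3),
    )
    info = pd.DataFrame(
        {"chromosome": ["1A", "1A", "2B"], "position": [1000, 2000, 5000],
         "n_best_hits": 1, "n_hit_positions": 1, "n_subgenomes_hit": 1,
         "subgenome": ["A", "A", "B"]},
        index=pd.Index(["m0", "m1", "m2"], name="marker_id"),
    )
    table = hp.pairwise_ld(gm, info, min_complete=2)
    # only the within-chromosome pair appears; identical columns give r2 = 1
    assert len(table) == 1
    assert table.iloc[0]["marker_i"] == "m0" and table.iloc[0]["marker_j"] == "m1"
    assert table.iloc[0]["distance"] == 1000
    assert table.iloc[0]["r2"] == pytest.approx(1.0)


def test_unlinked_null_deterministic_and_excludes_constants(structured_panel, structured_info):
    gm = structured_panel.snp
    a = hp.unlinked_null(gm, structured_info, n_pairs=500, seed=9, min_complete=20)
    b = hp.unlinked_null(gm, structured_info, n_pairs=500, seed=9, min_complete=20)
    assert a.q95 == b.q95
    assert np.isfinite(a.r2).all()
    c = hp.unlinked_null(gm, structured_info, n_pairs=500, seed=10, min_complete=20)
    assert c.q95 != a.q95


def test_unlinked_null_requires_two_chromosomes():
    calls = np.random.default_rng(0).integers(0, 3, size=(40, 5)).astype(np.int8)
    gm = hp.GenotypeMatrix(
        [f"k{i}" for i in range(40)], [f"m{j}" for j in range(5)], calls, "snp",
        ref_alleles=np.array(["A"] * 5), alt_alleles=np.array(["G"] * 5),
    )
    info = pd.DataFrame(
        {"chromosome": "1A", "position": np.arange(5) * 1000 + 1,
         "n_best_hits": 1, "n_hit_positions": 1, "n_subgenomes_hit": 1, "subgenome": "A"},
        index=pd.Index(gm.marker_ids, name="marker_id"),
    )
    with pytest.raises(ValueError, match="2 chromosomes"):
        hp.unlinked_null(gm, info, n_pairs=10)


def test_pspline_hits_target_effective_df():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 2e7, size=3000)
    y = np.exp(-x / 5e6) + rng.normal(0, 0.1, size=3000)
    sp = PSpline.fit(x, y, df=12.0)
    assert sp.edf == pytest.approx(12.0, abs=0.05)
    # smooth recovery of the trend at a few points
    grid = np.array([1e6, 5e6, 1.5e7])
    assert np.allclose(sp(grid), np.exp(-grid / 5e6), atol=0.05)


def _decay_table(rng, n=2000, scale=5e6):
    d = rng.uniform(1e4, 2e7, size=n)
    r2 = 0.4 * np.exp(-d / scale) + rng.gamma(1.0, 0.01, size=n)
    return pd.DataFrame({"distance": d, "r2": np.clip(r2, 0, 1),
                         "marker_i": "x", "marker_j": "y", "chromosome": "1A",
                         "n_complete": 100})


def test_fit_decay_basic_geometry():
    rng = np.random.default_rng(5)
    table = _decay_table(rng)
    model = hp.fit_decay(table, null_q95=0.05)
    assert 0 < model.decay_distance < 2e7
    # doubling the null cannot increase the decay distance
    model2 = hp.fit_decay(table, null_q95=0.10)
    assert model2.decay_distance <= model.decay_distance


def test_fit_decay_zero_ld_gives_zero():
    rng = np.random.default_rng(6)
    table = _decay_table(rng)
    table["r2"] = 0.0
    model = hp.fit_decay(table, null_q95=0.05)
    assert model.decay_distance == 0.0


def test_fit_decay_requires_enough_pairs():
    rng = np.random.default_rng(7)
    with pytest.raises(ValueError, match="100"):
        hp.fit_decay(_decay_table(rng, n=50), null_q95=0.05)


def test_upgma_blocks_on_constructed_ld():
    # two tight groups: within r2 ~ 1 (identical columns), across ~ 0
    rng = np.random.default_rng(8)
    base1 = rng.integers(0, 3, size=60)
    base2 = rng.permutation(base1)
    calls = np.stack([base1, base1, base2, base2], axis=1).astype(np.int8)
    gm = hp.GenotypeMatrix(
        [f"k{i}" for i in range(60)], ["m0", "m1", "m2", "m3"], calls, "snp",
        ref_alleles=np.array(["A"] * 4), alt_alleles=np.array(["G"] * 4),
    )
    info = pd.DataFrame(
        {"chromosome": "1A", "position": [1000, 2000, 3000, 4000],
         "n_best_hits": 1, "n_hit_positions": 1, "n_subgenomes_hit": 1, "subgenome": "A"},
        index=pd.Index(gm.marker_ids, name="marker_id"),
    )
    blocks = hp.cluster_markers_ld(gm, info, r2_threshold=0.2, min_complete=10)
    assert len(blocks.blocks) == 2
    members = blocks.membership.groupby("block_id")["marker_id"].apply(set)
    assert {"m0", "m1"} in members.tolist() and {"m2", "m3"} in members.tolist()


def test_blocks_never_span_chromosomes_and_singletons_when_unlinked(structured_panel, structured_info):
    gm = structured_panel.snp.subset_markers(structured_panel.snp.marker_ids[:60])
    info = structured_info.loc[gm.marker_ids]
    blocks = hp.cluster_markers_ld(gm, info, r2_threshold=0.99, min_complete=20)
    merged = blocks.membership.merge(blocks.blocks, on="block_id", suffixes=("", "_b"))
    assert (merged["chromosome"] == merged["chromosome_b"]).all()
    with pytest.raises(ValueError, match="r2_threshold"):
        hp.cluster_markers_ld(gm, info, r2_threshold=1.5)


def test_upgma_matches_bruteforce_oracle():
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(9)
    for trial in range(10):
        n = int(rng.integers(4, 9))
        D = rng.uniform(0.05, 1.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        cut = float(rng.uniform(0.2, 0.9))
        oracle = brute_upgma_partition(D, cut)
        Z = linkage(squareform(D, checks=False), method="average")
        labels = fcluster(Z, t=cut, criterion="distance")
        got = {frozenset(np.nonzero(labels == lab)[0].tolist()) for lab in np.unique(labels)}
        assert got == oracle
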