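"""Shared fixtures: small simulated panels built at test time."""

import numpy as np
import pytest

import hexapop as hp


def small_sizes(a=40, b=40, d=30, n_chrom=2, length=1e8):
    return {
        "A": hp.SubgenomeSpec(n_chrom, length, a),
        "B": hp.SubgenomeSpec(n_chrom, length, b),
        "D": hp.SubgenomeSpec(n_chrom, length, d),
    }


@pytest.fixture(scope="session")
def small_panel():
    """60 accessions, ~220 markers, 2 subpopulations — fast general fixture."""
    cfg = hp.SimConfig(
        n_accessions=60, n_subpops=2, fst=0.3, subgenome_sizes=small_sizes(),
        ld_decay_bp=5e6, missing_rate=0.05, seed=11,
    )
    return hp.simulate_panel(cfg)


@pytest.fixture(scope="session")
def structured_panel():
    """150 accessions, 2 clearly diverged subpopulations, moderate marker set."""
    cfg = hp.SimConfig(
        n_accessions=150, n_subpops=2, fst=0.3,
        subgenome_sizes=small_sizes(80, 80, 60),
        ld_decay_bp=5e6, pav_fraction=0.2, missing_rate=0.03, seed=7,
    )
    return hp.simulate_panel(cfg)


@pytest.fixture(scope="session")
def structured_info(structured_panel):
    snp = structured_panel.snp
    hits = structured_panel.hits
    return hp.derive_marker_info(hits[hits["marker_id"].isin(set(snp.marker_ids))], snp)


# ---------------------------------------------------------------------------
# independent brute-force oracles (never reuse package internals)
# ---------------------------------------------------------------------------

def brute_pic(p):
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def brute_marker_stats(column):
    """(call_rate, p_alt, mvf, heterozygosity) from a single SNP dosage column."""
    column = list(column)
    non_missing = [c for c in column if c != -1]
    cr = len(non_missing) / len(column)
    if not non_missing:
        return cr, float("nan"), float("nan"), float("nan")
    alt = sum(c for c in non_missing)
    p = alt / (2 * len(non_missing))
    het = sum(1 for c in non_missing if c == 1) / len(non_missing)
    return cr, p, min(p, 1 - p), het


def brute_dice(calls_i, calls_j, marker_type="snp"):
    """Set-based Dice similarity between two accessions' call vectors."""
    shared = total_i = total_j = 0
    for a, b in zip(calls_i, calls_j):
        if a == -1 or b == -1:
            continue
        if marker_type == "snp":
            bands_a = {("ref", a <= 1), ("alt", a >= 1)}
            bands_i = {name for name, on in bands_a if on}
            bands_j = {name for name, on in {("ref", b <= 1), ("alt", b >= 1)} if on}
        else:
            bands_i = {"band"} if a == 1 else set()
            bands_j = {"band"} if b == 1 else set()
        shared += len(bands_i & bands_j)
        total_i += len(bands_i)
        total_j += len(bands_j)
    if total_i + total_j == 0:
        return float("nan")
    return 2.0 * shared / (total_i + total_j)


def brute_bh(p_values):
    """Step-up Benjamini–Hochberg adjustment."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def brute_upgma_partition(D, cut_height):
    """Naive group-average agglomeration of a dissimilarity matrix, cut so
    that no merge above ``cut_height`` is applied. Returns frozenset labels."""
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        if d > cut_height:
            break
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return {c for c in clusters}
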