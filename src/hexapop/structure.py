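"""Dice kinship, principal coordinate analysis, bootstrap-stable groups,
kinship-distribution comparisons and the registration-year association scan.

Kinship between accessions is the Dice band-sharing coefficient: every SNP
marker contributes two binary "band" indicators (presence of the REF allele,
presence of the ALT allele — a heterozygote carries both, matching the
present/present reading of a dominant assay), PAV markers contribute their
0/1 call directly, and Dice(i, j) = 2 x shared bands / (bands_i + bands_j)
over pairwise-complete markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .containers import MISSING, PAV, SNP, GenotypeMatrix


# ---------------------------------------------------------------------------
# Dice kinship
# ---------------------------------------------------------------------------

def band_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Binary band indicators per accession.

    Returns ``(bands, marker_of_band)``: bands is float (n_accessions x
    n_bands) with NaN for missing calls; marker_of_band maps each band column
    to its source marker index (two bands per SNP, one per PAV), which is what
    marker-level bootstrap resampling needs.
    """
    calls = gm.calls
    if gm.marker_type == SNP:
        ref_band = np.where(calls == MISSING, np.nan, (calls <= 1).astype(float))
        alt_band = np.where(calls == MISSING, np.nan, (calls >= 1).astype(float))
        bands = np.empty((calls.shape[0], 2 * calls.shape[1]))
        bands[:, 0::2] = ref_band
        bands[:, 1::2] = alt_band
        marker_of_band = np.repeat(np.arange(calls.shape[1]), 2)
    else:
        bands = np.where(calls == MISSING, np.nan, calls.astype(float))
        marker_of_band = np.arange(calls.shape[1])
    return bands, marker_of_band


def dice_from_bands(bands: np.ndarray) -> np.ndarray:
    """Dice similarity matrix from a band matrix (NaN = missing band)."""
    a = np.nan_to_num(bands, nan=0.0)
    v = np.isfinite(bands).astype(float)
    shared = a @ a.T
    counts = a @ v.T  # bands of i restricted to markers also scored in j
    denom = counts + counts.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, 2.0 * shared / denom, np.nan)
    complete = v @ v.T
    K[complete == 0] = np.nan
    np.fill_diagonal(K, 1.0)
    return K


def dice_kinship(*genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Dice kinship of the panel from one or more marker datasets.

    Multiple datasets (e.g. the SNP and PAV matrices) are pooled at the band
    level. Accession pairs with zero pairwise-complete bands are NaN and
    reported with a warning.
    """
    if not genotypes:
        raise ValueError("need at least one genotype matrix")
    acc = genotypes[0].accession_ids
    if genotypes[0].n_accessions < 2:
        raise ValueError("kinship needs at least 2 accessions")
    parts = []
    for gm in genotypes:
        if gm.accession_ids != acc:
            raise ValueError("genotype matrices cover different accessions")
        parts.append(band_matrix(gm)[0])
    K = dice_from_bands(np.concatenate(parts, axis=1))
    n_undefined = int(np.isnan(K).sum() // 2)
    if n_undefined:
        warnings.warn(f"{n_undefined} accession pairs share no complete markers", stacklevel=2)
    return pd.DataFrame(K, index=pd.Index(acc, name="accession"), columns=acc)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # accessions x axes (PCO1, PCO2, ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    n_negative: int


def pcoa(kinship: pd.DataFrame, n_axes: int | None = None) -> PCoAResult:
    """Principal coordinate analysis of a similarity matrix.

    The similarity matrix is double-centered (Gower), eigendecomposed, and
    coordinates are the eigenvectors scaled by the square root of their
    (positive) eigenvalues. Axes with negative eigenvalues are dropped but
    the eigenvalues are reported. Axis signs are fixed by forcing the
    largest-magnitude loading on each axis to be positive.
    """
    S = np.asarray(kinship, dtype=float)
    if S.shape[0] != S.shape[1]:
        raise ValueError("kinship matrix must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    n = S.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ S @ J
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(1e-10, 1e-10 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for a in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    if n_axes is not None:
        coords = coords[:, :n_axes]
    idx = kinship.index if isinstance(kinship, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(coords, index=idx, columns=[f"PCO{i+1}" for i in range(coords.shape[1])])
    return PCoAResult(coordinates=frame, eigenvalues=evals, n_negative=int((evals < -tol).sum()))


# ---------------------------------------------------------------------------
# complete-link partitions and bootstrap stability
# ---------------------------------------------------------------------------

def partition_from_linkage(Z: np.ndarray, n: int, g: int) -> np.ndarray:
    """Exactly-g partition from a linkage matrix by applying the first n - g
    merges in merge order (robust to tied merge heights). Labels are 0-based
    and numbered by first appearance."""
    if not 1 <= g <= n:
        raise ValueError(f"g must lie in [1, {n}]")
    parent = np.arange(2 * n - 1)
    for i in range(n - g):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        parent[a] = parent[b] = n + i
    def root(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for leaf in range(n):
        r = root(leaf)
        labels[leaf] = seen.setdefault(r, len(seen))
    return labels


def kinship_linkage(kinship: np.ndarray | pd.DataFrame, method: str = "complete") -> np.ndarray:
    K = np.asarray(kinship, dtype=float)
    D = 1.0 - np.nan_to_num(K, nan=0.0)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    return linkage(squareform(D, checks=False), method=method)


def cut_partition(kinship: np.ndarray | pd.DataFrame, g: int) -> np.ndarray:
    """Complete-link clustering of dissimilarity 1 - kinship, cut into exactly
    g groups. Returns integer labels (0-based, numbered by first appearance)."""
    K = np.asarray(kinship, dtype=float)
    return partition_from_linkage(kinship_linkage(K), K.shape[0], g)


def pick_n_groups(kinship: pd.DataFrame, g_range=range(2, 13)) -> int:
    """Default group count: maximize the mean silhouette over candidate G."""
    K = np.asarray(kinship, dtype=float)
    D = 1.0 - np.nan_to_num(K, nan=0.0)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    best_g, best_s = None, -np.inf
    for g in g_range:
        if g >= K.shape[0]:
            break
        labels = cut_partition(K, g)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(D, labels, metric="precomputed")
        if s > best_s:
            best_g, best_s = g, s
    if best_g is None:
        raise ValueError("could not select a group count")
    return best_g


@dataclass
class GroupAssignment:
    labels: pd.Series  # accession -> group id (1..G) or 0 = ungrouped
    stability: pd.DataFrame  # per reference group: size, mean co-clustering, stable flag
    n_stable: int
    params: dict = field(default_factory=dict)


def stable_groups(
    *genotypes: GenotypeMatrix,
    n_bootstrap: int = 100,
    n_groups: int | None = None,
    tau: float = 0.7,
    min_size: int = 5,
    seed: int | None = None,
) -> GroupAssignment:
    """Bootstrap-stable accession groups.

    The reference partition is a complete-link clustering of 1 - Dice kinship
    cut into ``n_groups`` (silhouette-selected when None). Each bootstrap
    replicate resamples markers with replacement, recomputes kinship and the
    partition, and accumulates per-pair co-clustering frequencies. A
    reference group is stable iff its mean within-group co-clustering
    frequency is >= ``tau`` and its size >= ``min_size``; accessions outside
    stable groups are labeled 0 (ungrouped).
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if n_groups is not None and n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    acc = genotypes[0].accession_ids
    parts = [band_matrix(gm) for gm in genotypes]
    bands = np.concatenate([p[0] for p in parts], axis=1)
    offsets = np.cumsum([0] + [p[0].shape[1] for p in parts])
    marker_of_band = np.concatenate(
        [p[1] + off for p, off in zip(parts, offsets[:-1])]
    )
    n_markers_total = sum(gm.n_markers for gm in genotypes)
    # band columns grouped by global marker index
    cols_of_marker: list[np.ndarray] = [np.array([], dtype=int)] * 0
    order = np.argsort(marker_of_band, kind="stable")
    bounds = np.searchsorted(marker_of_band[order], np.arange(n_markers_total + 1))
    cols_of_marker = [order[bounds[m]:bounds[m + 1]] for m in range(n_markers_total)]

    K = dice_from_bands(bands)
    Kf = pd.DataFrame(K, index=pd.Index(acc, name="accession"), columns=acc)
    if n_groups is None:
        n_groups = pick_n_groups(Kf)
    ref = cut_partition(K, n_groups)

    rng = np.random.default_rng(seed)
    n = len(acc)
    co = np.zeros((n, n))
    for _ in range(n_bootstrap):
        sampled = rng.integers(0, n_markers_total, size=n_markers_total)
        cols = np.concatenate([cols_of_marker[m] for m in sampled])
        Kb = dice_from_bands(bands[:, cols])
        lab = cut_partition(Kb, n_groups)
        co += lab[:, None] == lab[None, :]
    co /= n_bootstrap

    rows = []
    labels = np.zeros(n, dtype=int)
    out_group = 1
    for g in np.unique(ref):
        members = np.nonzero(ref == g)[0]
        size = len(members)
        if size >= 2:
            sub = co[np.ix_(members, members)]
            mean_co = float(sub[np.triu_indices(size, k=1)].mean())
        else:
            mean_co = 0.0
        stable = bool(mean_co >= tau and size >= min_size)
        rows.append({"reference_group": int(g), "size": size, "mean_co_clustering": mean_co, "stable": stable})
        if stable:
            labels[members] = out_group
            out_group += 1
    stability = pd.DataFrame(rows)
    return GroupAssignment(
        labels=pd.Series(labels, index=pd.Index(acc, name="accession"), name="group"),
        stability=stability,
        n_stable=int(stability["stable"].sum()),
        params={"n_bootstrap": n_bootstrap, "n_groups": int(n_groups), "tau": tau,
                "min_size": min_size, "seed": seed},
    )


# ---------------------------------------------------------------------------
# distribution comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    note: str = ""


def _merge_bins(counts: np.ndarray) -> np.ndarray:
    """Merge adjacent histogram bins (columns of a 2 x k table) until every
    expected count under independence is >= 5."""
    counts = counts.astype(float)
    while counts.shape[1] > 1:
        total = counts.sum()
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
        if (expected >= 5).all():
            break
        j = int(np.argmin(counts.sum(axis=0)))
        tgt = j - 1 if j > 0 else j + 1
        counts[:, tgt] += counts[:, j]
        counts = np.delete(counts, j, axis=1)
    return counts


def chi_square_binned(
    sample_a: np.ndarray, sample_b: np.ndarray, bins: int = 10, value_range=(0.0, 1.0)
) -> ComparisonResult:
    """Chi-square comparison of two samples on binned histograms (default 10
    equal-width bins on [0, 1]), merging adjacent bins until every expected
    count is >= 5. Raises when fewer than 2 usable bins remain."""
    edges = np.linspace(value_range[0], value_range[1], bins + 1)
    ca, _ = np.histogram(sample_a, bins=edges)
    cb, _ = np.histogram(sample_b, bins=edges)
    table = _merge_bins(np.vstack([ca, cb]))
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 usable bins after merging")
    if np.allclose(table[0] / table[0].sum(), table[1] / table[1].sum()):
        return ComparisonResult("chi_square", 0.0, 1.0, "identical binned distributions")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonResult("chi_square", float(chi2), float(p))


def compare_kinship_distributions(
    sample_a, sample_b, test: str = "mann_whitney", bins: int = 10
) -> ComparisonResult:
    """Compare two sets of kinship coefficients.

    ``mann_whitney`` ranks the raw coefficients (exact for small samples,
    tie-corrected normal approximation otherwise, as scipy's auto mode);
    ``chi_square`` compares binned histograms. A degenerate binning (all
    values in one bin) is reported as a skipped test rather than an error.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult("mann_whitney", float(res.statistic), float(res.pvalue))
    if test == "chi_square":
        try:
            return chi_square_binned(a, b, bins=bins)
        except ValueError as exc:
            return ComparisonResult("chi_square", np.nan, np.nan, f"skipped: {exc}")
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def association_scan(
    gm: GenotypeMatrix,
    response: pd.Series,
    n_pcs: int = 3,
    pcs: pd.DataFrame | None = None,
    kinship: pd.DataFrame | None = None,
    mvf_min: float = 0.05,
    min_informative: int = 10,
) -> pd.DataFrame:
    """Per-marker fixed-effects scan of a quantitative response.

    For each marker: ordinary least squares of the response on the marker
    code plus the first ``n_pcs`` principal coordinate axes of the kinship
    matrix (the eigenanalysis structure correction), a two-sided t-test on
    the marker coefficient, and BH adjustment across tested markers. Markers
    below the MVF floor or with fewer than ``min_informative`` complete
    accessions are skipped (reason recorded, excluded from BH).
    """
    response = response.dropna()
    keep_acc = [a for a in gm.accession_ids if a in response.index]
    if len(keep_acc) < min_informative:
        raise ValueError(f"only {len(keep_acc)} accessions carry the response")
    y_all = response.loc[keep_acc].to_numpy(dtype=float)
    if np.ptp(y_all) == 0:
        raise ValueError("response is constant")
    sub = gm.subset_accessions(keep_acc)

    if pcs is None:
        if n_pcs > 0:
            if kinship is None:
                kinship = dice_kinship(sub)
            pcs_frame = pcoa(kinship, n_axes=n_pcs).coordinates
        else:
            pcs_frame = pd.DataFrame(index=pd.Index(keep_acc))
    else:
        pcs_frame = pcs.loc[keep_acc].iloc[:, :n_pcs]
    Zfull = np.column_stack([np.ones(len(keep_acc))] + (
        [pcs_frame.to_numpy(dtype=float)] if pcs_frame.shape[1] else []
    ))

    from .qc import allele_frequencies  # local import avoids a cycle

    p_freq, q_freq = allele_frequencies(sub.calls, sub.marker_type)
    with np.errstate(invalid="ignore"):
        mvf = np.minimum(p_freq, q_freq)

    rows = []
    for j, mid in enumerate(sub.marker_ids):
        x = sub.calls[:, j].astype(float)
        mask = x != MISSING
        n_used = int(mask.sum())
        rec = {"marker_id": mid, "p": p_freq[j], "q": q_freq[j], "n_used": n_used,
               "beta": np.nan, "se": np.nan, "t": np.nan, "p_raw": np.nan, "skipped": ""}
        if np.isnan(mvf[j]) or mvf[j] < mvf_min:
            rec["skipped"] = "mvf_below_floor"
        elif n_used < min_informative:
            rec["skipped"] = "too_few_informative"
        else:
            Z = Zfull[mask]
            X = np.column_stack([Z, x[mask]])
            XtX = X.T @ X
            try:
                beta = np.linalg.solve(XtX, X.T @ y_all[mask])
            except np.linalg.LinAlgError:
                rec["skipped"] = "singular_design"
                rows.append(rec)
                continue
            resid = y_all[mask] - X @ beta
            dof = n_used - X.shape[1]
            if dof < 1 or np.ptp(x[mask]) == 0:
                rec["skipped"] = "degenerate"
            else:
                sigma2 = resid @ resid / dof
                cov = sigma2 * np.linalg.inv(XtX)
                se = float(np.sqrt(cov[-1, -1]))
                tval = float(beta[-1] / se) if se > 0 else np.nan
                rec.update(
                    beta=float(beta[-1]), se=se, t=tval,
                    p_raw=float(2.0 * stats.t.sf(abs(tval), dof)) if np.isfinite(tval) else np.nan,
                )
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("marker_id")
    tested = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p_raw"].to_numpy())
    return out


def year_scan(
    gm: GenotypeMatrix,
    years: pd.Series,
    n_pcs: int = 3,
    **kwargs,
) -> pd.DataFrame:
    """Registration-year association scan (year treated as a quantitative
    trait); thin wrapper over :func:`association_scan`."""
    return association_scan(gm, years.astype(float), n_pcs=n_pcs, **kwargs)
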