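"""Structure-corrected linkage disequilibrium, empirical null, decay
estimation and LD-based marker clustering.

LD between two markers is the squared partial correlation of their numeric
codes (SNP: ALT dosage 0/1/2; PAV: 0/1) given population-structure
covariates — principal coordinate axes of the kinship matrix. Equivalently,
it is the r-squared of regressing one residualized marker on the other; with
zero covariates it reduces exactly to the squared Pearson correlation. The
empirical null is the 95th percentile of LD among random cross-chromosome
("unlinked") marker pairs, and the decay distance is the largest physical
distance up to which a 12-effective-df smoothing spline of LD on distance
stays above that null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import BSpline
from scipy.optimize import brentq
from scipy.spatial.distance import squareform

from .containers import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# squared partial correlation
# ---------------------------------------------------------------------------

def _design(pcs: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept plus covariate columns."""
    if pcs is None or (hasattr(pcs, "shape") and np.size(pcs) == 0):
        return np.ones((n, 1))
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim == 1:
        pcs = pcs[:, None]
    if pcs.shape[0] != n:
        raise ValueError(f"covariate rows ({pcs.shape[0]}) != accessions ({n})")
    return np.column_stack([np.ones(n), pcs])


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def structure_corrected_r2(
    x: np.ndarray,
    y: np.ndarray,
    pcs: np.ndarray | None = None,
    min_complete: int = 30,
) -> tuple[float, int]:
    """Squared partial correlation of marker codes x and y given ``pcs``.

    Missing codes (``-1``) are handled pairwise-complete. Returns
    ``(r2, n_complete)``; ``r2`` is NaN when fewer than ``min_complete``
    accessions are complete or either marker has no residual variance after
    projecting out the covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("marker code vectors differ in length")
    mask = (x != MISSING) & (y != MISSING) & np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < max(min_complete, 2):
        return np.nan, n
    Z = _design(pcs, len(x))[mask]
    rx = _residualize(x[mask], Z)
    ry = _residualize(y[mask], Z)
    sxx = rx @ rx
    syy = ry @ ry
    if sxx <= 1e-12 * n or syy <= 1e-12 * n:
        return np.nan, n
    r2 = (rx @ ry) ** 2 / (sxx * syy)
    return float(min(r2, 1.0)), n


# ---------------------------------------------------------------------------
# pairwise tables and the unlinked null
# ---------------------------------------------------------------------------

def _mapped_positions(gm: GenotypeMatrix, info: pd.DataFrame):
    info = info.loc[gm.marker_ids]
    ok = (info["n_best_hits"] == 1) & info["position"].notna()
    idx = np.nonzero(ok.to_numpy())[0]
    chrom = info["chromosome"].to_numpy()[idx]
    pos = info["position"].astype(float).to_numpy()[idx]
    return idx, chrom, pos


def pairwise_ld(
    gm: GenotypeMatrix,
    info: pd.DataFrame,
    max_distance: float = 2.0e7,
    pcs: np.ndarray | None = None,
    max_pairs: int | None = None,
    min_complete: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """LD table for within-chromosome marker pairs at distance <= ``max_distance``.

    When ``max_pairs`` caps the table, pairs are subsampled with a seeded
    draw stratified by distance decile so the spline fit keeps support over
    the whole distance range. Columns: marker_i, marker_j, chromosome,
    distance, r2, n_complete.
    """
    idx, chrom, pos = _mapped_positions(gm, info)
    pairs = []
    for c in np.unique(chrom):
        sel = np.nonzero(chrom == c)[0]
        order = sel[np.argsort(pos[sel])]
        p = pos[order]
        for a in range(len(order)):
            b = a + 1
            while b < len(order) and p[b] - p[a] <= max_distance:
                pairs.append((order[a], order[b], p[b] - p[a], c))
                b += 1
    if not pairs:
        warnings.warn("no eligible within-chromosome marker pairs", stacklevel=2)
        return pd.DataFrame(columns=["marker_i", "marker_j", "chromosome", "distance", "r2", "n_complete"])

    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        d = np.array([p[2] for p in pairs])
        deciles = np.quantile(d, np.linspace(0, 1, 11))
        strata = np.clip(np.searchsorted(deciles, d, side="right") - 1, 0, 9)
        chosen: list[int] = []
        per = max_pairs // 10
        for s in range(10):
            members = np.nonzero(strata == s)[0]
            take = min(per, len(members))
            if take:
                chosen.extend(rng.choice(members, size=take, replace=False).tolist())
        pairs = [pairs[i] for i in sorted(chosen)]

    rows = []
    for a, b, d, c in pairs:
        r2, n = structure_corrected_r2(gm.calls[:, idx[a]], gm.calls[:, idx[b]], pcs, min_complete)
        if np.isnan(r2):
            continue
        rows.append((gm.marker_ids[idx[a]], gm.marker_ids[idx[b]], c, float(d), r2, n))
    return pd.DataFrame(rows, columns=["marker_i", "marker_j", "chromosome", "distance", "r2", "n_complete"])


@dataclass
class UnlinkedNull:
    q95: float
    r2: np.ndarray
    n_pairs: int
    seed: int | None


def unlinked_null(
    gm: GenotypeMatrix,
    info: pd.DataFrame,
    n_pairs: int = 10_000,
    pcs: np.ndarray | None = None,
    min_complete: int = 30,
    seed: int | None = None,
) -> UnlinkedNull:
    """Empirical 95th percentile of LD for random cross-chromosome pairs.

    Pairs are drawn uniformly with a fixed seed; pairs whose LD is undefined
    (constant marker after covariate projection, too few complete calls) are
    excluded from the percentile.
    """
    idx, chrom, _ = _mapped_positions(gm, info)
    if len(np.unique(chrom)) < 2:
        raise ValueError("unlinked null needs markers on at least 2 chromosomes")
    rng = np.random.default_rng(seed)
    vals = []
    draws = 0
    limit = 50 * n_pairs
    while len(vals) < n_pairs and draws < limit:
        a, b = rng.integers(0, len(idx), size=2)
        draws += 1
        if a == b or chrom[a] == chrom[b]:
            continue
        r2, _ = structure_corrected_r2(gm.calls[:, idx[a]], gm.calls[:, idx[b]], pcs, min_complete)
        if not np.isnan(r2):
            vals.append(r2)
    vals = np.array(vals)
    if len(vals) == 0:
        raise ValueError("no defined cross-chromosome LD values")
    return UnlinkedNull(q95=float(np.quantile(vals, 0.95)), r2=vals, n_pairs=len(vals), seed=seed)


# ---------------------------------------------------------------------------
# penalized smoothing spline with a target effective df
# ---------------------------------------------------------------------------

class PSpline:
    """Cubic penalized B-spline with lambda chosen so the effective degrees
    of freedom (trace of the hat matrix) hit a target.

    A second-difference penalty on the coefficients shrinks toward a straight
    line (edf -> 2 as lambda -> infinity); ~20 equally spaced knot intervals
    give enough basis freedom for the usual 12-df target.
    """

    degree = 3

    def __init__(self, t: np.ndarray, coef: np.ndarray, x_range: tuple, lam: float, edf: float):
        self.t = np.asarray(t, dtype=float)
        self.coef = np.asarray(coef, dtype=float)
        self.x_range = (float(x_range[0]), float(x_range[1]))
        self.lam = float(lam)
        self.edf = float(edf)
        self._bs = BSpline(self.t, self.coef, self.degree, extrapolate=True)

    @classmethod
    def fit(cls, x: np.ndarray, y: np.ndarray, df: float = 12.0, n_segments: int = 20) -> "PSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 10:
            raise ValueError("need >= 10 (x, y) points")
        x0, x1 = float(x.min()), float(x.max())
        if x1 <= x0:
            raise ValueError("x has no spread")
        k = cls.degree
        inner = np.linspace(x0, x1, n_segments + 1)
        t = np.concatenate([[x0] * k, inner, [x1] * k])
        B = BSpline.design_matrix(np.clip(x, x0, x1), t, k, extrapolate=True)
        BtB = (B.T @ B).toarray()
        Bty = B.T @ y
        nb = BtB.shape[0]
        D = np.diff(np.eye(nb), n=2, axis=0)
        P = D.T @ D

        def edf(log_lam: float) -> float:
            lam = 10.0 ** log_lam
            return float(np.trace(np.linalg.solve(BtB + lam * P + 1e-9 * np.eye(nb), BtB)))

        target = min(df, nb - 0.5)
        lo, hi = -8.0, 14.0
        if edf(lo) <= target:
            log_lam = lo
        elif edf(hi) >= target:
            log_lam = hi
        else:
            log_lam = brentq(lambda L: edf(L) - target, lo, hi, xtol=1e-4)
        lam = 10.0 ** log_lam
        coef = np.linalg.solve(BtB + lam * P + 1e-9 * np.eye(nb), Bty)
        return cls(t, coef, (x0, x1), lam, edf(log_lam))

    def __call__(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), *self.x_range)
        return self._bs(x)

    def to_dict(self) -> dict:
        return {
            "knots": self.t.tolist(),
            "coef": self.coef.tolist(),
            "degree": self.degree,
            "x_range": list(self.x_range),
            "lambda": self.lam,
            "edf": self.edf,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PSpline":
        return cls(np.array(d["knots"]), np.array(d["coef"]), tuple(d["x_range"]), d["lambda"], d["edf"])


@dataclass
class LDDecayModel:
    spline: PSpline
    null_q95: float
    decay_distance: float
    n_pairs: int
    censored: bool = False  # spline still above the null at the largest distance
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "spline": self.spline.to_dict(),
            "null_q95": self.null_q95,
            "decay_distance": self.decay_distance,
            "n_pairs": self.n_pairs,
            "censored": self.censored,
            "notes": list(self.notes),
        }


def fit_decay(
    ld_table: pd.DataFrame,
    null_q95: float,
    df: float = 12.0,
    grid_step: float = 1000.0,
) -> LDDecayModel:
    """Fit the LD-vs-distance smoothing spline and locate the decay distance.

    The decay distance is the largest d* such that the fitted spline exceeds
    ``null_q95`` at every grid point (default 1 kb spacing) up to d*. A spline
    already at or below the null at the shortest distance yields 0; a spline
    above the null everywhere yields the largest observed distance with
    ``censored=True``.
    """
    if len(ld_table) < 100:
        raise ValueError(f"need >= 100 LD pairs to fit a decay curve, got {len(ld_table)}")
    d = ld_table["distance"].to_numpy(dtype=float)
    r2 = ld_table["r2"].to_numpy(dtype=float)
    spline = PSpline.fit(d, r2, df=df)

    grid = np.arange(max(grid_step, d.min()), d.max() + grid_step, grid_step)
    above = spline(grid) > null_q95
    notes = []
    if not above[0]:
        decay, censored = 0.0, False
        notes.append("spline at or below the null at the shortest distance")
    elif above.all():
        decay, censored = float(grid[-1]), True
        notes.append("spline above the null over the whole observed range")
    else:
        first_below = int(np.argmin(above))  # first False
        decay, censored = float(grid[first_below - 1]), False
    return LDDecayModel(
        spline=spline, null_q95=float(null_q95), decay_distance=decay,
        n_pairs=len(ld_table), censored=censored, notes=notes,
    )


# ---------------------------------------------------------------------------
# LD-based marker clustering (UPGMA blocks)
# ---------------------------------------------------------------------------

@dataclass
class BlockSet:
    membership: pd.DataFrame  # marker_id, chromosome, block_id
    blocks: pd.DataFrame  # block_id, chromosome, start, end, n_markers, representative


def ld_matrix(
    gm: GenotypeMatrix,
    marker_idx: np.ndarray,
    pcs: np.ndarray | None = None,
    min_complete: int = 30,
) -> np.ndarray:
    """Dense symmetric r2 matrix for the given marker columns; undefined
    pairs are NaN. Diagonal is 1."""
    m = len(marker_idx)
    R = np.full((m, m), np.nan)
    np.fill_diagonal(R, 1.0)
    for a in range(m):
        for b in range(a + 1, m):
            r2, _ = structure_corrected_r2(
                gm.calls[:, marker_idx[a]], gm.calls[:, marker_idx[b]], pcs, min_complete
            )
            R[a, b] = R[b, a] = r2
    return R


def cluster_markers_ld(
    gm: GenotypeMatrix,
    info: pd.DataFrame,
    r2_threshold: float = 0.2,
    pcs: np.ndarray | None = None,
    min_complete: int = 30,
) -> BlockSet:
    """UPGMA marker blocks from the within-chromosome LD matrix.

    Markers are agglomerated (group-average linkage) on dissimilarity
    ``1 - r2`` and the tree is cut at height ``1 - r2_threshold``; blocks
    never span chromosomes. Pairs with undefined LD get dissimilarity 1
    (conservative against false linkage). Each block's representative is the
    member with the highest call rate, ties broken by lowest marker id.
    """
    if not 0.0 < r2_threshold < 1.0:
        raise ValueError(f"r2_threshold must lie in (0, 1), got {r2_threshold}")
    idx, chrom, pos = _mapped_positions(gm, info)
    cr_all = (gm.calls != MISSING).mean(axis=0)

    mem_rows, block_rows = [], []
    next_block = 0
    for c in sorted(np.unique(chrom)):
        sel = np.nonzero(chrom == c)[0]
        order = sel[np.argsort(pos[sel])]
        cols = idx[order]
        if len(cols) == 1:
            labels = np.array([1])
        else:
            R = ld_matrix(gm, cols, pcs, min_complete)
            D = 1.0 - np.nan_to_num(R, nan=0.0)
            np.fill_diagonal(D, 0.0)
            Z = linkage(squareform(D, checks=False), method="average")
            labels = fcluster(Z, t=1.0 - r2_threshold, criterion="distance")
        for lab in np.unique(labels):
            members = order[labels == lab]
            ids = [gm.marker_ids[idx[m]] for m in members]
            crs = cr_all[idx[members]]
            rep = sorted(zip(-crs, ids))[0][1]
            block_rows.append(
                {"block_id": next_block, "chromosome": c,
                 "start": int(pos[members].min()), "end": int(pos[members].max()),
                 "n_markers": len(members), "representative": rep}
            )
            for mid in ids:
                mem_rows.append({"marker_id": mid, "chromosome": c, "block_id": next_block})
            next_block += 1
    return BlockSet(membership=pd.DataFrame(mem_rows), blocks=pd.DataFrame(block_rows))
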