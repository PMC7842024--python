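"""Per-marker QC statistics, filtering, subgenome diversity summaries and
hemizygosity diagnostics.

Conventions
-----------
* Variant frequencies for SNPs are allele-level: a homozygote contributes two
  copies, a heterozygote one of each; for PAV markers p is the frequency of
  the "present" state. MVF = min(p, 1-p).
* PIC is the Botstein index, ``1 - (p^2 + q^2) - 2 p^2 q^2`` for a biallelic
  locus (maximum 0.375 at p = 0.5).
* Heterozygosity = heterozygous calls / non-missing calls (SNP only; a
  dominant 0/1 marker has no observable heterozygote class).
* Filter thresholds are strict inequalities (retain MVF > mvf_min, call rate
  > call_rate_min), applied in the fixed order uniqueness -> MVF -> call rate
  so audit counts are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    MISSING,
    PAV,
    PURINES,
    PYRIMIDINES,
    SNP,
    SUBGENOMES,
    BASES,
    GenotypeMatrix,
)


# ---------------------------------------------------------------------------
# elementary per-marker statistics (vectorized over columns)
# ---------------------------------------------------------------------------

def call_rate(calls: np.ndarray) -> np.ndarray | float:
    """Fraction of non-missing calls per marker (column); scalar for 1-D input."""
    arr = np.asarray(calls)
    rate = (arr != MISSING).mean(axis=0)
    return float(rate) if arr.ndim == 1 else rate


def allele_frequencies(calls: np.ndarray, marker_type: str = SNP):
    """Tracked-variant frequency p (ALT for SNP dosages, "present" for PAV)
    and q = 1 - p, over non-missing calls. NaN when all calls are missing."""
    arr = np.atleast_2d(np.asarray(calls, dtype=float).T).T
    valid = arr != MISSING
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if marker_type == SNP:
            alt_copies = np.where(valid, arr, 0.0).sum(axis=0)
            p = np.where(n > 0, alt_copies / (2.0 * n), np.nan)
        else:
            p = np.where(n > 0, np.where(valid, arr, 0.0).sum(axis=0) / n, np.nan)
    q = 1.0 - p
    if np.asarray(calls).ndim == 1:
        return float(p[0]), float(q[0])
    return p, q


def pic(p, q=None) -> np.ndarray | float:
    """Botstein polymorphism information content for a biallelic locus."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p if q is None else np.asarray(q, dtype=float)
    val = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    # clamp the monomorphic case to exactly zero against float round-off
    val = np.where(np.isclose(p * q, 0.0), 0.0, val)
    return float(val) if val.ndim == 0 else val


def heterozygosity(calls: np.ndarray) -> np.ndarray | float:
    """Fraction of heterozygous calls among non-missing SNP calls."""
    arr = np.atleast_2d(np.asarray(calls).T).T
    valid = arr != MISSING
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n > 0, (arr == 1).sum(axis=0) / n, np.nan)
    if np.asarray(calls).ndim == 1:
        return float(het[0])
    return het


def classify_ts_tv(ref: str, alt: str) -> str:
    """"transition" for purine<->purine or pyrimidine<->pyrimidine pairs
    (A<->G, C<->T), "transversion" otherwise."""
    ref, alt = str(ref).upper(), str(alt).upper()
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"alleles must be A/C/G/T, got ({ref!r}, {alt!r})")
    if ref == alt:
        raise ValueError("transition/transversion needs two distinct bases")
    both_pur = ref in PURINES and alt in PURINES
    both_pyr = ref in PYRIMIDINES and alt in PYRIMIDINES
    return "transition" if (both_pur or both_pyr) else "transversion"


def marker_summary(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker table: call_rate, p, q, mvf, pic, heterozygosity, ts_tv."""
    cr = call_rate(gm.calls)
    p, q = allele_frequencies(gm.calls, gm.marker_type)
    with np.errstate(invalid="ignore"):
        mvf = np.minimum(p, q)
    df = pd.DataFrame(
        {
            "call_rate": cr,
            "p": p,
            "q": q,
            "mvf": mvf,
            "pic": pic(p, q),
            "all_missing": cr == 0.0,
        },
        index=gm.marker_index(),
    )
    if gm.marker_type == SNP:
        df["heterozygosity"] = heterozygosity(gm.calls)
        df["ts_tv"] = [classify_ts_tv(r, a) for r, a in zip(gm.ref_alleles, gm.alt_alleles)]
    return df


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    mvf_min: float = 0.1
    call_rate_min_snp: float = 0.6
    require_unique_mapping: bool = True

    def __post_init__(self):
        for name in ("mvf_min", "call_rate_min_snp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class FilterResult:
    genotypes: GenotypeMatrix
    audit: dict = field(default_factory=dict)


def filter_markers(gm: GenotypeMatrix, info: pd.DataFrame, config: FilterConfig | None = None) -> FilterResult:
    """Apply the selection rules in order: unique mapping, then MVF > mvf_min,
    then (SNPs only) call rate > call_rate_min. The audit log counts removals
    per rule and reports retention against both the total and the mapped
    marker count (the two denominators used when quoting selection rates).
    """
    config = config or FilterConfig()
    missing_info = [m for m in gm.marker_ids if m not in info.index]
    if missing_info:
        raise ValueError(f"marker info missing for {missing_info[:5]} (+{max(0, len(missing_info)-5)} more)")
    info = info.loc[gm.marker_ids]

    keep = np.ones(gm.n_markers, dtype=bool)
    audit = {
        "marker_type": gm.marker_type,
        "n_input": gm.n_markers,
        "n_mapped": int((info["n_hit_positions"] > 0).sum()),
        "rules": [],
    }

    if config.require_unique_mapping:
        unique = (info["n_best_hits"] == 1).to_numpy()
        removed = keep & ~unique
        audit["rules"].append({"rule": "unique_mapping", "removed": int(removed.sum())})
        keep &= unique

    p, q = allele_frequencies(gm.calls, gm.marker_type)
    with np.errstate(invalid="ignore"):
        mvf = np.minimum(p, q)
    pass_mvf = np.nan_to_num(mvf, nan=0.0) > config.mvf_min
    removed = keep & ~pass_mvf
    audit["rules"].append({"rule": f"mvf>{config.mvf_min}", "removed": int(removed.sum())})
    keep &= pass_mvf

    if gm.marker_type == SNP:
        pass_cr = call_rate(gm.calls) > config.call_rate_min_snp
        removed = keep & ~pass_cr
        audit["rules"].append({"rule": f"call_rate>{config.call_rate_min_snp}", "removed": int(removed.sum())})
        keep &= pass_cr

    audit["n_retained"] = int(keep.sum())
    audit["retained_of_total"] = audit["n_retained"] / audit["n_input"] if audit["n_input"] else 0.0
    audit["retained_of_mapped"] = (
        audit["n_retained"] / audit["n_mapped"] if audit["n_mapped"] else 0.0
    )
    if audit["n_retained"] == 0:
        import warnings

        warnings.warn("all markers removed by filtering", stacklevel=2)
    return FilterResult(genotypes=gm.subset_markers(keep), audit=audit)


# ---------------------------------------------------------------------------
# subgenome summaries
# ---------------------------------------------------------------------------

def _adjacent_distances(info: pd.DataFrame) -> pd.Series:
    """bp distances between physically adjacent mapped markers, per chromosome."""
    mapped = info[info["position"].notna()]
    dists, chroms = [], []
    for chrom, grp in mapped.groupby("chromosome"):
        pos = np.sort(grp["position"].astype(int).to_numpy())
        if len(pos) >= 2:
            d = np.diff(pos)
            dists.extend(d.tolist())
            chroms.extend([chrom] * len(d))
    return pd.Series(dists, index=pd.Index(chroms, name="chromosome"), dtype=float, name="distance")


def subgenome_summaries(gm: GenotypeMatrix, info: pd.DataFrame):
    """Diversity summary per subgenome (and per chromosome) plus pairwise
    Mann-Whitney contrasts of call rate / PIC / heterozygosity distributions
    between subgenomes A, B and D.

    Returns ``(summary, tests)``. Unanchored markers ("Un") appear in the
    summary but are excluded from the contrasts. Chromosomes with fewer than
    two mapped markers report an undefined median inter-marker distance.
    """
    summ = marker_summary(gm)
    info = info.loc[summ.index]
    summ = summ.join(info[["chromosome", "subgenome"]])
    dists = _adjacent_distances(info)
    chrom2sg = info.drop_duplicates("chromosome").set_index("chromosome")["subgenome"]

    stat_cols = ["call_rate", "pic"] + (["heterozygosity"] if gm.marker_type == SNP else [])
    rows = []
    for level, grouper in (("subgenome", "subgenome"), ("chromosome", "chromosome")):
        for name, grp in summ.groupby(grouper, dropna=True):
            if level == "subgenome":
                d = dists[dists.index.map(chrom2sg).to_numpy() == name]
            else:
                d = dists[dists.index == name]
            row = {
                "level": level,
                "name": name,
                "n_markers": len(grp),
                "median_adjacent_distance": float(np.median(d)) if len(d) else np.nan,
            }
            for c in stat_cols:
                row[f"mean_{c}"] = float(grp[c].mean())
                row[f"median_{c}"] = float(grp[c].median())
            rows.append(row)
    summary = pd.DataFrame(rows)

    tests = []
    present = [s for s in SUBGENOMES if (summ["subgenome"] == s).sum() > 0]
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            for c in stat_cols:
                xa = summ.loc[summ["subgenome"] == a, c].dropna()
                xb = summ.loc[summ["subgenome"] == b, c].dropna()
                if len(xa) < 2 or len(xb) < 2:
                    continue
                res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                tests.append(
                    {"subgenome_a": a, "subgenome_b": b, "statistic_name": c,
                     "u": float(res.statistic), "p_value": float(res.pvalue)}
                )
    return summary, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# hemizygosity diagnostics
# ---------------------------------------------------------------------------

@dataclass
class HemizygosityReport:
    strata: pd.DataFrame  # mean heterozygosity by n_subgenomes_hit
    contingency: pd.DataFrame | None  # subgenome x n_hit_positions {1, 2, >2}
    chi2_p: float | None
    flagged: list
    notes: list = field(default_factory=list)


def hemizygosity_diagnostics(
    gm: GenotypeMatrix,
    info: pd.DataFrame,
    het_threshold: float = 0.5,
) -> HemizygosityReport:
    """Diagnose pseudo-heterozygous (hemizygous) SNP markers.

    In an allopolyploid, fixed alternative alleles at homoeologous loci in
    different subgenomes look heterozygous to a marker assay. Three views:

    1. mean heterozygosity stratified by the number of subgenomes a marker's
       sequence hits (1/2/3) — hemizygosity inflates the multi-subgenome strata;
    2. a contingency table of best-hit subgenome x number of hit positions
       (1, 2, >2) with a Pearson chi-square p-value — tests whether some
       subgenome's markers map to alternative loci more often;
    3. a flag list: heterozygosity > ``het_threshold`` AND hits in >= 2
       subgenomes.
    """
    if gm.marker_type != SNP:
        raise ValueError("hemizygosity diagnostics apply to SNP markers")
    notes: list[str] = []
    info = info.loc[gm.marker_ids]
    het = pd.Series(heterozygosity(gm.calls), index=gm.marker_index())

    nsg = info["n_subgenomes_hit"].clip(lower=0)
    strata_rows = []
    for k in (1, 2, 3):
        sel = nsg == k
        strata_rows.append(
            {"n_subgenomes_hit": k, "n_markers": int(sel.sum()),
             "mean_heterozygosity": float(het[sel.to_numpy()].mean()) if sel.any() else np.nan}
        )
    strata = pd.DataFrame(strata_rows)
    for k in (2, 3):
        if strata.loc[strata["n_subgenomes_hit"] == k, "n_markers"].iloc[0] == 0:
            notes.append(f"stratum {k}: no markers")

    mapped = info[info["subgenome"].isin(SUBGENOMES) & (info["n_hit_positions"] > 0)]
    contingency = None
    chi2_p = None
    if (mapped["n_hit_positions"] > 1).any():
        cls = pd.cut(
            mapped["n_hit_positions"], bins=[0, 1, 2, np.inf], labels=["1", "2", ">2"]
        )
        contingency = pd.crosstab(mapped["subgenome"], cls)
        keep_cols = contingency.columns[(contingency.sum(axis=0) > 0)]
        contingency = contingency[keep_cols]
        if contingency.shape[0] >= 2 and contingency.shape[1] >= 2:
            chi2_p = float(stats.chi2_contingency(contingency.to_numpy())[1])
        else:
            notes.append("contingency degenerate; chi-square skipped")
    else:
        notes.append("all markers single-hit; chi-square skipped")

    flag = (het > het_threshold) & (info["n_subgenomes_hit"] >= 2)
    return HemizygosityReport(
        strata=strata,
        contingency=contingency,
        chi2_p=chi2_p,
        flagged=sorted(het.index[flag.to_numpy()].tolist()),
        notes=notes,
    )
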