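"""Core-collection construction.

A core collection here is the "representation" type: the panel is split into
g clusters by complete-link hierarchical clustering of 1 - kinship for every
g = 1..g_max, the average within-group kinship is computed for each partition
with singletons contributing 0, and the partition maximizing that average is
taken as optimal. One representative per cluster is then chosen — the member
with the highest mean yield, or a seeded random member when no yield data
exist for the cluster. The singleton = 0 convention is what creates an
interior maximum: splitting too far creates single-accession groups that
drag the average down, while splitting too little mixes unrelated material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .structure import (
    ComparisonResult,
    chi_square_binned,
    kinship_linkage,
    partition_from_linkage,
)


@dataclass
class CorePartition:
    g: int
    labels: pd.Series  # accession -> cluster id (0-based)
    avg_within_kinship: float
    curve: pd.DataFrame  # g, avg_within_kinship for the whole series
    representatives: pd.DataFrame | None = None  # cluster, accession, reason, yield
    seed: int | None = None

    @property
    def core_ids(self) -> list:
        if self.representatives is None:
            raise ValueError("representatives not selected yet")
        return self.representatives["accession"].tolist()


def _check_kinship(kinship: pd.DataFrame) -> np.ndarray:
    K = np.asarray(kinship, dtype=float)
    if K.shape[0] != K.shape[1]:
        raise ValueError("kinship matrix must be square")
    return K


def partition_series(kinship: pd.DataFrame, g_max: int | None = None) -> np.ndarray:
    """Labels for complete-link partitions at every g = 1..g_max.

    Returns an (n_accessions x g_max) integer array whose column g-1 holds
    the g-cluster partition; columns are nested (each refines the previous
    merge order) because they cut the same dendrogram.
    """
    K = _check_kinship(kinship)
    n = K.shape[0]
    g_max = n if g_max is None else g_max
    if not 1 <= g_max <= n:
        raise ValueError(f"g_max must lie in [1, {n}]")
    Z = kinship_linkage(K)
    return np.column_stack([partition_from_linkage(Z, n, g) for g in range(1, g_max + 1)])


def average_within_kinship(labels: np.ndarray, kinship: pd.DataFrame) -> float:
    """Unweighted mean over groups of the mean off-diagonal within-group
    kinship; single-accession groups contribute 0."""
    K = _check_kinship(kinship)
    labels = np.asarray(labels)
    if len(labels) != K.shape[0]:
        raise ValueError("labels must cover all accessions")
    means = []
    for g in np.unique(labels):
        members = np.nonzero(labels == g)[0]
        if len(members) == 1:
            means.append(0.0)
        else:
            sub = K[np.ix_(members, members)]
            means.append(float(sub[np.triu_indices(len(members), k=1)].mean()))
    return float(np.mean(means))


def optimal_partition(kinship: pd.DataFrame, g_max: int | None = None) -> CorePartition:
    """Scan g = 1..g_max and return the partition maximizing the average
    within-group kinship (ties broken toward smaller g)."""
    K = _check_kinship(kinship)
    ids = list(kinship.index) if isinstance(kinship, pd.DataFrame) else list(range(K.shape[0]))
    all_labels = partition_series(kinship, g_max)
    avgs = np.array([average_within_kinship(all_labels[:, j], kinship) for j in range(all_labels.shape[1])])
    j_star = int(np.argmax(avgs))  # argmax takes the first maximum: smaller g wins ties
    curve = pd.DataFrame({"g": np.arange(1, all_labels.shape[1] + 1), "avg_within_kinship": avgs})
    return CorePartition(
        g=j_star + 1,
        labels=pd.Series(all_labels[:, j_star], index=pd.Index(ids, name="accession"), name="cluster"),
        avg_within_kinship=float(avgs[j_star]),
        curve=curve,
    )


def select_representatives(
    partition: CorePartition,
    yields: pd.Series | None,
    seed: int | None = None,
) -> CorePartition:
    """Choose one representative accession per cluster.

    Within a cluster the accession with the highest mean yield wins (ties by
    lexicographically smallest accession id); clusters with no yield data get
    a seeded uniform random member. Clusters are processed in ascending id
    order so the random fallback is reproducible.
    """
    rng = np.random.default_rng(seed)
    labels = partition.labels
    rows = []
    for g in sorted(labels.unique()):
        members = sorted(labels.index[labels == g])
        with_yield = []
        if yields is not None:
            for m in members:
                y = yields.get(m, np.nan)
                if pd.notna(y):
                    with_yield.append((m, float(y)))
        if with_yield:
            best = sorted(with_yield, key=lambda t: (-t[1], t[0]))[0]
            rows.append({"cluster": int(g), "accession": best[0], "reason": "max_yield", "yield": best[1]})
        else:
            pick = members[int(rng.integers(0, len(members)))]
            rows.append({"cluster": int(g), "accession": pick, "reason": "random", "yield": np.nan})
    partition.representatives = pd.DataFrame(rows)
    partition.seed = seed
    return partition


def core_vs_whole_distribution(
    kinship: pd.DataFrame,
    core_ids,
    bins: int = 10,
) -> ComparisonResult:
    """Chi-square comparison of the off-diagonal kinship distribution of the
    whole panel against the within-core distribution (default 10 equal-width
    bins on [0, 1], adjacent bins merged until expected counts reach 5)."""
    K = _check_kinship(kinship)
    ids = list(kinship.index)
    core = [c for c in core_ids if c in set(ids)]
    if len(core) != len(list(core_ids)):
        raise ValueError("core contains accessions outside the panel")
    if len(core) < 2:
        raise ValueError("core must contain at least 2 accessions")
    whole = K[np.triu_indices(K.shape[0], k=1)]
    pos = {a: i for i, a in enumerate(ids)}
    ci = np.array([pos[c] for c in core])
    sub = K[np.ix_(ci, ci)]
    within_core = sub[np.triu_indices(len(ci), k=1)]
    return chi_square_binned(whole[np.isfinite(whole)], within_core[np.isfinite(within_core)], bins=bins)
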