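"""In-memory containers shared across the package.

The central object is :class:`GenotypeMatrix`, an accessions x markers call
matrix. SNP calls are stored as the dosage of the ALT allele (0, 1, 2) and
dominant presence/absence (PAV) calls as 0/1; missing calls are ``-1``
(:data:`MISSING`). Per-marker metadata (alleles, mapping, hit statistics)
live in a plain :class:`pandas.DataFrame` with the columns listed in
:data:`INFO_COLUMNS`, indexed by marker id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

SNP = "snp"
PAV = "pav"

BASES = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: subgenomes of an allohexaploid (AABBDD) genome; "Un" = unanchored scaffolds
SUBGENOMES = ("A", "B", "D")

#: columns of a marker-info table (index: marker_id)
INFO_COLUMNS = [
    "type",
    "ref_allele",
    "alt_allele",
    "chromosome",
    "position",
    "max_score",
    "n_best_hits",
    "n_hit_positions",
    "n_subgenomes_hit",
    "subgenome",
]

_CHROM_RE = re.compile(r"^(\d+)([ABD])$")


def subgenome_of(chromosome: str | None) -> str:
    """Subgenome stratum of a chromosome label: "2A" -> "A", "Un*" -> "Un".

    Unanchored labels are retained as a fourth stratum so they can be kept in
    genome-wide statistics while being excluded from subgenome contrasts.
    """
    if chromosome is None or (isinstance(chromosome, float) and np.isnan(chromosome)):
        return "Un"
    m = _CHROM_RE.match(str(chromosome))
    if m:
        return m.group(2)
    return "Un"


@dataclass
class GenotypeMatrix:
    """Accessions x markers call matrix for one marker dataset (SNP or PAV).

    Parameters
    ----------
    accession_ids, marker_ids
        Ordered labels for rows and columns.
    calls
        ``int8`` array of shape ``(n_accessions, n_markers)``. For SNP
        datasets entries are ALT-allele dosages in {0, 1, 2}; for PAV
        datasets {0, 1}. ``-1`` marks a missing call.
    marker_type
        ``"snp"`` or ``"pav"`` (one type per dataset).
    ref_alleles, alt_alleles
        Per-marker single-base allele labels (SNP datasets only). REF is the
        designated reference allele, so that dosage 0 means REF/REF.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    marker_type: str
    ref_alleles: np.ndarray | None = None
    alt_alleles: np.ndarray | None = None
    validation_notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_acc, n_mark = self.calls.shape
        if len(self.accession_ids) != n_acc or len(self.marker_ids) != n_mark:
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        if len(set(self.marker_ids)) != n_mark:
            raise ValueError("duplicated marker ids")
        if len(set(self.accession_ids)) != n_acc:
            raise ValueError("duplicated accession ids")
        if self.marker_type not in (SNP, PAV):
            raise ValueError(f"marker_type must be 'snp' or 'pav', got {self.marker_type!r}")
        hi = 2 if self.marker_type == SNP else 1
        bad = (self.calls < MISSING) | (self.calls > hi)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} call codes outside [-1, {hi}]")
        if self.marker_type == SNP:
            if self.ref_alleles is None or self.alt_alleles is None:
                raise ValueError("SNP dataset requires ref/alt alleles")
            self.ref_alleles = np.asarray(self.ref_alleles, dtype="U1")
            self.alt_alleles = np.asarray(self.alt_alleles, dtype="U1")
            for name, arr in (("ref", self.ref_alleles), ("alt", self.alt_alleles)):
                if arr.shape != (n_mark,):
                    raise ValueError(f"{name}_alleles length mismatch")
                offenders = [self.marker_ids[i] for i in np.nonzero(~np.isin(arr, list(BASES)))[0]]
                if offenders:
                    raise ValueError(f"non-ACGT {name} allele for markers: {offenders[:10]}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    # -- views ----------------------------------------------------------
    def marker_index(self) -> pd.Index:
        return pd.Index(self.marker_ids, name="marker_id")

    def subset_markers(self, keep) -> "GenotypeMatrix":
        """New matrix restricted to markers in ``keep`` (ids or boolean/int index)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.nonzero(keep)[0]
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            pos = {m: i for i, m in enumerate(self.marker_ids)}
            idx = np.array([pos[m] for m in keep], dtype=int)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            marker_type=self.marker_type,
            ref_alleles=None if self.ref_alleles is None else self.ref_alleles[idx].copy(),
            alt_alleles=None if self.alt_alleles is None else self.alt_alleles[idx].copy(),
        )

    def subset_accessions(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.nonzero(keep)[0]
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            pos = {a: i for i, a in enumerate(self.accession_ids)}
            idx = np.array([pos[a] for a in keep], dtype=int)
        return GenotypeMatrix(
            accession_ids=[self.accession_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            calls=self.calls[idx, :].copy(),
            marker_type=self.marker_type,
            ref_alleles=self.ref_alleles,
            alt_alleles=self.alt_alleles,
        )

    def call_strings(self) -> np.ndarray:
        """Render calls as text: SNP "X/Y" pairs, PAV "0"/"1", missing "-"."""
        out = np.full(self.calls.shape, "-", dtype="U3")
        if self.marker_type == PAV:
            out[self.calls == 0] = "0"
            out[self.calls == 1] = "1"
            return out
        ref = self.ref_alleles
        alt = self.alt_alleles
        for j in range(self.n_markers):
            col = self.calls[:, j]
            out[col == 0, j] = f"{ref[j]}/{ref[j]}"
            out[col == 1, j] = f"{ref[j]}/{alt[j]}"
            out[col == 2, j] = f"{alt[j]}/{alt[j]}"
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix({self.n_accessions} accessions x {self.n_markers} "
            f"{self.marker_type.upper()} markers)"
        )


def empty_marker_info(marker_ids) -> pd.DataFrame:
    """Marker-info frame with all mapping fields unset."""
    df = pd.DataFrame(index=pd.Index(marker_ids, name="marker_id"), columns=INFO_COLUMNS)
    df["n_best_hits"] = 0
    df["n_hit_positions"] = 0
    df["n_subgenomes_hit"] = 0
    df["subgenome"] = "Un"
    return df
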