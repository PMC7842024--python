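"""On-disk formats: DArT-style marker tables, hit tables, phenotypes,
VCF/BED export and JSON reports.

Marker CSV dialect (marker-major, as DArT exports are): one row per marker,
metadata columns first, then one column per accession::

    MarkerID,RefAllele,AltAllele,acc0001,acc0002,...
    m00001,A,G,A/A,G/A,...

SNP calls are unordered ``X/Y`` pairs over {A,C,G,T}; PAV calls are ``0``/``1``
(for PAV files the allele columns are omitted). Missing calls are written as
``-`` and parsed from ``-``, the Unicode minus sign, or an empty cell.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import (
    BASES,
    INFO_COLUMNS,
    MISSING,
    PAV,
    SNP,
    GenotypeMatrix,
    subgenome_of,
)

_MISSING_TOKENS = {"", "-", "−", "-/-", "−/−", "NA", "nan"}
_META_COLUMNS = ["MarkerID", "RefAllele", "AltAllele"]


# ---------------------------------------------------------------------------
# marker matrices
# ---------------------------------------------------------------------------

def _parse_snp_cell(cell: str) -> frozenset | None:
    """Unordered allele pair from an "X/Y" cell, or None for a missing call."""
    cell = cell.strip()
    if cell in _MISSING_TOKENS:
        return None
    parts = cell.split("/")
    if len(parts) == 1:  # single-base shorthand = homozygote
        parts = [parts[0], parts[0]]
    if len(parts) != 2:
        raise ValueError(f"malformed SNP call {cell!r}")
    alleles = frozenset(p.strip().upper() for p in parts)
    if alleles <= {"-", "−"}:
        return None
    if not alleles <= BASES:
        raise ValueError(f"non-ACGT allele in call {cell!r}")
    return alleles


def read_marker_csv(path, marker_type: str) -> GenotypeMatrix:
    """Read a marker CSV of the documented dialect into a GenotypeMatrix.

    SNP allele pairs are parsed order-insensitively and coded as ALT dosage
    against the file's RefAllele/AltAllele columns; when those columns are
    absent, REF defaults to the major allele (ties broken alphabetically).
    Markers showing more than two distinct alleles across the panel are
    flagged in ``validation_notes``, not silently dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "MarkerID" not in df.columns:
        raise ValueError(f"{path}: missing MarkerID column")
    marker_ids = df["MarkerID"].tolist()
    if len(set(marker_ids)) != len(marker_ids):
        dup = df["MarkerID"][df["MarkerID"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicated marker ids {dup[:5]}")
    accessions = [c for c in df.columns if c not in _META_COLUMNS]
    if not accessions:
        raise ValueError(f"{path}: no accession columns")

    notes: list[str] = []
    n_mark, n_acc = len(marker_ids), len(accessions)
    calls = np.full((n_acc, n_mark), MISSING, dtype=np.int8)

    if marker_type == PAV:
        bad_cells = []
        for j in range(n_mark):
            for i, acc in enumerate(accessions):
                cell = str(df.iloc[j][acc]).strip()
                if cell in _MISSING_TOKENS:
                    continue
                if cell in ("0", "1"):
                    calls[i, j] = int(cell)
                else:
                    bad_cells.append((marker_ids[j], acc, cell))
        if bad_cells:
            raise ValueError(f"{path}: malformed PAV cells {bad_cells[:10]}")
        return GenotypeMatrix(accessions, marker_ids, calls, PAV, validation_notes=notes)

    has_alleles = "RefAllele" in df.columns and "AltAllele" in df.columns
    ref = np.empty(n_mark, dtype="U1")
    alt = np.empty(n_mark, dtype="U1")
    bad_cells = []
    for j in range(n_mark):
        pairs = []
        for acc in accessions:
            try:
                pairs.append(_parse_snp_cell(str(df.iloc[j][acc])))
            except ValueError as exc:
                bad_cells.append((marker_ids[j], acc, str(exc)))
                pairs.append(None)
        observed = sorted(set().union(*[p for p in pairs if p] or [set()]))
        if has_alleles:
            r, a = df.iloc[j]["RefAllele"].strip().upper(), df.iloc[j]["AltAllele"].strip().upper()
        else:
            # REF = major allele; count allele copies (het contributes one each)
            counts = {b: 0 for b in observed}
            for p in pairs:
                if p is None:
                    continue
                for b in p:
                    counts[b] += 1 if len(p) == 2 else 2
            ranked = sorted(counts, key=lambda b: (-counts[b], b))
            r = ranked[0] if ranked else "A"
            a = ranked[1] if len(ranked) > 1 else next(b for b in "ACGT" if b != r)
        if not ({r, a} <= BASES) or r == a:
            raise ValueError(f"{path}: invalid REF/ALT ({r!r},{a!r}) for marker {marker_ids[j]}")
        extra = [b for b in observed if b not in (r, a)]
        if extra:
            notes.append(f"marker {marker_ids[j]}: >2 distinct alleles {observed}")
        ref[j], alt[j] = r, a
        for i, p in enumerate(pairs):
            if p is None:
                continue
            if not p <= {r, a}:
                notes.append(f"marker {marker_ids[j]}, accession {accessions[i]}: call outside REF/ALT, set missing")
                continue
            calls[i, j] = sum(2 if b == a and len(p) == 1 else (1 if b == a else 0) for b in p)
    if bad_cells:
        raise ValueError(f"{path}: malformed SNP cells {bad_cells[:10]}")
    return GenotypeMatrix(accessions, marker_ids, calls, SNP, ref, alt, validation_notes=notes)


def write_marker_csv(gm: GenotypeMatrix, path) -> None:
    cols = {"MarkerID": gm.marker_ids}
    if gm.marker_type == SNP:
        cols["RefAllele"] = gm.ref_alleles
        cols["AltAllele"] = gm.alt_alleles
    strings = gm.call_strings()
    for i, acc in enumerate(gm.accession_ids):
        cols[acc] = strings[i, :]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# hit tables and marker info
# ---------------------------------------------------------------------------

def read_hit_table(path) -> pd.DataFrame:
    """TSV of (marker_id, chromosome, position, score); positions 1-based."""
    hits = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    required = {"marker_id", "chromosome", "position", "score"}
    if not required <= set(hits.columns):
        raise ValueError(f"{path}: hit table needs columns {sorted(required)}")
    if (hits["position"] < 1).any():
        raise ValueError(f"{path}: hit positions must be >= 1")
    if not np.isfinite(hits["score"]).all():
        raise ValueError(f"{path}: non-finite hit scores")
    return hits


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def derive_marker_info(hits: pd.DataFrame, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker mapping summary from a hit table.

    For each marker: the maximum score, the number of hits tying that score
    (``n_best_hits``), the total number of hit positions, and the number of
    distinct subgenomes hit. A unique best-hit chromosome/position is assigned
    only when exactly one hit attains the maximum score — markers with tied
    best hits stay unplaced, mirroring the unique-mapping selection rule.
    Hits naming unknown markers are skipped with a warning.
    """
    known = set(genotypes.marker_ids)
    unknown = ~hits["marker_id"].isin(known)
    if unknown.any():
        warnings.warn(f"skipping {int(unknown.sum())} hits for unknown markers", stacklevel=2)
        hits = hits[~unknown]

    info = pd.DataFrame(index=pd.Index(genotypes.marker_ids, name="marker_id"), columns=INFO_COLUMNS)
    info["type"] = genotypes.marker_type
    if genotypes.marker_type == SNP:
        info["ref_allele"] = genotypes.ref_alleles
        info["alt_allele"] = genotypes.alt_alleles
    info["n_best_hits"] = 0
    info["n_hit_positions"] = 0
    info["n_subgenomes_hit"] = 0
    info["subgenome"] = "Un"

    for mid, grp in hits.groupby("marker_id", sort=False):
        mx = grp["score"].max()
        best = grp[grp["score"] == mx]
        info.at[mid, "max_score"] = float(mx)
        info.at[mid, "n_best_hits"] = len(best)
        info.at[mid, "n_hit_positions"] = len(grp)
        hit_subgenomes = set(grp["chromosome"].map(subgenome_of)) & {"A", "B", "D"}
        info.at[mid, "n_subgenomes_hit"] = len(hit_subgenomes)
        if len(best) == 1:
            info.at[mid, "chromosome"] = best.iloc[0]["chromosome"]
            info.at[mid, "position"] = int(best.iloc[0]["position"])
            info.at[mid, "subgenome"] = subgenome_of(best.iloc[0]["chromosome"])
    info["position"] = info["position"].astype("Int64")
    info["n_best_hits"] = info["n_best_hits"].astype(int)
    info["n_hit_positions"] = info["n_hit_positions"].astype(int)
    info["n_subgenomes_hit"] = info["n_subgenomes_hit"].astype(int)
    return info


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="accession")
    if "year" in df.columns:
        df["year"] = df["year"].astype("Int64")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="accession")


# ---------------------------------------------------------------------------
# VCF / BED / reports
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, info: pd.DataFrame, path) -> int:
    """Minimal VCF 4.2 export (GT only) of uniquely mapped SNP markers.

    Returns the number of records written. PAV datasets are refused: a
    dominant 0/1 presence call has no REF/ALT representation.
    """
    if genotypes.marker_type != SNP:
        raise ValueError("VCF export requires SNP markers (PAV calls are dominant 0/1)")
    mapped = info.loc[
        [m for m in genotypes.marker_ids if m in info.index]
    ]
    mapped = mapped[(mapped["n_best_hits"] == 1) & mapped["position"].notna()]
    order = mapped.sort_values(["chromosome", "position"]).index

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, grp in mapped.groupby("chromosome"):
        header.contigs.add(str(chrom), length=int(grp["position"].max()) + 1)
    for acc in genotypes.accession_ids:
        header.add_sample(acc)

    col = {m: j for j, m in enumerate(genotypes.marker_ids)}
    n_written = 0
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for mid in order:
            j = col[mid]
            rec = vcf.new_record(
                contig=str(mapped.at[mid, "chromosome"]),
                start=int(mapped.at[mid, "position"]) - 1,  # pysam start is 0-based
                alleles=(str(genotypes.ref_alleles[j]), str(genotypes.alt_alleles[j])),
                id=mid,
            )
            for i, acc in enumerate(genotypes.accession_ids):
                c = genotypes.calls[i, j]
                rec.samples[acc]["GT"] = None if c == MISSING else ((0, 0), (0, 1), (1, 1))[c]
            vcf.write(rec)
            n_written += 1
    return n_written


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED export: input 1-based inclusive (chromosome, start, end[, name]),
    written as 0-based half-open intervals."""
    out = intervals.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    cols = ["chromosome", "start", "end"] + (["name"] if "name" in out.columns else [])
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def marker_bed_intervals(info: pd.DataFrame, trimmed_length: int = 0) -> pd.DataFrame:
    """1-based inclusive intervals for uniquely mapped markers: [p, p] plus an
    optional trimmed-sequence extension."""
    mapped = info[(info["n_best_hits"] == 1) & info["position"].notna()]
    return pd.DataFrame(
        {
            "chromosome": mapped["chromosome"].to_numpy(),
            "start": mapped["position"].astype(int).to_numpy(),
            "end": mapped["position"].astype(int).to_numpy() + max(0, trimmed_length),
            "name": mapped.index.to_numpy(),
        }
    )


def write_report(results: dict, path) -> None:
    """JSON report writer; numpy scalars are coerced so the file round-trips."""

    def coerce(obj):
        if isinstance(obj, dict):
            return {str(k): coerce(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [coerce(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return coerce(obj.tolist())
        if isinstance(obj, float) and np.isnan(obj):
            return None
        return obj

    with open(path, "w") as fh:
        json.dump(coerce(results), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
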