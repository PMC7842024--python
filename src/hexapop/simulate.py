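"""Synthetic allohexaploid GBS panels with planted truth.

The generator emulates the statistical fingerprints of a GBS-genotyped
hexaploid (AABBDD) crop panel without any sequence-level simulation:

* subpopulation structure via a Balding–Nichols model — each subpopulation's
  allele frequency is a Beta draw around the ancestral frequency with
  dispersion set by ``fst``;
* distance-decaying linkage disequilibrium via Markovian haplotype copying
  along each chromosome — a latent uniform is carried from marker to marker
  and resampled with probability ``1 - exp(-d / ld_decay_bp)``, so that two
  markers at distance d share the latent (and hence correlate) with
  probability ``exp(-d / ld_decay_bp)``;
* a marker deficit on subgenome D (configurable per-subgenome marker counts);
* pseudo-heterozygous ("hemizygous") markers concentrated on subgenome D —
  fixed alternative alleles at homoeologous loci masquerade as heterozygotes,
  modelled phenomenologically by overwriting calls as heterozygous with
  probability ``het_call_prob``;
* residual true heterozygosity controlled by an inbreeding parameter (a
  selfing crop keeps marker heterozygosity mostly below 0.1);
* dominant presence/absence (PAV) markers derived from SNP markers by
  dominant recoding (present = at least one copy of the tracked variant);
* registration-year and yield phenotypes with planted per-marker effects.

All randomness flows from the single ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` child streams, so identical configurations
reproduce outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, PAV, SNP, GenotypeMatrix, subgenome_of

_BASES = np.array(list("ACGT"))


@dataclass
class SubgenomeSpec:
    """Marker layout for one subgenome: chromosomes of equal length, each
    carrying ``n_markers`` markers at uniform random positions."""

    n_chromosomes: int
    chromosome_length: float
    n_markers: int


@dataclass
class YieldParams:
    mean: float = 100.0
    sd: float = 5.0
    cluster_offset_sd: float = 4.0
    missing_rate: float = 0.3


@dataclass
class SimConfig:
    """Full description of one synthetic panel.

    Defaults describe a mid-sized winter-cereal breeding panel: 300
    accessions in 3 subpopulations at moderate divergence, three chromosomes
    per subgenome at wheat-like lengths, ~5 Mb LD decay, a subgenome-D
    marker deficit, hemizygous markers confined to subgenome D, high
    inbreeding (selfing crop) and sparse missing data.
    """

    n_accessions: int = 300
    n_subpops: int = 3
    fst: float = 0.1
    subgenome_sizes: dict = field(
        default_factory=lambda: {
            "A": SubgenomeSpec(3, 6.0e8, 250),
            "B": SubgenomeSpec(3, 7.0e8, 300),
            "D": SubgenomeSpec(3, 6.0e8, 120),
        }
    )
    ld_decay_bp: float = 5.0e6
    hemizygous_fraction: float = 0.2
    het_call_prob: float = 0.9
    missing_rate: float = 0.03
    pav_fraction: float = 0.3
    inbreeding: float = 0.9
    phenotype_effects: list = field(default_factory=list)  # [(marker_id, effect), ...]
    base_year: float = 2005.0
    year_noise_sd: float = 4.0
    year_range: tuple = (1960, 2025)
    year_missing_rate: float = 0.0
    yield_params: YieldParams = field(default_factory=YieldParams)
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "fst": self.fst,
            "hemizygous_fraction": self.hemizygous_fraction,
            "het_call_prob": self.het_call_prob,
            "missing_rate": self.missing_rate,
            "pav_fraction": self.pav_fraction,
            "inbreeding": self.inbreeding,
            "year_missing_rate": self.year_missing_rate,
            "yield_missing_rate": self.yield_params.missing_rate,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fst >= 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if self.n_accessions < 2:
            raise ValueError("need at least 2 accessions")
        if self.n_subpops < 1 or self.n_subpops > self.n_accessions:
            raise ValueError("n_subpops must lie in [1, n_accessions]")
        if not self.subgenome_sizes:
            raise ValueError("subgenome_sizes is empty")
        for sg, spec in self.subgenome_sizes.items():
            if spec.n_chromosomes < 1:
                raise ValueError(f"subgenome {sg}: n_chromosomes < 1")
            if spec.chromosome_length <= 0:
                raise ValueError(f"subgenome {sg}: chromosome_length must be > 0")
            if spec.n_markers < 2:
                raise ValueError(f"subgenome {sg}: need >= 2 markers per chromosome")
        if self.hemizygous_fraction > 0 and "D" not in self.subgenome_sizes:
            raise ValueError("hemizygous_fraction > 0 but the panel has no subgenome-D markers")
        if self.ld_decay_bp < 0:
            raise ValueError("ld_decay_bp must be >= 0")


@dataclass
class TruthRecord:
    """Planted ground truth accompanying a simulated panel."""

    subpop_labels: pd.Series  # accession -> subpopulation index
    ancestral_freqs: pd.Series  # marker -> ancestral tracked-variant frequency
    subpop_freqs: pd.DataFrame  # marker x subpopulation frequencies
    hemizygous_ids: list
    ld_decay_bp: float
    effect_marker_ids: list
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "subpop_labels": self.subpop_labels.to_dict(),
            "ancestral_freqs": self.ancestral_freqs.to_dict(),
            "subpop_freqs": {m: list(map(float, row)) for m, row in self.subpop_freqs.iterrows()},
            "hemizygous_ids": list(self.hemizygous_ids),
            "ld_decay_bp": float(self.ld_decay_bp),
            "effect_marker_ids": list(self.effect_marker_ids),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        sp = pd.DataFrame.from_dict(d["subpop_freqs"], orient="index")
        return cls(
            subpop_labels=pd.Series(d["subpop_labels"]),
            ancestral_freqs=pd.Series(d["ancestral_freqs"]),
            subpop_freqs=sp,
            hemizygous_ids=d["hemizygous_ids"],
            ld_decay_bp=d["ld_decay_bp"],
            effect_marker_ids=d["effect_marker_ids"],
            seed=d["seed"],
        )


@dataclass
class SimPanel:
    """Everything one simulation produces."""

    snp: GenotypeMatrix
    pav: GenotypeMatrix | None
    marker_info: pd.DataFrame  # true chromosome/position/alleles per marker
    truth: TruthRecord
    hits: pd.DataFrame | None = None
    phenotypes: pd.DataFrame | None = None


def _streams(seed: int) -> dict:
    names = ["layout", "freqs", "haplo", "assign", "hemi", "pav", "missing", "hits", "pheno"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _marker_layout(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Chromosome labels and sorted unique positions for every marker."""
    rows = []
    counter = 0
    for sg in sorted(config.subgenome_sizes):
        spec = config.subgenome_sizes[sg]
        for c in range(1, spec.n_chromosomes + 1):
            chrom = f"{c}{sg}"
            length = int(spec.chromosome_length)
            pos = np.unique(rng.integers(1, length + 1, size=spec.n_markers))
            while len(pos) < spec.n_markers:  # top up collisions (rare at bp scale)
                extra = rng.integers(1, length + 1, size=spec.n_markers - len(pos))
                pos = np.unique(np.concatenate([pos, extra]))
            pos = np.sort(pos)
            for p in pos:
                rows.append((f"m{counter:05d}", chrom, int(p), sg))
                counter += 1
    df = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position", "subgenome"])
    return df.set_index("marker_id")


def simulate_genotypes(config: SimConfig) -> SimPanel:
    """Draw a genotype panel under ``config``; see the module docstring for
    the generative model. Returns a :class:`SimPanel` whose ``hits`` and
    ``phenotypes`` slots are unset (use :func:`simulate_panel` for both)."""
    config.validate()
    rngs = _streams(config.seed)

    layout = _marker_layout(config, rngs["layout"])
    marker_ids = list(layout.index)
    n_markers = len(marker_ids)
    n = config.n_accessions
    K = config.n_subpops

    accession_ids = [f"acc{i:04d}" for i in range(n)]
    base = np.repeat(np.arange(K), int(np.ceil(n / K)))[:n]
    subpop = rngs["assign"].permutation(base)

    # Balding–Nichols: subpopulation frequencies around the ancestral frequency
    p_anc = rngs["freqs"].uniform(0.1, 0.9, size=n_markers)
    if config.fst > 0:
        disp = (1.0 - config.fst) / config.fst
        p_sub = rngs["freqs"].beta(
            np.outer(p_anc, np.full(K, disp)).T, np.outer(1.0 - p_anc, np.full(K, disp)).T
        )  # (K, n_markers)
        p_sub = np.clip(p_sub, 1e-4, 1.0 - 1e-4)
    else:
        p_sub = np.tile(p_anc, (K, 1))

    # alleles: REF / ALT letters per marker, ALT = tracked variant
    base_idx = rngs["freqs"].integers(0, 4, size=n_markers)
    shift = rngs["freqs"].integers(1, 4, size=n_markers)
    ref_alleles = _BASES[base_idx]
    alt_alleles = _BASES[(base_idx + shift) % 4]

    # haplotypes per subpopulation, chromosome by chromosome
    dosage = np.zeros((n, n_markers), dtype=np.int8)
    col_of = {m: i for i, m in enumerate(marker_ids)}
    chrom_groups = layout.groupby("chromosome", sort=False)
    rng_h = rngs["haplo"]
    for k in range(K):
        rows = np.nonzero(subpop == k)[0]
        nk = len(rows)
        if nk == 0:
            continue
        inbred = rng_h.random((nk, len(chrom_groups))) < config.inbreeding
        for ci, (chrom, grp) in enumerate(chrom_groups):
            cols = np.array([col_of[m] for m in grp.index])
            pos = grp["position"].to_numpy(dtype=float)
            pk = p_sub[k, cols]
            m = len(cols)
            hap = np.empty((nk, 2, m), dtype=np.int8)
            u = rng_h.random((nk, 2))
            hap[:, :, 0] = (u < pk[0]).astype(np.int8)
            for j in range(1, m):
                d = pos[j] - pos[j - 1]
                if config.ld_decay_bp > 0:
                    s = 1.0 - np.exp(-d / config.ld_decay_bp)
                else:
                    s = 1.0
                switch = rng_h.random((nk, 2)) < s
                fresh = rng_h.random((nk, 2))
                u = np.where(switch, fresh, u)
                hap[:, :, j] = (u < pk[j]).astype(np.int8)
            d2 = np.where(inbred[:, ci][:, None], hap[:, 0, :], hap[:, 1, :])
            dosage[np.ix_(rows, cols)] = hap[:, 0, :] + d2

    # split off PAV markers before hemizygosity (hemizygosity is an SNP artefact)
    n_pav = int(round(config.pav_fraction * n_markers))
    pav_idx = np.sort(rngs["pav"].choice(n_markers, size=n_pav, replace=False))
    pav_set = set(pav_idx.tolist())
    snp_idx = np.array([i for i in range(n_markers) if i not in pav_set], dtype=int)

    # hemizygous markers: subgenome-D SNP markers forced heterozygous
    d_snp = [i for i in snp_idx if layout["subgenome"].iloc[i] == "D"]
    n_hemi = int(round(config.hemizygous_fraction * len(d_snp)))
    if config.hemizygous_fraction > 0 and not d_snp:
        raise ValueError("hemizygous_fraction > 0 but no subgenome-D SNP markers emitted")
    hemi_idx = np.sort(rngs["hemi"].choice(d_snp, size=n_hemi, replace=False)) if n_hemi else np.array([], dtype=int)
    if n_hemi:
        force = rngs["hemi"].random((n, n_hemi)) < config.het_call_prob
        sub = dosage[:, hemi_idx]
        sub[force] = 1
        dosage[:, hemi_idx] = sub

    # dominant recoding for PAV markers: present = >=1 copy of the tracked variant
    pav_calls = (dosage[:, pav_idx] >= 1).astype(np.int8)

    snp_calls = dosage[:, snp_idx].copy()

    # missing-call injection, per dataset
    if config.missing_rate > 0:
        rng_m = rngs["missing"]
        snp_calls[rng_m.random(snp_calls.shape) < config.missing_rate] = MISSING
        pav_calls[rng_m.random(pav_calls.shape) < config.missing_rate] = MISSING

    snp_ids = [marker_ids[i] for i in snp_idx]
    pav_ids = [marker_ids[i] for i in pav_idx]

    snp = GenotypeMatrix(
        accession_ids=accession_ids,
        marker_ids=snp_ids,
        calls=snp_calls,
        marker_type=SNP,
        ref_alleles=ref_alleles[snp_idx],
        alt_alleles=alt_alleles[snp_idx],
    )
    pav = (
        GenotypeMatrix(
            accession_ids=accession_ids,
            marker_ids=pav_ids,
            calls=pav_calls,
            marker_type=PAV,
        )
        if n_pav
        else None
    )

    info = layout.copy()
    info["type"] = SNP
    info.loc[[marker_ids[i] for i in pav_idx], "type"] = PAV
    info["ref_allele"] = ref_alleles
    info["alt_allele"] = alt_alleles

    truth = TruthRecord(
        subpop_labels=pd.Series(subpop, index=accession_ids, name="subpop"),
        ancestral_freqs=pd.Series(p_anc, index=marker_ids, name="p_anc"),
        subpop_freqs=pd.DataFrame(p_sub.T, index=marker_ids, columns=[f"pop{k}" for k in range(K)]),
        hemizygous_ids=[marker_ids[i] for i in hemi_idx],
        ld_decay_bp=config.ld_decay_bp,
        effect_marker_ids=[m for m, _ in config.phenotype_effects],
        seed=config.seed,
    )
    return SimPanel(snp=snp, pav=pav, marker_info=info, truth=truth)


def simulate_hit_table(
    marker_info: pd.DataFrame,
    truth: TruthRecord,
    multi_hit_rate: float = 0.3,
    tie_rate: float = 0.05,
    hemi_alt_subgenome_prob: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emulated BLAST-style hit table for a simulated panel.

    Every marker receives one best hit at its true location; a
    ``multi_hit_rate`` fraction receive extra lower-scoring hits, a
    ``tie_rate`` fraction receive a second hit tying the best score (these
    markers are no longer uniquely mapped), and hemizygous markers receive,
    with high probability, an extra hit on a homoeologous chromosome of a
    different subgenome — mimicking markers whose sequence matches more than
    one subgenome.
    """
    if len(marker_info) == 0:
        raise ValueError("marker_info is empty")
    for name, v in (("multi_hit_rate", multi_hit_rate), ("tie_rate", tie_rate),
                    ("hemi_alt_subgenome_prob", hemi_alt_subgenome_prob)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)

    chroms = sorted(marker_info["chromosome"].unique())
    chrom_max = marker_info.groupby("chromosome")["position"].max().to_dict()
    hemi = set(truth.hemizygous_ids)

    rows = []
    for mid, rec in marker_info.iterrows():
        best = float(np.round(rng.uniform(95.0, 100.0), 2))
        rows.append((mid, rec["chromosome"], int(rec["position"]), best))
        if rng.random() < tie_rate:
            other = chroms[rng.integers(0, len(chroms))]
            rows.append((mid, other, int(rng.integers(1, chrom_max[other] + 1)), best))
        if rng.random() < multi_hit_rate:
            for _ in range(int(rng.integers(1, 3))):
                other = chroms[rng.integers(0, len(chroms))]
                rows.append(
                    (mid, other, int(rng.integers(1, chrom_max[other] + 1)),
                     float(np.round(best - rng.uniform(1.0, 10.0), 2)))
                )
        if mid in hemi and rng.random() < hemi_alt_subgenome_prob:
            sg = subgenome_of(rec["chromosome"])
            foreign = [c for c in chroms if subgenome_of(c) not in (sg, "Un")]
            if foreign:
                other = foreign[rng.integers(0, len(foreign))]
                rows.append(
                    (mid, other, int(rng.integers(1, chrom_max[other] + 1)),
                     float(np.round(best - rng.uniform(0.5, 5.0), 2)))
                )
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position", "score"])


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Registration year and two yield columns (practice levels A1/A2).

    ``year = base + sum(effect * dosage) + N(0, sd)``, rounded and clipped to
    ``config.year_range``. Yields share a per-subpopulation offset and differ
    only in noise; accessions missing from yield trials lack both columns.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 2)
    n = genotypes.n_accessions
    pos = {m: j for j, m in enumerate(genotypes.marker_ids)}
    year = np.full(n, config.base_year, dtype=float)
    for mid, eff in config.phenotype_effects:
        if mid not in pos:
            raise ValueError(f"phenotype effect on unknown marker id {mid!r}")
        col = genotypes.calls[:, pos[mid]].astype(float)
        miss = col == MISSING
        if miss.any():
            col[miss] = col[~miss].mean() if (~miss).any() else 0.0
        year += eff * col
    year += rng.normal(0.0, config.year_noise_sd, size=n)
    lo, hi = config.year_range
    year = np.clip(np.round(year), lo, hi)

    yp = config.yield_params
    offsets = rng.normal(0.0, yp.cluster_offset_sd, size=int(truth.subpop_labels.max()) + 1)
    labels = truth.subpop_labels.reindex(genotypes.accession_ids).to_numpy()
    y1 = yp.mean + offsets[labels] + rng.normal(0.0, yp.sd, size=n)
    y2 = yp.mean + offsets[labels] + rng.normal(0.0, yp.sd, size=n)

    df = pd.DataFrame(
        {"year": year.astype(int), "yield_A1": y1, "yield_A2": y2},
        index=pd.Index(genotypes.accession_ids, name="accession"),
    )
    if config.year_missing_rate > 0:
        df.loc[rng.random(n) < config.year_missing_rate, "year"] = np.nan
    if yp.missing_rate > 0:
        no_trial = rng.random(n) < yp.missing_rate
        df.loc[no_trial, ["yield_A1", "yield_A2"]] = np.nan
    df["year"] = df["year"].astype("Int64")
    return df


def simulate_panel(
    config: SimConfig,
    multi_hit_rate: float = 0.3,
    tie_rate: float = 0.05,
) -> SimPanel:
    """Genotypes + hit table + phenotypes in one call (the usual entry point)."""
    panel = simulate_genotypes(config)
    rngs = _streams(config.seed)
    panel.hits = simulate_hit_table(
        panel.marker_info, panel.truth, multi_hit_rate=multi_hit_rate,
        tie_rate=tie_rate, rng=rngs["hits"],
    )
    panel.phenotypes = simulate_phenotypes(panel.snp, panel.truth, config, rng=rngs["pheno"])
    return panel
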